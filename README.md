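# kascape

Exhaustive relative binding-energy landscapes for DNA-binding proteins from
randomized-library sequencing.

## The problem

A transcription factor's specificity is not one consensus site but a whole
landscape: every possible binding sequence has an affinity, including the
low-affinity sites that matter in vivo. One way to measure that landscape
exhaustively is to incubate the protein with a double-stranded DNA pool whose
central `n` bases (n = 4–7) are fully randomized between fixed flanks, pull
down the protein-bound molecules, and sequence both the input pool and the
bound pool. Enrichment of a sequence in the bound pool relative to the input
pool measures its binding free energy, for all `4^n` sequences at once —
with no mononucleotide-independence assumption.

`kascape` implements the complete computational side of such an assay:

- **Read processing** — locate the fixed flanks in each mate, extract the
  random core, and discard pairs whose read-1 and read-2 cores are not
  reverse complements; tally counts `R_Si` (input) and `B_Si` (bound) over
  the full `4^n` space with a per-reason QC report.
- **Energetics** — pool proportions `P(S_i) = R_Si / Σ R_Sj`,
  `P(S_i|bound) = B_Si / Σ B_Sj`, and the relative binding energy

  ```
  ΔΔG(S_i) = −log2( P(S_i | bound) / P(S_i) )      [log2 units]
  ```

  Lower is stronger; the landscape is defined up to an additive constant set
  by pool composition. Also: high-affinity selection (ΔΔG < cutoff),
  landscape correlations (replicates, proteins), (K+1)-mer → K-mer
  marginalization, the EMSA comparison statistic `−log2(bound/unbound)`,
  and log2 ↔ kcal/mol conversion (one log2 unit = RT·ln2 ≈ 0.411 kcal/mol).
- **K-mer graph** — a recursive-quadrant bijection of all length-k words
  onto a `2^k × 2^k` grid (words sharing a prefix fill one contiguous
  square block), with 3-D bar and heatmap rendering, core-sequence
  highlighting, and bit-exact sidecar TSVs.
- **Motif summary** — PWM and information-content sequence logo of the
  high-affinity set, with poorly informative flanking columns trimmed.
- **Simulation** — ground-truth energy models (planted-motif or a
  0.5–5 kcal/mol random landscape), a Boltzmann-reweighting generative model
  of the bound pool, synthetic paired FASTQ with configurable error and
  pair-corruption rates, hypergeometric downsampling, and accuracy-vs-depth
  curves for sequencing-depth planning.

## Worked example

Simulate an assay for a WRKY-like protein (core motif `GAC`, graded
preference C < T < G < A at the following position) and analyze it end to
end:

```python
import numpy as np
from kascape import (LibraryDesign, make_truth, sample_assay, synth_fastq,
                     count_fastq_pool, relative_binding_energy,
                     select_high_affinity, build_pwm, trim_logo,
                     compare_landscapes)

design = LibraryDesign(left_flank="TTGGA", right_flank="CCAAT", n=4)
truth = make_truth(design, core="GAC", seed=0)
inp_t, bnd_t = sample_assay(truth, 100_000, 100_000, seed=0)
synth_fastq(inp_t, design, "input_R1.fastq", "input_R2.fastq", seed=1)
synth_fastq(bnd_t, design, "bound_R1.fastq", "bound_R2.fastq", seed=2)

inp = count_fastq_pool("input_R1.fastq", "input_R2.fastq", design, "input")
bnd = count_fastq_pool("bound_R1.fastq", "bound_R2.fastq", design, "bound")
land = relative_binding_energy(inp, bnd)
print("ddG(GACC) = %.3f" % land["GACC"])
print("ddG(AAAA) = %.3f" % land["AAAA"])
sel = select_high_affinity(land, cutoff=-1.0)
print("high-affinity set:", sorted(sel))
pwm = trim_logo(build_pwm(sel), min_info=0.2)
print("consensus:", pwm.consensus())
print("info (bits):", np.round(pwm.info, 3))
print("r(est, truth) =", round(compare_landscapes(land.as_series(), truth.as_series()), 3))
```

Output:

```
ddG(GACC) = -2.929
ddG(AAAA) = 0.042
high-affinity set: ['GACC', 'GACG', 'GACT']
consensus: GACC
info (bits): [2.    2.    2.    0.415]
r(est, truth) = 0.932
```

`GACC` is strongly enriched in the bound pool (ΔΔG ≈ −2.9, planted −3),
a background sequence sits near 0, the ΔΔG < −1 set is the graded
`GAC(C/T/G)` family, and the PWM's fourth column carries 0.4 bits with a
C/T preference. The estimated landscape correlates with the planted truth
at r ≈ 0.93 at this depth (background sequences all have equal true energy,
so their sampling noise bounds r; on a truth spanning 0.5–5 kcal/mol, r
exceeds 0.99 at 10^6 read pairs).

The same workflow is available from a shell via the `kascape` CLI
(`extract`, `energy`, `marginalize`, `logo`, `render`, `simulate`, `depth`,
`downsample`, `compare`, `query`, `run`); `kascape run config.yaml
--outdir out/` executes the whole pipeline from a flat YAML config and
writes count tables, the landscape TSV, PWM, figures with sidecar TSVs,
QC reports and a JSON run manifest.

## Layout

```
src/kascape/
  sequence_space.py   spaces, reverse complement, core search, K-mer graph layout
  read_processing.py  FASTQ pairs -> count tables + QC
  energetics.py       proportions, ddG, selection, comparison, marginalization
  motif_logo.py       PWM, information content, trimming, logo rendering
  simulation.py       truth models, assay sampling, synthetic FASTQ, depth curves
  viz.py              K-mer graph rendering with sidecar TSVs
  pipeline.py         end-to-end run with manifest
  cli.py              click-based command line
docs/methods.md       model, assumptions, parameter choices, limitations
```
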