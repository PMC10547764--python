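# Methods

## The measurement model

The assay sequences two pools built from the same randomized-core dsDNA
library: the input pool (the library as synthesized) and the bound pool
(molecules recovered in complex with the protein). For each of the `4^n`
core sequence types `S_i`, read counts `R_Si` (input) and `B_Si` (bound)
give proportions

    P(S_i)        = R_Si / Σ_j R_Sj
    P(S_i|bound)  = B_Si / Σ_j B_Sj

and the relative binding energy

    ΔΔG(S_i) = −log2( P(S_i|bound) / P(S_i) ).

This is an enrichment statistic on a log scale, stored in dimensionless
log2 units; under equilibrium binding at fixed free-protein concentration
it differs from a true binding free energy by an additive constant common
to all sequences (the pool-composition normalizer), so only differences of
ΔΔG between sequences are meaningful. `log2_to_kcal`/`kcal_to_log2` convert
at RT·ln2 ≈ 0.411 kcal/mol per log2 unit (RT = 0.593 kcal/mol at 298 K).
No absolute Kd or ΔG is ever estimated.

Assumptions: binding has reached equilibrium, pull-down and amplification
do not distort sequence composition beyond what the input pool measurement
captures, and a read pair represents one library molecule.

## Read processing

Each construct is `left_flank + core + right_flank`; mates are reverse
complements across the insert. The core is located by exact substring
match: the first occurrence of the left flank, then the first occurrence of
the right flank after it. Read 2 is matched against the mirrored design
(flanks reverse-complemented and swapped). A pair is kept only when both
extractions succeed, the region has length exactly `n` with no ambiguity
codes, and the read-2 core equals the reverse complement of the read-1
core. Everything else is tallied per reason (`flank_not_found`,
`wrong_region_length`, `ambiguous_base`, `not_reverse_complement`), so
kept + discarded = processed on every input.

Choices made where the procedure was genuinely open:

- **Flank matching is exact by default.** A Hamming-tolerant option
  (`max_mismatch`) exists but is off: tolerant matching trades a few
  percent yield for a risk of misplacing the core.
- **Reads with N in the core are discarded** (`ambiguous_base`) rather
  than distributed fractionally — the conservative choice.
- **Types are counted in read-1 orientation** and not collapsed with their
  reverse complements; `collapse_rc=True` is available for double-strand
  summaries but changes the meaning of the space.
- **Quality scores are parsed but unused.** No quality filter is applied;
  the pair-consistency filter already removes most sequencing errors in
  the core (an error must hit both mates complementarily to survive).

## Zero counts and pseudocounts

With the default `pseudocount=0`, any sequence absent from either pool has
an undefined ΔΔG, reported as NaN in memory and `NA` in TSVs — the default
output never fabricates an energy for an unobserved sequence. An opt-in
pseudocount (1 is the suggested value, used by the depth-curve estimator)
adds the same offset to every count in a pool before normalizing, keeping
shallow samples defined at the cost of shrinking extreme energies toward 0.

## High-affinity selection and the PWM logo

`select_high_affinity` takes the strict set {S : ΔΔG(S) < cutoff}, default
cutoff −1 (a two-fold enrichment over the input pool). The PWM gives each
selected sequence equal weight by default — the selected set is treated as
a plain sequence set; bound-count weighting is available as an option.
Column information content is `2 + Σ_b p_b log2 p_b` bits against the
uniform 0.25 background (the randomized library is near-uniform by design;
its mild synthesis bias is already divided out by the ΔΔG ratio).
`trim_logo` drops poorly informative columns only from the two ends of the
logo (keeping the block from the first to the last column with
info ≥ `min_info`, default 0.2 bits); an interior dip is retained because
splitting a motif at a degenerate internal position would misrepresent it.
The untrimmed matrix is always kept alongside, with dropped indices
recorded.

## The K-mer graph

Every length-k word maps to a cell of a `2^k × 2^k` grid by a recursive
quadrant rule (a chaos-game arrangement): each base carries a
(row-bit, col-bit) pair — default A=(0,0), C=(0,1), G=(1,0), T=(1,1) — and
the word's bits, most significant base first, spell the binary row and
column. The map is a bijection, and all words sharing a length-p prefix
fill one contiguous `2^(k−p)`-square block, which is what makes related
binders cluster visually. The base→quadrant assignment and the
row-0-at-top orientation are explicit rendering conventions (configurable,
recorded in the sidecar TSV) rather than properties of the data; the
sidecar TSV (sequence, row, col, value, highlighted) is the bit-exact
record and figures are derived views. The "minus relative binding energy"
display negates ΔΔG so that taller bars mean stronger binding. No De Bruijn
machinery is involved; the graph is a display arrangement only.

## Marginalization across core lengths

To compare assays run at different `n`, the (K+1)-mer count tables are
reduced to K-mers by window sums: each (K+1)-mer adds its full count to
both its prefix and suffix K-mer (so marginal totals are exactly twice the
originals), per pool, before the energy formula is applied. Summing counts
rather than averaging energies propagates sampling weight correctly
(deep sequences dominate the windows they support); energy-averaging and
single-window (`windows="prefix"`/`"suffix"`) variants are exposed for
comparison. Exact marginal consistency — marginal ΔΔG equal to the K-mer
truth up to one additive constant — holds when the (K+1)-mer energies are
position-additive (then both windows contribute proportionally), and for
prefix-only energy models under prefix-window marginalization; for general
energy models the marginal map is a weighted summary, not an identity, and
the tests check the exact constructions.

## The synthetic-assay generator

The generator is first-class, tested code and defines the study conditions
for every simulation result in the package.

- **Input pool**: per-position independent base usage with the synthesis
  bias order T > A > C > G (defaults 0.30/0.27/0.23/0.20; the ordering is
  the documented feature, the numbers are this package's choice of a
  realistic mild bias). Input counts are multinomial draws from these
  probabilities.
- **Bound pool**: equilibrium Boltzmann reweighting,
  `b_i ∝ q_i · 2^(−ΔΔG_i)`, then a multinomial draw. Applied to exact
  proportions, the estimator recovers the truth up to the additive
  constant `log2 Σ_j q_j 2^(−ΔΔG_j)` — the closed form the consistency
  tests use. Washing, bead capture and PCR bias are not modeled; washing
  1–3 times was found not to change results experimentally, and the
  equilibrium reweighting is the documented generative model.
- **Truth models**: `make_truth` plants a core motif (default `GAC`,
  strong energy −3 log2 units, following-base grades C 0 < T 0.5 < G 1.5
  < A 2.5, terminal occurrences +2.2) on a 0 background with optional
  Gaussian noise. The grades put GACC/GACT/GACG below the −1 logo cutoff
  and GACA just above it, so the planted C/T preference at the post-core
  position is visible in the recovered logo. `random_truth` draws energies
  uniformly over an assumed 0.5–5 kcal/mol range (≈1.2–12.2 log2 units),
  the standard setting for depth-requirement analysis.
- **Reads**: `synth_fastq` writes `left_flank+core+right_flank` and its
  exact reverse complement with constant quality, per-base substitution
  errors at `error_rate`, and exactly `round(corrupt_pair_rate·N)` pairs
  (chosen without replacement) given one deliberate core substitution in
  read 2 to exercise the pair filter. Output is byte-identical for a fixed
  seed.
- **Downsampling** is multivariate-hypergeometric (without replacement),
  matching what random subsampling of a finite read set does.

What the generator does **not** emulate: position-dependent or correlated
sequencing error, quality-score structure, PCR duplicates and jackpotting,
flanking-sequence binding effects, and protein-concentration effects on
the additive constant. Passing tests therefore demonstrate correctness of
the analysis under the stated generative model, not robustness to every
artifact of real libraries.

## Depth curves and problem sizes

`depth_curve` draws `replicates` independent assays at each depth
(input reads = bound reads = d), estimates the landscape with pseudocount
1, and scores it against the truth with an offset-invariant metric —
Pearson r by default (Spearman and strongest-decile rank overlap
selectable, since "accuracy" admits several readings). On the n=4,
0.5–5 kcal/mol truth the mean r rises from ≈0.8 at 10^3 read pairs to
>0.998 at 10^6, consistent with a six-figure read requirement for a
near-exact n=4 landscape; at PE150 (300 bases per pair) 100,000 pairs
correspond to 30 M sequenced bases. The shipped tests and the acceptance
script use n=4 spaces, 10^3–10^6 sampled read pairs, 5 replicates, and
60,000-pair read-level pipelines — sizes chosen so the full suite
exercises every path at meaningful depth while remaining quick to run.

## Numerical and interface conventions

Sequence indices are lexicographic with A < C < G < T; all per-sequence
arrays align with that order, and TSVs are written in it with headers and
6-decimal floats (`NA` for undefined). Correlations require at least 3
shared defined sequences. Degenerate truths (zero energy variance) yield
NaN accuracy, flagged rather than silently dropped. All sampling goes
through a seeded `numpy.random.Generator`; every CLI entry point accepts
`--seed`, and rerunning any step with the same inputs and seed reproduces
its TSV outputs byte for byte. The interactive 3-D viewer is replaced by
batch rendering plus a `query` subcommand (sequence → values), which
preserves the viewer's click-to-inspect function without a GUI dependency.

## Known limitations

- ΔΔG values are relative within one assay; comparing absolute levels
  across assays (or to EMSA's `−log2(bound/unbound)`) is meaningful only
  up to an additive constant, which is why comparisons are made by
  correlation.
- The marginalization identity is exact only for the constructed model
  classes above; real landscapes marginalize approximately.
- For n > 7 the exhaustive representation still works (hard cap n = 12)
  but read depth per type, not the code, becomes the binding constraint.
- The logo is a summary of a thresholded set; it discards the landscape's
  information about graded and low-affinity binding by construction.
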