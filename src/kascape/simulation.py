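"""Synthetic assays: ground-truth energy models, multinomial read sampling,
paired-FASTQ generation, downsampling, and accuracy-versus-depth curves.

The generative model is an equilibrium Boltzmann-type reweighting of the
input pool: if sequence i has input probability q_i and true relative
binding energy ddG_i (log2 units, lower = stronger), the bound pool draws
reads with probability

    b_i = q_i * 2**(-ddG_i) / sum_j q_j * 2**(-ddG_j)

so an estimator applied to exact proportions recovers the truth up to the
additive constant log2(sum_j q_j 2**(-ddG_j)).  Input-pool composition
follows the synthesis bias of the real library: per-position base usage
T > A > C > G (defaults 0.30/0.27/0.23/0.20, configurable).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import kcal_to_log2, relative_binding_energy
from .read_processing import CountTable, empty_table
from .sequence_space import BASES, LibraryDesign, enumerate_space, reverse_complement

#: per-position base-usage bias of the synthesized input pool (T > A > C > G)
DEFAULT_BASE_BIAS: dict[str, float] = {"T": 0.30, "A": 0.27, "C": 0.23, "G": 0.20}

#: ddG grading of the base following the core: C strongest, then T, G, A
DEFAULT_FOLLOWING_GRADES: dict[str, float] = {"C": 0.0, "T": 0.5, "G": 1.5, "A": 2.5}


@dataclass
class TruthModel:
    """Ground-truth energies and input-pool composition for simulation."""

    design: LibraryDesign
    true_ddg: np.ndarray  # log2 units, aligned with enumerate_space(design.n)
    input_probs: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_ddg = np.asarray(self.true_ddg, dtype=float)
        self.input_probs = np.asarray(self.input_probs, dtype=float)
        size = self.design.space_size
        if self.true_ddg.shape != (size,) or self.input_probs.shape != (size,):
            raise ValueError(f"truth arrays must have shape ({size},)")
        if not np.all(np.isfinite(self.true_ddg)):
            raise ValueError("true_ddg must be finite everywhere")
        if (self.input_probs <= 0).any() or not np.isclose(self.input_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("input_probs must be positive and sum to 1")

    @property
    def space(self):
        return enumerate_space(self.design.n)

    def bound_probs(self) -> np.ndarray:
        w = self.input_probs * np.exp2(-self.true_ddg)
        return w / w.sum()

    def as_series(self) -> pd.Series:
        return pd.Series(self.true_ddg, index=list(self.space.sequences), name="true_ddg_log2")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "sequence": list(self.space.sequences),
                "true_ddg_log2": self.true_ddg,
                "input_prob": self.input_probs,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class DepthCurve:
    """Estimator accuracy per sequencing depth, averaged over replicates."""

    depths: list[int]
    metric: str
    values: np.ndarray  # mean metric per depth
    per_replicate: np.ndarray  # shape (len(depths), replicates)
    replicates: int
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_replicate, columns=[f"rep{i}" for i in range(self.replicates)])
        df.insert(0, "depth", self.depths)
        df["mean"] = self.values
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _bias_probs(design: LibraryDesign, bias) -> np.ndarray:
    """Input-pool probabilities as a per-position product of base frequencies."""
    if bias is None:
        bias = DEFAULT_BASE_BIAS
    vec = np.array([bias[b] for b in BASES], dtype=float)
    if (vec <= 0).any() or not np.isclose(vec.sum(), 1.0, atol=1e-9):
        raise ValueError("bias probabilities must be positive and sum to 1")
    space = enumerate_space(design.n)
    idx = {b: i for i, b in enumerate(BASES)}
    probs = np.array([np.prod([vec[idx[c]] for c in s]) for s in space.sequences])
    return probs / probs.sum()


def make_truth(
    design: LibraryDesign,
    core: str = "GAC",
    strong_energy: float = -3.0,
    following_grades: dict[str, float] | None = None,
    terminal_grade: float = 2.2,
    background_energy: float = 0.0,
    noise_sd: float = 0.0,
    bias: dict[str, float] | None = None,
    seed: int = 0,
) -> TruthModel:
    """Planted-motif truth: sequences containing ``core`` are strong binders.

    The energy of a core occurrence is ``strong_energy`` plus a grade for
    the base immediately 3' of the core (default C < T < G < A, echoing the
    W-box GAC(C/T) preference); an occurrence at the very 3' end, with no
    following base, gets ``terminal_grade`` instead.  The minimum over
    occurrences is taken.  Non-core sequences sit at ``background_energy``
    plus optional Gaussian noise (sd ``noise_sd``).
    """
    grades = DEFAULT_FOLLOWING_GRADES if following_grades is None else following_grades
    rng = np.random.default_rng(seed)
    space = enumerate_space(design.n)
    ddg = np.empty(len(space), dtype=float)
    for i, s in enumerate(space.sequences):
        energies = []
        start = s.find(core)
        while start >= 0:
            end = start + len(core)
            if end < len(s):
                energies.append(strong_energy + grades[s[end]])
            else:
                energies.append(strong_energy + terminal_grade)
            start = s.find(core, start + 1)
        if energies:
            ddg[i] = min(energies)
        else:
            ddg[i] = background_energy + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return TruthModel(design=design, true_ddg=ddg, input_probs=_bias_probs(design, bias), seed=seed)


def random_truth(
    design: LibraryDesign,
    ddg_range_kcal: tuple[float, float] = (0.5, 5.0),
    bias: dict[str, float] | None = None,
    seed: int = 0,
) -> TruthModel:
    """Truth with energies drawn uniformly over a kcal/mol range.

    The default 0.5-5 kcal/mol span (about 1.2-12.2 log2 units at 298 K) is
    the assumed protein-DNA ddG range of the depth-requirement analysis.
    """
    lo, hi = ddg_range_kcal
    if not lo < hi:
        raise ValueError("ddg_range_kcal must be an increasing pair")
    rng = np.random.default_rng(seed)
    ddg = kcal_to_log2(rng.uniform(lo, hi, size=design.space_size))
    return TruthModel(design=design, true_ddg=ddg, input_probs=_bias_probs(design, bias), seed=seed)


def sample_assay(
    truth: TruthModel,
    input_reads: int,
    bound_reads: int,
    seed: int | np.random.Generator = 0,
) -> tuple[CountTable, CountTable]:
    """Draw one synthetic assay: multinomial input and Boltzmann-reweighted bound counts."""
    if input_reads < 0 or bound_reads < 0:
        raise ValueError("read counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    input_table = empty_table(truth.design, "input")
    bound_table = empty_table(truth.design, "bound")
    input_table.counts[:] = rng.multinomial(input_reads, truth.input_probs)
    bound_table.counts[:] = rng.multinomial(bound_reads, truth.bound_probs())
    return input_table, bound_table


def _mutate(rng: np.random.Generator, base: str) -> str:
    return rng.choice([b for b in BASES if b != base])


def synth_fastq(
    counts,
    design: LibraryDesign,
    out1,
    out2,
    error_rate: float = 0.0,
    corrupt_pair_rate: float = 0.0,
    seed: int = 0,
    quality_char: str = "I",
) -> int:
    """Write paired FASTQ files for the given core multiplicities.

    Read 1 is ``left_flank + core + right_flank``; read 2 is its exact
    reverse complement.  Substitution errors hit each base independently at
    ``error_rate``.  Exactly ``round(corrupt_pair_rate * N)`` pairs (chosen
    without replacement) get one deliberate core substitution in read 2, so
    the reverse-complement filter must reject them.  Returns the number of
    pairs written; byte-identical output for a fixed seed.
    """
    if not 0 <= error_rate <= 1 or not 0 <= corrupt_pair_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if isinstance(counts, CountTable):
        items = [(s, int(c)) for s, c in zip(counts.space.sequences, counts.counts) if c > 0]
    else:
        items = sorted((s, int(c)) for s, c in counts.items() if c > 0)
    cores = [s for s, c in items for _ in range(c)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cores))
    n_corrupt = round(corrupt_pair_rate * len(cores))
    corrupt = np.zeros(len(cores), dtype=bool)
    corrupt[rng.choice(len(cores), size=n_corrupt, replace=False)] = True

    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    core_start = len(design.left_flank)
    with _open(out1) as fh1, _open(out2) as fh2:
        for out_i, i in enumerate(order):
            core = cores[i]
            read1 = design.construct(core)
            read2 = reverse_complement(read1)
            if error_rate > 0:
                read1 = "".join(_mutate(rng, b) if rng.random() < error_rate else b for b in read1)
                read2 = "".join(_mutate(rng, b) if rng.random() < error_rate else b for b in read2)
            if corrupt[i]:
                # read2 core occupies the mirrored position of the insert
                start2 = len(design.right_flank)
                pos = start2 + int(rng.integers(design.n))
                read2 = read2[:pos] + _mutate(rng, read2[pos]) + read2[pos + 1 :]
            name = f"pair_{out_i}"
            qual1, qual2 = quality_char * len(read1), quality_char * len(read2)
            fh1.write(f"@{name}/1\n{read1}\n+\n{qual1}\n")
            fh2.write(f"@{name}/2\n{read2}\n+\n{qual2}\n")
    return len(cores)


def downsample(table: CountTable, fraction: float | None = None, target_reads: int | None = None,
               seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample reads without replacement (multivariate hypergeometric).

    Exactly ``target_reads`` (or ``round(fraction * total)``) reads survive.
    """
    total = table.total_kept
    if (fraction is None) == (target_reads is None):
        raise ValueError("give exactly one of fraction or target_reads")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        target_reads = round(fraction * total)
    if target_reads > total:
        raise ValueError(f"target {target_reads} exceeds table total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = empty_table(table.design, table.pool_label)
    out.counts[:] = rng.multivariate_hypergeometric(table.counts, target_reads)
    return out


def _metric(est: np.ndarray, truth: np.ndarray, metric: str) -> float:
    """Offset-invariant accuracy of an estimated landscape against truth (NaN-safe)."""
    from scipy import stats

    mask = np.isfinite(est) & np.isfinite(truth)
    if mask.sum() < 3 or np.std(truth[mask]) == 0 or np.std(est[mask]) == 0:
        return float("nan")  # degenerate: accuracy undefined
    if metric == "pearson":
        return float(stats.pearsonr(est[mask], truth[mask]).statistic)
    if metric == "spearman":
        return float(stats.spearmanr(est[mask], truth[mask]).statistic)
    if metric == "rank-accuracy":
        m = max(1, mask.sum() // 10)  # overlap of the strongest decile
        top_est = set(np.argsort(est[mask], kind="stable")[:m])
        top_true = set(np.argsort(truth[mask], kind="stable")[:m])
        return len(top_est & top_true) / m
    raise ValueError(f"unknown metric {metric!r}")


def depth_curve(
    truth: TruthModel,
    depths,
    replicates: int = 5,
    metric: str = "pearson",
    seed: int = 0,
    pseudocount: float = 1.0,
) -> DepthCurve:
    """Estimator accuracy versus sequencing depth.

    For each depth d, ``replicates`` independent assays are drawn with
    input_reads = bound_reads = d, the landscape is estimated (pseudocount 1
    by default so shallow depths stay defined), and the offset-invariant
    metric against the truth is averaged.
    """
    depths = [int(d) for d in depths]
    if not depths or any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be a nonempty strictly increasing list")
    rng = np.random.default_rng(seed)
    per_rep = np.empty((len(depths), replicates))
    for di, d in enumerate(depths):
        for r in range(replicates):
            inp, bnd = sample_assay(truth, d, d, rng)
            land = relative_binding_energy(inp, bnd, pseudocount=pseudocount)
            per_rep[di, r] = _metric(land.ddg, truth.true_ddg, metric)
    return DepthCurve(
        depths=depths,
        metric=metric,
        values=np.nanmean(per_rep, axis=1),
        per_replicate=per_rep,
        replicates=replicates,
        seed=seed if isinstance(seed, int) else 0,
    )


def pe150_bases_required(read_pairs: int = 100_000, bases_per_pair: int = 300) -> int:
    """Total sequenced bases for a paired-end run (PE150: 300 bases per pair)."""
    if read_pairs < 0 or bases_per_pair <= 0:
        raise ValueError("read_pairs must be >= 0 and bases_per_pair > 0")
    return read_pairs * bases_per_pair
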