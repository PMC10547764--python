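"""Relative binding-energy landscapes from input/bound count tables.

For sequence type S_i with input-pool count R_i and bound-pool count B_i,
the pool proportions are P(S_i) = R_i / sum_j R_j and
P(S_i | bound) = B_i / sum_j B_j, and the relative binding energy is

    ddG(S_i) = -log2( P(S_i | bound) / P(S_i) )

in log2 units (dimensionless): lower means stronger binding, and the whole
landscape is defined only up to an additive constant set by pool
composition.  Zeros are never glossed over by default: with pseudocount 0 a
sequence unobserved in either pool has an undefined (NaN) energy rather
than a fabricated one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .read_processing import CountTable, empty_table
from .sequence_space import LibraryDesign, enumerate_space

#: RT at 298 K in kcal/mol; one log2 unit of ddG is RT*ln2 ~ 0.411 kcal/mol
RT_KCAL = 0.593
LOG2_UNIT_KCAL = RT_KCAL * math.log(2)


def log2_to_kcal(x):
    """Convert log2-unit relative energies to kcal/mol (298 K)."""
    return np.asarray(x, dtype=float) * LOG2_UNIT_KCAL


def kcal_to_log2(x):
    """Convert kcal/mol relative energies to log2 units (298 K)."""
    return np.asarray(x, dtype=float) / LOG2_UNIT_KCAL


@dataclass
class EnergyLandscape:
    """ddG per core sequence, with the proportions and counts it came from.

    Arrays are aligned with ``enumerate_space(design.n).sequences``.
    Sequences whose ratio is undefined under the pseudocount policy carry
    NaN in ``ddg`` and False in ``defined``.
    """

    design: LibraryDesign
    p_input: np.ndarray
    p_bound: np.ndarray
    ddg: np.ndarray
    input_counts: np.ndarray | None = None
    bound_counts: np.ndarray | None = None
    pseudocount: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def space(self):
        return enumerate_space(self.design.n)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.ddg)

    def __getitem__(self, seq: str) -> float:
        return float(self.ddg[self.space.index(seq)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.ddg, index=list(self.space.sequences), name="ddg_log2")

    def to_frame(self) -> pd.DataFrame:
        zeros = np.zeros(len(self.ddg), dtype=np.int64)
        return pd.DataFrame(
            {
                "sequence": list(self.space.sequences),
                "input_count": self.input_counts if self.input_counts is not None else zeros,
                "bound_count": self.bound_counts if self.bound_counts is not None else zeros,
                "p_input": self.p_input,
                "p_bound": self.p_bound,
                "ddg_log2": self.ddg,
            }
        )

    def to_tsv(self, path) -> None:
        """Landscape TSV: 6-decimal floats, "NA" for undefined energies."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def proportions(table: CountTable, pseudocount: float = 0.0) -> np.ndarray:
    """Pool proportions p_i = (count_i + pc) / sum_j (count_j + pc)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    counts = table.counts.astype(float) + pseudocount
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count table with pseudocount 0 has no proportions")
    return counts / total


def relative_binding_energy(
    input_table: CountTable,
    bound_table: CountTable,
    pseudocount: float = 0.0,
) -> EnergyLandscape:
    """Compute the ddG landscape from an input/bound count-table pair.

    Both tables must share the same library design.  Where either proportion
    is zero (possible only with pseudocount 0) the energy is NaN, flagged
    absent rather than fabricated.
    """
    if input_table.design != bound_table.design:
        raise ValueError("input and bound tables have different library designs")
    p_in = proportions(input_table, pseudocount)
    p_bd = proportions(bound_table, pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        ddg = -np.log2(p_bd / p_in)
    ddg[(p_in == 0) | (p_bd == 0)] = np.nan
    return EnergyLandscape(
        design=input_table.design,
        p_input=p_in,
        p_bound=p_bd,
        ddg=ddg,
        input_counts=input_table.counts.copy(),
        bound_counts=bound_table.counts.copy(),
        pseudocount=pseudocount,
        provenance={"input_pool": input_table.pool_label, "bound_pool": bound_table.pool_label},
    )


def select_high_affinity(landscape: EnergyLandscape, cutoff: float = -1.0) -> set[str]:
    """Sequences with ddG strictly below ``cutoff`` (default -1, the logo cutoff)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    mask = landscape.defined & (landscape.ddg < cutoff)
    seqs = landscape.space.sequences
    return {seqs[i] for i in np.flatnonzero(mask)}


def _values_of(x) -> pd.Series:
    if isinstance(x, EnergyLandscape):
        return x.as_series()
    if isinstance(x, pd.Series):
        return x
    if isinstance(x, dict):
        return pd.Series(x, dtype=float)
    return pd.Series(np.asarray(x, dtype=float))


def compare_landscapes(a, b, method: str = "pearson") -> float:
    """Correlation between two landscapes over their shared defined sequences.

    Accepts :class:`EnergyLandscape`, mappings, Series, or plain vectors
    (plain vectors are aligned by position).  Pearson by default, Spearman
    optional.  Requires at least 3 shared finite points.
    """
    va, vb = _values_of(a), _values_of(b)
    df = pd.concat({"a": va, "b": vb}, axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError(f"only {len(df)} sequences defined in both landscapes; need >= 3")
    if method == "pearson":
        return float(stats.pearsonr(df["a"], df["b"]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(df["a"], df["b"]).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def marginal_counts(table: CountTable, windows: str = "both") -> CountTable:
    """Marginalize a length-(K+1) count table to length K by window sums.

    Each (K+1)-mer contributes its full count to each of its length-K
    windows (prefix and suffix by default), so marginal totals are twice
    the original totals.  ``windows`` may be "both", "prefix" or "suffix".
    """
    n = table.design.n
    if n < 2:
        raise ValueError("cannot marginalize below length 1")
    if windows not in ("both", "prefix", "suffix"):
        raise ValueError(f"windows must be both/prefix/suffix, got {windows!r}")
    sub_design = LibraryDesign(table.design.left_flank, table.design.right_flank, n - 1)
    out = empty_table(sub_design, table.pool_label)
    sub_space = out.space
    for seq, c in zip(table.space.sequences, table.counts):
        if c == 0:
            continue
        if windows in ("both", "prefix"):
            out.counts[sub_space.index(seq[:-1])] += c
        if windows in ("both", "suffix"):
            out.counts[sub_space.index(seq[1:])] += c
    return out


def marginalize(
    input_table: CountTable,
    bound_table: CountTable,
    pseudocount: float = 0.0,
    windows: str = "both",
) -> EnergyLandscape:
    """Derive the K-mer landscape from (K+1)-mer input/bound tables.

    Counts are marginalized per pool first (window sums propagate sampling
    weight), then the energy formula is applied to the marginal tables.
    """
    if input_table.design != bound_table.design:
        raise ValueError("input and bound tables have different library designs")
    land = relative_binding_energy(
        marginal_counts(input_table, windows), marginal_counts(bound_table, windows), pseudocount
    )
    land.provenance["marginalized_from_n"] = input_table.design.n
    land.provenance["windows"] = windows
    return land


def emsa_statistic(bound_gray: float, unbound_gray: float) -> float:
    """-log2(bound/unbound) from gel band intensities, comparable to ddG."""
    if bound_gray <= 0 or unbound_gray <= 0:
        raise ValueError("band intensities must be positive")
    return -math.log2(bound_gray / unbound_gray)
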