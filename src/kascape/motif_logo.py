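"""Position weight matrices and information-content sequence logos.

The landscape itself is the model-free object; the PWM here is only a
summary of the high-affinity set (sequences below the energy cutoff).
Column information content is measured in bits against the uniform
background of the randomized library:

    info_j = 2 + sum_b p_bj * log2(p_bj)        (0*log2(0) = 0)

so a fully determined column carries 2 bits and a uniform one 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_space import BASES

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWMatrix:
    """Per-position base probabilities (columns indexed 0..L-1, rows A,C,G,T)."""

    probs: np.ndarray  # shape (L, 4), rows sum to 1
    info: np.ndarray  # shape (L,), bits in [0, 2]
    source_count: int
    weights_mode: str = "uniform"
    dropped_columns: tuple[int, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Most probable base per column (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def top_bases(self, j: int, k: int = 2) -> tuple[str, ...]:
        """The k most probable bases at column j, by decreasing probability."""
        order = np.argsort(-self.probs[j], kind="stable")
        return tuple(BASES[i] for i in order[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs.T, index=list(BASES), columns=[str(j + 1) for j in range(self.length)])

    def to_tsv(self, path) -> None:
        """PWM TSV: rows A,C,G,T x columns 1..L (6 decimals), then an info line."""
        with open(path, "w") as fh:
            df = self.to_frame()
            fh.write("base\t" + "\t".join(df.columns) + "\n")
            for base, row in df.iterrows():
                fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("info_bits\t" + "\t".join(f"{v:.6f}" for v in self.info) + "\n")


def _column_info(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    return np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)


def build_pwm(sequences, weights=None) -> PWMatrix:
    """Build a PWM from equal-length sequences, optionally weighted.

    With ``weights=None`` every sequence counts once (the default summary of
    a selected set); per-sequence weights (e.g. bound counts) are accepted
    for enrichment-weighted logos.
    """
    seqs = sorted(sequences) if isinstance(sequences, (set, frozenset)) else list(sequences)
    if not seqs:
        raise ValueError("cannot build a PWM from an empty sequence set")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have the same length")
    if weights is None:
        w = np.ones(len(seqs))
        mode = "uniform"
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(seqs),) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, one per sequence, with positive sum")
        mode = "weighted"
    probs = np.zeros((L, 4))
    for s, wi in zip(seqs, w):
        for j, base in enumerate(s):
            probs[j, _BASE_INDEX[base]] += wi
    probs /= w.sum()
    return PWMatrix(probs=probs, info=_column_info(probs), source_count=len(seqs), weights_mode=mode)


def trim_logo(pwm: PWMatrix, min_info: float = 0.2) -> PWMatrix:
    """Drop poorly informative flanking columns (info < ``min_info`` bits).

    Only contiguous runs at the two ends are dropped; the kept block runs
    from the first to the last column with info >= min_info.  Dropped
    indices are recorded; the input matrix is untouched, so the full PWM
    is always available alongside the trimmed one.
    """
    keep = np.flatnonzero(pwm.info >= min_info)
    if keep.size == 0:
        warnings.warn("all columns below the information threshold: empty logo")
        return PWMatrix(
            probs=pwm.probs[:0],
            info=pwm.info[:0],
            source_count=pwm.source_count,
            weights_mode=pwm.weights_mode,
            dropped_columns=tuple(range(pwm.length)),
        )
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    dropped = tuple(range(0, lo)) + tuple(range(hi, pwm.length))
    return PWMatrix(
        probs=pwm.probs[lo:hi],
        info=pwm.info[lo:hi],
        source_count=pwm.source_count,
        weights_mode=pwm.weights_mode,
        dropped_columns=dropped,
    )


def plot_logo(pwm: PWMatrix, path, title: str | None = None) -> None:
    """Render an information-content sequence logo (letter height = p * info).

    A compact matplotlib renderer: each column stacks the four base letters,
    scaled so the column's total height equals its information content.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(2, 0.6 * pwm.length + 1), 2.5))
    for j in range(pwm.length):
        y = 0.0
        order = np.argsort(pwm.probs[j], kind="stable")  # draw small letters first
        for bi in order:
            h = pwm.probs[j, bi] * pwm.info[j]
            if h <= 1e-9:
                continue
            base = BASES[bi]
            tp = TextPath((0, 0), base, size=1.0, prop=fp)
            bb = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(j + 0.05, y)
            )
            ax.add_patch(PathPatch(tp.transformed(transform), facecolor=colors[base], edgecolor="none"))
            y += h
    ax.set_xlim(0, pwm.length)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(pwm.length) + 0.5, [str(j + 1) for j in range(pwm.length)])
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
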