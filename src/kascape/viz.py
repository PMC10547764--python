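"""Static rendering of value landscapes on the K-mer graph grid.

Replaces the interactive 3-D viewer with batch figures: every length-k
sequence gets one bar (3-D) or cell (heatmap) at its grid position, with
height/color giving the value and an optional core-sequence highlight.
The figure is always accompanied by a sidecar TSV (sequence, row, col,
value, highlighted) which is the bit-exact record; figures are derived
views, never the source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_space import KmerGraphLayout, core_mask, enumerate_space

VALUE_KINDS = ("read_depth", "ddg", "minus_ddg")


@dataclass
class RenderSpec:
    """What to draw and how.

    ``value_kind`` fixes the transform applied before drawing: raw values
    for ``read_depth`` and ``ddg``, negated values for ``minus_ddg`` (the
    viewer's "- relative binding energy" convention, where taller bars mean
    stronger binding).
    """

    layout: KmerGraphLayout
    value_kind: str = "ddg"
    highlight_core: str | None = None
    cmap: str = "viridis"
    style: str = "3d"  # "3d" bars or "heatmap"
    title: str | None = None
    label_scale: float = 1.0
    out: str | Path = "landscape.png"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if self.style not in ("3d", "heatmap"):
            raise ValueError("style must be '3d' or 'heatmap'")


def _transform(values: np.ndarray, kind: str) -> np.ndarray:
    return -values if kind == "minus_ddg" else values


def render_landscape(values, spec: RenderSpec) -> pd.DataFrame:
    """Render a sequence -> value mapping on the K-mer graph.

    ``values`` may be a dict, a pandas Series, or an array aligned with the
    lexicographic space of the layout's k.  Writes the figure to ``spec.out``
    and a sidecar TSV next to it (same stem, ``.tsv``); returns the sidecar
    frame.  NaN values are drawn as empty cells/zero-height bars.
    """
    space = enumerate_space(spec.layout.k)
    if isinstance(values, dict):
        series = pd.Series(values, dtype=float)
    elif isinstance(values, pd.Series):
        series = values.astype(float)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(space),):
            raise ValueError(f"value vector must have length {len(space)} for k={spec.layout.k}")
        series = pd.Series(arr, index=list(space.sequences))
    unknown = [s for s in series.index if s not in space]
    if unknown:
        raise ValueError(f"sequences not in the k={spec.layout.k} layout: {unknown[:5]}")

    highlight = core_mask(space, spec.highlight_core) if spec.highlight_core else set()
    rows, cols = zip(*(spec.layout.cell(s) for s in series.index))
    shown = _transform(series.to_numpy(), spec.value_kind)
    sidecar = pd.DataFrame(
        {
            "sequence": series.index,
            "row": rows,
            "col": cols,
            "value": shown,
            "highlighted": [int(s in highlight) for s in series.index],
        }
    ).sort_values("sequence", kind="stable", ignore_index=True)

    out = Path(spec.out)
    sidecar.to_csv(out.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f", na_rep="NA")
    _draw(sidecar, spec, out)
    return sidecar


def _draw(sidecar: pd.DataFrame, spec: RenderSpec, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    side = spec.layout.side
    vals = np.asarray(sidecar["value"], dtype=float)
    finite = np.isfinite(vals)
    vmin = float(np.nanmin(vals)) if finite.any() else 0.0
    vmax = float(np.nanmax(vals)) if finite.any() else 1.0
    norm = colors.Normalize(vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1)
    cmap = plt.get_cmap(spec.cmap)

    if spec.style == "heatmap":
        grid = np.full((side, side), np.nan)
        grid[sidecar["row"], sidecar["col"]] = vals
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(grid, cmap=cmap, norm=norm, origin="upper")
        for _, r in sidecar[sidecar["highlighted"] == 1].iterrows():
            ax.add_patch(plt.Rectangle((r["col"] - 0.5, r["row"] - 0.5), 1, 1, fill=False,
                                       edgecolor="white", linewidth=1.5))
        fig.colorbar(im, ax=ax, label=spec.value_kind)
        ax.set_xlabel("column")
        ax.set_ylabel("row")
    else:
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(projection="3d")
        height = np.where(finite, vals - min(vmin, 0.0), 0.0)
        face = cmap(norm(np.where(finite, vals, vmin)))
        hl = sidecar["highlighted"].to_numpy(dtype=bool)
        face[hl] = (1.0, 1.0, 0.2, 1.0)  # highlighted bars in bright yellow
        # row 0 drawn at the far top edge: flip rows onto the y axis
        ax.bar3d(sidecar["col"], side - 1 - sidecar["row"], np.full(len(vals), min(vmin, 0.0)),
                 0.8, 0.8, height, color=face, shade=True)
        ax.set_xlabel("column", fontsize=10 * spec.label_scale)
        ax.set_ylabel("row (flipped)", fontsize=10 * spec.label_scale)
        ax.set_zlabel(spec.value_kind, fontsize=10 * spec.label_scale)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
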