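"""End-to-end pipeline: FASTQ pair(s) -> counts -> landscape -> logo -> figures.

Configuration is a flat mapping (YAML file or dict); every run writes its
artifacts plus a JSON manifest recording parameters, versions and seed so
that outputs are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import yaml

from . import __version__
from .energetics import relative_binding_energy, select_high_affinity
from .motif_logo import build_pwm, plot_logo, trim_logo
from .read_processing import count_fastq_pool, write_counts, write_qc
from .sequence_space import LibraryDesign, layout
from .viz import RenderSpec, render_landscape

log = logging.getLogger("kascape")

DEFAULTS = {
    "pseudocount": 0.0,
    "cutoff": -1.0,
    "min_info": 0.2,
    "highlight_core": None,
    "cmap": "viridis",
    "style": "3d",
    "max_mismatch": 0,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return cfg


def design_from_config(cfg: dict) -> LibraryDesign:
    try:
        return LibraryDesign(cfg["left_flank"], cfg["right_flank"], int(cfg["n"]))
    except KeyError as e:
        raise ValueError(f"config is missing required design key {e}") from None


def run_pipeline(config: dict, outdir) -> dict:
    """Execute extract -> count -> energy -> select -> logo -> render.

    Required config keys: left_flank, right_flank, n, input_r1, input_r2,
    bound_r1, bound_r2.  Returns a manifest dict (also written to
    ``outdir/manifest.json``) mapping artifact names to paths.
    """
    cfg = {**DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design_from_config(cfg)
    for key in ("input_r1", "input_r2", "bound_r1", "bound_r2"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key}: {cfg[key]} does not exist")

    artifacts: dict[str, str] = {}

    def _save(name: str, path: Path) -> Path:
        artifacts[name] = str(path)
        log.info("wrote %s -> %s", name, path)
        return path

    tables = {}
    for pool in ("input", "bound"):
        table = count_fastq_pool(cfg[f"{pool}_r1"], cfg[f"{pool}_r2"], design, pool,
                                 max_mismatch=int(cfg["max_mismatch"]))
        tables[pool] = table
        write_counts(table, _save(f"{pool}_counts", outdir / f"{pool}_counts.tsv"))
        write_qc(table, _save(f"{pool}_qc", outdir / f"{pool}_qc.tsv"))
        log.info("%s pool: %d kept, %d discarded", pool, table.total_kept, table.total_discarded)

    landscape = None
    if tables["input"].total_kept and tables["bound"].total_kept:
        landscape = relative_binding_energy(tables["input"], tables["bound"], float(cfg["pseudocount"]))
        landscape.to_tsv(_save("landscape", outdir / "landscape.tsv"))
        selected = select_high_affinity(landscape, float(cfg["cutoff"]))
    else:
        # an empty pool still yields count tables and the QC report
        log.warning("a pool kept zero pairs; see the QC report -- skipping landscape and logo")
        selected = set()
    (outdir / "high_affinity.txt").write_text("".join(f"{s}\n" for s in sorted(selected)))
    _save("high_affinity", outdir / "high_affinity.txt")

    pwm = trimmed = None
    if selected:
        pwm = build_pwm(selected)
        pwm.to_tsv(_save("pwm", outdir / "pwm.tsv"))
        trimmed = trim_logo(pwm, float(cfg["min_info"]))
        if trimmed.length:
            plot_logo(trimmed, _save("logo", outdir / "logo.png"))
    else:
        log.warning("no sequences below cutoff %.3g: skipping PWM/logo", float(cfg["cutoff"]))

    grid = layout(design.n)
    renders = [
        ("input_depth", tables["input"].as_series(), "read_depth"),
        ("bound_depth", tables["bound"].as_series(), "read_depth"),
    ]
    if landscape is not None:
        renders.append(("energy", landscape.as_series(), "minus_ddg"))
    for name, values, kind in renders:
        spec = RenderSpec(layout=grid, value_kind=kind, highlight_core=cfg["highlight_core"],
                          cmap=cfg["cmap"], style=cfg["style"], title=name,
                          out=outdir / f"{name}.png")
        render_landscape(values, spec)
        _save(name, outdir / f"{name}.png")
        _save(f"{name}_sidecar", outdir / f"{name}.tsv")

    manifest = {
        "kascape_version": __version__,
        "python": platform.python_version(),
        "parameters": {k: v for k, v in cfg.items()},
        "design": {"left_flank": design.left_flank, "right_flank": design.right_flank, "n": design.n},
        "qc": {pool: dict(kept=t.total_kept, **t.qc) for pool, t in tables.items()},
        "n_high_affinity": len(selected),
        "consensus": trimmed.consensus() if trimmed is not None and trimmed.length else None,
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
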