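"""Result serialization, plotting and run manifests.

CSV (tidy long form) is the canonical result format; complex impedance
changes are stored as two real columns.  Every CLI run writes a JSON
manifest with a deterministic hash of the canonicalized config, the
seed and the produced files, sufficient to re-execute it exactly.
Figures are conveniences for inspection, never acceptance surfaces.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .experiments import SWEEP_COLUMNS

log = logging.getLogger("hemoradar")


def setup_logging(path: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    fmt = logging.Formatter("%(levelname)s %(asctime)s %(name)s: %(message)s")
    log.setLevel(level)
    handler = logging.FileHandler(path) if path else logging.StreamHandler()
    handler.setFormatter(fmt)
    log.addHandler(handler)


def _canonical(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Deterministic sha256 of the canonicalized (sorted, JSON) config."""
    payload = json.dumps(_canonical(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(path: str | Path, config, seed: int,
                   output_files: list) -> dict:
    manifest = {
        "config_hash": config_hash(config),
        "config": _canonical(config),
        "seed": int(seed),
        "artifact_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "output_files": [str(p) for p in output_files],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_sweep_csv(result: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep table with the documented fixed column order.

    Complex dZ is stored as (dz_re_ohm, dz_im_ohm); the absolute-value
    column is kept redundantly for convenient plotting.  Empty tables
    (everything flagged away) produce a header-only file with a
    warning.  Round-trips losslessly through :func:`read_sweep_csv`.
    """
    missing = [c for c in SWEEP_COLUMNS if c not in result.columns]
    if missing:
        raise ValueError(f"sweep table missing columns {missing}")
    if len(result) == 0:
        warnings.warn(f"writing header-only sweep file to {path}")
    result[SWEEP_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"orientation": str},
                       float_precision="round_trip")


def plot_curves(result: pd.DataFrame, kind: str, path: str | Path,
                bins: int = 50) -> Path:
    """Deterministic figure for a result table.

    ``volume_vs_dz``: |dZ| vs lesion volume, one curve per frequency.
    ``mie_curve``: log-log normalized RCS vs r/lambda (region diagram).
    ``noise_hist``: histogram of a ``differences`` column.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    if kind == "volume_vs_dz":
        need = {"frequency_hz", "volume_ml", "dz_abs_ohm"}
        if not need <= set(result.columns):
            raise ValueError(f"columns {need} required for {kind}")
        for f, grp in result.groupby("frequency_hz"):
            ax.plot(grp["volume_ml"], grp["dz_abs_ohm"], marker="o",
                    label=f"{f / 1e6:g} MHz")
        ax.set_xlabel("lesion volume (ml)")
        ax.set_ylabel(r"$|\Delta Z|$ ($\Omega$)")
        ax.legend()
    elif kind == "mie_curve":
        need = {"r_over_lambda", "normalized_rcs"}
        if not need <= set(result.columns):
            raise ValueError(f"columns {need} required for {kind}")
        ax.loglog(result["r_over_lambda"], result["normalized_rcs"])
        ax.set_xlabel(r"$r / \lambda$")
        ax.set_ylabel(r"$\sigma / \pi r^2$")
    elif kind == "noise_hist":
        if "differences" not in result.columns:
            raise ValueError("column 'differences' required for noise_hist")
        ax.hist(result["differences"], bins=bins)
        ax.set_xlabel(r"$|\Delta Z|$ error ($\Omega$)")
        ax.set_ylabel("count")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def export_nifti(phantom, path: str | Path) -> Path:
    """Optional NIfTI export of a phantom label grid for visualization."""
    import nibabel as nib

    affine = np.diag([phantom.spacing * 1000] * 3 + [1.0])
    affine[:3, 3] = phantom.origin * 1000
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    nib.save(img, str(path))
    return Path(path)
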