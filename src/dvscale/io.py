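"""Delimited-text readers and writers for the pipeline's artifacts.

All on-disk formats are plain TSV (one header row) or JSON:

* point clouds — ``cells.tsv`` with columns embryo_id, group, batch, x, y,
  z, intensity (one row per cell) plus a ``samples.tsv`` sample sheet
  (embryo_id, group, batch) and an optional ``truth.json`` sidecar with the
  generator's ground truth;
* margin profiles — one row per embryo × bin;
* normalized profiles and the filtering report;
* per-embryo Hill fits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hill import HillParams
from .margin import N_BINS, MarginProfile
from .normalize import NormalizedProfile, RejectionReason
from .synthetic import EmbryoPointCloud

CELL_COLUMNS = ["embryo_id", "group", "batch", "x", "y", "z", "intensity"]


def write_point_clouds(
    clouds: list[EmbryoPointCloud], outdir: str | Path, truth: bool = True
) -> None:
    """Write cells.tsv + samples.tsv (+ truth.json for synthetic clouds)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for c in clouds:
        df = pd.DataFrame(c.cells, columns=["x", "y", "z", "intensity"])
        df.insert(0, "batch", c.batch)
        df.insert(0, "group", c.group)
        df.insert(0, "embryo_id", c.embryo_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "cells.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        [(c.embryo_id, c.group, c.batch) for c in clouds],
        columns=["embryo_id", "group", "batch"],
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if truth and all(c.truth is not None for c in clouds):
        sidecar = {
            c.embryo_id: {
                "L_true": c.truth.L_true,
                "hill_true": list(c.truth.hill_true),
                "mode": c.truth.mode,
                "ventral_direction": c.truth.ventral_direction.tolist(),
            }
            for c in clouds
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1))


def read_point_clouds(indir: str | Path) -> list[EmbryoPointCloud]:
    """Read point clouds written by :func:`write_point_clouds`."""
    indir = Path(indir)
    cells_path = indir / "cells.tsv"
    if not cells_path.exists():
        raise FileNotFoundError(f"no cells.tsv under {indir}")
    df = pd.read_csv(cells_path, sep="\t", float_precision="round_trip")
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cells.tsv missing columns: {sorted(missing)}")
    out = []
    for eid, sub in df.groupby("embryo_id", sort=True):
        out.append(
            EmbryoPointCloud(
                embryo_id=str(eid),
                group=str(sub["group"].iloc[0]),
                batch=str(sub["batch"].iloc[0]),
                cells=sub[["x", "y", "z", "intensity"]].to_numpy(float),
            )
        )
    return out


def write_profiles(profiles: list[MarginProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for k in range(N_BINS):
            rows.append(
                (p.embryo_id, p.group, p.batch, p.L, p.bin_center_deg[k],
                 p.bin_mean_intensity[k], p.bin_cell_count[k],
                 int(p.orientation_flag))
            )
    pd.DataFrame(
        rows,
        columns=["embryo_id", "group", "batch", "L", "bin_center_deg",
                 "bin_mean_intensity", "bin_cell_count", "orientation_flag"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profiles(path: str | Path) -> list[MarginProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for eid, sub in df.groupby("embryo_id", sort=True):
        sub = sub.sort_values("bin_center_deg")
        out.append(
            MarginProfile(
                embryo_id=str(eid),
                group=str(sub["group"].iloc[0]),
                batch=str(sub["batch"].iloc[0]),
                L=float(sub["L"].iloc[0]),
                bin_mean_intensity=sub["bin_mean_intensity"].to_numpy(float),
                bin_cell_count=sub["bin_cell_count"].to_numpy(int),
                orientation_flag=bool(sub["orientation_flag"].iloc[0]),
            )
        )
    return out


def write_normalized(
    profiles: list[NormalizedProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for k in range(N_BINS):
            rows.append(
                (p.embryo_id, p.group, p.batch, p.L, p.xi[k], p.xrel[k],
                 p.bin_mean_intensity[k], p.norm_intensity[k],
                 p.bin_cell_count[k], p.retained, p.rejection_reason.value)
            )
    pd.DataFrame(
        rows,
        columns=["embryo_id", "group", "batch", "L", "xi", "xrel",
                 "bin_mean_intensity", "norm_intensity", "bin_cell_count",
                 "retained", "rejection_reason"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_filter_report(
    profiles: list[NormalizedProfile], path: str | Path
) -> None:
    pd.DataFrame(
        [(p.embryo_id, p.group, p.peak, p.vd_diff, p.retained,
          p.rejection_reason.value) for p in profiles],
        columns=["embryo_id", "group", "peak", "vd_diff", "retained",
                 "reason"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_fits(
    fits: dict[str, HillParams], path: str | Path
) -> None:
    """Write per-embryo fits keyed by embryo_id."""
    pd.DataFrame(
        [(eid, f.axis, f.a, f.b, f.c, f.r_squared, f.n_points, f.converged)
         for eid, f in sorted(fits.items())],
        columns=["embryo_id", "axis", "a", "b", "c", "r_squared",
                 "n_points", "converged"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, RejectionReason):
        return obj.value
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True))
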