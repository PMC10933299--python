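"""Readers and writers for the pipeline's table and image formats.

All tables are comma-separated UTF-8 with a mandatory header and "." as the
decimal mark; missing values are empty fields, never 0. Unit-bearing
columns are suffixed (``_s`` seconds, ``_h`` hours, ``_um`` micrometres).
Images are single-plane grayscale TIFF, written as 16-bit.

Schemas
-------
tracks.csv
    ``cell_id, experiment_id, well, genotype, day, reporter_mean,
    reporter_sd, [cv,] alive`` — one row per cell per imaging day. A stored
    ``cv`` column is used verbatim; otherwise CV is computed as
    ``reporter_sd / reporter_mean``.
frap traces.csv
    ``granule_id, genotype, time_s, phase (pre|post), bleached_intensity,
    [whole_intensity,] roi_radius_um`` — pre-bleach rows carry negative
    ``time_s``.
decay.csv
    ``well_id, experiment_id, condition, time_h, tritc_intensity`` with
    ``time_h = -1`` coding the pre-conversion background (T0) and ``0`` the
    post-conversion peak (T1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu

from .flux import DecayTrace
from .frap import FrapTrace
from .puncta import ClassifierConfig, cell_cv

__all__ = [
    "IOError_",
    "read_tracks",
    "write_tracks",
    "read_frap_traces",
    "write_frap_traces",
    "read_decay_traces",
    "write_decay_traces",
    "read_images",
    "write_image",
    "write_table",
    "read_table",
]

TRACK_REQUIRED = [
    "cell_id",
    "experiment_id",
    "well",
    "genotype",
    "day",
    "reporter_mean",
    "reporter_sd",
    "alive",
]


class IOError_(ValueError):
    """Malformed input file."""


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format tracks CSV.

    Checks required columns, rejects duplicate ``(cell_id, day)`` rows
    (naming the first offending row) and cells observed alive after being
    observed dead. A present ``cv`` column takes precedence over
    recomputation from mean and SD. Returns the table sorted by cell and
    day.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_REQUIRED if c not in df.columns]
    if missing:
        raise IOError_(f"tracks file missing required columns: {missing}")
    dup = df.duplicated(subset=["cell_id", "day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IOError_(
            f"duplicate (cell_id, day) = ({row['cell_id']!r}, {row['day']!r}) in tracks file"
        )
    df["alive"] = df["alive"].astype(bool)
    df = df.sort_values(["cell_id", "day"]).reset_index(drop=True)
    for cell_id, sub in df.groupby("cell_id", sort=False):
        alive = sub["alive"].to_numpy()
        dead = np.nonzero(~alive)[0]
        if dead.size and alive[dead[0] :].any():
            raise IOError_(f"cell {cell_id!r} observed alive after death")
    if "cv" not in df.columns:
        df["cv"] = df["reporter_sd"] / df["reporter_mean"]
    return df


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_frap_traces(path: str | Path) -> list[FrapTrace]:
    """Read a FRAP trace CSV into one :class:`FrapTrace` per granule."""
    df = pd.read_csv(path)
    required = ["granule_id", "genotype", "time_s", "phase", "bleached_intensity", "roi_radius_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"FRAP file missing required columns: {missing}")
    if not df["phase"].isin(["pre", "post"]).all():
        raise IOError_("phase must be 'pre' or 'post'")
    bad = (df["phase"] == "pre") != (df["time_s"] < 0)
    if bad.any():
        raise IOError_("pre-bleach rows must carry negative time_s, post-bleach >= 0")
    traces = []
    for gid, sub in df.groupby("granule_id", sort=True):
        sub = sub.sort_values("time_s")
        whole = None
        if "whole_intensity" in sub.columns and sub["whole_intensity"].notna().all():
            whole = sub["whole_intensity"].to_numpy(dtype=float)
        traces.append(
            FrapTrace(
                times=sub["time_s"].to_numpy(dtype=float),
                bleached_intensity=sub["bleached_intensity"].to_numpy(dtype=float),
                whole_intensity=whole,
                granule_id=str(gid),
                genotype=str(sub["genotype"].iloc[0]),
                roi_radius_um=float(sub["roi_radius_um"].iloc[0]),
            )
        )
    return traces


def write_frap_traces(traces: list[FrapTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, t in enumerate(tr.times):
            rows.append(
                {
                    "granule_id": tr.granule_id,
                    "genotype": tr.genotype,
                    "time_s": t,
                    "phase": "pre" if t < 0 else "post",
                    "bleached_intensity": tr.bleached_intensity[i],
                    "whole_intensity": (
                        tr.whole_intensity[i] if tr.whole_intensity is not None else np.nan
                    ),
                    "roi_radius_um": tr.roi_radius_um,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay_traces(path: str | Path) -> list[DecayTrace]:
    """Read a decay CSV (time_h = -1 for T0, 0 for T1) into DecayTraces."""
    df = pd.read_csv(path)
    required = ["well_id", "experiment_id", "condition", "time_h", "tritc_intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"decay file missing required columns: {missing}")
    traces = []
    for (well, exp, cond), sub in df.groupby(
        ["well_id", "experiment_id", "condition"], sort=True
    ):
        sub = sub.sort_values("time_h")
        t0_rows = sub[sub["time_h"] == -1]
        t1_rows = sub[sub["time_h"] == 0]
        if len(t0_rows) != 1 or len(t1_rows) != 1:
            raise IOError_(
                f"well {well!r}/{exp!r} needs exactly one T0 (time_h=-1) and one T1 (time_h=0) row"
            )
        post = sub[sub["time_h"] > 0]
        traces.append(
            DecayTrace(
                well_id=str(well),
                experiment_id=str(exp),
                condition=str(cond),
                t0=float(t0_rows["tritc_intensity"].iloc[0]),
                t1=float(t1_rows["tritc_intensity"].iloc[0]),
                times_h=post["time_h"].to_numpy(dtype=float),
                values=post["tritc_intensity"].to_numpy(dtype=float),
            )
        )
    return traces


def write_decay_traces(traces: list[DecayTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        base = {
            "well_id": tr.well_id,
            "experiment_id": tr.experiment_id,
            "condition": tr.condition,
        }
        rows.append({**base, "time_h": -1.0, "tritc_intensity": tr.t0})
        rows.append({**base, "time_h": 0.0, "tritc_intensity": tr.t1})
        for t, v in zip(tr.times_h, tr.values):
            rows.append({**base, "time_h": t, "tritc_intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as 16-bit TIFF (values clipped to uint16 range)."""
    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))


def read_images(
    reporter_path: str | Path,
    morphology_path: str | Path,
    mask_path: str | Path | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Per-cell-region intensity statistics from a TIFF image pair.

    When no mask is supplied, the cell mask is derived by Otsu thresholding
    of the morphology channel. A labeled mask yields one row per label;
    a binary mask yields a single region. Columns: ``label, n_pixels,
    reporter_mean, reporter_sd, cv``.
    """
    reporter = tifffile.imread(reporter_path).astype(float)
    morphology = tifffile.imread(morphology_path).astype(float)
    if reporter.shape != morphology.shape:
        raise IOError_("reporter and morphology image dimensions differ")
    if mask_path is not None:
        mask = tifffile.imread(mask_path)
        if mask.shape != reporter.shape:
            raise IOError_("mask dimensions differ from images")
    else:
        mask = (morphology > threshold_otsu(morphology)).astype(np.uint8)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise IOError_("empty mask: no cell regions")
    rows = []
    ddof = 0 if config.sd_convention == "population" else 1
    for lab in labels:
        pix = reporter[mask == lab]
        cv = cell_cv(pix, config)  # raises on zero-mean regions
        rows.append(
            {
                "label": int(lab),
                "n_pixels": int(pix.size),
                "reporter_mean": float(pix.mean()),
                "reporter_sd": float(pix.std(ddof=ddof)),
                "cv": cv,
            }
        )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table; floats use repr formatting so values round-trip."""
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
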