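"""Coefficient-of-variation puncta scoring and longitudinal event extraction.

A cell expressing a diffusely distributed fluorescent reporter has nearly
uniform pixel intensities inside its mask; when the reporter condenses into
puncta, a few bright pixels coexist with a dim background and the
coefficient of variation (CV = SD / mean of in-mask pixel intensity) rises.
Cells whose CV lies strictly above a fixed threshold (default 0.62) are
classified as punctate. CV is dimensionless and invariant to illumination
scale, which is what makes it usable across wells and days.

Longitudinal tracks (one row per cell per imaging day) are reduced to
time-to-event records for two endpoints:

* death — first day the cell is observed dead, else right-censored at the
  last observation;
* puncta formation — first day the CV exceeds the threshold, treated as an
  absorbing state; censored at death or at the last observation if the
  threshold is never crossed.

Tracks are long-format :class:`pandas.DataFrame` objects with columns
``cell_id, experiment_id, well, genotype, day, reporter_mean, reporter_sd,
cv, alive`` (see :mod:`punctakit.io` for the file schema).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CV_THRESHOLD",
    "ClassifierConfig",
    "PunctaError",
    "cell_cv",
    "classify_punctate",
    "extract_events",
    "extract_event_table",
    "percent_punctate_over_time",
    "group_complexity",
]

DEFAULT_CV_THRESHOLD = 0.62

TRACK_COLUMNS = [
    "cell_id",
    "experiment_id",
    "well",
    "genotype",
    "day",
    "reporter_mean",
    "reporter_sd",
    "cv",
    "alive",
]


class PunctaError(ValueError):
    """Invalid input to the puncta classifier or event extraction."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of the CV classifier.

    ``cv_threshold``: a cell is punctate iff its CV is strictly above this.
    ``sd_convention``: "population" (divide by n, the default) or "sample"
    (divide by n-1) when computing SD from pixels.
    """

    cv_threshold: float = DEFAULT_CV_THRESHOLD
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.cv_threshold <= 0:
            raise PunctaError("cv_threshold must be positive")
        if self.sd_convention not in ("population", "sample"):
            raise PunctaError("sd_convention must be 'population' or 'sample'")


def cell_cv(pixels, config: ClassifierConfig = ClassifierConfig()) -> float:
    """Coefficient of variation of in-mask pixel intensities.

    Scale-invariant: multiplying every pixel by a positive constant leaves
    the CV unchanged. A constant region has CV exactly 0.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0:
        raise PunctaError("empty mask: no pixels to score")
    mean = pixels.mean()
    if mean <= 0:
        raise PunctaError("mean intensity must be positive to form a CV")
    ddof = 0 if config.sd_convention == "population" else 1
    if ddof == 1 and pixels.size < 2:
        raise PunctaError("sample SD needs at least 2 pixels")
    if np.all(pixels == pixels[0]):  # exact zero for constant regions
        return 0.0
    return float(pixels.std(ddof=ddof) / mean)


def classify_punctate(cv: float, config: ClassifierConfig = ClassifierConfig()) -> str:
    """Classify a cell as ``"punctate"`` (CV strictly above threshold) or ``"diffuse"``."""
    if cv < 0:
        raise PunctaError("cv must be non-negative")
    return "punctate" if cv > config.cv_threshold else "diffuse"


def _validate_track(track: pd.DataFrame) -> pd.DataFrame:
    if track.empty:
        raise PunctaError("empty track")
    track = track.sort_values("day").reset_index(drop=True)
    days = track["day"].to_numpy()
    if np.any(np.diff(days) <= 0):
        raise PunctaError("track days must be strictly increasing (duplicate day?)")
    alive = track["alive"].to_numpy(dtype=bool)
    dead_idx = np.nonzero(~alive)[0]
    if dead_idx.size and np.any(alive[dead_idx[0] :]):
        raise PunctaError("cell observed alive after being observed dead")
    if dead_idx.size > 1:
        # later dead rows after the first death are redundant; reject to keep
        # "at most one death" well defined
        raise PunctaError("more than one death observation for a cell")
    return track


def extract_events(
    track: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> dict:
    """Reduce one cell's track to death and puncta time-to-event records.

    Returns a dict with ``death_time, death_event, puncta_time,
    puncta_event, day1_intensity, day1_cv, day1_punctate`` plus the cell's
    identifiers. Puncta formation is absorbing: the first threshold crossing
    defines the event even if later observations drop below. A cell already
    punctate on its first day is a prevalent (day-1) event and is flagged
    for diffuse-vs-punctate subgroup analyses.
    """
    track = _validate_track(track)
    days = track["day"].to_numpy(dtype=float)
    alive = track["alive"].to_numpy(dtype=bool)
    cv = track["cv"].to_numpy(dtype=float)

    dead_idx = np.nonzero(~alive)[0]
    if dead_idx.size:
        death_time, death_event = days[dead_idx[0]], 1
    else:
        death_time, death_event = days[-1], 0

    crossed = np.nonzero(alive & (cv > config.cv_threshold))[0]
    if crossed.size:
        puncta_time, puncta_event = days[crossed[0]], 1
    else:
        puncta_time, puncta_event = death_time, 0

    first = track.iloc[0]
    return {
        "cell_id": first["cell_id"],
        "group": first["genotype"],
        "stratum": first["experiment_id"],
        "death_time": float(death_time),
        "death_event": int(death_event),
        "puncta_time": float(puncta_time),
        "puncta_event": int(puncta_event),
        "day1_intensity": float(first["reporter_mean"]),
        "day1_cv": float(first["cv"]),
        "day1_punctate": bool(first["alive"]) and float(first["cv"]) > config.cv_threshold,
    }


def extract_event_table(
    tracks: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Apply :func:`extract_events` to every cell of a long-format table."""
    if tracks.empty:
        raise PunctaError("empty tracks table")
    rows = [
        extract_events(group, config)
        for _, group in tracks.groupby("cell_id", sort=True)
    ]
    return pd.DataFrame(rows)


def percent_punctate_over_time(
    tracks: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Percentage of living cells in the (absorbing) punctate state per day.

    For each genotype and imaging day: ``100 * punctate_alive / alive``
    pooled over experiments, plus the SEM of the per-experiment percentages
    when more than one experiment is present. Days on which a group has no
    living cells yield a missing percentage (NaN), never 0.
    """
    if tracks.empty:
        raise PunctaError("empty tracks table")
    df = tracks.sort_values(["cell_id", "day"]).copy()
    df["_punctate_now"] = df["alive"].astype(bool) & (df["cv"] > config.cv_threshold)
    df["_punctate"] = df.groupby("cell_id")["_punctate_now"].cummax()
    alive = df[df["alive"].astype(bool)]

    per_exp = (
        alive.groupby(["genotype", "day", "experiment_id"])
        .agg(n_alive=("cell_id", "size"), n_punctate=("_punctate", "sum"))
        .reset_index()
    )
    per_exp["percent"] = 100.0 * per_exp["n_punctate"] / per_exp["n_alive"]

    def _pool(g: pd.DataFrame) -> pd.Series:
        n_alive = int(g["n_alive"].sum())
        pooled = 100.0 * g["n_punctate"].sum() / n_alive
        sem = g["percent"].sem(ddof=1) if len(g) > 1 else np.nan
        return pd.Series(
            {"percent": pooled, "sem": sem, "n_alive": n_alive, "n_experiments": len(g)}
        )

    out = (
        per_exp.groupby(["genotype", "day"])
        .apply(_pool, include_groups=False)
        .reset_index()
    )
    # re-insert missing (genotype, day) combinations as NaN percentages
    all_days = sorted(tracks["day"].unique())
    full = pd.MultiIndex.from_product(
        [sorted(tracks["genotype"].unique()), all_days], names=["genotype", "day"]
    )
    out = out.set_index(["genotype", "day"]).reindex(full).reset_index()
    return out


def group_complexity(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group manually scored granule complexity into low/high classes.

    ``records`` needs columns ``granule_id, genotype, score`` and optionally
    ``mobile_fraction``. Scores are integers 1-4 from blinded visual
    scoring; 1-2 are "low" complexity, 3-4 "high".

    Returns ``(records_with_class, score_summary, mobility_summary)``:
    per-genotype n/mean/median/SD of the scores, and per genotype-by-class
    n/mean/median/SD of the mobile fraction (empty when mobile fractions
    are absent).
    """
    records = records.copy()
    scores = records["score"].to_numpy()
    if not np.isin(scores, [1, 2, 3, 4]).all():
        raise PunctaError("complexity scores must be integers in 1..4")
    records["complexity_class"] = np.where(scores <= 2, "low", "high")

    score_summary = (
        records.groupby("genotype")["score"]
        .agg(n="size", mean="mean", median="median", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    if "mobile_fraction" in records.columns and records["mobile_fraction"].notna().any():
        mobility_summary = (
            records.dropna(subset=["mobile_fraction"])
            .groupby(["genotype", "complexity_class"])["mobile_fraction"]
            .agg(n="size", mean="mean", median="median", sd=lambda s: s.std(ddof=1))
            .reset_index()
        )
    else:
        mobility_summary = pd.DataFrame(
            columns=["genotype", "complexity_class", "n", "mean", "median", "sd"]
        )
    return records, score_summary, mobility_summary
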