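"""Seeded generators for every input the analysis pipeline consumes.

The live-cell experiments behind this pipeline (confocal FRAP of granules,
longitudinal automated microscopy of transfected neurons, optical pulse
labeling of an autophagy reporter) are not deposited as raw data, so every
stage is validated against synthetic inputs generated here, each emitted
together with its ground truth:

* :func:`simulate_frap_trace` — bleach-recovery series following
  ``y(t) = A (1 - exp(-tau t))`` on the standard acquisition schedule
  (every 5 s for 1 min, then every 10 s for 4 min) with additive Gaussian
  noise;
* :func:`simulate_cell_image` — two-channel cell images (reporter +
  morphology) on a disk mask, with Gaussian puncta placed inside the mask
  and, optionally, puncta amplitude or read noise solved so that the
  noiseless in-mask CV equals a requested design value;
* :func:`simulate_cohort` / :func:`simulate_event_cohort` — longitudinal
  cohorts whose death and puncta-formation times follow proportional
  hazards with genotype-dependent log-hazards and lognormal day-1
  expression; the track form reports daily observations on the imaging
  grid, the event form emits the latent continuous times directly;
* :func:`simulate_decay_traces` — mono-exponential photoconverted-reporter
  decay per well with multiplicative noise and well/experiment nesting.

All generators are deterministic given their seed (``numpy`` Generator
seeded per call; the cohort generator derives independent substreams from
one :class:`numpy.random.SeedSequence`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flux import DecayTrace
from .frap import FrapTrace
from .puncta import TRACK_COLUMNS

__all__ = [
    "DEFAULT_FRAP_SCHEDULE",
    "DEFAULT_GROUPS",
    "DEFAULT_LOG_HAZARD_DEATH",
    "DEFAULT_LOG_HAZARD_PUNCTA",
    "SimulationError",
    "FrapSimParams",
    "ImageSimParams",
    "CohortSimParams",
    "DecaySimParams",
    "simulate_frap_trace",
    "simulate_frap_traces",
    "simulate_cell_image",
    "simulate_cohort",
    "simulate_event_cohort",
    "simulate_decay_traces",
]


class SimulationError(ValueError):
    """Invalid simulation parameters."""


def _frap_schedule() -> tuple[float, ...]:
    # first post-bleach frame at t=0, every 5 s to 60 s, then every 10 s to 300 s
    return tuple(np.concatenate([np.arange(0.0, 61.0, 5.0), np.arange(70.0, 301.0, 10.0)]))


DEFAULT_FRAP_SCHEDULE = _frap_schedule()

DEFAULT_GROUPS = ("iRFP", "WT", "A282V", "M446R", "P497H", "P497S", "P506T")

#: Default genotype log-hazards of death, ln(HR) vs the iRFP reference arm.
DEFAULT_LOG_HAZARD_DEATH = {
    "iRFP": 0.0,
    "WT": math.log(1.0775),
    "A282V": math.log(1.2866),
    "M446R": math.log(1.2392),
    "P497H": math.log(1.2045),
    "P497S": math.log(0.9539),
    "P506T": math.log(1.4332),
}

#: Default genotype log-hazards of puncta formation, ln(HR) vs WT. The iRFP
#: tag alone stays diffuse, so its puncta hazard is pushed near zero.
DEFAULT_LOG_HAZARD_PUNCTA = {
    "iRFP": -4.0,
    "WT": 0.0,
    "A282V": math.log(0.7909),
    "M446R": math.log(0.7497),
    "P497H": math.log(1.085),
    "P497S": math.log(0.6521),
    "P506T": math.log(1.6306),
}


# --------------------------------------------------------------------------
# FRAP traces
# --------------------------------------------------------------------------


@dataclass
class FrapSimParams:
    """Ground-truth recovery parameters and acquisition settings.

    ``noise_sd`` is in normalized-intensity units (pre-bleach = 1, bleach
    floor = 0). The emitted raw trace carries a baseline of ``scale`` with a
    bleach depth of ``depth * scale``, so the two-point normalization
    recovers the model exactly in the noiseless case.
    """

    mobile_fraction: float = 0.7
    rate_per_s: float = math.log(2.0) / 30.0
    noise_sd: float = 0.0
    schedule: tuple[float, ...] = DEFAULT_FRAP_SCHEDULE
    pre_bleach_count: int = 5
    seed: int = 0
    scale: float = 1000.0
    depth: float = 0.8  # bleach depth as a fraction of the baseline
    genotype: str = "WT"
    roi_radius_um: float = 3.7

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 3 or np.any(np.diff(sched) <= 0):
            raise SimulationError("schedule must be strictly increasing with >= 3 samples")
        if not math.isclose(sched[0], 0.0, abs_tol=1e-12):
            raise SimulationError("schedule must start at 0 (first post-bleach frame)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if not 0.0 <= self.mobile_fraction <= 1.5:
            raise SimulationError("mobile_fraction must lie in [0, 1.5]")
        if self.rate_per_s <= 0:
            raise SimulationError("rate_per_s must be positive")
        if self.pre_bleach_count < 2:
            raise SimulationError("need at least 2 pre-bleach samples")
        if not 0 < self.depth <= 1:
            raise SimulationError("depth must lie in (0, 1]")


def simulate_frap_trace(params: FrapSimParams, *, granule_id: str = "g0") -> FrapTrace:
    """One granule's raw bleach-recovery trace with ground truth attached.

    Pre-bleach samples sit at the baseline (``scale``); the first
    post-bleach sample sits at the bleached floor; recovery follows
    ``A (1 - exp(-tau t))`` scaled by the bleach depth. Gaussian noise of sd
    ``noise_sd`` (normalized units) is added to every sample. The attached
    ``truth`` dict records A, tau, and the raw-scale anchors needed to
    invert the scaling exactly.
    """
    rng = np.random.default_rng(params.seed)
    pre_times = -np.arange(params.pre_bleach_count, 0, -1, dtype=float)
    post_times = np.asarray(params.schedule, dtype=float)
    times = np.concatenate([pre_times, post_times])

    model_norm = np.concatenate(
        [
            np.ones(params.pre_bleach_count),
            params.mobile_fraction * (1.0 - np.exp(-params.rate_per_s * post_times)),
        ]
    )
    noise = rng.normal(0.0, params.noise_sd, size=times.size) if params.noise_sd > 0 else 0.0
    floor = params.scale * (1.0 - params.depth)
    raw = floor + params.scale * params.depth * (model_norm + noise)
    return FrapTrace(
        times=times,
        bleached_intensity=raw,
        granule_id=granule_id,
        genotype=params.genotype,
        roi_radius_um=params.roi_radius_um,
        truth={
            "mobile_fraction": params.mobile_fraction,
            "rate_per_s": params.rate_per_s,
            "noise_sd": params.noise_sd,
            "scale": params.scale,
            "depth": params.depth,
            "floor": floor,
        },
    )


def simulate_frap_traces(params: FrapSimParams, n_traces: int) -> list[FrapTrace]:
    """``n_traces`` independent traces with per-trace seeds derived from ``params.seed``."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_traces)
    return [
        simulate_frap_trace(replace(params, seed=int(s % 2**31)), granule_id=f"g{i}")
        for i, s in enumerate(seeds)
    ]


# --------------------------------------------------------------------------
# Cell images
# --------------------------------------------------------------------------


@dataclass
class ImageSimParams:
    """Two-channel single-cell image with a disk mask and Gaussian puncta.

    When ``target_cv`` is set, the generator solves for the parameter that
    controls in-mask contrast — the puncta amplitude when ``puncta_count >
    0``, otherwise the read-noise sd — so that the design CV of the
    noiseless (respectively noise-only) reporter pattern equals it.
    """

    image_shape: tuple[int, int] = (64, 64)
    cell_radius: float = 20.0
    background_level: float = 100.0
    cell_level: float = 1000.0
    puncta_count: int = 0
    puncta_amplitude: float = 8000.0
    puncta_sigma: float = 1.5
    read_noise_sd: float = 10.0
    seed: int = 0
    target_cv: float | None = None

    def __post_init__(self) -> None:
        if self.puncta_count < 0:
            raise SimulationError("puncta_count must be >= 0")
        if self.cell_radius <= 0:
            raise SimulationError("cell_radius must be positive")
        if self.cell_radius + 1 > min(self.image_shape) / 2:
            raise SimulationError("cell does not fit in the frame")
        if self.read_noise_sd < 0:
            raise SimulationError("read_noise_sd must be non-negative")
        if self.target_cv is not None and self.target_cv < 0:
            raise SimulationError("target_cv must be non-negative")

    @classmethod
    def diffuse_preset(cls, target_cv: float = 0.35, seed: int = 0, **kw) -> "ImageSimParams":
        """Diffuse cell whose in-mask CV is set by read noise alone."""
        return cls(puncta_count=0, target_cv=target_cv, seed=seed, **kw)

    @classmethod
    def punctate_preset(
        cls, target_cv: float = 1.0, puncta_count: int = 5, seed: int = 0, **kw
    ) -> "ImageSimParams":
        """Punctate cell whose puncta amplitude is solved for a design CV."""
        return cls(puncta_count=puncta_count, target_cv=target_cv, seed=seed, **kw)


@dataclass
class ImageTruth:
    """Ground truth emitted with each simulated image."""

    mask: np.ndarray
    design_cv: float | None
    realized_cv: float
    puncta_centers: np.ndarray  # (k, 2) row/col coordinates
    params: ImageSimParams


def _disk_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def simulate_cell_image(
    params: ImageSimParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ImageTruth]:
    """Generate (reporter, morphology, mask, truth) for one synthetic cell.

    The morphology channel is a uniform disk (used downstream for Otsu
    segmentation); the reporter channel adds Gaussian puncta whose centers
    fall inside the mask. ``truth.realized_cv`` is the CV actually measured
    on the emitted reporter pixels inside the mask.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    mask = _disk_mask(shape, params.cell_radius)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0

    spots = np.zeros(shape, dtype=float)
    centers = np.empty((0, 2), dtype=float)
    if params.puncta_count > 0:
        # rejection-free placement: uniform in a disk that keeps the bulk of
        # each spot inside the mask
        r_max = max(params.cell_radius - 2.0 * params.puncta_sigma, 1.0)
        r = r_max * np.sqrt(rng.uniform(size=params.puncta_count))
        theta = rng.uniform(0.0, 2.0 * math.pi, size=params.puncta_count)
        centers = np.column_stack([cy + r * np.sin(theta), cx + r * np.cos(theta)])
        for py, px in centers:
            spots += np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * params.puncta_sigma**2)
            )

    amplitude = params.puncta_amplitude
    read_noise = params.read_noise_sd
    if params.target_cv is not None:
        if params.puncta_count > 0:
            s = spots[mask]
            mean_s, sd_s = s.mean(), s.std()
            denom = sd_s - params.target_cv * mean_s
            if denom <= 0:
                raise SimulationError(
                    "target_cv unreachable with this puncta layout; "
                    "use fewer/sharper puncta"
                )
            amplitude = params.target_cv * params.cell_level / denom
        else:
            read_noise = params.target_cv * params.cell_level

    reporter = np.where(mask, params.cell_level + amplitude * spots, params.background_level)
    morphology = np.where(mask, params.cell_level, params.background_level).astype(float)
    if read_noise > 0:
        reporter = reporter + rng.normal(0.0, read_noise, size=shape)
        morphology = morphology + rng.normal(0.0, params.read_noise_sd, size=shape)

    in_mask = reporter[mask]
    realized_cv = float(in_mask.std() / in_mask.mean())
    truth = ImageTruth(
        mask=mask,
        design_cv=params.target_cv,
        realized_cv=realized_cv,
        puncta_centers=centers,
        params=params,
    )
    return reporter, morphology, mask, truth


# --------------------------------------------------------------------------
# Longitudinal cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortSimParams:
    """Longitudinal cohort under genotype-dependent proportional hazards.

    Per cell: a genotype, an experiment (stratum), a lognormal day-1
    reporter intensity, and latent exponential death and puncta-formation
    times whose rates are ``baseline * exp(log_hazard_group + effect * z)``
    with ``z`` the standardized log-intensity. The event clock starts at the
    first imaging day (every cell is observed alive at least once); puncta
    times start at 0 so a fraction of cells is already punctate on day 1.

    Observed per-day CVs are drawn from a truncated-normal punctate regime
    (mean 1.0, sd 0.15, > 0.62) once the latent puncta time has passed and
    from a diffuse regime (mean 0.35, sd 0.10, >= 0) before — straddling
    the 0.62 classifier threshold cleanly.
    """

    n_cells: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    log_hazard_death: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HAZARD_DEATH))
    log_hazard_puncta: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HAZARD_PUNCTA))
    baseline_rate_death: float = 0.13  # per day; ~30% of reference cells censored at day 10
    baseline_rate_puncta: float = 0.15  # per day
    expression_meanlog: float = 6.2
    expression_sdlog: float = 0.6
    expression_effect_death: float = 0.0  # log-hazard per SD of log day-1 intensity
    expression_effect_puncta: float = 0.0
    censor_day: float = 10.0
    imaging_days: tuple[float, ...] = tuple(float(d) for d in range(1, 11))
    n_experiments: int = 3
    wells_per_experiment: int = 8
    seed: int = 0
    punctate_cv_mean: float = 1.0
    punctate_cv_sd: float = 0.15
    diffuse_cv_mean: float = 0.35
    diffuse_cv_sd: float = 0.10
    cv_threshold: float = 0.62

    def __post_init__(self) -> None:
        if not self.groups:
            raise SimulationError("groups must be non-empty")
        if self.baseline_rate_death <= 0 or self.baseline_rate_puncta <= 0:
            raise SimulationError("baseline rates must be positive")
        days = np.asarray(self.imaging_days, dtype=float)
        if days.size == 0 or np.any(np.diff(days) <= 0):
            raise SimulationError("imaging_days must be strictly increasing")
        if self.censor_day < days[0]:
            raise SimulationError("censor_day must not precede the first imaging day")
        for g in self.groups:
            self.log_hazard_death.setdefault(g, 0.0)
            self.log_hazard_puncta.setdefault(g, 0.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Resampling-based truncated normal (low bound only)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def _latent_cells(params: CohortSimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_cells
    group = np.asarray(params.groups)[np.arange(n) % len(params.groups)]
    experiment = np.array([f"exp{1 + i % params.n_experiments}" for i in range(n)])
    well = np.array(
        [
            f"w{1 + (i // params.n_experiments) % params.wells_per_experiment}"
            for i in range(n)
        ]
    )
    log_i = rng.normal(params.expression_meanlog, params.expression_sdlog, size=n)
    z = (log_i - params.expression_meanlog) / params.expression_sdlog
    lhd = np.array([params.log_hazard_death[g] for g in group])
    lhp = np.array([params.log_hazard_puncta[g] for g in group])
    rate_death = params.baseline_rate_death * np.exp(lhd + params.expression_effect_death * z)
    rate_puncta = params.baseline_rate_puncta * np.exp(lhp + params.expression_effect_puncta * z)
    first_day = float(np.asarray(params.imaging_days)[0])
    # death clock starts at the first imaging day so every cell is seen alive once;
    # the puncta clock starts at 0 so day-1 prevalent puncta exist
    death_time = first_day + rng.exponential(1.0 / rate_death)
    puncta_time = rng.exponential(1.0 / rate_puncta)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "genotype": group,
            "experiment_id": experiment,
            "well": well,
            "day1_intensity": np.exp(log_i),
            "z_expression": z,
            "log_hazard_death": lhd,
            "log_hazard_puncta": lhp,
            "death_time": death_time,
            "puncta_time": puncta_time,
        }
    )


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a longitudinal cohort; returns ``(tracks, truth)``.

    ``tracks`` is the long-format observation table (one row per cell per
    imaging day, ending at the first day the cell is seen dead or at the
    censoring day). ``truth`` records per-cell latent event times, log-
    hazards and expression, sufficient to score every downstream estimator.
    """
    seq = np.random.SeedSequence(params.seed).spawn(2)
    rng_latent = np.random.default_rng(seq[0])
    rng_obs = np.random.default_rng(seq[1])
    truth = _latent_cells(params, rng_latent)
    days = np.asarray(params.imaging_days, dtype=float)
    days = days[days <= params.censor_day]

    rows: list[dict] = []
    for cell in truth.itertuples(index=False):
        for day in days:
            if day >= cell.death_time:
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "experiment_id": cell.experiment_id,
                        "well": cell.well,
                        "genotype": cell.genotype,
                        "day": day,
                        "reporter_mean": np.nan,
                        "reporter_sd": np.nan,
                        "cv": np.nan,
                        "alive": False,
                    }
                )
                break
            punctate = cell.puncta_time <= day
            if punctate:
                cv = float(
                    _truncated_normal(
                        rng_obs,
                        params.punctate_cv_mean,
                        params.punctate_cv_sd,
                        params.cv_threshold,
                        1,
                    )[0]
                )
            else:
                cv = float(
                    _truncated_normal(
                        rng_obs, params.diffuse_cv_mean, params.diffuse_cv_sd, 0.0, 1
                    )[0]
                )
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "experiment_id": cell.experiment_id,
                    "well": cell.well,
                    "genotype": cell.genotype,
                    "day": day,
                    "reporter_mean": cell.day1_intensity,
                    "reporter_sd": cv * cell.day1_intensity,
                    "cv": cv,
                    "alive": True,
                }
            )
    tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return tracks, truth


def simulate_event_cohort(
    params: CohortSimParams, endpoint: str = "death"
) -> pd.DataFrame:
    """Continuous-time event records under the same proportional hazards.

    Emits, per cell, the latent event time administratively censored at
    ``censor_day`` (measured from the first imaging day for death, from 0
    for puncta formation) — the cohort as the hazard model sees it, without
    the imaging-grid discretization of :func:`simulate_cohort`. Columns:
    ``cell_id, group, stratum, time, event, day1_intensity, z_expression``.
    """
    if endpoint not in ("death", "puncta"):
        raise SimulationError("endpoint must be 'death' or 'puncta'")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    truth = _latent_cells(params, rng)
    first_day = float(np.asarray(params.imaging_days)[0])
    if endpoint == "death":
        latent = truth["death_time"].to_numpy() - first_day
        horizon = params.censor_day - first_day
    else:
        latent = truth["puncta_time"].to_numpy()
        horizon = params.censor_day
    time = np.minimum(latent, horizon)
    event = (latent <= horizon).astype(int)
    return pd.DataFrame(
        {
            "cell_id": truth["cell_id"],
            "group": truth["genotype"],
            "stratum": truth["experiment_id"],
            "time": time,
            "event": event,
            "day1_intensity": truth["day1_intensity"],
            "z_expression": truth["z_expression"],
        }
    )


# --------------------------------------------------------------------------
# Photoconversion decay traces
# --------------------------------------------------------------------------


@dataclass
class DecaySimParams:
    """Mono-exponential reporter decay with well/experiment nesting.

    Hourly values follow ``(T1 - T0) * exp(-k t) + T0`` with
    ``k = ln 2 / half_life``; multiplicative Gaussian noise of coefficient
    ``noise_cv`` perturbs each hourly sample. ``T0`` and ``T1`` anchors are
    emitted noiselessly.
    """

    half_life_h: float = 10.0
    t0_level: float = 100.0
    t1_level: float = 1100.0
    noise_cv: float = 0.0
    hours: tuple[float, ...] = tuple(float(h) for h in range(1, 15))
    n_wells: int = 6
    n_experiments: int = 3
    condition: str = "DMSO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise SimulationError("half_life_h must be positive")
        if self.t1_level <= self.t0_level:
            raise SimulationError("t1_level must exceed t0_level")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be non-negative")


def simulate_decay_traces(params: DecaySimParams) -> tuple[list[DecayTrace], pd.DataFrame]:
    """All wells of all experiments for one condition; returns ``(traces, truth)``."""
    rng = np.random.default_rng(params.seed)
    k = math.log(2.0) / params.half_life_h
    t = np.asarray(params.hours, dtype=float)
    model = (params.t1_level - params.t0_level) * np.exp(-k * t) + params.t0_level
    traces = []
    truth_rows = []
    for e in range(1, params.n_experiments + 1):
        for w in range(1, params.n_wells + 1):
            noise = (
                rng.normal(0.0, params.noise_cv, size=t.size) if params.noise_cv > 0 else 0.0
            )
            values = model * (1.0 + noise)
            traces.append(
                DecayTrace(
                    well_id=f"w{w}",
                    experiment_id=f"exp{e}",
                    condition=params.condition,
                    t0=params.t0_level,
                    t1=params.t1_level,
                    times_h=t,
                    values=values,
                )
            )
            truth_rows.append(
                {
                    "well_id": f"w{w}",
                    "experiment_id": f"exp{e}",
                    "condition": params.condition,
                    "half_life_h": params.half_life_h,
                    "k_per_h": k,
                }
            )
    return traces, pd.DataFrame(truth_rows)
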