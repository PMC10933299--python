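"""Optical-pulse-labeling turnover analysis (photoconvertible LC3 reporter).

A photoconvertible autophagy reporter (Dendra2-LC3) is pulse-converted to
its red form; the red signal then decays as the labeled protein pool is
degraded, so the decay half-life reads out autophagic flux. Per well the
measured quantities are a pre-conversion background intensity ``T0``, the
post-conversion peak ``T1`` (time zero), and hourly intensities ``Tx``.

Two normalization conventions are supported:

* ``"as-printed"``: ``Tx / (T1 - T0)`` — the conversion-depth ratio with no
  background subtraction, so the t=0 value is ``T1/(T1-T0) >= 1``;
* ``"background-subtracted"``: ``(Tx - T0) / (T1 - T0)`` — starts exactly
  at 1 and decays toward 0, matching the pure-exponential model.

The half-life comes from a least-squares fit of ``y = exp(-k t)`` (scale
fixed at 1 by default; a free scale accommodates the as-printed offset),
with ``t_half = ln 2 / k``. Wells aggregate superplot-style: well fits are
averaged within an experiment, and the condition-level mean/SD/SEM are
taken across experiment means (biological, not technical, replication).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "DecayTrace",
    "FluxResult",
    "FluxError",
    "NonDecayingError",
    "normalize_decay",
    "fit_halflife",
    "analyze_trace",
    "aggregate_flux",
]

NORMALIZATION_MODES = ("as-printed", "background-subtracted")


class FluxError(ValueError):
    """Invalid optical-pulse-labeling input."""


class NonDecayingError(FluxError):
    """The fitted series does not decay (k_hat <= 0)."""


@dataclass
class DecayTrace:
    """Photoconverted-channel intensities for one well."""

    well_id: str
    experiment_id: str
    condition: str
    t0: float  # pre-conversion background intensity
    t1: float  # post-conversion peak intensity (defines time zero)
    times_h: np.ndarray  # hours after conversion, all > 0
    values: np.ndarray  # red-channel intensities at times_h

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t1 <= self.t0:
            raise FluxError("zero conversion depth: T1 must exceed T0")
        if self.times_h.shape != self.values.shape:
            raise FluxError("times and values lengths differ")
        if np.any(self.times_h <= 0) or np.any(np.diff(self.times_h) <= 0):
            raise FluxError("times must be positive and strictly increasing")


@dataclass
class FluxResult:
    """Fitted turnover parameters for one well."""

    well_id: str
    experiment_id: str
    condition: str
    k_per_h: float
    half_life_h: float
    fit_rss: float
    n_timepoints: int
    mode: str


def normalize_decay(trace: DecayTrace, mode: str = "as-printed") -> np.ndarray:
    """Normalize hourly intensities by the conversion depth ``T1 - T0``."""
    if mode not in NORMALIZATION_MODES:
        raise FluxError(f"unknown normalization mode {mode!r}")
    depth = trace.t1 - trace.t0
    if mode == "as-printed":
        return trace.values / depth
    return (trace.values - trace.t0) / depth


def _decay_model(t: np.ndarray, k: float, scale: float) -> np.ndarray:
    return scale * np.exp(-k * t)


def fit_halflife(
    times_h: np.ndarray,
    normalized: np.ndarray,
    *,
    free_scale: bool = False,
    log_linear: bool = False,
    well_id: str = "w0",
    experiment_id: str = "e0",
    condition: str = "",
    mode: str = "background-subtracted",
) -> FluxResult:
    """Fit ``y = s * exp(-k t)`` and report ``t_half = ln 2 / k``.

    With ``free_scale=False`` (default) the scale is fixed at 1, matching
    the background-subtracted normalization where y(0) = 1 by construction.
    ``log_linear=True`` instead regresses ``log y`` on ``t`` (requires
    strictly positive values); the default nonlinear fit is robust to
    near-zero late samples.

    Raises :class:`NonDecayingError` when the estimated rate is not
    positive (flat or rising series).
    """
    times_h = np.asarray(times_h, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if times_h.size < 4:
        raise FluxError("need at least 4 timepoints to fit a decay")
    if np.any(times_h <= 0):
        raise FluxError("fit times must be strictly after conversion (t > 0)")

    if log_linear:
        if np.any(y <= 0):
            raise FluxError("log-linear fit requires positive values")
        res = linregress(times_h, np.log(y))
        k_hat = -float(res.slope)
        scale = float(np.exp(res.intercept)) if free_scale else 1.0
        if k_hat <= 1e-9:
            raise NonDecayingError("series does not decay (log-linear slope >= 0)")
        rss = float(np.sum((y - _decay_model(times_h, k_hat, scale)) ** 2))
    else:
        # crude rate guess from endpoints; clipped into the fit bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            span = y[0] / y[-1] if y[-1] > 0 else np.inf
        k0 = math.log(span) / (times_h[-1] - times_h[0]) if np.isfinite(span) and span > 1 else 0.1
        k0 = float(np.clip(k0, 1e-6, 50.0))
        if free_scale:
            popt, _ = curve_fit(
                _decay_model,
                times_h,
                y,
                p0=(k0, max(float(y[0]), 1e-6)),
                bounds=([1e-9, 1e-9], [100.0, 1e6]),
                xtol=1e-14,
                ftol=1e-14,
                maxfev=20000,
            )
            k_hat, scale = float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                lambda t, k: _decay_model(t, k, 1.0),
                times_h,
                y,
                p0=(k0,),
                bounds=([1e-9], [100.0]),
                xtol=1e-14,
                ftol=1e-14,
                maxfev=20000,
            )
            k_hat, scale = float(popt[0]), 1.0
        if k_hat <= 1e-4:  # half-life >> any 14 h assay: effectively flat
            raise NonDecayingError("series does not decay (k_hat at lower bound)")
        rss = float(np.sum((y - _decay_model(times_h, k_hat, scale)) ** 2))

    return FluxResult(
        well_id=well_id,
        experiment_id=experiment_id,
        condition=condition,
        k_per_h=k_hat,
        half_life_h=math.log(2.0) / k_hat,
        fit_rss=rss,
        n_timepoints=int(times_h.size),
        mode=mode,
    )


def analyze_trace(
    trace: DecayTrace,
    mode: str = "background-subtracted",
    *,
    free_scale: bool = False,
    log_linear: bool = False,
) -> FluxResult:
    """Normalize one well's trace and fit its half-life."""
    normalized = normalize_decay(trace, mode)
    return fit_halflife(
        trace.times_h,
        normalized,
        free_scale=free_scale or mode == "as-printed",
        log_linear=log_linear,
        well_id=trace.well_id,
        experiment_id=trace.experiment_id,
        condition=trace.condition,
        mode=mode,
    )


def aggregate_flux(results: list[FluxResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Superplot-style nested aggregation of per-well half-lives.

    Returns ``(per_experiment, summary)``: per-experiment means of the well
    half-lives, and per-condition grand mean, SD and SEM across experiment
    means with n = number of experiments. SEM (and SD) are missing when a
    condition has a single experiment — technical replicates within one
    experiment are not independent.
    """
    if not results:
        raise FluxError("no flux results to aggregate")
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "experiment_id": [r.experiment_id for r in results],
            "well_id": [r.well_id for r in results],
            "half_life_h": [r.half_life_h for r in results],
        }
    )
    per_experiment = (
        df.groupby(["condition", "experiment_id"])["half_life_h"]
        .agg(n_wells="size", mean="mean")
        .reset_index()
    )
    summary = (
        per_experiment.groupby("condition")["mean"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    return per_experiment, summary
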