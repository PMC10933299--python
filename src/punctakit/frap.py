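"""Fluorescence recovery after photobleaching (FRAP) analysis.

A circular region of a fluorescent granule is photobleached and its
fluorescence is followed over time. Recovery of the bleached region reports
the mobility of molecules inside the structure: liquid-like condensates
exchange material quickly and recover most of their signal, gels and
aggregates do not.

The analysis chain implemented here:

1. ``normalize_frap_trace`` — optional bleached/whole-granule ratio
   correction, then a two-point affine normalization that sets the mean of
   the pre-bleach samples to 1 and the first post-bleach sample to 0.
2. ``fit_recovery`` — least-squares fit of the single-exponential model
   ``y(t) = A * (1 - exp(-tau * t))`` where ``A`` is the mobile fraction and
   ``tau`` the recovery rate.
3. Derived physics: half-time ``t_half = ln 2 / tau``, effective diffusion
   coefficient ``D = 0.88 * r_roi**2 / (4 * t_half)`` for a bleach spot of
   radius ``r_roi``, and apparent viscosity from the Einstein–Stokes
   relation ``D = k_B * T / (6 * pi * eta * r_s)`` given a Stokes radius
   ``r_s`` for the diffusing species.

Conventions: time zero is the first post-bleach frame; pre-bleach samples
carry negative times and never enter the fit. The mobile fraction reported
is the fitted plateau ``A``, not the last observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_STOKES_RADIUS_NM",
    "DEFAULT_ROI_RADIUS_UM",
    "FrapError",
    "FrapFitError",
    "FrapTrace",
    "FrapFit",
    "normalize_frap_trace",
    "fit_recovery",
    "half_time",
    "diffusion_coefficient",
    "stokes_radius",
    "viscosity",
    "analyze_trace",
    "summarize_recovery",
]

BOLTZMANN_J_PER_K = 1.380649e-23
#: Cell-culture temperature; the assay is performed on live cells at 37 C.
DEFAULT_TEMPERATURE_K = 310.0
#: Stokes radius assumed for the GFP-tagged diffusing species, nanometres.
DEFAULT_STOKES_RADIUS_NM = 4.5
#: Radius of the circular bleach region of interest, micrometres.
DEFAULT_ROI_RADIUS_UM = 3.7


class FrapError(ValueError):
    """Invalid FRAP input (trace shape, degenerate normalization, ...)."""


class FrapFitError(FrapError):
    """Recovery fit failed (unidentifiable parameters or non-convergence)."""


@dataclass
class FrapTrace:
    """One granule's raw bleach-recovery time series.

    ``times`` are seconds relative to the first post-bleach frame (= 0);
    pre-bleach samples carry negative times. Intensities are integrated
    densities in arbitrary units. ``whole_intensity``, when present, is the
    simultaneously measured whole-granule signal used for ratio correction
    against acquisition bleaching.
    """

    times: np.ndarray
    bleached_intensity: np.ndarray
    whole_intensity: np.ndarray | None = None
    granule_id: str = "g0"
    genotype: str = "WT"
    roi_radius_um: float = DEFAULT_ROI_RADIUS_UM
    truth: dict | None = None  # ground truth attached by the simulator

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached_intensity = np.asarray(self.bleached_intensity, dtype=float)
        if self.whole_intensity is not None:
            self.whole_intensity = np.asarray(self.whole_intensity, dtype=float)
            if self.whole_intensity.shape != self.times.shape:
                raise FrapError("whole_intensity length does not match times")
        if self.times.shape != self.bleached_intensity.shape:
            raise FrapError("bleached_intensity length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise FrapError("times must be strictly increasing")
        if self.pre_mask.sum() < 2:
            raise FrapError("need at least 2 pre-bleach samples (negative times)")
        if self.post_mask.sum() < 3:
            raise FrapError("need at least 3 post-bleach samples")
        if not math.isclose(self.times[self.post_mask][0], 0.0, abs_tol=1e-12):
            raise FrapError("first post-bleach sample must be at time 0")
        if np.any(self.bleached_intensity < 0):
            raise FrapError("intensities must be non-negative")
        if self.roi_radius_um <= 0:
            raise FrapError("roi_radius_um must be positive")

    @property
    def pre_mask(self) -> np.ndarray:
        return self.times < 0

    @property
    def post_mask(self) -> np.ndarray:
        return self.times >= 0


@dataclass
class FrapFit:
    """Fitted recovery parameters and derived physical quantities."""

    mobile_fraction: float
    rate_per_s: float
    t_half_s: float
    fit_rss: float
    n_points: int
    converged: bool
    granule_id: str = "g0"
    genotype: str = "WT"
    diffusion_um2_per_s: float = float("nan")
    viscosity_pa_s: float = float("nan")
    stokes_radius_nm: float = float("nan")
    temperature_k: float = float("nan")


def normalize_frap_trace(trace: FrapTrace) -> np.ndarray:
    """Normalize a raw trace to the standard 0–1 recovery scale.

    When a whole-granule channel is present the per-timepoint ratio
    bleached/whole is formed first (corrects for acquisition photobleaching
    of the whole structure). The affine map then sends the mean of the
    pre-bleach values to 1 and the first post-bleach value to 0.

    Returns a float array aligned with ``trace.times``. Idempotent: applying
    it to an already-normalized trace is the identity.
    """
    if trace.whole_intensity is not None:
        if np.any(trace.whole_intensity <= 0):
            raise FrapError("whole_intensity must be positive for ratio correction")
        y = trace.bleached_intensity / trace.whole_intensity
    else:
        y = trace.bleached_intensity.astype(float)
    pre_mean = y[trace.pre_mask].mean()
    y0 = y[trace.post_mask][0]
    depth = pre_mean - y0
    if depth == 0:
        raise FrapError("zero bleach depth: pre-bleach mean equals first post-bleach value")
    return (y - y0) / depth


def _recovery_model(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * (1.0 - np.exp(-tau * t))


def fit_recovery(
    times: np.ndarray,
    normalized: np.ndarray,
    *,
    granule_id: str = "g0",
    genotype: str = "WT",
) -> FrapFit:
    """Least-squares fit of ``y(t) = A (1 - exp(-tau t))`` to a recovery.

    Only samples with ``t >= 0`` are used; the first must be at t = 0.
    Bounds: ``A`` in [0, 1.5] (granules can overshoot their pre-bleach ratio
    slightly), ``tau`` in (0, 10] per second. Initialization: ``A0`` from the
    tail of the series, ``tau0`` from the first crossing of ``A0 / 2``.

    Raises :class:`FrapFitError` for an all-zero series (tau is
    unidentifiable when there is no recovery signal) or non-convergence.
    """
    times = np.asarray(times, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    post = times >= 0
    t = times[post]
    y = normalized[post]
    if t.size < 3:
        raise FrapError("need at least 3 post-bleach samples to fit")
    if not math.isclose(t[0], 0.0, abs_tol=1e-12):
        raise FrapError("post-bleach times must start at 0")
    if np.allclose(y, 0.0):
        raise FrapFitError("unidentifiable tau: series shows no recovery")

    a0 = float(np.clip(np.max(y[-3:]), 1e-3, 1.5))
    above = np.nonzero((y >= a0 / 2) & (t > 0))[0]
    if above.size:
        tau0 = math.log(2.0) / t[above[0]]
    else:
        tau0 = math.log(2.0) / (t[-1] / 2.0)
    tau0 = float(np.clip(tau0, 1e-6, 10.0))

    try:
        popt, _ = curve_fit(
            _recovery_model,
            t,
            y,
            p0=(a0, tau0),
            bounds=([0.0, 1e-9], [1.5, 10.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - solver pathologies
        raise FrapFitError(f"recovery fit did not converge: {exc}") from exc
    a_hat, tau_hat = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _recovery_model(t, a_hat, tau_hat)) ** 2))
    return FrapFit(
        mobile_fraction=a_hat,
        rate_per_s=tau_hat,
        t_half_s=half_time(tau_hat),
        fit_rss=rss,
        n_points=int(t.size),
        converged=True,
        granule_id=granule_id,
        genotype=genotype,
    )


def half_time(tau_per_s: float) -> float:
    """Half-maximal recovery time, ``t_half = ln 2 / tau`` (seconds)."""
    if tau_per_s <= 0:
        raise FrapError("tau must be positive")
    return math.log(2.0) / tau_per_s


def diffusion_coefficient(roi_radius_um: float, t_half_s: float) -> float:
    """Effective diffusion coefficient of the recovering species, um^2/s.

    Uses the circular-spot approximation ``D = 0.88 r^2 / (4 t_half)`` with
    the bleach ROI radius ``r`` in micrometres.
    """
    if roi_radius_um <= 0 or t_half_s <= 0:
        raise FrapError("roi_radius_um and t_half_s must be positive")
    return 0.88 * roi_radius_um**2 / (4.0 * t_half_s)


def stokes_radius(molecular_weight_da: float) -> float:
    """Minimum Stokes radius of a globular protein of mass M daltons, in nm.

    ``R_min = (0.66 M)^(1/3)`` yields angstroms for M in daltons; the result
    is converted to nanometres. This is a lower bound (a perfect sphere);
    tagged fusion proteins are typically somewhat larger.
    """
    if molecular_weight_da <= 0:
        raise FrapError("molecular weight must be positive")
    return (0.66 * molecular_weight_da) ** (1.0 / 3.0) / 10.0


def viscosity(
    diffusion_um2_per_s: float,
    stokes_radius_nm: float = DEFAULT_STOKES_RADIUS_NM,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Apparent viscosity from the Einstein–Stokes relation, Pa*s.

    ``eta = k_B T / (6 pi D r_s)`` with D converted from um^2/s and r_s from
    nm to SI units.
    """
    if diffusion_um2_per_s <= 0 or stokes_radius_nm <= 0 or temperature_k <= 0:
        raise FrapError("all Einstein-Stokes inputs must be positive")
    d_si = diffusion_um2_per_s * 1e-12  # m^2/s
    r_si = stokes_radius_nm * 1e-9  # m
    return BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * d_si * r_si)


def analyze_trace(
    trace: FrapTrace,
    *,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    stokes_radius_nm: float = DEFAULT_STOKES_RADIUS_NM,
) -> FrapFit:
    """Full per-granule chain: normalize, fit, derive t_half, D and eta."""
    normalized = normalize_frap_trace(trace)
    fit = fit_recovery(
        trace.times, normalized, granule_id=trace.granule_id, genotype=trace.genotype
    )
    fit.diffusion_um2_per_s = diffusion_coefficient(trace.roi_radius_um, fit.t_half_s)
    fit.viscosity_pa_s = viscosity(fit.diffusion_um2_per_s, stokes_radius_nm, temperature_k)
    fit.stokes_radius_nm = stokes_radius_nm
    fit.temperature_k = temperature_k
    return fit


def summarize_recovery(
    times: np.ndarray,
    series: list[np.ndarray],
    fits: list[FrapFit] | None = None,
) -> pd.DataFrame:
    """Per-timepoint mean +/- SEM across granules of one group.

    ``series`` are normalized recoveries sampled on the shared post-bleach
    grid ``times``. When ``fits`` are given, a second pair of columns holds
    the plateau-normalized curves (each granule divided by its fitted mobile
    fraction before averaging) that emphasize kinetics over extent.
    SEM uses the sample standard deviation and is 0 for a single granule.
    """
    if not series:
        raise FrapError("empty group: no recovery series to summarize")
    times = np.asarray(times, dtype=float)
    stack = np.vstack([np.asarray(s, dtype=float) for s in series])
    if stack.shape[1] != times.size:
        raise FrapError("series length does not match times")
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    out = pd.DataFrame({"time_s": times, "mean": mean, "sem": sem, "n": n})
    if fits is not None:
        if len(fits) != n:
            raise FrapError("fits length does not match series")
        plateaus = np.array([f.mobile_fraction for f in fits], dtype=float)
        if np.any(plateaus <= 0):
            raise FrapError("plateau normalization requires positive mobile fractions")
        norm_stack = stack / plateaus[:, None]
        out["mean_plateau_norm"] = norm_stack.mean(axis=0)
        out["sem_plateau_norm"] = (
            norm_stack.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else 0.0
        )
    return out
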