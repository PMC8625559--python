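"""Permeation metrics: steady-state flux, lag time, permeability
coefficient, normalized AUC, and permeability class."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .timecourse import CumulativeProfile

__all__ = [
    "FLAG_NEGATIVE_FLUX",
    "FLAG_UNDEFINED_LOGPM",
    "FitWindow",
    "FluxFit",
    "PermeationMetrics",
    "SolventSummary",
    "fit_flux",
    "permeability_coefficient",
    "auc_normalized",
    "classify_permeability",
    "analyze_profile",
    "summarize_replicates",
]

FLAG_NEGATIVE_FLUX = "negative_flux"
FLAG_UNDEFINED_LOGPM = "undefined_logPm"

#: Contiguous permeability class cutpoints on log10(cm/h):
#: low below the first, high above the second, medium in between.
DEFAULT_CLASS_CUTPOINTS = (-2.4, -1.2)


@dataclass(frozen=True)
class FitWindow:
    """Time window (hours) of the linear range used for the flux fit.

    ``include_origin`` adds the implicit (0, 0) point so a two-parameter
    line can be fit even with few early samples.
    """

    t_min: float = 0.0
    t_max: float = 0.5
    include_origin: bool = True

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")


@dataclass(frozen=True)
class FluxFit:
    J_ug_cm2_h: float
    lag_min: float
    intercept_ug_cm2: float
    n_points: int
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PermeationMetrics:
    """Per-replicate permeation summary for one solvent."""

    solvent_code: str
    replicate: int
    J_ug_cm2_h: float
    lag_min: float
    logPm: float
    auc_norm: float
    Q_horizon_ug_cm2: float
    perm_class: str
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SolventSummary:
    """Mean +/- sample SD across replicates (SD is NaN for n = 1)."""

    solvent_code: str
    n: int
    C_D_mg_ml: float
    J_mean: float
    J_sd: float
    lag_min_mean: float
    lag_min_sd: float
    Q_horizon_mean: float
    Q_horizon_sd: float
    auc_norm_mean: float
    auc_norm_sd: float
    logPm_mean: float
    logPm_sd: float
    perm_class: str
    flags: frozenset[str] = frozenset()


def fit_flux(profile: CumulativeProfile, window: FitWindow | None = None) -> FluxFit:
    """Ordinary least squares of Q on t over the linear window.

    Flux is the slope (ug cm-2 h-1); lag time is the x-intercept
    ``-intercept/slope`` expressed in minutes and clamped at 0. A
    negative slope is clamped to 0 with a flag.
    """
    window = window or FitWindow()
    t = profile.times_h
    q = profile.Q_ug_cm2
    mask = (t >= window.t_min) & (t <= window.t_max)
    t_fit = t[mask]
    q_fit = q[mask]
    if window.include_origin and not np.any(t_fit == 0.0):
        t_fit = np.concatenate(([0.0], t_fit))
        q_fit = np.concatenate(([0.0], q_fit))
    if t_fit.size < 2:
        raise ValueError("need at least 2 points in the fit window")
    if np.ptp(t_fit) == 0:
        raise ValueError("singular fit: all times in window are equal")

    slope, intercept = np.polyfit(t_fit, q_fit, 1)
    flags: set[str] = set()
    if slope < 0:
        flags.add(FLAG_NEGATIVE_FLUX)
        return FluxFit(0.0, 0.0, float(intercept), t_fit.size, frozenset(flags))
    lag_h = -intercept / slope if slope > 0 else 0.0
    lag_min = max(0.0, lag_h * 60.0)
    return FluxFit(float(slope), float(lag_min), float(intercept), t_fit.size, frozenset(flags))


def permeability_coefficient(J_ug_cm2_h: float, C_D_mg_ml: float) -> float:
    """log10 permeability coefficient, log10(J / C_D), in log10(cm/h).

    C_D is converted from mg/mL to ug/cm3 (x1000) so that J/C_D carries
    units of cm/h. Returns NaN for J <= 0 (undefined on the log scale;
    callers attach :data:`FLAG_UNDEFINED_LOGPM`).
    """
    if C_D_mg_ml <= 0:
        raise ValueError("donor concentration must be > 0")
    if J_ug_cm2_h <= 0:
        return math.nan
    return math.log10(J_ug_cm2_h / (C_D_mg_ml * 1000.0))


def auc_normalized(
    profile: CumulativeProfile,
    horizon_h: float,
    C_D_mg_ml: float,
) -> float:
    """Trapezoidal integral of Q(t) from 0 to the horizon, over C_D.

    The implicit origin (0, 0) is included; Q at the horizon is linearly
    interpolated when the horizon falls between samples. Units:
    (ug h / cm2) / (mg/mL).
    """
    if C_D_mg_ml <= 0:
        raise ValueError("donor concentration must be > 0")
    t = np.concatenate(([0.0], profile.times_h))
    q = np.concatenate(([0.0], profile.Q_ug_cm2))
    if horizon_h > t[-1] + 1e-9:
        raise ValueError(f"horizon {horizon_h} h beyond last sample {t[-1]} h")
    q_h = float(np.interp(horizon_h, t, q))
    keep = t < horizon_h
    tt = np.concatenate((t[keep], [horizon_h]))
    qq = np.concatenate((q[keep], [q_h]))
    return float(np.trapezoid(qq, tt)) / C_D_mg_ml


def classify_permeability(
    logPm: float,
    cutpoints: tuple[float, float] = DEFAULT_CLASS_CUTPOINTS,
) -> str:
    """Classify into low / medium / high by contiguous logPm bands.

    Strict inequalities at both cutpoints; NaN maps to ``undefined``.
    """
    low_below, high_above = cutpoints
    if not low_below < high_above:
        raise ValueError("cutpoints must be ordered (low_below < high_above)")
    if math.isnan(logPm):
        return "undefined"
    if logPm < low_below:
        return "low"
    if logPm > high_above:
        return "high"
    return "medium"


def analyze_profile(
    profile: CumulativeProfile,
    C_D_mg_ml: float,
    window: FitWindow | None = None,
    horizon_h: float = 6.0,
    cutpoints: tuple[float, float] = DEFAULT_CLASS_CUTPOINTS,
) -> PermeationMetrics:
    """Run the full per-replicate metric stack on one cumulative profile."""
    fit = fit_flux(profile, window)
    logpm = permeability_coefficient(fit.J_ug_cm2_h, C_D_mg_ml) if fit.J_ug_cm2_h > 0 else math.nan
    flags = set(profile.flags) | set(fit.flags)
    if math.isnan(logpm):
        flags.add(FLAG_UNDEFINED_LOGPM)
    auc = auc_normalized(profile, horizon_h, C_D_mg_ml)
    t = np.concatenate(([0.0], profile.times_h))
    q = np.concatenate(([0.0], profile.Q_ug_cm2))
    q_horizon = float(np.interp(horizon_h, t, q))
    return PermeationMetrics(
        solvent_code=profile.solvent_code,
        replicate=profile.replicate,
        J_ug_cm2_h=fit.J_ug_cm2_h,
        lag_min=fit.lag_min,
        logPm=logpm,
        auc_norm=auc,
        Q_horizon_ug_cm2=q_horizon,
        perm_class=classify_permeability(logpm, cutpoints),
        flags=frozenset(flags),
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


def summarize_replicates(
    metrics: list[PermeationMetrics],
    C_D_mg_ml: float,
    cutpoints: tuple[float, float] = DEFAULT_CLASS_CUTPOINTS,
) -> SolventSummary:
    """Per-solvent mean +/- sample SD across replicates.

    logPm is averaged on the log scale (arithmetic mean of the per-
    replicate log values). The class is assigned from the mean logPm.
    """
    if not metrics:
        raise ValueError("need at least one replicate")
    codes = {m.solvent_code for m in metrics}
    if len(codes) != 1:
        raise ValueError(f"mixed solvent codes in replicate set: {sorted(codes)}")
    j_mean, j_sd = _mean_sd([m.J_ug_cm2_h for m in metrics])
    lag_mean, lag_sd = _mean_sd([m.lag_min for m in metrics])
    q_mean, q_sd = _mean_sd([m.Q_horizon_ug_cm2 for m in metrics])
    auc_mean, auc_sd = _mean_sd([m.auc_norm for m in metrics])
    logpm_mean, logpm_sd = _mean_sd([m.logPm for m in metrics])
    flags = frozenset().union(*(m.flags for m in metrics))
    return SolventSummary(
        solvent_code=metrics[0].solvent_code,
        n=len(metrics),
        C_D_mg_ml=C_D_mg_ml,
        J_mean=j_mean,
        J_sd=j_sd,
        lag_min_mean=lag_mean,
        lag_min_sd=lag_sd,
        Q_horizon_mean=q_mean,
        Q_horizon_sd=q_sd,
        auc_norm_mean=auc_mean,
        auc_norm_sd=auc_sd,
        logPm_mean=logpm_mean,
        logPm_sd=logpm_sd,
        perm_class=classify_permeability(logpm_mean, cutpoints),
        flags=flags,
    )
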