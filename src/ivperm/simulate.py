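"""Synthetic assay generator: Fickian membrane permeation with lag,
acceptor sampling/replacement bookkeeping, Beer-Lambert absorbances,
shake-flask partition experiments, and dissolution oracles.

The membrane model is the classic constant-donor / perfect-sink solution
of Fick's second law for a homogeneous slab: the cumulative permeated
amount approaches the straight line ``J_ss * (t - lag)`` with
``J_ss = K * D * C_D / h`` and ``lag = h^2 / (6 D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .solubility import ShakeFlaskRun
from .timecourse import (
    FULL_REPLACEMENT,
    SAMPLE_AND_REPLACE,
    CalibrationCurve,
    ConcentrationRecord,
    SamplingPlan,
)

__all__ = [
    "MembraneParams",
    "NoiseModel",
    "SimulatedAssay",
    "ThresholdDissolutionOracle",
    "analytic_cumulative",
    "simulate_assay",
    "simulate_partition",
    "make_dissolution_oracle",
    "membrane_from_targets",
    "pampa_plan",
    "skin_plan",
    "PAMPA_SAMPLING_TIMES_H",
]

#: Plate-assay sampling schedule: 7.5, 15, 30, 60, 120, 240, 360 min.
PAMPA_SAMPLING_TIMES_H = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0)


@dataclass(frozen=True)
class MembraneParams:
    """Homogeneous-slab membrane: partition coefficient K (unitless),
    diffusivity D (cm2/h), thickness h (cm)."""

    K: float
    D_cm2_h: float
    h_cm: float

    def __post_init__(self) -> None:
        if self.K <= 0 or self.D_cm2_h <= 0 or self.h_cm <= 0:
            raise ValueError("K, D and h must all be > 0")

    @property
    def Pm_cm_h(self) -> float:
        return self.K * self.D_cm2_h / self.h_cm

    @property
    def lag_h(self) -> float:
        return self.h_cm**2 / (6.0 * self.D_cm2_h)

    @property
    def lag_min(self) -> float:
        return self.lag_h * 60.0

    def Jss_ug_cm2_h(self, C_D_mg_ml: float) -> float:
        return self.Pm_cm_h * C_D_mg_ml * 1000.0


def membrane_from_targets(
    Pm_cm_h: float,
    lag_min: float,
    h_cm: float = 0.01,
) -> MembraneParams:
    """Back-solve (K, D) from a target permeability and lag time at a
    fixed membrane thickness."""
    if Pm_cm_h <= 0 or lag_min <= 0:
        raise ValueError("Pm and lag must be > 0")
    lag_h = lag_min / 60.0
    D = h_cm**2 / (6.0 * lag_h)
    K = Pm_cm_h * h_cm / D
    return MembraneParams(K=K, D_cm2_h=D, h_cm=h_cm)


@dataclass(frozen=True)
class NoiseModel:
    """Mean-preserving multiplicative lognormal noise on measured
    concentrations, parameterized by its coefficient of variation."""

    cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, values: np.ndarray, seed: int | None = None) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float).copy()
        rng = np.random.default_rng(self.seed if seed is None else seed)
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(values))
        return np.asarray(values, dtype=float) * factors


@dataclass(frozen=True)
class SimulatedAssay:
    plan: SamplingPlan
    true_J_ug_cm2_h: float
    true_lag_min: float
    true_logPm: float
    records: tuple[ConcentrationRecord, ...]
    absorbances: tuple[float, ...] | None = None


def analytic_cumulative(
    t_h: float | np.ndarray,
    mp: MembraneParams,
    C_D_mg_ml: float,
) -> np.ndarray:
    """Cumulative permeated amount per area Q(t) in ug/cm2 for the slab
    membrane under constant-donor, perfect-sink boundary conditions.

    Q(t) = K h C_D [ D t/h^2 - 1/6 - (2/pi^2) sum_n ((-1)^n / n^2)
    exp(-D n^2 pi^2 t / h^2) ], with the series truncated once a term
    falls below 1e-12 of the leading scale. t = 0 returns exactly 0
    (guards the alternating-series cancellation).
    """
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau = mp.D_cm2_h * t / mp.h_cm**2
    bracket = tau - 1.0 / 6.0
    scale = np.maximum(np.abs(bracket), 1.0 / 6.0)
    series = np.zeros_like(tau)
    active = tau > 0
    n = 1
    while np.any(active) and n <= 100_000:
        term = np.zeros_like(tau)
        term[active] = ((-1.0) ** n / n**2) * np.exp(-(n**2) * math.pi**2 * tau[active])
        series += term
        active = active & (np.abs(term) >= 1e-12 * scale)
        n += 1
    q = mp.K * mp.h_cm * C_D_mg_ml * 1000.0 * (bracket - (2.0 / math.pi**2) * series)
    q[tau == 0] = 0.0
    q = np.maximum(q, 0.0)  # clamp residual cancellation error at tiny t
    if np.ndim(t_h) == 0:
        return float(q[0])
    return q


def _concentrations_from_Q(q_ug_cm2: np.ndarray, plan: SamplingPlan) -> np.ndarray:
    """Invert the cumulative-amount bookkeeping: acceptor concentration
    observed at each sampling, given true Q at the sampling times."""
    area = plan.exposure_area_cm2
    v_a = plan.acceptor_volume_ml
    q_mg = q_ug_cm2 / 1000.0
    if plan.replacement_mode == FULL_REPLACEMENT:
        dq = np.diff(np.concatenate(([0.0], q_mg)))
        return area * dq / v_a
    v_s = plan.sampled_volume_ml
    c = np.zeros_like(q_mg)
    removed = 0.0
    for i in range(len(q_mg)):
        c[i] = (area * q_mg[i] - v_s * removed) / v_a
        removed += c[i]
    return c


def simulate_assay(
    mp: MembraneParams,
    plan: SamplingPlan,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    calib: CalibrationCurve | None = None,
    solvent_code: str = "SIM",
    replicate: int = 1,
    donor_decay_per_h: float = 0.0,
) -> SimulatedAssay:
    """Simulate one replicate of a permeation assay.

    True cumulative amounts come from :func:`analytic_cumulative`;
    per-interval increments are converted to acceptor concentrations
    according to the plan's replacement mode; mean-preserving lognormal
    noise is applied to the measured concentrations; absorbances are
    emitted through the calibration forward map when a curve is given.

    ``donor_decay_per_h > 0`` scales per-interval increments by
    ``exp(-rate * t_start)`` to fabricate donor-depletion QC cases
    (depletion is otherwise not modeled: infinite dose).
    """
    noise = noise or NoiseModel()
    times = np.asarray(plan.sampling_times_h)
    q_true = analytic_cumulative(times, mp, plan.donor_concentration_mg_ml)
    if donor_decay_per_h > 0:
        dq = np.diff(np.concatenate(([0.0], q_true)))
        starts = np.concatenate(([0.0], times[:-1]))
        q_true = np.cumsum(dq * np.exp(-donor_decay_per_h * starts))
    c_true = _concentrations_from_Q(q_true, plan)
    c_obs = noise.apply(c_true, seed=seed)

    dilutions = plan.dilution_factors or (1.0,) * plan.n_samples
    absorbances = None
    if calib is not None:
        absorbances = tuple(
            calib.to_absorbance(c / d) for c, d in zip(c_obs, dilutions)
        )
    records = tuple(
        ConcentrationRecord(
            solvent_code=solvent_code,
            replicate=replicate,
            time_h=float(t),
            concentration_mg_ml=float(c),
        )
        for t, c in zip(times, c_obs)
    )
    return SimulatedAssay(
        plan=plan,
        true_J_ug_cm2_h=mp.Jss_ug_cm2_h(plan.donor_concentration_mg_ml),
        true_lag_min=mp.lag_min,
        true_logPm=math.log10(mp.Pm_cm_h),
        records=records,
        absorbances=absorbances,
    )


def simulate_partition(
    P: float,
    Vaq_ml: float,
    Voct_ml: float,
    A0: float = 1.0,
) -> ShakeFlaskRun:
    """Equilibrium shake-flask mass balance with absorbance proportional
    to aqueous concentration: A1 = A0 * Vaq / (Vaq + P * Voct)."""
    if P <= 0 or Vaq_ml <= 0 or Voct_ml <= 0 or A0 <= 0:
        raise ValueError("P, volumes and A0 must be > 0")
    A1 = A0 * Vaq_ml / (Vaq_ml + P * Voct_ml)
    return ShakeFlaskRun(A0=A0, A1=A1, Vaq_ml=Vaq_ml, Voct_ml=Voct_ml)


@dataclass(frozen=True)
class ThresholdDissolutionOracle:
    """Ideal visual observer: fully dissolved iff c <= true solubility
    (boundary inclusive), monotone by construction."""

    S_true_mg_ml: float

    def __post_init__(self) -> None:
        if self.S_true_mg_ml <= 0:
            raise ValueError("true solubility must be > 0")

    def query(self, concentration_mg_ml: float) -> bool:
        return concentration_mg_ml <= self.S_true_mg_ml


def make_dissolution_oracle(S_true_mg_ml: float) -> ThresholdDissolutionOracle:
    return ThresholdDissolutionOracle(S_true_mg_ml)


def pampa_plan(
    C_D_mg_ml: float,
    acceptor_volume_ml: float = 0.18,
    exposure_area_cm2: float = 0.3,
    donor_volume_ml: float = 0.07,
    sampling_times_h: tuple[float, ...] = PAMPA_SAMPLING_TIMES_H,
) -> SamplingPlan:
    """Default 96-well sandwich-plate plan: full acceptor replacement at
    7.5, 15, 30, 60, 120, 240 and 360 min."""
    return SamplingPlan(
        sampling_times_h=sampling_times_h,
        acceptor_volume_ml=acceptor_volume_ml,
        exposure_area_cm2=exposure_area_cm2,
        donor_volume_ml=donor_volume_ml,
        donor_concentration_mg_ml=C_D_mg_ml,
        replacement_mode=FULL_REPLACEMENT,
    )


def skin_plan(
    C_D_mg_ml: float,
    receptor_volume_ml: float,
    exposure_area_cm2: float,
    sampled_volume_ml: float = 0.2,
    hours: int = 16,
    dose_volume_ml_cm2: float = 1.13,
) -> SamplingPlan:
    """Diffusion-cell plan: hourly sample-and-replace up to ``hours``.

    The receptor volume has no defensible default and must be supplied.
    """
    return SamplingPlan(
        sampling_times_h=tuple(float(t) for t in range(1, hours + 1)),
        acceptor_volume_ml=receptor_volume_ml,
        exposure_area_cm2=exposure_area_cm2,
        donor_volume_ml=dose_volume_ml_cm2 * exposure_area_cm2,
        donor_concentration_mg_ml=C_D_mg_ml,
        sampled_volume_ml=sampled_volume_ml,
        replacement_mode=SAMPLE_AND_REPLACE,
    )
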