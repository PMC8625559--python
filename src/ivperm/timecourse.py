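"""Raw plate readings -> replacement-corrected cumulative permeated amount.

Canonical units throughout the package: time in hours, area in cm**2,
volume in mL, concentration in mg/mL, amount in ug. All unit conversions
happen at the boundary (readers, CLI), never inside the math.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FLAG_BELOW_BLANK",
    "FLAG_CALIB_RANGE",
    "FLAG_SINK",
    "FLAG_DEPLETION",
    "FULL_REPLACEMENT",
    "SAMPLE_AND_REPLACE",
    "CalibrationCurve",
    "SamplingPlan",
    "ConcentrationRecord",
    "CumulativeProfile",
    "absorbance_to_concentration",
    "cumulative_amount",
    "sink_check",
    "donor_depletion_check",
]

FLAG_BELOW_BLANK = "below_blank"
FLAG_CALIB_RANGE = "outside_calibration_range"
FLAG_SINK = "sink_exceeded"
FLAG_DEPLETION = "donor_depletion"

FULL_REPLACEMENT = "full_replacement"
SAMPLE_AND_REPLACE = "sample_and_replace"


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance calibration ``A = slope * c + intercept``.

    ``slope`` is absorbance per (mg/mL); ``valid_range_ug_ml`` is the
    concentration interval (ug/mL, on the *measured*, i.e. post-dilution
    solution) over which the line was established.
    """

    slope: float
    intercept: float = 0.0
    valid_range_ug_ml: tuple[float, float] = (9.0, 90.0)
    n_points: int | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        lo, hi = self.valid_range_ug_ml
        if not lo < hi:
            raise ValueError(f"invalid calibration range {self.valid_range_ug_ml}")

    def to_absorbance(self, concentration_mg_ml: float) -> float:
        """Forward map, used by the simulator to emit raw readings."""
        return self.slope * concentration_mg_ml + self.intercept


@dataclass(frozen=True)
class SamplingPlan:
    """Acceptor geometry and sampling schedule of one permeation assay.

    ``replacement_mode`` is either ``full_replacement`` (whole acceptor
    volume exchanged for fresh buffer at each sampling) or
    ``sample_and_replace`` (``sampled_volume_ml`` withdrawn and replaced
    with fresh fluid).
    """

    sampling_times_h: tuple[float, ...]
    acceptor_volume_ml: float
    exposure_area_cm2: float
    donor_volume_ml: float
    donor_concentration_mg_ml: float
    sampled_volume_ml: float | None = None
    replacement_mode: str = FULL_REPLACEMENT
    dilution_factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times_h, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be positive and strictly increasing")
        object.__setattr__(self, "sampling_times_h", tuple(float(x) for x in t))
        if self.replacement_mode not in (FULL_REPLACEMENT, SAMPLE_AND_REPLACE):
            raise ValueError(f"unknown replacement mode {self.replacement_mode!r}")
        if self.acceptor_volume_ml <= 0:
            raise ValueError("acceptor volume must be > 0")
        if self.exposure_area_cm2 <= 0:
            raise ValueError("exposure area must be > 0")
        if self.donor_volume_ml <= 0:
            raise ValueError("donor volume must be > 0")
        if self.donor_concentration_mg_ml <= 0:
            raise ValueError("donor concentration must be > 0")
        if self.replacement_mode == SAMPLE_AND_REPLACE:
            if self.sampled_volume_ml is None:
                raise ValueError("sample_and_replace requires sampled_volume_ml")
            if not 0 < self.sampled_volume_ml <= self.acceptor_volume_ml:
                raise ValueError("sampled volume must be in (0, acceptor volume]")
        if self.dilution_factors is not None:
            d = tuple(float(x) for x in self.dilution_factors)
            if len(d) != len(self.sampling_times_h):
                raise ValueError("need one dilution factor per sampling time")
            if any(x < 1 for x in d):
                raise ValueError("dilution factors must be >= 1")
            object.__setattr__(self, "dilution_factors", d)

    @property
    def n_samples(self) -> int:
        return len(self.sampling_times_h)

    @property
    def applied_dose_ug_cm2(self) -> float:
        """Applied dose per unit area (ug/cm2) for infinite-dose QC."""
        return (
            self.donor_concentration_mg_ml
            * self.donor_volume_ml
            * 1000.0
            / self.exposure_area_cm2
        )

    @property
    def dose_volume_ul_cm2(self) -> float:
        """Applied donor volume per unit area (uL/cm2)."""
        return self.donor_volume_ml * 1000.0 / self.exposure_area_cm2


@dataclass(frozen=True)
class ConcentrationRecord:
    """Acceptor concentration measured at one sampling time."""

    solvent_code: str
    replicate: int
    time_h: float
    concentration_mg_ml: float
    flags: frozenset[str] = frozenset()


@dataclass
class CumulativeProfile:
    """Cumulative permeated amount per unit area versus time.

    ``Q_ug_cm2[i]`` corresponds to ``times_h[i]``; the point (0, 0) is
    implicit and not stored.
    """

    solvent_code: str
    replicate: int
    times_h: np.ndarray
    Q_ug_cm2: np.ndarray
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.Q_ug_cm2 = np.asarray(self.Q_ug_cm2, dtype=float)
        if self.times_h.shape != self.Q_ug_cm2.shape:
            raise ValueError("times and Q must have equal length")


def absorbance_to_concentration(
    absorbance: float,
    calib: CalibrationCurve,
    dilution: float = 1.0,
) -> tuple[float, frozenset[str]]:
    """Invert the calibration line and undo dilution.

    Returns ``(concentration_mg_ml, flags)`` where the concentration is
    ``dilution * (A - intercept) / slope``. Readings below the blank
    (A < intercept) are clamped to 0 and flagged rather than rejected —
    instrument noise near the blank is expected. A flag is raised when
    the measured (undiluted) concentration falls outside the calibration
    range.
    """
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution}")
    flags: set[str] = set()
    c_measured = (absorbance - calib.intercept) / calib.slope  # mg/mL as measured
    if c_measured < 0:
        c_measured = 0.0
        flags.add(FLAG_BELOW_BLANK)
    lo, hi = calib.valid_range_ug_ml
    if not lo <= c_measured * 1000.0 <= hi:
        flags.add(FLAG_CALIB_RANGE)
    return dilution * c_measured, frozenset(flags)


def cumulative_amount(
    records: list[ConcentrationRecord],
    plan: SamplingPlan,
) -> CumulativeProfile:
    """Replacement-corrected cumulative amount per area, Q(t) in ug/cm2.

    Full replacement: every sampling removes the whole acceptor content,
    so ``Q(t_i) = (V_A / A) * sum_{j<=i} c_j``.

    Sample-and-replace: only ``V_s`` leaves the cell at each sampling
    while the rest stays and accumulates, giving the standard diffusion-
    cell correction ``Q(t_i) = (c_i * V_A + V_s * sum_{j<i} c_j) / A``.

    Concentrations are mg/mL, volumes mL, area cm2; amounts come out in
    mg/cm2 and are scaled to ug/cm2.
    """
    if len(records) != plan.n_samples:
        raise ValueError(
            f"expected {plan.n_samples} records (one per sampling time), got {len(records)}"
        )
    records = sorted(records, key=lambda r: r.time_h)
    times = np.array([r.time_h for r in records], dtype=float)
    if not np.allclose(times, plan.sampling_times_h, rtol=0, atol=1e-9):
        raise ValueError(
            f"record times {times.tolist()} do not match plan {list(plan.sampling_times_h)}"
        )
    c = np.array([r.concentration_mg_ml for r in records], dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration in records")

    area = plan.exposure_area_cm2
    v_a = plan.acceptor_volume_ml
    # full replacement is sample-and-replace with V_s = V_A; one formula
    # keeps the two modes bitwise identical in that limit
    v_s = v_a if plan.replacement_mode == FULL_REPLACEMENT else plan.sampled_volume_ml
    removed_before = np.concatenate(([0.0], np.cumsum(c)[:-1]))  # sum_{j<i} c_j
    q_mg = (c * v_a + v_s * removed_before) / area

    flags: set[str] = set()
    for r in records:
        flags |= r.flags
    return CumulativeProfile(
        solvent_code=records[0].solvent_code,
        replicate=records[0].replicate,
        times_h=times,
        Q_ug_cm2=q_mg * 1000.0,
        flags=flags,
    )


def sink_check(
    records: list[ConcentrationRecord],
    acceptor_solubility_mg_ml: float,
    fraction: float = 0.1,
) -> bool:
    """True when any acceptor concentration strictly exceeds the sink cap.

    The cap is ``fraction * acceptor_solubility``; boundary values pass
    (strict inequality).
    """
    if acceptor_solubility_mg_ml <= 0:
        raise ValueError("acceptor solubility must be > 0")
    cap = fraction * acceptor_solubility_mg_ml
    return any(r.concentration_mg_ml > cap for r in records)


def donor_depletion_check(
    profile: CumulativeProfile,
    plan: SamplingPlan,
    fraction: float = 0.1,
) -> bool:
    """True when the final permeated amount strictly exceeds ``fraction``
    of the applied dose per area (infinite-dose validity check)."""
    dose = plan.applied_dose_ug_cm2
    return bool(profile.Q_ug_cm2[-1] > fraction * dose)
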