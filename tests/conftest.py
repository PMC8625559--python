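import numpy as np
import pytest

from ivperm.simulate import PAMPA_SAMPLING_TIMES_H
from ivperm.timecourse import (
    CalibrationCurve,
    ConcentrationRecord,
    SamplingPlan,
)


@pytest.fixture
def calib():
    """The study's UV calibration line: A = 117.95 c + 0.01, 9-90 ug/mL."""
    return CalibrationCurve(slope=117.95, intercept=0.01, valid_range_ug_ml=(9.0, 90.0))


@pytest.fixture
def plate_plan():
    """Default plate-assay plan (full replacement, 7.5 min - 6 h)."""
    return SamplingPlan(
        sampling_times_h=PAMPA_SAMPLING_TIMES_H,
        acceptor_volume_ml=0.18,
        exposure_area_cm2=0.3,
        donor_volume_ml=0.07,
        donor_concentration_mg_ml=1.0,
        replacement_mode="full_replacement",
    )


def make_records(concentrations, times=None, code="S1", replicate=1):
    times = PAMPA_SAMPLING_TIMES_H if times is None else times
    return [
        ConcentrationRecord(
            solvent_code=code,
            replicate=replicate,
            time_h=float(t),
            concentration_mg_ml=float(c),
        )
        for t, c in zip(times, concentrations)
    ]


@pytest.fixture
def linear_profile_factory():
    """Exact Q(t) = J * (t - lag_h) profiles (clamped at 0) for fit tests."""
    from ivperm.timecourse import CumulativeProfile

    def factory(J, lag_h=0.0, times=(0.125, 0.25, 0.5), code="SIM"):
        t = np.asarray(times, dtype=float)
        q = J * (t - lag_h)
        return CumulativeProfile(solvent_code=code, replicate=1, times_h=t, Q_ug_cm2=q)

    return factory
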