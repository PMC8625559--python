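import math

import numpy as np
import pandas as pd
import pytest

from ivperm.comparison import (
    ONE_TO_2_ORDERS,
    OVER_2_ORDERS,
    WITHIN_1_ORDER,
    PairedPermeability,
    correlate_amounts,
    flag_outliers,
    flux_concordance,
    integrity_assessment,
    pair_models,
    regress_log_permeability,
)
from ivperm.datasets import fixture_tables


def fixture_pairs():
    tables = fixture_tables()
    membrane = pd.DataFrame(
        {
            "code": tables["membrane"]["code"],
            "logPm": tables["membrane"]["logPm_mean"],
            "auc_norm": tables["membrane"]["auc_norm"],
            "J": tables["membrane"]["J_mean"],
        }
    )
    skin = pd.DataFrame(
        {
            "code": tables["skin"]["code"],
            "logKp": tables["skin"]["logKp_mean"],
            "Qt": tables["skin"]["Q16h_mean"],
            "J": tables["skin"]["J_mean"],
        }
    )
    pairs, only_membrane, only_skin = pair_models(membrane, skin)
    return pairs, only_membrane, only_skin


def synthetic_pairs(x, y, amounts=None):
    amounts = amounts if amounts is not None else np.abs(y)
    return [
        PairedPermeability(
            solvent_code=f"P{i}",
            logPm_membrane=float(xi),
            logKp_skin=float(yi),
            auc_norm_membrane=float(xi) + 10.0,
            Qt_skin_ug_cm2=float(a),
            J_membrane=1.0,
            J_skin=1.0,
        )
        for i, (xi, yi, a) in enumerate(zip(x, y, amounts))
    ]


class TestPairModels:
    def test_panel_pairs_nine_of_thirteen(self):
        pairs, only_membrane, only_skin = fixture_pairs()
        assert len(pairs) == 9
        assert only_membrane == ["S11", "S12", "S13", "S3"]
        assert only_skin == []

    def test_disjoint_codes_give_empty(self):
        a = pd.DataFrame({"code": ["A"], "logPm": [1.0], "auc_norm": [1.0], "J": [1.0]})
        b = pd.DataFrame({"code": ["B"], "logKp": [1.0], "Qt": [1.0], "J": [1.0]})
        pairs, only_membrane, only_skin = pair_models(a, b)
        assert pairs == []
        assert only_membrane == ["A"] and only_skin == ["B"]

    def test_duplicate_codes_rejected(self):
        a = pd.DataFrame(
            {"code": ["S1", "S1"], "logPm": [1.0, 1.0], "auc_norm": [1, 1], "J": [1, 1]}
        )
        b = pd.DataFrame({"code": ["S1"], "logKp": [1.0], "Qt": [1.0], "J": [1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            pair_models(a, b)


class TestRegressions:
    def test_collinear_r2_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        pairs = synthetic_pairs(x, 2 * x + 1)
        assert regress_log_permeability(pairs).r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r2_equals_squared_correlation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(scale=0.5, size=12)
        pairs = synthetic_pairs(x, y)
        summary = regress_log_permeability(pairs)
        assert summary.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_r2_symmetric_in_axes(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(scale=0.3, size=10)
        forward = regress_log_permeability(synthetic_pairs(x, y)).r_squared
        backward = regress_log_permeability(synthetic_pairs(y, x)).r_squared
        assert forward == pytest.approx(backward, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        pairs = synthetic_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            regress_log_permeability(pairs)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            regress_log_permeability(synthetic_pairs([1.0, 2.0], [1.0, 2.0]))

    def test_panel_log_permeability_regression(self):
        pairs, _, _ = fixture_pairs()
        summary = regress_log_permeability(pairs)
        x = np.array([p.logPm_membrane for p in pairs])
        y = np.array([p.logKp_skin for p in pairs])
        assert summary.n == 9
        assert summary.slope > 0
        assert summary.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_amount_correlation_excludes_requested(self):
        pairs, _, _ = fixture_pairs()
        summary = correlate_amounts(pairs, exclude=("S1", "S6"))
        assert summary.n == 7
        assert summary.excluded == ("S1", "S6")
        # published text reports 0.843 for this seven-solvent correlation
        assert summary.r_squared == pytest.approx(0.843, abs=0.01)

    def test_exclusion_leaving_two_rejected(self):
        pairs = synthetic_pairs([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            correlate_amounts(pairs, exclude=("P0", "P1"))


class TestFlagOutliers:
    def test_displaced_point_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 2 * x
        y[3] += 10.0
        flags = flag_outliers(synthetic_pairs(x, y), "log_permeability")
        assert flags["P3"]
        assert sum(flags.values()) == 1

    def test_collinear_data_unflagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        flags = flag_outliers(synthetic_pairs(x, 2 * x + 1), "log_permeability")
        assert not any(flags.values())

    def test_infinite_threshold_flags_nothing(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([1.0, 5.0, 2.0, 9.0, 1.0])
        flags = flag_outliers(synthetic_pairs(x, y), threshold=math.inf)
        assert not any(flags.values())

    def test_unknown_quantity_rejected(self):
        pairs = synthetic_pairs([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        with pytest.raises(ValueError):
            flag_outliers(pairs, "nope")


class TestFluxConcordance:
    def test_hand_ratios_from_panel(self):
        pairs, _, _ = fixture_pairs()
        df = flux_concordance(pairs).set_index("code")
        assert df.loc["S1", "log_ratio"] == pytest.approx(0.46, abs=0.005)
        assert df.loc["S1", "category"] == WITHIN_1_ORDER
        assert df.loc["S4", "log_ratio"] == pytest.approx(3.42, abs=0.005)
        assert df.loc["S4", "category"] == OVER_2_ORDERS

    def test_equal_fluxes(self):
        p = PairedPermeability("X", -1, -1, 1, 1, J_membrane=5.0, J_skin=5.0)
        df = flux_concordance([p])
        assert df.loc[0, "log_ratio"] == 0.0
        assert df.loc[0, "category"] == WITHIN_1_ORDER

    def test_intermediate_band(self):
        p = PairedPermeability("X", -1, -1, 1, 1, J_membrane=50.0, J_skin=1.0)
        assert flux_concordance([p]).loc[0, "category"] == ONE_TO_2_ORDERS

    def test_zero_flux_undefined(self):
        p = PairedPermeability("X", -1, -1, 1, 1, J_membrane=0.0, J_skin=5.0)
        df = flux_concordance([p])
        assert df.loc[0, "category"] == "undefined"
        assert math.isnan(df.loc[0, "log_ratio"])

    def test_rescaling_invariance(self):
        p = PairedPermeability("X", -1, -1, 1, 1, J_membrane=72.4, J_skin=25.0)
        q = PairedPermeability("X", -1, -1, 1, 1, J_membrane=724.0, J_skin=250.0)
        a, b = flux_concordance([p]), flux_concordance([q])
        assert a.loc[0, "log_ratio"] == pytest.approx(b.loc[0, "log_ratio"], abs=1e-12)
        assert a.loc[0, "category"] == b.loc[0, "category"]


class TestIntegrity:
    def test_small_shift_passes(self):
        report = integrity_assessment({"S1": [-4.81, -4.81]}, reference_mean=-4.98, reference_sd=0.01)
        row = report.per_solvent.iloc[0]
        assert row["delta"] == pytest.approx(0.17, abs=1e-9)
        assert row["passed"]

    def test_sd_just_under_threshold_passes(self):
        # replicates engineered to an SD of 0.23
        vals = [-4.5 - 0.23 / math.sqrt(2), -4.5 + 0.23 / math.sqrt(2)]
        report = integrity_assessment({"S2": vals}, reference_mean=-4.98, reference_sd=0.01)
        row = report.per_solvent.iloc[0]
        assert row["sd"] == pytest.approx(0.23, abs=1e-9)
        assert row["passed"]

    def test_large_sd_fails(self):
        vals = [-4.5 - 0.5 / math.sqrt(2), -4.5 + 0.5 / math.sqrt(2)]
        report = integrity_assessment({"S2": vals}, reference_mean=-4.98, reference_sd=0.01)
        assert not report.per_solvent.iloc[0]["passed"]

    def test_large_shift_fails(self):
        report = integrity_assessment({"S3": [-3.5, -3.5]}, reference_mean=-4.98, reference_sd=0.01)
        assert not report.per_solvent.iloc[0]["passed"]

    def test_overall_summary(self):
        report = integrity_assessment(
            {"S1": [-4.2], "S2": [-4.3]}, reference_mean=-4.98, reference_sd=0.01
        )
        assert report.overall_mean == pytest.approx(-4.25)
        assert report.overall_sd == pytest.approx(np.std([-4.2, -4.3], ddof=1))
        assert report.all_passed
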