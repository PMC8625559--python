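"""Artificial-membrane vs ex vivo skin comparison: pairing, regressions,
flux concordance, outlier flagging, and membrane-integrity QC."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "PairedPermeability",
    "RegressionSummary",
    "IntegrityReport",
    "pair_models",
    "regress_log_permeability",
    "correlate_amounts",
    "flag_outliers",
    "flux_concordance",
    "integrity_assessment",
    "WITHIN_1_ORDER",
    "ONE_TO_2_ORDERS",
    "OVER_2_ORDERS",
]

WITHIN_1_ORDER = "within_1_order"
ONE_TO_2_ORDERS = "1_to_2_orders"
OVER_2_ORDERS = "over_2_orders"


@dataclass(frozen=True)
class PairedPermeability:
    solvent_code: str
    logPm_membrane: float
    logKp_skin: float
    auc_norm_membrane: float
    Qt_skin_ug_cm2: float
    J_membrane: float
    J_skin: float


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n: int
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class IntegrityReport:
    """Per-solvent integrity-probe permeability vs an untreated-membrane
    reference; pass when the mean shift and the replicate SD are both
    within threshold."""

    per_solvent: pd.DataFrame  # code, n, mean, sd, delta, passed
    reference_mean: float
    reference_sd: float
    overall_mean: float
    overall_sd: float
    delta_threshold: float
    sd_threshold: float

    @property
    def all_passed(self) -> bool:
        return bool(self.per_solvent["passed"].all())


def pair_models(
    membrane: pd.DataFrame,
    skin: pd.DataFrame,
) -> tuple[list[PairedPermeability], list[str], list[str]]:
    """Inner-join the two per-solvent metric tables on ``code``.

    Expected columns: ``code, logPm, auc_norm, J`` for the membrane
    table and ``code, logKp, Qt, J`` for the skin table. Returns the
    pairs plus the codes present in only one table.
    """
    for name, df, key in (("membrane", membrane, "code"), ("skin", skin, "code")):
        if df[key].duplicated().any():
            dupes = sorted(df.loc[df[key].duplicated(), key].unique())
            raise ValueError(f"duplicate solvent codes in {name} table: {dupes}")
    merged = membrane.merge(skin, on="code", suffixes=("_membrane", "_skin"))
    pairs = [
        PairedPermeability(
            solvent_code=row["code"],
            logPm_membrane=row["logPm"],
            logKp_skin=row["logKp"],
            auc_norm_membrane=row["auc_norm"],
            Qt_skin_ug_cm2=row["Qt"],
            J_membrane=row["J_membrane"],
            J_skin=row["J_skin"],
        )
        for _, row in merged.iterrows()
    ]
    only_membrane = sorted(set(membrane["code"]) - set(skin["code"]))
    only_skin = sorted(set(skin["code"]) - set(membrane["code"]))
    return pairs, only_membrane, only_skin


def _ols_summary(x: np.ndarray, y: np.ndarray, excluded: tuple[str, ...]) -> RegressionSummary:
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(len(x)),
        excluded=excluded,
    )


def regress_log_permeability(pairs: list[PairedPermeability]) -> RegressionSummary:
    """OLS of skin logKp on membrane logPm (the screen is the predictor).

    R-squared is direction-invariant, so the reported correlation does
    not depend on this orientation choice.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p.logPm_membrane for p in pairs])
    y = np.array([p.logKp_skin for p in pairs])
    return _ols_summary(x, y, ())


def correlate_amounts(
    pairs: list[PairedPermeability],
    exclude: tuple[str, ...] = (),
) -> RegressionSummary:
    """OLS of skin cumulative amount on membrane normalized AUC over the
    non-excluded pairs. Exclusions are caller-specified (outlier calls
    are a judgement, not an algorithm) and recorded in the summary."""
    kept = [p for p in pairs if p.solvent_code not in exclude]
    if len(kept) < 3:
        raise ValueError(f"need at least 3 pairs after exclusion, have {len(kept)}")
    x = np.array([p.auc_norm_membrane for p in kept])
    y = np.array([p.Qt_skin_ug_cm2 for p in kept])
    return _ols_summary(x, y, tuple(exclude))


def flag_outliers(
    pairs: list[PairedPermeability],
    quantity: str = "log_permeability",
    threshold: float = 2.0,
) -> dict[str, bool]:
    """Flag pairs whose externally studentized OLS residual exceeds the
    threshold in absolute value.

    ``quantity`` selects the regression: ``log_permeability``
    (logKp ~ logPm) or ``amount`` (Qt ~ auc_norm).
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs to studentize residuals")
    if quantity == "log_permeability":
        x = np.array([p.logPm_membrane for p in pairs])
        y = np.array([p.logKp_skin for p in pairs])
    elif quantity == "amount":
        x = np.array([p.auc_norm_membrane for p in pairs])
        y = np.array([p.Qt_skin_ug_cm2 for p in pairs])
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = OLSInfluence(model).resid_studentized_external
    return {
        p.solvent_code: bool(abs(r) > threshold) for p, r in zip(pairs, resid)
    }


def flux_concordance(pairs: list[PairedPermeability]) -> pd.DataFrame:
    """Per-pair log10 membrane/skin flux ratio with order-of-magnitude
    category (bands at 1 and 2, strict)."""
    rows = []
    for p in pairs:
        if p.J_membrane <= 0 or p.J_skin <= 0:
            rows.append({"code": p.solvent_code, "log_ratio": math.nan, "category": "undefined"})
            continue
        ratio = math.log10(p.J_membrane / p.J_skin)
        if abs(ratio) < 1:
            cat = WITHIN_1_ORDER
        elif abs(ratio) > 2:
            cat = OVER_2_ORDERS
        else:
            cat = ONE_TO_2_ORDERS
        rows.append({"code": p.solvent_code, "log_ratio": ratio, "category": cat})
    return pd.DataFrame(rows, columns=["code", "log_ratio", "category"])


def integrity_assessment(
    probe_logPm: dict[str, list[float]],
    reference_mean: float,
    reference_sd: float,
    delta_threshold: float = 1.0,
    sd_threshold: float = 0.3,
) -> IntegrityReport:
    """Membrane-integrity QC from a probe permeant measured after
    solvent pre-treatment.

    A solvent passes when |mean - reference| <= delta_threshold and the
    replicate SD <= sd_threshold (large shifts or variance indicate
    membrane damage).
    """
    if not probe_logPm:
        raise ValueError("need at least one solvent")
    rows = []
    for code, vals in probe_logPm.items():
        if not vals:
            raise ValueError(f"no probe replicates for {code}")
        arr = np.asarray(vals, dtype=float)
        mean = float(np.mean(arr))
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        delta = abs(mean - reference_mean)
        rows.append(
            {
                "code": code,
                "n": int(arr.size),
                "mean": mean,
                "sd": sd,
                "delta": delta,
                "passed": bool(delta <= delta_threshold and sd <= sd_threshold),
            }
        )
    per_solvent = pd.DataFrame(rows, columns=["code", "n", "mean", "sd", "delta", "passed"])
    means = per_solvent["mean"].to_numpy()
    overall_sd = float(np.std(means, ddof=1)) if means.size > 1 else math.nan
    return IntegrityReport(
        per_solvent=per_solvent,
        reference_mean=reference_mean,
        reference_sd=reference_sd,
        overall_mean=float(np.mean(means)),
        overall_sd=overall_sd,
        delta_threshold=delta_threshold,
        sd_threshold=sd_threshold,
    )
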