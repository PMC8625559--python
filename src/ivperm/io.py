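"""File formats and configuration: long-format timecourse CSVs, YAML
pipeline config, and deterministic report writers."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .metrics import DEFAULT_CLASS_CUTPOINTS, FitWindow, SolventSummary
from .timecourse import (
    FULL_REPLACEMENT,
    SAMPLE_AND_REPLACE,
    CalibrationCurve,
    ConcentrationRecord,
    SamplingPlan,
    absorbance_to_concentration,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_timecourse",
    "records_from_frame",
    "write_summary_csv",
    "write_json_report",
]

SCHEMA_VERSION = "1"

_REQUIRED_COLUMNS = ("solvent_code", "replicate")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to turn a raw timecourse into a report.

    All thresholds carry defaults; the acceptor (receptor) volume does
    not — it is assay-specific and must be stated in the config.
    """

    calibration: CalibrationCurve
    acceptor_volume_ml: float
    exposure_area_cm2: float
    donor_volume_ml: float
    replacement_mode: str = FULL_REPLACEMENT
    sampled_volume_ml: float | None = None
    window: FitWindow = field(default_factory=FitWindow)
    horizon_h: float = 6.0
    sink_fraction: float = 0.1
    depletion_fraction: float = 0.1
    class_cutpoints: tuple[float, float] = DEFAULT_CLASS_CUTPOINTS
    acceptor_solubility_mg_ml: float | None = None
    seed: int | None = None

    def plan_for(self, C_D_mg_ml: float, sampling_times_h: tuple[float, ...]) -> SamplingPlan:
        return SamplingPlan(
            sampling_times_h=sampling_times_h,
            acceptor_volume_ml=self.acceptor_volume_ml,
            exposure_area_cm2=self.exposure_area_cm2,
            donor_volume_ml=self.donor_volume_ml,
            donor_concentration_mg_ml=C_D_mg_ml,
            sampled_volume_ml=self.sampled_volume_ml,
            replacement_mode=self.replacement_mode,
        )

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in reports."""
        payload = {
            "calibration": {
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept,
                "valid_range_ug_ml": list(self.calibration.valid_range_ug_ml),
            },
            "acceptor_volume_ml": self.acceptor_volume_ml,
            "exposure_area_cm2": self.exposure_area_cm2,
            "donor_volume_ml": self.donor_volume_ml,
            "replacement_mode": self.replacement_mode,
            "sampled_volume_ml": self.sampled_volume_ml,
            "window": [self.window.t_min, self.window.t_max, self.window.include_origin],
            "horizon_h": self.horizon_h,
            "sink_fraction": self.sink_fraction,
            "depletion_fraction": self.depletion_fraction,
            "class_cutpoints": list(self.class_cutpoints),
            "acceptor_solubility_mg_ml": self.acceptor_solubility_mg_ml,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config.

    Required keys: ``calibration.slope``, ``acceptor_volume_ml``,
    ``exposure_area_cm2``, ``donor_volume_ml``. ``sampled_volume_ml`` is
    additionally required for ``replacement_mode: sample_and_replace``
    (diffusion-cell receptors have no default volume).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    try:
        calib_raw = raw["calibration"]
        calib = CalibrationCurve(
            slope=float(calib_raw["slope"]),
            intercept=float(calib_raw.get("intercept", 0.0)),
            valid_range_ug_ml=tuple(calib_raw.get("valid_range_ug_ml", (9.0, 90.0))),
            n_points=calib_raw.get("n_points"),
            r_squared=calib_raw.get("r_squared"),
        )
        win_raw = raw.get("window", {})
        window = FitWindow(
            t_min=float(win_raw.get("t_min", 0.0)),
            t_max=float(win_raw.get("t_max", 0.5)),
            include_origin=bool(win_raw.get("include_origin", True)),
        )
        cfg = PipelineConfig(
            calibration=calib,
            acceptor_volume_ml=float(raw["acceptor_volume_ml"]),
            exposure_area_cm2=float(raw["exposure_area_cm2"]),
            donor_volume_ml=float(raw["donor_volume_ml"]),
            replacement_mode=raw.get("replacement_mode", FULL_REPLACEMENT),
            sampled_volume_ml=(
                float(raw["sampled_volume_ml"]) if "sampled_volume_ml" in raw else None
            ),
            window=window,
            horizon_h=float(raw.get("horizon_h", 6.0)),
            sink_fraction=float(raw.get("sink_fraction", 0.1)),
            depletion_fraction=float(raw.get("depletion_fraction", 0.1)),
            class_cutpoints=tuple(raw.get("class_cutpoints", DEFAULT_CLASS_CUTPOINTS)),
            acceptor_solubility_mg_ml=(
                float(raw["acceptor_solubility_mg_ml"])
                if raw.get("acceptor_solubility_mg_ml") is not None
                else None
            ),
            seed=raw.get("seed"),
        )
    except KeyError as exc:
        raise ValueError(f"config {path} missing required key: {exc}") from exc
    if cfg.replacement_mode == SAMPLE_AND_REPLACE and cfg.sampled_volume_ml is None:
        raise ValueError("sample_and_replace config requires sampled_volume_ml")
    return cfg


def read_timecourse(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format timecourse CSV.

    Required columns: ``solvent_code``, ``replicate``, a time column
    (``time_h`` or ``time_min``, converted to hours), and a measurement
    column (``absorbance`` or ``concentration_mg_ml``). Optional:
    ``dilution`` (default 1). Errors name the offending CSV row.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "time_h" in df.columns:
        time_h = df["time_h"]
    elif "time_min" in df.columns:
        time_h = df["time_min"] / 60.0
    else:
        raise ValueError(f"{path}: need a time_h or time_min column")
    if "absorbance" not in df.columns and "concentration_mg_ml" not in df.columns:
        raise ValueError(f"{path}: need an absorbance or concentration_mg_ml column")

    numeric_cols = [
        c
        for c in ("time_h", "time_min", "absorbance", "concentration_mg_ml", "dilution")
        if c in df.columns
    ]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ValueError(f"{path}: non-numeric value in column {col!r} at CSV row {bad[0] + 2}")
        if converted.isna().any():
            row = int(df.index[converted.isna()][0]) + 2
            raise ValueError(f"{path}: empty value in column {col!r} at CSV row {row}")
        df[col] = converted

    out = df.copy()
    out["time_h"] = time_h.astype(float)
    if "dilution" not in out.columns:
        out["dilution"] = 1.0
    dup = out.duplicated(subset=["solvent_code", "replicate", "time_h"])
    if dup.any():
        row = int(out.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (solvent, replicate, time) at CSV row {row}")
    return out


def records_from_frame(
    df: pd.DataFrame,
    calib: CalibrationCurve | None = None,
) -> dict[tuple[str, int], list[ConcentrationRecord]]:
    """Group a validated timecourse frame into per-(solvent, replicate)
    record lists, converting absorbances through the calibration curve
    when concentrations are not given directly."""
    if "concentration_mg_ml" not in df.columns and calib is None:
        raise ValueError("absorbance data requires a calibration curve")
    groups: dict[tuple[str, int], list[ConcentrationRecord]] = {}
    for _, row in df.sort_values(["solvent_code", "replicate", "time_h"]).iterrows():
        if "concentration_mg_ml" in df.columns and not (
            isinstance(row.get("concentration_mg_ml"), float)
            and math.isnan(row["concentration_mg_ml"])
        ):
            conc, flags = float(row["concentration_mg_ml"]), frozenset()
        else:
            conc, flags = absorbance_to_concentration(
                float(row["absorbance"]), calib, float(row.get("dilution", 1.0))
            )
        rec = ConcentrationRecord(
            solvent_code=str(row["solvent_code"]),
            replicate=int(row["replicate"]),
            time_h=float(row["time_h"]),
            concentration_mg_ml=conc,
            flags=flags,
        )
        groups.setdefault((rec.solvent_code, rec.replicate), []).append(rec)
    return groups


_SUMMARY_COLUMNS = [
    "code",
    "n",
    "C_D_mg_ml",
    "J_mean",
    "J_sd",
    "lag_min",
    "lag_min_sd",
    "Q_horizon_mean",
    "Q_horizon_sd",
    "auc_norm",
    "logPm_mean",
    "logPm_sd",
    "perm_class",
    "flags",
]


def write_summary_csv(summaries: list[SolventSummary], path: str | Path) -> None:
    """Write per-solvent summaries as a tidy CSV with a fixed column
    order mirroring the published report layout."""
    rows = [
        {
            "code": s.solvent_code,
            "n": s.n,
            "C_D_mg_ml": s.C_D_mg_ml,
            "J_mean": s.J_mean,
            "J_sd": s.J_sd,
            "lag_min": s.lag_min_mean,
            "lag_min_sd": s.lag_min_sd,
            "Q_horizon_mean": s.Q_horizon_mean,
            "Q_horizon_sd": s.Q_horizon_sd,
            "auc_norm": s.auc_norm_mean,
            "logPm_mean": s.logPm_mean,
            "logPm_sd": s.logPm_sd,
            "perm_class": s.perm_class,
            "flags": ";".join(sorted(s.flags)),
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLUMNS).to_csv(path, index=False)


def write_json_report(payload: dict, path: str | Path, config: PipelineConfig | None = None) -> None:
    """Versioned JSON report; records the config hash and seed so runs
    are reproducible byte for byte."""
    doc = {"schema_version": SCHEMA_VERSION}
    if config is not None:
        doc["config_digest"] = config.digest()
        doc["seed"] = config.seed
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, allow_nan=True) + "\n")
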