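"""End-to-end analysis: validated timecourse frame + config + donor
concentrations -> per-replicate metrics and per-solvent summaries."""

from __future__ import annotations

import pandas as pd

from .io import PipelineConfig, records_from_frame
from .metrics import (
    PermeationMetrics,
    SolventSummary,
    analyze_profile,
    summarize_replicates,
)
from .timecourse import (
    FLAG_DEPLETION,
    FLAG_SINK,
    cumulative_amount,
    donor_depletion_check,
    sink_check,
)

__all__ = ["run_analysis"]


def run_analysis(
    df: pd.DataFrame,
    config: PipelineConfig,
    donor_concentrations: dict[str, float],
) -> tuple[list[PermeationMetrics], list[SolventSummary]]:
    """Run the full pipeline on a validated timecourse frame.

    ``donor_concentrations`` maps solvent code -> C_D (mg/mL). Each
    (solvent, replicate) group is converted to a cumulative profile,
    QC-checked (sink condition when an acceptor solubility is
    configured, donor depletion always), and reduced to permeation
    metrics; replicates are then aggregated per solvent.
    """
    groups = records_from_frame(df, config.calibration)
    per_replicate: list[PermeationMetrics] = []
    by_solvent: dict[str, list[PermeationMetrics]] = {}
    for (code, _replicate), records in sorted(groups.items()):
        if code not in donor_concentrations:
            raise ValueError(f"no donor concentration given for solvent {code!r}")
        c_d = donor_concentrations[code]
        times = tuple(r.time_h for r in records)
        plan = config.plan_for(c_d, times)
        profile = cumulative_amount(records, plan)
        if config.acceptor_solubility_mg_ml is not None and sink_check(
            records, config.acceptor_solubility_mg_ml, config.sink_fraction
        ):
            profile.flags.add(FLAG_SINK)
        if donor_depletion_check(profile, plan, config.depletion_fraction):
            profile.flags.add(FLAG_DEPLETION)
        metrics = analyze_profile(
            profile,
            c_d,
            window=config.window,
            horizon_h=config.horizon_h,
            cutpoints=config.class_cutpoints,
        )
        per_replicate.append(metrics)
        by_solvent.setdefault(code, []).append(metrics)
    summaries = [
        summarize_replicates(ms, donor_concentrations[code], config.class_cutpoints)
        for code, ms in sorted(by_solvent.items())
    ]
    return per_replicate, summaries
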