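"""Packaged study fixtures: the published per-solvent panel used for
regression tests and worked examples.

Thirteen solvents (S1-S13) with approximate and equilibrium
solubilities, per-solvent plate-assay (membrane) metrics, and ex vivo
skin metrics for the nine solvents measured on both models. The skin
table's S8 donor concentration is printed as 51 mg/mL in the source but
back-calculation of its logKp matches the equilibrium solubility of
5.1 mg/mL (decimal-point typo); both variants are shipped
(``C_D_mg_ml`` as printed, ``C_D_corrected_mg_ml`` with the fix).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["fixture_tables"]

_COMPOUND = {
    "name": "4-phenylethyl-resorcinol",
    "cas": "94-77-9",
    "mw_g_mol": 214.3,
    "logP": 2.98,
    "pKa": "9.77-10.77",
    "buffer_solubility_mg_ml": 3.45,
    "water_solubility_mg_ml": 3.85,
}

# code, class, solvent, MW (string for mixtures/triglycerides), approx
# solubility label, equilibrium solubility mean/sd (mg/mL; None = not measured)
_SOLVENTS = [
    ("S1", "low-MW polar", "water", "18.0", "1", 1.3, 0.2),
    ("S2", "low-MW polar", "ethanol", "46.1", ">1000", 368.0, 52.0),
    ("S3", "low-MW polar", "glycerol", "92.1", "5", None, None),
    ("S4", "low-MW polar", "dimethylisosorbide", "174.2", "75", 60.0, 5.7),
    ("S5", "low-MW polar", "water/ethanol 80:20 (w/w)", None, "10", 8.1, 4.3),
    ("S6", "low-MW polar", "water/dimethylisosorbide 90:10 (w/w)", None, "1", 1.1, 0.1),
    ("S7", "low-MW polar glycol", "propylene glycol", "76.1", "500", 350.0, 21.0),
    ("S8", "low-MW polar glycol", "water/propylene glycol 80:20 (w/w)", None, "10", 5.1, 0.8),
    ("S9", "low-MW polar glycol", "water/propylene glycol/ethanol 10:30:60 (w/w/w)", None, ">1000", 373.0, 49.0),
    ("S10", "high-MW non-polar", "capric/caprylic triglycerides", "554.8/470.7", "75", 74.0, 5.1),
    ("S11", "high-MW non-polar", "octyl dodecanol", "298.6", "1", None, None),
    ("S12", "high-MW non-polar", "apricot kernel oil", None, "1", None, None),
    ("S13", "high-MW non-polar", "corn oil", None, "1", None, None),
]

# code, C_D, J mean/sd, lag min, Q(6 h) mean/sd, AUC/C_D, logPm mean/sd
_MEMBRANE = [
    ("S1", 1.0, 72.4, 7.8, 1.4, 169.0, 4.0, 647.0, -1.12, 0.06),
    ("S2", 500.0, 12033.0, 252.0, 0.0, 13575.0, 1710.0, 105.0, -1.62, 0.01),
    ("S3", 5.0, 137.0, 22.0, 5.5, 869.0, 112.0, 491.0, -1.57, 0.07),
    ("S4", 70.0, 209.0, 53.0, 3.6, 1342.0, 298.0, 55.2, -2.54, 0.13),
    ("S5", 10.0, 589.0, 25.0, 0.9, 1662.0, 169.0, 569.0, -1.23, 0.03),
    ("S6", 1.0, 76.4, 15.2, 0.0, 175.0, 22.0, 551.0, -1.13, 0.07),
    ("S7", 500.0, 2118.0, 502.0, 3.8, 11142.0, 729.0, 69.1, -2.38, 0.11),
    ("S8", 10.0, 570.0, 5.0, 1.1, 1772.0, 98.0, 595.0, -1.24, 0.01),
    ("S9", 500.0, 10846.0, 326.0, 1.4, 14926.0, 2431.0, 114.0, -1.66, 0.01),
    ("S10", 70.0, 377.0, 36.0, 3.0, 749.0, 92.0, 38.2, -2.27, 0.04),
    ("S11", 1.0, 7.18, 1.6, 3.9, 19.0, 0.4, 64.5, -2.16, 0.08),
    ("S12", 1.0, 2.45, 0.57, 3.3, 13.0, 1.9, 36.7, -2.63, 0.07),
    ("S13", 1.0, 3.26, 0.41, 1.4, 13.0, 1.3, 38.6, -2.48, 0.06),
]

# code, C_D printed, C_D corrected, J mean/sd, Q(16 h) mean/sd, logKp mean/sd
_SKIN = [
    ("S1", 1.0, 1.0, 25.0, 9.6, 261.0, 100.0, -1.71, 0.32),
    ("S2", 368.0, 368.0, 20.0, 15.0, 98.0, 67.0, -4.26, 0.51),
    ("S4", 60.0, 60.0, 0.08, 0.024, 1.09, 0.39, -5.88, 0.19),
    ("S5", 8.0, 8.0, 61.0, 18.0, 515.0, 203.0, -1.97, 0.34),
    ("S6", 1.0, 1.0, 7.5, 3.0, 100.0, 37.0, -2.16, 0.26),
    ("S7", 350.0, 350.0, 20.0, 17.6, 147.0, 120.0, -4.24, 0.81),
    ("S8", 51.0, 5.1, 98.0, 50.0, 516.0, 109.0, -1.72, 0.34),
    ("S9", 373.0, 373.0, 40.0, 15.0, 320.0, 149.0, -3.97, 0.24),
    ("S10", 75.0, 75.0, 8.0, 3.5, 54.0, 34.0, -3.97, 0.29),
]

# Membrane-integrity probe study (reference permeant on pre-treated
# membranes): reference from untreated plates, observed panel summary.
_INTEGRITY = {
    "reference_logPm_mean": -4.98,
    "reference_logPm_sd": 0.01,
    "panel_logPm_mean": -4.25,
    "panel_logPm_sd": 0.30,
    "panel_logPm_range": (-4.81, -3.82),
    "max_solvent_sd": 0.23,  # ethanol, highest replicate variation
}


def fixture_tables() -> dict[str, object]:
    """Return the packaged study data as structured tables.

    Keys: ``compound`` (dict of physico-chemical properties),
    ``solvents``, ``membrane``, ``skin`` (DataFrames keyed by solvent
    code), and ``integrity`` (dict of probe-study summary numbers).
    """
    solvents = pd.DataFrame(
        _SOLVENTS,
        columns=[
            "code",
            "solvent_class",
            "solvent",
            "mw",
            "approx_solubility",
            "eq_solubility_mg_ml",
            "eq_solubility_sd",
        ],
    )
    membrane = pd.DataFrame(
        _MEMBRANE,
        columns=[
            "code",
            "C_D_mg_ml",
            "J_mean",
            "J_sd",
            "lag_min",
            "Q6h_mean",
            "Q6h_sd",
            "auc_norm",
            "logPm_mean",
            "logPm_sd",
        ],
    )
    skin = pd.DataFrame(
        _SKIN,
        columns=[
            "code",
            "C_D_mg_ml",
            "C_D_corrected_mg_ml",
            "J_mean",
            "J_sd",
            "Q16h_mean",
            "Q16h_sd",
            "logKp_mean",
            "logKp_sd",
        ],
    )
    return {
        "compound": dict(_COMPOUND),
        "solvents": solvents,
        "membrane": membrane,
        "skin": skin,
        "integrity": dict(_INTEGRITY),
    }
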