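"""Reference inputs for the XZP-5610 translation analysis.

These are the measured and reported study values that the pipeline consumes
as inputs: physicochemical/binding constants of XZP-5610 (an FXR agonist in
development for NASH), preclinical PK parameter tables from rat and dog
single-dose studies, the blood/tissue distribution coefficients, NOAEL and
toxicokinetic exposures, and the interspecies clearance/volume predictions
used by the aggregation policies.
"""

from __future__ import annotations

import pandas as pd

from .core_io import DrugProperties

# ---------------------------------------------------------------------------
# compound constants

XZP5610 = DrugProperties(
    mw=556.46,
    pka_list=((10.13, "acid"), (3.39, "acid")),
    logp=3.2,
    solubility=25.0,            # ug/mL at pH 6.0
    papp=10.1,                  # 1e-6 cm/s, Caco-2
    fup_by_species={
        "mouse": 0.0055, "rat": 0.013, "dog": 0.003,
        "monkey": 0.0075, "human": 0.002,
    },
    bp_ratio=0.58,
    kp_overrides={"liver": 37.0},         # calibrated liver:plasma coefficient
    cl_plasma_per_kg={"rat": 1.93, "human": 0.138},   # L/h/kg
    cl_biliary_per_kg=0.18,               # L/h/kg
    ka=1.46,                              # 1/h, typical human value
)

#: Caco-2 apparent permeability (1e-6 cm/s) by loading concentration (uM)
PAPP_A2B = {1: 5.29, 5: 10.3, 30: 14.7}
PAPP_B2A = {1: 7.51, 5: 7.12, 30: 6.09}

#: blood:plasma concentration ratios observed at 0.5, 2 and 8 h post-dose
BP_RATIO_TIMES_H = [0.5, 2.0, 8.0]
BP_RATIOS_OBSERVED = [0.54, 0.55, 0.66]
LIVER_KP_OBSERVED = 12.9

# ---------------------------------------------------------------------------
# preclinical PK parameter summaries (group mean values)

RAT_PK = pd.DataFrame(
    [
        ("iv_bolus", 1.0, "M", None, 2.9, None, 488.3, 2.0, 0.9, None),
        ("iv_bolus", 1.0, "F", None, 2.2, None, 569.8, 1.8, 0.6, None),
        ("oral", 2.0, "M", 0.5, 1.3, 56.6, 94.9, None, None, 9.6),
        ("oral", 1.0, "F", 0.5, 1.3, 50.4, 89.0, None, None, 15.6),
        ("oral", 6.0, "M", 0.5, 1.0, 255.8, 293.8, None, None, 9.9),
        ("oral", 3.0, "F", 0.8, 1.2, 175.6, 271.1, None, None, 15.9),
        ("oral", 20.0, "M", 1.0, 1.4, 762.9, 1276.6, None, None, 12.9),
        ("oral", 10.0, "F", 0.5, 1.9, 1014.0, 1367.8, None, None, 24.1),
    ],
    columns=["route", "dose_mg_kg", "sex", "tmax_h", "t_half_h",
             "cmax_ng_ml", "auc_0_t", "cl_l_h_kg", "vss_l_kg", "f_pct"],
)

DOG_PK = pd.DataFrame(
    [
        ("iv_bolus", 0.2, "M", None, 7.9, None, 864.4, 0.2, 1.1, None),
        ("iv_bolus", 0.2, "F", None, 5.5, None, 871.4, 0.2, 1.0, None),
        ("oral", 0.05, "M", 1.7, 10.1, 15.8, 88.2, None, None, 43.4),
        ("oral", 0.05, "F", 1.7, 13.1, 21.1, 125.9, None, None, 82.9),
        ("oral", 0.2, "M", 2.0, 6.1, 126.0, 508.3, None, None, 51.2),
        ("oral", 0.2, "F", 1.3, 6.5, 67.3, 319.4, None, None, 38.2),
        ("oral", 0.8, "M", 1.0, 5.8, 533.7, 2140.0, None, None, 61.4),
        ("oral", 0.8, "F", 1.3, 7.0, 626.7, 2279.2, None, None, 67.1),
    ],
    columns=["route", "dose_mg_kg", "sex", "tmax_h", "t_half_h",
             "cmax_ng_ml", "auc_0_t", "cl_l_h_kg", "vss_l_kg", "f_pct"],
)


def mean_iv_cl_per_kg(table: pd.DataFrame) -> float:
    """Sex-averaged IV plasma clearance, L/h/kg."""
    iv = table[table["route"] == "iv_bolus"]
    return float(iv["cl_l_h_kg"].mean())


def mean_iv_vss_per_kg(table: pd.DataFrame) -> float:
    """Sex-averaged IV steady-state volume, L/kg."""
    iv = table[table["route"] == "iv_bolus"]
    return float(iv["vss_l_kg"].mean())


def oral_f_values(table: pd.DataFrame) -> list[float]:
    po = table[table["route"] == "oral"]
    return [float(v) for v in po["f_pct"]]


# ---------------------------------------------------------------------------
# reported interspecies predictions (mL/min for CL, L for Vss); these feed
# the aggregation policies, which is deliberately insensitive to the
# method-variant ambiguities of the individual entries.

REPORTED_CL_PREDICTIONS = {
    ("SSS", "rat"): 293.0, ("SSS", "dog"): 96.4,
    ("SSAS", "rat"): 75.4, ("SSAS", "dog"): 92.3,
    ("TSAS", "rat+dog"): 177.0,
    ("FCIM", "rat"): 58.6, ("FCIM", "dog"): 181.0,
    ("HBF", "rat"): 845.0, ("HBF", "dog"): 184.0,
}
REPORTED_VSS_PREDICTIONS = {
    ("OieTozer", "rat+dog"): 17.1,
    ("PerKgVss", "rat"): 45.3,
    ("PerKgVss", "dog"): 63.0,
}

#: human PK values adopted for dose mathematics
HUMAN_CL_L_H = 8.3          # predicted human i.v. plasma clearance
HUMAN_F = 0.574             # predicted oral bioavailability (dog policy)
HUMAN_BW_KG = 60.0
KA_RANGE_PER_H = (0.589, 2.34)   # dog (low) and rat (high) absorption rates

# ---------------------------------------------------------------------------
# safety / toxicokinetic inputs for FIH dose selection

NOAEL_MG_KG = {("rat", "M"): 1.5, ("rat", "F"): 1.0,
               ("dog", "M"): 0.05, ("dog", "F"): 0.05}
STEADY_AUC24 = {("rat", "M"): 75.2, ("rat", "F"): 46.4,
                ("dog", "M"): 127.6, ("dog", "F"): 152.1}   # ng*h/mL
MABEL_MG_KG = {"mouse": 1.0, "rat": 0.5}


def drug_properties_from_config(cfg: dict) -> DrugProperties:
    """DrugProperties from a config ``drug`` section; defaults to XZP-5610."""
    if not cfg:
        return XZP5610
    from dataclasses import replace

    allowed = {"mw", "logp", "solubility", "papp", "bp_ratio",
               "cl_biliary_per_kg", "ka"}
    scalars = {k: v for k, v in cfg.items() if k in allowed}
    out = replace(XZP5610, **scalars)
    if "fup_by_species" in cfg:
        out = replace(out, fup_by_species={**out.fup_by_species,
                                           **cfg["fup_by_species"]})
    if "kp_overrides" in cfg:
        out = replace(out, kp_overrides={**out.kp_overrides,
                                         **cfg["kp_overrides"]})
    if "cl_plasma_per_kg" in cfg:
        out = replace(out, cl_plasma_per_kg={**out.cl_plasma_per_kg,
                                             **cfg["cl_plasma_per_kg"]})
    return out
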