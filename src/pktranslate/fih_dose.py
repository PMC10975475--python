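"""First-in-human dose mathematics.

Two routes from animal safety data to a maximum recommended starting dose
(MRSD): the body-surface-area method (human equivalent dose via Km factors,
HED = NOAEL * Km_animal/Km_human * BW_human) and the systemic-exposure
method (unbound-exposure matching, AUC_h = AUC_a * fup_a/fup_h, then
Dose = AUC * CL / F).  A safety factor divides the HED; a plan-building
policy assembles the MRSD together with the configured MABEL/MTD decisions
and the computed efficacy-dose ranges as provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class DoseRecommendation:
    species: str
    sex: str | None
    noael_mg_kg: float
    hed_mg: float
    safety_factor: float
    mrsd_mg: float
    method: str                      # "BSA" or "exposure"
    steady_auc24: float | None = None          # ng*h/mL (exposure method)
    human_equivalent_auc24: float | None = None

    def __post_init__(self) -> None:
        if abs(self.mrsd_mg - self.hed_mg / self.safety_factor) > 1e-9 * self.hed_mg:
            raise ValueError("mrsd must equal hed / safety_factor")


@dataclass(frozen=True)
class DosePlan:
    mrsd_mg: float
    mabel_mg: float
    mtd_mg: float
    rationale: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mrsd_mg <= self.mabel_mg <= self.mtd_mg:
            raise ValueError("dose plan must satisfy MRSD <= MABEL <= MTD")


def hed_bsa(noael_mg_kg: float, km_animal: float, km_human: float,
            bw_human_kg: float) -> float:
    """Human equivalent dose (mg) by body-surface-area conversion."""
    if km_animal <= 0 or km_human <= 0:
        raise ValueError("Km factors must be positive")
    return noael_mg_kg * (km_animal / km_human) * bw_human_kg


def auc_human_equivalent(auc_animal: float, fup_animal: float,
                         fup_human: float) -> float:
    """Human AUC giving the same unbound exposure as the animal AUC."""
    for fu in (fup_animal, fup_human):
        if not 0 < fu <= 1:
            raise ValueError(f"fup outside (0, 1]: {fu}")
    return auc_animal * fup_animal / fup_human


def dose_from_exposure(auc_ng_h_ml: float, cl_l_h: float,
                       f_fraction: float) -> float:
    """Dose (mg) producing a target AUC: Dose = AUC * CL / F.

    AUC in ng*h/mL (== ug*h/L), CL in L/h, so AUC*CL is in ug -> /1000 mg.
    """
    if f_fraction > 1:
        raise ValueError("bioavailability fraction cannot exceed 1")
    if min(auc_ng_h_ml, cl_l_h, f_fraction) <= 0:
        raise ValueError("AUC, CL and F must be positive")
    return auc_ng_h_ml * cl_l_h / f_fraction / 1000.0


def apply_safety_factor(hed_mg: float, sf: float) -> float:
    if sf < 1:
        raise ValueError("safety factor must be >= 1")
    return hed_mg / sf


def bsa_recommendation(species: str, noael_mg_kg: float, km_animal: float,
                       km_human: float, bw_human_kg: float,
                       sf: float = 10.0, sex: str | None = None
                       ) -> DoseRecommendation:
    hed = hed_bsa(noael_mg_kg, km_animal, km_human, bw_human_kg)
    return DoseRecommendation(species, sex, noael_mg_kg, hed, sf,
                              apply_safety_factor(hed, sf), method="BSA")


def exposure_recommendation(species: str, noael_mg_kg: float,
                            steady_auc24: float, fup_animal: float,
                            fup_human: float, cl_human_l_h: float,
                            f_human: float, sf: float = 10.0,
                            sex: str | None = None) -> DoseRecommendation:
    auc_h = auc_human_equivalent(steady_auc24, fup_animal, fup_human)
    hed = dose_from_exposure(auc_h, cl_human_l_h, f_human)
    return DoseRecommendation(species, sex, noael_mg_kg, hed, sf,
                              apply_safety_factor(hed, sf),
                              method="exposure", steady_auc24=steady_auc24,
                              human_equivalent_auc24=auc_h)


def build_dose_plan(recommendations: Sequence[DoseRecommendation],
                    mabel_mg: float, mtd_mg: float,
                    granularity: float = 0.01,
                    efficacy_heds_mg: Sequence[float] = (),
                    rationale: str = "",
                    mrsd_override: float | None = None) -> DosePlan:
    """Assemble the dose plan: MRSD = min recommendation, rounded down to
    the policy granularity; MABEL/MTD are configured judgment values with
    the computed ranges carried as provenance.  ``mrsd_override`` pins a
    more conservative judgment value (must not exceed the computed MRSD)."""
    if not recommendations:
        raise ValueError("no dose recommendations supplied")
    raw = min(r.mrsd_mg for r in recommendations)
    mrsd = math.floor(raw / granularity + 1e-12) * granularity
    if mrsd_override is not None:
        if mrsd_override > mrsd + 1e-12:
            raise ValueError("override may only lower the starting dose")
        mrsd = mrsd_override
    prov = {
        "mrsd_range_mg": (min(r.mrsd_mg for r in recommendations),
                          max(r.mrsd_mg for r in recommendations)),
        "hed_range_mg": (min(r.hed_mg for r in recommendations),
                         max(r.hed_mg for r in recommendations)),
    }
    if efficacy_heds_mg:
        prov["efficacy_hed_range_mg"] = (min(efficacy_heds_mg),
                                         max(efficacy_heds_mg))
    return DosePlan(mrsd_mg=mrsd, mabel_mg=mabel_mg, mtd_mg=mtd_mg,
                    rationale=rationale or "configured judgment values",
                    provenance=prov)


def recommendations_table(recs: Sequence[DoseRecommendation]) -> pd.DataFrame:
    rows = []
    for r in recs:
        rows.append({
            "species": r.species, "sex": r.sex or "", "method": r.method,
            "noael_mg_kg": r.noael_mg_kg,
            "steady_auc24": r.steady_auc24,
            "human_equivalent_auc24": r.human_equivalent_auc24,
            "hed_mg": r.hed_mg, "safety_factor": r.safety_factor,
            "mrsd_mg": r.mrsd_mg,
        })
    return pd.DataFrame(rows)


def dose_stage(cfg: Mapping) -> tuple[DosePlan, list[tuple[str, pd.DataFrame]]]:
    """Pipeline dose stage: BSA and exposure recommendations from config.

    Config keys: noael (species/sex -> mg/kg), steady_auc24, km_factors,
    fup, cl_human_l_h, f_human, bw_human_kg, safety_factor, mabel_mg,
    mtd_mg, granularity.
    """
    from .physiology import SPECIES

    km = {**{s.name: s.km_factor for s in SPECIES.values()},
          **cfg.get("km_factors", {})}
    bw_h = cfg.get("bw_human_kg", 60.0)
    sf = cfg.get("safety_factor", 10.0)
    bsa = [bsa_recommendation(sp, noael, km[sp], km["human"], bw_h, sf, sex)
           for (sp, sex), noael in cfg["noael"].items()]
    expo = []
    for (sp, sex), auc in cfg.get("steady_auc24", {}).items():
        expo.append(exposure_recommendation(
            sp, cfg["noael"][(sp, sex)], auc, cfg["fup"][sp],
            cfg["fup"]["human"], cfg["cl_human_l_h"], cfg["f_human"],
            sf, sex))
    plan = build_dose_plan(
        bsa + expo, mabel_mg=cfg["mabel_mg"], mtd_mg=cfg["mtd_mg"],
        granularity=cfg.get("granularity", 0.01),
        efficacy_heds_mg=cfg.get("efficacy_heds_mg", ()),
        mrsd_override=cfg.get("mrsd_override"))
    tables = [("mrsd_bsa", recommendations_table(bsa))]
    if expo:
        tables.append(("mrsd_exposure", recommendations_table(expo)))
    tables.append(("dose_plan", pd.DataFrame([{
        "mrsd_mg": plan.mrsd_mg, "mabel_mg": plan.mabel_mg,
        "mtd_mg": plan.mtd_mg}])))
    return plan, tables
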