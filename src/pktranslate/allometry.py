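"""Interspecies scaling of clearance and volume of distribution.

Clearance predictors: simple single-species scaling (SSS), fup-corrected
single-species allometric scaling (SSAS), two-species allometric regression
(TSAS), the fu-corrected intercept method (FCIM, Tang-Mayersohn form
CL_h = 33.35 * (a / Rfu)^0.77), and hepatic-blood-flow extraction transfer
(HBF).  Volume predictors: per-kg scaling (exponent 1) and the Oie-Tozer
decomposition with a cross-species mean unbound tissue fraction.  An
aggregation operation applies the species/method selection policies that
produce the headline human values.

Units: per-animal clearance in mL/min, body weight kg, volumes L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .physiology import SpeciesProfile


@dataclass(frozen=True)
class AllometricInput:
    """Per-animal inputs of one source species."""

    species: str
    body_weight: float       # kg
    cl: float | None = None  # mL/min per animal
    vss: float | None = None  # L per animal
    fup: float | None = None
    q_hepatic: float | None = None   # mL/min per animal

    def __post_init__(self) -> None:
        for name in ("body_weight", "cl", "vss", "fup", "q_hepatic"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class AllometricPrediction:
    method: str              # SSS | SSAS | TSAS | FCIM | HBF | OieTozer | PerKgVss
    parameter: str           # "cl" (mL/min) or "vss" (L)
    source_species: tuple[str, ...]
    value: float
    exponent: float | None = None
    coefficient: float | None = None
    rfu: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class Aggregate:
    value: float
    policy: str
    members: tuple[AllometricPrediction, ...]


def cl_sss(inp: AllometricInput, target_bw: float,
           exponent: float = 0.66) -> AllometricPrediction:
    """Single-species scaling: CL_h = CL_a * (BW_h / BW_a)^b."""
    if not 0 < exponent <= 1.2:
        raise ValueError("exponent outside (0, 1.2]")
    value = inp.cl * (target_bw / inp.body_weight) ** exponent
    return AllometricPrediction("SSS", "cl", (inp.species,), value,
                                exponent=exponent)


def cl_ssas_fu(inp: AllometricInput, target_bw: float, target_fup: float,
               exponent: float = 0.75) -> AllometricPrediction:
    """fup-corrected single-species scaling of unbound clearance."""
    if not 0 < target_fup <= 1:
        raise ValueError("target fup outside (0, 1]")
    value = (inp.cl / inp.fup) * (target_bw / inp.body_weight) ** exponent \
        * target_fup
    return AllometricPrediction("SSAS", "cl", (inp.species,), value,
                                exponent=exponent)


def cl_tsas(inputs: Sequence[AllometricInput],
            target_bw: float) -> AllometricPrediction:
    """Multi-species power-law regression log CL = log a + b log BW."""
    if len(inputs) < 2:
        raise ValueError("TSAS needs at least 2 species")
    bw = np.array([i.body_weight for i in inputs])
    cl = np.array([i.cl for i in inputs])
    if len(np.unique(bw)) < 2:
        raise ValueError("TSAS needs distinct body weights")
    b, loga = np.polyfit(np.log(bw), np.log(cl), 1)
    a = math.exp(loga)
    value = a * target_bw ** b
    return AllometricPrediction("TSAS", "cl",
                                tuple(i.species for i in inputs), value,
                                exponent=float(b), coefficient=a)


def cl_fcim(inp: AllometricInput, target_fup: float) -> AllometricPrediction:
    """fu-corrected intercept method, CL_h = 33.35 * (a / Rfu)^0.77.

    a = CL_a / BW_a^0.75 (mL/min/kg^0.75, single-species coefficient);
    Rfu = fup_animal / fup_human.
    """
    a = inp.cl / inp.body_weight ** 0.75
    rfu = inp.fup / target_fup
    value = 33.35 * (a / rfu) ** 0.77
    return AllometricPrediction("FCIM", "cl", (inp.species,), value,
                                coefficient=a, rfu=rfu, exponent=0.77)


def cl_hbf(inp: AllometricInput,
           target_q_hepatic: float) -> AllometricPrediction:
    """Hepatic-blood-flow method: transfer the extraction ratio CL_a/Q_a."""
    extraction = inp.cl / inp.q_hepatic
    flags = ("extraction_ratio_gt_1",) if extraction > 1 else ()
    value = extraction * target_q_hepatic
    return AllometricPrediction("HBF", "cl", (inp.species,), value,
                                coefficient=extraction, flags=flags)


def vss_perkg(inp: AllometricInput, target_bw: float) -> AllometricPrediction:
    """Direct per-kg (exponent 1) scaling of Vss."""
    value = (inp.vss / inp.body_weight) * target_bw
    return AllometricPrediction("PerKgVss", "vss", (inp.species,), value,
                                exponent=1.0)


def oie_tozer_fut(vss_per_kg: float, fup: float,
                  vols) -> float:
    """Unbound tissue fraction implied by an observed Vss/kg.

    fut = fup*Vr / (Vss/kg - Vp - fup*Ve - (1-fup)*(RE/I)*Vp).
    """
    denom = (vss_per_kg - vols.vp - fup * vols.ve
             - (1 - fup) * vols.re_i * vols.vp)
    if denom <= 0:
        raise ValueError("Vss below plasma space: non-positive fut")
    return fup * vols.vr / denom


def vss_oie_tozer(inputs: Sequence[AllometricInput],
                  species_profiles: dict[str, SpeciesProfile],
                  target: SpeciesProfile,
                  target_fup: float) -> AllometricPrediction:
    """Oie-Tozer Vss prediction using the cross-species mean fut.

    Vss_h/kg = Vp + fup_h*Ve + (1-fup_h)*(RE/I)*Vp + Vr*fup_h/mean(fut),
    scaled by the target body weight.
    """
    if not inputs:
        raise ValueError("need at least one source species")
    futs = []
    for inp in inputs:
        vols = species_profiles[inp.species].oie_tozer
        futs.append(oie_tozer_fut(inp.vss / inp.body_weight, inp.fup, vols))
    fut_mean = float(np.mean(futs))
    tv = target.oie_tozer
    vss_kg = (tv.vp + target_fup * tv.ve
              + (1 - target_fup) * tv.re_i * tv.vp
              + tv.vr * target_fup / fut_mean)
    return AllometricPrediction("OieTozer", "vss",
                                tuple(i.species for i in inputs),
                                vss_kg * target.body_weight,
                                coefficient=fut_mean)


def aggregate(predictions: Sequence[AllometricPrediction],
              policy: str = "mean",
              species: str | None = None,
              methods: Sequence[str] | None = None) -> Aggregate:
    """Aggregate method outputs into a single human prediction.

    policy "mean" averages the supplied predictions; "dog_single_species"
    restricts to dog-sourced single-species clearance methods (SSS, SSAS,
    FCIM, HBF) before averaging.  Explicit ``species``/``methods`` filters
    compose with either policy.  The member list is returned as provenance.
    """
    preds = list(predictions)
    if policy == "dog_single_species":
        species = species or "dog"
        methods = methods or ("SSS", "SSAS", "FCIM", "HBF")
    elif policy != "mean":
        raise ValueError(f"unknown aggregation policy {policy!r}")
    if species is not None:
        preds = [p for p in preds if p.source_species == (species,)]
    if methods is not None:
        preds = [p for p in preds if p.method in methods]
    if not preds:
        raise ValueError("aggregation filter left no predictions")
    return Aggregate(value=float(np.mean([p.value for p in preds])),
                     policy=policy, members=tuple(preds))


def predictions_from_reference(reference: dict | None = None
                               ) -> list[AllometricPrediction]:
    """Wrap reported prediction values (method/species -> value) as
    AllometricPrediction rows for aggregation.

    With no argument, uses the packaged reference tables (clearance in
    mL/min, volumes in L).
    """
    if not reference:
        from .reference import REPORTED_CL_PREDICTIONS, REPORTED_VSS_PREDICTIONS
        reference = {"cl": {f"{m}:{s}": v for (m, s), v
                            in REPORTED_CL_PREDICTIONS.items()},
                     "vss": {f"{m}:{s}": v for (m, s), v
                             in REPORTED_VSS_PREDICTIONS.items()}}
    out = []
    for param, entries in reference.items():
        for key, value in entries.items():
            method, _, species = key.partition(":")
            out.append(AllometricPrediction(
                method=method, parameter=param,
                source_species=(species,), value=float(value)))
    return out
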