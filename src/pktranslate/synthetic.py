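"""Seeded generators emulating the preclinical study designs.

Every stage of the pipeline can be exercised without external data: the
generators emulate the single-dose IV+PO PK studies in rats and dogs (four
arms: one IV group and three oral dose groups, three males and three females
each), the 4-timepoint radiolabel tissue-distribution study (24 rats,
destructive sampling, six animals per timepoint), Caco-2 transwell
transport, equilibrium dialysis and hepatocyte depletion curves.

Statistical structure: between-subject parameter variability is lognormal,
residual concentration error is lognormal, subjects are independent, and all
sampling derives from a single named seed recorded in the truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import DATASET_COLUMNS, StudyDataset
from .invitro import DepletionCurve, DialysisObservation, TranswellObservation
from .ka_fit import onecomp_oral_conc

DESIGNS = ("pk_study", "tissue_study", "transwell", "dialysis", "depletion")

#: default blood sampling schedule, h
PK_TIMEPOINTS = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
TISSUE_TIMEPOINTS = (0.5, 2.0, 8.0, 24.0)
DEPLETION_TIMEPOINTS_MIN = (0.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0)

#: default between-subject CV on disposition parameters and residual CV
DEFAULT_BSV_CV = 0.20
DEFAULT_RESIDUAL_CV = 0.15


@dataclass(frozen=True)
class GeneratorSpec:
    design: str
    true_params: Mapping[str, object]
    n_subjects: int = 3                      # per sex per group (pk_study)
    timepoints: Sequence[float] | None = None
    noise_cv: float = DEFAULT_RESIDUAL_CV
    bsv_cv: float = DEFAULT_BSV_CV
    seed: int = 0
    species: str = "rat"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {DESIGNS}")
        if self.noise_cv < 0 or self.bsv_cv < 0:
            raise ValueError("noise CVs must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log(1 + cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def _iv_conc(t, cl_per_kg, vss_per_kg, dose_mg_kg, model, params):
    """Disposition concentration after IV bolus, ng/mL."""
    t = np.asarray(t, dtype=float)
    if model == "one_compartment":
        ke = cl_per_kg / vss_per_kg
        return dose_mg_kg * 1000.0 / vss_per_kg * np.exp(-ke * t)
    if model == "two_compartment":
        # central volume v1 and exchange rates; unless k12 is given
        # explicitly it is chosen so the model realizes the stated Vss:
        # Vss = v1 * (1 + k12/k21)
        v1 = params.get("v1_per_kg", vss_per_kg / 2.0)
        k21 = params.get("k21", 0.15)
        if "k12" in params:
            k12 = params["k12"]
        else:
            if vss_per_kg <= v1:
                raise ValueError("two-compartment truth needs vss > v1")
            k12 = k21 * (vss_per_kg / v1 - 1.0)
        k10 = cl_per_kg / v1
        s = k10 + k12 + k21
        disc = np.sqrt(s ** 2 - 4 * k10 * k21)
        alpha, beta = (s + disc) / 2, (s - disc) / 2
        c0 = dose_mg_kg * 1000.0 / v1
        A = c0 * (alpha - k21) / (alpha - beta)
        B = c0 * (k21 - beta) / (alpha - beta)
        return A * np.exp(-alpha * t) + B * np.exp(-beta * t)
    raise ValueError(f"unknown disposition model {model!r}")


def _oral_conc(t, cl_per_kg, vss_per_kg, ka, f, dose_mg_kg, model, params):
    """Oral concentration: first-order (Bateman) input into the disposition."""
    t = np.asarray(t, dtype=float)
    if model == "one_compartment":
        ke = cl_per_kg / vss_per_kg
        return f * onecomp_oral_conc(t, ka, ke, vss_per_kg, dose_mg_kg)
    if model == "two_compartment":
        # superpose the IV unit response through the absorption input by
        # convolution on a fine grid (adequate for smooth truth curves)
        tf = np.linspace(0.0, float(np.max(t)), 4001)
        unit_iv = _iv_conc(tf, cl_per_kg, vss_per_kg, 1.0, model, params)
        rate = ka * np.exp(-ka * tf)           # absorbed fraction density
        dt = tf[1] - tf[0]
        conv = np.convolve(rate, unit_iv)[: len(tf)] * dt
        return f * dose_mg_kg * np.interp(t, tf, conv)
    raise ValueError(f"unknown disposition model {model!r}")


def gen_pk_study(spec: GeneratorSpec) -> tuple[StudyDataset, dict]:
    """Single-dose PK study: 1 IV arm + 3 oral dose arms, n/sex/group.

    true_params: model ("one_compartment"|"two_compartment"), cl_per_kg
    (L/h/kg), vss_per_kg (L/kg), ka (1/h), f (fraction), iv_dose (mg/kg),
    oral_doses (3 mg/kg values), optional two-compartment micro-rates.
    """
    p = dict(spec.true_params)
    model = p.get("model", "one_compartment")
    if model not in ("one_compartment", "two_compartment"):
        raise ValueError(f"invalid model name {model!r}")
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(PK_TIMEPOINTS if spec.timepoints is None
                       else spec.timepoints, dtype=float)
    iv_dose = float(p.get("iv_dose", 1.0))
    oral_doses = list(p.get("oral_doses", (2.0, 6.0, 20.0)))
    arms = [("iv_bolus", iv_dose, "G1")] + [
        ("oral", d, f"G{i + 2}") for i, d in enumerate(oral_doses)]
    rows = []
    subj = 0
    for route, dose, group in arms:
        for sex in ("M", "F"):
            for _ in range(spec.n_subjects):
                subj += 1
                cl = p["cl_per_kg"] * _lognormal_factor(rng, spec.bsv_cv)
                v = p["vss_per_kg"] * _lognormal_factor(rng, spec.bsv_cv)
                ka = p.get("ka", 1.0) * _lognormal_factor(rng, spec.bsv_cv)
                if route == "iv_bolus":
                    c = _iv_conc(times, cl, v, dose, model, p)
                else:
                    c = _oral_conc(times, cl, v, ka, p.get("f", 1.0), dose,
                                   model, p)
                c = c * _lognormal_factor(rng, spec.noise_cv, size=len(times))
                for t, cc in zip(times, c):
                    rows.append((f"S{subj:03d}", spec.species, sex, group,
                                 route, dose, "mg/kg", "plasma", t, cc))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    manifest = {"design": "pk_study", "seed": spec.seed,
                "species": spec.species, "true_params": p,
                "n_subjects_per_sex_per_group": spec.n_subjects,
                "noise_cv": spec.noise_cv, "bsv_cv": spec.bsv_cv,
                "n_records": len(df)}
    return StudyDataset(records=df, label=f"synthetic_pk_{spec.species}"), manifest


def gen_tissue_study(spec: GeneratorSpec) -> tuple[StudyDataset, dict]:
    """Radiolabel tissue-distribution study with destructive sampling.

    true_params: kp (tissue -> ratio), bp_ratio, plus the oral disposition
    parameters (cl_per_kg, vss_per_kg, ka, f, dose).  Six animals per
    timepoint at 0.5/2/8/24 h; tissue concentration = plasma * Kp, blood =
    plasma * BP, both time-independent in truth.
    """
    p = dict(spec.true_params)
    kp = dict(p.get("kp", {}))
    bp = float(p.get("bp_ratio", 1.0))
    rng = np.random.default_rng(spec.seed)
    times = list(TISSUE_TIMEPOINTS if spec.timepoints is None
                 else spec.timepoints)
    dose = float(p.get("dose", 3.0))
    rows = []
    subj = 0
    for t in times:
        for i in range(6):                      # six rats per timepoint
            subj += 1
            sex = "M" if i < 3 else "F"
            cp = float(_oral_conc([t], p.get("cl_per_kg", 1.9),
                                  p.get("vss_per_kg", 0.75),
                                  p.get("ka", 2.0), p.get("f", 0.12), dose,
                                  "one_compartment", p)[0])
            sid = f"T{subj:03d}"
            for matrix, scale in (
                    [("plasma", 1.0), ("blood", bp)]
                    + [(tis, k) for tis, k in kp.items()]):
                c = cp * scale * _lognormal_factor(rng, spec.noise_cv)
                rows.append((sid, spec.species, sex, "TD", "oral", dose,
                             "mg/kg", matrix, t, c))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    manifest = {"design": "tissue_study", "seed": spec.seed,
                "true_params": {**p, "kp": kp, "bp_ratio": bp},
                "timepoints": times, "noise_cv": spec.noise_cv,
                "n_records": len(df)}
    return StudyDataset(records=df, label="synthetic_tissue"), manifest


def gen_transwell(spec: GeneratorSpec) -> tuple[list[TranswellObservation], dict]:
    """Transwell fixtures at the assay loading concentrations.

    true_params: papp (1e-6 cm/s, may be a mapping conc->value), area
    (cm2), concentrations (uM), sample times (h).
    """
    p = dict(spec.true_params)
    area = float(p.get("area", 1.12))
    concs = list(p.get("concentrations", (1.0, 5.0, 30.0)))
    times = list((0.5, 1.0, 1.5, 2.0) if spec.timepoints is None
                 else spec.timepoints)
    rng = np.random.default_rng(spec.seed)
    papp_true = p["papp"]
    obs = []
    for c0 in concs:
        pval = float(papp_true[c0] if isinstance(papp_true, Mapping)
                     else papp_true)
        rate = pval * 1e-6 * 3600.0 * area * c0    # nmol/h
        amounts = []
        for t in times:
            a = rate * t * float(_lognormal_factor(rng, spec.noise_cv))
            amounts.append((t, a))
        obs.append(TranswellObservation(direction=p.get("direction", "A2B"),
                                        c0=c0, area=area,
                                        receiver_amounts=tuple(amounts)))
    manifest = {"design": "transwell", "seed": spec.seed,
                "true_params": p, "noise_cv": spec.noise_cv}
    return obs, manifest


def gen_dialysis(spec: GeneratorSpec) -> tuple[list[DialysisObservation], dict]:
    """Equilibrium-dialysis fixtures; true_params: fup, c_plasma (ng/mL),
    concentrations (uM levels), replicates."""
    p = dict(spec.true_params)
    fup_true = float(p["fup"])
    cp = float(p.get("c_plasma", 1000.0))
    levels = list(p.get("concentrations", (0.2, 2.0, 10.0)))
    reps = int(p.get("replicates", 1))
    rng = np.random.default_rng(spec.seed)
    obs = []
    for level in levels:
        for _ in range(reps):
            noise = float(_lognormal_factor(rng, spec.noise_cv))
            cb = min(fup_true * cp * noise, cp)
            obs.append(DialysisObservation(c_plasma=cp, c_buffer=cb,
                                           species=spec.species,
                                           nominal_conc=level))
    manifest = {"design": "dialysis", "seed": spec.seed, "true_params": p,
                "noise_cv": spec.noise_cv}
    return obs, manifest


def gen_depletion(spec: GeneratorSpec) -> tuple[DepletionCurve, dict]:
    """Hepatocyte depletion fixture; true_params: k_min (1/min) or
    t_half_min, cell_density (1e6 cells/mL)."""
    p = dict(spec.true_params)
    if "k_min" in p:
        k = float(p["k_min"])
    else:
        k = np.log(2) / float(p["t_half_min"])
    dens = float(p.get("cell_density", 1.0))
    times = np.asarray(DEPLETION_TIMEPOINTS_MIN if spec.timepoints is None
                       else spec.timepoints, float)
    rng = np.random.default_rng(spec.seed)
    noise = _lognormal_factor(rng, spec.noise_cv, size=len(times))
    frac = np.exp(-k * times) * noise
    frac[times == 0] = np.exp(-k * 0)   # anchor t=0 at 1 (normalisation)
    curve = DepletionCurve(times_min=tuple(times),
                           fraction_remaining=tuple(frac),
                           cell_density=dens)
    manifest = {"design": "depletion", "seed": spec.seed,
                "true_params": {**p, "k_min": k}, "noise_cv": spec.noise_cv}
    return curve, manifest


def generate(spec: GeneratorSpec):
    """Dispatch on the design name; returns (fixture(s), truth manifest)."""
    return {
        "pk_study": gen_pk_study,
        "tissue_study": gen_tissue_study,
        "transwell": gen_transwell,
        "dialysis": gen_dialysis,
        "depletion": gen_depletion,
    }[spec.design](spec)
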