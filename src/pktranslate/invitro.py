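"""In-vitro and tissue-distribution parameter derivation.

Turns raw transwell, equilibrium-dialysis, radiolabel tissue-distribution and
hepatocyte-depletion observations into model constants: apparent permeability
(Papp), efflux ratio, unbound plasma fraction (fup), blood:plasma and
tissue:plasma ratios, intrinsic clearance (CLint) and the well-stirred
hepatic clearance prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .physiology import SpeciesProfile


@dataclass(frozen=True)
class TranswellObservation:
    """Receiver-side amounts over time from a Caco-2 monolayer assay.

    direction: "A2B" (apical to basolateral) or "B2A".
    c0: donor concentration, uM (== nmol/mL == nmol/cm3).
    area: insert area, cm2.
    receiver_amounts: (time h, cumulative amount nmol) pairs.
    """

    direction: str
    c0: float
    area: float
    receiver_amounts: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.direction not in ("A2B", "B2A"):
            raise ValueError(f"direction must be A2B or B2A, got {self.direction!r}")
        if self.c0 <= 0 or self.area <= 0:
            raise ValueError("c0 and area must be positive")


@dataclass(frozen=True)
class DialysisObservation:
    c_plasma: float      # ng/mL
    c_buffer: float      # ng/mL
    species: str = "human"
    nominal_conc: float = 1.0    # uM

    def __post_init__(self) -> None:
        if self.c_buffer < 0 or self.c_plasma < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class DepletionCurve:
    """Substrate-depletion time course in a hepatocyte incubation."""

    times_min: tuple[float, ...]
    fraction_remaining: tuple[float, ...]
    cell_density: float = 1.0    # 1e6 cells/mL

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.fraction_remaining[0] - 1.0) > 0.2:
            raise ValueError("fraction remaining at t=0 must be ~1")


@dataclass(frozen=True)
class ClintResult:
    t_half_min: float
    clint_invitro: float          # uL/min/1e6 cells
    clint_scaled: float           # mL/min/kg
    cl_hepatic_predicted: float   # mL/min/kg, well-stirred
    r_squared: float
    poor_fit: bool


def papp(obs: TranswellObservation,
         window: tuple[float, float] | None = None) -> float:
    """Apparent permeability in 1e-6 cm/s.

    Papp = (d amount / dt) / (area * c0), slope by ordinary least squares
    over the sampling window; two points degrade to a two-point slope.
    Assumes sink conditions in the receiver.
    """
    pts = [(t, a) for t, a in obs.receiver_amounts
           if window is None or window[0] <= t <= window[1]]
    if len(pts) < 2:
        raise ValueError("need at least 2 receiver samples in the window")
    t = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    slope = np.polyfit(t, a, 1)[0]            # nmol/h
    if slope <= 0:
        raise ValueError("no measurable transport (non-positive slope)")
    papp_cm_s = slope / (obs.area * obs.c0 * 3600.0)
    return papp_cm_s * 1e6


def efflux_ratio(papp_ab: float, papp_ba: float) -> float:
    """Basolateral-to-apical over apical-to-basolateral permeability."""
    if papp_ab <= 0 or papp_ba <= 0:
        raise ValueError("permeabilities must be positive")
    return papp_ba / papp_ab


def fup(observations: DialysisObservation | Sequence[DialysisObservation]) -> float:
    """Unbound plasma fraction: c_buffer / c_plasma, replicate mean."""
    if isinstance(observations, DialysisObservation):
        observations = [observations]
    vals = []
    for obs in observations:
        if obs.c_plasma <= 0:
            raise ValueError("plasma concentration must be positive")
        if obs.c_buffer > obs.c_plasma:
            raise ValueError(
                f"binding artifact: buffer {obs.c_buffer} exceeds plasma {obs.c_plasma}")
        vals.append(obs.c_buffer / obs.c_plasma)
    return float(np.mean(vals))


def matrix_ratio(numerator: Sequence[tuple[float, float]],
                 denominator: Sequence[tuple[float, float]],
                 times: Sequence[float]) -> tuple[dict[float, float], float]:
    """Per-time concentration ratios and their arithmetic mean.

    Used for both the blood:plasma ratio and tissue:plasma partition
    coefficients.  Times where the denominator is zero are excluded (with
    all excluded being an error).  Both profiles must be sampled at the
    requested times.
    """
    num = dict(numerator)
    den = dict(denominator)
    ratios: dict[float, float] = {}
    for t in times:
        if t not in num or t not in den:
            raise ValueError(f"profiles not sampled at requested time {t}")
        if den[t] == 0:
            continue
        ratios[t] = num[t] / den[t]
    if not ratios:
        raise ValueError("denominator zero at every requested time")
    return ratios, float(np.mean(list(ratios.values())))


def well_stirred_cl(q_h: float, fu_b: float, clint: float) -> float:
    """Well-stirred hepatic clearance: Qh*fub*CLint / (Qh + fub*CLint).

    All clearances and flow in the same units (here mL/min/kg); monotone in
    CLint and bounded above by Qh.
    """
    if q_h <= 0:
        raise ValueError("hepatic blood flow must be positive")
    return q_h * fu_b * clint / (q_h + fu_b * clint)


def clint_from_depletion(curve: DepletionCurve, species: SpeciesProfile,
                         fup_plasma: float, bp_ratio: float) -> ClintResult:
    """Intrinsic clearance from a log-linear substrate-depletion fit.

    k = -slope of ln(fraction remaining) vs time; CLint(in vitro) =
    k * 1000 / cell density (uL/min/1e6 cells); scaled to mL/min/kg through
    hepatocellularity and liver weight; hepatic clearance by the
    well-stirred model with fu_blood = fup / BP.
    """
    t = np.asarray(curve.times_min, dtype=float)
    f = np.asarray(curve.fraction_remaining, dtype=float)
    pos = f > 0
    if pos.sum() < 3:
        raise ValueError("need >=3 timepoints with positive fraction remaining")
    t, lf = t[pos], np.log(f[pos])
    slope, intercept = np.polyfit(t, lf, 1)
    k = -slope
    if k <= 0:
        raise ValueError("no measurable depletion")
    pred = intercept + slope * t
    ss_res = float(np.sum((lf - pred) ** 2))
    ss_tot = float(np.sum((lf - lf.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    t_half = math.log(2) / k
    clint_invitro = k * 1000.0 / curve.cell_density
    liver_g_per_kg = species.liver_weight_fraction * 1000.0
    clint_scaled = (clint_invitro * species.hepatocellularity
                    * liver_g_per_kg / 1000.0)      # mL/min/kg
    fu_b = fup_plasma / bp_ratio
    cl_h = well_stirred_cl(species.q_hepatic, fu_b, clint_scaled)
    return ClintResult(
        t_half_min=t_half, clint_invitro=clint_invitro,
        clint_scaled=clint_scaled, cl_hepatic_predicted=cl_h,
        r_squared=r2, poor_fit=r2 < 0.8,
    )
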