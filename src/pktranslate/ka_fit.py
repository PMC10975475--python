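"""One-compartment oral absorption model and Ka estimation.

The Bateman disposition C(t) = D*Ka / (V/F * (Ka-Ke)) * (exp(-Ke t) -
exp(-Ka t)) is fitted to mean concentration-time data on the log scale.  The
model is symmetric under exchanging Ka and Ke with V/F rescaled ("flip-flop"
ambiguity); estimates are reported under the convention Ka > Ke, with the
ambiguity flagged.  Species-level estimates feed a min/midpoint/max policy
for the human absorption rate constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class OneCompartmentFit:
    ka: float              # 1/h
    ke: float              # 1/h
    v_over_f: float        # L/kg when dose is mg/kg
    objective: float       # sum of squared log residuals
    converged: bool
    flip_flop: bool


@dataclass
class KaPolicy:
    typical: float
    low: float
    high: float
    by_species: dict[str, float]


def onecomp_oral_conc(t, ka: float, ke: float, v_over_f: float,
                      dose: float) -> np.ndarray:
    """Bateman concentration in ng/mL for dose in mg/kg, V/F in L/kg.

    The removable singularity at ka == ke is evaluated by its analytic
    limit dose*ke*t*exp(-ke*t)/v_over_f.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times not allowed")
    if min(ka, ke, v_over_f, dose) <= 0:
        raise ValueError("ka, ke, v_over_f and dose must be positive")
    scale = dose * 1000.0 / v_over_f      # mg/kg / (L/kg) -> ug/L == ng/mL
    if abs(ka - ke) < 1e-9 * max(ka, ke):
        k = 0.5 * (ka + ke)
        return scale * k * t * np.exp(-k * t)
    return scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def _objective(params: np.ndarray, t: np.ndarray, logc: np.ndarray,
               dose: float) -> float:
    ka, ke, v = np.exp(params)
    pred = onecomp_oral_conc(t, ka, ke, v, dose)
    if np.any(pred <= 0):
        return 1e12
    return float(np.sum((np.log(pred) - logc) ** 2))


#: multi-start absorption-rate grid, 1/h
KA_GRID = (0.1, 0.5, 1.0, 2.0, 5.0)


def fit_onecomp(times, mean_concs, dose: float,
                flip_flop_rtol: float = 0.01) -> OneCompartmentFit:
    """Least squares on log concentrations with a fixed multi-start grid.

    Ke is initialised from the terminal slope of the last three points; the
    local searches are Nelder-Mead.  The returned solution is canonicalised
    to ka > ke (the mirrored solution fits identically by construction and
    is reported through the flip_flop flag).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(mean_concs, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    if len(t) < 4:
        raise ValueError("need at least 4 positive observations")
    logc = np.log(c)
    # terminal-slope initialisation for ke
    slope = np.polyfit(t[-3:], logc[-3:], 1)[0]
    ke0 = max(-slope, 1e-3)
    v0 = dose * 1000.0 / max(c.max(), 1e-9)
    best = None
    for ka0 in KA_GRID:
        x0 = np.log([ka0, ke0, max(v0, 1e-6)])
        res = optimize.minimize(
            _objective, x0, args=(t, logc, dose), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("one-compartment fit failed from every start")
    ka, ke, v = np.exp(best.x)
    # canonical orientation ka > ke; the mirror (ke, ka, v*ke/ka) traces the
    # identical curve, so reorienting does not change the objective
    if ka < ke:
        ka, ke, v = ke, ka, v * ke / ka
    mirrored = _objective(np.log([ke, ka, v * ke / ka]), t, logc, dose)
    flip = bool(np.isfinite(mirrored)
                and mirrored <= best.fun + flip_flop_rtol * max(best.fun, 1e-12))
    return OneCompartmentFit(ka=float(ka), ke=float(ke), v_over_f=float(v),
                             objective=float(best.fun),
                             converged=bool(best.success), flip_flop=flip)


def ka_policy(fits) -> KaPolicy:
    """Human Ka policy: range = [min, max] of species estimates, typical =
    midpoint of the range."""
    if len(fits) < 2:
        raise ValueError("Ka policy needs estimates from at least 2 species")
    kas = {sp: (f.ka if isinstance(f, OneCompartmentFit) else float(f))
           for sp, f in fits.items()}
    lo, hi = min(kas.values()), max(kas.values())
    return KaPolicy(typical=0.5 * (lo + hi), low=lo, high=hi, by_species=kas)
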