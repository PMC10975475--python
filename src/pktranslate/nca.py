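"""Non-compartmental pharmacokinetic analysis.

Cmax/Tmax, trapezoidal AUC (linear or linear-up/log-down), terminal-phase
regression with adjusted-R2 point selection, CL/Vss from IV bolus data,
bioavailability against an IV reference, and the species-level
bioavailability summary policy.

Unit conventions: time h, concentration ng/mL, dose mg/kg, clearance L/h/kg,
volume L/kg.  AUC in h*ng/mL.  With dose in mg/kg, CL (L/h/kg) =
dose * 1000 / AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import StudyDataset


@dataclass
class TerminalFit:
    lambda_z: float | None      # 1/h
    t_half: float | None        # h
    n_points: int
    adj_r_squared: float | None
    defined: bool


@dataclass
class PKParameters:
    cmax: float | None = None          # ng/mL
    tmax: float | None = None          # h
    auc_0_t: float | None = None       # h*ng/mL
    auc_0_inf: float | None = None
    lambda_z: float | None = None      # 1/h
    t_half: float | None = None        # h
    mrt: float | None = None           # h
    cl: float | None = None            # L/h/kg (IV only)
    vss: float | None = None           # L/kg (IV only)
    f: float | None = None             # percent (oral only)
    flags: list[str] = field(default_factory=list)


def auc_trapezoid(times, concs, method: str = "linear") -> float:
    """AUC over the observed span by the trapezoidal rule.

    method "linear" or "linear_up_log_down"; the latter applies logarithmic
    interpolation on strictly decreasing, positive segments.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linear_up_log_down":
        raise ValueError(f"unknown AUC method {method!r}")
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if 0 < c2 < c1:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return float(total)


def _aumc_trapezoid(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(t * c, t))


def terminal_fit(times, concs, min_points: int = 3) -> TerminalFit:
    """Log-linear terminal regression with adjusted-R2 subset selection.

    Candidate subsets are the last k points after (and excluding) Tmax,
    k = min_points..n; the subset maximizing adjusted R2 wins, ties going to
    more points.  Profiles with no decreasing terminal phase are flagged
    undefined rather than raising.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    i_max = int(np.argmax(c))
    t_term = t[i_max + 1:]
    c_term = c[i_max + 1:]
    pos = c_term > 0
    t_term, c_term = t_term[pos], c_term[pos]
    n = len(t_term)
    if n < min_points:
        return TerminalFit(None, None, 0, None, defined=False)
    best: tuple[float, int, float] | None = None   # (adj_r2, k, lambda_z)
    logc = np.log(c_term)
    for k in range(min_points, n + 1):
        tt, ll = t_term[-k:], logc[-k:]
        slope, intercept = np.polyfit(tt, ll, 1)
        if slope >= 0:
            continue
        pred = intercept + slope * tt
        ss_res = float(np.sum((ll - pred) ** 2))
        ss_tot = float(np.sum((ll - ll.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1 - ss_res / ss_tot
        adj = 1 - (1 - r2) * (k - 1) / (k - 2)
        if best is None or adj >= best[0] - 1e-12:
            best = (adj, k, -slope)
    if best is None:
        return TerminalFit(None, None, 0, None, defined=False)
    adj, k, lz = best
    return TerminalFit(lambda_z=lz, t_half=math.log(2) / lz, n_points=k,
                       adj_r_squared=adj, defined=True)


def _profile_params(t: np.ndarray, c: np.ndarray, tail_warn: float = 0.20,
                    method: str = "linear") -> PKParameters:
    p = PKParameters()
    i_max = int(np.argmax(c))
    p.cmax = float(c[i_max])
    p.tmax = float(t[i_max])     # argmax returns the earliest tie
    p.auc_0_t = auc_trapezoid(t, c, method)
    fit = terminal_fit(t, c)
    if fit.defined:
        p.lambda_z = fit.lambda_z
        p.t_half = fit.t_half
        tail = float(c[-1]) / fit.lambda_z
        p.auc_0_inf = p.auc_0_t + tail
        if tail > tail_warn * p.auc_0_inf:
            p.flags.append("auc_tail_gt_20pct")
        aumc = _aumc_trapezoid(t, c)
        aumc_tail = (float(c[-1]) * float(t[-1]) / fit.lambda_z
                     + float(c[-1]) / fit.lambda_z ** 2)
        p.mrt = (aumc + aumc_tail) / p.auc_0_inf
    else:
        p.flags.append("terminal_phase_undefined")
    return p


def nca_iv(times, concs, dose_mg_kg: float,
           method: str = "linear") -> PKParameters:
    """IV-bolus NCA: CL = dose / AUC(0-inf), MRT = AUMC/AUC, Vss = CL*MRT."""
    if dose_mg_kg is None or not dose_mg_kg > 0:
        raise ValueError("IV dose (mg/kg) required and positive")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t[0] > 0:
        # bolus convention: back-extrapolate C0 from the first two points
        # (log-linear when declining, else carry the first value back)
        if len(c) >= 2 and 0 < c[1] < c[0]:
            slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
            c0 = c[0] * math.exp(-slope * t[0])
        else:
            c0 = c[0]
        t = np.insert(t, 0, 0.0)
        c = np.insert(c, 0, c0)
    p = _profile_params(t, c, method=method)
    if p.auc_0_inf:
        p.cl = dose_mg_kg * 1000.0 / p.auc_0_inf        # L/h/kg
        if p.mrt and p.mrt > 0:
            p.vss = p.cl * p.mrt                        # L/kg
        else:
            p.flags.append("mrt_invalid")
    return p


def nca_oral(times, concs, dose_mg_kg: float,
             method: str = "linear") -> PKParameters:
    if dose_mg_kg is None or not dose_mg_kg > 0:
        raise ValueError("oral dose (mg/kg) required and positive")
    return _profile_params(np.asarray(times, float), np.asarray(concs, float),
                           method=method)


def bioavailability(auc_po: float, dose_po: float,
                    auc_iv: float, dose_iv: float) -> float:
    """Absolute oral bioavailability in percent."""
    if auc_iv <= 0:
        raise ValueError("IV AUC must be positive")
    return 100.0 * (auc_po / dose_po) / (auc_iv / dose_iv)


def summarize_f(values) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and range of per-group bioavailability values."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no bioavailability values supplied")
    return float(np.mean(vals)), (min(vals), max(vals))


def nca_summary(dataset: StudyDataset, matrix: str = "plasma",
                method: str = "linear") -> pd.DataFrame:
    """Per-subject NCA, summarized mean +/- sd per (route, group, sex).

    Below-LLOQ records are excluded from the computation (counted in the
    ``n_blq`` column).  Oral bioavailability is computed per subject against
    the sex-matched mean dose-normalized IV exposure when an IV arm exists.
    """
    df = dataset.records
    df = df[df["matrix"] == matrix]
    rows = []
    for (subj, route, group, sex), g in df.groupby(
            ["subject_id", "route", "group", "sex"], sort=False):
        gg = g.sort_values("time_h")
        kept = gg[~gg["below_lloq"]]
        if len(kept) < 2:
            continue
        dose = float(gg["dose"].iloc[0])
        t = kept["time_h"].to_numpy()
        c = kept["conc_ng_per_ml"].to_numpy()
        p = (nca_iv(t, c, dose, method) if route == "iv_bolus"
             else nca_oral(t, c, dose, method))
        rows.append({
            "subject_id": subj, "route": route, "group": group, "sex": sex,
            "dose": dose, "n_blq": int(gg["below_lloq"].sum()),
            "cmax": p.cmax if route == "oral" else None, "tmax": p.tmax,
            "t_half": p.t_half, "auc_0_t": p.auc_0_t,
            "auc_0_inf": p.auc_0_inf, "cl": p.cl, "vss": p.vss,
        })
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValueError("no evaluable profiles in dataset")
    # reference dose-normalized IV exposure per sex for F
    iv = per_subject[per_subject["route"] == "iv_bolus"]
    iv_ref = {sex: (g["auc_0_t"] / g["dose"]).mean()
              for sex, g in iv.groupby("sex")} if len(iv) else {}
    f_vals = []
    for _, r in per_subject.iterrows():
        if r["route"] == "oral" and r["sex"] in iv_ref:
            f_vals.append(100.0 * (r["auc_0_t"] / r["dose"]) / iv_ref[r["sex"]])
        else:
            f_vals.append(None)
    per_subject["f_pct"] = f_vals

    def _ms(x):
        x = x.dropna()
        return (float(x.mean()), float(x.std(ddof=1))) if len(x) else (None, None)

    out = []
    for (route, group, sex), g in per_subject.groupby(["route", "group", "sex"]):
        rec = {"route": route, "group": group, "sex": sex,
               "dose": float(g["dose"].iloc[0]), "n": len(g)}
        for col in ("cmax", "tmax", "t_half", "auc_0_t", "auc_0_inf",
                    "cl", "vss", "f_pct"):
            m, s = _ms(g[col])
            rec[f"{col}_mean"], rec[f"{col}_sd"] = m, s
        out.append(rec)
    return pd.DataFrame(out)
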