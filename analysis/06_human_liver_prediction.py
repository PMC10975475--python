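#!/usr/bin/env python
"""Human PBPK model and liver concentration prediction.

Extrapolates the rat model to a 60-kg adult (scaled clearance, human
unbound fraction, typical absorption rate), simulates the single-ascending-
dose levels (0.15, 0.5, 1 and 3 mg oral), and predicts liver
concentration-time profiles with a virtual-population 90% band at the top
dose.  Writes results/human_liver_profiles.csv, human_liver_band.csv and
human_liver_summary.tsv.
"""

import numpy as np
import pandas as pd

from pktranslate import pbpk, reference as ref
from pktranslate.core_io import write_report
from pktranslate.nca import auc_trapezoid
from pktranslate.physiology import HUMAN

model = pbpk.build_model(ref.XZP5610, HUMAN, ka=1.46)
model = pbpk.calibrate_f_abs(model, ref.HUMAN_F)
print(f"human model: CL {model.cl_plasma:.2f} L/h, f_abs {model.f_abs:.2f}, "
      f"liver Kp {model.kp['liver']}")

DOSES_MG = (0.15, 0.5, 1.0, 3.0)
frames, rows = [], []
for dose in DOSES_MG:
    sim = pbpk.simulate(model, [(0.0, "oral", dose)], t_end=48.0)
    frame = sim.to_frame(["plasma", "liver"])
    frame.insert(0, "dose_mg", dose)
    frames.append(frame)
    liver = sim.concentrations["liver"].to_numpy()
    rows.append({"dose_mg": dose,
                 "liver_cmax_ng_ml": liver.max(),
                 "liver_auc_ng_h_ml": auc_trapezoid(sim.times, liver),
                 "plasma_cmax_ng_ml": sim.plasma().max(),
                 "plasma_auc_ng_h_ml": auc_trapezoid(sim.times,
                                                     sim.plasma())})
pd.concat(frames).to_csv("results/human_liver_profiles.csv", index=False)

summary = pd.DataFrame(rows)
sys_sim = pbpk.simulate(model, [(0.0, "iv_bolus", 1.0)], t_end=96.0,
                        grid_dt=0.1)
sys_ratio = pbpk.liver_plasma_ratio(sys_sim, basis="auc")
write_report([("human_liver_summary", summary)], "results")

# virtual-population 90% band at the top dose
bands = pbpk.population_simulate(model, [(0.0, "oral", 3.0)], t_end=48.0,
                                 n=100, seed=2024, grid_dt=0.2,
                                 percentiles=(5.0, 50.0, 95.0))
band = pd.DataFrame({"time_h": bands.times,
                     "liver_p5": bands.liver[0],
                     "liver_median": bands.liver[1],
                     "liver_p95": bands.liver[2]})
band.to_csv("results/human_liver_band.csv", index=False)

print(summary.to_string(index=False))
print(f"\nsystemic liver:plasma AUC ratio {sys_ratio:.1f} "
      f"(reported Cmax/AUC-based ratios 10.3 / 13.5)")
print("dose-normalised liver exposure is constant across doses "
      "(linear kinetics):",
      np.allclose(summary['liver_auc_ng_h_ml'] / summary['dose_mg'],
                  (summary['liver_auc_ng_h_ml'] / summary['dose_mg']).iloc[0],
                  rtol=1e-6))
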