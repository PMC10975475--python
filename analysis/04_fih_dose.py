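#!/usr/bin/env python
"""First-in-human dose selection.

Builds the BSA-method and systemic-exposure-method dose recommendations
from the animal NOAELs and steady-state exposures, applies the 10-fold
safety factor, and assembles the dose plan (starting dose, anticipated
effect level, maximum dose).  Writes results/mrsd_bsa.tsv,
mrsd_exposure.tsv and dose_plan.tsv.
"""

import pandas as pd

from pktranslate import fih_dose as fd, reference as ref
from pktranslate.core_io import write_report
from pktranslate.physiology import DOG, HUMAN, RAT

fup = ref.XZP5610.fup_by_species
km = {"rat": RAT.km_factor, "dog": DOG.km_factor, "mouse": 3.0}
BW_H, SF = HUMAN.body_weight, 10.0

bsa = [fd.bsa_recommendation(sp, noael, km[sp], HUMAN.km_factor, BW_H,
                             sf=SF, sex=sex)
       for (sp, sex), noael in ref.NOAEL_MG_KG.items()
       if not (sp == "dog" and sex == "F")]          # one dog NOAEL level

expo = [fd.exposure_recommendation(
            sp, ref.NOAEL_MG_KG[(sp, sex)], auc, fup[sp], fup["human"],
            ref.HUMAN_CL_L_H, ref.HUMAN_F, sf=SF, sex=sex)
        for (sp, sex), auc in ref.STEADY_AUC24.items()]

# efficacy-dose extrapolation from the pharmacology models (BSA method)
efficacy_heds = [fd.hed_bsa(ref.MABEL_MG_KG["mouse"], km["mouse"],
                            HUMAN.km_factor, BW_H),
                 fd.hed_bsa(ref.MABEL_MG_KG["rat"], km["rat"],
                            HUMAN.km_factor, BW_H)]

plan = fd.build_dose_plan(bsa + expo, mabel_mg=2.0, mtd_mg=3.0,
                          efficacy_heds_mg=efficacy_heds,
                          mrsd_override=0.15,
                          rationale="conservative starting dose below the "
                                    "computed minimum MRSD of 0.16 mg")

tables = [("mrsd_bsa", fd.recommendations_table(bsa)),
          ("mrsd_exposure", fd.recommendations_table(expo)),
          ("dose_plan", pd.DataFrame([{
              "mrsd_mg": plan.mrsd_mg, "mabel_mg": plan.mabel_mg,
              "mtd_mg": plan.mtd_mg,
              "mrsd_range_lo": plan.provenance["mrsd_range_mg"][0],
              "mrsd_range_hi": plan.provenance["mrsd_range_mg"][1],
              "efficacy_hed_lo": plan.provenance["efficacy_hed_range_mg"][0],
              "efficacy_hed_hi": plan.provenance["efficacy_hed_range_mg"][1],
          }]))]
write_report(tables, "results")
print(fd.recommendations_table(bsa + expo).to_string(index=False))
print(f"\nDose plan: MRSD {plan.mrsd_mg} mg, MABEL {plan.mabel_mg} mg, "
      f"MTD {plan.mtd_mg} mg ({plan.rationale})")
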