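#!/usr/bin/env python
"""Hypoxic cardiorespiratory response metrics for the cohort: clean the
breath-by-breath series, take exercise-phase medians, and compute HVR, HCR
(normalized to desaturation, normoxia-minus-hypoxia convention) and the
simple differences ΔIDR, ΔCV, ΔVO2 for CON->H1 and CON->H2."""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from hdemg_hypoxia.cardioresp import clean_bxb, deltas, exercise_median, hcr, hvr
from hdemg_hypoxia.core import BxBSeries
from hdemg_hypoxia.muprops import summarize_mus

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=Path, default=Path("results/sim"))
ap.add_argument("--task-window", type=float, nargs=2, default=(0.0, 180.0))
args = ap.parse_args()

bxb = pd.read_csv(args.out / "cohort_bxb.csv")
sessions = pd.read_csv(args.out / "cohort_sessions.csv").set_index(
    ["participant", "condition"]
)
mu = pd.read_csv(args.out / "cohort_mu_properties.csv")
medians = summarize_mus(mu).set_index(["participant", "condition"])

rows = []
for (pid, cond), sub in bxb.groupby(["participant", "condition"]):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = clean_bxb(
            BxBSeries(times=sub.time_s.to_numpy(), hr=sub.hr.to_numpy(),
                      ve=sub.ve.to_numpy(), vo2=sub.vo2.to_numpy())
        )
    med = exercise_median(series, *args.task_window)
    rows.append({"participant": pid, "condition": cond, **med,
                 "spo2": sessions.loc[(pid, cond), "spo2_end"]})
phys = pd.DataFrame(rows).set_index(["participant", "condition"])

responses = []
for pid in phys.index.get_level_values(0).unique():
    n = phys.loc[(pid, "CON")]
    for contrast, hcond in (("CON->H1", "H1"), ("CON->H2", "H2")):
        h = phys.loc[(pid, hcond)]
        responses.append(
            {"participant": pid, "contrast": contrast,
             "hvr": hvr(h.ve, n.ve, n.spo2, h.spo2),
             "hcr": hcr(h.hr, n.hr, n.spo2, h.spo2),
             "d_vo2": deltas(h.vo2, n.vo2),
             "d_idr": deltas(medians.loc[(pid, hcond), "idr"],
                             medians.loc[(pid, "CON"), "idr"]),
             "d_cv": deltas(medians.loc[(pid, hcond), "cv"],
                            medians.loc[(pid, "CON"), "cv"])}
        )
resp = pd.DataFrame(responses)
resp.to_csv(args.out / "cohort_responses.csv", index=False)
print(resp.groupby("contrast")[["hvr", "hcr", "d_vo2", "d_idr", "d_cv"]]
      .mean().round(3).to_string())
print("\nHVR/HCR positive (ventilation and heart rate rise with "
      "desaturation):",
      f"{np.mean(resp.hvr > 0) * 100:.0f}% / {np.mean(resp.hcr > 0) * 100:.0f}%")
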