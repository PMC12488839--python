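#!/usr/bin/env python
"""Inferential analysis of the cohort: z-score outlier filtering and log
transform of IDR, REML linear mixed models (condition and sex fixed,
participant random) with Satterthwaite effect sizes and Holm post-hocs,
and Pearson correlations between motor-unit responses and hypoxic
cardiorespiratory responses."""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from hdemg_hypoxia.stats import corr_matrix, correlate, fit_lmm, prepare_mu_table

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=Path, default=Path("results/sim"))
args = ap.parse_args()

mu = prepare_mu_table(pd.read_csv(args.out / "cohort_mu_properties.csv"))
print(f"{(~mu.idr_kept).sum()} IDR outliers removed of {len(mu)} observations")

for response in ("log_idr", "cv"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = fit_lmm(mu, response)
    rep.terms.round(4).to_csv(args.out / f"lmm_{response}_terms.csv", index=False)
    rep.contrasts.round(4).to_csv(
        args.out / f"lmm_{response}_contrasts.csv", index=False
    )
    summary = pd.DataFrame(
        [{"response": response, "AIC": rep.aic, "BIC": rep.bic,
          "R2_marginal": rep.r2_marginal, "R2_conditional": rep.r2_conditional,
          "sigma2_subject": rep.sigma2_subject, "sigma2_resid": rep.sigma2_resid,
          "random_effect_p": rep.random_effect_p}]
    )
    summary.round(4).to_csv(args.out / f"lmm_{response}_model.csv", index=False)
    print(f"\n=== {response} ===")
    print(rep.terms.round(4).to_string(index=False))
    print(rep.contrasts.round(4).to_string(index=False))
    print(f"R2 marginal {rep.r2_marginal:.3f} / conditional "
          f"{rep.r2_conditional:.3f}; AIC {rep.aic:.0f} BIC {rep.bic:.0f}")

resp = pd.read_csv(args.out / "cohort_responses.csv")
pairs = [("d_idr", "hvr"), ("d_idr", "hcr"), ("d_idr", "d_vo2"),
         ("d_cv", "hvr"), ("d_cv", "hcr"), ("d_cv", "d_vo2"),
         ("d_idr", "d_cv")]
tables = []
for contrast, sub in resp.groupby("contrast"):
    out = correlate(sub, pairs)
    out.insert(0, "contrast", contrast)
    tables.append(out)
corr = pd.concat(tables, ignore_index=True)
corr.round(4).to_csv(args.out / "response_correlations.csv", index=False)
print("\nresponse correlations:")
print(corr.round(3).to_string(index=False))

r, p = corr_matrix(resp[resp.contrast == "CON->H2"], ["hvr", "hcr", "d_vo2", "d_idr", "d_cv"])
r.round(3).to_csv(args.out / "response_corr_matrix_h2.csv")
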