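#!/usr/bin/env python
"""Simulate the trial cohort and fit the per-tumor survival models.

The cohort generator draws per-tumor progression from a proportional-hazards
model at the published effect sizes (p16 coefficient -1.578, per-SD ADC
coefficient 0.645); the ITFFR table is built with the per-tumor censoring
rule and refit with the interaction model of the published analysis. Also
runs the coefficient-recovery and type-I calibration studies and the
18-month landmark classification.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from hnqi.experiments import cox_recovery_study, type1_error_study
from hnqi.io import write_report, write_table
from hnqi.phantom import CohortSpec, simulate_cohort
from hnqi.survival import CoxSpec, build_dffs, build_itffr, fit_cox, landmark_groups

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--fast", action="store_true", help="skip the replicate studies")
args = parser.parse_args()
seed = args.seed % (2**20)

spec = CohortSpec(n_patients=54, betas={"p16": -1.578, "adc_sd": 0.645}, seed=seed)
sim = simulate_cohort(spec)
itffr = build_itffr(sim).merge(
    sim[["tumor_id", "p16", "adc_sd"]], left_on="unit_id", right_on="tumor_id"
)
dffs = build_dffs(sim)

fit = fit_cox(
    itffr,
    CoxSpec(covariates=["p16", "adc_sd"], interactions=[("adc_sd", "p16")],
            per_sd=frozenset({"adc_sd"}), center=frozenset({"adc_sd"}),
            cluster_col="patient_id"),
)

args.out.mkdir(parents=True, exist_ok=True)
write_table(itffr, args.out / "itffr_table.csv")
write_table(dffs, args.out / "dffs_table.csv")

print(f"simulated cohort: {sim['patient_id'].nunique()} patients, {len(sim)} tumors, "
      f"{itffr['event'].sum()} locoregional events, {dffs['event'].sum()} distant failures")
print("\nper-tumor Cox model (p16 + ADC/SD + interaction, ADC centered):")
print(fit.summary[["coef", "hr", "ci95_lo", "ci95_hi", "wald_p"]].round(3).to_string())
print("\nderived ADC effects by p16 group:")
print(fit.group_effects[["coef", "hr", "wald_p"]].round(3).to_string())
print(f"\nconcordance (naive SE above; cluster-robust SE also computed): "
      f"c-index = {fit.c_index:.3f}")

landmark = landmark_groups(sim, cutoff=18.0)
counts = landmark["group"].value_counts()
write_table(landmark, args.out / "landmark_groups.csv")
print("\n18-month landmark groups:")
print(counts.to_string())

report = {
    "cox_summary": fit.summary.reset_index().to_dict(orient="records"),
    "group_effects": fit.group_effects.reset_index().to_dict(orient="records"),
    "c_index": fit.c_index,
    "landmark_counts": counts.to_dict(),
}

if not args.fast:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recov = cox_recovery_study(n_replicates=100, seed=seed)
        null = type1_error_study(n_replicates=400, seed=seed)
    print(f"\nrecovery study (100 cohorts of ~500 tumors at the published betas): "
          f"p16 within 2 SE {recov['p16_within_2se_pct']:.0f}%, "
          f"ADC within 2 SE {recov['adc_within_2se_pct']:.0f}%")
    print(f"type-I study (400 null cohorts of 54 patients): "
          f"Wald rejection {null['rejection_rate_pct']:.1f}% at nominal 5%")
    report["recovery_study"] = recov
    report["type1_study"] = null

write_report(report, args.out / "survival_models.json")
print(f"\ntables -> {args.out}/itffr_table.csv, {args.out}/survival_models.json")
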