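#!/usr/bin/env python
"""Bland-Altman agreement and fit metrics.

Compares each estimator's agreement with measured LDL-C: mean bias with
95% limits of agreement (overall and in the high-TG 300-399 mg/dL
subgroup, where the fixed Friedewald ratio under-estimates most), plus
prediction R^2, signed mean relative error, MAE and MSE. Writes the
metrics table under results/.
"""

from pathlib import Path

import pandas as pd

from ldlratio.core import read_cohort
from ldlratio.estimators import (
    estimate_friedewald,
    estimate_martin_hopkins,
    method_label,
    read_ratio_table,
)
from ldlratio.evaluate import bland_altman, fit_metrics

OUT = Path(__file__).resolve().parent.parent / "results"
cohort = read_cohort(OUT / "cohort_population1.csv")
meas = cohort["ldl_d"]

estimates = {"LDL-C_F": estimate_friedewald(cohort)}
for stat in ("median", "optimal"):
    table = read_ratio_table(OUT / f"ratios_twelve_combined_{stat}.json")
    estimates[method_label(stat, table.scheme)] = estimate_martin_hopkins(cohort, table)

rows = []
print(f"{'method':>14} {'bias':>7} {'LoA':>18} {'bias@TG300+':>12} {'R2':>6} {'MRE%':>6} {'MAE':>6} {'MSE':>7}")
for label, est in estimates.items():
    ba = bland_altman(est, meas)
    hi = bland_altman(est, meas, tg=cohort["tg"], tg_interval=(300.0, 400.0))
    fm = fit_metrics(est, meas)
    rows.append(
        {"method": label, "mean_bias": ba.mean_bias, "loa_lo": ba.loa_lo,
         "loa_hi": ba.loa_hi, "bias_tg300": hi.mean_bias, **fm}
    )
    print(
        f"{label:>14} {ba.mean_bias:>7.2f} ({ba.loa_lo:>7.2f},{ba.loa_hi:>7.2f})"
        f" {hi.mean_bias:>12.2f} {fm['r2']:>6.3f} {fm['mre']:>6.2f} {fm['mae']:>6.2f} {fm['mse']:>7.1f}"
    )

pd.DataFrame(rows).to_csv(OUT / "agreement.csv", index=False)
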