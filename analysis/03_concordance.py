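#!/usr/bin/env python
"""Concordance of LDL-C estimators with measured LDL-C.

On the validation cohort, classifies Friedewald and the locally derived
median/optimal Martin-Hopkins-form estimates into the six guideline
bands against measured LDL-C, and tabulates concordant counts and rates
(with exact 95% CIs) overall and by TG stratum, plus pairwise exact
McNemar comparisons of median vs optimal within each scheme. Writes the
concordance table under results/.
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
from ldlratio.evaluate import classify, concordance_summary, mcnemar_exact

OUT = Path(__file__).resolve().parent.parent / "results"
cohort = read_cohort(OUT / "cohort_population1.csv")
meas = cohort["ldl_d"]

estimates = {"LDL-C_F": estimate_friedewald(cohort)}
for scheme_name in ("six_tg", "twelve_combined"):
    for stat in ("median", "optimal"):
        table = read_ratio_table(OUT / f"ratios_{scheme_name}_{stat}.json")
        estimates[method_label(stat, table.scheme)] = estimate_martin_hopkins(cohort, table)

rows = []
print(f"{'method':>16} {'concordant':>11} {'rate':>7}  95% CI")
for label, est in estimates.items():
    results = classify(est, meas)
    (overall,) = concordance_summary(results)
    print(
        f"{label:>16} {overall.concordant:>6}/{overall.n} {overall.pct:>6}%"
        f"  ({100 * overall.ci_lo:.1f}-{100 * overall.ci_hi:.1f})"
    )
    rows.append({"method": label, **overall.as_dict()})
    for s in concordance_summary(results, group_by="tg_strata", tg=cohort["tg"]):
        rows.append({"method": label, **s.as_dict()})

pd.DataFrame(rows).to_csv(OUT / "concordance.csv", index=False)

print("\nmedian vs optimal (paired McNemar, exact):")
for scheme_name, km, ko in (
    ("six_tg", "LDL-C_KM-6-TG", "LDL-C_KO-6-TG"),
    ("twelve_combined", "LDL-C_KM-12", "LDL-C_KO-12"),
):
    ok_m = classify(estimates[km], meas)["status"] == "concordant"
    ok_o = classify(estimates[ko], meas)["status"] == "concordant"
    b = int((ok_m & ~ok_o).sum())
    c = int((~ok_m & ok_o).sum())
    print(f"  {km} vs {ko}: discordant ({b}, {c}), p = {mcnemar_exact(b, c):.3f}")
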