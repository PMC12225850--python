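#!/usr/bin/env python
"""Derive median and concordance-optimal TG/VLDL-C ratio tables.

On the combined derivation cohort, derives per-cell median ratios (with
distribution-free 95% CIs and achieved confidence levels) and optimal
ratios (grid search 1.0-10.0 step 0.1 maximizing guideline-category
concordance) for the 6-cell TG scheme and the 12-cell TG x non-HDL-C
scheme, and prints them side by side — the shape of the published
ratio table. Writes the four tables as JSON under results/.
"""

from pathlib import Path

from ldlratio.core import read_cohort
from ldlratio.estimators import write_ratio_table
from ldlratio.ratios import median_ratio_table, optimal_ratio_table
from ldlratio.strata import CellId, builtin_scheme

OUT = Path(__file__).resolve().parent.parent / "results"
cohort = read_cohort(OUT / "cohort_combined.csv")

for scheme_name in ("six_tg", "twelve_combined"):
    scheme = builtin_scheme(scheme_name)
    med = median_ratio_table(cohort, scheme)
    opt = optimal_ratio_table(cohort, scheme)
    write_ratio_table(med, OUT / f"ratios_{scheme_name}_median.json")
    write_ratio_table(opt, OUT / f"ratios_{scheme_name}_optimal.json")
    print(f"\n{scheme_name} ({scheme.n_cells} cells)")
    print(f"{'cell':>12} {'n':>6} {'median (95% CI, ACL)':>28} {'optimal':>8}")
    edges = scheme.tg_edges()
    for cid, (tg_lo, tg_hi, nh_lo, nh_hi) in scheme.cells():
        m, o = med.cells[cid], opt.cells[cid]
        nh = "" if nh_lo is None and nh_hi is None else (
            f" nh<{nh_hi:g}" if nh_lo is None else f" nh>={nh_lo:g}"
        )
        label = f"{tg_lo:g}-{tg_hi:g}{nh}"
        ci = f"{m.af} ({m.ci_lo:.2f}-{m.ci_hi:.2f}, {100 * m.acl:.1f}%)"
        print(f"{label:>12} {m.n:>6} {ci:>28} {o.af:>8}")
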