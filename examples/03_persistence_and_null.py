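"""Cell-line persistence curves, log-rank contrast and a random-signature null.

A persistence curve treats IC50 as a survival time: a cell line "persists"
at a drug concentration until its IC50 is reached, every observation is an
event, and the Kaplan-Meier estimate reduces exactly to 1 - ECDF. Cohorts
defined by the top and bottom score quintiles are contrasted by log-rank
test and hazard ratio, and the hazard ratio is calibrated against random
gene signatures of the same length.
"""

import numpy as np

from convsig import (
    build_null_distribution,
    cohort_hazard_ratio,
    logrank_test,
    persistence_curve,
    sample_null_signatures,
    signature_score,
    simulate_cellline_panel,
)
from convsig.simulate import SyntheticConfig

cfg = SyntheticConfig(n_lines=200, n_genes=400, n_program_genes=12, seed=11)
panel, resp, _, truth = simulate_cellline_panel(cfg)

scores = signature_score(panel, truth)
order = sorted(scores.score.index, key=lambda i: (scores.score[i], i))
k = len(order) // 5
low, high = set(order[:k]), set(order[-k:])

c_hi = persistence_curve(resp, high, "high score")
c_lo = persistence_curve(resp, low, "low score")
print(f"median persistence, high-score quintile: {c_hi.median:.2f} log2 uM")
print(f"median persistence, low-score quintile:  {c_lo.median:.2f} log2 uM")
print("(high scorers reach their IC50 at lower concentrations: sensitive)")

lr = logrank_test(resp, high, low)
hr = cohort_hazard_ratio(resp, high, low)
print(f"\nlog-rank chi-square = {lr.chi_square:.1f}, p = {lr.p:.2e}")
print(f"hazard ratio (high vs low) = {hr:.2f}")

# null calibration: the same analysis on random signatures of equal length
def hr_metric(sig):
    s = signature_score(panel, sig)
    o = sorted(s.score.index, key=lambda i: (s.score[i], i))
    try:
        return cohort_hazard_ratio(resp, set(o[-k:]), set(o[:k]))
    except RuntimeError:
        return float("nan")

nulls = sample_null_signatures(panel.gene_ids, len(truth), 100, seed=11)
nd = build_null_distribution(hr_metric, nulls, truth, metric_name="hazard_ratio")
print(f"\nnull hazard ratios: median = {np.median(nd.values):.2f}, "
      f"95th percentile = {np.percentile(nd.values, 95):.2f} "
      f"({nd.n_degenerate} degenerate draws dropped)")
print(f"observed signature percentile within null = "
      f"{nd.percentile_of_observed:.1f}")
print("\nA percentile near 100 means the signature outperforms essentially all")
print("random gene sets of the same length, not just the average one.")
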