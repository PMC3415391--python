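"""Correlation structure and PCA of the behavioural metrics.

On a simulated cohort the only programmed source of between-individual
variation is the per-walk speed scale, so speed-linked metrics correlate
strongly while, e.g., stripe deviation stays independent — a useful
baseline for separating mathematical from biological correlations in
real cohorts.
"""

import numpy as np

from buridan import (FilterConfig, compute_metrics, correlation_matrix,
                     derive_steps, gen_cohort, pca_metrics, preprocess)

cfg = FilterConfig()
walks = gen_cohort("correlated", n_walks=20, seed=3)
records = []
for i, w in enumerate(walks, start=1):
    traj = preprocess(w.to_trajectory(), cfg)
    records.append(compute_metrics(traj, derive_steps(traj, cfg),
                                   id=f"sim_{i:02d}", group="correlated"))

corr = correlation_matrix(records, alpha=0.05)
pairs = [(a, b) for i, a in enumerate(corr.metrics)
         for b in corr.metrics[i + 1:] if corr.significant.loc[a, b]]
print(f"significant metric pairs at alpha=0.05 ({len(pairs)}):")
for a, b in pairs[:8]:
    print(f"  {a:>24} ~ {b:<24} r = {corr.r.loc[a, b]:+.2f}")

pca = pca_metrics(records)       # ST activity metrics dropped beforehand
print(f"\nPCA over {len(pca.metrics)} metrics:")
print("  variance fractions:",
      np.round(pca.variance_fraction[:4] * 100, 1), "% ...")
print("  eigenvalue sum:", round(float(np.sum(pca.eigenvalues)), 6),
      "= number of metrics")

# The leading component bundles the speed-driven metrics (median speed,
# distance, activity); its share of variance quantifies how dominant the
# speed scale is in this cohort.
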