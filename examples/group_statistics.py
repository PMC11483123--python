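"""Compare per-neuron event counts across conditions the way the assays do.

Simulates per-neuron fusion-event totals for three conditions, screens for
normality, runs the Kruskal-Wallis omnibus with Dunn-Holm post hocs, and
prints Tukey boxplot descriptives.
"""

from dataclasses import asdict

import numpy as np

from vesiclefuse.stats import compare, describe, normalize_to_control

rng = np.random.default_rng(11)
groups = {
    "WT": rng.poisson(6, size=30).astype(float),
    "KO": rng.poisson(18, size=30).astype(float),
    "KO+rescue": rng.poisson(7, size=30).astype(float),
}

report = compare(groups)
print(f"omnibus: {report.test}  H = {report.statistic:.2f}  p = {report.p_value:.2e}")
print(report.posthoc.to_string(index=False))
for name, vals in groups.items():
    d = describe(vals)
    print(f"{name:10s} n={d.n}  median {d.median:4.1f}  mean {d.mean:5.2f}  "
          f"IQR [{d.q1:.1f}, {d.q3:.1f}]  whiskers [{d.whisker_lo:.0f}, {d.whisker_hi:.0f}]")
# Dunn p-values are Holm-corrected; whiskers span the most extreme points
# within 1.5x IQR of the quartiles (Tukey convention).
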