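"""Compare transfer between conditions the way a screening experiment does.

Simulates per-donor-cell integrated transfer intensities for a control and
three treatments (one genuinely inhibited), then runs the analysis pipeline:
normalize to the control median (= 100%), natural-log transform, one-way
ANOVA, and Dunnett's post-hoc test of each condition against the control.
"""

import numpy as np

import codeit as ci

rng = np.random.default_rng(8)
datasets = [
    ci.ConditionDataset("control siRNA", rng.lognormal(12.0, 1.0, 60), is_control=True),
    ci.ConditionDataset("siRNA-A", rng.lognormal(12.0, 1.0, 55)),
    ci.ConditionDataset("siRNA-B (inhibits)", rng.lognormal(11.0, 1.0, 58)),
    ci.ConditionDataset("siRNA-C", rng.lognormal(12.1, 1.0, 52)),
]

report = ci.compare_conditions(datasets, random_state=0)

print(f"normality of ln-transformed control: p = {report.normality_p:.3f}")
print(f"ANOVA: F = {report.anova_F:.2f}, p = {report.anova_p:.2e}")
for c in report.conditions:
    p = "" if c.dunnett_p is None else f", Dunnett p = {c.dunnett_p:.4f}"
    flag = "  *" if c.significant else ""
    print(f"  {c.label:20s} n={c.n:3d} median {c.median_pct:6.1f}%{p}{flag}")
# Medians are % of the control median; '*' marks conditions that differ from
# control at alpha = 0.05 after Dunnett's many-to-one adjustment.
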