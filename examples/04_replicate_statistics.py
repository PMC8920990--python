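"""Replicate-level group comparisons: t-test, ANOVA + Dunnett, Tukey-Kramer.

Statistics in this package operate on per-replicate summary values (e.g. the
%CCA-added of a condition's replicates), not on pooled read counts.  This
example fabricates three conditions of three replicates each and runs the
three designs.
"""

import numpy as np

from trnaterm import compare_groups

rng = np.random.default_rng(3)
values = {
    "control": 95.0 + rng.normal(0, 0.4, 3),
    "ANG":     94.6 + rng.normal(0, 0.4, 3),
    "SA":      91.5 + rng.normal(0, 0.4, 3),   # a genuinely shifted condition
}
for name, v in values.items():
    print(f"{name:>8}: " + "  ".join(f"{x:6.2f}" for x in v))

print("\ntwo_group (control vs ANG): Student's t, equal variance")
for r in compare_groups({k: values[k] for k in ("control", "ANG")}, "two_group"):
    print(f"  {r.comparison}: t={r.statistic:+.3f}, p={r.p_value:.4f}")

print("\nvs_control: one-way ANOVA, then Dunnett-adjusted comparisons")
for r in compare_groups(values, "vs_control", control="control"):
    adj = " (adjusted)" if r.adjusted else ""
    print(f"  [{r.method}] {r.comparison}: stat={r.statistic:.3f}, "
          f"p={r.p_value:.4f}{adj}")

print("\nall_pairs: Tukey-Kramer")
for r in compare_groups(values, "all_pairs"):
    print(f"  {r.comparison}: p={r.p_value:.4f} (adjusted)")
# Expect: ANG indistinguishable from control; SA significantly lower in both
# the Dunnett and Tukey-Kramer outputs.
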