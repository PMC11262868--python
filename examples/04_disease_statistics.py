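"""Summary statistics and cross-disease comparison of fitted radii.

Per-experiment best-fit domain radii are aggregated into a mean and sample
SD per disease, and two diseases are compared with a two-sided unpaired
t-test.  The circulatory-disease radii below are the five published
per-experiment values; the skin group here is a synthetic stand-in (the
published skin study reports only its summary, 0.187 +/- 0.052 um).
"""

from mkrbe import compare_diseases, summarize_disease

dcs = summarize_disease([0.173, 0.233, 0.237, 0.227, 0.284],
                        label="circulatory disease")
skin = summarize_disease([0.14, 0.17, 0.19, 0.21, 0.23],
                         label="skin (synthetic stand-in)")

for s in (dcs, skin):
    print(f"{s.label:28s} n={s.r_d_values.size}  "
          f"mean={s.mean:.3f} um  SD={s.sd:.3f} um")

for variant in ("pooled", "welch"):
    t = compare_diseases(dcs, skin, variant=variant)
    print(f"{variant:6s} t = {t.statistic:+.3f}  df = {t.df:.2f}  "
          f"p = {t.p_value:.4f}")
# A larger mean radius means a *lower* RBE: radius and RBE are
# anti-correlated through z* ~ 1/r_d^2.
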