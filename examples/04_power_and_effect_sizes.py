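"""Power analysis and effect-size conversions for the paradigm's design.

Computes the minimum sample size for detecting the aftereffect with a paired
t-test, converts a pilot interaction F ratio to Cohen's f, and illustrates
the default-prior (JZS) Bayes factor for a t statistic.
"""

from vaelab.stats import (cohens_f_from_F, jzs_bf_ttest, paired_t_power,
                          power_paired_t)

dz = 0.94
n = power_paired_t(d_z=dz, alpha=0.05, target_power=0.80)
print(f"smallest effect in the fixed-disparity data: d_z = {dz}")
print(f"minimum n for 80% power (two-tailed paired t, alpha .05): {n}")
print(f"achieved power at n = {n}: {paired_t_power(n, dz):.3f}; "
      f"at n - 1: {paired_t_power(n - 1, dz):.3f}")

f = cohens_f_from_F(F=3.32, df_num=1.59, df_den=6.36)
print(f"\npilot interaction F(1.59, 6.36) = 3.32 -> Cohen's f = {f:.2f}")

for t in (0.5, 2.0, 3.5):
    bf = jzs_bf_ttest(t, n=20)
    verdict = "favours the effect" if bf > 1 else "favours the null"
    print(f"JZS Bayes factor at t = {t}, n = 20: BF10 = {bf:6.2f} ({verdict})")
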