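"""One-sample tests with a JZS Bayes factor.

Terminal-swing coefficients of the foot placement model are tested
against zero across participants, as in the standard analysis of this
design.  The Bayes factor integrates the non-central-t likelihood over a
Cauchy(0, sqrt(2)/2) prior on the standardised effect size.
"""

from fpcontrol import one_sample_test, simulate_cohort

table = simulate_cohort(n_participants=10, conditions=("steady",),
                        speeds=("normal",), seed=9, n_strides=100)

for coef in ("beta_pos_ts", "beta_vel_ts"):
    res = one_sample_test(table[coef], bayes=True)
    print(f"{coef}: mean = {res['mean']:.3f}, t({res['df']}) = {res['t']:.1f}, "
          f"p = {res['p']:.2g}, BF10 = {res['bf10']:.3g}")

null = one_sample_test([0.01, -0.02, 0.015, -0.005, 0.0, 0.008, -0.012],
                       bayes=True)
print(f"a null-ish sample for contrast: t = {null['t']:.2f}, "
      f"BF10 = {null['bf10']:.2f} (< 1 leans toward the null)")
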