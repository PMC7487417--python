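"""Error-bound analysis: how unlikely is a bad weight after CUE?

The probability of a relative weight error above eps = 1% factorizes into
(a) the analytic probability that a presynaptic gap outruns the L-step
look-back horizon and (b) the Monte-Carlo probability that the spike
predictor then errs intolerably.  With M = 100 minicolumns per hypercolumn
and L = 100, the adaptive predictor pushes the overall probability to the
1e-8 regime at full network activity.
"""

from bcpnn_cue import (
    beyond_lbh_probability,
    conditional_error_probability,
    rate_distribution,
    rate_expectancy,
)

dist = rate_distribution(alpha=1.0, n_mcu=10)
print(f"alpha=1, M=10: rates (r_l, r_w, r_s) = "
      f"({dist.r_l}, {dist.r_w}, {dist.r_s}); <r> = {rate_expectancy(dist):.7f}")
for L in (0, 50, 100, 200):
    print(f"  P(gap beyond LBH), L={L:>3}: {beyond_lbh_probability(L, dist):.3e}")

print("\nconditional and overall error probabilities at M=100, L=100 "
      "(50k Monte-Carlo trials each):")
for approx in ("static", "adaptive"):
    for alpha in (0.0, 0.5, 1.0):
        est = conditional_error_probability(approx, alpha, 100,
                                            n_trials=50_000, seed=17)
        print(f"  {approx:>8}, alpha={alpha:3}: p_beyond={est.p_beyond:.3e}  "
              f"p_cond={est.p_cond:.2e} (99% CI {est.ci_low:.1e}..{est.ci_high:.1e})  "
              f"p_overall={est.p_overall:.2e}")
print("(p_overall is the probability that a row update commits a >1% weight error)")
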