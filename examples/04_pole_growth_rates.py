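"""Estimate per-pole exponential growth rates from a movie.

For every dividing cell the pipeline splits the parent at the detected
septum position, takes the two septum-to-pole lengths at condensation and
the two daughter lengths at division, and applies the two-point exponential
estimator r = ln(L_div / L_sep) / (t_div - t_sep) to each side.  The fast
and slow means should recover the generator's rate distributions.
"""

import numpy as np

from poletrack import SimConfig, analyze_movie, render_movie, simulate_population

cfg = SimConfig(n_cells=30, seed=5)
truths = simulate_population(cfg)
stack, _truth = render_movie(truths, cfg)
result = analyze_movie(stack)

s = result.summary
rf = np.array([r.r_fast for r in result.growth_records])
rs = np.array([r.r_slow for r in result.growth_records])
print(f"{len(rf)} growth records")
print(f"mean r_fast = {rf.mean():.3e} min^-1  "
      f"(generator {cfg.fast_rate_mean:.3e})")
print(f"mean r_slow = {rs.mean():.3e} min^-1  "
      f"(generator {cfg.slow_rate_mean:.3e})")
print(f"mean per-cell fast:slow ratio = {s['mean_ratio']:.2f}  "
      f"(ratio of means = {s['ratio_of_means']:.2f})")
print(f"fraction growing faster on the shorter side = "
      f"{s['fraction_faster_on_shorter']:.2f}")
print(f"asymmetry-vs-differential-growth Pearson r = {s['pearson_r']:.3f} "
      f"(p = {s['pearson_p']:.3f})")
print("\nThe per-cell ratio mean exceeds the ratio of means because the "
      "two-point estimator's noise enters the denominator; both are "
      "reported.")
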