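"""Track septal-spot condensation and the division timer through a movie.

Simulates 12 dividing lineages, runs the full measurement pipeline
(segmentation, cell tracking, focus detection/tracking, condensation
detection, division detection), and reports where septa were placed and
how long cells took from condensation to division.
"""

import numpy as np

from poletrack import SimConfig, analyze_movie, render_movie, simulate_population

cfg = SimConfig(n_cells=12, seed=11)
truths = simulate_population(cfg)
stack, truth = render_movie(truths, cfg)
result = analyze_movie(stack)

pl = result.placement
print(f"tracked {result.summary['n_tracks']} cells, "
      f"{result.summary['n_divisions']} divisions, "
      f"{result.summary['n_septum_events']} condensation events")
print(f"septum positions at condensation: mean p = {np.mean(pl.positions):.3f}, "
      f"central-band fraction = {pl.central_frac:.2f}")
print(f"cell length at condensation: {pl.mean_length:.2f} "
      f"+/- {pl.sd_length:.2f} µm")
print(f"condensation-to-division delay: "
      f"mean {np.mean(result.delays_min):.1f} min over "
      f"{len(result.delays_min)} cells (generator timer: "
      f"{cfg.invagination_delay:.0f} min)")
print("\nSepta sit near p = 0.5 (mid-cell) over a wide range of cell "
      "lengths, and the measured delay recovers the division timer to "
      "within a frame interval.")
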