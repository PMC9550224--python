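"""Comet-track analytics on a synthetic axon population.

Generates EB1-comet tracks with known region/orientation-specific growth
parameters, applies the quality filters, and recovers the growth length per
cycle d_g with bootstrapped confidence intervals -- the same route a real
kymograph-track table would take.
"""

import numpy as np

from axonmt import synth
from axonmt.tracks import (
    bootstrap_median_ci,
    filter_tracks,
    orientation_fraction,
    per_axon_growth_summary,
)

table, truth = synth.gen_comet_tracks(synth.MEASURED_DEFAULTS, n_axons=120, seed=7)
survivors, log = filter_tracks(table)
print("filter removals per rule:")
print(log.to_string(index=False))
print(f"\norientation fraction (tip-ward / all): "
      f"{orientation_fraction(survivors):.2f}")

summary = per_axon_growth_summary(survivors)
print("\nacross-axon median d_g [95% CI] per region and orientation:")
for (region, direction), grp in summary.groupby(["region", "direction"]):
    ci = bootstrap_median_ci(grp["d_g_um"].to_numpy(), seed=1)
    orient = "plus-end-out " if direction == 1 else "minus-end-out"
    true_dg = synth.MEASURED_DEFAULTS.v_g[(region, direction)] / 60 / synth.MEASURED_DEFAULTS.f_g[
        (region, direction)]
    print(f"  {region:8s} {orient}: {ci} µm  (generator truth {true_dg:.2f})")

# the per-cycle catastrophe rate is recovered as 1/(mean growth duration)
near_plus = summary[(summary["region"] == "near_tip") & (summary["direction"] == 1)]
print(f"\nrecovered f_g (near tip, plus-end-out): "
      f"{np.median(near_plus['f_g_per_s']):.3f} /s (truth 0.040)")
print("\nnote: the quality filters drop events shorter than 4 frames, so the "
      "recovered d_g\nslightly overestimates the generator truth -- the same "
      "visibility bias affects\nreal kymograph data (see docs/methods.md).")
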