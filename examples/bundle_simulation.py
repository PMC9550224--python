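"""Dynein-sliding bundle simulation: sorting alone vs. the full model.

Runs short (8 h simulated) replicates of the MT-bundle simulator under two
addition models and prints the orientation profile along the axon.  With
sliding only, minus-end-out MTs pile up proximally; adding templating and
the unbounded-growth nucleation filter orients the whole axon
plus-end-out, as in developing axons.
"""

import numpy as np

from axonmt import sliding

N_ITER = 14_400      # 8 h at dt = 2 s (desk-scale; full runs last ~28 h)
N_REPLICATES = 5

for mode in ("sliding", "sliding+templating+unbounded"):
    cfg = sliding.SimConfig(mode=mode, seed=11, n_iter=N_ITER)
    trajs, states = sliding.run_replicates(cfg, n_replicates=N_REPLICATES,
                                           snapshot_every=2000)
    lengths = [sliding.axon_length(st, cfg) for st in states]
    prof = sliding.orientation_profile(trajs, n_bins=5, config=cfg)
    print(f"\nmode = {mode}")
    print(f"  mean axon length after {N_ITER * cfg.dt / 3600:.0f} h: "
          f"{np.mean(lengths):.1f} µm ({N_REPLICATES} replicates)")
    print("  plus-end-out fraction by normalized position (proximal -> distal):")
    fr = prof.sort_values("bin")["plus_fraction"].to_numpy()
    print("   ", " ".join(f"{v:.2f}" for v in fr))
print("\nsliding-only leaves the proximal axon minus-end-out; the full model "
      "does not.")
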