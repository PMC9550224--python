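# axonmt

Analysis toolkit for the question of how axonal microtubules (MTs) become
uniformly oriented. In developing neurons, axonal MTs start with mixed
orientation and end up ~95% plus-end-out — the prerequisite for polarized
long-range transport. `axonmt` implements the quantitative chain of
reasoning behind one explanation: MTs near the axon tip catastrophe less
often, which tips correctly oriented MTs into *unbounded* growth, and this
growth bias — together with dynein sliding and orientation templating —
is enough to orient an entire axon.

The package is aimed at people analysing EB1-comet kymograph tracks or
modelling cytoskeletal polarity: it consumes plain CSV track/profile
tables, never raw images.

## What is inside

* **`axonmt.model`** — the two-state (growth/shrinkage) model of dynamic
  instability. With growth velocity `v_g`, shrinkage velocity `v_s`,
  catastrophe rate `f_g` and rescue rate `f_s`, the tip performs
  advection–diffusion with drift `v̄ = (f_s v_g − f_g v_s)/(f_s+f_g)` and
  diffusion `D̄ = f_g f_s (v_g+v_s)²/(f_g+f_s)³`. In terms of per-cycle
  lengths `d_g = v_g/f_g`, `d_s = v_s/f_s`:

      l_MT = d_g d_s / (d_s − d_g)   if d_s > d_g   (bounded growth)
      l_MT = ∞                        if d_s ≤ d_g   (unbounded growth)

  plus an exact event-driven stochastic simulator used as the model's
  oracle.
* **`axonmt.tracks`** — comet-track quality filters, the 0.95-quantile
  axon tip, orientation fraction, growth statistics (`d_g`, `v_g`, `f_g`)
  binned by distance from the tip, shrinkage lengths `d_s`, and
  bootstrapped median confidence intervals.
* **`axonmt.gradient`** — exponential fit `p150(x) = b + e^{−s(x−x0)}` of
  tip-enriched anti-catastrophe protein profiles and the power-law
  coupling `d_g(x) = A·p150(x)^α` fitted jointly over both growth
  directions.
* **`axonmt.sliding`** — agent-based simulation of a dynein-crosslinked MT
  bundle (force-balance sliding, leaky proximal boundary, 50 pN distal
  load) with six MT-addition models combining sliding, templating and
  unbounded-growth-filtered nucleation.
* **`axonmt.synth`** — synthetic comet tracks, shrinkage events and
  intensity profiles with known ground truth.
* **`axonmt.cli`** — `axonmt model|tracks|fit|simulate|synth` subcommands,
  thin wrappers over the library.

See `docs/methods.md` for the models, estimators and design choices, and
`examples/` for one narrative script per capability.

## Worked example

```
$ python examples/growth_regimes.py
shrinkage length per cycle d_s = 2.03 µm

plus-end-out, near tip     d_g = 2.11 µm -> unbounded mean length diverges
minus-end-out, near tip    d_g = 1.39 µm -> bounded   mean length  4.41 µm
plus-end-out, shaft        d_g = 1.53 µm -> bounded   mean length  6.21 µm
minus-end-out, shaft       d_g = 1.16 µm -> bounded   mean length  2.71 µm

plus-end-out kinetics: drift v_bar = +0.07 µm/min, D_bar = 0.0931 µm²/s
minus-end-out kinetics: mean length 4.39 µm (bounded: the tip drifts back on average)
```

Reading: with the measured shrinkage length per cycle (2.03 µm), only
plus-end-out MTs within ~10 µm of the axon tip add more length per growth
cycle than they lose per shrinkage cycle — their predicted mean length
diverges (positive drift), while every other MT population relaxes to a
short exponential length distribution of mean 2.7–6.2 µm. That asymmetry
is the orientation bias.

And the simulation counterpart (`python examples/bundle_simulation.py`):

```
mode = sliding
  mean axon length after 8 h: 37.0 µm (5 replicates)
  plus-end-out fraction by normalized position (proximal -> distal):
    0.00 0.62 0.69 0.96 1.00

mode = sliding+templating+unbounded
  mean axon length after 8 h: 24.6 µm (5 replicates)
  plus-end-out fraction by normalized position (proximal -> distal):
    0.73 0.87 1.00 1.00 1.00
```

Dynein sliding alone sorts minus-end-out MTs into the proximal axon (plus
fraction 0 in the proximal bin); adding templating and unbounded-growth
nucleation orients the whole axon plus-end-out.

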