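# Methods

`axonmt` models and measures how axonal microtubule (MT) arrays become
uniformly plus-end-out. This note documents the models, the estimators, the
synthetic-data generators, and the numerical and design choices, in enough
detail to judge what a passing test does and does not show.

## Two-state model of MT dynamic instability (`axonmt.model`)

A MT tip alternates between growth (velocity `v_g`, µm/s) and shrinkage
(velocity `v_s`), switching with catastrophe rate `f_g` (1/s) and rescue
rate `f_s`. Writing the master equation for the joint density over length
and state and expanding its dispersion relation at small wavenumber, the
long-time behaviour is advection–diffusion with

    v̄ = (f_s v_g − f_g v_s) / (f_s + f_g)
    D̄ = f_g f_s (v_g + v_s)² / (f_g + f_s)³

`D̄` is equivalently the integrated velocity autocorrelation of the
dichotomous velocity process, `(v_g+v_s)² p_g p_s / (f_g+f_s)` with state
occupancies `p_g = f_s/(f_g+f_s)`, `p_s = f_g/(f_g+f_s)`; the prefactor was
verified against the stochastic simulator (ensemble variance of free
trajectories, `var(l_T)/2T`, agreement within sampling error).

For `v̄ < 0` the length distribution has an exponential stationary state
`p(l) = (|v̄|/D̄) exp(−|v̄| l/D̄)` with mean `l_MT = D̄/|v̄|` — *bounded*
growth. For `v̄ ≥ 0` no stationary state exists and the mean length
diverges — *unbounded* growth. In terms of the per-cycle lengths
`d_g = v_g/f_g` and `d_s = v_s/f_s` the transition sits exactly at
`d_s = d_g`, and near it

    l_MT ≈ d_g d_s / (d_s − d_g).

Two facts matter for interpreting the tests:

* The Taylor form is also the **exact** stationary mean of the event-driven
  two-state process; `D̄/|v̄|` is its diffusion approximation. The two
  differ by the factor `f_g f_s (v_g+v_s)² / ((f_g+f_s)² v_g v_s)`, which
  is 1 at `v_s/v_g = f_s/f_g = 1` and stays within ~2% for ratios within
  ~±15% of 1. Oracle-equivalence tests therefore draw bounded parameter
  sets in that near-critical regime (`v_s/v_g ∈ [0.9, 1.1]`,
  `f_s/f_g ∈ [0.82, 0.93]·v_s/v_g`) — which is also where the measured
  axonal parameters live (`d_g` 1.2–2.1 µm vs. `d_s` ≈ 2 µm). Outside this
  regime the diffusion approximation degrades and the tests would not
  (and should not) pass at 5%.
* `classify_regime` and `mean_length_taylor` operate on `(d_g, d_s)` alone
  and are exact statements about the transition; they carry no
  approximation.

The stochastic simulator `simulate_two_state` is an exact event-driven
(Gillespie-style) implementation: exponential dwell times, linear length
change within a state, and a reflecting boundary at length 0 (a MT that
shrinks to zero re-enters growth immediately — the standard convention for
this model class). `reflect=False` removes the boundary, giving the free
advection–diffusion process used to verify `v̄` and `D̄`. The inner loop is
numba-compiled and consumes pre-drawn dwell arrays from a seeded numpy
`Generator`, so runs are bit-reproducible and long oracles (10⁷–10⁸ s of
simulated time, millions of events) take seconds. Time averages use the
exact trapezoid of the piecewise-linear path; stationary samples are read
at uniformly spaced times after a burn-in of ≥50 relaxation times
(`τ = D̄/v̄²`), with the simulated duration scaled as `3·10⁴·τ` (clipped to
[4·10⁶, 1.2·10⁸] s) so the time-average standard error stays below ~1%.

A zero catastrophe rate (`f_g = 0`) is admitted in `MTDynamicsParams` and
describes a permanently growing MT (`d_g = ∞`); all other rates and
velocities must be strictly positive.

## Comet-track analytics (`axonmt.tracks`)

Tables are long CSV (`axon_id, track_id, direction, t_s, x_um`), positions
in µm along the axon with the cell body at 0, `direction = +1` for tip-ward
growth (plus-end-out MT). Filters remove tracks that (1) displace less than
two pixels net (pixel size 0.103 µm default, the only pixel-dependent
rule), (2) average below 1.5 µm/min, (3) above 20 µm/min, or (4) span fewer
than four frames. A removed track is logged under every rule it violates.

* **Axon tip** — 0.95 linear-interpolation sample quantile of all comet
  point positions (robust to single outlier comets).
* **Growth event** — one surviving track: `d_g` = absolute net displacement
  (not path length), duration = last minus first time, speed in µm/min.
* **Binning** — distance from tip of the event *start* position, 10 µm
  bins, starts beyond the tip clamped to bin 0.
* **Catastrophe rate** — `f_g = 1/(mean growth duration)` per
  bin × orientation. Tracks truncated by the movie end or the 4-frame
  visibility rule are not censor-corrected, matching how kymographs are
  read in practice; this biases `f_g` down and `d_g` up slightly (the
  synthetic round-trip in `examples/track_metrics.py` makes the size of
  the bias visible).
* **Per-axon d_g** — mean over the axon's events (per region×orientation),
  with across-axon medians and percentile-bootstrap 95% CIs (10,000
  resamples, seeded). A constant sample yields the degenerate CI [c, c].
* **QC gate** — control axons failing orientation ≥ 0.8 or mean growth
  speed ≥ 2 µm/min are flagged; paired treatments inherit the flag.

## Gradient fitting (`axonmt.gradient`)

Raw per-axon intensity traces (p150, tubulin, CellTracker volume marker vs.
distance from tip) are median-normalized per channel, the p150 channel is
divided by the normalized CellTracker channel, averaged in 10 µm bins, and
treatment profiles are divided by the mean of their paired control profile.

The profile model `p150(x) = b + exp(−s(x − x0))` is fitted by least
squares to the first 12 bins (0–120 µm). Because the data are bin means,
the model is evaluated as its exact bin average rather than at bin centres
(avoids a ~1% convexity bias). The parameterization is redundant along
`(s·x0 ↔ amplitude)`; fits are started from three decay-rate guesses and
the best solution kept. A fitted profile whose exponential term spans less
than 0.1% of the mean level across the window (or `s < 10⁻⁴`/µm) is flagged
`degenerate`: flat data cannot constrain a coupling.

Growth couples to the gradient as `d_g(x) = A·p150(x)^α`. A growth event
starting at `x` and growing with sign `σ` (−1 toward the tip, +1 away —
the sign convention is stated here because it is easy to invert) adds on
average the endpoint mean

    d_g(x, σ) = ½ [ d_g(x + σ·d_g(x)) + d_g(x) ]

evaluated as written (single composition, no fixed-point iteration), with
tip-ward growth allowed to overshoot the tip by 2 µm and away-growing MTs
constrained to start ≥ 4 µm from the tip (one mean MT length). `(A, α)`
minimize the summed squared difference between observed per-bin mean `d_g`
and the per-bin average of `d_g(x, σ)` (adaptive quadrature, relative
tolerance 10⁻⁶), jointly over both directions, with bounded least squares
(`A > 0` via log-parameterization, `α ∈ [−10, 10]`) from five deterministic
starts (`α₀ ∈ {0, 1, 2, 4, 6}`) — fourth-power couplings make the
objective stiff and multi-start guards the global minimum.

## Bundle simulator (`axonmt.sliding`)

Rigid 4 µm MTs slide along the axon axis, centres on lines of a hexagonal
lattice; filaments on adjacent lines that overlap in x are cross-linked by
`n_ij = χ·λ·overlap` dynein motors (χ = 1, λ = 5/µm). Each step solves the
overdamped linear force balance

    0 = −ξ l_MT v_i + Σ_j n_ij f_stall [ (o_i − o_j)/2 − (v_i − v_j)/(2 v₀) ] + F_boundary

(ξ = 1 pN·s/µm², f_stall = 1.4 pN, v₀ = 0.86 µm/s, dt = 2 s). Dynein walks
toward minus-ends, so an antiparallel pair is driven apart at up to `2 v₀`
with the minus-end-out filament moving proximally; a parallel pair is
velocity-coupled with no net drive (no self-propulsion). The system matrix
is strictly diagonally dominant (drag on the diagonal), so one dense solve
per step suffices. The closed-form two-filament solution is the oracle the
scheme is tested against. In the two motor-randomized control modes every
newly formed link draws a persistent ±1 gliding direction instead of the
orientation term, removing sorting while keeping agitation.

Boundaries: the proximal boundary is a leaky spring — penetrating filaments
feel 50 pN/µm (integrated implicitly: the spring stiffness adds `k·dt` to
the diagonal, since 50 pN/µm against a 4 pN·s/µm drag is stiff at dt = 2 s)
and exit with probability 2.4·10⁻⁴/s·dt. The distal boundary opposes
outgrowth with a constant 50 pN load shared by filaments whose distal ends
are within 0.1 µm of the tip; the load is applied in a second solve only to
contacts that were moving outward, and cannot reverse them past zero
velocity (a growth-cone load resists extension, it does not retract
filaments). Same-line filaments are hard-core: after each position update,
per-line overlaps are removed by the least-squares projection onto the
non-overlapping set (pool-adjacent-violators), which preserves cluster
centres of mass. Per-step displacements are capped below half a filament
length to prevent tunnelling.

MT addition runs on a deterministic timer (every 1100 s; 435 s in the
unbounded-filter modes, where most candidates are rejected): a candidate
centre is uniform along the current axon (ends may overhang the
boundaries), orientation 50/50, or templated — `P(plus-end-out)` equals the
plus fraction of filaments covering the candidate centre (0.5 if none) — in
the templating modes. In the unbounded-growth modes the candidate
nucleates only with probability `P(unbounded | distance from tip,
orientation)`, an exponential `amp·exp(−d/20 µm)` with amplitudes 0.7
(plus-end-out) and 0.2 (minus-end-out). These defaults encode the measured
asymmetry qualitatively — amplitudes and decay would have to be re-fitted per
dataset — and are config-overridable; conclusions drawn from
these modes are therefore qualitative (orientation orderings), never
quantitative.

Free choices fixed here, and why:

* **Cross-section**: 1-ring hexagonal patch (7 lattice lines) by default.
  Nothing in the mechanical scheme pins the size; thin larval
  fly axons carry only a few MTs per cross-section, and with the reference
  parameter set the 7-line bundle reproduces the calibration anchor (sliding-only axons of ≈50 µm after ~24 h; measured 50.9 µm mean
  over 10 replicates). Wider lattices let the same filament count pack
  into a much shorter axon. Configurable via `lattice_rings`.
* **Exit rule**: the exit rate applies only to filaments currently
  penetrating the proximal boundary.
* **Initial state**: 10 randomly oriented MTs on a 6 µm domain; greedy
  random placement can dead-lock on small lattices, so the placement
  restarts from the ongoing RNG stream (bounded retries) before raising a
  placement error.
* **Determinism**: a replicate is a pure function of (config, seed);
  replicate seeds are spawned from the master seed via `SeedSequence`.

The simulator deliberately has no filament growth/shrinkage (fixed 4 µm
lengths), no kinesin, no 3D mechanics, and no actin — the question it
answers is how sliding, templating and growth-biased nucleation shape the
orientation profile, not axon mechanics.

## Synthetic data (`axonmt.synth`)

The generators emulate the statistical structure the estimators assume,
with full ground-truth records (`TruthRecord`) that replay byte-identically.

* **Comet tracks**: per event, an exponential duration with the regional
  catastrophe rate and constant velocity, so event `d_g` is exponential
  with mean `v_g/f_g`; points are emitted at the 2 s frame interval plus
  the exact end point (so a track's net displacement equals `v_g·duration`
  rather than its frame-floor). Defaults (`MEASURED_DEFAULTS`) use 5 µm/min
  everywhere, near-tip rates 0.04/s (plus-end-out) and 0.06/s
  (minus-end-out) and shaft rates matching per-cycle lengths of
  1.53/1.16 µm; 75% of events are plus-end-out, 66% start within 10 µm of
  the tip, 40 events per axon, axon lengths normal around 60 µm (10%
  spread, floor 30 µm). Start positions respect the 4 µm / 2 µm placement
  constraints used by the gradient fit.
* **Shrinkage events**: lengths exponential with mean `v_s/f_s`; defaults
  (0.1 µm/s, 0.0493/s) put the mean at the measured 2.03 µm scale.
* **Intensity profiles**: exact bin averages of `b + exp(−s(x−x0))` with
  multiplicative lognormal noise; `treatment=True` flattens the gradient
  (knockdown-like) at the same mean level.

What the generators do **not** emulate: pausing states, velocity
variability within a track, tracking errors and track fragmentation,
spatial inhomogeneity of shrinkage, detector noise, or any coupling between
orientation fraction and position. Passing recovery tests therefore show
that the estimators are correct and unbiased *under the stated model*, not
that real kymograph data are free of these complications.

## Reported problem sizes

Desk-scale defaults used by the tests and the acceptance script: 250 axons
× 40 events for growth-length recovery; 10 replicates of 21,600 iterations
(43,200 s ≈ 24 h simulated) for bundle-simulation statistics, against the
full reference scale of 50,001 iterations × 50 replicates (the `SimConfig`
defaults); 20 parameter sets with adaptively scaled durations for the
stochastic oracle; 20 noisy replicates for power-law recovery. These sizes
put sampling error well inside each test's tolerance.

## Known limitations

* `f_g` estimation ignores censoring (see above).
* The force-balance scheme is a documented stand-in constrained by the
  reference parameters; absolute axon lengths inherit its conventions
  (cross-section, tip-load distribution), which is why the length check
  carries a ±20% band while orientation comparisons are ordinal.
* The unbounded-growth likelihood amplitudes are qualitative defaults.
* The gradient fit window (12 bins) assumes profiles reach 120 µm; shorter
  axons raise a fit error rather than silently extrapolating.
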