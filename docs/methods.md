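# Methods

## Model

Each agent carries a cell-cycle phase ϑ ∈ [0, 2π) and a volume V. The
phase is frozen while V < V_c (daughter cells); above V_c it advances at
a strain-dependent rate plus an input-gated term, and the volume grows
exponentially during G1 only:

    dϑ/dt = 0                      if V < V_c
          = f(ϑ) + z(ϑ)·u          if V ≥ V_c
    dV/dt = β·V   if ϑ < ϑ_G1S,  else 0

`u ∈ {0, 1}` is the binary medium input (0 = +MET, 1 = −MET). For the
non-cycling strain f is 0 in G1 (the cell arrests) and ω = 2π/T beyond
the G1/S point; for the cycling strain f = ω everywhere. The phase
response z adds ω_z in G1 only: −MET accelerates passage through START
and does nothing elsewhere. At ϑ = 2π the phase wraps to 0 and a daughter
agent is created with V = 0.61·V_mother; the mother's volume is not
reduced (S-G2-M mass goes to the bud in this budding-yeast picture, and
the mother only ever grows in G1, so subtraction would be unphysical).

Parameters (defaults):

| symbol | non-cycling | cycling | units | meaning |
|---|---|---|---|---|
| V_c | 1 | 1 | rel. | critical volume gating START and daughter/mother status |
| β | 0.0083 | 0.0083 | 1/min | G1 volume growth rate |
| T | 75 | 105 | min | nominal cycle period; ω = 2π/T |
| ω_z | 2π/75 | π/105 | rad/min | input-added G1 angular velocity |
| ϑ_G1S | π/2 | 4π/5 | rad | G1 → S phase |
| daughter fraction | 0.61 | 0.61 | – | daughter/mother volume at division |

Populations start from N0 = 3 founders (phases 2πk/N0, volumes V_c)
unless stated; estimation studies use 50 founders with seeded random
phases. Simulations are sampled every 2 min, the cadence of time-lapse
imaging.

**Integration.** The vector field is piecewise constant in phase regions
and linear in V, so every segment has a closed form. The stepper advances
each agent exactly from event to event — V reaching V_c, ϑ reaching
ϑ_G1S, ϑ reaching 2π (division), and input breakpoints — pinning states
exactly at events. Integration is therefore exact and bitwise
reproducible; the `dt` argument (default 0.1 min) only caps step length,
and refining it does not change sampled states. The closed-form cycle
lengths (75 min non-cycling under −MET; 105 / 91 min cycling under
+MET / −MET) hold to machine precision and are asserted in the tests.

**Chamber capacity.** Divisions double the population every cycle, which
is neither tractable over 1500-min horizons nor representative of a
fixed-size microfluidic trap, where resident cells stay and excess
newborns are washed out of the field of view. `capacity=n` keeps the
first n agents and logs (but does not retain) later daughters; the cell
count stays non-decreasing and the division log is complete. Default is
unbounded; presets and the long sweeps use capacity 300, the order of an
imaged field. Note that a saturated capacity also stops the influx of
out-of-phase newborns, so long-horizon coherence under a cap is an upper
bound on the uncapped value.

## Reporter synthesis

No forward fluorescence model is inherited from experiment, so the
package defines one that is exactly self-consistent with its estimators:

* **CLN2 reporter** (non-cycling strain): baseline + amplitude ·
  (½ − ½cos(ϑ − π/2)); a cell cycling at ω traces the estimator
  reference's cosine segment exactly.
* **CDC10 reporter** (cycling strain): `on_level` while budded
  (ϑ ≥ ϑ_G1S), `off_level` otherwise — the ideal binary septin signal.

Additive white Gaussian noise, one draw per cell and sample, seeded.
Defaults: off 1, on 5 a.u., noise sd 0.4 (10% of the separation).
Samples before a cell's birth are absent. Not modelled: photobleaching,
autofluorescence drift, maturation delay, segmentation/tracking errors,
cell-to-cell period variability. Passing round-trip tests therefore
demonstrates estimator correctness on the model's own terms, not
robustness to every real-microscopy artifact; the noisy-trace pipeline
tests (noise at 10% of signal separation) cover the first-order
degradation that matters for thresholding.

## Phase estimation

**Cross-correlation (non-cycling).** The trailing T_flat = 30 min of a
trace is Pearson-correlated with every same-length sub-window [τ−T_flat,
τ], τ ∈ [T_flat, T] on the sampling grid, of a T-periodic reference that
is 0 for T_flat and then one raised-cosine cycle of T0 = 75 min; the
cosine argument is taken relative to the segment start so the reference
is continuous at the junction. The phase is ϑ̂ = (2π/T0)(τ* − T_flat) +
π/2 mod 2π at the argmax τ* (ties toward the smallest τ). Pearson makes
the estimate invariant to affine rescaling. Windows with relative
variance below 10⁻⁹ are G1-arrested: the cell keeps its last valid
estimate, or 0 if none. Because the dictionary contains only
flat-then-rise windows and windows interior to one cosine period, a
trailing window spanning the waveform minimum (about 40% of the circle
for a continuously cycling cell) has no matching position and the
estimate there can be off by up to ~1 rad; exact (≤ one sampling
quantum) recovery holds on the covered arc and is asserted there. In
closed loop this blind spot is benign: arrested cells produce flat
windows and are classified into G1, which is all the stop&go trigger
needs.

**Binarization (cycling).** Traces are smoothed by centered moving
averages of 5 then 3 samples (shrinking symmetrically at the ends),
thresholded, and scanned for edges with a 14-min refractory rule: an
edge closer than 14 min to the previously accepted one removes both, so
accepted transitions always alternate. The threshold is the intersection
of the two weighted normal densities of a two-component Gaussian mixture
(EM, quantile-initialised, fixed seed) fitted to the pooled raw values
of the trailing 100 min, solved in closed form from the log-density
quadratic, with the means' midpoint as fallback; in closed loop it is
refitted at every sampling time. Phase is ω₀ × (time since the last
accepted transition), plus ϑ_G1S if that transition was off→on, clamped
just below the segment's end boundary on overruns; cells without a
transition have no estimate. Nominal timing is recovered as the medians
of the unbudded and budded inter-transition intervals pooled over all
traces: T0 = T_G1 + T_SG2M and ϑ_G1S = 2π·T_G1/T0. On the 2-min grid the
odd 63-min budded interval quantises to alternating 62/64-min
measurements, so recovered medians land within one quantum of 42/63/105.
Edges detected within 6 min of a trace start sit inside the smoothing
filters' end support and can shift by up to 2 samples; round-trip
assertions exclude samples governed by such edges.

## Synchronisation metrics

R(t) and ψ(t) are modulus and argument of the Kuramoto order parameter
over all live agents (in estimated-mode analyses: over cells with valid
estimates). Scalar summaries are arithmetic time averages over the
control-active window. The PSD of the mean-subtracted population-average
fluorescence is estimated parametrically with a modified-covariance
(forward-backward least-squares) AR fit — order 20 by default, validated
on a sinusoid (period recovered within ±2 min of 90 on a 600-min
record) — evaluated on a dense one-sided frequency grid; the leading
peak is reported as 10·log₁₀(peak density) (reference 1 a.u.²/frequency
unit) and its period, or "not determined" when the period exceeds the
record length or the signal is degenerate. Tracking quality is the
Spearman correlation between reference and mean phase ranked as wrapped
angles: two series that track produce aligned sawtooths (ρ → 1), whereas
ranking unwrapped phases would score ~1 for any two increasing series
and carry no information.

## Control

All strategies act at 2-min sampling times under zero-order hold.

* **Open loop**: u = 1 on [k·T_u, k·T_u + D), D = 30 min, pulses aligned
  to period starts.
* **Stop&go** (non-cycling): if no pulse is active and the G1 fraction
  strictly exceeds ν% (default 50; the ideal variant ν = 100 fires at
  exactly 100%, which a strict inequality could never reach), start a
  −MET pulse of exactly D = 30 min; the trigger is not re-evaluated
  during a pulse. 30-min calibration.
* **Reference oscillator** (cycling): u = 1 iff Σ a_m sin(ϑ_m − ϑ_r) < 0
  with a_m = 1 for G1 cells; ϑ_r integrates ω_r + γΣ sin(ϑ_m − ϑ_r)
  (sum over all cells, ungated, as a `gated_coupling` switch lets you
  change) over each hold interval with the measured phases held
  constant. ω_r = 2π/105, γ = 1, ϑ_r0 = 0, 100-min calibration. The
  coupling slope scales with γN, so the hold interval is subdivided to
  keep the classical RK4 steps well inside stability — with ~100 cells a
  single 2-min step would be violently unstable, which is why the
  reference ODE gets its own inner stepping. When locked (all ϑ_m =
  ϑ_r), the reference is immediately pulled back as it drifts ahead, so
  it advances by slightly less than ω_r per unit time; the free-running
  rate is recovered exactly as γ → 0 or with no cells.

Pre/post-control medium defaults follow the strains' conventional
overnight growth: −MET before and +MET after for non-cycling runs, the
converse for cycling runs. In estimated mode cells without a valid
estimate are excluded from both controllers' sums; with no measurements
at all the medium stays +MET and the event is logged.

## Findings the tests pin down

* Entrainment threshold: a full cycle needs 18.75 min of −MET plus
  56.25 min of free running = 75 min, so forcing below 75 min cannot
  entrain 1:1 (cells skip pulses, steady R̄ ≈ 0.4–0.6). At exactly
  T_u = 75 the entrained cycle has zero slack: any start offset up to
  D − 18.75 = 11.25 min inside the pulse is neutrally stable, offset
  lineages persist, and steady R̄ saturates near 0.986 — *marginal*
  entrainment. Strict full synchronisation (R̄ > 0.99; here exactly 1.0)
  first appears above the intrinsic period, at T_u = 80 min in the swept
  grid. The corresponding acceptance test asserts the strict bar at 75
  as well and is expected to fail there; the assertion message explains
  the marginal-entrainment mechanism.
* Volume vs forcing period: within the entrained regime longer T_u
  leaves cells longer in G1 per cycle, so mean volume grows strictly
  with T_u (75 → 90 → 150 min). Below the threshold the effective cycle
  doubles (divisions every second pulse) and volumes are *larger* than
  at 75 min, so the monotone-volume claim is asserted over the entrained
  periods only.
* Stop&go with the ideal threshold self-organises a quasi-periodic
  ~76–86-min pulse rhythm and drives R̄ ≈ 0.8–0.9 without knowing the
  cycle period; pulses never overlap and last exactly D.
* The reference oscillator roughly triples steady coherence over free
  cycling and tracks with ρ ≈ 0.88; after switch-off, newborn daughters
  (born in phase but frozen below V_c for ~17 min and released out of
  phase) steadily erode coherence.

## Problem sizes

Defaults used by the tests and the acceptance script: 50 mother cells ×
600 min for estimation studies; 6 forcing periods × 1500 min at capacity
300 for the open-loop sweep; 530–800-min closed-loop runs at capacity
300–600. The whole suite runs in well under a minute of simulation time
thanks to the event-exact stepper.

## Known limitations

Deterministic single-cell dynamics (no period variability, no noise in
progression), no mother-cell ageing, no spatial or crowding effects, no
nutrient depletion; the capacity rule retains the oldest agents rather
than a random subset; reporter traces omit microscopy artifacts beyond
additive Gaussian noise. The cross-correlation estimator's blind arc and
the marginal entrainment at the critical forcing period are properties
of the estimator and model as specified, not implementation defects.
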