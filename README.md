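# cyclesync

An in silico testbed for **closed-loop synchronisation of the budding-yeast
cell cycle**. Individual *S. cerevisiae* cells bud on a precise internal
schedule, but a population drifts out of phase within a few cycles. With a
methionine-gated G1 cyclin (P<sub>MET3</sub>-*CLN2*), the G1 → S commitment
of every cell can be pushed from outside by switching the growth medium
between methionine-rich (+MET) and methionine-depleted (−MET). `cyclesync`
reproduces, end to end and purely in simulation, the control stack that
exploits this handle: the agent-based population model, the single-cell
phase estimators that would normally read fluorescence microscopy, the
synchronisation metrics, and three medium-switching control strategies
closed in a sampled-data loop.

It is written for control engineers and systems biologists who want to
prototype or stress cybergenetic synchronisation strategies without a
microfluidic rig: everything a wet experiment would measure is replaced by
a simulator plus a reporter-synthesis module, so the whole loop —
dynamics → fluorescence → estimation → decision → medium — runs on a
laptop in seconds.

## The model

Each cell is a phase oscillator with a volume:

$$\frac{d\vartheta}{dt}=\begin{cases}0 & 0 \le V < V_c\\ f(\vartheta)+z(\vartheta)\,u & V\ge V_c\end{cases}
\qquad \frac{dV}{dt}=g(\vartheta)$$

with phase ϑ ∈ [0, 2π), critical volume `V_c = 1`, and binary input
`u` (0 = +MET, 1 = −MET). Volume grows exponentially only in G1
(`g = βV` for ϑ < ϑ<sub>G1/S</sub>, β = 0.0083 min⁻¹); the drift `f` is 0
in G1 and ω = 2π/T beyond it for the *non-cycling* strain (T = 75 min,
arrests in G1 under +MET) and ω everywhere for the *cycling* strain
(T = 105 min); the phase response `z` adds ω_z in G1 only. When ϑ crosses
2π the cell divides: the phase wraps to 0 and a new agent is born with
0.61× the mother's volume (frozen in G1 until it reaches `V_c`).

Phases are read back from synthetic fluorescence: a cross-correlation
estimator matches the trailing 30 min of a CLN2-reporter trace against a
flat-then-raised-cosine reference (non-cycling strain), and a binarization
estimator thresholds a two-level CDC10 septin reporter at the intersection
of a fitted two-Gaussian mixture, deglitches on/off transitions with a
14-min refractory rule, and converts time-since-last-transition to phase
(cycling strain). Synchrony is the modulus R of the Kuramoto order
parameter $R e^{j\psi} = \frac1N\sum_m e^{j\vartheta_m}$, complemented by
the leading peak of an autoregressive PSD of the population-mean
fluorescence and, for tracking controllers, the Spearman correlation ρ
between reference and mean phase.

Three controllers drive `u` under zero-order hold (2-min sampling):
open-loop pulse trains (period T_u, 30-min −MET pulses), event-triggered
**stop&go** (release everyone once the G1 fraction exceeds a threshold),
and a **reference oscillator** — a virtual cell
$\dot\vartheta_r=\omega_r+\gamma\sum_m\sin(\vartheta_m-\vartheta_r)$
coupled star-wise to the population, with −MET applied exactly when the
G1-gated sum $\sum_m a_m\sin(\vartheta_m-\vartheta_r)$ is negative.

## Worked example

Recover the cycling strain's timing from noisy synthetic traces
(`examples/02_recover_cell_cycle_timing.py`):

```
binarization threshold l = 3.01 a.u. (mixture means 1.01 / 5.03)
median unbudded (G1) interval  T_G1   =  42.0 min (model value 42)
median budded (S-G2-M) interval T_SG2M =  62.0 min (model value 63)
nominal period  T0 = T_G1 + T_SG2M    = 104.0 min (model value 105)
G1/S phase      2*pi*T_G1/T0          = 2.537 rad (model value 2.513)
```

Fifty simulated mothers, 600 min of +MET, reporter noise at 10% of the
on/off separation: the pipeline recovers the 42 / 63 / 105-min cell-cycle
anatomy within one 2-min sampling quantum. The other examples show
open-loop entrainment (`R_bar` jumps from 0.42 at T_u = 60 min to 1.000
at 80–150 min, with mean volume growing with T_u in the entrained
regime), stop&go closing the loop with a self-organised ~80-min pulse
rhythm, and the reference oscillator roughly tripling coherence over free
cycling (0.61 vs 0.18) with ρ = 0.88 tracking — then losing it again once
switched off.

A thin CLI mirrors the library (`cyclesync simulate|traces|estimate|
metrics|control|sweep`), with presets `fig3-sim` (ideal stop&go),
`fig4-sim` (reference oscillator) and `period-sweep`.

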