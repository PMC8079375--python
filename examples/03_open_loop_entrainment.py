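"""Entrain the non-cycling strain with periodic -MET pulses.

A pulse train of 30-min -MET pulses with period T_u drives the arrested
population.  The cycle needs 18.75 min of -MET (G1) plus 56.25 min of
free running, i.e. 75 min minimum, so forcing periods below 75 min make
cells skip pulses while longer ones entrain 1:1.  Steady-state coherence
is the time-averaged Kuramoto order parameter modulus over the final
stretch of the run.
"""

from cyclesync import non_cycling_params
from cyclesync.control import open_loop_sweep

sweep = open_loop_sweep(non_cycling_params(), [60, 75, 80, 90, 150], 30.0,
                        1200.0, steady_window=400.0, dt=0.5, capacity=300,
                        seed=0)

print("T_u (min)   steady R_bar   mean volume")
for tu, r, v in zip(sweep["T_u"], sweep["R_bar"], sweep["mean_volume"]):
    print(f"  {tu:5.0f}       {r:7.4f}      {v:8.2f}")

print("\nBelow 75 min the population splits into pulse-skipping clusters "
      "(low R); at exactly 75 min entrainment is marginal (within-pulse "
      "offsets persist); above it every cell locks 1:1 and R_bar reaches "
      "1. Within the entrained regime, longer periods leave cells longer "
      "in G1, so the mean volume grows with T_u.")
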