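"""Closed-loop stop&go synchronisation of the non-cycling strain.

The event-triggered controller watches the fraction of cells in G1 at
every 2-min sampling time; when it exceeds the threshold it releases the
whole population with one 30-min -MET pulse.  With the ideal 100%
threshold the emitted input settles into a quasi-periodic rhythm near
the intrinsic 75-min period without the controller knowing that period.
"""

import numpy as np

from cyclesync import StopAndGoConfig, non_cycling_params, run_closed_loop

res = run_closed_loop(non_cycling_params(), "stop_and_go", 530.0,
                      stop_go=StopAndGoConfig(threshold_pct=100.0),
                      dt=0.5, capacity=300, seed=0)

starts, prev = [], 0
for t, u, _ in res.controller_state.log:
    if u == 1 and prev == 0:
        starts.append(t)
    prev = u
spacing = np.diff(starts)

m = res.metrics
print(f"pulses delivered: {len(starts)} at t = {starts} min")
print(f"inter-pulse spacing: {spacing} min "
      "(quasi-periodic, near the 75-min cycle)")
print(f"coherence R_bar over the control window: {m.R_bar:.3f}")
print(f"coherence over the final 130 min:        "
      f"{m.R[m.times >= 400].mean():.3f}")
print(f"population: 3 -> {res.trajectory.n_cells} cells (stepwise growth: "
      "synchronised cells bud together)")
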