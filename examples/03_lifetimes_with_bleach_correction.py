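"""Recover composite IF/OF lifetimes through the full analysis pipeline.

At 300 ms frames the four inward-facing substates blur into one composite
IF state, so the kinetics reduce to IF <-> OF exchange.  The observed dwell
times are shortened by photobleaching (an independent exponential clock at
k = 0.010 1/s); the competing-rates identity 1/tau_true = 1/tau_obs - k
removes that contribution.  This script simulates at the wild-type
saturating-ATP lifetimes (t_IF = 16.1 s, tau_OF = 28.8 s), runs
QC -> segmental-k-means idealization -> composite dwell extraction ->
exponential fitting -> bleach correction, and prints the recovered values.
"""

import fretcycle as fc
from fretcycle import presets

t_if_true, t_of_true = 16.1, 28.8
sim = fc.SimulationConfig(
    scheme=presets.composite_scheme(t_if_true, t_of_true),
    n_traces=300,
    n_frames=1334,
    frame_interval=0.3,
    photophysics=presets.photophysics_preset("300ms"),
    initial_state="IF",
    seed=5,
)
result = fc.run_pipeline(fc.RunConfig(seed=5, simulation=sim, n_boot=2000,
                                      make_plots=False))

print(f"estimated k_bleach = {result.k_bleach:.4f} +- {result.k_bleach_sem:.4f} 1/s "
      f"(true 0.0100)")
for label, true in [("IF", t_if_true), ("OF", t_of_true)]:
    est = result.lifetimes[label]
    print(f"corrected {label} lifetime = {est.mean_s:5.1f} +- {est.sem_s:.1f} s "
          f"(generator {true} s, n = {est.n_dwells} dwells)")
# Both lifetimes return within ~1 bootstrap SEM of the generator values;
# without the correction the OF lifetime would read ~22 s instead of ~29 s.
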