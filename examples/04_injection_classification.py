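"""Classify active vs inactive molecules after mid-movie ATP injection.

In perturbation experiments the ligand reaches the chamber at t = 10 s.
Roughly 60% of molecules then start cycling between IF and OF
conformations; the rest never leave the inward-facing states.  A molecule
is classified active when its idealized trajectory visits the OF state
after the injection and before photobleaching; the wait time t_wait runs
from the injection to the first OF entry.
"""

import numpy as np

import fretcycle as fc
from fretcycle import presets

vals = presets.TABLE1_LIFETIMES["WT_ATP_LTC4"]  # t_IF = 4.7 s, tau_OF = 30.8 s
sim = fc.SimulationConfig(
    scheme=presets.composite_scheme(vals["t_if"], vals["t_of"]),
    n_traces=400,
    n_frames=333,  # 100 s movie
    frame_interval=0.3,
    photophysics=presets.photophysics_preset("300ms"),
    active_fraction=presets.ACTIVE_FRACTION,  # 60/40 mixture
    injection_time=10.0,
    initial_state="IF",
    seed=3,
)
traceset = fc.simulate_dataset(sim)
trajs = [fc.compute_fret(tr, fc.detect_bleach(tr).bleach_frame) for tr in traceset]
ideal, model = fc.idealize_skm(trajs, presets.FIVE_STATE_MEANS)
of_states = presets.of_state_indices(model.mu)

table = fc.classify_active(ideal, sim.injection_frame, of_states)
waits = fc.wait_times(ideal, sim.injection_frame, of_states)

truth = np.mean([tr.truth.active for tr in traceset])
print(f"classified active fraction: {table.attrs['active_fraction']:.2f} "
      f"(simulated truth {truth:.2f}, nominal {presets.ACTIVE_FRACTION})")
print(f"mean wait time to first OF entry: {np.mean(waits):.1f} s over "
      f"{len(waits)} active molecules")
# The classifier recovers the mixture within a few percent; the shortfall
# comes from active molecules whose fluorophore bleaches before their first
# OF visit.  Mean t_wait ~ t_IF, since ATP binding is not rate limiting here.
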