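# fretcycle

Single-molecule FRET (smFRET) kinetic analysis of an ABC transporter's
alternating-access cycle, built for biophysicists who want to go from raw
two-channel fluorescence traces (or simulations with known ground truth) to
conformational state models, dwell-time kinetics, and a quantitative
transport-cycle scheme.

The package grew out of the analysis of the multidrug transporter MRP1,
which interconverts between four inward-facing (IF) conformations and an
outward-facing (OF), NBD-dimerized conformation. Distances between the two
nucleotide-binding domains map onto five FRET states with mean efficiencies

```
E = 0.23 (IF4), 0.42 (IF3), 0.63 (IF2), 0.80 (IF1, substrate-bound), 0.92 (OF)
```

and the transport cycle is summarized by four rate constants

```
        k1              k2              k3
  IF  ----->  OF_pre  ----->  OF_post  ----->  IF
      <-----
       k-1
```

where `k1` is the ATP/substrate-driven IF-to-OF isomerization, `k-1` the
reverse isomerization, `k2` ATP hydrolysis (fast), and `k3` the
rate-limiting NBD-dimer dissociation. Both OF states emit E = 0.92, which
is why the OF lifetime stays single-exponential: one slow step (`k3`)
dominates.

## What it does

- **`fretcycle.simulate`** — generate smFRET datasets with known truth:
  exact (Gillespie) continuous-time Markov simulation of any labeled
  kinetic scheme, camera-style majority-occupancy frame integration,
  Gaussian channel noise, single-step donor photobleaching, donor blinking,
  active/inactive molecule mixtures, and mid-movie ligand injection.
- **`fretcycle.qc`** — FRET efficiency `E = I_A / (I_D + I_A)` and the
  standard trace filter: single-step donor photobleaching, SNR_bg ≥ 8,
  < 4 blinking events, ≥ 15 frames with E > 0.1.
- **`fretcycle.hmm`** — Gaussian-emission hidden Markov models implemented
  in-package: Baum–Welch EM with multi-restart, BIC state-number selection
  with unpopulated/degenerate-state overfitting flags, Viterbi decoding,
  segmental k-means idealization with fixed state means, FRET histograms
  and contour data (0.03 bins).
- **`fretcycle.dwell`** — dwell tables with left/right censoring, composite
  IF/OF lifetimes, transition density plots, post-injection active/inactive
  classification and wait times, censored-exponential fits, the
  photobleaching correction `1/τ_true = 1/τ_obs − k_bleach`, and
  molecule-level bootstrap errors (10,000 resamples).
- **`fretcycle.dose`** — Hill dose-response fits of state occupancy versus
  ligand concentration (EC50 with fit covariance errors).
- **`fretcycle.cycle`** — the four-rate cycle model: lifetimes → rates,
  closed-form first-passage predictions (OF occupancy, cycle time, ATP
  turnover), wild-type versus hydrolysis-dead (E1454Q, `k2 = 0`) variants.
- **`fretcycle.pipeline`** — `run_pipeline(RunConfig)` chains
  simulate/load → QC → idealization → kinetics reproducibly and writes
  TSV/JSON artifacts plus diagnostic plots.

## Worked example

Recover composite lifetimes through the whole pipeline
(`examples/03_lifetimes_with_bleach_correction.py`):

```python
import fretcycle as fc
from fretcycle import presets

sim = fc.SimulationConfig(
    scheme=presets.composite_scheme(t_if=16.1, t_of=28.8),
    n_traces=300, n_frames=1334, frame_interval=0.3,
    photophysics=presets.photophysics_preset("300ms"),
    initial_state="IF", seed=5,
)
result = fc.run_pipeline(fc.RunConfig(seed=5, simulation=sim, n_boot=2000))
```

prints

```
estimated k_bleach = 0.0104 +- 0.0006 1/s (true 0.0100)
corrected IF lifetime =  14.8 +- 0.9 s (generator 16.1 s, n = 342 dwells)
corrected OF lifetime =  28.3 +- 1.7 s (generator 28.8 s, n = 410 dwells)
```

The simulator hid the true kinetics (mean IF dwell 16.1 s, OF dwell 28.8 s)
behind photon noise and photobleaching at 0.010 1/s; the pipeline re-detects
the bleaching rate from the traces themselves, idealizes each trajectory,
and returns both lifetimes within about one bootstrap SEM of the truth —
without the correction the OF lifetime would read ~22 s.

The other scripts under `examples/` demonstrate dataset simulation and QC,
five-state model selection (K = 5 chosen, K = 6 flagged as overfit),
post-injection active/inactive classification, EC50 fitting, and the cycle
model. Each prints the numbers it computes and a line on what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates every headline quantity from scratch by running the package on
synthetic data at the published operating points: the highest fitted state
mean after model selection, the two titration EC50s, the three
photobleaching-corrected composite lifetime pairs, the bleaching rate and
observation window at the 300 ms preset, and the recovered active-molecule
percentage. It writes one JSON object mapping each quantity to its value
and the problem size used.
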