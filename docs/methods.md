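# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `fretcycle`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The physical picture

An ABC transporter alternates between inward-facing (IF) and outward-facing
(OF) conformations. smFRET reports the distance between the two
nucleotide-binding domains as an efficiency `E = I_A / (I_D + I_A)`; five
states are resolved at E = 0.23, 0.42, 0.63, 0.80 (four IF substates, the
highest substrate-bound) and 0.92 (OF, NBD-dimerized). Two mechanistically
distinct OF states — pre-hydrolysis (two ATP bound) and post-hydrolysis
(ATP + ADP) — share E = 0.92 and are optically one state. The cycle model
carries four rates: `k1` (IF→OF), `k-1` (reverse isomerization), `k2`
(hydrolysis), `k3` (NBD-dimer dissociation).

## Synthetic data generator

The generator is a first-class, tested component, because parameter
recovery on data with known ground truth is the package's validation
surface.

**Conformational layer.** Exact stochastic simulation (Gillespie) of the
continuous-time Markov chain defined by a `KineticScheme`: sojourns are
exponential with the state's total exit rate, jumps proportional to the
outgoing rate constants. Frames are discretized by *majority occupancy*
(the state occupying > 50% of the frame interval), which reproduces the
camera-integration blurring of transitions faster than the frame time —
at 300 ms resolution fast IF-substate exchange is deliberately obscured,
which is exactly why downstream analysis works on the composite IF state.

**Photophysics layer.** Per frame, `donor = S(1−E) + N(0,σ)` and
`acceptor = SE + N(0,σ)` with `S` the total intensity. Donor
photobleaching occurs at an exponential time with rate `k_bleach` and
zeroes both channels to background noise in a single step; donor blinking
(two-state telegraph, rates `k_blink_off`/`k_blink_on`) zeroes both
channels temporarily since a dark donor cannot transfer. Acceptor-only
bleaching is not in the default presets: the QC filter keys on single-step
*donor* bleaching. For independent channel noise the FRET scatter is
`σ_E = (σ/S)·sqrt(E² + (1−E)²)` (first-order propagation of the ratio;
verified against Monte Carlo in the tests). Note this *grows* toward the
extremes of E for fixed per-channel σ; a shot-noise-limited detector would
instead narrow high-FRET states. The HMM therefore keeps per-state
(heteroscedastic) widths and asserts no direction for the trend.

**Imaging presets** (`presets.photophysics_preset`): total intensity 1000,
per-channel σ = 75 (σ_E ≈ 0.05–0.07 across the five states — chosen inside
the 0.05–0.1 band typical of these measurements; no per-state widths are
published), background σ = 50 (SNR_bg = 20). The two frame rates are
modeled as two presets rather than a laser-power law:
`"300ms"` with `k_bleach = 0.010 1/s` (≈101 s observation window) and
`"25ms"` with `k_bleach = 1/4.1 1/s` (≈4.1 s window). Blinking defaults
(`k_off = 0.005 1/s`, `k_on = 2 1/s`) put the expected blink count well
under the QC limit of 4 per trace.

**Mixtures and injection.** A Bernoulli fraction (`active_fraction`,
default presets use 0.6) of molecules follows the active scheme; the rest
follow the IF-only submatrix (entry rates into OF zeroed), matching the
observation that inactive molecules still wander between IF substates.
With `injection_time` set (10 s in the perturbation presets), active
molecules follow the pre-injection (IF-only) scheme first and switch to the
active scheme mid-movie, continuing from their current state.

**Five-state preset rates.** Only the state means, the ~1 s per-IF-state
lifetimes, the +30% IF1 lifetime under substrate, and the composite
lifetimes are published. `presets.five_state_scheme` therefore wires a
nearest-neighbour IF ladder (IF4–IF3–IF2–IF1) with ~1 s state lifetimes,
OF entry from IF1/IF2 only (where transitions into OF are observed to
originate), and OF exit at the measured composite rate. Datasets meant for
state-model fitting start molecules in the IF states (as after ligand
arrival); at stationarity the long-lived OF state would otherwise dominate
the short 25 ms observation window and starve the IF populations.

## Trace QC

- `E` uses raw intensities; frames whose total falls below 10% of the
  trace's median pre-bleach total are flagged invalid instead of divided
  (blinks and background would otherwise produce ratio blow-ups).
- Bleach detection: change-point on the 5-frame median-filtered total
  intensity. A step qualifies when the local drop exceeds 4 background σ
  and the signal never recovers above the post-step plateau; the bleach
  frame is the step that lands at the final background level, and
  `step_count` counts all sustained steps so an acceptor-then-donor
  two-step bleach fails the single-step criterion. Blinks recover and are
  thereby excluded. With no qualifying step the whole trace counts as
  pre-bleach (censored).
- `SNR_bg` is defined as mean pre-bleach total intensity over the standard
  deviation of the post-bleach background (the criterion's source software
  does not publish a formula; this is the standard field usage and is
  computable from the trace alone). A trace that never bleaches has no
  background segment and fails QC.
- "E > 0.1 for at least 15 frames" is read as *cumulative*, not
  consecutive: the criterion screens for FRET-active molecules.
- The filter is monotone (tightening any threshold never admits a trace)
  and never mutates intensities; downstream stages see only pre-bleach
  frames.

## Hidden Markov modeling

Gaussian-emission HMMs with per-state widths, fitted by Baum–Welch EM.
All recursions (forward, backward, Viterbi) run batched over the whole
dataset on padded arrays with per-sequence lengths; QC-invalid frames
contribute emission probability 1, so the hidden state evolves through
them and frame indexing stays intact for dwell analysis.

Numerical choices:

- Scaled (normalized) forward/backward passes; exactness is verified
  against exhaustive path enumeration for K ≤ 3, T ≤ 8 and against an
  independent HMM library on longer series.
- EM: 5 random restarts by default (seeds derived from the run seed), best
  likelihood kept; convergence at relative log-likelihood change < 1e-6 or
  100 iterations; the log-likelihood is asserted non-decreasing in tests.
  A state that loses essentially all posterior mass is reinitialized from a
  random data quantile with a warning.
- Emission widths are clipped to [1e-3, 0.3]. The ceiling matters: FRET
  lives on [0, 1], and an unbounded width lets one state absorb ratio
  outliers (frames just above the intensity floor) and degenerate into a
  garbage-collector state that swallows the dataset.
- Model selection over K = 2..6 ranks by BIC and flags two overfitting
  symptoms: *unpopulated* (a state claims < 1% of Viterbi-assigned frames)
  and *degenerate* (two means closer than the emission width separating
  them). Assignment fraction, rather than the stationary distribution of
  the transition matrix, is used for "unpopulated" because state-assignment
  histograms are how populated states are judged in practice; a redundant
  state can carry stationary mass while never winning a frame. The design
  keeps per-K scores so an evidence-based selector could be swapped in.
- Idealization uses segmental k-means with the five state means *fixed*
  across all conditions (as in the original analysis): Viterbi decoding
  alternates with re-estimation of the transition matrix (pseudocount
  0.01), initial distribution, and per-state widths, until the decoded
  paths repeat or 100 iterations. Viterbi ties resolve to the lowest state
  index; the procedure is deterministic given its inputs.
- States are always reported in canonical mu-ascending order.

## Dwell-time kinetics

Dwells are run-length encodings of idealized paths; they tile each
trajectory without gaps. A dwell is **left-censored** if it starts at the
trace start or spans the injection instant (its start predates the
condition), **right-censored** if it ends at the trace end (photobleaching).

Two estimation routes coexist deliberately:

- *Rate-subtraction route* (the convention used for reported lifetimes,
  and the default in the pipeline): mean (IF) or exponential fit (OF) of
  **uncensored** dwells estimates `1/(k_state + k_bleach)`, since
  bleaching competes as an independent exponential clock; the correction
  `1/τ_true = 1/τ_obs − k_bleach` then removes it. SEMs propagate by the
  delta method from the dwell SEM and the bleaching-rate SEM. The
  correction refuses lifetimes with `1/τ_obs ≤ k_bleach` (unresolvable at
  that bleaching rate).
- *Censored-MLE route*: `τ = Σ(all durations) / #uncensored` estimates the
  true rate directly with no subtraction. The pipeline exposes it as a
  cross-check (`correction="mle"`); applying the bleach correction after it
  would double-count.

Composite IF lifetimes use the arithmetic dwell mean; OF lifetimes use the
single-exponential fit, with a Kolmogorov–Smirnov statistic flagging
multi-component decays. The bleaching rate itself is a censored-exponential
MLE over per-trace times to the detected bleach step, using **all** traces:
restricting to QC-passing traces would discard exactly the censored
(never-bleached) observations and bias the rate upward.

Active/inactive classification: a molecule is active when its idealized
trajectory visits OF at least once after the injection frame; molecules
whose trace ends at or before injection are unclassifiable and excluded
from the denominator. Wait times run from injection to first OF entry;
molecules already outward-facing at injection are excluded with a warning.
Bootstrap errors resample molecules (not dwells) with replacement,
10,000 times by default, to respect within-molecule correlation.

## Dose-response

Occupancy is the fraction of idealized frames assigned to a state
("relative occupancy" is not further defined in the source analysis; both
all-states and IF-subset normalizations are provided — the choice moves the
ceiling, not the EC50). Hill fits are weighted least squares with the fit
covariance supplying the EC50 SEM; the Hill coefficient is free by default
and fixable to 1 (single-site binding — the recovery presets generate with
n = 1). Flat data are flagged unidentifiable instead of returning an
arbitrary EC50. Synthetic titrations use 8 log-spaced concentrations and
per-point SEM 0.03, the bootstrap-SEM scale of an occupancy measured over a
few hundred molecules; with a response amplitude of ~0.4 this determines a
single-titration EC50 only to tens of percent — matching the large quoted
uncertainty on such fits — so green EC50 tests establish calibration (truth
inside the fit CI), not high precision.

## Cycle model

`rates_from_lifetimes`: `k1 = 1/t_IF`; `k3 = 1/τ_OF(WT)` (valid because a
single-exponential OF decay implies hydrolysis is fast, `k2 ≫ k3`);
`k-1 = 1/τ_OF(E1454Q)` (the hydrolysis-dead mutant returns only by reverse
isomerization). `k2` is unidentifiable from dwell data beyond "fast" and
is carried as a lower bound, default `10·k3`.

The observed OF dwell (both OF states at E = 0.92) has the first-passage
mean `E[t_OF] = 1/(k-1 + k2) + [k2/(k-1+k2)]·(1/k3)`; limits `k2 → ∞`
(→ `1/k3`) and `k2 = 0` (→ `1/k-1`) are exact. OF occupancy and cycle time
follow from the alternating-renewal identity, turnover is the hydrolysis
flux per molecule at stationarity, and all closed forms are verified
against Gillespie simulation of the same scheme in the tests. Spontaneous
ATP-free OF visits can be added as an extra IF→OF rate in apo presets; the
known several-fold gap between single-molecule cycle time and bulk ATPase
turnover is reported, not reconciled (the bulk assay is out of scope).

## What a green test does and does not establish

The generator emulates the *statistical* structure of the measurements:
exponential kinetics on a labeled state graph, Gaussian channel noise,
single-step donor bleaching, blinking, mixtures, injection. It does not
emulate EMCCD noise physics, spectral crosstalk calibration (γ), baseline
drift, spot-detection artifacts, or day-to-day instrument variation, and
its rate presets beyond the published lifetimes are plausible choices, not
measurements. Parameter-recovery tests therefore validate the estimators
and the pipeline plumbing — not the biology, and not robustness to
instrument systematics. Two small biases are inherent and documented
rather than corrected: conditioning analysis on traces with an observed
bleach step slightly shortens the surviving observation windows, and active
molecules that bleach before their first OF visit depress the recovered
active fraction by a few points.
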