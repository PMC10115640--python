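# Methods

## The gating-cycle model

CFTR is an ATP-gated anion channel of the ABC-transporter family. Its two
nucleotide-binding domains (NBDs) dimerize when ATP occupies both composite
binding sites; pore opening requires a further, rate-limiting conformational
change within the NBD-dimerized channel; hydrolysis at the catalytically
competent (consensus) site drives the cycle forward. `cftrgate` encodes this
cycle as a nine-state continuous-time Markov chain (CTMC):

```
SEP_apo <-> SEP_atp -> DIM_closed -> OPEN_pre <-> FLICKER
                ^                       |
                |                       v (hydrolysis, k3)
             (k8)|                   OPEN_post
                |                       |
            INT_sep <-> INT_dimer <- DIM_ADP
                        (k6*[ATP] back to DIM_closed)
```

Model assumptions, in order of consequence:

* **Openings only from the dimerized channel.** Conducting states are a
  subset of NBD-dimerized states, so the coupling ratio Po/Pdim is bounded
  by 1 structurally.
* **Phosphorylation is a binary switch.** The unphosphorylated regulatory
  domain blocks dimerization (`k1 = 0`); multi-site phosphorylation kinetics
  are out of scope.
* **Lumped ATP binding.** Separate degenerate/consensus-site occupancy is
  collapsed into one ATP-bound separated state plus the rebinding path into
  the intermediate. Site-resolved occupancy is not identifiable from the
  ensemble observables this package is calibrated to, and the known
  multimodality of dwell distributions (attributed to single-site-occupied
  periods) is therefore *not* reproduced.
* **Two ATP-proportional transitions.** Initial association (`k_bind`) and
  rebinding to the intermediate (`k6`) are pseudo-first-order in [ATP];
  everything else is unimolecular. ADP competition is not modelled.
* **Opening is irreversible; closure is hydrolytic.** Non-hydrolytic closure
  and ATP-free openings are rare events excluded from the model. This is the
  main structural limitation for hydrolysis-dead variants (below).
* **Piecewise-constant ATP.** At protocol breakpoints the pending stochastic
  dwell is re-drawn under the new generator — exact for a CTMC because
  exponential holding times are memoryless.
* **Perfusion kinetics are not convolved** into relaxations: the measured
  490 ms activation is treated as intrinsic because it is ~3-fold slower
  than solvent exchange.

Deterministic quantities come from linear algebra on the generator Q:
stationary occupancy from the null space of Qᵀ (one balance row replaced by
normalization), relaxations from a single matrix exponential per grid step,
and mean aggregated dwells from first-passage solves. The bridged open-burst
mean handles sub-threshold gaps exactly: gap-return probabilities and
truncated gap durations are computed from the matrix exponential of the
non-conducting sub-generator, and the burst recursion is solved linearly.
Stochastic trajectories use the exact Gillespie algorithm with one
`numpy.random.default_rng(seed)` stream per simulation; identical inputs and
seed give bit-identical paths.

## Calibration

The rate constants are not inputs; they are estimated so that deterministic
model observables reproduce measured wild-type behaviour. The shipped target
set (`data/calibration_targets.yaml`) contains: Po = 0.22 and Pdim = 0.85 at
3 mM ATP; dimerized/open-burst dwell ratio 20 (25% tolerance, with flickers
< 10 ms bridged to mirror 100 Hz recording bandwidth); activation constant
490 ms after an ATP jump; bi-exponential high-FRET decay constants 1.6 s and
20 s after ATP withdrawal; Hill midpoints (coefficient fixed to 1) 53 µM for
opening and 55 µM for dimerization; and an ATP turnover *window* of
0.3–1 s⁻¹.

The objective is weighted least squares over log₁₀ rates within bounds
(unimolecular 10⁻³–10³ s⁻¹; bimolecular 10³–10⁸ M⁻¹s⁻¹ — spanning
physiological channel kinetics), multi-start with seeded Gaussian
perturbations; ties go to the lowest restart index. Only noise-free CTMC
quantities enter the objective; stochastic simulation is reserved for
validation. The best fit is frozen in `data/wt_rates.json` and is the
package default (`RateSet.wt_calibrated()`); `cftrgate calibrate`
regenerates it.

The calibrated model reproduces every point target within its tolerance.
Its hydrolysis flux is 0.26 ATP/s — just below the 0.3–1 s⁻¹ ensemble
window. The window is deliberately soft: the calibration report flags the
residual rather than failing, and the discrepancy is the expected behaviour
of a minimal single-pathway cycle whose flux is pinned by Po and the burst
duration (flux ≈ Po / mean burst). A model with this topology cannot move
turnover independently of the open-probability and dwell-ratio targets.

Identifiability: with 13 free rates and ~9 targets the rates themselves are
not unique — only the observables are. The round-trip property (calibrating
against observables generated from a known rate set recovers those
observables within 5%) is what the tests assert.

### Variant presets

Presets are qualitative, documented multipliers on the calibrated wild-type
rates; no variant-specific fitting is performed.

| preset  | changes | phenotype captured |
|---------|---------|--------------------|
| E1371Q  | k3 → 10⁻⁶ s⁻¹ | no hydrolysis; separation all but abolished; zero hydrolysis events in simulation |
| W401A   | k1×0.02, k7_fwd×4, k7_rev×0.2, k8×30, k6×0.3 | no degenerate-site ATP retention: fast full separation and slower re-dimerization, rapid low/high cycling at roughly half the wild-type dimerized occupancy |
| Y1219A  | k1×0.001, k2×0.04 | consensus-site binding lost: slow infrequent dimerization, near-zero opening |
| G551D   | k1×0.1, k2×0.01, k3×0.4; DIM_closed/INT_dimer are mid-FRET | ATP-bound channel arrests in an intermediate NBD approach (0.37), opening and hydrolysis nearly abolished |
| L927P   | k2×0.2, k3×15, k4×15; DIM_closed/INT_dimer are mid-FRET | intermediate approach (0.31) with frequent but ~15-fold shorter open events, ~60% lower ATPase |

Because the topology's only dimer-exit route is hydrolytic, hydrolysis-dead
variants cannot dynamically leave the dimerized/intermediate states except
through the residual hydrolysis rate. G551D's rare excursions to the 0.49
state and Y1219A's sporadic openings are therefore represented only
approximately; E1371Q is effectively trapped once open, which is the
intended behaviour for path-level comparisons but makes its *stationary*
occupancy uninformative.

## Synthetic traces: what they emulate, and what they do not

`synthetic_traces` renders state paths into the two raw data types the
analysis chain consumes.

FRET traces: the noise-free frame value is the *dwell-time-weighted average*
of state emission means within the frame, so fast dynamics are genuinely
blurred at 100 ms integration (the regime in which transition rates are
underestimated). Emission means: separated 0.25 (apo) or 0.28 (nucleotide
bound), dimerized 0.49, variant intermediates 0.37 (G551D) / 0.31 (L927P).
Channel intensities are `total·E` and `total·(1−E)` plus per-channel
Gaussian noise (defaults: total 1000, sd 70 → FRET sd ≈ 0.045 and
total-intensity SNR ≈ 10). A single exponential donor-bleach time (mean
30 s) and Poisson blink intervals (0.02 s⁻¹, mean 0.3 s) darken *both*
channels — a dark donor excites nothing — with partial-frame scaling at
interval edges. Truth annotations (per-frame class, noise-free FRET, bleach
time, blink intervals) are carried alongside and never consumed by the
analysis code under test.

Current traces: boxcar conduction at a single open level plus white noise,
filtered with a 4-pole low-pass Bessel filter (scipy `bessel(4, fc, fs)`,
applied causally with `sosfilt`) — the electrophysiology convention; 2 ms
flickers at 100 Hz are attenuated by well over half, as in real filtered
recordings.

Not emulated: spectral crosstalk and gamma, acceptor photophysics,
multi-channel records, baseline drift, and the dwell-time multimodality
noted above. Passing round-trip tests therefore demonstrates that the
*analysis chain* is unbiased for data of this structure, not that real
recordings lack these complications.

## QC and idealization

Selection criteria (defaults; every report serializes them): single-step
donor photobleaching, total-intensity SNR > 8, fewer than 4 donor blinks,
FRET above baseline (0.1, a package default — no published value exists)
for ≥ 50 frames, and exclusion of traces with median FRET > 0.8. Bleach
detection is a change-point on the running-mean total intensity requiring
≥ 80% depletion; persistent intermediate levels (≥ 5 frames below 70% of
the fluorophore level) mark multi-step bleaching. The SNR definition — mean
pre-bleach total intensity over the within-state sd of total intensity — is
a package definition; total intensity is state-independent in this emission
model, which makes the within-state qualifier exact. Interactive curation of
photophysical artefacts is replaced by these deterministic filters.

Idealization is segmental k-means: Viterbi segmentation under Gaussian
emissions (two states, initial means 0.25/0.48, sd 0.1) with a uniform
switch penalty (default 3 nats — the segmentation prior is not published,
so it is exposed as a parameter), alternated with state-mean re-estimation
until the assignment is stable. The path objective is non-decreasing across
iterations. Dark/blink frames are excluded from re-estimation, and dwells
spanning them are censored in downstream tables.

## Dwell, dose-response and relaxation fitting

* Aggregated sojourns with gap bridging; first/last sojourns censored.
  Censored dwells enter exponential MLE through survival terms (dropping
  them biases rates upward — tested). BIC compares 1- vs 2-component fits.
* Hill fits use `A·c/(c+EC50)` with the coefficient fixed to 1 (free-n
  optional); EC50 is exactly scale-equivariant in the dose units.
* Relaxations are fitted by separable least squares (log-spaced grid over
  time constants, amplitudes solved linearly) followed by non-linear
  refinement — robust for time constants separated by an order of magnitude
  (1.6 s vs 20 s).
* When fitted dwells are shorter than ~3 camera frames the package warns
  that time averaging biases rate estimates.

## Numerical choices

Stationary solves require ATP > 0 and verify the residual (10⁻⁹) so a
reducible generator fails loudly rather than returning junk. Relaxation
grids: activation 8 s at 5 ms; withdrawal 120 s at 50 ms; dose-response
grid 1 µM–3 mM, 25 log-spaced points. The activation curve overshoots its
steady state (the intermediate pool fills slowly), so the mono-exponential
activation constant is defined operationally as the best single-exponential
fit over the 8 s window — the same definition applied to the measured
current time courses. Problem sizes in the validation suite (2000 s
trajectories, 300-trace ensembles at 100 ms frames, 60 s traces) were
chosen to give standard errors comfortably inside the assertion tolerances:
a 2000 s trajectory yields ~450 dimerized dwells (≈7% SE on the dwell
ratio, against its 25% tolerance), and 300 traces leave ≳200 after QC
(state-mean SE ≪ the ±0.02 assertion).

## Known limitations

* Turnover sits at 0.26 s⁻¹, below the 0.3–1 s⁻¹ ensemble window (flagged,
  not hidden); see Calibration.
* Single gating pathway: no dwell-time multimodality, no site-resolved
  nucleotide occupancy, no ADP competition, no voltage dependence.
* Hydrolysis-dead variants have no non-hydrolytic dimer-exit route.
* The QC bleach/blink detector is tuned for the generator's noise regime
  (SNR ≳ 4); pathological real-world baselines may need threshold changes.
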