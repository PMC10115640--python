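# cftrgate

Kinetic modelling and single-molecule analysis of the CFTR gating cycle.

CFTR (the cystic fibrosis transmembrane conductance regulator) is an
ATP-gated anion channel. Single-molecule FRET on its two nucleotide-binding
domains (NBDs), together with single-channel electrophysiology, shows that
NBD dimerization and pore opening are *allosterically*, not strictly,
coupled: at saturating ATP the channel is NBD-dimerized ~85% of the time
but open only ~22% of the time, and it remains dimerized through many
cycles of ATP hydrolysis. `cftrgate` is for biophysicists who want to work
with that picture quantitatively. It provides:

* **`gating_model`** — the gating cycle as a nine-state continuous-time
  Markov chain (separated ⇌ ATP-bound ⇌ dimerized-closed → open burst with
  flicker closures → hydrolysis → post-hydrolytic open → ADP-bound dimer →
  isomerizing intermediate → rebinding or full separation), with exact
  stationary/relaxation solves, first-passage dwell means, and Gillespie
  simulation under piecewise-constant ATP protocols. Presets for the
  E1371Q, W401A, Y1219A, G551D and L927P variants.
* **`calibration`** — constrained multi-start estimation of the rate
  constants from measured observables (occupancies, dwell ratio, relaxation
  constants, EC50s, turnover window). The shipped wild-type rate set is the
  output of this procedure.
* **`synthetic_traces`** — camera-integrated two-colour FRET traces (frame
  averaging, intensity noise, single-step donor bleaching, blinking) and
  Bessel-filtered single-channel currents, with ground-truth annotations.
* **`trace_qc`** — the standard smFRET selection criteria (single-step
  bleach, SNR > 8, < 4 blinks, ≥ 50 frames above baseline, > 0.8 excluded)
  and segmental k-means idealization with a two-state model.
* **`kinetics`** — censoring-aware exponential dwell fits, Hill
  dose-response fits (n fixed to 1), mono/bi-exponential relaxation fits,
  coupling ratio, transition frequency.
* **`pipeline` / `cftrgate` CLI** — reproducible end-to-end runs with a
  config hash embedded in every output.

## The model in brief

The generator Q(c) at ATP concentration c has two pseudo-first-order
binding steps (k_bind·c, k6·c) and eleven unimolecular rates. Headline
quantities:

* Po = Σ π(open states), Pdim = Σ π(dimerized + intermediate states),
  where πᵀQ = 0;
* coupling ratio = Po / Pdim ≤ 1 by construction (openings occur only from
  dimerized states);
* turnover = k3·π(pre-hydrolytic open state);
* dose responses fitted with the Hill equation A·c/(c + EC50), n = 1;
* relaxations p(t) solve ṗ = Qᵀp and are fitted mono/bi-exponentially.

## Worked example

```python
from cftrgate import build_topology, stationary_distribution, observable_vector

graph = build_topology("WT")                    # calibrated wild-type rates
stat = stationary_distribution(graph, 3e-3)     # 3 mM ATP
print(f"Po   = {stat.po:.3f}")
print(f"Pdim = {stat.pdim:.3f}")
print(f"coupling ratio = {stat.po / stat.pdim:.3f}")

obs = observable_vector(graph)                  # the full observable set
print(f"tau_opening = {obs.tau_opening_s*1000:.0f} ms")
print(f"tau_sep = {obs.tau_sep_fast_s:.2f} s, {obs.tau_sep_slow_s:.1f} s")
print(f"EC50(open) = {obs.ec50_open_M*1e6:.1f} uM")
print(f"dwell ratio = {obs.dwell_ratio:.1f}")
```

prints

```
Po   = 0.220
Pdim = 0.851
coupling ratio = 0.259
tau_opening = 489 ms
tau_sep = 1.60 s, 20.0 s
EC50(open) = 53.6 uM
dwell ratio = 20.3
```

That is: the channel dimerizes far more readily than it opens (coupling
ratio ~0.26); opening after an ATP jump is rate-limited by a ~490 ms
conformational step downstream of dimerization; NBD separation after ATP
withdrawal is biphasic (a fast hydrolytic drain and a slow ~20 s escape of
the isomerizing intermediate); and opening and dimerization titrate with
nearly identical ~50 µM midpoints because both are limited by the same
binding events.

A full synthetic experiment — simulate an ensemble, render noisy traces,
QC-select, idealize, extract dwells and fits, write report + figures:

```
cftrgate run --out run_output          # default wild-type config
cftrgate simulate --variant E1371Q --atp 3e-3 --duration 500 --out e1371q.csv
cftrgate render --n 50 --out traces.csv && cftrgate idealize --traces traces.csv
```

`run_output/report.json` then contains the observables above plus the
trace-pipeline results (QC counts, re-estimated FRET state means, high-FRET
occupancy, transition frequency), and re-running the same config reproduces
every file bit for bit.

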