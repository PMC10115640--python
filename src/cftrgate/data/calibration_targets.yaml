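# Default calibration targets: measured observables of phosphorylated
# wild-type CFTR.  Values are the published single-molecule FRET /
# electrophysiology estimates; tolerances are relative weighting scales
# for the fit, not acceptance bands.
#
#   po            stationary open probability at 3 mM ATP (bilayer recordings)
#   pdim          stationary NBD-dimerized (high-FRET) occupancy at 3 mM ATP
#   dwell_ratio   mean dimerized dwell / mean open-burst dwell (~20-fold)
#   tau_opening_s activation constant of current after an ATP jump (490 ms)
#   tau_sep_*     bi-exponential high-FRET decay after ATP withdrawal (1.6 s, 20 s)
#   ec50_*        Hill midpoints (n = 1) of opening / dimerization dose response
#   turnover      ensemble ATPase estimate 0.3-1 ATP per channel per second;
#                 a window target because the model is expected to sit at or
#                 above the upper end of the ensemble estimate.
targets:
  - {name: po, value: 0.22, tolerance: 0.03, weight: 3.0, kind: point}
  - {name: pdim, value: 0.85, tolerance: 0.03, weight: 3.0, kind: point}
  - {name: dwell_ratio, value: 20.0, tolerance: 0.25, weight: 1.0, kind: point}
  - {name: tau_opening_s, value: 0.49, tolerance: 0.05, weight: 2.0, kind: point}
  - {name: tau_sep_fast_s, value: 1.6, tolerance: 0.08, weight: 1.5, kind: point}
  - {name: tau_sep_slow_s, value: 20.0, tolerance: 0.08, weight: 1.5, kind: point}
  - {name: ec50_open_M, value: 53.0e-6, tolerance: 0.05, weight: 2.0, kind: point}
  - {name: ec50_dim_M, value: 55.0e-6, tolerance: 0.08, weight: 2.0, kind: point}
  - {name: turnover_per_s, kind: window, lo: 0.3, hi: 1.0, tolerance: 0.2, weight: 3.0}
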