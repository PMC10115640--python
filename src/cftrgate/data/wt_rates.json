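{
 "rates": {
  "k_bind": 4696.68,
  "k_unbind": 25.7862,
  "k1": 49.1574,
  "k2": 0.498151,
  "k3": 1.26103,
  "k_flick_on": 6.0683,
  "k_flick_off": 22.2147,
  "k4": 15.9763,
  "k5": 4.40444,
  "k6": 202972.0,
  "k7_fwd": 647.854,
  "k7_rev": 1.36953,
  "k8": 0.237186
 },
 "provenance": {
  "method": "multi-start bounded least squares against the default target set",
  "targets": "cftrgate/data/calibration_targets.yaml",
  "objective": 0.7588,
  "note": "regenerate with: cftrgate calibrate --restarts 8 --seed 13"
 }
}
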