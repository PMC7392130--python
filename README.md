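# coroflow

Analysis of coronary blood-flow regulation from paired intracoronary
pressure and Doppler flow-velocity recordings, as acquired with a
pressure/flow sensor-tipped guidewire in a coronary artery.

The package targets two complementary assessments performed in one
experimental session on an intact (e.g. porcine) preparation:

- **Metabolic regulation** — after an intracoronary vasodilator bolus
  (adenosine, endothelium-independent; bradykinin,
  endothelium-dependent), compute

  - *baseline flow* `F_base`: mean flow velocity of 5 successive beats
    at rest (cm/s),
  - *hyperemic flow* `F_hyp`: mean of the 3 successive beats with the
    highest flow at maximal vasodilation,
  - *coronary flow reserve* `CFR = F_hyp / F_base`
    (clinically: > 3.0 normal, < 2.0 pathological),
  - *hyperemic microvascular resistance*
    `HMR = P_hyp / F_hyp` in mmHg/(cm/s), with `P_hyp` the mean
    coronary pressure over the same peak-flow beats.

- **Autoregulation** — during progressive balloon inflation that lowers
  distal coronary pressure, beat-level (pressure, flow) coordinates are
  pooled and averaged in 5-mmHg bins; every contiguous split of the
  binned curve is fitted with a pair of straight lines (the
  autoregulatory *plateau* and the pressure-dependent *ischemic*
  relation), the best-fitted pair (minimal pooled residual sum of
  squares) is selected, and the **lower autoregulatory breakpoint** is
  the intersection of the two lines.

Because such animal recordings are rarely shareable, the package also
ships a seeded synthetic hemodynamics generator
(`coroflow.simulate`) that emulates the full protocol — pulsatile rest
traces at ~85 bpm and ~89 mmHg, gamma-variate hyperemia transients that
triple flow, and a balloon ramp crossing a breakpoint near 49 mmHg —
so the entire pipeline is testable end to end.

## Worked example

```
$ coroflow simulate --out experiment.csv
[simulate] generating experiment with seed 0
[simulate] wrote 142500 samples (570 s) to experiment.csv

$ coroflow analyze experiment.csv --out report.json
[analyze] read 142500 samples, 15 events
[analyze] wrote report to report.json
```

The report (abridged) for the default synthetic experiment:

```json
{
  "hyperemia_means": {
    "adenosine":  {"baseline_flow": 19.07, "hyperemic_flow": 57.75,
                   "hyperemic_pressure": 61.23, "cfr": 3.031,
                   "hmr": 1.060, "classification": "normal"},
    "bradykinin": {"baseline_flow": 19.55, "hyperemic_flow": 57.56,
                   "hyperemic_pressure": 61.36, "cfr": 2.947,
                   "hmr": 1.066, "classification": "intermediate"}
  },
  "autoregulation": {
    "ischemic": {"slope": 0.455, "r2": 0.996},
    "plateau":  {"slope": 0.007, "r2": 0.045},
    "breakpoint_pressure": 49.70, "breakpoint_flow": 18.33,
    "score": 0.994, "in_range": true
  }
}
```

Reading: each vasodilator bolus roughly triples flow
(CFR ≈ 3 against a configured hyperemic gain of 3.0), distal pressure
at peak hyperemia is ≈ 61 mmHg, HMR ≈ 1.06 mmHg/(cm/s), and the fitted
lower limit of autoregulation (49.7 mmHg) recovers the generator's
configured 49 mmHg breakpoint.  The steep ischemic line and near-flat
plateau have distinctly different slopes, so the intersection is well
conditioned; `score` is the global two-segment R².

The same operations are available as a library
(`generate_experiment`, `detect_beats`, `analyze_bolus`,
`bin_pressure_flow`, `fit_breakpoint`, `run_pipeline`, ...), and
`coroflow recover` runs Monte-Carlo parameter-recovery studies.

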