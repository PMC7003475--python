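# coroflow

One-dimensional coronary haemodynamics on arterial tree geometries:
computed fractional flow reserve (cFFR, hyperaemic) and computed
instantaneous wave-free ratio (ciFR, resting), plus the threshold-
determination statistics used to map ciFR onto the FFR cut-off of 0.8.

## What it does

* **geometry** — coronary trees of tapering 1D segments with focal/diffuse
  stenoses; a deterministic synthetic-tree generator emulating segmented
  CCTA centreline output; versioned JSON network files.
* **wall_model** — viscoelastic tube law with a diameter-dependent empirical
  reference wave speed, stiffness exponent and wall viscous coefficient
  `Gamma = 100 D + 400`.
* **solver1d** — implicit (Crank–Nicolson) staggered control-volume solver
  for the 1D pressure–flow equations with the coronary friction coefficient
  of 22; second-order in space and time, exact junction flow balance, cycle
  periodicity detection, HDF5/CSV result export.
* **boundaries** — prescribed inflow at the root; five-element lumped
  coronary beds (Ra, Ca, Rm, Cim biased by intramyocardial pressure, Rv) at
  the terminals; branch resistance from `(sys/3 + 2 dia/3)/Q` distributed
  over terminals by proximal-diameter Murray weighting with power 2.27.
* **tier1** — a small closed-loop 0D circulation (two elastance chambers,
  systemic/pulmonary Windkessels, aggregate coronary branches) calibrated to
  population-average pressures, cardiac output and heart rate; generates the
  two canonical inflow waveform pairs and ventricular pressure traces, and
  the hyperaemia transform (coronary bed resistance × 0.22, giving a
  hyperaemic/resting mean coronary flow ratio of ≈3.5).
* **indices** — cFFR (cycle mean of instantaneous Pd/Pp) and ciFR (mean of
  Pd/Pp over the diastolic wave-free window, from 1/5 into diastole to the
  end of the cycle); forward/backward wave separation.
* **stats** — confusion-matrix diagnostics, Bland–Altman, Pearson,
  polynomial index–index fits with threshold extraction at FFR = 0.8,
  ROC/AUC with Youden-optimal thresholding.

Units are CGS internally (cm, g, s, dyn/cm²); pressures cross the I/O
boundary in mmHg (1 mmHg = 1333.22 dyn/cm²).

## CLI

```sh
coroflow tier1  --out out/tier1             # the two canonical waveform pairs
coroflow run    --config case.yaml --out out/case   # one case -> cFFR, ciFR
coroflow cohort --config cohort.yaml --out out/cohort  # synthetic cohort + stats
coroflow stats  --cohort cohort.csv --out report.json --plots out/plots
```

Configuration is a single YAML file; unknown keys are rejected with the
offending key named, and every artifact embeds the fully resolved
configuration and seed. Example:

```yaml
seed: 3
stenosis: {segment_id: s1, center_fraction: 0.5, stenosed_length: 1.0,
           area_reduction: 0.6}
solver: {dt: 0.001, target_dx: 0.1, max_cycles: 8}
```

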