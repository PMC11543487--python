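# descreen

Rational screening of deep eutectic solvents (DESs) for biocatalysis,
demonstrated on the enzymatic reduction of CO₂ to formate by
NADH-dependent formate dehydrogenase (FDH).

Choosing a DES co-solvent for an enzymatic reaction means reconciling
conflicting targets: solvents that stabilize the enzyme and coenzyme are
usually viscous and suppress activity, while dilute, low-viscosity media
behave like plain buffer. `descreen` packages the quantitative workflow
for navigating that trade-off:

- **Stability kinetics** — enzyme inactivation and NADH degradation are
  first-order, `A(t) = A₀·e^(−kt)`; the package fits `k` by nonlinear
  least squares and reports half-lives `t½ = ln 2 / k`.
- **Michaelis–Menten productivity** — NADH-depletion progress curves are
  fitted against `dc/dt = −v_max·c/(K_S + c)`, and product formation over
  a horizon `t_f` under first-order enzyme inactivation `k` follows the
  closed form `P = v_max·c/(K_S + c) · (1 − e^(−k·t_f))/k`.
- **σ-profile mixture descriptors** — COSMO-RS σ-profiles of the
  components are mole-fraction mixed and integrated over ten equal σ
  regions on [−0.025, +0.025] e/Å², giving the QSAR inputs S¹mix…S¹⁰mix.
- **Spearman screening** — tie-corrected rank correlations with two-sided
  t significance select the QSAR inputs.
- **Piecewise-linear QSAR** — two linear segments joined at a *response*
  breakpoint `b_n`, fitted exactly by profiling the breakpoint over
  observed-response midpoints with per-segment OLS; validated with
  R², adjusted R², RMSEC/RMSEP, RPD and RER and their conventional
  qualitative thresholds.
- **Trade-off ranking** — per-property 0–100 min–max ratings (radar-chart
  geometry) and a maximin "balanced candidate" ranking.
- **Synthetic data** — seeded generators for every input the pipeline
  consumes, so the whole workflow is testable without laboratory data.

The screening study's solvent table (20 glycerol-DES dilutions plus the
reference phosphate buffer) and its published QSAR coefficient tables
ship as packaged fixtures.

## Worked example

Fit the DES-medium kinetics from a simulated NADH-depletion curve and
compare 10-day productivity against the reference buffer
(`examples/productivity_estimate.py`):

```text
recovered v_max = 0.133 umol/mL/min, K_S = 12.133 umol/mL
buffer        : 10-day product =   295.9 umol/mL
20% DES buffer: 10-day product =  1120.8 umol/mL
batch volumetric productivity, 26.5 umol/mL over 4 h: 6.6 umol/mL/h
```

The fitted constants reproduce the generating values exactly; with the
enzyme's half-life extended from 2.1 days (buffer) to 29.9 days (20%
choline chloride:glycerol in buffer), the same reaction yields several
times more product over ten days, and the 4-h batch number reproduces the
measured 6.6 μmol mL⁻¹ h⁻¹.

Ranking the buffered dilution series (`examples/tradeoff_ranking.py`):

```text
maximin ranking (worst-axis rating, best first):
candidate
ChCl:Gly_80%B    30.0
ChCl:Gly_30%B     5.0
ChCl:Gly_90%B     3.8
ChCl:Gly_10%B     0.0
ChCl:Gly_50%B     0.0
buffer            0.0
```

Every candidate except the 20% DES dilution collapses on at least one
axis — the buffer on post-CO₂ coenzyme stability, the concentrated
dilutions on activity — which is exactly why it is the balanced choice.

Other examples cover decay fitting (`stability_kinetics.py`), descriptor
construction (`sigma_mixture_descriptors.py`) and the full
screen-then-model QSAR loop (`qsar_screening.py`). A thin CLI wraps the
same functions (`descreen --help`), including an end-to-end
`descreen run --seed 17 --outdir out/`.

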