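# Methods

## Scope and data model

The package operates on a solvent-screening table: one record per solvent
system (a DES dilution or the reference buffer) carrying composition
(hydrogen-bond acceptor and donor, molar ratio, diluent kind and mass
fraction), physicochemical properties (pH, viscosity in mPa·s, density in
g/cm³), saturated dissolved-CO₂ concentration (mg/L), pH after CO₂
saturation, the short-term NADH degradation constant in CO₂-saturated
solvent (min⁻¹) and 14-day residual enzyme activity (%). The packaged
`table1` fixture transcribes the screening study's published table at its
printed precision; `0.000` degradation constants are stored as exact
zeros (no detectable loss over the 90-min window), and the reference
buffer is stored as a component-free record (`hba = hbd = "none"`,
diluent mass fraction 1.0) so screening statistics can include it. The
source restates the CO₂ concentrations once with mg/mL units; the fixture
follows the tabulated mg/L and records the discrepancy in its provenance
note.

## Stability kinetics

Enzyme inactivation and NADH degradation are modelled as single-phase
first-order decays, `A(t) = A₀·e^(−kt)`, fitted by nonlinear least
squares (`scipy.optimize.curve_fit`) with `A₀` estimated jointly and
`k ≥ 0` enforced by bounds. Initialisation uses the log-linear slope of
`ln A` vs `t` over strictly positive values. The classical
single-time-point estimator `k = ln(A₀/A(t))/t` is retained as a
diagnostic oracle; on noiseless data the two agree to the optimizer
tolerance. An exactly constant signal short-circuits to `k = 0` with the
half-life reported as `+inf`; an identically zero signal is a fit error.
Rate constants are reported in the series' declared time unit (day for
the 14-day stability assays, minute for the 90-min post-CO₂ assay), and
`k·t½ = ln 2` holds identically for every fit. Records with zero residual
activity at the horizon are treated as fully inactivated rather than
assigned a rate. Absorbance is never converted to concentration — no
extinction coefficient is carried — which is immaterial for first-order
rate estimation. Initial reaction rates are ordinary least-squares slopes
over the assay window (default 5 time units, matching a 5-min
plate-reader assay), and relative activity is the percentage ratio of two
such slopes.

## Michaelis–Menten productivity

Substrate (NADH) depletion follows
`dc/dt = −v_max·c/(K_S + c)·e^(−k_FDH·t)`, integrated with classic
fixed-step fourth-order Runge–Kutta at steps ≤ 0.1 min; `k_FDH = 0`
recovers pure Michaelis–Menten depletion. An adaptive-step integrator
(`scipy.integrate.solve_ivp` at rtol 1e-10) serves as the independent
oracle in tests; the fixed-step curve matches it to better than 1e-6
relative at 4 h. Parameter fitting runs `scipy.optimize.least_squares`
over `(v_max, K_S)` against this forward model, initialised at the
steepest observed depletion rate and `c₀/2` with positive bounds. `K_S`
is flagged weakly identified when its linearised relative standard error
exceeds 0.5 *or* the curve never comes within a factor of ten of it
(zero-order regime, where the data carry no curvature information).

Productivity over a horizon `t_f` with the substrate held constant has
the closed form `v_max·c/(K_S+c)·(1−e^(−k t_f))/k` (`rate·t_f` at
`k = 0`); a quadrature route (`scipy.integrate.quad`, rtol 1e-10) is kept
as a cross-check and the two agree to ≤1e-8 relative across the tested
parameter grid. Deactivation rates supplied per day are converted to
min⁻¹ (÷1440) before combination with `v_max` in min⁻¹. The
constant-substrate assumption is the user's to justify; the depleting
simulator quantifies its error. The source's own 10-day projections are
not reproducible from its printed constants under any documented
substrate concentration (the printed constants give ≈296 μmol/mL for the
buffer against a printed 185.7), so the package treats those projections
as illustrative and does not target them; the NADH molar mass used for
mg↔μmol conversion defaults to 709.4 g/mol (free acid) and is
configurable because the source never states its own conversion.

## σ-profile mixture descriptors

A σ-profile is an unnormalized histogram of screened surface-charge
density; the package consumes profiles as data (two-column CSV) and never
computes them quantum-chemically. Mixture profiles are
mole-fraction-weighted pointwise sums after linear resampling to the
finest common grid. Mole fractions derive from the HBA:HBD molar ratio
and the diluent mass fraction by per-unit-mass balance; the buffer
diluent is treated as pure water (its 50 mM phosphate is ignored for
descriptor purposes). Descriptors are trapezoidal areas over ten
contiguous equal-width σ regions spanning [−0.025, +0.025] e/Å² — the
conventional plotting range — ordered from most negative σ (region 1,
donor surface) to most positive (region 10, acceptor surface). The
ten-region split is the only structural commitment the source states;
the equal-width-over-conventional-bounds choice is this package's, is
configurable, and is recorded with descriptor output so alternative bin
schemes can be matched. Region areas are conserved (their sum equals the
total area over the bounds) and linear in mixing, both enforced by
property tests. The donor/nonpolar/acceptor classification threshold is
±0.01 e/Å², configurable.

## Spearman screening

Rank correlations use average ranks with Pearson's r on ranks (the
tie-corrected estimator — the screening table has many tied viscosities
and densities), pairwise-complete over missing cells, with two-sided
significance from `t = ρ√((n−2)/(1−ρ²))` and no multiple-testing
correction (matching the source's raw p < 0.05 bolding). QSAR inputs for
a target are the variables significant at α in table order. Statistics
run on the 21 tabulated system means; the source computed its matrix on
63 replicate-level points that are not published. Four of the six
correlations among {pH, viscosity, density, CO₂ solubility} reproduce
within ±0.05 of the printed values; the two pH pairs (printed 0.461 and
0.301; recomputed 0.283 and 0.221) do not, and cannot from the printed
means — exact triplication of identical rows leaves ρ unchanged, so the
difference must come from unpublished replicate variation. The
corresponding acceptance check is intentionally left failing for those
two pairs rather than widened.

## Piecewise-linear QSAR

The model is two linear segments joined at a breakpoint defined on the
*response*: rows with `y ≤ b_n` follow one hyperplane, rows with
`y > b_n` another. Because fitting assigns membership from the observed
response, the least-squares coefficients for any fixed `b_n` are exactly
the per-segment OLS solutions and the profiled SSE is piecewise constant
between consecutive observed responses; the package therefore solves the
joint nonlinear problem exactly by searching the midpoints of sorted
unique responses (each candidate must leave at least
`max(p+1, 10% of n)` rows per segment). No iterative optimizer or
indicator smoothing is involved, which keeps the published models'
semantics exact; the test suite checks the fit against an independently
written brute-force grid search.

At prediction time the observed response does not exist, so both
segments are evaluated and the self-consistent one returned (low value
≤ `b_n`, or high value > `b_n`); when neither or both are consistent the
value closest to the breakpoint wins (configurable). The published
activity model at all-zero predictors exercises exactly this tie-break:
both intercepts (31.635, 25.079) are inconsistent with their own domains
and the closer one to the 30.081 breakpoint is returned. The synthetic
table generator rejection-samples design points for which exactly one
branch is self-consistent, so noiseless planted tables are refit exactly.

Validation uses a reproducible random 70:30 calibration/prediction split
(floor convention: 63 rows → 44 + 19). Metrics: `R² = 1 − SSE/SST`,
adjusted R² with `(n−1)/(n−p−1)`, `RMSE = √(SSE/n)`,
`RPD = SD(y_pred)/RMSEP` (sample SD) and
`RER = range(y_pred)/RMSEP`, both on the prediction set's reference
values. Qualitative thresholds: R² ≥ 0.75 significant / ≥ 0.50 moderate /
≥ 0.26 weak; RPD < 1.4 non-reliable / 1.4–2 fair / > 2 excellent;
RER > 4 screening / > 10 quality-control / > 15 quantification. The three
published coefficient sets ship as fixtures; the NADH model's printed
segment conditions ("≤ 23.872" / "> 22.872") disagree by one in the tens
digit, which is read as a typographical slip and stored as the single
breakpoint 23.872 with a provenance note. Published R²/RMSE values are
not acceptance targets: the replicate-level data and split seed behind
them are unpublished.

## Trade-off rating and ranking

Each target property is rated 0–100 by min–max scaling over the displayed
candidate set after orienting so better is larger (lower-better
properties are negated first), matching the 0-to-edge geometry of a radar
chart whose axes are bounded by the per-property extremes; a
ratio-to-best alternative (`100·v/best`) sits behind a flag since the
source does not state its scaling. Post-CO₂ coenzyme stability enters as
the negated short-term degradation constant. The default candidate set is
the buffered dilution series (water dilutions fail the post-CO₂
criterion). Ranking formalizes the source's visual "balanced profile"
judgement as maximin — score each candidate by its worst axis — with a
mean rule as alternative and stable tie-breaking in candidate order.

Two narrative values needed by the choline-chloride panel are not printed
anywhere (activity for the 10–80% buffered dilutions, enzyme half-life
for the 10–50% and 90% dilutions); a reconstruction file, labelled
synthetic in name and header, fills them respecting the narrative's
qualitative ordering ("little or no activity at ≤50% aqueous phase",
"90% dilutions stabilize like the buffer"). The maximin winner is
insensitive to these fills: every competitor holds a *printed* near-zero
axis (the buffer and the 50% dilution on post-CO₂ coenzyme stability,
the 90% dilution on printed enzyme half-life), while the 20% DES
dilution is the only candidate without one. The source's stronger claim
that this winner tops *every* axis except activity contradicts its own
table — the 90% dilution has the higher CO₂ solubility (1,149 vs 1,057
mg/L) and lower viscosity — and the corresponding acceptance check is
left failing on those axes rather than redefined.

## Synthetic data generation

Generators emulate each measured input with an explicit error model:
multiplicative Gaussian noise for activity/absorbance decays (assay-CV
behaviour; default studies use 5% CV, 15 daily points), additive Gaussian
noise for progress curves (instrument-floor behaviour; 2% of initial
concentration in recovery studies), three-Gaussian σ-profiles (water
symmetric; a glycerol-like donor with heavier σ < −0.01 mass; a salt-like
profile with a dominant nonpolar peak plus an acceptor-side chloride
peak), and screening tables of 21 systems × 3 replicates = 63 rows with
predictors drawn from the observed screening ranges (viscosity
log-uniform on [1, 360] mPa·s, density uniform on [1.02, 1.21] g/cm³, pH
uniform on [5.3, 9.2]) and responses from a planted piecewise model plus
additive noise; replicates share predictors with independent noise. All
generators are seeded and bitwise reproducible, and every noiseless mode
is exactly the corresponding forward model. What passing tests show is
parameter recovery and pipeline correctness under these idealized error
models — they do not certify behaviour under real assay artefacts
(baseline drift, pipetting bias, correlated replicate error), which none
of the generators emulate.

## Numerical and interface choices

Problem sizes used in tests and the acceptance script — 15-point decay
series, 240-minute progress curves at 1-min sampling, 63-row QSAR tables,
200-replicate recovery studies — mirror the study's own designs and keep
every check comfortably fast on one core. CSV is the interchange format
throughout (RFC-4180, thousands separators accepted on load; time series
carry `# unit=` / `# signal=` metadata lines). Models serialize to JSON.
The pipeline runner requires a seed, logs per stage and writes one
artifact per stage plus a JSON summary, so stages can be rerun and
diffed independently. When no variable clears the significance screen —
as happens for the 14-day residual-activity response on the 21 published
means — the pipeline's QSAR stage falls back to the strongest-|ρ|
variables and flags the fallback in its summary rather than failing.

## Known limitations

Single-phase first-order kinetics only (no biphasic inactivation or pH
dependence of rates); no cofactor-regeneration modelling; no
regularization or cross-validation beyond the single random split; no
weighted multi-criteria schemes; descriptors depend on supplied or preset
σ-profiles, not quantum-chemical computation; and published
dataset-level regression metrics are reproduction-tolerant references,
not targets, because the underlying replicate data are unpublished.
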