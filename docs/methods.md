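# Methods

## Scope and data

The package reanalyses a complete HPLC method-development and
single-marker-quantification study for three *Euphorbia lathyris*
diterpenoids (euphorbia factors L1, L3, L4). All study data are small
printed tables; they ship verbatim as CSV fixtures inside the package
(`qamskit.fixtures`) and are treated strictly as data. Raw replicate-level
chromatograms behind the study's validation RSDs and batch contents were
never published, so those exact values cannot be recomputed; the
corresponding procedures are implemented in full and exercised against the
synthetic generator instead.

Units are fixed package-wide: retention in minutes, temperature in °C
(kelvin internally where thermodynamics needs it), flow in mL/min,
injection volume in µL, concentrations in mg/mL, injected amounts in µg,
contents in % w/w (mg per 100 mg dried powder, from the 0.5 g / 50 mL
extraction constants). There is no unit-conversion layer.

## Screening model

The 12-run two-level screen is analysed as a main-effects OLS model
(intercept + four coded factors), leaving 7 residual degrees of freedom for
two-sided t-tests — the default analysis of replicate-free two-level
screens in mainstream DoE software. On an orthogonal ±1 design each
coefficient equals half the difference of level means, which the tests
assert exactly. Pareto ranking orders |t| against the critical t at the
residual df; ties break lexicographically on factor name. With a perfect
fit (zero residual variance) no t-test exists; zero coefficients are then
reported with p = 1 and nonzero ones with p = 0.

The printed 12-run matrix is not the textbook cyclic PB12 projection (it
contains one repeated factor setting with two different responses, kept
as printed); it is therefore loaded as data, while `make_pbd12` constructs
the standard cyclic design for new campaigns. Recomputing the screen from
the printed responses flags flow rate (p = 0.033) alongside column
temperature and methanol fraction, whereas the original development carried
only methanol and temperature forward; the package reports what the data
give and does not use the original classification as an oracle.

## Response surface

The 13-run rotatable CCD (4 factorial + 4 axial at α = 1.414 as printed +
5 center replicates) is fitted with the full six-term quadratic by OLS, in
actual or coded units; the two parameterizations are exact affine
re-expressions of one another and predict identically. ANOVA term rows use
partial (Type-III) sums of squares — drop-one refits — matching the
conventions of the DoE software the study used; for this orthogonal CCD
they coincide with sequential SS for the linear and interaction terms,
which a brute-force normal-equations oracle verifies in the tests. The
residual splits into pure error (within-group deviations over replicated
settings, 4 df here) and lack of fit (3 df); without replicates the split
is omitted with a warning.

Optimization is deterministic: the analytic stationary point is returned
when it is a maximum inside the requested rectangle, otherwise a dense grid
(default step 0.01 coded units, boundaries included, first-occurrence
tie-break) is scanned. The region is always caller-supplied: over the
studied rectangle the fitted surface peaks at (60 % methanol, 30 °C),
consistent with the operating point the study selected, but the surface
predicts higher resolution below the studied temperature range, so no
operating point is hard-coded.

Verification deviation is |predicted − mean(measured)| / mean(measured) ×
100. The headline prediction is quoted at two decimals by truncation toward
zero (`quote_floor`): a resolution claim should state a value the method
can actually reach, and the quoted 2.33 (from the computed 2.3392) against
the measured mean 2.30 gives the 1.30 % deviation the workflow reports.
Rounding half-up would quote 2.34 and report 1.74 %.

## QAMS calculus

Correction factors follow f_si = (A_s/C_s)/(A_i/C_i); the marker defaults
to L1 but any component may serve. All reproducibility summaries (factor
means, relative retentions, RSDs) use the sample (n−1) standard deviation —
the printed RSDs (0.90 %, 1.48 %) reproduce only under that convention.
Contents use single-point external calibration (one reference injection),
with injection volumes checked for equality between sample and reference
runs. When f_si derives from the same reference injection that supplies the
marker calibration, the marker terms cancel and QAMS equals the
external-standard content exactly (asserted to 1e−12 relative); with a
pooled f̄ averaged across reference runs the two methods diverge only by
the factor's sampling error.

Peak localization assigns unlabeled peaks by relative retention within a
tolerance window (default 5 %): all in-window (analyte, peak) pairs are
ranked by relative error and assigned greedily, nearest first, each peak
and analyte at most once; analytes without a surviving candidate are
reported unassigned rather than raising. The method-comparison report flags
any QAMS/external pair differing by more than 2 % relative.

## Synthetic chromatograph

`qamskit.chromsim` generates integrated peak tables (no signal traces, no
tailing, no gradient elution) from a standard isocratic model:

- retention: tR = t0·(1 + k)/flow with ln k = c0 − S·φ + c2·(1/T − 1/T_ref),
  φ the methanol fraction (% v/v), T in kelvin, T_ref = 298.15 K. S > 0 and
  c2 > 0 for all components, so retention — and with it the L1/L4
  resolution — decreases monotonically in both methanol fraction and
  temperature, the sign structure the screening and CCD responses show.
- peaks: Gaussian at constant plate count N, baseline width w = 4·tR/√N,
  USP resolution Rs = 2·ΔtR/(w1 + w2). Because widths scale with retention,
  Rs is flow-invariant — consistent with flow and injection volume being
  the screen's lesser factors.
- detector: area = RF_i · amount · (1 + ε), ε ~ N(0, noise_cv) truncated at
  −3σ so areas stay positive; optional multiplicative retention jitter for
  localization stress tests. Everything is reproducible under a single
  integer seed.

Default calibration (t0 = 2.5 min, S = 0.09 per %, c2 = 2000 K — ordinary
reversed-phase magnitudes) is anchored to the study's observables at the
selected operating point (60 %, 30 °C): L1 retained 10.0 min, relative
retentions 0.5728 (L3) and 1.1271 (L4), and Rs(L1, L4) = 2.30, which fixes
N ≈ 5 900 plates (solved from the anchor, a realistic figure for a 250 mm
column). Response factors equal the study's calibration-curve slopes (area
per µg). The default area noise is noise_cv = 1 %, matching the ~1 %
replicate RSDs the validation schemes report; the pipeline's validation
demo uses 0.5 % because a spike-recovery statistic roughly doubles the
per-area CV (recovery = difference of two noisy amounts), and 0.5 % keeps
recovery RSDs near the ~1 % the study observed.

Over the studied factor rectangle the simulated resolution response is
smooth and gently curved, so a quadratic fit of a noise-free simulated CCD
attains R² > 0.999; the elution order L3 < L1 < L4 holds across the whole
region. What passing simulator-based tests show is that the analysis
pipeline is correct and well-conditioned under the study's assumed error
structure — they do not certify behaviour under real-world pathologies the
generator deliberately omits (peak tailing, co-elution, drift,
heteroscedastic integration error).

## Problem sizes and numerical choices

All fixture-based statistics are exact recomputations on 12–13-run designs
and 3–8-row tables and complete in milliseconds. Simulation-based checks
use the sizes the procedures prescribe: n = 6 replicates per validation
scheme, 8 synthetic batches, and 1000 jittered runs for the localization
recovery rate (≥ 99 % required; at 1 % retention jitter the observed rate
is ~99.8 %, as the 5 % window sits ≈ 3.5 combined-jitter SDs from the
expected ratios). Degenerate inputs are explicit errors (tied retention
times, duplicate components, n < 2 for RSDs, zero spike) or flagged results
(flat calibration line → correlation not computable). Sum-of-squares
identities (model + residual = total; lack-of-fit + pure error = residual)
hold to 1e−8 and are asserted.

## Known limitations

- Single-marker variant only: one marker, no two-reference QAMS, no
  uncertainty propagation beyond replicate SD.
- The content path uses single-point calibration, as the study does; the
  linearity module fits calibration lines but they do not feed
  quantification.
- The simulator's effective response surface is smooth by construction;
  lack-of-fit behaviour of real campaigns (the study's LOF F = 5.01) can
  only be reproduced from the printed runs, not generated.
- Designs beyond PB12 and the two-factor CCD (blocking, D-optimal,
  desirability-based multi-response optimization) are out of scope.
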