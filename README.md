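# qamskit

Quality-by-Design HPLC method development and single-marker quantification
for the *Euphorbia lathyris* diterpenoids euphorbia factor L1, L3 and L4.

Reference standards for herbal diterpenoids are scarce and expensive. The
QAMS approach (quantitative analysis of multi-components by single marker)
quantifies several analytes from one reference substance: with L1 as the
internal marker, a relative correction factor

    f_si = f_s / f_i = (A_s / C_s) / (A_i / C_i)

links the marker's detector response (peak area `A_s` at concentration
`C_s`) to each analyte's, so an analyte's concentration in a sample follows
from its own peak area and the marker's single-point calibration:

    C_i = A_i,sample · f̄_si · C_s,ref / A_s,ref

Analyte peaks are located without their standards via relative retention
time (`tR_i / tR_s`, matched within a 5 % window). Upstream of the
quantification sits the Quality-by-Design method development itself: a
12-run Plackett–Burman screen of four chromatographic factors (methanol
fraction, flow rate, column temperature, injection volume) against the
L1/L4 resolution, followed by a 13-run central composite design in the two
critical factors and a full second-order fit

    Y = b0 + b1·X1 + b2·X2 + b12·X1X2 + b11·X1² + b22·X2²

with ANOVA (partial sums of squares, lack-of-fit vs pure error from the
five replicated center points), optimum prediction and verification.
Method-validation statistics (linearity, RSD-based stability /
repeatability / precision checks, spike recovery) and a QAMS vs
external-standard method comparison close the loop.

A calibrated synthetic chromatograph (`qamskit.chromsim`) generates peak
tables with the statistical structure the analysis assumes — solvent-strength
/ van 't Hoff retention, Gaussian peaks at constant plate count,
multiplicative detector noise — so every stage is testable without
instrument data. The study's nine printed data tables ship as package
fixtures.

## Worked example

The numbered drivers under `analysis/` run the whole study; each writes its
tables under `results/`. Fitting the response surface:

```bash
python analysis/02_fit_response_surface.py
```

prints

```
Quadratic model (actual units):
  Intercept  +22.2312
  X1         -0.548852
  X2         +0.0366769
  X1X2       -0.0186
  X1^2       +0.00715217
  X2^2       +0.0218566
  R^2 = 0.8101
...
predicted resolution at (60% methanol, 30 degC): 2.3392 (quoted 2.33)
verification vs measured mean 2.30: deviation 1.30%
in-region optimum: (60.00% methanol, 30.00 degC) -> predicted 2.3392
```

`X1` is the methanol fraction (% v/v), `X2` the column temperature (°C) and
the response the L1/L4 resolution: both linear coefficients act against
resolution over the studied region, the model explains 81 % of the response
variance, and the measured resolution at the selected operating point
deviates from the prediction by 1.3 %. Equivalently, from Python:

```python
from qamskit import fixtures, rsm

model = rsm.fit_quadratic(fixtures.ccd_design(), units="actual")
print(model.r_squared)            # 0.8101
print(rsm.predict(model, (60, 30)))  # 2.3392
```

The same workflow is exposed as a CLI (`qamskit screen`, `qamskit rsm
fit|anova|predict|optimize|surface`, `qamskit qams
factors|locate|quantify|compare`, `qamskit validate`, `qamskit pipeline`)
and as one orchestrated run, `qamskit.pipeline.run_pipeline`, which is
deterministic under its configured seed.

## Layout

- `src/qamskit/` — the library: peak-table model and I/O, packaged study
  tables, synthetic chromatograph, design construction, screening, response
  surface, QAMS calculus, validation statistics, pipeline, CLI
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property-based, end-to-end)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
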