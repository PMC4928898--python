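# bisqc — quality control for bioimpedance spectroscopy measurements

Bioimpedance spectroscopy (BIS) measures a tissue's complex electrical
impedance Z(ω) = R(ω) + jX(ω) over a range of frequencies. In practice the
recorded spectra are frequently corrupted — parasitic capacitive leakage
(the "hook" effect), impedance mismatch, cross-talk — and a corrupted
spectrum silently poisons whatever analysis follows (body-composition
estimation, cerebral monitoring, skin characterization). `bisqc`
implements an automatic pre-processing step that decides whether a
measurement is clean and, if not, which of six artifact types it carries,
so the measurement can be repeated, corrected, or discarded on the spot.

The package is aimed at people who work with BIS spectra: instrument
developers who want a quality flag on acquisition, and analysts who need
to triage measurement databases.

## The method

1. **Cole model fit.** Each measurement is fitted in the complex impedance
   plane to the Cole function

   Z(ω) = R<sub>∞</sub> + (R<sub>0</sub> − R<sub>∞</sub>) / (1 + (jωτ)<sup>α</sup>),

   by bounded nonlinear least squares on the stacked real and imaginary
   residuals. The characteristic frequency ω<sub>c</sub> = 1/τ anchors five
   relative frequency bands: VLF (ω < ω<sub>c</sub>/5), LF, MF, HF, and
   VHF (ω > 5ω<sub>c</sub>).

2. **Features.** For the six immittance magnitudes R, X, G, B, |Z|, ∠Z
   (impedance and admittance components), the signed mean relative error
   between measurement and fit is computed per band: 30 dimensionless,
   application-independent features f1–f30, plus f31 = sign X(ω<sub>max</sub>),
   which flags inductive crossover.

3. **Classification.** Multi-class linear discriminants trained by least
   squares against one-hot targets (LS-LDA), V = T Qᵀ(Q Qᵀ)⁻¹, with the
   feature subset chosen by an evolutionary wrapper (population 50,
   truncation selection of the best 10%, uniform crossover, duplicate-only
   mutation, 100 generations, 5-fold cross-validated error as fitness).
   Two schemes are provided:
   * **all-at-once** — one 7-class LS-LDA (clean + six artifact types);
   * **divide and conquer** — a 5-class LS-LDA with the hard pairs B+C
     and E+F merged, then two one-feature threshold classifiers (feature
     chosen by Fisher score, threshold from fold-averaged binary LS-LDA)
     to split each pair.

A synthetic spectrum generator (Cole parameters drawn from
application-like profiles, multiplicative measurement noise, parametric
artifact injectors for all six error types) makes the whole method
trainable and testable without any external data.

## Worked example

Fit the Cole model to one noisy synthetic measurement:

```python
import numpy as np
import bisqc as bq

params = bq.ColeParameters(r0=450.0, rinf=250.0, alpha=0.75,
                           tau=1 / (2 * np.pi * 40e3))
omega = 2 * np.pi * np.logspace(np.log10(5e3), 6, 50)
rng = np.random.default_rng(0)
z = bq.evaluate_cole(params, omega).z
z = z.real * (1 + 0.003 * rng.standard_normal(50)) \
    + 1j * z.imag * (1 + 0.003 * rng.standard_normal(50))
result = bq.ColeModel(bq.ComplexSpectrum(omega, z)).fit()
print(result.summary())
```

```
Cole model fit
==============
  R0          450.1146 ohm
  Rinf        250.4817 ohm
  alpha       0.750077
  tau     4.010827e-06 s
  fc          39681.33 Hz
  SSR     3.748376e+01 ohm^2
  rms rel 2.586105e-03
  points      50
```

The four parameters are recovered to ~0.1% and the root-mean-square
relative residual (~0.26%) matches the injected 0.3% noise.

Train and evaluate the two-step classifier on a synthetic database of
700 labeled spectra (100 per class), split 60/40 into design and test:

```python
import bisqc as bq

collection = bq.generate_dataset(bq.GeneratorConfig(rng_seed=1))
data = bq.build_feature_dataset(collection)        # Cole fits + 31 features
design, test = bq.split_dataset(data, rng_seed=1)  # stratified 60/40
results = bq.DivideConquerModel(design, n_feat=7, rng_seed=1).fit()
print(results.summary())
print(results.evaluate(test).summary())
```

```
Divide-and-conquer scheme (5 merged classes + 2 thresholds)
===========================================================
  design samples   420
  feature budget   7
  step-1 features  f4, f9, f14, f15, f18, f25, f31
  CV error (EA)    1.43%
  B/C split        f14 threshold -0.100528
  E/F split        f19 threshold 0.23219

overall test error: 1.79%

           CLEAN  TYPE_A  TYPE_B  TYPE_C  TYPE_D  TYPE_E  TYPE_F
   CLEAN      40       0       0       0       0       0       0
  TYPE_A       0      40       0       0       0       0       0
  TYPE_B       3       0      35       0       2       0       0
  TYPE_C       0       0       0      40       0       0       0
  TYPE_D       0       0       0       0      40       0       0
  TYPE_E       0       0       0       0       0      40       0
  TYPE_F       0       0       0       0       0       0      40

step 1 (merged classes) error: 1.79%
step 2 B/C error: 0.00%
step 2 E/F error: 0.00%
```

The evolutionary search kept 7 of the 31 features (spanning the R, X, G,
B and |Z| error families plus the reactance-sign flag); 1.79% of the 280 held-out
spectra are misclassified, all of them in step 1 — both one-feature
sub-classifiers separate their pairs perfectly on this test set.

The same pipeline is available from a shell:

```sh
bisqc --seed 1 simulate --out data/
bisqc --seed 1 train data/ --scheme divide-conquer --out model.json --report report.json
bisqc --seed 1 sweep data/ --scheme all-at-once --out sweep.csv   # CV error vs budget 1..31
```

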