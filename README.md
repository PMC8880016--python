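# tensorspec

Qualitative (multi-class) analysis of near-infrared spectra by tensor
robust principal component analysis and support-vector classification.

NIR spectra of complex mixtures from the same product family — e.g. the
five sensory grades of a distilled liquor — are extremely similar: the
information that separates the classes lives in a handful of weak,
class-specific absorption features buried under shared structure,
baseline drift and band-localized noise. `tensorspec` extracts those
features and classifies on them:

1. **Norris derivative filtering (NDF).** Each spectrum is partitioned
   into consecutive fragments of *N* raw points and each fragment is
   replaced by its mean absorbance (van-average smoothing, block
   decimation), then differentiated by the direct-difference rule
   x'ₖ = (x₍ₖ₊g₎ − x₍ₖ₋g₎) / 2g. Smoothing suppresses the noise that the
   derivative would otherwise amplify; the derivative removes baseline
   offsets and sharpens overlapping bands.
2. **Tensor robust PCA (TRPCA).** The preprocessed spectra are stacked
   into a third-order tensor **D** (wavenumbers × samples × classes) and
   split as **D** = **A** + **E** by solving
   min ‖**A**‖\* + η‖**E**‖₁ s.t. **D** = **A** + **E**, where ‖·‖\* is the
   tubal tensor nuclear norm of the t-SVD (DFT along the class mode) and
   η = 1/√(max(w, s)·c). The low-rank **A** holds structure common to
   all classes; the sparse **E** holds class-differential features. The
   problem is solved by ADMM: tensor singular-value thresholding for
   **A**, elementwise soft-thresholding for **E**, and a growing penalty μ.
3. **Characteristic wavenumbers.** For each class slice of **E** the
   score p₍hi₎ = Σⱼ |w₍ij₎| is summed over samples, the per-class profiles
   Pₕ are summed over classes into Q, and wavenumbers whose max-normalized
   qᵢ exceeds 0.2 form the characteristic set.
4. **Classification.** A soft-margin SVM with polynomial kernel
   G(xᵢ, xⱼ) = (γ xᵢᵀxⱼ + r)^q (one-vs-one, standardized features) is
   trained on the characteristic columns; the smoothing window and
   penalty factor C are tuned by a joint grid search scored with
   stratified k-fold cross-validation.

Because real graded-liquor spectra are not publicly distributable, the
package ships a synthetic generator (`tensorspec.synthgen`) that
emulates the assumed structure — a shared Gaussian-band spectrum with
near-rank-1 sample variation, small planted class-specific bands in the
5415–4732 cm⁻¹ combination region, baseline drift, and band-boosted
noise — with recorded ground truth, so every stage is testable.

## Worked example

```python
import tensorspec as ts
from tensorspec.pipeline import run_pipeline, PipelineConfig

spectra, truth = ts.generate(ts.SynthConfig(seed=42))   # 750 samples x 2125 points, 5 grades
report = run_pipeline(spectra, PipelineConfig())        # window 23, band 8000-4500, thr 0.2, C=145
print(report.accuracy)        # 1.0
print(report.dimensionality)  # {'raw': 2125, 'post_ndf': 90, 'post_band': 38, 'characteristic': 9}
print(list(report.characteristic.wavenumbers))
# [5464.0, 5372.0, 5280.0, 5188.0, 5096.0, 5004.0, 4912.0, 4820.0, 4728.0]
```

Reading the output: the 2125-point spectra decimate to 90 fragment
means under window 23 (the derivative drops one point per edge), the
8000–4500 cm⁻¹ target band keeps 38 of them, and thresholding the
aggregate sparse-component score keeps 9 characteristic wavenumbers —
all inside the 5415–4732 cm⁻¹ region where the generator planted the
class differences (`truth.coverage(report.characteristic.indices, ...)`
is 1.0). The stratified 5-fold CV accuracy of the SVM on those 9
features is 100%.

The same chain is available from the shell:

```bash
tensorspec synth raw.csv truth.json --seed 42
tensorspec run raw.csv report.json
tensorspec gridsearch raw.csv grid.json --windows 13,18,23 --penalties 1,10,145
```

## Layout

- `tensorspec.io` — labeled-spectra data model; CSV/TSV and minimal
  JCAMP-DX readers/writers.
- `tensorspec.preprocess` — van-average smoothing and gap derivative.
- `tensorspec.trpca` — t-SVD tensor robust PCA by ADMM.
- `tensorspec.features` — band restriction, difference profiles,
  characteristic-wavenumber selection.
- `tensorspec.classify` — polynomial-kernel SVM, CV, window × penalty
  grid search (leakage-safe and paper-protocol modes).
- `tensorspec.synthgen` — synthetic spectra with planted ground truth.
- `tensorspec.pipeline` / `tensorspec.cli` — the chained pipeline and
  its `tensorspec` command-line front end.
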