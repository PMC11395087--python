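# ginkgoflav

A hyperspectral chemometrics pipeline for predicting the total flavonoid
content (TFC, mg·g⁻¹ dry mass) of *Ginkgo biloba* leaves from visible/NIR
reflectance imagery, aimed at plant-phenotyping and spectroscopy
practitioners who want a fully testable implementation of the standard
leaf-analyte workflow:

1. **Reflectance calibration** — raw intensity to reflectance via white and
   dark reference frames, `I = (I_raw − I_b) / (I_w − I_b)`.
2. **Leaf segmentation** — an RGB rendering is sliced from the cube
   (670/550/450 nm); the leaf mask is the intersection of the grayscale
   Otsu foreground and the excess-green (`EGI = 2G − R − B`) Otsu
   foreground, cleaned to its largest connected component; masked pixels
   are averaged into one spectrum per sample.
3. **Spectral pretreatments** — multiplicative scatter correction
   (regress each spectrum xᵢ on the mean spectrum x̄, correct as
   `(xᵢ − bᵢ)/kᵢ`), standard normal variate (row-wise
   `(x − mean)/sd`, n−1 denominator), and Savitzky–Golay smoothing
   (window 2m+1, local least-squares polynomial).
4. **Outlier screening** — Hotelling T² in PCA score space (components to
   95% cumulative variance), `T²ᵢ = Σⱼ t²ᵢⱼ/λⱼ`, against the control
   limit `p(n−1)(n+1)/(n(n−p)) · F(1−α; p, n−p)`.
5. **Regression** — a shared 4:1 train/test split; SVR, PLSR, Bayesian
   ridge, linear, Lasso and Ridge regression, each tuned by grid search
   with 5-fold cross-validated RMSE on the training rows only; evaluated
   by `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` and `RMSE = √(Σ(y−ŷ)²/n)`.

No public hyperspectral leaf dataset accompanies this workflow, so the
package includes a first-class, seeded **synthetic-scene generator**
(`ginkgoflav.simulate`): fan-shaped leaves (with marginal clefts for the
lobed phenotype) on a dark cloth, vegetation-like spectra with a
chlorophyll plateau, red edge and water features, an explicit affine link
between TFC and a 560–620 nm band window, and raw cubes rendered through
the exact inverse of the calibration map.  Every downstream stage is
validated against this ground truth.

## Worked example

Run the numbered analysis drivers (each writes its tables under
`results/`), or the whole chain at once:

```sh
python analysis/01_simulate_dataset.py --seed 7
python analysis/02_extract_spectra.py  --seed 7
python analysis/03_screen_outliers.py
python analysis/04_fit_models.py       --seed 7
python analysis/05_report.py
```

The first two stages report the simulated survey and its recovery:

```
simulated 407 sample groups (207 lobed, 200 unlobed), seed 7
true TFC range 7.9124-20.0231 mg/g; 20 injected gross outliers
lobed mean 15.009 +/- 2.463 mg/g, unlobed mean 13.563 +/- 2.482 mg/g
LL - UL mean difference 1.446 mg/g (SE 0.245): lobed leaves carry more
flavonoid, as configured
extracted 407 mean spectra (99 bands each)
segmentation recovered the true masks with mean IoU 0.9999 (min 0.9677)
```

The screen then flags exactly the 20 injected gross outliers
(`flagged 20 spectral outliers; retained 387 samples for modeling`), and
the model comparison prints, e.g.:

```
family   prep      train R2  train RMSE   test R2  test RMSE
br       raw         0.9838      0.3232    0.9752     0.4007
lasso    raw         0.9810      0.3508    0.9786     0.3721
br       savgol      0.9808      0.3519    0.9796     0.3630
...
best: br+savgol (min test RMSE)
```

Test R² ≈ 0.97–0.98 and RMSE ≈ 0.4 mg·g⁻¹ mean the models recover the
simulator's configured TFC–reflectance link almost completely at the
default band-noise level (0.005 reflectance units); at zero noise the
recovery is exact (R² ≈ 1).  The same experiment is available as a single
command (`ginkgoflav run-all --seed 7 --out results/`), and the
`ginkgoflav` CLI also exposes each stage (`simulate`, `calibrate`,
`segment`, `preprocess`, `outliers`, `fit`, `report`) over ENVI cubes and
spectra-table CSVs.

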