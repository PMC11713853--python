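# mahm — Matrix Analysis of Hybrid Multidimensional MRI

Hybrid multidimensional MRI (HM-MRI) acquires each image pixel over a grid of
echo times (TE) and diffusion weightings (b-values), so every pixel carries an
M × N signal matrix **A** instead of a single intensity.  Because the signal is
approximately exponential in both TE and b, `mahm` linearizes **A** entrywise
(natural log) and forms the symmetric positive-semidefinite hybrid matrix

```
H = lnA · (lnA)ᵀ      (or (lnA)ᵀ · lnA, whichever is smaller, K = min(M, N))
```

whose eigenvalues λ₁ ≥ λ₂ ≥ … ≥ λ_K and eigenvectors summarize the pixel's
joint TE/b signal structure without any curve fitting.  For mono-exponential
(single water compartment) signal, ln a_ij = ln A₀ − TE_i/T2 − b_j·D separates
into a row term plus a column term, so lnA has rank ≤ 2 and λ₃ vanishes;
multi-compartment tissue (stroma / epithelium / lumen in the prostate) makes
λ₃ > 0.  The scalar ratio

```
λr = (λ1/λ2)/λ3
```

condenses this into one per-pixel statistic that is elevated in prostate
cancer, which is epithelium-rich and lumen-poor compared with normal
peripheral-zone tissue.  The package is aimed at quantitative-MRI researchers
who want to reproduce, probe or extend this matrix-based analysis alongside
the conventional per-TE ADC and per-b T2 mono-exponential fits
(S_b = S_SE·e^(−b·D), S_TE = S₀·e^(−TE/T2)).

## What's inside

| module              | contents |
|---------------------|----------|
| `mahm.core`         | log transform, hybrid matrix, eigensolver (+ 2×2 closed forms and first-order approximation), λr, grid harmonization, per-pixel eigen-maps |
| `mahm.relaxometry`  | per-TE ADC maps and per-b T2 maps (log-linear / nonlinear fits) |
| `mahm.phantom`      | multi-compartment synthetic HM-MRI phantoms with Rician noise |
| `mahm.rendering`    | 8-bit scaling, merged RGB eigenvalue maps, rainbow λr overlays |
| `mahm.stats`        | ROI medians, paired Wilcoxon signed-rank, ROC/AUC, logistic feature combination |
| `mahm.io`, `mahm.pipeline`, `mahm.cli` | NIfTI + JSON-sidecar I/O, the end-to-end pipeline and the `mahm` command line |

## Worked example

Simulate a paired 18-patient cohort (each patient: one epithelium-rich
"cancer" ROI and one lumen-rich "normal" ROI on a 4 TE × 4 b grid, harmonized
to 3 × 3, SNR 50) and compare the three per-case features:

```python
from mahm.pipeline import simulate_cohort, cohort_analysis

table = simulate_cohort(n_cases=18, seed=7)
report = cohort_analysis(table)
for feat, r in report["features"].items():
    print(feat, "p=%.3g auc=%.3f dir=%+d medians %.4g / %.4g"
          % (r["wilcoxon_p"], r["auc"], r["direction"],
             r["median_cancer"], r["median_normal"]))
print("combined", report["combined_auc"])
```

prints

```
lambda_r p=0.000839 auc=0.744 dir=+1 medians 1.178e+05 / 5.718e+04
adc p=7.63e-06 auc=1.000 dir=-1 medians 0.001045 / 0.001401
t2 p=7.63e-06 auc=1.000 dir=-1 medians 90.83 / 151.4
combined 1.0
```

Reading this: λr is roughly twice as high in the simulated cancer ROIs
(direction +1) while ADC (mm²/s) and T2 (ms) are lower (direction −1); all
three paired differences are significant at n = 18, and the in-sample logistic
combination of the three features separates the pooled 36 ROIs perfectly.

The same study is available from the shell:

```sh
mahm stats --n-cases 18 --seed 7 --out cohort_stats.json
mahm render --out-dir demo --seed 1     # phantom + eigen/λr maps + PNG renders
```

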