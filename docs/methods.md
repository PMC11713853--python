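# Methods

## The matrix analysis

A hybrid acquisition samples each pixel at M echo times and N b-values,
giving a signal matrix A with rows indexed by TE and columns by b.  Signal
is modelled as (a sum of) exponential decays in both variables, so the
entrywise natural log approximately linearizes it.  The analysis forms the
Gram matrix H = lnA·(lnA)ᵀ when M ≤ N, or (lnA)ᵀ·lnA otherwise, so H is
always the smaller K × K product (K = min(M, N)), symmetric and positive
semidefinite by construction.  Its descending eigenvalues λ₁…λ_K and
orthonormal eigenvectors are computed per pixel; for K = 2 the closed forms

    λ₁,₂ = ½(tr H ± √((tr H)² − 4 det H)),
    λ₁,₂ ≈ tr H − det H / tr H,  det H / tr H     (first order in det/tr²)

and eigenvectors (H₁₂, λ − H₁₁) (or (λ − H₂₂, H₂₁) when the off-diagonal
vanishes) are provided alongside the general solver.  The scalar summary is
λr = (λ₁/λ₂)/λ₃, defined for K ≥ 3.

Assumptions: signal positivity (magnitude images), approximate exponential
decay, and a common TE/b grid across pixels and cases.  Raw eigenvalues are
gauge-dependent — multiplying all signals by c adds ln c to every entry of
lnA and shifts the spectrum — so only λr (and only on a shared grid) is
compared across cases.  Eigenvectors additionally depend on the product
order; on square input the TE-major order is the default and is recorded in
every output.

### Rank structure

Single-compartment signal gives ln a_ij = ln A₀ − TE_i/T2 − b_j·D, a row
term plus a column term, hence rank(lnA) ≤ 2 and λ₃ = 0 up to round-off.
Multi-compartment signal breaks this separability and lifts λ₃.  One
property worth flagging: λ₃/λ₁ is **not monotone** in the minor
compartment's volume fraction f.  For every compartment pair we tested
(including very small (T2, D) contrasts, on both protocol grids, with and
without an amplitude factor) the ratio rises to a local maximum near
f ≈ 0.05–0.1, dips sharply near f ≈ 0.15–0.2 — the non-separable components
of ln((1−f)e^u + f e^v) interfere destructively there, and at the dip λ₃/λ₁
can fall below the 1e−9 threshold that otherwise flags rank-2 pixels — and
only then grows steadily through f = 0.5.  This was confirmed against a
50-digit-precision SVD oracle, so it is a property of the signal model, not
of floating point.  Tests therefore assert positivity for all f and strict
growth on f ∈ [0.2, 0.5] only.  Practical consequence: λ₃ (and hence λr)
does not order tissues by compartmental mixedness near the dip.

### Numerical choices

- General eigensolver: LAPACK symmetric eigendecomposition
  (`numpy.linalg.eigh`), eigenvalues re-sorted descending.
- PSD clamping: eigenvalues in [−1e−10·λ₁, 0) are round-off and clamped to
  0; larger negatives raise.
- Eigenvector sign: the largest-magnitude component is made positive (ties:
  earliest index), removing the intrinsic sign ambiguity from the maps.
- Log floor: entries ≤ 0 (possible at high TE/b under noise) are floored at
  1e−6 × the slice median positive signal before the log; a flag records
  flooring, and all-non-positive pixels are marked invalid (NaN, never 0).
- λr capping: λr diverges on rank-2 pixels.  λr is reported as
  min(raw, cap) with a flag; the default cap is 10 × the 99th percentile of
  finite in-mask λr (falling back to 1e12 when no finite values exist).
  ROI summaries exclude flagged pixels by default.
- Batched and scalar code paths may differ in summation order; agreement is
  to ~1e−12 relative to λ₁, which the tests reflect.

## Grid harmonization

Mixed protocols (3–4 TEs × 3–4 b-values across patients) must be reduced to
a common grid before eigenvalues are comparable.  Defaults drop the largest
TE first and the smallest nonzero b-value first — the long-TE images are the
noisiest and low-b images add little diffusion contrast, and the surviving
values stay closest to a native 3 × 3 protocol.  On the default 4 × 4 grid,
TEs (57, 80, 150, 200) ms reduce to (57, 80, 150) and b-values
(0, 150, 1000, 1500) s/mm² to (0, 1000, 1500).  Explicit subsets always
override the heuristic.

## Relaxometry

ADC is fitted across b at each TE and T2 across TE at each b, by unweighted
least squares on ln S (deterministic, no initialization); a nonlinear
refinement on the exponential model, started from the log-linear estimate,
and S²-weighted log fits are options.  No Rician-floor correction is
applied.  In two-compartment tissue with co-sorted (T2, D) — the slow
compartment also has lower diffusivity — the fitted ADC is nondecreasing in
TE and the fitted T2 nonincreasing in b, because long TEs and large b each
re-weight the compartment mix toward, respectively, long-T2 fast water and
slow short-T2 water.  Non-physical fits (D ≤ 0, T2 ≤ 0 or infinite) are
flagged and excluded from maps.

## The phantom

Tissue is a mixture of non-exchanging compartments,
S(TE, b) = A₀ Σ_k V_k e^(−TE/T2_k) e^(−b·D_k), Σ V_k = 1, with Rician noise
(out = √((s+n₁)² + n₂²), n₁, n₂ ~ N(0, σ²)).  Defaults, chosen as typical
3 T prostate values: stroma (T2 70 ms, D 1.2e−3 mm²/s), epithelium (60 ms,
0.8e−3), lumen (600 ms, 2.8e−3); normal peripheral zone mixes them
(0.35, 0.35, 0.30), cancer (0.25, 0.65, 0.10) — cancer replaces luminal
space with epithelium.  Noise is specified as SNR at the (shortest TE,
b = 0) image, default 50, converted to σ via the mean in-tissue signal
there.  The default grid is the 4 × 4 protocol above so harmonization is
exercised end to end.

With these defaults the synthetic cancer ROIs show **higher λr, lower ADC
and lower T2** than normal ROIs — the same directions reported clinically.
This is a measured property of the chosen compartment values, recorded
here, not an assumption baked into any test of the generator itself.

What the phantom does not emulate: water exchange, TE-dependent
diffusivity, per-TE proportionality constants (one amplitude per pixel),
partial-volume anatomy, motion/ghosting/distortion artifacts, B0/B1
inhomogeneity, or spatially correlated noise.  Passing tests therefore
demonstrate correctness of the algorithms under the stated signal model,
not clinical performance on patient data.

## Cohort studies

The paired design is emulated as n = 18 patients, each a single-slice
16 × 16 phantom with one 5 × 5 cancer and one 5 × 5 normal ROI (sizes
chosen to keep a 200-replicate power study fast while leaving ≥ 25 pixels
per ROI).  Between patients, compartment fractions are jittered with
SD 0.04 (renormalized) and the base amplitude log-normally with SD 0.10 —
inter-patient biological and gain variability; within patients, noise is
independent.  Per-case features are ROI medians: λr (capped pixels
excluded), ADC at the shortest TE, T2 at b = 0.  Features are compared with
the paired Wilcoxon signed-rank test (zeros dropped, midranks, exact null
for n ≤ 25 without ties, normal approximation with tie correction
otherwise) and ROC AUC (Mann–Whitney pair ordering, ties ½; orientation
flipped and flagged when a feature is lower in cancer).  The combined score
is a near-unpenalized logistic regression on the standardized features,
evaluated in-sample — appropriate to an n = 18 exploratory setting, with no
out-of-sample claim.  If the logistic score ever ranks worse in-sample than
its best single input (possible under perfect separation numerics), that
single oriented feature is used as the combined score, so the combination
never loses to its inputs by construction.

## Rendering

Display-only: eigenvalue channels scale linearly from 0 to the median
in-mask eigenvalue (each channel by its own median), eigenvector components
from −1 to 1 (0 → 128), both to 8-bit with rounding half away from zero and
clamping.  Merged maps assign R/G/B to λ₁/λ₂/λ₃.  λr overlays use the
"turbo" rainbow colormap over [0, cap] on the shortest-TE/b = 0 image.
Scaling bounds are written to JSON sidecars so renders are reproducible.

## Known limitations

- λ₃ non-monotonicity in compartment fraction (above) limits λr's
  interpretability at low mixing fractions.
- Raw eigenvalues are not comparable across scanner gains or grids; only
  λr on a harmonized grid is.
- No noise-floor correction: at high TE·b the Rician bias inflates the
  floored log signal and hence perturbs eigenvalues and fits.
- The in-sample combined AUC is optimistic by construction; cross-validated
  performance is out of scope.
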