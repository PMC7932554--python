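# Methods

## Model and assumptions

The package fits the standardized multivariate linear regression
Y = b\*ᵀX + ε on a joint correlation matrix: all variables are assumed
jointly multivariate normal and standardized, so the model is fully
parameterized by the (m+p)×(m+p) correlation matrix R and the sample size
n. The system is an observed-variable causal diagram — predictors are
"causes", responses "results", and no latent variables are admitted. The
causal reading of the decompositions (direct vs correlation-mediated
effects) inherits path analysis's usual assumptions: correct variable
classification, linearity, and no unmodeled confounding.

All computations happen on the correlation scale. The raw sums-of-squares
scale differs by factors of (n−1) that cancel in every statistic reported
here; correlations are computed with the (n−1)-denominator sample
convention (the Pearson correlation itself is denominator-invariant, but
the convention matters for documentation of the standardization step).

## Quantities

| quantity | definition | notes |
| --- | --- | --- |
| b\* (m×p) | solution of Rxx b\* = Rxy | linear solve, never an explicit inverse |
| c_jj | diag(Rxx⁻¹) | Gauss multipliers; enter all standard errors |
| θ (p×p) | Ryy⁻¹ | weights of the generalized division |
| U | b\*ᵀRxy = b\*ᵀRxx b\* | diag = R(α)², off-diag = X-mediated corr(yα,y_t) |
| B | θU | eigenvalues in [0,1] |
| v_xy | det(R)/(det(Rxx)det(Ryy)) | likelihood-ratio statistic for block independence |
| R² | 1 − v_xy = 1 − det(I−B) | exact generalized determination coefficient |
| tr(B) | Σθ_αα R(α)² + 2Σ_{α<t}θ_αt U[α,t] | overestimates R²; the division basis |

Determinants are computed through sign/log-magnitude factorizations
(`slogdet`) so v_xy is stable for large m+p, and v_xy is always computed
twice — the determinant ratio and the block identity det(E)/det(Ryy) with
E = Ryy − U — with a runtime warning if the routes disagree beyond 1e-8.

## Divisions and conventions

Three decompositions are exact identities, asserted to 1e-10 on every fit
in the test suite:

1. r_{j,yα} = b\*_{jα} + Σ_{k≠j} r_{jk}b\*_{kα} (per-response correlation);
2. R(α)² = Σ_j b\*² + Σ_{j<k} 2b\*r b\* (per-response determination);
3. U[α,t] = Σ_j b\*_{jα}b\*_{jt} + Σ_{j≠k} b\*_{jα}r_{jk}b\*_{kt}
   (cross-response, m² composite terms).

Stored term values follow the doubled printed-table convention of the
field: same-response pair terms carry the factor 2 and are stored once per
unordered pair; cross-response terms are stored as 2b\*b\* (direct) and
2b\*rb\* (each ordering), so a report cell equals the stored value and the
stored cross terms sum to 2·U[α,t]. In the θ-weighted division of tr(B)
the two orderings of a cross pair are merged into one combined term
(matching the division's vector form), which gives the term count
p·m·(m+1)·(p+1)/4 — 36 at m = p = 3.

The generalized decision coefficient R_y(j) sums the θ-weighted terms
touching predictor j; each unordered pair contributes its full doubled
value to both members, so Σ_j R_y(j) intentionally exceeds tr(B). Its
part_I satisfies the identity part_I = Σ_α θ_αα(2b\*r − b\*²) through the
normal equations, which the suite checks to 1e-12.

tr(B) rather than the exact 1 − det(I−B) is the division basis; both are
always reported side by side, and a report warning fires when the gap
exceeds 0.05 (on the packaged wheat system the gap is 0.166 — the division
there is a genuinely rough approximation, which the warning surfaces). No
renormalization of the division terms by the gap is applied: the terms are
reported on the tr(B) scale that defines them, and rescaling would break
the cell-by-cell interpretability that is the method's point.

## Hypothesis tests

* Block independence: V = −(n−1−(p+m+1)/2)·ln v_xy ~ χ²(pm).
* Per equation: F = (R(α)²/m)/((1−R(α)²)/(n−m−1)) on (m, n−m−1).
* Per coefficient: t = b\*/√(c_jj(1−R(α)²)/(n−m−1)) on n−m−1. On the
  correlation scale the raw-scale residual variance σ̂α² reduces to
  (1−R(α)²)/(n−m−1); this reproduces the wheat reference t values to ~1%
  (the residual discrepancy comes from the 3-decimal published inputs).
* Per predictor row (all p coefficients of x_j jointly): Wilks
  Λ = det(E)/det(E+H_j) with the rank-one hypothesis matrix
  H_j = b_j b_jᵀ/c_jj. Two F transforms are offered: the legacy
  (n−m−2)(1−Λ)/Λ on (2, 2(n−m−2)), kept as the default for fidelity with
  the method's source literature, and the textbook exact transform for one
  hypothesis degree of freedom, ((ν−p+1)/p)(1−Λ)/Λ on (p, ν−p+1) with
  ν = n−m−1, behind `exact_transform=True`. Λ itself is the well-defined
  quantity; the legacy transform's degrees of freedom should be read with
  caution.
* Decision coefficients: t = R_α(j)/(2|r−b\*|·√(c_jj(1−R(α)²)/(n−m−1))).
  The denominator vanishes when the indirect channel is exactly zero
  (e.g. orthogonal predictors); the result is then returned with an
  `undefined` status rather than raising, so batch runs never crash.
* Generalized decision coefficients: delta-method t with the closed-form
  gradient ∂R_y(j)/∂b\*_{jα} = 2Σ_t θ_αt r_{j,y_t}, obtained by
  differentiating the θ-weighted term sum and simplifying with the normal
  equations; the closed form is verified against central finite differences
  of the term sum (quadratic in each coefficient, so agreement is at
  rounding level). The gradient definition in the method's source
  literature is not spelled out beyond the partial-derivative notation, so
  this derived form is the package's own reading; its t values should be
  compared across predictors, not against external tables.

Significance flags: `**` for p < 0.01, `*` for 0.01 ≤ p < 0.05, two-sided
for t, upper-tail for F and χ². Classification of decision coefficients
(positive_decision / restrictive / nonsignificant) uses the 0.05 level by
default, configurable per call and from the CLI (`--alpha`).

## Validation and numerical choices

Correlation inputs must be square, symmetric within 1e-8 (smaller
asymmetry is repaired by averaging), unit-diagonal within 1e-8,
off-diagonal in [−1, 1], and positive definite with smallest eigenvalue
> 1e-10 × largest. Sample size must exceed m+1 so n−m−1 ≥ 1. Rxx and Ryy
must have condition number below 1e12 to be inverted inside a fit. Missing
values in raw data are rejected by default, with opt-in complete-case
deletion (`dropna=True`). Rank ties break by ascending predictor index.

## Synthetic data

`simulate` draws exact multivariate normal samples N(0, R_true) through a
Cholesky factor of the truth matrix. One master seed is spawned into
per-replicate `SeedSequence` streams, so batteries are reproducible and
replicates independent. The null battery uses a block-diagonal truth
(Σxy = 0) with exchangeable within-block correlation 0.3 — correlated
enough to exercise the c_jj machinery, far enough from singularity to keep
every replicate well-conditioned — and reports empirical rejection rates of
the block-independence and coefficient tests at 0.05 and 0.01.

The generator emulates exactly the model's assumptions: Gaussian,
standardized, homoscedastic, independent rows. It deliberately omits the
features of real trial data — non-normal margins, measurement error,
block/replicate structure, missingness. Passing calibration and recovery
tests therefore certify the implementation, not the model's robustness on
real phenotypes; with real data the usual regression diagnostics still
apply before a path analysis is interpreted.

Problem sizes used by the always-on suite: the ordinary-least-squares
equivalence check simulates n = 10⁶ rows (coefficient agreement within
3e-3), null calibration uses 2000 replicates at n = 105, and the property
tests run 10–25 derandomized cases each; the whole suite completes in
roughly ten seconds.

## Known limitations

* The trace-based division degrades as correlations approach 1 (large
  tr(B) − R² gap); the warning threshold is 0.05 and no alternative exact
  division is provided.
* The legacy Wilks F transform's degrees of freedom are reported as-is for
  fidelity; use the exact transform for inference.
* No multiple-testing correction is applied across the battery.
* Decision-coefficient t tests are delta-method approximations; their
  finite-sample calibration has not been studied here beyond the null
  batteries.
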