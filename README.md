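# pathdecomp

Multiple-to-multiple path analysis for systems with several correlated
predictors (X₁…X_m) and several correlated responses (Y₁…Y_p) — the setting
of crop-breeding trials, where a handful of agronomic traits jointly drive a
handful of yield components, and of any observed-variable causal system
without latent factors.

Classical (Wright-style) path analysis treats one response at a time: each
total correlation r_{j,yα} splits into a direct effect (the standardized
partial regression coefficient b\*_{jα}) and indirect effects routed through
correlated predictors (r_{jk}·b\*_{kα}). When the responses are themselves
correlated through the common predictors, per-response analyses give
contradictory advice. This package implements the multivariate extension:
the part of each response–response correlation carried by the predictors is
decomposed into m² composite paths, the generalized determination
coefficient of the whole system is divided along five path types, and each
predictor gets a single signed **generalized decision coefficient** ranking
its comprehensive influence on the entire response system.

## The model

Everything is defined on the joint correlation matrix

```
R = [[Rxx, Rxy],
     [Ryx, Ryy]]      (m + p) × (m + p),  sample size n
```

* Path coefficients: `Rxx b* = Rxy` (normal equations, solved per response).
* Determination matrix: `U = b*ᵀ Rxx b*`; its diagonal holds the per-response
  R(α)², its off-diagonal the X-mediated parts of corr(yα, y_t).
* Generalized determination: `R² = 1 − v_xy`, with
  `v_xy = det(R)/(det(Rxx)·det(Ryy))` the likelihood-ratio statistic for
  independence of the two blocks; `tr(B)` with `B = Ryy⁻¹U` is the
  (over-estimating) trace approximation that the division is based on.
* Division of tr(B): every determination term — squared direct effects
  b\*², doubled pair terms 2b\*r b\*, cross-response terms 2b\*_{jα}b\*_{jt}
  and 2b\*_{jα}r_{jk}b\*_{kt} — weighted by the matching entry θ_{αt} of
  `Ryy⁻¹`; the weighted terms sum back to tr(B) exactly.
* Decision coefficients: per response `R_α(j) = 2b\*r − b\*²`; for the whole
  system `R_y(j) = R_y(j)_I + R_y(j)_II`, the θ-weighted sum of every
  division term touching predictor j. A significantly negative value marks a
  restrictive factor, a significantly positive one a positive decision
  factor.
* Inference: Bartlett's chi-square test of block independence, per-equation
  F tests, per-coefficient t tests, a Wilks-lambda test per predictor row,
  and delta-method t tests for both kinds of decision coefficient.

## Worked example

The packaged dataset is a wheat breeding study from an arid region: n = 105
observations, responses y1 (panicles per plant), y2 (grain number per
panicle), y3 (1000-grain weight), predictors x1 (biomass per plant),
x2 (single-stem grass weight), x3 (economic coefficient), supplied as the
published 6×6 phenotypic correlation matrix.

```python
import pathdecomp as pdp

system = pdp.datasets.wheat()
fit = pdp.fit(system)
pdp.write_correlation_csv(system, "wheat.csv")
```

```text
$ pathdecomp decide --corr wheat.csv --n 105
m	3
p	3
n	105
v_xy	0.2987
R2_generalized	0.7013
r_xy	0.8374
trB	0.8670
R2_exact_from_B	0.7013
trB_gap	0.1657

# generalized_decisions
x	generalized_decision	part_I	part_II	t	p_value	stars	rank	classification
x3	0.0906	0.0457	0.0448	2.2860	0.0243	*	1	positive_decision
x2	-0.1160	-0.1679	0.0519	-2.4714	0.0151	*	2	restrictive
x1	-0.3855	-0.5915	0.2060	-12.6108	0.0000	**	3	restrictive
```

Reading: the two X/Y blocks are far from independent (v_xy = 0.2987, so the
generalized R² = 0.7013 and the generalized complex correlation is 0.8374).
The economic coefficient x3 is the only positive decision factor for the
yield system as a whole (R_y(3) = 0.0906) — it should be increased in
selection — while biomass per plant x1 is a strong restrictive factor
(R_y(1) = −0.3855): its direct and correlation-mediated determinations of
the three yield components are, net of the θ weights, negative. The run also
warns (stderr) that tr(B) = 0.8670 overshoots the exact generalized R² by
0.166 here, so the trace-based division should be read as approximate.

Other subcommands: `fit` (coefficients), `test` (the full test battery),
`paths` (all division tables, including the m² cross-response terms per
response pair and the 36-term weighted division of tr(B)), `simulate`
(seeded null batteries from a YAML spec). The same functionality is
available as a library: `decompose_correlation`, `decompose_determination`,
`cross_correlation_decomposition`, `generalized_r2_division`,
`rank_decisions`, and the tests in `pathdecomp.inference`.

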