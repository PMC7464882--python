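# Methods

## The compositional model

A foliar analysis reports 11 nutrient concentrations on a dry-matter
basis.  Because all parts compete for the same closed total, raw
concentrations carry spurious correlation; only log ratios between parts
are scale-free.  `cndiag` therefore closes every profile to a 12-part
composition — the 11 nutrients plus a filling value Fv = κ − Σxᵢ
(κ = 1000 g kg⁻¹ dry matter, configurable) absorbing the unquantified
remainder — and performs all geometry on log-ratio coordinates.

The geometric mean, and hence every clr coordinate, is taken over all
**12** parts (D = 12, χ² df = D − 1 = 11).  This convention is forced by
the published reference norms the package ships: their 12 clr means sum
to zero, and the worked-example shortage/excess rankings reproduce only
under the 12-part geometric mean.  Printed formulations that divide by
D − 1 = 11 under the root are treated as typographical.

Unit handling is explicit: micronutrients are stored in mg kg⁻¹ and
divided by 1000 only at closure; interval sets remain in native units.
Zero or censored values must be replaced before closure
(`replace_below_detection`, default 0.65 × detection limit); silently
dropping such rows would bias the norms, so an unresolvable zero is a
hard error.

The ilr balances use a fixed, documented sequential binary partition
(nutrients | Fv; macro | micro; then cascading bisections).  By
orthonormality any valid partition yields identical distances; the tests
verify the isometry |ε_clr − ε_ilr| ≤ 1e-10 across two different
partitions.

## Regional diagnosis

Reference norms are the clr mean and SD per part of the TN (high-yield,
nutritionally balanced) specimens aged 0.9–1.1 yr (inclusive window;
minimum 30 retained specimens, configurable).  CND indices
Iᵢ = (clrᵢ − clrᵢ*)/SDᵢ* rank nutrients from shortage to excess; ties
fall back to the canonical part order; Fv participates in the geometry
but is excluded from ranked reports and interval sets (it is not a
nutrient anyone fertilizes).  The global imbalance r² = ΣIᵢ² is referred
to χ²₁₁; reports carry a caveat that the χ² reference is approximate
because the zero-sum constraint correlates the indices.  Norm SDs below
1e-6 are rejected rather than allowed to produce unbounded indices.

Compatibility intervals are concentration quartiles (Q1, Q3) with the
linear-interpolation quantile estimator; the estimator name is recorded
on the interval set because published tables rarely state theirs.
Classification uses inclusive bounds (lower ≤ x ≤ upper → Normal) —
required to reproduce the published worked-example labels, where values
sitting exactly on a bound are Normal.

`joint_interval_survival` quantifies the geometric collapse argument:
with 11 independent margins each retaining ~50%, joint survival is
0.5¹¹ ≈ 5 × 10⁻⁴, so essentially no specimen is "Normal everywhere"
even in the reference population itself.  Survival is monotonically
non-increasing in the number of nutrients diagnosed (tested), which is
the case against assembling marginal critical ranges into a
multivariate verdict.

## Local diagnosis

The successful pool is the TN quadrant with DBH strictly above 5 cm.
Factor matching is exact on categorical features and windowed on numeric
ones (default clone exact, age ± 0.1 yr).  When nothing matches, the
spec broadens in a fixed, logged order — drop location, drop soil type,
double numeric windows, drop clone, finally unrestricted — a fallback
the package defines itself since the source method is silent.  Neighbors
are the k = 10 closest by Aitchison distance (ties by id).  Two
reference-selection objectives are exposed: `distance` (ε-argmin; the
default, since closeness defines comparability) and `parsimony` (fewest,
then smallest, clr shortages — the cheapest corrective program).  The
attainable yield reported is the selected neighbor's DBH; no
extrapolation beyond observed neighbors is attempted.

A known limitation, surfaced by the property tests: diagnosing against a
*single* neighbor is only as good as that neighbor's own balance.  If
the pool contains a specimen that shares the query's deficiency, the
shortage can be masked.  In simulation, a 60% knockdown of one nutrient
is recovered as the top-ranked shortage in 100% of trials when a
compositionally close healthy neighbor exists, but a harsher 40%
knockdown against a purely random TN pool is recovered only ~88% of the
time.  Screening the pool for balance (low r²) and inspecting all k
neighbors, not just the selected one, are the practical mitigations.

## Classification bench

Yield classes split at DBH 4.3 cm, boundary assigned to *high*
(documented convention; the source is silent).  The protocol is
Monte-Carlo holdout — 10 runs × random 10% test — rather than 10-fold
CV, matching the "randomly removing 10%" description; both the per-run
seeds and the identity of folds across feature expressions are fixed by
the top-level seed, so expression comparisons are paired and the whole
bench replays bit-identically.  Holdouts missing a class are resampled
with a logged retry.

The default model is a random forest (200 trees, √p features, unlimited
depth, per-run seed); the original analysis used a GUI tool whose exact
settings are unrecoverable, so no attempt is made to reproduce its
published AUC values — only structural identities (CA from confusion
counts) and qualitative contrasts.  AUC is the rank-based Mann–Whitney
statistic with midrank ties, written out explicitly and cross-checked in
tests against brute-force pair counting and scikit-learn.  "Diagnosed
balanced" defaults to "predicted high-yield" when partitioning the
confusion quadrants; a χ²-on-r² balance criterion is available but
non-default.

## Synthetic populations

The generator is logistic-normal: multivariate normal in clr space at
the packaged TN location/scale (exchangeable correlation, default 0 —
the published norms give no covariances), projected onto the zero-sum
hyperplane and inverted to κ-closed compositions.  Factors mirror the
survey catalog (8 clones, 48 soils, 148 locations); ages are uniform on
0.9–1.1 yr with a 3% spill outside, matching the survey's 97% in-window
share.

DBH is modeled as

    dbh = b₀ − β·ε(clr, optimum_clone) + u_clone + u_soil + u_location + e

with per-clone compositional optima (clr shifts, SD 0.15), truncated
strictly positive.  The default variance budget is calibrated to the
survey's qualitative finding that tissue composition alone is a weak
yield predictor until local features are added: b₀ = 5.4 cm, β = 1.0 cm
per unit ε (imbalance-term SD ≈ 0.26 cm), factor effect SDs
0.8/0.6/0.8 cm (combined ≈ 1.3 cm), noise 0.4 cm.  Under this budget a
nutrients-only random forest scores near-uninformative AUC (~0.55)
while adding factor features lifts it by 0.10–0.20 — the contrast the
regional-vs-local argument rests on.  The two benchmark scenarios
(`nutrients-only`, `nutrients+factors`) share identical compositions at
the same seed because composition and factor/DBH draws use separate
streams split from one seed.

The generator reproduces the *statistical* structure the method assumes
(clr-normal tissue data, categorical factor effects, imbalance-linked
yield); it does not emulate meteorology, pests, spatial autocorrelation,
measurement error or real inter-nutrient covariance.  Passing tests
therefore demonstrate correctness of the machinery and internal
consistency of the method under its own assumptions, not field validity
on real surveys.

An optional realism screen (`clip_to_ranges`) resamples draws outside
supplied survey min–max concentration ranges.  It is off by default:
the shipped survey ranges are not jointly consistent with the shipped
TN norms for B, Mn and Fe (the norms place those nutrients largely
outside the printed ranges), so screening against them would reject the
bulk of norm-consistent draws and bias parameter recovery.

## Numerical choices

* Closure tolerance 1e-9·κ; a filling value below that is an error.
* clr inversion demands |Σ coordinates| ≤ 1e-6 and subtracts the max
  before exponentiation to avoid overflow.
* Quantiles: numpy linear interpolation; χ² tail: scipy.
* All stochastic components consume `numpy.random.Generator` streams
  spawned from one `SeedSequence`; no global RNG state anywhere.
* Reports serialize with sorted JSON keys / fixed CSV column order, so
  identical inputs produce byte-identical files.
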