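# Methods

`caperisk` implements a chain of comparative and spatial analyses linking
plant extinction risk to the tempo and mode of diversification, together
with a synthetic-data generator that reproduces the statistical structure
those analyses assume. This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data do
and do not establish.

## Red List semantics

Categories follow the ordered IUCN scale LC < NT < VU < EN < CR < EW < EX.
Two conventions coexist and are kept deliberately separate:

- **Binary threat**: VU and above count as threatened. EX species *are*
  threatened under this dichotomy and enter proportions and selectivity
  tests.
- **Ordinal score**: the continuous 0 (LC) – 5 (EW) scale used as a tip
  trait for signal and disparity analyses. EX has no score; callers must
  exclude extinct species from trait analyses, and `threat_score` raises on
  EX rather than guessing.

DD/NE codes are rejected at parse time: they are non-assessments, and
silently mapping them to any rank would bias every downstream proportion.

### Status transitions and the tertile G-test

Species present in two Red List snapshots are scored +1/0/−1 by the sign of
their rank change; the per-genus change index is the within-genus sum.
Genera are ranked by the mean old-snapshot score of their species (ties
broken by name for determinism) and split into tertiles. Species
transitions are pooled within the top and bottom tertiles and dichotomized
as increased vs unchanged-or-decreased. The default test is a 1-df
goodness-of-fit G-test of the top-tertile counts against expected
proportions taken from the bottom tertile: with counts 43:44 against
28:62 this yields G = 12.61. The 2×2 independence framing of the same
table (G ≈ 6.21) is available via `framing="independence"` but is not the
default, because the goodness-of-fit framing is the one consistent with the
published statistic for those counts. Genera with a single assessed species
stay in the ranking and are flagged in the output.

## Taxonomic selectivity

The statistic is the unweighted variance across taxa of the proportion of
threatened species; significance comes from shuffling threat labels over
species, which holds every taxon's size and the global threatened count
fixed (asserted on each draw). p-values use the (count+1)/(n+1) convention
so a permutation p is never exactly zero. A size-weighted variance is
available but non-default. Per-taxon enrichment/depletion flags compare
each taxon's observed proportion with its own randomization distribution,
two one-sided p-values, no multiple-testing correction — the flags are
descriptive, matching how such family-level results are usually displayed.

## Trees, contrasts, and Blomberg's K

Trees are rooted, branch lengths in millions of years (my); ultrametricity
is required where node heights carry meaning (K, DTT, simulation) with a
relative tolerance of 1e-6 on the tip-height spread. Newick I/O goes
through dendropy with underscores preserved; computation runs on a flat
preorder array representation.

Independent contrasts use the standard pruning recursion: contrast
(x₁−x₂)/√(v₁+v₂), ancestral value the variance-weighted mean, parent branch
extended by v₁v₂/(v₁+v₂). Blomberg's K is

K = [(MSE₀/MSE)_obs] / [(tr V − n/(1ᵀV⁻¹1)) / (n−1)],

where MSE₀ is the variance of tips around the phylogenetically weighted
(GLS) mean and MSE the mean squared standardized contrast. Everything is
computed in O(n) through the pruning algorithm: tr V is the sum of tip
depths and 1ᵀV⁻¹1 the reciprocal root-value variance, so no dense matrix is
formed. Tests verify exact agreement (1e-8) with dense GLS linear algebra
on trees up to 12 tips.

Polytomies are resolved arbitrarily into bifurcations whose new internal
branches get 1e-8 × tree height (configurable), with a warning. Because a
proportion- or score-valued trait is bounded and violates the Brownian
normality behind K's parametric expectation, pipelines report only the
tip-randomization p (1000 shuffles by default, p = (1+#{K_rand ≥ K_obs})/(n+1));
K itself is still returned for display.

## Disparity through time

Disparity defaults to the average squared pairwise difference (`avg_sq`,
equal to twice the sample variance); average absolute difference
(`avg_abs`) is provided because "mean pairwise distance" admits both
readings. The DTT profile reports, at each divergence epoch, the mean over
lineages crossing that time of within-lineage disparity divided by
whole-clade disparity. The value plotted at epoch t describes the lineage
configuration created by all divergences strictly before t, so the profile
starts at exactly 1 at the root (one lineage = whole clade), and ends at 0
at the present (every lineage a single tip). Single-tip lineages contribute
zero terms to the epoch mean (configurable exclusion was considered and
rejected: dropping them changes the level of the curve as tips accumulate
and makes profiles across clades incomparable). Ties in node height are
handled by the strict time cut; values above 1 are legitimate and occur
whenever variation concentrates within subclades.

"Late-burst" comparisons use the mean observed-minus-null difference over
relative times in [2/3, 1), excluding the terminal epoch where both curves
are structurally zero.

### Null models

**Brownian**: traits diffuse along branches with variance ∝ branch length.
The DTT ratio cancels the rate, and the tests assert the null mean curve is
rate-invariant. Envelopes are pointwise 2.5%/97.5% quantiles over
replicates; all replicates share one time grid because epochs depend only
on the tree.

**Punctuated / peripatric**: at each speciation one daughter (fair coin)
starts at parent/`asymmetry_factor` — the peripheral isolate with the
restricted range — and the other keeps the parental value. Along a branch
of length t each lineage drifts by Normal(0, drift_sd·√t), and the reduced
daughter additionally gains trend·t on the branch immediately following its
origin, then evolves symmetrically. Defaults: asymmetry 2, drift sd 2,
trend 0.3. Two deliberately open points, both flag-selected:

- *Drift time-scaling.* The √t scaling makes the no-asymmetry limit
  consistent with Brownian motion; `time_scaled=False` gives the literal
  one-draw-per-branch reading. The printed parameter values cannot
  distinguish the two, so the Brownian-consistent version is the default.
- *Direction of asymmetry.* Factors < 1 are rejected rather than silently
  inverting the convention that the reduced daughter divides by the factor.

Values are floored at 1e-6 to keep range-like traits positive. Replicates
with constant tips (possible only for degenerate parameters) are dropped
with a warning and counted; if all are dropped the null errors out.

## Diversification models

Net diversification rate is ln(n)/age (per my). The threat GLMs are
binomial with logit link on per-genus (threatened, listed−threatened)
counts, with predictor transforms ln(richness), √age, ln(rate). Monotypic
genera have rate 0; ln(0) being undefined, they are dropped from
rate-predictor models and counted in the fit object rather than fudged with
an offset. Weights (`log_records`: ln(listed+1); `listed_ratio`:
listed/richness) multiply the binomial denominators, the R `glm` prior-
weight convention. Fits go through statsmodels; an independent hand-rolled
IRLS oracle in the test suite confirms coefficients to 1e-6. Marginal
deviance of a variable is (deviance(reduced) − deviance(full)) / null
deviance. Endemic-only filtering is a flag, default on: non-endemic genera
have stem branches likely broken by unsampled relatives, biasing ages.

Partial Mantel tests correlate upper-triangle residuals of two distance
matrices after OLS on a conditioning matrix, permuting object labels of the
first matrix; trait-to-distance conversion uses |xᵢ−xⱼ| and the default
tail is one-sided (r ≥ observed), both exposed as options since neither
convention is forced by the analysis.

## Spatial analyses

Cells are quarter-degree-style integer lattice indices. Adjacency defaults
to queen (8-neighbour) binary weights — the common default for lattice
floristic data — with rook and row-standardization available. Moran's I
uses the randomization-null moments for its z-score (E[I] = −1/(n−1)) with
an optional permutation p. The headline clumping test runs I on the
residuals of mean threat regressed on ln(genus count), so clumped richness
alone cannot produce clumped threat; with constant richness the correction
degrades gracefully to centred threat with a warning.

The spatially corrected correlation follows Clifford–Richardson–Hémon:
sample autocovariances of both fields over integer Chebyshev distance
classes (default cap 10), variance of r estimated as
Σ_k N_k Ĉx(k) Ĉy(k) / (n² s²x s²y) with class 0 the variances themselves,
effective sample size n_eff = 1 + 1/var̂(r), and r²(n_eff−2)/(1−r²) referred
to F(1, n_eff−2). The correction changes only the degrees of freedom, never
r. Calibration tests show the naive test rejecting a true null ~50% of the
time on strongly autocorrelated 25×25 fields while the corrected test stays
near nominal; on white noise n_eff recovers n within 10%.

## Synthetic data

The generator emulates the *mechanisms* the analyses assume, not any real
flora:

- **Trees**: forward-time birth–death from the two crown lineages, extinct
  lineages pruned, unifurcations suppressed; n-tip stopping cuts the tree
  at a random point inside the waiting time to the next event so terminal
  branches stay positive. Under pure birth the expected tip count after
  time t is 2e^(λt), which the tests check against simulation.
- **Ranges and categories**: per-genus species trees (log-uniform richness
  5–200, stem ages 2–40 my, rescaled to age) carry peripatric range
  evolution; tip values map through a log-linear transform to occupied-cell
  counts, and fixed thresholds (≤1 CR, ≤3 EN, ≤10 VU, else LC) assign
  categories — encoding the range-size criterion that makes rapid
  diversifiers threat-prone.
- **Taxonomic clustering**: 25 families whose identity shifts the ancestral
  log range (sd 0.8), so whole families lean threatened or safe.
- **Grid**: moving-average-smoothed Gaussian fields; mean threat is coupled
  to the diversification field (r ≈ 0.6 by default) while habitat impact is
  generated independently — the built-in negative control for the
  threat-vs-habitat correlation.
- **Snapshots**: per-species one-step transitions whose upgrade probability
  grows with the genus' old-snapshot mean score, so the most threatened
  tertile deteriorates fastest by construction.

Defaults (200 genera, 12 species-level trees, 40×40 grid) are large enough
for the calibration tests yet run in seconds. What passing tests show:
the estimators recover effects that are truly present under the assumed
mechanisms, and stay calibrated when effects are absent. What they do not
show: robustness to assessment bias, spatial sampling artefacts, taxonomy
errors, or category-criteria changes between real Red List editions — none
of which the generator models.

## Problem sizes and numerical conventions

Simulation-based tests use 128-tip trees with 500 trait replicates for the
Brownian expectation of K, 200 replicates on a 64-tip tree for the
late-burst check, and 500 simulated datasets for each calibration band;
these sizes put Monte-Carlo error well inside the asserted bands while the
whole suite runs in minutes. Permutation p-values always use
(count+1)/(n+1). All stochastic functions accept explicit seeds and are
bit-reproducible given one; the CLI makes seeds mandatory for stochastic
stages.

## Known limitations

- The punctuated simulator does not couple diversification rate to trait
  values, so it cannot generate deep between-clade structure in threat —
  only the tipward disparity excess.
- K's parametric expectation is not trusted for bounded traits; only
  randomization inference is reported by the pipelines.
- The Clifford correction assumes second-order stationarity; heavily
  anisotropic or trended fields will mis-estimate n_eff.
- The genus-level Mantel analysis in the bundled drivers conditions on an
  age-difference proxy rather than a true genus phylogeny when no
  genus-level tree is supplied.
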