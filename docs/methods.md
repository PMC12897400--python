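# Methods

`phylostand` quantifies the phylogenetic structure of forest inventory
plots and relates it to abiotic gradients and community trait composition.
This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic generator does and does
not emulate.

## Phylogenies and patristic distances

The pipeline consumes a rooted phylogeny with branch lengths (Newick).
Polytomies are accepted unresolved and trees are not assumed ultrametric:
branch lengths are used exactly as supplied, and the patristic distance
between two tips is the sum of branch lengths on their connecting path.
Missing branch lengths are a hard error rather than a silent default —
an invented length would flow directly into every distance-based
statistic downstream. Distances are stored dense; the intended pool sizes
(tens to a few hundred species) make this trivial.

## SES.MPD under the tip-shuffle null

For each plot, the observed mean pairwise distance (MPD) is the unweighted
mean of patristic distances over all unordered pairs of species present
(presence-based: abundances never weight the pairs). The null model
permutes species labels across the tips of the phylogeny while leaving the
plot-by-species incidence untouched ("taxa-labels" shuffle); this
preserves richness and occurrence frequencies and randomizes only
relatedness. With `n_rand` shuffles (default 1000),

    SES.MPD = (MPD_obs − mean(MPD_null)) / sd(MPD_null)

Plots are classified with the two-tailed 5% convention, inclusive at the
boundary: SES ≤ −1.96 clustered, SES ≥ +1.96 overdispersed, otherwise
random. Exact boundary hits are logged because the literature is split on
inclusivity. Richness-1 plots and degenerate nulls (a plot containing the
whole pool) are reported with category `undefined`, never dropped
silently.

The null pool is the species set of the supplied community matrix. The
orchestrator runs SES separately for the total plot set and for each
stand type, each standardized against its own pool on a tree pruned to
that pool — so cross-scope SES values are pool-conditional, not
comparable as absolute effect sizes.

Reproducibility: each plot draws its shuffles from a private substream
keyed by (global seed, CRC-32 of the plot id). Results are bit-identical
across runs and invariant to adding or removing *other* plots, which a
position-keyed stream could not guarantee.

Implementation note: shuffles are vectorized — `n_rand` permutations are
generated at once and the plot's pairwise submatrix gathered in a single
indexing operation, so 500 plots × 999 shuffles takes on the order of a
second.

## Community descriptors

Basal area per stem is π(DBH/200)² m² for DBH in cm. Stand types use
basal-area shares summed by species: conifer if the conifer share is
≥ 75%, broadleaved if the broadleaved share is ≥ 75%, otherwise mixed
(threshold inclusive; shares sum to one, so test order is irrelevant).
CWM traits are basal-area-weighted species means, CWM = Σ p_i t_i. A
species with a missing trait value is dropped and the weights
renormalized, with a warning reporting coverage; synthetic data always
has 100% coverage, so tests can treat any warning as a failure.

## Variable preparation and multi-model inference

Variables are transformed, then z-scored. The default transform spec is
explicit and overridable: log for precipitation, stand age and both CWMs;
log(1+x) for elevation (sea-level plots survive); square root for
richness; identity for temperature (which can be negative) and for the
already-dimensionless SES response. A zero-variance column after
transformation is a hard error naming the column.

Collinearity: predictor pairs with |Pearson r| above 0.65 are flagged and
the lower-priority member dropped (default priority keeps elevation and
drops mean annual temperature, the classic lapse-rate pair). Variance
inflation factors (1/(1−R²_j)) are reported afterwards; values below 3
are expected once the screen has run.

All 2^p predictor subsets (p ≤ 6 after screening, intercept-only
included) are fit by OLS on the standardized data. The information
criterion is the Gaussian profile form AIC = n·ln(RSS/n) + 2(p+2),
counting slopes, intercept and error variance. Models within ΔAIC ≤ 2 of
the best are retained; coefficients are averaged over that set with
renormalized Akaike weights, substituting β = 0 where a model omits a
predictor (full averaging; conditional averaging is a switch). Two
spreads are reported because the field is ambiguous about which one
figures display: the across-model SD of β, and the unconditional
model-averaged standard error √(Σ w(se² + (β−β̄)²)). Relative importance
is the normalized sum of absolute standardized coefficients,

    importance_j = Σ_selected |β_j| / Σ_k Σ_selected |β_k|,

which is non-negative and sums to one by construction. This is
deliberately not the sum-of-Akaike-weights importance.

## Piecewise SEM

A `PathModel` is a DAG plus free covariances (pairs acknowledged as
correlated but not causally modelled). Each endogenous node is regressed
on its parents by OLS on standardized data, giving standardized path
coefficients. The d-separation basis set contains one claim per
non-adjacent pair without a free covariance, conditioning on the union of
the two nodes' parents, with the topologically later node as regression
response. Claim p-values (t-test on the focal coefficient) combine into
Fisher's C = −2Σ ln p, chi-square with 2k df under the model; claim
p-values are floored at 1e-300 before the log. Model AIC is C + 2K with K
the count of slopes, intercepts and error variances across submodels.
Optional pruning repeatedly removes the least significant path with
p > 0.05, refitting, and stops when all paths are significant or AIC
rises (the removal is then reverted).

Indirect effects between two variables are sums over all directed
mediated paths (length ≥ 2) of the product of standardized coefficients;
the per-path decomposition is reported alongside the sum, since "the"
indirect effect is ambiguous when several mediators exist. Free
covariances are reported as Pearson correlations (of residuals, for nodes
with parents), never modelled as latent structure.

The shipped default DAG sends elevation, precipitation and stand age to
richness and both CWM traits, and all six to SES.MPD, with free
covariances among the three abiotic variables. It is an informed
reconstruction of the usual abiotic → biotic → phylogenetic-structure
ordering, not a fitted object. Its basis set is the three biotic-biotic
claims (df = 6): the d-separation test is calibrated under the package's
linear-Gaussian DAG simulator, while on assembled synthetic forests the
biotic claims can reject because assembly genuinely couples richness and
CWM residuals — a property of the data, not a bug in the test.

## The synthetic generator

`generate_study` produces a complete study with known ground truth:

* **Phylogeny** — a birth–death tree (birth 1.0, death 0.3 per lineage)
  conditioned on the pool size, extinct lineages discarded, stem edge
  removed; ultrametric by construction, tips `sp0001…`.
* **Traits** — two Brownian-motion traits (σ² = 1 per unit branch length).
  The SLA-like trait drives filtering. Because two independent BM traits
  on a *single* tree realization can be strongly correlated across tips,
  the MH-like axis is orthogonalized against SLA across the pool; observed
  scales are lognormal (SLA ≈ 12 mm²/mg, MH ≈ 18 m at the median).
* **Abiotic covariates** — latent standard-normal drivers zE, zP, zA
  (corr(zE, zP) = 0.3, corr(zE, zA) = 0.1) map log-linearly to elevation
  (median ≈ 400 m), precipitation (≈ 1000–1900 mm) and stand age
  (≈ 30–70 yr). Temperature follows elevation through a 6.5 °C/km lapse
  rate plus noise, giving |r| > 0.65 with elevation by construction so the
  collinearity screen always has something to catch.
* **Wiring** — plot richness (mapped linearly to the 5–20 range, clipped)
  and the per-plot SLA optimum are linear in the latent drivers with
  configured standardized coefficients (defaults: elevation −0.25, MAP
  +0.30, age +0.10 into richness; +0.40, +0.15, −0.20 into the SLA
  optimum; exact zeros into CWM.MH, which is not filtered). Residual
  variances top each latent up to one, so the configured values are
  standardized path coefficients.
* **Assembly** — `neutral` draws species uniformly; `filtering` samples
  without replacement with weight ∝ exp(−s·(t_i − optimum)²) on the
  z-scored trait axis (Gumbel top-k; s = 0 degenerates exactly to
  neutral); `repulsion` greedily maximizes the minimum patristic distance.
  Stems per species are 1 + Poisson(2) with lognormal DBH (median 20 cm,
  σ_log 0.4) — fixed conventions that exercise basal-area weighting, not
  claims about real size distributions.
* **Calibration** — selecting the k best-weighted species from a finite
  pool shrinks the community trait mean toward the pool mean with a
  k-dependent gain; richness is wired to the same drivers, so an
  uncorrected gain would leak richness wiring into the CWM paths. The
  generator estimates the per-k mean response curve by Monte Carlo and
  places each optimum through its inverse, making the configured
  coefficients realized, not merely intended.
* **Conifers** — one clade sized closest to the configured fraction
  (default 0.3) is flagged conifer, so stand types correlate with
  phylogeny and all three types emerge.

What the generator does *not* emulate: spatial structure and dispersal,
succession through time, intraspecific trait variation, observation error
in species identification, and pool-delimitation ambiguity. Tests passing
on synthetic data therefore demonstrate correctness of the computations
and recoverability of known signals — not that real inventories satisfy
the generating assumptions.

## Numerical choices

* Null SD below 1e-12 (relative) is treated as exactly zero; float
  summation order otherwise turns a degenerate null into garbage SES.
* p-value floor 1e-300 in Fisher's C; singular designs and
  zero-variance columns are hard errors naming the offender.
* Ties in stand typing cannot occur (shares sum to one; threshold
  inclusive); ties in topological order are broken lexicographically so
  basis sets and outputs are deterministic.
* All result tables are written with a fixed float format and no
  timestamps, so a fixed seed reproduces output bytes exactly.

## Test problem sizes

The standing study conditions are a 50-species pool, 500 plots with
richness 5–20, and 999 shuffles for regime-level checks; 200 replicates
for the importance-recovery and pSEM-calibration simulations (n = 500
each); a 10-species pool against exhaustive k-subset enumeration for the
null-equivalence check. Generator path-coefficient recovery is assessed
on coefficients averaged over three replicate studies with a 200-species
pool — the scale of the national inventories this emulates — because the
claim under test is generator bias, which single-study sampling noise
(SE ≈ 0.04 per coefficient at n = 500) would otherwise dominate. The
richness equation is fit with the identity transform in that check, as
richness is wired on the linear scale.

## Known limitations

* MPD/SES only; nearest-taxon and abundance-weighted metrics are out of
  scope, as are richness-constrained and swap-based nulls.
* Gaussian OLS submodels throughout; no mixed effects, no spatial
  autocorrelation, no GLMs.
* The default DAG treats free covariances as reporting-only; correlated
  errors are not estimated as latent structure.
* CWM with partial trait coverage renormalizes rather than imputes;
  heavily incomplete trait tables will bias CWMs toward covered species.
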