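# phylostand

Phylogenetic community structure of forest inventory plots: who grows
with whom, and how far apart on the tree of life.

Forest plots assemble under a mix of deterministic filters (climate,
topography, competition) and chance (dispersal, disturbance history).
One widely used way to read the net outcome is the standardized effect
size of mean pairwise phylogenetic distance,

    SES.MPD = (MPD_obs − mean MPD_null) / SD MPD_null,

where MPD_obs is the mean patristic distance over all species pairs
co-occurring in a plot, and the null distribution comes from shuffling
species labels across the tips of the phylogeny while keeping the
plot-by-species incidence fixed. SES.MPD ≤ −1.96 flags phylogenetic
clustering (close relatives co-occur — consistent with environmental
filtering of conserved traits), SES.MPD ≥ +1.96 flags overdispersion
(distant relatives co-occur — consistent with limiting similarity), and
values between are indistinguishable from the null.

`phylostand` implements the full analysis pipeline around that statistic
for plot-level tree lists:

* **phylo** — validated Newick handling and patristic distance matrices;
* **community** — basal areas (π(DBH/200)²), the ≥75% basal-area-share
  stand-type rule (conifer / broadleaved / mixed), species richness, and
  community-weighted mean traits CWM = Σ pᵢtᵢ with pᵢ the species' share
  of plot basal area (here: specific leaf area and maximum height);
* **sesmpd** — observed MPD, the tip-shuffle null, SES and dispersion
  categories, reproducible per plot via seeded substreams;
* **model_inference** — transformation and z-scoring, an |r| > 0.65
  collinearity screen with VIF reporting, all-subsets OLS, ΔAIC ≤ 2
  model averaging, and a normalized relative-importance score
  (Σ|β| across selected models, scaled to sum to one);
* **psem** — piecewise structural equation models: standardized path
  coefficients, d-separation basis sets, Fisher's C, AIC, pruning, and
  path-product indirect effects;
* **synthetic** — a forest-study generator (birth–death phylogeny,
  Brownian traits, neutral / filtering / repulsion assembly, covariates
  wired through a known path model) so every stage is testable against
  ground truth;
* **pipeline / cli** — an orchestrator that runs everything per stand
  type against that stand type's own species pool, plus a `phylostand`
  command-line tool.

## Worked example

Generate a synthetic study in which species are filtered on a
phylogenetically conserved SLA-like trait, then compute SES.MPD and the
model-averaged predictor table:

```sh
$ phylostand simulate --out demo --seed 42 --n-pool 50 --n-plots 300 --mode filtering
wrote synthetic study: 300 plots, 50-species pool -> demo

$ phylostand ses --tree-list demo/tree_list.csv --covariates demo/covariates.csv \
    --traits demo/traits.csv --phylogeny demo/phylogeny.nwk \
    --out ses.tsv --n-rand 999 --seed 42
mean SES.MPD = -2.475 +/- 2.076
```

A strongly negative mean SES.MPD is exactly what trait filtering on a
conserved trait should produce: co-occurring species are far closer
relatives than label shuffles allow. The first rows of `ses.tsv`:

```
plot_id  richness  mpd_obs  null_mean  null_sd   ses_mpd    n_rand  category
p0001    15        7.44669  8.40239    0.270048  -3.539     999     clustered
p0002    11        8.14566  8.41318    0.388348  -0.688879  999     random
p0003    11        7.38423  8.39235    0.386091  -2.61109   999     clustered
```

```sh
$ phylostand mmi --tree-list demo/tree_list.csv --covariates demo/covariates.csv \
    --traits demo/traits.csv --phylogeny demo/phylogeny.nwk \
    --out mmi.tsv --n-rand 999 --seed 42
retained predictors: elevation, map, stand_age, richness, cwm_sla, cwm_mh
VIF: {"elevation": 1.32, "map": 1.255, "stand_age": 1.077, "richness": 1.113,
      "cwm_sla": 1.292, "cwm_mh": 1.015}
```

Mean annual temperature was screened out (it tracks elevation with
|r| > 0.65 by construction); the remaining VIFs sit near 1. In
`mmi.tsv`, the biotic variables carry most of the normalized importance
— richness 0.32 and CWM.SLA 0.49 versus ≤ 0.06 for each abiotic
predictor — the expected signature of a system where abiotic gradients
act on SES.MPD mainly through trait composition and richness:

```
predictor  beta_avg    beta_sd    p_value      importance  n_models  r2_best
richness   -0.241954   0.0113675  7.10197e-06  0.320942    14        0.211769
cwm_sla     0.370943   0.0150564  5.49184e-11  0.490707    14        0.211769
...
```

`phylostand run-all --out results ...` runs the same analyses per stand
type (total / broadleaved / conifer / mixed), each against its own
species pool and pruned phylogeny, and adds the piecewise SEM tables
(path coefficients, Fisher's C fit, indirect effects) plus a manifest
with input hashes and the seed, from which every number is reproducible.

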