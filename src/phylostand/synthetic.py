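"""Synthetic forest studies: phylogeny, traits, plots and wired covariates.

The generator produces everything the pipeline consumes, with known ground
truth, so every stage is testable without any external data:

* a birth--death phylogeny conditioned on the pool size (ultrametric,
  tips ``sp0001`` ...),
* two independent Brownian-motion traits (an SLA-like resource-use trait
  and an MH-like stature trait) with phylogenetic signal by construction,
* plots assembled under one of three regimes — ``neutral`` (uniform
  species draws), ``filtering`` (species sampled by Gaussian proximity of
  the SLA-like trait to a plot optimum) and ``repulsion`` (greedy max–min
  patristic-distance selection) — with per-species stem counts and DBH
  draws so that basal-area weighting is exercised,
* abiotic covariates (elevation, temperature, precipitation, stand age)
  generated log-linearly from latent standard-normal drivers, with an
  elevation–temperature correlation far beyond the |r| > 0.65 screening
  threshold by construction (a 6.5 degC/km lapse rate plus noise),
* plot richness and the filtering optimum wired to the latent abiotic
  drivers through configured standardized path coefficients, so that a
  piecewise SEM fitted to the generating DAG can recover them.

What the regimes emulate: environmental filtering of a phylogenetically
conserved trait should produce phylogenetic clustering (negative
SES.MPD), limiting-similarity-style repulsion should produce
overdispersion (positive SES.MPD), and neutral draws should match the
tip-shuffle null exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from dendropy.simulate import treesim

from .community import PlotCommunity, TraitTable, TreeRecord
from .errors import ValidationError
from .phylo import Phylogeny, patristic_distances
from .psem import PathModel, default_path_model
from .sesmpd import CommunityMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "DEFAULT_PATH_COEFFICIENTS",
    "DEFAULT_SEM_COEFFICIENTS",
    "DEFAULT_EXO_CORR",
    "simulate_tree",
    "simulate_bm_traits",
    "assemble_communities",
    "simulate_dag_data",
    "generate_study",
]

#: standardized path coefficients wired into the generator (latent abiotic
#: drivers -> plot richness and the SLA filtering optimum).  The MH trait
#: is not filtered, so its CWM carries no abiotic signal: those paths are
#: configured as exact zeros and recoverable as such.
DEFAULT_PATH_COEFFICIENTS: dict[str, float] = {
    "elevation -> richness": -0.25,
    "map -> richness": 0.30,
    "stand_age -> richness": 0.10,
    "elevation -> cwm_sla": 0.40,
    "map -> cwm_sla": 0.15,
    "stand_age -> cwm_sla": -0.20,
    "elevation -> cwm_mh": 0.0,
    "map -> cwm_mh": 0.0,
    "stand_age -> cwm_mh": 0.0,
}

#: coefficients for direct linear-Gaussian simulation from the shipped
#: conceptual DAG (used to exercise the piecewise SEM machinery end to
#: end).  Signs echo the study system: the SLA-like trait depresses
#: SES.MPD strongly, precipitation mildly raises it.
DEFAULT_SEM_COEFFICIENTS: dict[str, float] = {
    **{k: v for k, v in DEFAULT_PATH_COEFFICIENTS.items()},
    "elevation -> cwm_mh": -0.15,
    "map -> cwm_mh": 0.10,
    "stand_age -> cwm_mh": 0.35,
    "richness -> ses": -0.15,
    "cwm_sla -> ses": -0.45,
    "cwm_mh -> ses": 0.15,
    "elevation -> ses": 0.05,
    "map -> ses": 0.10,
    "stand_age -> ses": 0.05,
}

#: correlations among the exogenous abiotic drivers
DEFAULT_EXO_CORR: dict[str, float] = {
    "elevation ~~ map": 0.30,
    "elevation ~~ stand_age": 0.10,
    "map ~~ stand_age": 0.0,
}

ASSEMBLY_MODES = ("neutral", "filtering", "repulsion")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults are the package's standing study conditions: a 50-species
    pool, 500 plots with richness 5–20, Gaussian filtering strength 5 on
    the standardized trait axis, and roughly one third of the pool flagged
    conifer by clade.
    """

    n_pool: int = 50
    birth_rate: float = 1.0
    death_rate: float = 0.3
    bm_sigma2: float = 1.0
    n_plots: int = 500
    richness_range: tuple[int, int] = (5, 20)
    assembly_mode: str = "filtering"
    filter_strength: float = 5.0
    conifer_fraction: float = 0.3
    path_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_pool < 2:
            problems.append("n_pool must be >= 2")
        if not (self.birth_rate > 0 and self.death_rate >= 0):
            problems.append("rates must be positive (death rate >= 0)")
        if self.death_rate >= self.birth_rate:
            problems.append("death_rate must be below birth_rate")
        if self.bm_sigma2 < 0:
            problems.append("bm_sigma2 must be >= 0")
        if self.n_plots < 1:
            problems.append("n_plots must be >= 1")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            problems.append("richness_range must satisfy 1 <= min <= max")
        if hi > self.n_pool:
            problems.append("richness_range.max must not exceed n_pool")
        if self.assembly_mode not in ASSEMBLY_MODES:
            problems.append(f"assembly_mode must be one of {ASSEMBLY_MODES}")
        if self.filter_strength < 0:
            problems.append("filter_strength must be >= 0")
        if not (0 < self.conifer_fraction < 1):
            problems.append("conifer_fraction must be in (0, 1)")
        for key, v in self.path_coefficients.items():
            if not (-1 < v < 1):
                problems.append(f"path coefficient {key} = {v} outside (-1, 1)")
        if problems:
            raise ValidationError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    config: SyntheticConfig
    tree: Phylogeny
    traits: TraitTable
    plots: list[PlotCommunity]
    community: CommunityMatrix
    stems: pd.DataFrame  # plot_id, species, dbh_cm
    covariates: pd.DataFrame
    ground_truth: dict

    def write(self, out_dir) -> dict[str, Path]:
        """Emit the study as the pipeline's plain-text input files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree_list": out / "tree_list.csv",
            "covariates": out / "covariates.csv",
            "traits": out / "traits.csv",
            "phylogeny": out / "phylogeny.nwk",
            "ground_truth": out / "ground_truth.json",
        }
        self.stems.to_csv(paths["tree_list"], index=False, float_format="%.6f")
        self.covariates.to_csv(paths["covariates"], index=False, float_format="%.6f")
        trait_rows = [
            {
                "species": sp,
                "sla_mm2_mg": round(self.traits.sla[sp], 6),
                "mh_m": round(self.traits.mh[sp], 6),
                "is_conifer": int(self.traits.is_conifer[sp]),
            }
            for sp in sorted(self.traits.is_conifer)
        ]
        pd.DataFrame(trait_rows).to_csv(
            paths["traits"], index=False, float_format="%.6f"
        )
        paths["phylogeny"].write_text(self.tree.to_newick() + "\n", encoding="utf-8")
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.3, seed: int = 0
) -> Phylogeny:
    """Birth--death tree conditioned on ``n_tips`` surviving tips.

    Extinct lineages are discarded, so the returned tree is ultrametric
    over its extant tips.  Tips are relabelled ``sp0001`` ... in a
    deterministic traversal order.
    """
    if n_tips < 2:
        raise ValidationError("simulate_tree needs n_tips >= 2")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
        repeat_until_success=True,
    )
    tree.seed_node.edge.length = None  # drop the stem: crown tree only
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(label=f"sp{i + 1:04d}")
    # guard against zero-length pendant edges from the simulator
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 0.0
    return Phylogeny(tree)


def simulate_bm_traits(
    tree: Phylogeny, sigma2: float = 1.0, root_value: float = 0.0, seed: int = 0
) -> dict[str, float]:
    """Brownian-motion trait values at the tips.

    Each branch adds an independent Normal(0, sigma2 * branch_length)
    increment, so trait covariance among tips equals sigma2 times shared
    path length — the phylogenetic signal the filtering regime relies on.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict = {tree.tree.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            pass
        else:
            parent_val = values[node.parent_node]
            bl = node.edge.length
            values[node] = parent_val + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def _gumbel_topk(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct indices sampled with probability proportional to weights
    without replacement (Gumbel top-k trick)."""
    g = rng.gumbel(size=len(log_w))
    return np.argsort(-(log_w + g))[:k]


def _repulsion_pick(
    d: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy max–min selection: start uniformly, then repeatedly add the
    species whose minimum patristic distance to the selection is largest."""
    n = d.shape[0]
    start = int(rng.integers(n))
    chosen = [start]
    mind = d[start].copy()
    mind[start] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, d[nxt])
        mind[nxt] = -np.inf
    return np.array(sorted(chosen))


def assemble_communities(
    tree: Phylogeny,
    traits: dict[str, float],
    config: SyntheticConfig,
    optima: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, CommunityMatrix]:
    """Assemble plot communities under the configured regime.

    ``traits`` is the filtering trait (SLA-like); it is z-scored across
    the pool so ``filter_strength`` acts on a scale-free axis.  In
    filtering mode each plot draws (or is given, via ``optima``) an
    optimum on that axis and samples species without replacement with
    weight proportional to ``exp(-filter_strength * (t_i - optimum)^2)``;
    strength 0 degenerates to neutral.  Repulsion mode greedily maximizes
    the minimum patristic distance within the plot.  Every plot then
    receives ``1 + Poisson(2)`` stems per species with lognormal DBH
    (median 20 cm, sigma_log 0.4).

    Returns the stem table (plot_id, species, dbh_cm) and the binary
    incidence matrix.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.richness_range[1] > len(tree.tips):
        raise ValidationError("richness_range.max exceeds the species pool")
    lo, hi = config.richness_range
    richness = rng.integers(lo, hi + 1, size=config.n_plots)
    if optima is None and config.assembly_mode == "filtering":
        optima = rng.normal(0.0, 0.8, size=config.n_plots)
    return _assemble_with_richness(tree, traits, config, richness, optima, rng)


def _edge_key(a: str, b: str) -> str:
    return f"{a} -> {b}"


def simulate_dag_data(
    model: PathModel,
    coefficients: dict[str, float],
    n: int,
    rng: np.random.Generator,
    exo_corr: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate standardized linear-Gaussian data from a DAG.

    Exogenous nodes are multivariate normal with unit variances and the
    correlations given in ``exo_corr`` ("a ~~ b" keys, default 0).  Each
    endogenous node is the coefficient-weighted sum of its parents plus an
    independent Gaussian error whose variance is chosen from the implied
    covariance so every column has exact unit population variance —
    making the configured coefficients standardized path coefficients.
    """
    order = list(nx.lexicographical_topological_sort(model.graph()))
    exo = [v for v in order if not model.parents(v)]
    exo_corr = exo_corr or {}
    cov = {(v, v): 1.0 for v in order}

    def get_cov(a, b):
        return cov.get((a, b), cov.get((b, a), 0.0))

    for i, a in enumerate(exo):
        for b in exo[i + 1 :]:
            r = exo_corr.get(f"{a} ~~ {b}", exo_corr.get(f"{b} ~~ {a}", 0.0))
            cov[(a, b)] = r

    sigma_exo = np.array([[get_cov(a, b) for b in exo] for a in exo])
    data = pd.DataFrame(
        rng.multivariate_normal(np.zeros(len(exo)), sigma_exo, size=n),
        columns=exo,
    )
    resid_var = {}
    for pos, node in enumerate(order):
        parents = model.parents(node)
        if not parents:
            continue
        beta = np.array([coefficients.get(_edge_key(p, node), 0.0) for p in parents])
        sigma_pp = np.array([[get_cov(a, b) for b in parents] for a in parents])
        explained = float(beta @ sigma_pp @ beta)
        if explained >= 1.0:
            raise ValidationError(
                f"path coefficients into {node!r} imply variance {explained:.3f} >= 1"
            )
        resid_var[node] = 1.0 - explained
        data[node] = data[parents].to_numpy() @ beta + rng.normal(
            0.0, np.sqrt(resid_var[node]), size=n
        )
        # propagate the implied covariance against already-processed nodes
        # (parents of any later node are earlier in the topological order,
        # so these entries are all that downstream nodes will ever query)
        for other in order[:pos]:
            cov[(node, other)] = float(
                sum(b * get_cov(p, other) for b, p in zip(beta, parents))
            )
    return data[order]


def _filter_response_inverse(
    t: np.ndarray,
    ks,
    strength: float,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    n_rep: int = 60,
):
    """Inverse of the filter's mean community-trait response, per richness.

    For each k, the expected mean selected trait as a function of the
    optimum is estimated by Monte Carlo on a grid, forced monotone, and
    returned as an interpolating inverse: given a desired community mean,
    it yields the optimum to filter at.  Targets beyond the achievable
    response saturate at the grid ends.
    """
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 33)
    out = {}
    for k in ks:
        y = np.empty(len(grid))
        for gi, o in enumerate(grid):
            log_w = -strength * (t - o) ** 2
            y[gi] = np.mean(
                [t[_gumbel_topk(log_w, k, rng)].mean() for _ in range(n_rep)]
            )
        y = np.maximum.accumulate(y)  # enforce monotone response
        resp, opt = y, grid

        def inverse(target, resp=resp, opt=opt):
            return float(np.interp(target, resp, opt))

        out[k] = inverse
    return out


def _conifer_clade(tree: Phylogeny, fraction: float) -> set[str]:
    """Flag one clade as conifer, sized as close as possible to
    ``fraction`` of the pool (at least 1 tip, at most pool - 1)."""
    n = tree.n_tips
    target = fraction * n
    best: tuple[float, list[str]] | None = None
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        if not (1 <= len(leaves) <= n - 1):
            continue
        score = abs(len(leaves) - target)
        if best is None or score < best[0]:
            best = (score, leaves)
    assert best is not None
    return set(best[1])


def generate_study(config: SyntheticConfig, out_dir=None) -> SyntheticStudy:
    """Generate a complete synthetic study with known ground truth.

    The causal wiring: latent standard-normal drivers zE, zP, zA generate
    elevation, precipitation and stand age log-linearly (plus a
    temperature column tied to elevation through a lapse rate, giving the
    |r| > 0.65 collinearity the screen must catch).  Plot richness and,
    in filtering mode, the plot's SLA optimum are linear in the latent
    drivers with the configured standardized path coefficients (residual
    variance topped up to one).  Assembly, stems and DBH then follow
    :func:`assemble_communities`.  Ground truth (every generating
    parameter and the realized elevation–temperature correlation) is
    recorded, and files are written if ``out_dir`` is given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(
        config.n_pool,
        config.birth_rate,
        config.death_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    sla_bm = simulate_bm_traits(
        tree, config.bm_sigma2, seed=int(rng.integers(2**31 - 1))
    )
    mh_bm = simulate_bm_traits(
        tree, config.bm_sigma2, seed=int(rng.integers(2**31 - 1))
    )
    labels = tree.tips
    z_sla = _zscore(np.array([sla_bm[lab] for lab in labels]))
    z_mh = _zscore(np.array([mh_bm[lab] for lab in labels]))
    # two independent BM traits can still be strongly correlated across the
    # tips of a single tree realization (few effective deep contrasts);
    # orthogonalize the MH axis against SLA across the pool so filtering on
    # SLA does not mechanically drag CWM.MH along
    z_mh = _zscore(z_mh - (z_mh @ z_sla / (z_sla @ z_sla)) * z_sla)
    # observable trait scales: lognormal around ~12 mm^2/mg SLA, ~18 m MH
    sla_obs = np.exp(2.5 + 0.35 * z_sla)
    mh_obs = np.exp(2.9 + 0.35 * z_mh)
    conifers = _conifer_clade(tree, config.conifer_fraction)
    traits = TraitTable(
        sla={lab: float(v) for lab, v in zip(labels, sla_obs)},
        mh={lab: float(v) for lab, v in zip(labels, mh_obs)},
        is_conifer={lab: lab in conifers for lab in labels},
    )

    n = config.n_plots
    exo_corr = dict(DEFAULT_EXO_CORR)
    rho_ep = exo_corr["elevation ~~ map"]
    rho_ea = exo_corr["elevation ~~ stand_age"]
    z_e = rng.normal(size=n)
    z_p = rho_ep * z_e + np.sqrt(1 - rho_ep**2) * rng.normal(size=n)
    z_a = rho_ea * z_e + np.sqrt(1 - rho_ea**2) * rng.normal(size=n)
    lat_cov = np.array(
        [[1.0, rho_ep, rho_ea], [rho_ep, 1.0, rho_ea * rho_ep], [rho_ea, rho_ea * rho_ep, 1.0]]
    )
    latents = np.column_stack([z_e, z_p, z_a])

    elevation = np.exp(6.0 + 0.5 * z_e)  # median ~400 m
    mat = 13.5 - 0.0065 * elevation + rng.normal(0.0, 0.8, size=n)  # lapse rate
    map_mm = np.exp(7.23 + 0.17 * z_p)  # ~1000-1900 mm
    stand_age = np.exp(3.78 + 0.22 * z_a)  # ~30-70 yr

    def wired(target: str) -> np.ndarray:
        beta = np.array(
            [
                config.path_coefficients.get(_edge_key(src, target), 0.0)
                for src in ("elevation", "map", "stand_age")
            ]
        )
        explained = float(beta @ lat_cov @ beta)
        if explained >= 1.0:
            raise ValidationError(f"paths into {target} imply variance >= 1")
        return latents @ beta + rng.normal(0.0, np.sqrt(1 - explained), size=n)

    rich_latent = wired("richness")
    sla_latent = wired("cwm_sla")
    lo, hi = config.richness_range
    k_mid, k_scale = (lo + hi) / 2.0, (hi - lo) / 4.0
    richness = np.clip(np.rint(k_mid + k_scale * rich_latent), lo, hi).astype(int)
    # Selecting the k nearest-by-weight species from a finite pool shrinks
    # and distorts the community trait mean relative to the optimum, and
    # more so for large k.  Because richness is wired to the same drivers,
    # an uncorrected response would leak richness wiring into the CWM
    # paths.  Calibrate the per-k mean response curve by Monte Carlo and
    # place each plot's optimum through its inverse, so the realized
    # community mean tracks 0.8 * latent with unit gain.
    if config.assembly_mode == "filtering":
        target = 0.8 * sla_latent
        inverse = _filter_response_inverse(
            z_sla, range(lo, hi + 1), config.filter_strength, rng
        )
        optima = np.array([inverse[k](target[i]) for i, k in enumerate(richness)])
    else:
        optima = 0.8 * sla_latent  # on the z-scored SLA axis

    stems, cm = _assemble_with_richness(
        tree, sla_bm, config, richness, optima, rng
    )

    covariates = pd.DataFrame(
        {
            "plot_id": cm.plots,
            "elevation_m": elevation,
            "mat_c": mat,
            "map_mm": map_mm,
            "stand_age_yr": stand_age,
        }
    )
    cov_by_plot = covariates.set_index("plot_id")
    plots = []
    for pid, grp in stems.groupby("plot_id", sort=True):
        c = cov_by_plot.loc[pid]
        plots.append(
            PlotCommunity(
                plot_id=pid,
                trees=[
                    TreeRecord(species=r.species, dbh=float(r.dbh_cm))
                    for r in grp.itertuples(index=False)
                ],
                elevation=float(c["elevation_m"]),
                mat=float(c["mat_c"]),
                map_mm=float(c["map_mm"]),
                stand_age=float(c["stand_age_yr"]),
            )
        )

    realized_r = float(np.corrcoef(np.log(elevation), mat)[0, 1])
    ground_truth = {
        "config": {**asdict(config), "richness_range": list(config.richness_range)},
        "path_coefficients": dict(config.path_coefficients),
        "exogenous_correlations": exo_corr,
        "elevation_mat_correlation": realized_r,
        "trait_scaling": {
            "sla": "exp(2.5 + 0.35 * z)",
            "mh": "exp(2.9 + 0.35 * z)",
        },
        "richness_mapping": {"mid": k_mid, "scale": k_scale},
        "optimum_scale": 0.8,
        "n_conifer_species": len(conifers),
        "assembly_mode": config.assembly_mode,
    }
    study = SyntheticStudy(
        config=config,
        tree=tree,
        traits=traits,
        plots=plots,
        community=cm,
        stems=stems,
        covariates=covariates,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study


def _assemble_with_richness(
    tree: Phylogeny,
    filter_trait: dict[str, float],
    config: SyntheticConfig,
    richness: np.ndarray,
    optima: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, CommunityMatrix]:
    """Like :func:`assemble_communities` but with externally wired
    per-plot richness (and optima in filtering mode)."""
    labels = tree.tips
    n = len(labels)
    t = _zscore(np.array([filter_trait[lab] for lab in labels]))
    dist = patristic_distances(tree) if config.assembly_mode == "repulsion" else None
    plot_ids = [f"p{i + 1:04d}" for i in range(config.n_plots)]
    presence = np.zeros((config.n_plots, n), dtype=bool)
    rows = []
    for i, pid in enumerate(plot_ids):
        k = int(richness[i])
        if config.assembly_mode == "neutral":
            idx = rng.choice(n, size=k, replace=False)
        elif config.assembly_mode == "filtering":
            log_w = -config.filter_strength * (t - optima[i]) ** 2
            idx = _gumbel_topk(log_w, k, rng)
        else:
            idx = _repulsion_pick(dist.d, k, rng)
        idx = np.sort(idx)
        presence[i, idx] = True
        for j in idx:
            n_stems = 1 + rng.poisson(2.0)
            for dbh in rng.lognormal(np.log(20.0), 0.4, size=n_stems):
                rows.append({"plot_id": pid, "species": labels[j], "dbh_cm": dbh})
    stems = pd.DataFrame(rows, columns=["plot_id", "species", "dbh_cm"])
    used = presence.any(axis=0)
    cm = CommunityMatrix(
        plots=plot_ids,
        species=[lab for lab, u in zip(labels, used) if u],
        presence=presence[:, used],
    )
    return stems, cm
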