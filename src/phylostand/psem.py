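"""Piecewise structural equation modelling with d-separation tests.

A :class:`PathModel` is a DAG of observed variables plus optional free
covariances (pairs whose association is acknowledged but not causally
modelled).  Fitting proceeds piecewise: each endogenous variable is
regressed on its direct causes by OLS on standardized data, so the fitted
coefficients are standardized path coefficients.  Goodness of fit uses the
d-separation test: the DAG's missing edges imply a basis set of
conditional-independence claims; each claim is tested by regression, and
the claim p-values combine into Fisher's C = -2 * sum(ln p), which is
chi-square with 2k degrees of freedom when the DAG is consistent with the
data.  Model AIC is C + 2K with K the number of estimated parameters
(path coefficients, intercepts and error variances across submodels).

Indirect effects between two variables are sums over all directed
mediated paths of the product of standardized coefficients along each
path; the per-path decomposition is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, ValidationError
from .model_inference import AnalysisTable, ols_fit

__all__ = [
    "PathModel",
    "IndependenceClaim",
    "PSEMResult",
    "default_path_model",
    "basis_set",
    "dsep_pvalues",
    "fishers_c",
    "fit_psem",
    "indirect_effects",
    "indirect_paths",
    "total_effect",
]

#: p-values are floored at this value before taking logs in Fisher's C;
#: an exactly-zero p would otherwise make C infinite.
P_FLOOR = 1e-300


@dataclass
class PathModel:
    """A DAG of variables with optional free (unmodelled) covariances."""

    nodes: list[str]
    directed_edges: list[tuple[str, str]]
    free_covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate nodes in path model")
        nodeset = set(self.nodes)
        seen = set()
        for a, b in self.directed_edges:
            if a not in nodeset or b not in nodeset:
                raise ValidationError(f"edge {a} -> {b} uses unknown node")
            if (a, b) in seen:
                raise ValidationError(f"duplicate edge {a} -> {b}")
            seen.add((a, b))
        for a, b in self.free_covariances:
            if a not in nodeset or b not in nodeset:
                raise ValidationError(f"covariance {a} ~~ {b} uses unknown node")
            if (a, b) in seen or (b, a) in seen:
                raise ValidationError(
                    f"covariance {a} ~~ {b} duplicates a directed edge"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"directed part contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(a for a, b in self.directed_edges if b == node)

    def endogenous(self) -> list[str]:
        """Nodes with at least one parent, in deterministic topological order."""
        order = list(nx.lexicographical_topological_sort(self.graph()))
        return [n for n in order if self.parents(n)]

    @classmethod
    def from_spec(cls, spec: dict) -> "PathModel":
        """Build from a dict with ``nodes``, ``edges`` ("a -> b" strings)
        and optional ``covariances`` ("a ~~ b" strings)."""
        edges = []
        for s in spec.get("edges", []):
            parts = [p.strip() for p in s.split("->")]
            if len(parts) != 2 or not all(parts):
                raise ValidationError(f"cannot parse edge spec {s!r}")
            edges.append((parts[0], parts[1]))
        covs = []
        for s in spec.get("covariances", []):
            parts = [p.strip() for p in s.split("~~")]
            if len(parts) != 2 or not all(parts):
                raise ValidationError(f"cannot parse covariance spec {s!r}")
            covs.append((parts[0], parts[1]))
        return cls(list(spec["nodes"]), edges, covs)


@dataclass(frozen=True)
class IndependenceClaim:
    """x independent of y given ``conditioning``; ``y`` is the regression
    response (the topologically later variable)."""

    x: str
    y: str
    conditioning: tuple[str, ...]

    def __str__(self) -> str:
        cond = ", ".join(self.conditioning) if self.conditioning else "{}"
        return f"{self.x} _||_ {self.y} | {cond}"


@dataclass
class PSEMResult:
    """Fitted piecewise SEM: paths, fit statistics and pruning trail."""

    model: PathModel
    edges: pd.DataFrame  # columns: from, to, beta, se, p_value
    r2: dict[str, float]
    claims: list[IndependenceClaim]
    claim_pvalues: list[float]
    fisher_c: float
    df: int
    p_value: float
    aic: float
    n_params: int
    n: int
    removed_edges: list[tuple[str, str]] = field(default_factory=list)
    covariances: pd.DataFrame | None = None

    def coefficient(self, source: str, target: str) -> float:
        row = self.edges[(self.edges["from"] == source) & (self.edges["to"] == target)]
        if row.empty:
            raise KeyError(f"no fitted edge {source} -> {target}")
        return float(row["beta"].iloc[0])


def default_path_model() -> PathModel:
    """The shipped conceptual model: abiotic drivers feed the biotic
    descriptors, and both feed SES.MPD.

    Elevation, precipitation and stand age each point at richness and both
    CWM traits, the three biotic variables point at SES.MPD, and direct
    abiotic -> SES.MPD paths are retained so that mediation is a result,
    not an assumption.  The abiotic variables are exogenous and mutually
    correlated, expressed as free covariances.  This DAG is an informed
    reconstruction of a typical abiotic -> biotic -> phylogenetic-structure
    causal ordering, not a fitted object.
    """
    abiotic = ["elevation", "map", "stand_age"]
    biotic = ["richness", "cwm_sla", "cwm_mh"]
    edges = [(a, b) for a in abiotic for b in biotic]
    edges += [(b, "ses") for b in biotic]
    edges += [(a, "ses") for a in abiotic]
    covs = [("elevation", "map"), ("elevation", "stand_age"), ("map", "stand_age")]
    return PathModel(abiotic + biotic + ["ses"], edges, covs)


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """The d-separation basis set implied by the DAG's missing edges.

    One claim per non-adjacent node pair that carries no free covariance,
    conditioning on the union of the two nodes' parents.  The
    topologically later node is the regression response.
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    rank = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in model.directed_edges}
    free = {frozenset(c) for c in model.free_covariances}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            pair = frozenset((a, b))
            if pair in adjacent or pair in free:
                continue
            x, y = sorted((a, b), key=rank.get)
            cond = sorted((set(model.parents(x)) | set(model.parents(y))) - {x, y})
            claims.append(IndependenceClaim(x=x, y=y, conditioning=tuple(cond)))
    return claims


def dsep_pvalues(claims: list[IndependenceClaim], data: pd.DataFrame) -> list[float]:
    """Test each independence claim by regression.

    For the claim (x _||_ y | S) the p-value is that of x's coefficient in
    the OLS regression of y on {x} union S.
    """
    pvals = []
    for claim in claims:
        cols = [claim.x, *claim.conditioning]
        missing = [c for c in cols + [claim.y] if c not in data.columns]
        if missing:
            raise ValidationError(f"claim {claim}: missing columns {missing}")
        try:
            fit = ols_fit(data[claim.y].to_numpy(), data[cols])
        except NumericalError as exc:
            raise NumericalError(f"singular regression for claim {claim}") from exc
        pvals.append(fit.pvalues[claim.x])
    return pvals


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C = -2 * sum(ln p), chi-square with 2k df under the model.

    An empty claim list denotes a saturated model: (0, 0, 1).  A p-value of
    exactly zero is an error; callers floor p at ``P_FLOOR`` upstream.
    """
    pvalues = list(pvalues)
    if not pvalues:
        return 0.0, 0, 1.0
    arr = np.asarray(pvalues, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("Fisher's C needs p-values in (0, 1]")
    c = float(-2.0 * np.log(arr).sum())
    df = 2 * len(arr)
    return c, df, float(stats.chi2.sf(c, df))


def _fit_once(model: PathModel, data: pd.DataFrame, n: int):
    rows = []
    r2 = {}
    n_params = 0
    for node in model.endogenous():
        parents = model.parents(node)
        fit = ols_fit(data[node].to_numpy(), data[parents])
        r2[node] = fit.r2
        n_params += len(parents) + 2  # slopes + intercept + error variance
        for p in parents:
            rows.append(
                {
                    "from": p,
                    "to": node,
                    "beta": fit.beta[p],
                    "se": fit.se[p],
                    "p_value": fit.pvalues[p],
                }
            )
    edges = pd.DataFrame(rows, columns=["from", "to", "beta", "se", "p_value"])
    claims = basis_set(model)
    pvals = [max(p, P_FLOOR) for p in dsep_pvalues(claims, data)]
    c, df, p = fishers_c(pvals)
    aic = c + 2 * n_params
    return PSEMResult(
        model=model,
        edges=edges,
        r2=r2,
        claims=claims,
        claim_pvalues=pvals,
        fisher_c=c,
        df=df,
        p_value=p,
        aic=aic,
        n_params=n_params,
        n=n,
    )


def _covariance_report(model: PathModel, data: pd.DataFrame) -> pd.DataFrame:
    """Free covariances reported as Pearson correlations.

    For a node with parents, its residual (after regressing on parents)
    enters the correlation, mirroring the correlated-errors reading; an
    exogenous node enters as-is.
    """
    def residual(node: str) -> np.ndarray:
        parents = model.parents(node)
        v = data[node].to_numpy()
        if not parents:
            return v
        X = np.column_stack([np.ones(len(v))] + [data[p].to_numpy() for p in parents])
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ coef

    rows = []
    for a, b in model.free_covariances:
        ra, rb = residual(a), residual(b)
        r, p = stats.pearsonr(ra, rb)
        rows.append({"a": a, "b": b, "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["a", "b", "pearson_r", "p_value"])


def fit_psem(
    model: PathModel,
    data: AnalysisTable | pd.DataFrame,
    prune: bool = False,
    alpha_drop: float = 0.05,
) -> PSEMResult:
    """Fit a piecewise SEM on standardized data.

    With ``prune=True`` the least significant path with p above
    ``alpha_drop`` is removed, the model refit, and so on — stopping when
    every remaining path is significant or when removing a path raises the
    AIC (the removal is then reverted).  Removed edges are recorded in the
    result.
    """
    df = data.data if isinstance(data, AnalysisTable) else data
    missing = [n for n in model.nodes if n not in df.columns]
    if missing:
        raise ValidationError(f"data table lacks path-model nodes: {missing}")
    result = _fit_once(model, df, len(df))
    removed: list[tuple[str, str]] = []
    while prune and not result.edges.empty:
        worst = result.edges.loc[result.edges["p_value"].idxmax()]
        if worst["p_value"] <= alpha_drop:
            break
        pruned_model = PathModel(
            model.nodes,
            [e for e in model.directed_edges if e != (worst["from"], worst["to"])],
            model.free_covariances,
        )
        candidate = _fit_once(pruned_model, df, len(df))
        if candidate.aic > result.aic:
            break
        removed.append((worst["from"], worst["to"]))
        model = pruned_model
        result = candidate
    result.removed_edges = removed
    result.covariances = _covariance_report(model, df)
    return result


def indirect_paths(
    result: PSEMResult, source: str, target: str
) -> list[tuple[tuple[str, ...], float]]:
    """All mediated directed paths source -> ... -> target (length >= 2)
    with the product of standardized coefficients along each."""
    if source not in result.model.nodes or target not in result.model.nodes:
        raise ValidationError(f"unknown node in {source!r} -> {target!r}")
    g = nx.DiGraph()
    g.add_nodes_from(result.model.nodes)
    for _, row in result.edges.iterrows():
        g.add_edge(row["from"], row["to"], beta=row["beta"])
    out = []
    for path in nx.all_simple_paths(g, source, target):
        if len(path) < 3:
            continue  # direct edge, not a mediated path
        prod = 1.0
        for a, b in zip(path[:-1], path[1:]):
            prod *= g.edges[a, b]["beta"]
        out.append((tuple(path), prod))
    return out


def indirect_effects(result: PSEMResult, source: str, target: str) -> float:
    """Summed mediated effect: sum over all directed source -> target paths
    of length >= 2 of the product of path coefficients (0 if none)."""
    return float(sum(prod for _, prod in indirect_paths(result, source, target)))


def total_effect(result: PSEMResult, source: str, target: str) -> float:
    """Direct coefficient (0 if the edge is absent) plus indirect effect."""
    try:
        direct = result.coefficient(source, target)
    except KeyError:
        direct = 0.0
    return direct + indirect_effects(result, source, target)
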