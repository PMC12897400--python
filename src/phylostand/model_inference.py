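"""Multi-model inference for SES.MPD: transformation, screening, averaging.

Workflow (per stand-type scope):

1. assemble a plot-level table (abiotic covariates, richness, CWM traits,
   SES.MPD response),
2. transform each variable (log or square-root, pinned in an explicit
   default spec) and z-score it,
3. screen predictor pairs with |Pearson r| above a threshold (default
   0.65), dropping the lower-priority member (default priority keeps
   elevation and drops mean annual temperature),
4. confirm variance inflation factors are acceptable (< 3 expected),
5. fit every predictor subset by OLS, keep models with delta-AIC <= 2 of
   the best, and average standardized coefficients across that set with
   Akaike weights,
6. score each predictor's relative importance as the sum of its |beta|
   across the selected models, normalized so importances sum to one.

The importance score is deliberately the normalized-sum-of-|beta| flavour
(not the more common sum-of-Akaike-weights), because that is the score the
surrounding analysis reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .community import PlotCommunity, TraitTable, cwm, species_richness
from .errors import NumericalError, ValidationError
from .sesmpd import SESResult

__all__ = [
    "DEFAULT_TRANSFORMS",
    "DEFAULT_PRIORITY",
    "AnalysisTable",
    "FittedModel",
    "AveragedModel",
    "assemble_plot_table",
    "prepare_table",
    "collinearity_screen",
    "vif",
    "ols_fit",
    "multimodel_average",
]

#: variable -> transformation applied before z-scoring.  "As appropriate"
#: is pinned to an explicit, overridable choice: log for the right-skewed
#: positive variables (elevation offset by +1 so sea-level plots survive),
#: square root for the count-like richness, identity for temperature
#: (which may be negative) and for the already-dimensionless response.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "elevation": "log1p",
    "mat": "identity",
    "map": "log",
    "stand_age": "log",
    "richness": "sqrt",
    "cwm_sla": "log",
    "cwm_mh": "log",
    "ses": "identity",
}

#: collinearity drop order: earlier = kept in preference.  Temperature is
#: last so an elevation/temperature correlation drops temperature.
DEFAULT_PRIORITY: list[str] = [
    "elevation",
    "map",
    "stand_age",
    "richness",
    "cwm_sla",
    "cwm_mh",
    "mat",
]

_TRANSFORM_FUNCS = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
    "sqrt": np.sqrt,
}


@dataclass
class AnalysisTable:
    """Plot-level variables in raw, transformed and standardized form."""

    raw: pd.DataFrame
    transformed: pd.DataFrame
    data: pd.DataFrame  # z-scored
    response: str
    predictors: list[str]
    n_excluded: int = 0  # plots dropped for undefined SES

    def matrix(self, columns) -> np.ndarray:
        return self.data[list(columns)].to_numpy()


@dataclass
class FittedModel:
    """One OLS fit on standardized data."""

    predictors: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    aic: float
    r2: float
    n: int


@dataclass
class AveragedModel:
    """Model-averaged coefficients and normalized relative importance."""

    predictors: list[str]
    beta_avg: dict[str, float]
    beta_sd: dict[str, float]  # across-model SD of beta over the selected set
    beta_se: dict[str, float]  # unconditional model-averaged standard error
    pvalues: dict[str, float]
    importance: dict[str, float]
    n_models: int
    delta: float
    r2_best: float
    models: list[FittedModel] = field(repr=False, default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": p,
                "beta_avg": self.beta_avg[p],
                "beta_sd": self.beta_sd[p],
                "beta_se": self.beta_se[p],
                "p_value": self.pvalues[p],
                "importance": self.importance[p],
                "n_models": self.n_models,
                "r2_best": self.r2_best,
            }
            for p in self.predictors
        ]
        return pd.DataFrame(rows)


def assemble_plot_table(
    plots: list[PlotCommunity],
    traits: TraitTable,
    ses_results: list[SESResult],
) -> tuple[pd.DataFrame, int]:
    """Join covariates, richness, CWM traits and SES into one raw table.

    Plots whose SES is undefined (richness < 2 or degenerate null) are
    excluded; the count of exclusions is returned alongside the table.
    """
    ses_by_plot = {r.plot_id: r for r in ses_results}
    rows = []
    n_excluded = 0
    for p in plots:
        r = ses_by_plot.get(p.plot_id)
        if r is None or not np.isfinite(r.ses):
            n_excluded += 1
            continue
        rows.append(
            {
                "plot_id": p.plot_id,
                "elevation": p.elevation,
                "mat": p.mat,
                "map": p.map_mm,
                "stand_age": p.stand_age,
                "richness": species_richness(p),
                "cwm_sla": cwm(p, traits, "sla"),
                "cwm_mh": cwm(p, traits, "mh"),
                "ses": r.ses,
            }
        )
    return pd.DataFrame(rows), n_excluded


def prepare_table(
    raw: pd.DataFrame,
    transform_spec: dict[str, str] | None = None,
    response: str = "ses",
) -> AnalysisTable:
    """Transform and z-score a raw plot table.

    ``transform_spec`` maps variable name to one of ``identity``, ``log``,
    ``log1p``, ``sqrt``; unlisted variables default to identity.  Every
    column must be finite after transformation and must have positive
    variance (a zero-variance column cannot be standardized and is a hard
    error naming the column).
    """
    spec = dict(DEFAULT_TRANSFORMS)
    if transform_spec:
        spec.update(transform_spec)
    cols = [c for c in raw.columns if c != "plot_id"]
    if response not in cols:
        raise ValidationError(f"response column {response!r} missing from table")
    transformed = pd.DataFrame(index=raw.index)
    data = pd.DataFrame(index=raw.index)
    for c in cols:
        fname = spec.get(c, "identity")
        if fname not in _TRANSFORM_FUNCS:
            raise ValidationError(f"unknown transformation {fname!r} for {c!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            t = _TRANSFORM_FUNCS[fname](raw[c].to_numpy(dtype=float))
        if not np.all(np.isfinite(t)):
            raise ValidationError(
                f"column {c!r} not finite after {fname} transformation"
            )
        sd = t.std(ddof=1)
        if not sd > 0:
            raise ValidationError(f"zero-variance column after transformation: {c!r}")
        transformed[c] = t
        data[c] = (t - t.mean()) / sd
    predictors = [c for c in cols if c != response]
    return AnalysisTable(
        raw=raw,
        transformed=transformed,
        data=data,
        response=response,
        predictors=predictors,
    )


def collinearity_screen(
    table: AnalysisTable,
    r_threshold: float = 0.65,
    priority: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one member of every strongly correlated predictor pair.

    Returns the retained predictors (in priority order) and every flagged
    pair with its correlation.  Within a flagged pair, the member that
    comes later in the priority list is dropped; iteration continues until
    no retained pair exceeds the threshold.
    """
    prio = list(priority) if priority is not None else list(DEFAULT_PRIORITY)
    for p in table.predictors:
        if p not in prio:
            prio.append(p)
    retained = sorted(table.predictors, key=prio.index)
    if len(retained) < 2:
        raise ValidationError("collinearity screen needs >= 2 predictors")
    corr = table.data[retained].corr()
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for a, b in combinations(retained, 2)
        if abs(corr.loc[a, b]) > r_threshold
    ]
    # pairwise correlations do not change as members are dropped, so one
    # pass over the flagged pairs suffices: repeatedly drop the
    # lowest-priority member of any still-live pair
    while True:
        live = [(a, b) for a, b, _ in flagged if a in retained and b in retained]
        if not live:
            return retained, flagged
        drop = max((m for pair in live for m in pair), key=prio.index)
        retained = [p for p in retained if p != drop]


def vif(table: AnalysisTable, predictors: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    ``R^2_j`` comes from regressing predictor j on the remaining
    predictors (with intercept).  Perfect collinearity reports ``inf``.
    """
    preds = list(predictors) if predictors is not None else list(table.predictors)
    n = len(table.data)
    if n <= len(preds) + 1:
        raise ValidationError("vif needs n > p + 1")
    out: dict[str, float] = {}
    for j, p in enumerate(preds):
        others = [q for q in preds if q != p]
        if not others:
            out[p] = 1.0
            continue
        y = table.data[p].to_numpy()
        X = np.column_stack([np.ones(n)] + [table.data[q].to_numpy() for q in others])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss
        out[p] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def ols_fit(y: np.ndarray, X: pd.DataFrame | None, n_obs: int | None = None) -> FittedModel:
    """Ordinary least squares with intercept on standardized columns.

    ``X`` may be ``None`` or empty for the intercept-only model.  The
    information criterion is the Gaussian profile form

        AIC = n * ln(RSS / n) + 2 * (p + 2)

    counting the p slopes, the intercept and the error variance as
    estimated parameters.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        names: tuple[str, ...] = ()
        M = np.ones((n, 1))
    else:
        names = tuple(X.columns)
        M = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p = len(names)
    if n <= p + 1:
        raise ValidationError(f"ols_fit needs n > p + 1 (n={n}, p={p})")
    coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        raise NumericalError(f"singular design for predictors {names}")
    resid = y - M @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - p - 1
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    tvals = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    aic = n * np.log(rss / n) + 2 * (p + 2)
    return FittedModel(
        predictors=names,
        beta={nm: float(coef[i + 1]) for i, nm in enumerate(names)},
        se={nm: float(se[i + 1]) for i, nm in enumerate(names)},
        pvalues={nm: float(pvals[i + 1]) for i, nm in enumerate(names)},
        aic=float(aic),
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        n=n,
    )


def multimodel_average(
    table: AnalysisTable,
    predictors: list[str] | None = None,
    delta: float = 2.0,
    averaging: str = "full",
) -> AveragedModel:
    """Fit all predictor subsets, keep the delta-AIC set, average and score.

    ``averaging='full'`` (default) substitutes beta = 0 whenever a selected
    model omits a predictor, matching common zero-method model-averaged
    reporting; ``'conditional'`` averages only over models containing the
    predictor.  Relative importance is always

        importance_j = sum_selected |beta_j| / sum_k sum_selected |beta_k|

    so importances are non-negative and sum to one.
    """
    preds = list(predictors) if predictors is not None else list(table.predictors)
    if not preds:
        raise ValidationError("multimodel_average needs >= 1 predictor")
    if averaging not in ("full", "conditional"):
        raise ValidationError(f"unknown averaging flavour {averaging!r}")
    y = table.data[table.response].to_numpy()
    fits: list[FittedModel] = []
    for r in range(len(preds) + 1):
        for subset in combinations(preds, r):
            X = table.data[list(subset)] if subset else None
            fits.append(ols_fit(y, X))
    aics = np.array([f.aic for f in fits])
    best = aics.min()
    selected = [f for f, a in zip(fits, aics) if a - best <= delta]
    d = np.array([f.aic - best for f in selected])
    w = np.exp(-0.5 * d)
    w = w / w.sum()  # Akaike weights renormalized over the selected set

    beta_avg, beta_sd, beta_se, pvalues, importance = {}, {}, {}, {}, {}
    abs_sums = {}
    for p in preds:
        betas = np.array([f.beta.get(p, 0.0) for f in selected])
        ses = np.array([f.se.get(p, 0.0) for f in selected])
        contains = np.array([p in f.beta for f in selected])
        if averaging == "conditional" and contains.any():
            wc = w[contains] / w[contains].sum()
            bavg = float(wc @ betas[contains])
            se_u = float(
                np.sqrt(wc @ (ses[contains] ** 2 + (betas[contains] - bavg) ** 2))
            )
        else:
            bavg = float(w @ betas)
            se_u = float(np.sqrt(w @ (ses**2 + (betas - bavg) ** 2)))
        beta_avg[p] = bavg
        beta_sd[p] = float(betas.std(ddof=1)) if len(betas) > 1 else 0.0
        beta_se[p] = se_u
        z = bavg / se_u if se_u > 0 else 0.0
        pvalues[p] = float(2 * stats.norm.sf(abs(z)))
        abs_sums[p] = float(np.abs(betas).sum())
    denom = sum(abs_sums.values())
    if denom > 0:
        importance = {p: abs_sums[p] / denom for p in preds}
    else:
        warnings.warn(
            "all selected models are intercept-only; importance is uninformative",
            stacklevel=2,
        )
        importance = {p: 1.0 / len(preds) for p in preds}

    best_fit = min(fits, key=lambda f: f.aic)
    return AveragedModel(
        predictors=preds,
        beta_avg=beta_avg,
        beta_sd=beta_sd,
        beta_se=beta_se,
        pvalues=pvalues,
        importance=importance,
        n_models=len(selected),
        delta=delta,
        r2_best=best_fit.r2,
        models=selected,
    )
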