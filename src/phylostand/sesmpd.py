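"""SES.MPD: observed mean pairwise distance against a tip-shuffle null.

For each plot we compute the observed mean pairwise patristic distance
(MPD) among the species present, then a null distribution obtained by
randomly permuting species labels across the tips of the phylogeny while
keeping the plot-by-species incidence matrix fixed ("taxa-labels" null).
The standardized effect size is

    SES.MPD = (MPD_obs - mean(MPD_null)) / sd(MPD_null)

Negative values indicate that co-occurring species are more closely
related than expected under the null (phylogenetic clustering), positive
values that they are less related (overdispersion).  Plots are classified
with the two-tailed 5% convention: SES <= -1.96 clustered, SES >= +1.96
overdispersed, otherwise random; the thresholds are inclusive, and exact
boundary hits are logged because the convention is not universal.

The null pool is the full species set of the supplied community matrix —
run the function separately per stand type to standardize each stand type
against its own pool.

Reproducibility: each plot draws its shuffles from a private random
substream keyed by (global seed, plot id), so per-plot results do not
change when other plots are added to or removed from the matrix.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import PlotCommunity
from .errors import PhylostandError, ValidationError
from .phylo import PatristicDistanceMatrix, Phylogeny, patristic_distances

__all__ = [
    "CommunityMatrix",
    "SESResult",
    "UndefinedMPD",
    "mpd_observed",
    "shuffle_tip_labels",
    "null_mpd_samples",
    "ses_mpd",
    "classify_ses",
    "ses_results_frame",
    "summarize_ses",
    "CLUSTER_THRESHOLD",
]

log = logging.getLogger(__name__)

#: two-tailed 5% normal quantile used to call clustering/overdispersion
CLUSTER_THRESHOLD = 1.96


class UndefinedMPD(PhylostandError):
    """MPD is undefined: fewer than two species present."""


@dataclass
class CommunityMatrix:
    """Binary plot x species incidence for one species pool."""

    plots: list[str]
    species: list[str]
    presence: np.ndarray  # bool, shape (n_plots, n_species)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.plots), len(self.species)):
            raise ValidationError("presence shape does not match plots x species")
        if len(set(self.plots)) != len(self.plots):
            raise ValidationError("duplicate plot ids in community matrix")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species in community matrix")
        if self.presence.shape[0] and not self.presence.any(axis=1).all():
            empty = [p for p, row in zip(self.plots, self.presence) if not row.any()]
            raise ValidationError(f"plots with no species present: {empty[:5]}")
        if self.presence.shape[0] and not self.presence.any(axis=0).all():
            unused = [
                s for s, col in zip(self.species, self.presence.T) if not col.any()
            ]
            raise ValidationError(f"species occurring in no plot: {unused[:5]}")

    @classmethod
    def from_plots(cls, plots: list[PlotCommunity]) -> "CommunityMatrix":
        """Build incidence over the union of species observed in ``plots``."""
        species = sorted({sp for p in plots for sp in p.species})
        index = {sp: j for j, sp in enumerate(species)}
        presence = np.zeros((len(plots), len(species)), dtype=bool)
        for i, p in enumerate(plots):
            for sp in p.species:
                presence[i, index[sp]] = True
        return cls([p.plot_id for p in plots], species, presence)


@dataclass
class SESResult:
    """Per-plot SES.MPD summary."""

    plot_id: str
    richness: int
    mpd_obs: float  # NaN when undefined
    null_mean: float
    null_sd: float
    ses: float
    n_rand: int
    category: str  # clustered | random | overdispersed | undefined


def mpd_observed(present_species, dist: PatristicDistanceMatrix) -> float:
    """Mean patristic distance over all unordered pairs of present species.

    Presence-based and unweighted: every species pair counts once,
    regardless of abundance.  Raises :class:`UndefinedMPD` for fewer than
    two species.
    """
    species = sorted(set(present_species))
    missing = [s for s in species if s not in dist.index]
    if missing:
        raise ValidationError(f"species not in distance matrix: {missing}")
    k = len(species)
    if k < 2:
        raise UndefinedMPD(f"MPD undefined for {k} species")
    idx = np.array([dist.index[s] for s in species])
    sub = dist.d[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def shuffle_tip_labels(
    dist: PatristicDistanceMatrix, rng: np.random.Generator
) -> PatristicDistanceMatrix:
    """Permute species labels across tips, leaving the distances untouched.

    The returned matrix has the same numeric entries with the label list
    permuted uniformly at random, which is exactly what shuffling labels
    across the tips of the tree does to the induced distance matrix.  The
    multiset of off-diagonal distances is conserved by construction.
    """
    perm = rng.permutation(len(dist.labels))
    return PatristicDistanceMatrix([dist.labels[i] for i in perm], dist.d)


def _plot_rng(seed: int, plot_id: str) -> np.random.Generator:
    # stable per-plot substream: keyed by plot id, not position, so results
    # do not move when other plots are added or removed
    return np.random.default_rng([seed, zlib.crc32(plot_id.encode("utf-8"))])


def null_mpd_samples(
    d: np.ndarray, member_idx: np.ndarray, n_rand: int, rng: np.random.Generator
) -> np.ndarray:
    """Null MPD values for one plot under ``n_rand`` label shuffles.

    ``member_idx`` are the pool indices of the species present in the plot.
    Each shuffle relabels the pool with a uniform permutation; the plot's
    incidence is untouched, so its k members map to the images of the
    permutation — computed vectorized for all shuffles at once.
    """
    n = d.shape[0]
    k = len(member_idx)
    # n_rand independent uniform permutations of the pool (rows)
    perms = np.argsort(rng.random((n_rand, n)), axis=1)
    images = perms[:, member_idx]  # (n_rand, k)
    sub = d[images[:, :, None], images[:, None, :]]  # (n_rand, k, k)
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


def classify_ses(ses: float) -> str:
    """Dispersion category from SES.MPD (inclusive +/-1.96 thresholds)."""
    if not np.isfinite(ses):
        return "undefined"
    if abs(ses) == CLUSTER_THRESHOLD:
        log.info("SES.MPD exactly at the %.2f boundary", CLUSTER_THRESHOLD)
    if ses <= -CLUSTER_THRESHOLD:
        return "clustered"
    if ses >= CLUSTER_THRESHOLD:
        return "overdispersed"
    return "random"


def ses_mpd(
    cm: CommunityMatrix,
    tree: Phylogeny | PatristicDistanceMatrix,
    n_rand: int = 1000,
    seed: int = 0,
) -> list[SESResult]:
    """SES.MPD for every plot of a community matrix under the tip-shuffle null.

    Parameters
    ----------
    cm
        Incidence matrix whose species list defines the null pool.
    tree
        Phylogeny (or a precomputed patristic distance matrix) covering at
        least the pool species.
    n_rand
        Number of label shuffles per plot (default 1000).
    seed
        Global seed; each plot uses a substream keyed by (seed, plot id).

    Plots with richness < 2 are reported with category ``undefined`` rather
    than silently dropped; a degenerate null (sd = 0, e.g. a plot holding
    the entire pool) likewise yields an undefined SES.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    dist = tree if isinstance(tree, PatristicDistanceMatrix) else patristic_distances(tree)
    missing = [s for s in cm.species if s not in dist.index]
    if missing:
        raise ValidationError(f"species absent from phylogeny: {missing}")
    # restrict to the pool: the null shuffles labels within this pool only
    pool = dist.submatrix(cm.species)
    d = pool.d

    results: list[SESResult] = []
    for i, plot_id in enumerate(cm.plots):
        member_idx = np.flatnonzero(cm.presence[i])
        k = len(member_idx)
        if k < 2:
            results.append(
                SESResult(plot_id, k, np.nan, np.nan, np.nan, np.nan, n_rand, "undefined")
            )
            continue
        sub = d[np.ix_(member_idx, member_idx)]
        mpd_obs = float(sub.sum() / (k * (k - 1)))
        rng = _plot_rng(seed, plot_id)
        null = null_mpd_samples(d, member_idx, n_rand, rng)
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=1)) if n_rand > 1 else 0.0
        if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
            null_sd = 0.0  # degenerate null up to summation round-off
        if null_sd > 0:
            ses = (mpd_obs - null_mean) / null_sd
            category = classify_ses(ses)
        else:
            ses = np.nan
            category = "undefined"
        results.append(
            SESResult(plot_id, k, mpd_obs, null_mean, null_sd, ses, n_rand, category)
        )
    return results


def ses_results_frame(results: list[SESResult]) -> pd.DataFrame:
    """Tabulate SES results (one row per plot)."""
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in results],
            "richness": [r.richness for r in results],
            "mpd_obs": [r.mpd_obs for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "ses_mpd": [r.ses for r in results],
            "n_rand": [r.n_rand for r in results],
            "category": [r.category for r in results],
        }
    )


def summarize_ses(results: list[SESResult]) -> dict:
    """Mean +/- SD of SES.MPD and category proportions over defined plots."""
    ses = np.array([r.ses for r in results if np.isfinite(r.ses)])
    n_def = len(ses)
    counts = {c: 0 for c in ("clustered", "random", "overdispersed", "undefined")}
    for r in results:
        counts[r.category] += 1
    out = {
        "n_plots": len(results),
        "n_defined": n_def,
        "ses_mean": float(ses.mean()) if n_def else np.nan,
        "ses_sd": float(ses.std(ddof=1)) if n_def > 1 else np.nan,
    }
    for c, n in counts.items():
        out[f"prop_{c}"] = n / len(results) if results else np.nan
    return out
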