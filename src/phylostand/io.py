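"""Readers and writers for the pipeline's plain-text interchange formats.

Formats (all UTF-8, header row mandatory, decimal point):

* plot tree list CSV — columns ``plot_id, species, dbh_cm[, height_m]``
* covariate CSV — columns ``plot_id, elevation_m, mat_c, map_mm, stand_age_yr``
* trait CSV — columns ``species, sla_mm2_mg, mh_m, is_conifer`` (0/1)

Output tables are written as TSV with a fixed float format so that runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import math

import pandas as pd

from .community import PlotCommunity, TraitTable, TreeRecord
from .errors import ValidationError

__all__ = [
    "read_tree_list",
    "read_covariates",
    "read_traits",
    "load_plots",
    "write_tsv",
]

FLOAT_FORMAT = "%.6g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns: {', '.join(missing)}")


def read_tree_list(path) -> pd.DataFrame:
    """Read a plot tree-list CSV into a tidy stems DataFrame."""
    df = pd.read_csv(path, dtype={"plot_id": str, "species": str})
    _require_columns(df, ["plot_id", "species", "dbh_cm"], path)
    if df["dbh_cm"].isna().any() or (df["dbh_cm"] <= 0).any():
        bad = df.loc[df["dbh_cm"].isna() | (df["dbh_cm"] <= 0)].index[0]
        raise ValidationError(f"{path}: non-positive or missing dbh_cm at row {bad}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str})
    _require_columns(
        df, ["plot_id", "elevation_m", "mat_c", "map_mm", "stand_age_yr"], path
    )
    if df["plot_id"].duplicated().any():
        dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate plot_id {dup!r}")
    return df


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, dtype={"species": str})
    _require_columns(df, ["species", "sla_mm2_mg", "mh_m", "is_conifer"], path)
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].iloc[0]
        raise ValidationError(f"{path}: duplicate species {dup!r}")
    sla, mh, flags = {}, {}, {}
    for row in df.itertuples(index=False):
        sla[row.species] = None if _isna(row.sla_mm2_mg) else float(row.sla_mm2_mg)
        mh[row.species] = None if _isna(row.mh_m) else float(row.mh_m)
        flags[row.species] = bool(int(row.is_conifer))
    return TraitTable(sla=sla, mh=mh, is_conifer=flags)


def _isna(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return x is None


def load_plots(tree_list_path, covariates_path) -> list[PlotCommunity]:
    """Join a tree-list CSV with a covariate CSV into PlotCommunity objects.

    Plots present in one file but not the other are a hard error: a plot
    without covariates cannot enter the regressions, and covariates without
    stems indicate an upstream join bug.
    """
    stems = read_tree_list(tree_list_path)
    cov = read_covariates(covariates_path).set_index("plot_id")
    stem_ids = set(stems["plot_id"])
    cov_ids = set(cov.index)
    if stem_ids != cov_ids:
        only_stems = sorted(stem_ids - cov_ids)[:5]
        only_cov = sorted(cov_ids - stem_ids)[:5]
        raise ValidationError(
            "tree list and covariates disagree on plots "
            f"(stems-only: {only_stems}, covariates-only: {only_cov})"
        )
    has_height = "height_m" in stems.columns
    plots = []
    for pid, grp in stems.groupby("plot_id", sort=True):
        trees = [
            TreeRecord(
                species=r.species,
                dbh=float(r.dbh_cm),
                height=(
                    float(r.height_m)
                    if has_height and not _isna(r.height_m)
                    else None
                ),
            )
            for r in grp.itertuples(index=False)
        ]
        c = cov.loc[pid]
        plots.append(
            PlotCommunity(
                plot_id=str(pid),
                trees=trees,
                elevation=float(c["elevation_m"]),
                mat=float(c["mat_c"]),
                map_mm=float(c["map_mm"]),
                stand_age=float(c["stand_age_yr"]),
            )
        )
    return plots


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a deterministic float format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
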