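"""End-to-end orchestration: classify stands, SES.MPD, inference, pSEM.

:func:`run_all` mirrors a full study: plots are classified into
broadleaved / conifer / mixed stand types, and every analysis is run per
scope — the total plot set plus each stand type — against that scope's
own species pool and pruned phylogeny.  Each scope directory receives

* ``variables.tsv`` — per-variable summaries of the raw plot table,
* ``ses_mpd.tsv`` and ``ses_summary.tsv`` — per-plot SES.MPD and the
  mean +/- SD with dispersion-category proportions,
* ``multimodel.tsv`` — model-averaged coefficients and importances,
* ``vif.tsv`` / ``screen.tsv`` — collinearity diagnostics,
* ``psem_edges.tsv``, ``psem_fit.json``, ``indirect_effects.tsv`` — the
  piecewise SEM outputs.

A ``manifest.json`` (input hashes, seed, parameters, package version, per
scope plot and pool counts) makes every number reproducible from the
recorded inputs alone; nothing time- or host-dependent is written, so
repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import classify_stand
from .errors import ValidationError
from .io import load_plots, read_traits, write_tsv
from .model_inference import (
    assemble_plot_table,
    collinearity_screen,
    multimodel_average,
    prepare_table,
    vif,
)
from .phylo import read_newick
from .psem import (
    PathModel,
    default_path_model,
    fit_psem,
    indirect_effects,
    total_effect,
)
from .sesmpd import CommunityMatrix, ses_mpd, ses_results_frame, summarize_ses

__all__ = ["RunConfig", "run_all"]

SCOPES = ("total", "broadleaved", "conifer", "mixed")


@dataclass
class RunConfig:
    """Inputs and knobs for one full pipeline run."""

    tree_list: Path
    covariates: Path
    traits: Path
    phylogeny: Path
    out_dir: Path
    scope: str = "all"  # one scope name or "all"
    n_rand: int = 1000
    seed: int = 0
    delta_aic: float = 2.0
    r_threshold: float = 0.65
    averaging: str = "full"
    transform_spec: dict[str, str] = field(default_factory=dict)
    path_model: PathModel | None = None
    prune: bool = False

    def validate(self) -> None:
        for name in ("tree_list", "covariates", "traits", "phylogeny"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"input file for {name} not found: {p}")
        if self.scope != "all" and self.scope not in SCOPES:
            raise ValidationError(f"scope must be 'all' or one of {SCOPES}")
        if self.n_rand < 1:
            raise ValidationError("n_rand must be >= 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _variable_summary(raw: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for c in raw.columns:
        if c == "plot_id":
            continue
        v = raw[c].to_numpy(dtype=float)
        rows.append(
            {
                "variable": c,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "min": float(np.min(v)),
                "median": float(np.median(v)),
                "max": float(np.max(v)),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis per scope; returns the manifest dict.

    Scopes with no plots produce an ``empty_scope.json`` note and no
    tables; scopes with too few plots for regression (n <= p + 2) still
    get SES output plus a note explaining what was skipped.
    """
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    plots = load_plots(config.tree_list, config.covariates)
    traits = read_traits(config.traits)
    tree = read_newick(config.phylogeny)
    stand_type = {p.plot_id: classify_stand(p, traits) for p in plots}
    counts = {s: 0 for s in SCOPES[1:]}
    for t in stand_type.values():
        counts[t] += 1

    scopes = list(SCOPES) if config.scope == "all" else [config.scope]
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "n_rand": config.n_rand,
        "delta_aic": config.delta_aic,
        "r_threshold": config.r_threshold,
        "averaging": config.averaging,
        "prune": config.prune,
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("tree_list", "covariates", "traits", "phylogeny")
        },
        "n_plots": len(plots),
        "stand_type_counts": counts,
        "scopes": {},
    }

    model = config.path_model if config.path_model is not None else default_path_model()

    for scope in scopes:
        scope_dir = out_root / scope
        scope_dir.mkdir(parents=True, exist_ok=True)
        scope_plots = (
            plots if scope == "total" else [p for p in plots if stand_type[p.plot_id] == scope]
        )
        scope_info: dict = {"n_plots": len(scope_plots)}
        manifest["scopes"][scope] = scope_info
        if not scope_plots:
            (scope_dir / "empty_scope.json").write_text(
                json.dumps({"scope": scope, "n_plots": 0, "note": "no plots in scope"})
                + "\n"
            )
            continue

        cm = CommunityMatrix.from_plots(scope_plots)
        scope_info["pool_size"] = len(cm.species)
        if len(cm.species) < 2:
            (scope_dir / "empty_scope.json").write_text(
                json.dumps(
                    {
                        "scope": scope,
                        "n_plots": len(scope_plots),
                        "note": "species pool below 2; SES undefined",
                    }
                )
                + "\n"
            )
            continue
        # each scope is standardized against its own pool and pruned tree
        scope_tree = tree.pruned_to(cm.species)
        ses_results = ses_mpd(cm, scope_tree, n_rand=config.n_rand, seed=config.seed)
        write_tsv(
            ses_results_frame(ses_results).assign(stand_type=scope),
            scope_dir / "ses_mpd.tsv",
        )
        summary = summarize_ses(ses_results)
        write_tsv(pd.DataFrame([{"stand_type": scope, **summary}]), scope_dir / "ses_summary.tsv")
        scope_info["ses_mean"] = summary["ses_mean"]

        raw, n_excluded = assemble_plot_table(scope_plots, traits, ses_results)
        scope_info["n_excluded_undefined_ses"] = n_excluded
        write_tsv(_variable_summary(raw), scope_dir / "variables.tsv")

        n_preds = len([c for c in raw.columns if c not in ("plot_id", "ses")])
        if len(raw) <= n_preds + 2:
            (scope_dir / "skipped.json").write_text(
                json.dumps(
                    {
                        "scope": scope,
                        "note": "too few plots with defined SES for regression",
                        "n_usable": len(raw),
                    }
                )
                + "\n"
            )
            continue

        try:
            table = prepare_table(raw, config.transform_spec or None)
        except ValidationError as exc:
            (scope_dir / "skipped.json").write_text(
                json.dumps({"scope": scope, "note": str(exc)}) + "\n"
            )
            continue
        retained, flagged = collinearity_screen(table, config.r_threshold)
        write_tsv(
            pd.DataFrame(flagged, columns=["a", "b", "pearson_r"]),
            scope_dir / "screen.tsv",
        )
        vifs = vif(table, retained)
        write_tsv(
            pd.DataFrame(
                [{"predictor": p, "vif": v, "below_3": bool(v < 3)} for p, v in vifs.items()]
            ),
            scope_dir / "vif.tsv",
        )
        avg = multimodel_average(
            table, retained, delta=config.delta_aic, averaging=config.averaging
        )
        write_tsv(avg.frame(), scope_dir / "multimodel.tsv")
        scope_info["mmi_n_models"] = avg.n_models
        scope_info["r2_best"] = avg.r2_best

        psem_nodes = [n for n in model.nodes if n in table.data.columns]
        if set(psem_nodes) != set(model.nodes):
            (scope_dir / "skipped.json").write_text(
                json.dumps(
                    {"scope": scope, "note": "path model nodes missing from table"}
                )
                + "\n"
            )
            continue
        result = fit_psem(model, table, prune=config.prune)
        write_tsv(result.edges, scope_dir / "psem_edges.tsv")
        fit_payload = {
            "fisher_c": result.fisher_c,
            "df": result.df,
            "p_value": result.p_value,
            "aic": result.aic,
            "n_params": result.n_params,
            "n": result.n,
            "r2": result.r2,
            "removed_edges": [list(e) for e in result.removed_edges],
            "claims": [str(c) for c in result.claims],
            "claim_pvalues": result.claim_pvalues,
        }
        (scope_dir / "psem_fit.json").write_text(
            json.dumps(fit_payload, indent=2, sort_keys=True) + "\n"
        )
        if result.covariances is not None and not result.covariances.empty:
            write_tsv(result.covariances, scope_dir / "psem_covariances.tsv")
        ind_rows = []
        for src in model.nodes:
            for tgt in model.nodes:
                if src == tgt:
                    continue
                ind = indirect_effects(result, src, tgt)
                if ind != 0.0:
                    ind_rows.append(
                        {
                            "source": src,
                            "target": tgt,
                            "indirect": ind,
                            "total": total_effect(result, src, tgt),
                        }
                    )
        write_tsv(
            pd.DataFrame(ind_rows, columns=["source", "target", "indirect", "total"]),
            scope_dir / "indirect_effects.tsv",
        )
        scope_info["fisher_c"] = result.fisher_c
        scope_info["psem_p"] = result.p_value

    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
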