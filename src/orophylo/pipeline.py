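"""End-to-end pipeline: tree assembly -> metrics -> ages -> tests -> models."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .ages import mdt_table, pairwise_group_tests
from .config import PipelineConfig
from .metrics import ses_metrics
from .spatial import build_design, fit_glm, fit_sem_ml, knn_weights, morans_i
from .trees import bind_species_midpoint, bladj_smooth, graft_missing_genus, \
    prune_to_pool, species_ages

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages, writing CSVs plus metadata sidecars.

    Returns the output directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = oio.config_hash(config.to_dict())

    def meta(stage: str, **extra) -> dict:
        return {"config_hash": chash, "seed": config.seed, "stage": stage, **extra}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    state: dict = {}

    def build_tree():
        tree = oio.read_newick(config.tree)
        if config.sister_map:
            for missing, sister in oio.read_sister_map(config.sister_map).items():
                tree = graft_missing_genus(tree, missing, sister,
                                           f"{missing}_sp")
        if config.checklist:
            tree = bind_species_midpoint(tree, oio.read_checklist(config.checklist))
        if config.age_constraints:
            tree = bladj_smooth(tree, oio.read_age_constraints(config.age_constraints))
        matrix = oio.read_matrix(config.matrix, config.matrix_orientation)
        tree = prune_to_pool(tree, set(matrix.columns), drop_unknown=False)
        oio.write_newick(tree, outdir / "tree_pruned.nwk")
        state["tree"], state["matrix"] = tree, matrix

    def metrics():
        table = ses_metrics(
            state["tree"], state["matrix"], engine=config.ses_engine,
            n_rand=config.n_rand, seed=config.substream("ses"),
            pd_include_root=config.pd_include_root,
        )
        state["metrics"] = table
        oio.write_with_sidecar(
            table, outdir / "flora_metrics.csv",
            meta("metrics", engine=config.ses_engine, n_rand=config.n_rand,
                 ses_seed=config.substream("ses")),
        )

    def ages():
        age_map = species_ages(state["tree"])
        matrix = state["matrix"]
        ages_by_site = {
            site: np.array([age_map[s] for s in matrix.columns[row.astype(bool)]])
            for site, row in zip(matrix.index, matrix.to_numpy())
        }
        table = mdt_table(ages_by_site)
        state["metrics"] = state["metrics"].join(table)
        oio.write_with_sidecar(table, outdir / "flora_mdt.csv", meta("ages"))

    def tests():
        predictors = oio.read_predictors(config.predictors)
        merged = state["metrics"].join(predictors["landform"])
        frames = []
        for col in state["metrics"].columns:
            sub = merged[[col, "landform"]].dropna()
            try:
                tab = pairwise_group_tests(sub[col], sub["landform"])
            except ValueError as exc:
                logger.warning("skipping group tests for %s: %s", col, exc)
                continue
            tab.insert(0, "metric", col)
            frames.append(tab)
        table = pd.concat(frames, ignore_index=True)
        oio.write_with_sidecar(table, outdir / "landform_tests.csv",
                               meta("tests"), index_label="row")

    def fit():
        predictors = oio.read_predictors(config.predictors)
        merged = state["metrics"].join(predictors, how="inner")
        merged["log_SR"] = np.log(merged["SR"].astype(float))
        numeric = [c for c in predictors.columns
                   if pd.api.types.is_numeric_dtype(predictors[c])
                   and c not in ("lon", "lat")]
        categorical = [c for c in ("landform", "tectonic")
                       if c in predictors.columns]
        full_terms = categorical + numeric + [
            i for i in config.interactions
            if i.split(":", 1)[1] in numeric and i.split(":", 1)[0] in categorical]
        coords = predictors.loc[merged.index, ["lon", "lat"]] \
            if {"lon", "lat"}.issubset(predictors.columns) else None
        weights = knn_weights(coords, k=config.knn_k) if coords is not None else None
        summaries, coef_rows, resid = [], [], {}
        for response in config.responses:
            if response not in merged.columns:
                logger.warning("response %s unavailable; skipped", response)
                continue
            sub = merged.dropna(subset=[response])
            if len(sub) < len(merged):
                logger.warning("response %s: dropping %d sites with undefined "
                               "values", response, len(merged) - len(sub))
            y = sub[response]
            for label, terms in (("landform", ["landform"]),
                                 ("full", full_terms)):
                glm = fit_glm(y, sub, terms, config.reference_levels)
                row = {"response": response, "model": label, "kind": "GLM",
                       "aic": glm.aic,
                       "deviance_explained": glm.deviance_explained}
                if weights is not None and len(sub) == weights.n:
                    mi = morans_i(glm.residuals, weights)
                    row["residual_moran_I"] = mi.I
                    row["residual_moran_p"] = mi.p
                    design, _ = build_design(sub, terms, config.reference_levels)
                    sem = fit_sem_ml(y.to_numpy(),
                                     design.drop(columns="Intercept").to_numpy(),
                                     weights)
                    summaries.append({
                        "response": response, "model": label, "kind": "SEM",
                        "aic": sem.aic, "lambda": sem.lam,
                        "deviance_explained": sem.pseudo_r2,
                        "residual_moran_I": sem.residual_moran.I,
                        "residual_moran_p": sem.residual_moran.p,
                    })
                summaries.append(row)
                for name, value in glm.params.items():
                    coef_rows.append({"response": response, "model": label,
                                      "coef": name, "estimate": value,
                                      "se": glm.bse[name],
                                      "p": glm.pvalues[name]})
                if label == "full":
                    resid[response] = glm.residuals
        oio.write_with_sidecar(pd.DataFrame(summaries),
                               outdir / "model_summaries.csv",
                               meta("fit", knn_k=config.knn_k), index_label="row")
        oio.write_with_sidecar(pd.DataFrame(coef_rows),
                               outdir / "model_coefficients.csv",
                               meta("fit"), index_label="row")
        if resid:
            oio.write_with_sidecar(pd.DataFrame(resid),
                                   outdir / "model_residuals.csv", meta("fit"))

    stages = [("build_tree", build_tree, config.run_build_tree),
              ("metrics", metrics, config.run_metrics),
              ("ages", ages, config.run_ages),
              ("tests", tests, config.run_tests),
              ("fit", fit, config.run_fit)]
    for name, fn, enabled in stages:
        if enabled:
            run_stage(name, fn)
    return outdir
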