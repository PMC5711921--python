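"""End-to-end orchestration: simulate/ingest -> screen -> ANN I -> DANN -> PPSN -> evaluate.

A single run seed fans out deterministically to per-stage seeds by hashing
the stage name, so any stage can be re-run in isolation and reproduce its
part of a pipeline run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cohort import CohortTable, read_cohort, write_cohort
from .dann import M_RANGE_DEFAULT, train_dann
from .evaluation import (
    accuracy_at_threshold,
    dagostino_pearson,
    delong_test,
    kfold_cv,
    optimal_cutoff,
    roc,
    se_at_fixed_sp,
)
from .ppsn import DEFAULT_EDGE_THRESHOLD, build_ppsn, density_peak_cluster, export_graph
from .rbf import RBFConfig
from .screening import (
    COLLINEARITY_THRESHOLD,
    P_THRESHOLD,
    RHO_THRESHOLD,
    collinearity,
    records_frame,
    screen_items,
    select_model_inputs,
)
from .simulate import GeneratorConfig, external_cohort_config, generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (base_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """All thresholds of the analysis, at their published defaults, overridable."""

    cohort_path: str | None = None          # None -> simulate
    external_path: str | None = None        # None -> simulate external cohort
    seed: int = 0
    n: int = 230
    n_external: int = 30
    selection_mode: str = "noncollinear"
    max_eis: int = 5
    rho_threshold: float = RHO_THRESHOLD
    p_threshold: float = P_THRESHOLD
    collinearity_threshold: float = COLLINEARITY_THRESHOLD
    ppsn_threshold: float = DEFAULT_EDGE_THRESHOLD
    sp_floor: float = 0.9
    risk_threshold: float = 0.38
    m_range: tuple[int, ...] = M_RANGE_DEFAULT
    cv_folds: int = 10
    run_cv: bool = True
    rbf: RBFConfig = field(default_factory=RBFConfig)
    out_dir: str = "osteomir_run"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; write artifacts and a hashed manifest.

    Returns the metrics dictionary (also written as ``metrics.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed, "stages": {}, "files": {},
    }
    metrics: dict = {}
    t_all = time.time()

    def _stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return manifest["stages"][name]["seed"], time.time()

    def _done(name, t0):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)

    # -- ingest / simulate --------------------------------------------------
    s, t0 = _stage("ingest")
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        cohort = generate_cohort(GeneratorConfig(n=config.n), seed=s)
        write_cohort(cohort, out / "cohort.csv")
    metrics["n_participants"] = len(cohort)
    metrics["status_counts"] = cohort.status_counts()
    _done("ingest", t0)

    # -- screening ----------------------------------------------------------
    s, t0 = _stage("screen")
    records = screen_items(cohort, config.rho_threshold, config.p_threshold)
    rec_df = records_frame(records)
    rec_df.to_csv(out / "screening.csv", index=False)
    matrix = collinearity(cohort, threshold=config.collinearity_threshold)
    matrix.frame().to_csv(out / "collinearity.csv")
    features = select_model_inputs(
        records, matrix, mode=config.selection_mode, max_eis=config.max_eis,
        registry_order=cohort.item_names,
    )
    marker_rec = next(r for r in records if r.item == cohort.item_names[0])
    metrics["marker_rho"] = marker_rec.rho
    metrics["n_bmd_correlated_eis"] = int(
        sum(r.bmd_correlated for r in records if r.item != cohort.item_names[0])
    )
    metrics["model_features"] = features
    _done("screen", t0)

    # -- marker-alone ROC ---------------------------------------------------
    s, t0 = _stage("marker_roc")
    labels = cohort.risk_labels()
    marker_vals = cohort.df[cohort.item_names[0]].to_numpy(dtype=float)
    marker_roc = roc(marker_vals, labels, orientation="high")
    thr, se_opt, sp_opt = optimal_cutoff(marker_roc)
    metrics["marker"] = {
        "auc": marker_roc.auc, "se_optimal": se_opt, "sp_optimal": sp_opt,
        "se_at_sp90": se_at_fixed_sp(marker_roc, config.sp_floor),
    }
    _done("marker_roc", t0)

    # -- DANN training ------------------------------------------------------
    s, t0 = _stage("train_dann")
    model, diag = train_dann(cohort, features, seed=s, m_range=config.m_range,
                             rbf_config=config.rbf)
    diag.grid.to_csv(out / "division_grid.csv", index=False)
    (out / "dann_model.json").write_text(json.dumps(model.to_dict()))
    dann_scores = model.score_internal()
    dann_roc = roc(dann_scores, labels, orientation="low")
    thr_d, se_d, sp_d = optimal_cutoff(dann_roc)
    model.threshold = thr_d
    metrics["ann1"] = {"r_train": diag.ann1_report.r_train,
                       "r_test": diag.ann1_report.r_test,
                       "n_centers": diag.ann1_report.n_centers}
    metrics["ann2"] = {"r_train": diag.ann2_report.r_train,
                       "r_test": diag.ann2_report.r_test}
    metrics["dann"] = {
        "m": model.m, "d_index": model.d_index, "rho": diag.rho_full,
        "auc": dann_roc.auc, "se_optimal": se_d, "sp_optimal": sp_d,
        "threshold": thr_d, "se_at_sp90": se_at_fixed_sp(dann_roc, config.sp_floor),
    }
    comp = delong_test(marker_vals, dann_scores, labels,
                       orientation1="high", orientation2="low")
    metrics["delong_marker_vs_dann"] = {
        "auc_marker": comp.auc1, "auc_dann": comp.auc2, "z": comp.z, "p": comp.p,
    }
    norm_rep = dagostino_pearson(dann_scores)
    metrics["dann_output_normality"] = {
        "k2": norm_rep.k2, "p": norm_rep.p, "passes": norm_rep.passes,
    }
    _done("train_dann", t0)

    # -- PPSN ---------------------------------------------------------------
    s, t0 = _stage("ppsn")
    graph = build_ppsn(cohort, model.normalization, features,
                       threshold=config.ppsn_threshold)
    export_graph(graph, out / "ppsn.graphml", "graphml")
    from scipy.spatial.distance import cdist
    X = model.normalization.transform(cohort, features)
    clusters = density_peak_cluster(cdist(X, X), d_c=config.ppsn_threshold,
                                    ids=cohort.ids)
    clusters.frame().to_csv(out / "clusters.csv", index=False)
    sizes = clusters.cluster_sizes()
    metrics["ppsn"] = {
        "n_edges": graph.number_of_edges(),
        "n_clusters": len(clusters.centers),
        "largest_cluster_fraction": float(sizes.max() / len(cohort)),
    }
    _done("ppsn", t0)

    # -- cross-validation ---------------------------------------------------
    if config.run_cv:
        s, t0 = _stage("crossval")
        cv = kfold_cv(cohort, features, k=config.cv_folds, seed=s,
                      m_range=config.m_range, rbf_config=config.rbf)
        metrics["cv"] = {"rho": cv.rho, "auc": cv.roc.auc,
                         "se_at_sp90": se_at_fixed_sp(cv.roc, config.sp_floor)}
        _done("crossval", t0)

    # -- external validation ------------------------------------------------
    s, t0 = _stage("external")
    if config.external_path:
        external = read_cohort(config.external_path)
    else:
        external = generate_cohort(
            external_cohort_config(n=config.n_external, features=features),
            seed=s)
        write_cohort(external, out / "external_cohort.csv")
    ext_scores = model.score_external(external)
    ext_labels = external.risk_labels()
    ext_rho, ext_p = stats.spearmanr(ext_scores, external.bmd)
    metrics["external"] = {
        "n": len(external),
        "status_counts": external.status_counts(),
        "accuracy_at_threshold": accuracy_at_threshold(
            ext_scores, ext_labels, config.risk_threshold, orientation="low"),
        "rho": float(ext_rho), "rho_p": float(ext_p),
    }
    _done("external", t0)

    metrics["seconds_total"] = round(time.time() - t_all, 3)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics
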