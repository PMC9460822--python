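"""End-to-end pipeline orchestration.

Runs simulate/load -> feature extraction -> k-selection curves -> clustering
(all requested methods) -> BNN validation per method -> group statistics per
method, writing every artifact (with the seed and configuration embedded) to
an output directory and returning the consolidated report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bnn, io
from ._rng import stage_rng
from .cluster import cut_tree, kmeans, selection_curves, ward_linkage
from .cohort import CohortConfig, generate_cohort, traces_frame, trials_frame
from .consensus import build_base_clusterings, cspa, hgpa, incidence_matrix, mcla
from .kinematics import features_table
from .stats import cluster_profile, lsd_pairwise, one_way_manova, partial_eta_squared, tukey_hsd

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("liftclust")

ALL_METHODS = ("ward", "kmeans", "cspa", "hgpa", "mcla")
FEATURES = ["trunk_rom", "hip_rom", "knee_rom"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features_csv: Optional[str] = None  # real-data mode: skip simulation
    k: int = 4
    kmeans_runs: int = 50
    kmeans_restarts: int = 10
    methods: Sequence[str] = ALL_METHODS
    l_values: Sequence[int] = tuple(range(1, 16))
    bnn_config: bnn.TrainConfig = field(default_factory=bnn.TrainConfig)
    split_fraction: float = 0.5
    k_min: int = 2
    k_max: int = 8
    seed: int = 0
    out_dir: str = "liftclust_out"

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {ALL_METHODS}")
        if not self.methods:
            raise ValueError("at least one method required")


class _StageError(RuntimeError):
    pass


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            start = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # tag failures with the stage name
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - start)
            return out

        return run

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all requested stages and write the report bundle to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    seed = config.seed
    report: dict = {"seed": seed, "config": _jsonable(config)}

    # --- simulate or load -------------------------------------------------
    if config.features_csv is None:
        trials = _stage("simulate")(generate_cohort)(config.cohort, seed=seed)
        meta = trials_frame(trials)
        meta.to_csv(out / "trials.csv", index=False, float_format=io.FLOAT_FORMAT)
        io.write_traces(traces_frame(trials), out / "traces.csv")
        feats = _stage("extract")(features_table)(trials)
        scores = meta[["pseq", "pain"]]
    else:
        feats = _stage("load")(io.read_features)(config.features_csv)
        trials = None
        scores = None
        meta = feats[["participant_id", "trial_index"]].copy()
    io.write_features(feats, out / "features.csv")
    X = feats[FEATURES].to_numpy()

    # --- k-selection ------------------------------------------------------
    curves = {}
    for method in ("kmeans", "ward"):
        curve = _stage(f"select-k[{method}]")(selection_curves)(
            X,
            config.k_min,
            config.k_max,
            method=method,
            seed=int(stage_rng(seed, f"select-{method}").integers(2**31)),
        )
        io.write_curve(curve, out / f"selection_{method}.csv")
        curves[method] = {
            "elbow_k": curve.elbow_k,
            "silhouette_k": curve.silhouette_k,
        }
    report["k_selection"] = curves
    report["k_used"] = config.k

    # --- clustering -------------------------------------------------------
    labels = {}
    ensemble_inc = None
    if "ward" in config.methods:
        tree = _stage("cluster[ward]")(ward_linkage)(X)
        io.write_merge_tree(tree, out / "ward_tree.csv")
        labels["ward"] = cut_tree(tree, config.k).labels
    if "kmeans" in config.methods:
        part = _stage("cluster[kmeans]")(kmeans)(
            X,
            config.k,
            n_restarts=config.kmeans_restarts,
            seed=int(stage_rng(seed, "kmeans").integers(2**31)),
        )
        labels["kmeans"] = part.labels
    consensus_methods = [m for m in config.methods if m in ("cspa", "hgpa", "mcla")]
    if consensus_methods:
        base = _stage("ensemble[base]")(build_base_clusterings)(
            X,
            config.k,
            runs=config.kmeans_runs,
            seed=int(stage_rng(seed, "ensemble").integers(2**31)),
        )
        ensemble_inc = incidence_matrix(base)
        report["ensemble_r"] = base.r
        fns = {"cspa": cspa, "hgpa": hgpa, "mcla": mcla}
        diag = {}
        for method in consensus_methods:
            res = _stage(f"ensemble[{method}]")(fns[method])(
                ensemble_inc,
                config.k,
                seed=int(stage_rng(seed, method).integers(2**31)),
            )
            labels[method] = res.partition.labels
            diag[method] = {
                k2: v for k2, v in res.diagnostics.items() if np.isscalar(v) or isinstance(v, (list, int, float))
            }
        (out / "consensus_diagnostics.json").write_text(json.dumps(_jsonable(diag), indent=2))

    labels_df = meta[["participant_id", "trial_index"]].copy()
    for method, lab in labels.items():
        labels_df[method] = lab
    io.write_labels(labels_df, out / "labels.csv")

    # --- validation + stats per method ------------------------------------
    per_method: dict = {}
    for method, lab in labels.items():
        entry: dict = {}
        split_seed = int(stage_rng(seed, f"split-{method}").integers(2**31))
        train_idx, test_idx = bnn.split_train_test(
            lab, fraction=config.split_fraction, seed=split_seed
        )
        sweep_seed = int(stage_rng(seed, f"bnn-{method}").integers(2**31))
        # standardize inputs on training statistics (raw degrees saturate tanh)
        mu_x = X[train_idx].mean(axis=0)
        sd_x = X[train_idx].std(axis=0)
        Xn = (X - mu_x) / sd_x
        spec, w, points = _stage(f"validate[{method}]")(bnn.sweep_hidden_nodes)(
            Xn[train_idx], lab[train_idx], l_values=config.l_values,
            config=config.bnn_config, seed=sweep_seed,
        )
        rep = bnn.evaluate(w, spec, Xn[test_idx], lab[test_idx])
        entry["bnn"] = {
            "hidden_nodes": spec.l,
            "accuracy": rep.accuracy,
            "recall": rep.recall.tolist(),
            "precision": rep.precision.tolist(),
            "confusion": rep.confusion.tolist(),
            "evidence_curve": [(p.hidden_nodes, p.log_evidence) for p in points],
        }
        manova = _stage(f"stats[{method}]")(one_way_manova)(X, lab)
        entry["manova"] = {
            "wilks_lambda": manova.wilks_lambda,
            "f": manova.f_stat,
            "df1": manova.df1,
            "df2": manova.df2_display,
            "p": manova.p_value,
        }
        entry["partial_eta_squared"] = {
            feat: partial_eta_squared(X[:, i], lab) for i, feat in enumerate(FEATURES)
        }
        entry["tukey"] = {
            feat: tukey_hsd(X[:, i], lab).to_dict("records")
            for i, feat in enumerate(FEATURES)
        }
        if scores is not None:
            entry["lsd_pseq"] = lsd_pairwise(scores["pseq"].to_numpy(), lab).to_dict("records")
            profile = cluster_profile(feats, scores, lab)
            profile.to_csv(out / f"profile_{method}.csv", index=False, float_format=io.FLOAT_FORMAT)
            entry["profile"] = profile.to_dict("records")
        per_method[method] = entry
    report["methods"] = per_method

    # --- ranking (reported, never auto-decided) ---------------------------
    ranking = sorted(
        per_method,
        key=lambda mth: (
            -per_method[mth]["bnn"]["accuracy"],
            -max(per_method[mth]["partial_eta_squared"].values()),
        ),
    )
    report["method_ranking_by_accuracy_and_effect_size"] = ranking

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
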