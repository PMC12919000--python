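"""Gradient-boosted pair / non-pair classifier for E2-E3 combinations.

Assembles per-complex feature vectors (3 interfaces x 11 interface features +
5 complex-level features = 38 columns), evaluates with nested stratified
cross-validation (feature selection and hyperparameter choice strictly inside
the inner folds), selects a decision threshold by maximizing the
F(beta=0.75)-score over out-of-fold probabilities, and predicts E2 partners
for unannotated E3s behind a structural prefilter.

The boosted-tree backend is scikit-learn's GradientBoostingClassifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import SelectFromModel
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline

__all__ = [
    "INTERFACE_FEATURES",
    "COMPLEX_FEATURES",
    "FEATURE_COLUMNS",
    "TrainingConfig",
    "CVReport",
    "PredictionPrefilter",
    "ClassifierModel",
    "ClassifierError",
    "assemble_features",
    "balance_classes",
    "nested_cv",
    "fbeta",
    "choose_threshold",
    "train_final",
    "predict_partners",
    "save_model",
    "load_model",
]

INTERFACE_PREFIXES = {"UB-E2": "ub_e2", "UB-E3": "ub_e3", "E2-E3": "e2_e3"}
INTERFACE_FEATURES = [
    "ipsae", "iptm", "pdockq", "pdockq2", "dG", "dSASA", "dSASA_polar",
    "dSASA_nonpolar", "hbonds_int", "hbonds_unsat", "nres",
]
COMPLEX_FEATURES = [
    "ile44_helix_dist", "tail_cys_dist", "linchpin_flag",
    "n_e3_loops", "n_e3_loop_residues",
]
FEATURE_COLUMNS = [
    f"{prefix}_{feat}"
    for prefix in INTERFACE_PREFIXES.values()
    for feat in INTERFACE_FEATURES
] + COMPLEX_FEATURES

MAX_MISSING_FRACTION = 0.20


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    n_outer_folds: int = 5
    n_inner_folds: int = 3
    stratified: bool = True
    beta: float = 0.75
    seed: int = 0
    feature_selection: str = "importance_threshold"  # or "none"
    balance: bool = True
    n_estimators: int = 100
    param_grid: dict = field(default_factory=lambda: {
        "clf__max_depth": [2, 3],
        "clf__learning_rate": [0.1, 0.3],
    })

    def __post_init__(self):
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ClassifierError("folds must be >= 2")
        if self.beta <= 0:
            raise ClassifierError("beta must be positive")


@dataclass
class CVReport:
    fold_metrics: pd.DataFrame             # accuracy / precision / recall / roc_auc per fold
    mean_metrics: dict
    oof_probabilities: np.ndarray
    labels: np.ndarray
    threshold: float
    confusion: np.ndarray                  # at the chosen threshold
    selected_features: list


@dataclass(frozen=True)
class PredictionPrefilter:
    require_closed: bool = True
    require_ring_engagement: bool = True
    min_ptm: float = 0.5
    min_iptm: float = 0.5


@dataclass
class ClassifierModel:
    pipeline: Pipeline
    feature_columns: list
    threshold: float
    seed: int
    config_hash: str
    selected_features: list = field(default_factory=list)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_columns].to_numpy(dtype=float)
        return self.pipeline.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def _pivot_interface(frame: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    wide = frame.pivot(index="complex_id", columns="interface", values=list(value_cols))
    wide.columns = [
        f"{INTERFACE_PREFIXES[iface]}_{col}" for col, iface in wide.columns
    ]
    return wide.reset_index()


def assemble_features(structural: pd.DataFrame, confidence: pd.DataFrame,
                      energetics: pd.DataFrame,
                      require_closed: bool = True) -> pd.DataFrame:
    """Inner-join structural, confidence and energetics sources into one
    labeled feature table keyed by complex_id.

    Rows not in the Closed conformation are removed. Mean interface PAE is
    deliberately never a feature. A feature column missing in more than 20%
    of rows is a schema error.
    """
    for col in ("complex_id", "label", "conformation", *COMPLEX_FEATURES):
        if col not in structural.columns:
            raise ClassifierError(f"structural table missing column {col!r}")
    conf_wide = _pivot_interface(confidence, ["ipsae", "iptm", "pdockq", "pdockq2"])
    energy_cols = ["dG", "dSASA", "dSASA_polar", "dSASA_nonpolar",
                   "hbonds_int", "hbonds_unsat", "nres"]
    energy_wide = _pivot_interface(energetics, energy_cols)
    table = (
        structural.merge(conf_wide, on="complex_id", how="inner")
        .merge(energy_wide, on="complex_id", how="inner")
    )
    if require_closed:
        table = table[table["conformation"] == "Closed"].reset_index(drop=True)
    for col in FEATURE_COLUMNS:
        if col not in table.columns:
            raise ClassifierError(f"assembled table missing feature column {col!r}")
        missing = table[col].isna().mean() if len(table) else 0.0
        if missing > MAX_MISSING_FRACTION:
            raise ClassifierError(
                f"feature {col!r} missing in {missing:.0%} of rows (> 20% allowed)"
            )
    return table


def balance_classes(table: pd.DataFrame, candidate_nonpairs: pd.DataFrame,
                    seed: int) -> pd.DataFrame:
    """Top up the minority 'nonpair' class from a candidate pool until class
    counts are equal. Deterministic under seed; reports achievable balance
    when the pool is too small."""
    n_pair = int((table["label"] == "pair").sum())
    n_nonpair = int((table["label"] == "nonpair").sum())
    deficit = n_pair - n_nonpair
    if deficit <= 0:
        return table.reset_index(drop=True)
    pool = candidate_nonpairs[~candidate_nonpairs["complex_id"].isin(table["complex_id"])]
    take = min(deficit, len(pool))
    if take > 0:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(pool), size=take, replace=False))
        table = pd.concat([table, pool.iloc[idx]], ignore_index=True)
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

def _make_pipeline(config: TrainingConfig) -> Pipeline:
    base = GradientBoostingClassifier(
        n_estimators=config.n_estimators, random_state=config.seed
    )
    steps = []
    if config.feature_selection == "importance_threshold":
        selector = SelectFromModel(
            GradientBoostingClassifier(
                n_estimators=max(50, config.n_estimators // 2),
                random_state=config.seed,
            ),
            threshold="mean",
        )
        steps.append(("select", selector))
    steps.append(("clf", base))
    return Pipeline(steps)


def _labels_to_int(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    return (arr == "pair").astype(int)


def nested_cv(table: pd.DataFrame, config: TrainingConfig) -> CVReport:
    """Nested stratified cross-validation with leakage-free feature selection.

    Outer folds are stratified by label; the inner grid search (hyperparameters
    + importance-threshold feature selection) sees only outer-training rows.
    Out-of-fold probabilities for every row feed the threshold choice.
    """
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = _labels_to_int(table["label"])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 10:
        raise ClassifierError("need >= 10 rows per class for nested CV")
    outer = StratifiedKFold(config.n_outer_folds, shuffle=True, random_state=config.seed)
    inner = StratifiedKFold(config.n_inner_folds, shuffle=True, random_state=config.seed)
    oof = np.full(len(y), np.nan)
    rows = []
    selected: list[str] = []
    for fold, (train_idx, test_idx) in enumerate(outer.split(X, y)):
        search = GridSearchCV(
            _make_pipeline(config), config.param_grid, cv=inner,
            scoring="roc_auc", n_jobs=1, refit=True,
        )
        search.fit(X[train_idx], y[train_idx])
        best = search.best_estimator_
        proba = best.predict_proba(X[test_idx])[:, 1]
        oof[test_idx] = proba
        pred = (proba >= 0.5).astype(int)
        rows.append({
            "fold": fold,
            "accuracy": accuracy_score(y[test_idx], pred),
            "precision": precision_score(y[test_idx], pred, zero_division=0),
            "recall": recall_score(y[test_idx], pred, zero_division=0),
            "roc_auc": roc_auc_score(y[test_idx], proba),
        })
        if "select" in best.named_steps:
            mask = best.named_steps["select"].get_support()
            selected.append([c for c, keep in zip(FEATURE_COLUMNS, mask) if keep])
        else:
            selected.append(list(FEATURE_COLUMNS))
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    threshold = choose_threshold(oof, y, beta=config.beta)
    pred_at_thr = (oof >= threshold).astype(int)
    confusion = confusion_matrix(y, pred_at_thr)
    assert confusion.sum() == len(y)
    return CVReport(
        fold_metrics=fold_metrics,
        mean_metrics=fold_metrics.mean().to_dict(),
        oof_probabilities=oof,
        labels=y,
        threshold=threshold,
        confusion=confusion,
        selected_features=selected,
    )


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def fbeta(precision: float, recall: float, beta: float) -> float:
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    denom = b2 * precision + recall
    return 0.0 if denom == 0 else (1 + b2) * precision * recall / denom


def choose_threshold(probabilities: Sequence[float], labels: Sequence,
                     beta: float = 0.75) -> float:
    """Threshold maximizing the F(beta)-score over unique probability values;
    ties break toward the lower threshold."""
    proba = np.asarray(probabilities, dtype=float)
    y = _labels_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ClassifierError("threshold undefined for single-class labels")
    best_thr, best_score = None, -1.0
    for thr in sorted(np.unique(proba)):
        pred = (proba >= thr).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        score = fbeta(precision, recall, beta)
        if score > best_score:
            best_thr, best_score = float(thr), score
    return best_thr


# ---------------------------------------------------------------------------
# Final model + prediction
# ---------------------------------------------------------------------------

def _config_hash(config: TrainingConfig) -> str:
    payload = json.dumps({
        "n_outer_folds": config.n_outer_folds,
        "n_inner_folds": config.n_inner_folds,
        "beta": config.beta,
        "seed": config.seed,
        "feature_selection": config.feature_selection,
        "n_estimators": config.n_estimators,
        "param_grid": {k: list(v) for k, v in config.param_grid.items()},
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_final(table: pd.DataFrame, config: TrainingConfig,
                threshold: Optional[float] = None) -> ClassifierModel:
    """Fit the final pipeline on all rows.

    The decision threshold should come from nested-CV out-of-fold
    probabilities; when not supplied it is derived here from a fresh CV run.
    """
    if threshold is None:
        threshold = nested_cv(table, config).threshold
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = _labels_to_int(table["label"])
    inner = StratifiedKFold(config.n_inner_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        _make_pipeline(config), config.param_grid, cv=inner,
        scoring="roc_auc", n_jobs=1, refit=True,
    )
    search.fit(X, y)
    pipeline = search.best_estimator_
    if "select" in pipeline.named_steps:
        mask = pipeline.named_steps["select"].get_support()
        selected = [c for c, keep in zip(FEATURE_COLUMNS, mask) if keep]
    else:
        selected = list(FEATURE_COLUMNS)
    return ClassifierModel(
        pipeline=pipeline,
        feature_columns=list(FEATURE_COLUMNS),
        threshold=float(threshold),
        seed=config.seed,
        config_hash=_config_hash(config),
        selected_features=selected,
    )


def save_model(model: ClassifierModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.pipeline, directory / "pipeline.joblib")
    manifest = {
        "feature_columns": model.feature_columns,
        "selected_features": model.selected_features,
        "threshold": model.threshold,
        "seed": model.seed,
        "config_hash": model.config_hash,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory) -> ClassifierModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    pipeline = joblib.load(directory / "pipeline.joblib")
    return ClassifierModel(
        pipeline=pipeline,
        feature_columns=manifest["feature_columns"],
        threshold=manifest["threshold"],
        seed=manifest["seed"],
        config_hash=manifest["config_hash"],
        selected_features=manifest.get("selected_features", []),
    )


def predict_partners(model: ClassifierModel, candidates: pd.DataFrame,
                     prefilter: PredictionPrefilter = PredictionPrefilter()
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Score candidate E2-E3 complexes and summarize predicted partners per E3.

    Candidate rows must carry ``e2``, ``e3``, ``conformation``,
    ``ring_engagement``, ``ptm`` and ``iptm`` columns alongside the feature
    columns. Rows failing the prefilter are excluded before scoring.

    Returns (scored rows, per-E3 summary, prefilter reason counts). E3s with
    exactly one predicted-pair E2 are flagged unique.
    """
    required = {"e2", "e3", "conformation", "ring_engagement", "ptm", "iptm"}
    missing = required - set(candidates.columns)
    if missing:
        raise ClassifierError(f"candidate table missing columns {sorted(missing)}")
    reasons = {"open_conformation": 0, "no_ring_engagement": 0, "low_ptm": 0, "low_iptm": 0}
    keep = np.ones(len(candidates), dtype=bool)
    if prefilter.require_closed:
        bad = (candidates["conformation"] != "Closed").to_numpy()
        reasons["open_conformation"] = int((keep & bad).sum())
        keep &= ~bad
    if prefilter.require_ring_engagement:
        bad = ~candidates["ring_engagement"].astype(bool).to_numpy()
        reasons["no_ring_engagement"] = int((keep & bad).sum())
        keep &= ~bad
    bad = (candidates["ptm"] < prefilter.min_ptm).to_numpy()
    reasons["low_ptm"] = int((keep & bad).sum())
    keep &= ~bad
    bad = (candidates["iptm"] < prefilter.min_iptm).to_numpy()
    reasons["low_iptm"] = int((keep & bad).sum())
    keep &= ~bad
    survivors = candidates[keep].reset_index(drop=True)
    if len(survivors) == 0:
        empty = pd.DataFrame(columns=list(candidates.columns) + ["probability", "predicted_pair"])
        summary = pd.DataFrame(columns=["e3", "predicted_e2s", "n_predicted", "unique"])
        return empty, summary, reasons
    proba = model.predict_proba(survivors)
    scored = survivors.assign(
        probability=proba, predicted_pair=proba >= model.threshold
    )
    rows = []
    for e3, group in scored.groupby("e3"):
        predicted = sorted(group.loc[group["predicted_pair"], "e2"].unique())
        rows.append({
            "e3": e3,
            "predicted_e2s": ",".join(predicted),
            "n_predicted": len(predicted),
            "unique": len(predicted) == 1,
        })
    summary = pd.DataFrame(rows).sort_values("e3").reset_index(drop=True)
    return scored, summary, reasons
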