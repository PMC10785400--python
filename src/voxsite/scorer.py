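"""Voxel-scoring classifier: bagged base learners with multi-layer stacking.

The scorer maps a voxel's consensus features to a probability in [0, 1] that
the voxel contains the ligand binding site. Layer 1 fits each base learner
(gradient-boosted trees, random forest, regularized logistic model by
default) on bootstrap resamples and averages the bags; out-of-fold
predictions of each layer — computed with target-grouped folds so no voxel
of a target ever informs a prediction on that same target — feed the next
layer; the final meta-learner is a logistic model, so the output is a
calibrated probability without a separate calibration stage.

The ~1 positive : dozens of negatives imbalance per target is handled by
balanced class weights in every learner, not by resampling.

Data hygiene: train/validation splitting is at *target* granularity, and an
optional similarity-based dedup drops training targets too similar
(precomputed score > 0.5, e.g. a TM-score) to any benchmark target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from voxsite.voxelizer import FeatureTable, LABEL_COL, POSITIVE, apply_impute


@dataclass
class StackConfig:
    base_learner_specs: tuple[str, ...] = ("hist_gbdt", "random_forest", "logistic")
    bags_per_learner: int = 5
    stack_layers: int = 2
    folds_for_oof: int = 5
    validation_fraction: float = 0.2
    class_weighting: str = "balanced"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0,1)")
        if self.folds_for_oof < 2:
            raise ValueError("folds_for_oof must be ≥ 2")
        if self.stack_layers < 1:
            raise ValueError("stack_layers must be ≥ 1")
        if self.bags_per_learner < 1:
            raise ValueError("bags_per_learner must be ≥ 1")


def _make_learner(name: str, seed: int):
    """Base-learner registry; extend here to vary the roster."""
    if name == "hist_gbdt":
        return HistGradientBoostingClassifier(
            class_weight="balanced", random_state=seed, max_iter=100
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if name == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(class_weight="balanced", max_iter=2000, random_state=seed),
        )
    raise ValueError(f"unknown base learner {name!r}")


class BaggedLearner:
    """One base learner averaged over bootstrap resamples.

    A single bag fits on the full data (plain classifier); multiple bags each
    fit a clone on a resample drawn with replacement and predictions are the
    mean probability.
    """

    def __init__(self, spec: str, bags: int, seed: int):
        self.spec = spec
        self.bags = bags
        self.seed = seed
        self.models_ = []

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        self.models_ = []
        for _ in range(self.bags):
            model = _make_learner(self.spec, int(rng.integers(2**31)))
            if self.bags == 1:
                idx = np.arange(len(y))
            else:
                idx = rng.integers(0, len(y), size=len(y))
                if len(np.unique(y[idx])) < 2:  # resample must keep both classes
                    idx = np.concatenate([idx, np.flatnonzero(y == 1)[:1],
                                          np.flatnonzero(y == 0)[:1]])
            model.fit(X[idx], y[idx])
            self.models_.append(model)
        return self

    def predict_proba_pos(self, X) -> np.ndarray:
        return np.mean([m.predict_proba(X)[:, 1] for m in self.models_], axis=0)


@dataclass
class SiteScorer:
    """The trained selection + stacking bundle producing a 0–1 voxel score."""

    selected_features: list[str]
    column_means: dict[str, float]
    config: StackConfig
    layers: list[list[BaggedLearner]] = field(default_factory=list)
    meta: object = None
    training_report: dict = field(default_factory=dict)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        Z = X
        preds = None
        for layer in self.layers:
            preds = np.column_stack([l.predict_proba_pos(Z) for l in layer])
            Z = np.hstack([X, preds])
        if self.meta is None:
            scores = preds.mean(axis=1)
        else:
            scores = self.meta.predict_proba(preds)[:, 1]
        return np.clip(scores, 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.selected_features):
            raise ValueError(
                f"expected {len(self.selected_features)} features, got {X.shape[1]}"
            )
        return self._forward(np.asarray(X, dtype=float))

    def save(self, directory) -> None:
        """Model bundle: config + feature list + imputation means as JSON,
        fitted learners serialized alongside."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps({
            **asdict(self.config),
            "base_learner_specs": list(self.config.base_learner_specs),
        }, indent=1))
        (directory / "features.json").write_text(json.dumps(self.selected_features, indent=1))
        (directory / "column_means.json").write_text(json.dumps(self.column_means, indent=1))
        (directory / "training_report.json").write_text(json.dumps(self.training_report, indent=1))
        joblib.dump({"layers": self.layers, "meta": self.meta}, directory / "learners.joblib")

    @classmethod
    def load(cls, directory) -> "SiteScorer":
        directory = Path(directory)
        raw = json.loads((directory / "config.json").read_text())
        raw["base_learner_specs"] = tuple(raw["base_learner_specs"])
        config = StackConfig(**raw)
        bundle = joblib.load(directory / "learners.joblib")
        return cls(
            selected_features=json.loads((directory / "features.json").read_text()),
            column_means=json.loads((directory / "column_means.json").read_text()),
            config=config,
            layers=bundle["layers"],
            meta=bundle["meta"],
            training_report=json.loads((directory / "training_report.json").read_text()),
        )


# ---------------------------------------------------------------------------
# Target-level hygiene


def split_by_target(tables: list[FeatureTable], fraction: float = 0.2,
                    seed: int = 0) -> tuple[list[FeatureTable], list[FeatureTable]]:
    """Split a corpus at target granularity: every voxel of a target lands on
    one side, preventing leakage between training and validation."""
    if len(tables) < 2:
        raise ValueError("need at least 2 targets to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tables))
    n_val = max(1, int(round(fraction * len(tables))))
    n_val = min(n_val, len(tables) - 1)
    val_idx = set(order[:n_val].tolist())
    train = [t for i, t in enumerate(tables) if i not in val_idx]
    val = [t for i, t in enumerate(tables) if i in val_idx]
    return train, val


def dedup_by_similarity(train_targets: list[str], benchmark_targets: list[str],
                        similarity: dict, threshold: float = 0.5) -> list[str]:
    """Drop training targets whose precomputed structural-similarity score
    (e.g. TM-score) to *any* benchmark target strictly exceeds the threshold;
    a score of exactly the threshold is kept. Similarity computation is
    external — this accepts a pairwise score table keyed by (a, b)."""
    missing = []
    kept = []
    for t in train_targets:
        drop = False
        for b in benchmark_targets:
            s = similarity.get((t, b), similarity.get((b, t)))
            if s is None:
                missing.append((t, b))
                continue
            if s > threshold:
                drop = True
        if not drop:
            kept.append(t)
    if missing:
        raise KeyError(f"similarity scores missing for pairs: {missing}")
    return kept


# ---------------------------------------------------------------------------
# Training


def _stack_xyg(tables: list[FeatureTable]):
    X = np.vstack([t.X for t in tables])
    y = np.concatenate([(t.y == POSITIVE).astype(int) for t in tables])
    groups = np.concatenate([np.full(len(t), i) for i, t in enumerate(tables)])
    return X, y, groups


def train(train_tables: list[FeatureTable], config: StackConfig | None = None
          ) -> SiteScorer:
    """Fit the stacked voxel scorer on imputed, feature-selected tables.

    An internal target-level split holds out ``validation_fraction`` of the
    targets for the training report (AUROC, log-loss, top-1 site hit rate);
    the model itself is fit only on the remaining targets. Deterministic for
    a fixed seed.
    """
    config = config or StackConfig()
    if len(train_tables) < 2:
        raise ValueError("need at least 2 targets to train")
    names = train_tables[0].feature_names
    for t in train_tables[1:]:
        if t.feature_names != names:
            raise ValueError("feature sets differ across tables; align and select first")
    means = train_tables[0].column_means or {}

    fit_tables, val_tables = split_by_target(
        train_tables, config.validation_fraction, seed=config.seed
    )
    X, y, groups = _stack_xyg(fit_tables)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values; impute first")

    rng = np.random.default_rng(config.seed)
    n_groups = len(np.unique(groups))
    n_folds = min(config.folds_for_oof, n_groups)
    layers: list[list[BaggedLearner]] = []
    Z = X
    preds = None
    for _layer in range(config.stack_layers):
        layer = [
            BaggedLearner(spec, config.bags_per_learner, int(rng.integers(2**31)))
            for spec in config.base_learner_specs
        ]
        oof = np.zeros((len(y), len(layer)))
        splitter = GroupKFold(n_splits=n_folds)
        for tr, te in splitter.split(Z, y, groups):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a training fold lost one class; use more targets")
            for j, learner in enumerate(layer):
                fold_learner = BaggedLearner(learner.spec, learner.bags, learner.seed)
                fold_learner.fit(Z[tr], y[tr])
                oof[te, j] = fold_learner.predict_proba_pos(Z[te])
        for learner in layer:  # refit on everything for inference
            learner.fit(Z, y)
        layers.append(layer)
        preds = oof
        Z = np.hstack([X, preds])

    if config.stack_layers >= 2 or len(config.base_learner_specs) > 1:
        meta = LogisticRegression(
            class_weight="balanced", max_iter=2000,
            random_state=int(rng.integers(2**31)),
        )
        meta.fit(preds, y)
    else:
        meta = None

    model = SiteScorer(
        selected_features=list(names),
        column_means=dict(means),
        config=config,
        layers=layers,
        meta=meta,
    )
    model.training_report = _validation_report(model, val_tables)
    return model


def _validation_report(model: SiteScorer, val_tables: list[FeatureTable]) -> dict:
    Xv = np.vstack([t.X for t in val_tables])
    yv = np.concatenate([(t.y == POSITIVE).astype(int) for t in val_tables])
    report = {"n_validation_targets": len(val_tables), "n_validation_rows": int(len(yv))}
    scores = model.predict(Xv)
    if len(np.unique(yv)) == 2:
        report["auroc"] = float(roc_auc_score(yv, scores))
        report["log_loss"] = float(log_loss(yv, np.clip(scores, 1e-9, 1 - 1e-9)))
    hits = 0
    labelled = 0
    for t in val_tables:
        yt = (t.y == POSITIVE).astype(int)
        if yt.sum() == 0:
            continue
        labelled += 1
        st = model.predict(t.X)
        if yt[int(np.argmax(st))] == 1:
            hits += 1
    if labelled:
        report["top1_site_hit_rate"] = hits / labelled
    return report


def score_voxels(model: SiteScorer, table: FeatureTable) -> dict[tuple[int, int, int], float]:
    """Score every voxel row of a table with a trained model.

    Columns must match the model's selected features by name and order;
    missing cells are imputed with the *training* means before scoring.
    """
    if table.feature_names != model.selected_features:
        extra = [c for c in table.feature_names if c not in model.selected_features]
        absent = [c for c in model.selected_features if c not in table.feature_names]
        raise ValueError(
            f"feature mismatch: unexpected columns {extra}, missing columns {absent}"
        )
    work = table
    if table.frame[table.feature_names].isna().any().any():
        work = apply_impute(table, model.column_means)
    scores = model.predict(work.X)
    return {idx: float(s) for idx, s in zip(work.voxel_indices(), scores)}
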