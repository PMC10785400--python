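"""Shadow-feature (Boruta) selection and ANOVA F-score reporting.

Boruta decides, per feature, whether it carries more information about the
voxel label than chance: each iteration appends one column-shuffled "shadow"
copy per still-undecided feature, fits a class-weighted random-forest
importance model, and credits a feature with a hit when its impurity
importance exceeds the *maximum* shadow importance. Hits accumulate across
iterations and are tested against Binomial(trials, 1/2) two-sided: features
significantly above chance are confirmed, significantly below rejected, and
anything undecided at the iteration cap stays tentative. No multiple-testing
correction is applied across features, matching the canonical algorithm.

ANOVA F-scores are reported for interpretability only — they play no part
in the selection decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

#: sentinel for an infinite F statistic (zero within-group variance)
F_CAP = 1e12

CONFIRMED, REJECTED, TENTATIVE = "confirmed", "rejected", "tentative"


@dataclass
class BorutaConfig:
    max_iterations: int = 100
    alpha: float = 0.05
    ensemble_size: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")


@dataclass
class FeatureDecision:
    feature: str
    status: str  # confirmed | rejected | tentative
    hits: int
    trials: int
    mean_importance: float

    def __post_init__(self):
        if self.hits > self.trials:
            raise ValueError("hits cannot exceed trials")


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


def boruta_select(X, y, config: BorutaConfig | None = None,
                  feature_names=None) -> list[FeatureDecision]:
    """Run shadow-feature selection; returns one decision per input feature.

    Deterministic for a fixed (X, y, seed). Requires a fully-imputed design
    matrix and a binary label vector with both classes present.
    """
    config = config or BorutaConfig()
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values; impute first")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")

    rng = np.random.default_rng(config.seed)
    n_features = len(names)
    undecided = list(range(n_features))
    hits = np.zeros(n_features, dtype=int)
    trials = np.zeros(n_features, dtype=int)
    imp_sum = np.zeros(n_features)
    status = {i: TENTATIVE for i in range(n_features)}

    for _ in range(config.max_iterations):
        if not undecided:
            break
        sub = X[:, undecided]
        shadows = sub.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([sub, shadows])
        forest = RandomForestClassifier(
            n_estimators=config.ensemble_size,
            class_weight="balanced",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        real_imp = imp[: len(undecided)]
        shadow_max = imp[len(undecided):].max()
        for pos, i in enumerate(undecided):
            trials[i] += 1
            imp_sum[i] += real_imp[pos]
            if real_imp[pos] > shadow_max:
                hits[i] += 1
        still = []
        for i in undecided:
            p = binomtest(int(hits[i]), int(trials[i]), 0.5).pvalue
            if p < config.alpha:
                status[i] = CONFIRMED if hits[i] * 2 > trials[i] else REJECTED
            else:
                still.append(i)
        undecided = still

    return [
        FeatureDecision(
            names[i], status[i], int(hits[i]), int(trials[i]),
            float(imp_sum[i] / trials[i]) if trials[i] else 0.0,
        )
        for i in range(n_features)
    ]


def anova_f_scores(X, y, feature_names=None) -> dict[str, float]:
    """Per-feature one-way ANOVA F statistic between the two label groups.

    Zero-variance features score 0; an infinite F (perfect separation with
    zero within-group variance) is reported as the F_CAP sentinel.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    out = {}
    for name, v in zip(names, f):
        if np.isnan(v):
            out[name] = 0.0
        elif np.isinf(v) or v > F_CAP:
            out[name] = F_CAP
        else:
            out[name] = float(v)
    return out


def apply_selection(table, decisions: list[FeatureDecision],
                    keep_tentative: bool = False):
    """Project a FeatureTable onto the confirmed (optionally + tentative)
    columns. Refuses to emit an empty design matrix."""
    from voxsite.voxelizer import CENTER_COLS, INDEX_COLS, LABEL_COL

    by_name = {d.feature: d for d in decisions}
    uncovered = [c for c in table.feature_names if c not in by_name]
    if uncovered:
        raise ValueError(f"decisions do not cover columns {uncovered}")
    wanted = {CONFIRMED, TENTATIVE} if keep_tentative else {CONFIRMED}
    keep = [c for c in table.feature_names if by_name[c].status in wanted]
    if not keep:
        raise ValueError("no features survive selection; refusing an empty design matrix")
    out = table.copy()
    out.frame = out.frame[INDEX_COLS + CENTER_COLS + keep + [LABEL_COL]]
    out.feature_names = keep
    if out.imputed is not None:
        out.imputed = out.imputed[keep]
    if out.column_means is not None:
        out.column_means = {c: out.column_means[c] for c in keep}
    return out


def decisions_to_frame(decisions: list[FeatureDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.feature, d.status, d.hits, d.trials, d.mean_importance) for d in decisions],
        columns=["feature", "status", "hits", "trials", "mean_importance"],
    )
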