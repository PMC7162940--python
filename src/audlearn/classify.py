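"""Early separation of learners (L) from non-learners (notL).

Each participant is summarised by twelve coarse performance features —
block sensitivity and block specificity over six 40-trial blocks — plus
the two design factors (target configuration, response button), and the
binary label from the end-of-experiment questionnaire.  Nested feature
subspaces truncate the blocks at increasing trial horizons (upto_40 …
upto_200, complete), asking how early the label can be predicted.

The classifier is a gradient-boosted decision-tree ensemble (LightGBM)
with native categorical handling.  Class imbalance is handled by weighting
positive (L) instances by #notL / #L while notL instances keep weight 1 —
i.e. the majority class is down-weighted so both classes carry equal total
weight.  Quality is measured as balanced accuracy, the mean of per-class
recalls, under stratified k-fold cross-validation; feature importance is
the ensemble's split-gain attribution normalised to sum 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cohort import ParticipantRecord, cohort_to_frame
from .metrics import block_series

__all__ = [
    "SENS_FEATURES",
    "SPEC_FEATURES",
    "CATEGORICAL_FEATURES",
    "SUBSPACES",
    "FittedClassifier",
    "CVReport",
    "build_feature_table",
    "subspace_select",
    "compute_weights",
    "balanced_accuracy",
    "train_classifier",
    "stratified_cv",
]

FEATURE_BLOCK_SIZE = 40
N_FEATURE_BLOCKS = 6

SENS_FEATURES = tuple(
    f"sens_{40 * b + 1}_to_{40 * (b + 1)}" for b in range(N_FEATURE_BLOCKS)
)
SPEC_FEATURES = tuple(
    f"spec_{40 * b + 1}_to_{40 * (b + 1)}" for b in range(N_FEATURE_BLOCKS)
)
CATEGORICAL_FEATURES = ("TargetConf", "Button")
LABEL_COLUMN = "Learner"  # notL: 0, L: 1

#: Subspace name -> number of 40-trial blocks whose features are included.
SUBSPACES: dict[str, int] = {
    "upto_40": 1,
    "upto_80": 2,
    "upto_120": 3,
    "upto_160": 4,
    "upto_200": 5,
    "complete": 6,
}

#: Booster defaults; unstated upstream, kept fixed so synthetic-cohort
#: results do not hinge on tuning.
DEFAULT_BOOSTER_PARAMS: dict = {
    "n_estimators": 500,
    "learning_rate": 0.1,
    "max_depth": 6,
    "num_leaves": 63,
    "min_child_samples": 2,
    "deterministic": True,
    "n_jobs": 1,
    "verbosity": -1,
}


def build_feature_table(cohort) -> pd.DataFrame:
    """One feature row per participant, indexed by participant id.

    Numeric features are block sensitivity/specificity at block size 40;
    TargetConf and Button are pandas categoricals; Learner is 0/1.
    """
    if isinstance(cohort, pd.DataFrame):
        frame = cohort
    else:
        frame = cohort_to_frame(cohort)
    rows = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        if len(grp) != 240:
            raise ValueError(f"participant {pid!r} has {len(grp)} trials, expected 240")
        grp = grp.sort_values("trial_index")
        sens = block_series(grp, "sensitivity", FEATURE_BLOCK_SIZE).values
        spec = block_series(grp, "specificity", FEATURE_BLOCK_SIZE).values
        meta = grp.iloc[0]
        rows.append(
            (
                pid,
                *sens,
                *spec,
                int(meta["config"]),
                str(meta["button"]),
                1 if str(meta["label"]) == "L" else 0,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            *SENS_FEATURES,
            *SPEC_FEATURES,
            *CATEGORICAL_FEATURES,
            LABEL_COLUMN,
        ],
    ).set_index("participant_id")
    table["TargetConf"] = table["TargetConf"].astype("category")
    table["Button"] = table["Button"].astype("category")
    return table


def subspace_select(table: pd.DataFrame, subspace: str) -> pd.DataFrame:
    """Predictor columns of a subspace: sens/spec features of the first
    1..k blocks plus the two design factors; never the label."""
    if subspace not in SUBSPACES:
        raise ValueError(f"unknown subspace {subspace!r}; choose from {sorted(SUBSPACES)}")
    k = SUBSPACES[subspace]
    cols = [*SENS_FEATURES[:k], *SPEC_FEATURES[:k], *CATEGORICAL_FEATURES]
    return table[cols]


def compute_weights(labels: Sequence[int]) -> np.ndarray:
    """Per-instance weights: weight(L=1) = #notL / #L, weight(notL=0) = 1."""
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute weights")
    return np.where(y == 1, n_neg / n_pos, 1.0)


def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Mean of per-class recalls: (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = yt == 1
    neg = yt == 0
    if not pos.any() or not neg.any():
        raise ValueError("y_true must contain both classes")
    tpr = (yp[pos] == 1).mean()
    tnr = (yp[neg] == 0).mean()
    return float(0.5 * tpr + 0.5 * tnr)


@dataclass
class FittedClassifier:
    """A trained boosted-tree model with normalised gain importances."""

    model: lgb.LGBMClassifier
    importances: pd.Series  # descending, sums to 100 (0 if degenerate)
    degenerate: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.model.predict(X), dtype=int)


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[int],
    weights: Sequence[float] | None = None,
    categorical_features: Sequence[str] | None = None,
    seed: int = 0,
    params: Mapping | None = None,
) -> FittedClassifier:
    """Train the boosted-tree ensemble; deterministic given the seed.

    A model that found no useful split (all gain importances zero, e.g. on
    constant input) is returned flagged as degenerate: it predicts the
    weighted-majority class.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if categorical_features is None:
        categorical_features = [c for c in CATEGORICAL_FEATURES if c in X.columns]
    X = X.copy()
    for c in categorical_features:
        X[c] = X[c].astype("category")
    merged = dict(DEFAULT_BOOSTER_PARAMS)
    if params:
        merged.update(params)
    model = lgb.LGBMClassifier(random_state=seed, **merged)
    model.fit(
        X,
        y,
        sample_weight=None if weights is None else np.asarray(weights, dtype=float),
        categorical_feature=list(categorical_features),
    )
    gains = model.booster_.feature_importance(importance_type="gain")
    total = gains.sum()
    degenerate = total <= 0
    norm = gains / total * 100.0 if not degenerate else np.zeros_like(gains, dtype=float)
    importances = pd.Series(norm, index=X.columns).sort_values(ascending=False)
    return FittedClassifier(model=model, importances=importances, degenerate=degenerate)


@dataclass
class CVReport:
    """Cross-validated evaluation of one feature subspace."""

    subspace: str
    fold_scores: list[float]
    mean: float
    ci_half_width: float  # t-based 95% half-width over the fold scores
    importances: pd.Series = field(repr=False)  # from a refit on all rows

    def to_dict(self) -> dict:
        return {
            "subspace": self.subspace,
            "fold_scores": self.fold_scores,
            "mean": self.mean,
            "ci_half_width": self.ci_half_width,
            "importances": self.importances.to_dict(),
        }


def stratified_cv(
    table: pd.DataFrame,
    subspace: str = "complete",
    k: int = 5,
    seed: int = 0,
    params: Mapping | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of one subspace.

    Folds preserve the class ratio within one instance; instance weights
    are recomputed on each training fold.  The reported importances come
    from a refit on the full table.  The 95% interval half-width is
    t(0.975, k-1) * sd(fold scores) / sqrt(k).
    """
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    if n_min < k:
        raise ValueError(
            f"minority class has {n_min} instances, fewer than k={k} folds; use a smaller k"
        )
    X = subspace_select(table, subspace)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = train_classifier(
            X.iloc[tr], y[tr], compute_weights(y[tr]), seed=seed + fold, params=params
        )
        scores.append(balanced_accuracy(y[te], clf.predict(X.iloc[te])))
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    half = float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k))
    full = train_classifier(X, y, compute_weights(y), seed=seed, params=params)
    return CVReport(
        subspace=subspace,
        fold_scores=[float(s) for s in scores],
        mean=mean,
        ci_half_width=half,
        importances=full.importances,
    )
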