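"""Euploidy prediction: printed decision rules, model benchmark, evaluation.

Two prediction paths:

* an interpretable rule classifier with the thresholds read off the
  published decision tree — a blastocyst is called euploid when its TE
  cell count exceeds 94, or when its TE cell size variance is at most
  478 um^2 while its ICM area exceeds 8007 um^2;
* a six-model benchmark harness (logistic regression, decision tree,
  XGBoost, random forest, SVM, multilayer perceptron) with stratified
  80/20 splitting, k-fold AUC-maximizing grid tuning, ROC operating
  point closest to (0, 1), and evaluation with exact Clopper-Pearson
  proportion CIs, DeLong AUC inference, McNemar accuracy comparison and
  permutation feature importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .synthgen import FEATURE_COLUMNS

# ---------------------------------------------------------------------------
# Rule classifier


@dataclass(frozen=True)
class RuleSet:
    """Decision thresholds extracted from the published decision tree."""

    te_count_threshold: float = 94.0  # cells, strict >
    variance_threshold: float = 478.0  # um^2, inclusive <=
    icm_threshold: float = 8007.0  # um^2, strict >

    def __post_init__(self) -> None:
        if min(self.te_count_threshold, self.variance_threshold, self.icm_threshold) <= 0:
            raise ValueError("rule thresholds must be positive")


def rule_classify(
    te_count, te_size_variance, icm_area_um2, rules: RuleSet | None = None
):
    """Predict euploid (1) / non-euploid (0) from the printed rules.

    Euploid iff ``te_count > 94`` or
    (``te_size_variance <= 478`` and ``icm_area > 8007``); the strict and
    non-strict inequalities follow the printed rules exactly.  Accepts
    scalars or arrays.
    """
    r = rules or RuleSet()
    count = np.asarray(te_count, dtype=float)
    var = np.asarray(te_size_variance, dtype=float)
    icm = np.asarray(icm_area_um2, dtype=float)
    rule1 = count > r.te_count_threshold
    rule2 = (var <= r.variance_threshold) & (icm > r.icm_threshold)
    out = (rule1 | rule2).astype(int)
    return out if out.ndim else int(out)


def rule_decomposition(table: pd.DataFrame, rules: RuleSet | None = None) -> dict:
    """How the euploid calls decompose over the two rules.

    Counts, among truly euploid blastocysts, those satisfying rule 1
    (TE count above threshold) and those additionally captured only by
    rule 2 (low size variance and large ICM).
    """
    r = rules or RuleSet()
    eu = table[table["euploid"] == 1]
    rule1 = eu["te_count"] > r.te_count_threshold
    rule2 = (eu["te_size_variance"] <= r.variance_threshold) & (
        eu["icm_area_um2"] > r.icm_threshold
    )
    return {
        "euploid_total": int(len(eu)),
        "euploid_via_rule1": int(rule1.sum()),
        "euploid_added_by_rule2": int((~rule1 & rule2).sum()),
    }


# ---------------------------------------------------------------------------
# Benchmark harness


def split_train_test(
    table: pd.DataFrame,
    test_frac: float = 0.2,
    stratify: bool = True,
    seed: int = 0,
    outcome_col: str = "euploid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, stratified and seeded train/test split."""
    y = table[outcome_col]
    if stratify and y.value_counts().min() < 2:
        raise ValueError("each class needs >= 2 members for a stratified split")
    n_test = int(round(test_frac * len(table)))  # 20% of 226 -> 45
    train, test = train_test_split(
        table,
        test_size=n_test,
        stratify=y if stratify else None,
        random_state=seed,
    )
    return train, test


MODEL_REGISTRY = ("LR", "DT", "XGBoost", "RF", "SVM", "MLP")


def _model_and_grid(name: str, seed: int):
    if name == "LR":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        )
        grid = {"clf__C": [0.1, 1.0, 10.0]}
    elif name == "DT":
        est = DecisionTreeClassifier(random_state=seed)
        grid = {"max_depth": [2, 3, 4, 5], "min_samples_leaf": [1, 5, 10]}
    elif name == "XGBoost":
        est = XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, tree_method="hist"
        )
        grid = {
            "n_estimators": [50, 100],
            "max_depth": [2, 3],
            "learning_rate": [0.1, 0.3],
        }
    elif name == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
        grid = {"n_estimators": [100], "max_depth": [3, 5, None]}
    elif name == "SVM":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]
        )
        grid = {"clf__C": [0.5, 1.0, 5.0], "clf__gamma": ["scale", 0.1]}
    elif name == "MLP":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(max_iter=3000, random_state=seed),
                ),
            ]
        )
        grid = {"clf__hidden_layer_sizes": [(8,), (16,)], "clf__alpha": [1e-3, 1e-2]}
    else:
        raise ValueError(f"unknown model {name!r}; registry: {MODEL_REGISTRY}")
    return est, grid


@dataclass
class FittedScorer:
    """A tuned classifier exposing a calibrated score in [0, 1]."""

    name: str
    estimator: object
    best_params: dict
    cv_auc: float
    features: list[str]

    def score(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


def tune_and_train(
    model_name: str,
    train: pd.DataFrame,
    features: list[str] | None = None,
    outcome_col: str = "euploid",
    k: int = 5,
    seed: int = 0,
) -> FittedScorer:
    """Grid-tune one model by k-fold mean validation AUC, refit on train."""
    features = features or FEATURE_COLUMNS
    est, grid = _model_and_grid(model_name, seed)
    X = train[features].to_numpy(dtype=float)
    y = train[outcome_col].to_numpy(dtype=int)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
    search.fit(X, y)
    return FittedScorer(
        name=model_name,
        estimator=search.best_estimator_,
        best_params=search.best_params_,
        cv_auc=float(search.best_score_),
        features=list(features),
    )


# ---------------------------------------------------------------------------
# ROC threshold and evaluation


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating threshold closest to the ROC top-left point (0, 1).

    Candidates are midpoints between consecutive sorted unique scores;
    ties break toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("constant scores: no discrimination")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    npos, nneg = (y == 1).sum(), (y == 0).sum()
    best = None
    for t in cands:
        pred = s > t
        sens = (pred & (y == 1)).sum() / npos
        spec = (~pred & (y == 0)).sum() / nneg
        d = np.hypot(1 - sens, 1 - spec)
        key = (d, -spec)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI via the beta-quantile formulation."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values (structural components) and the Mann-Whitney AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    return auc, v10, v01, m, n


def auc_with_ci(scores, labels, conf: float = 0.95) -> tuple[float, float, float]:
    """Mann-Whitney AUC with a DeLong variance, logit-transformed CI."""
    auc, v10, v01, m, n = _placements(scores, labels)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0 or auc in (0.0, 1.0):
        # degenerate: fall back to exact binomial bound on the m*n pair wins
        wins = int(round(auc * m * n))
        lo, hi = clopper_pearson(wins, m * n, conf)
        return float(auc), lo, hi
    z = stats.norm.ppf(0.5 + conf / 2)
    logit = np.log(auc / (1 - auc))
    se_logit = np.sqrt(var) / (auc * (1 - auc))
    lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    return float(auc), float(lo), float(hi)


@dataclass
class ModelEval:
    """Threshold, confusion counts and all Table-style metrics with CIs."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: tuple[float, float, float]  # point, ci_low, ci_high
    specificity: tuple[float, float, float]
    precision: tuple[float, float, float]
    accuracy: tuple[float, float, float]
    auc: tuple[float, float, float] | None = None
    extras: dict = field(default_factory=dict)


def evaluate(
    labels: np.ndarray,
    predictions: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    threshold: float | None = None,
) -> ModelEval:
    """Confusion metrics with exact Clopper-Pearson 95% CIs (+AUC if scored)."""
    y = np.asarray(labels, dtype=int)
    if predictions is None:
        if scores is None or threshold is None:
            raise ValueError("provide predictions, or scores plus threshold")
        predictions = (np.asarray(scores, dtype=float) > threshold).astype(int)
    pred = np.asarray(predictions, dtype=int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def prop(k, n):
        if n == 0:
            return (np.nan, np.nan, np.nan)
        lo, hi = clopper_pearson(k, n)
        return (k / n, lo, hi)

    auc = None
    if scores is not None:
        auc = auc_with_ci(scores, y)
    return ModelEval(
        threshold=float(threshold) if threshold is not None else np.nan,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=prop(tp, tp + fn),
        specificity=prop(tn, tn + fp),
        precision=prop(tp, tp + fp),
        accuracy=prop(tp + tn, tp + tn + fp + fn),
        auc=auc,
    )


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong's paired comparison of two AUCs on the same specimens."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("paired scores must have equal lengths")
    auc_a, v10a, v01a, m, n = _placements(sa, y)
    auc_b, v10b, v01b, _, _ = _placements(sb, y)

    def cov(u, v, size):
        if size < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1]) / size

    var_a = cov(v10a, v10a, m) + cov(v01a, v01a, n)
    var_b = cov(v10b, v10b, m) + cov(v01b, v01b, n)
    cov_ab = cov(v10a, v10b, m) + cov(v01a, v01b, n)
    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 1e-15:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "auc_a": float(auc_a),
        "auc_b": float(auc_b),
        "var_a": var_a,
        "var_b": var_b,
        "covariance": cov_ab,
        "z": float(z),
        "p": p,
    }


def mcnemar_test(preds_a, preds_b, labels) -> dict:
    """Exact two-sided McNemar test on paired classification accuracy."""
    pa = np.asarray(preds_a, dtype=int)
    pb = np.asarray(preds_b, dtype=int)
    y = np.asarray(labels, dtype=int)
    correct_a, correct_b = pa == y, pb == y
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5))
    return {"b": b, "c": c, "p": float(p)}


def feature_importance(
    scorer: FittedScorer,
    table: pd.DataFrame,
    outcome_col: str = "euploid",
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop per shuffled feature.

    Uniform across all model types, so importances are comparable
    between the six benchmark models.  Returns features in descending
    importance order.
    """
    rng = np.random.default_rng(seed)
    y = table[outcome_col].to_numpy(dtype=int)
    base_auc, _, _, _, _ = _placements(scorer.score(table), y)
    rows = []
    for f in scorer.features:
        drops = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            auc, _, _, _, _ = _placements(scorer.score(shuffled), y)
            drops.append(base_auc - auc)
        rows.append({"feature": f, "importance": float(np.mean(drops))})
    return (
        pd.DataFrame(rows)
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


def benchmark(
    table: pd.DataFrame,
    models: tuple[str, ...] = MODEL_REGISTRY,
    seeds: tuple[int, ...] = (0,),
    k: int = 5,
    test_frac: float = 0.2,
    outcome_col: str = "euploid",
) -> pd.DataFrame:
    """Run the full split/tune/threshold/evaluate harness per model per seed.

    The published test-split seed is unknowable, so point metrics are
    reported as distributions over seeds rather than single numbers.
    """
    rows = []
    for seed in seeds:
        train, test = split_train_test(table, test_frac=test_frac, seed=seed)
        y_test = test[outcome_col].to_numpy(dtype=int)
        for name in models:
            scorer = tune_and_train(name, train, outcome_col=outcome_col, k=k, seed=seed)
            thr = roc_threshold(scorer.score(train), train[outcome_col].to_numpy(int))
            s = scorer.score(test)
            ev = evaluate(y_test, scores=s, threshold=thr)
            rows.append(
                {
                    "model": name,
                    "seed": seed,
                    "threshold": thr,
                    "cv_auc": scorer.cv_auc,
                    "sensitivity": ev.sensitivity[0],
                    "specificity": ev.specificity[0],
                    "precision": ev.precision[0],
                    "accuracy": ev.accuracy[0],
                    "auc": ev.auc[0],
                    "auc_ci_low": ev.auc[1],
                    "auc_ci_high": ev.auc[2],
                    "tp": ev.tp,
                    "fp": ev.fp,
                    "tn": ev.tn,
                    "fn": ev.fn,
                }
            )
    return pd.DataFrame(rows)
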