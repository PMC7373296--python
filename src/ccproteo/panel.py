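"""Consensus biomarker panel: three-classifier importance and CV evaluation.

Feature importance is measured three ways on the missingness-filtered
protein matrix (linear terms only, no covariates): L1-logistic selection
frequency over repeated 80/20 holdouts (penalty chosen per split by inner
10-fold cross-validated deviance), random-forest out-of-bag permutation
importance (Breiman's mean decrease in accuracy), and gradient-boosting
total split gain.  The panel is the intersection of the three top-k sets
(default k = 20) and is evaluated by repeated stratified 80/20 holdout
with three classifiers (plain logistic regression replacing the Lasso),
summarizing per-iteration AUROC with a percentile interval.

Because only linear terms enter the classifiers, proteins whose
association with the outcome is purely quadratic (U-shaped) are expected
to be filtered out by the consensus rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "ImportanceScores",
    "PanelSpec",
    "CVResult",
    "auroc",
    "roc_points",
    "lasso_selection_frequency",
    "rf_permutation_importance",
    "boost_gain_importance",
    "compute_importances",
    "consensus_panel",
    "evaluate_panel",
]


@dataclass
class ImportanceScores:
    """Per-protein importance under the three measures, with ranks.

    ``table`` columns: direction, lasso_pct, rank_lasso, rf_mda, rank_rf,
    boost_gain, rank_boost.  Rank 1 = most important; within each measure
    ranks are a permutation of 1..P (ties broken by higher lasso
    fraction, then protein id).
    """

    table: pd.DataFrame


@dataclass
class PanelSpec:
    proteins: list[str]
    k: int
    outcome_contrast: str = "all"


@dataclass
class CVResult:
    classifier: str
    aurocs: np.ndarray
    mean_auroc: float
    ci95: tuple[float, float]
    roc: pd.DataFrame  # pooled (fpr, tpr)


def auroc(scores, labels) -> float:
    """Rank-statistic AUROC: P(case score > control score) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve with one threshold per distinct score.

    Starts at (0, 0), ends at (1, 1); the trapezoidal area equals the
    rank-statistic AUROC (up to float rounding).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    fpr = np.r_[0.0, fp / n0]
    tpr = np.r_[0.0, tp / n1]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
    train = np.concatenate(train_idx)
    mask = np.zeros(y.size, dtype=bool)
    mask[train] = True
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def lasso_selection_frequency(
    X: pd.DataFrame,
    y,
    iterations: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    inner_cv: int = 10,
) -> pd.Series:
    """Fraction of holdout iterations in which each protein's L1 coefficient
    is nonzero.

    Each iteration draws a stratified 80% training split, standardizes the
    predictors on that split, picks the L1 penalty by ``inner_cv``-fold
    cross-validated deviance, refits at that penalty, and records the
    nonzero pattern.  An iteration whose training split cannot support the
    inner CV (a class smaller than the fold count) is redrawn from an
    advanced substream and logged.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1])
    redraws = 0
    done = 0
    while done < iterations:
        tr, _ = _stratified_split(y, train_frac, rng)
        ytr = y[tr]
        n_min = min((ytr == 0).sum(), (ytr == 1).sum())
        cv = min(inner_cv, int(n_min))
        if cv < 2:
            redraws += 1
            if redraws > 10 * iterations:
                raise ValueError("cannot draw a usable training split")
            continue
        Xtr = Xv[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        model = LogisticRegressionCV(
            Cs=10, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", random_state=0, n_jobs=1, max_iter=200,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        counts += (np.abs(model.coef_[0]) > 0).astype(float)
        done += 1
    if redraws:
        warnings.warn(f"redrew {redraws} degenerate training split(s)", stacklevel=2)
    return pd.Series(counts / iterations, index=X.columns, name="lasso_pct")


def rf_permutation_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | int = "sqrt",
) -> pd.Series:
    """Out-of-bag permutation importance (mean decrease in accuracy).

    Explicit bagging over decision trees: each tree is fit on a bootstrap
    sample; its out-of-bag accuracy is compared with the accuracy after
    permuting one predictor's out-of-bag values; the drop is averaged over
    trees.  Unimportant predictors score near zero (either sign within
    noise).  Constant predictors get importance 0 with a warning.
    """
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    constant = np.ptp(Xv, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant protein column(s) get zero importance: "
            f"{list(X.columns[constant])[:5]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(Xv[boot], y[boot])
        X_oob = Xv[oob]
        y_oob = y[oob]
        base = (tree.predict(X_oob) == y_oob).mean()
        feats = np.flatnonzero(tree.feature_importances_ > 0)
        for j in feats:
            if constant[j]:
                continue
            col = X_oob[:, j].copy()
            X_oob[:, j] = col[rng.permutation(oob.size)]
            perm_acc = (tree.predict(X_oob) == y_oob).mean()
            X_oob[:, j] = col
            drops[j] += base - perm_acc
        used += 1  # unused features contribute a zero drop on every tree
    if used.max() == 0:
        raise ValueError("no tree produced an out-of-bag sample")
    return pd.Series(drops / used, index=X.columns, name="rf_mda")


def boost_gain_importance(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    n_rounds: int = 200,
    max_depth: int = 3,
    learning_rate: float = 0.1,
) -> pd.Series:
    """Gradient-boosted-trees total split gain per protein, normalized to 1.

    Single-thread, fixed-seed, exact tree method for determinism.  Raises
    if the model makes no splits at all.
    """
    y = np.asarray(y, dtype=int)
    model = XGBClassifier(
        n_estimators=n_rounds, max_depth=max_depth, learning_rate=learning_rate,
        nthread=1, random_state=seed, tree_method="exact",
        eval_metric="logloss", base_score=0.5,
    )
    model.fit(X.to_numpy(dtype=float), y)
    booster = model.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    if not raw:
        raise ValueError("boosted model made zero splits; gain undefined")
    gains = np.zeros(X.shape[1])
    for name, g in raw.items():
        gains[int(name[1:])] = g  # feature names are f0, f1, ...
    return pd.Series(gains / gains.sum(), index=X.columns, name="boost_gain")


def _rank(primary: pd.Series, lasso: pd.Series) -> pd.Series:
    """Rank 1 = most important; ties by higher lasso fraction then protein id."""
    order = sorted(
        primary.index,
        key=lambda prot: (-primary[prot], -lasso[prot], prot),
    )
    return pd.Series({prot: i + 1 for i, prot in enumerate(order)})


def compute_importances(
    X: pd.DataFrame,
    y,
    iterations: int = 1000,
    seed: int = 0,
    n_trees: int = 500,
    boost_rounds: int = 200,
) -> ImportanceScores:
    """All three importance measures on the same (filtered) protein matrix.

    The lasso measure aggregates over holdout iterations; the forest and
    boosting importances come from full-data fits.  ``direction`` is the
    sign of the case-minus-control mean level.
    """
    y = np.asarray(y, dtype=int)
    ss = np.random.SeedSequence(seed)
    s_lasso, s_rf, s_boost = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    lasso = lasso_selection_frequency(X, y, iterations=iterations, seed=s_lasso)
    rf = rf_permutation_importance(X, y, n_trees=n_trees, seed=s_rf)
    boost = boost_gain_importance(X, y, seed=s_boost, n_rounds=boost_rounds)
    diff = X.loc[y == 1].mean(axis=0) - X.loc[y == 0].mean(axis=0)
    table = pd.DataFrame({
        "direction": np.where(diff >= 0, "increased", "decreased"),
        "lasso_pct": lasso,
        "rank_lasso": _rank(lasso, lasso),
        "rf_mda": rf,
        "rank_rf": _rank(rf, lasso),
        "boost_gain": boost,
        "rank_boost": _rank(boost, lasso),
    })
    table.index.name = "protein"
    return ImportanceScores(table)


def consensus_panel(scores: ImportanceScores, k: int = 20,
                    outcome_contrast: str = "all") -> PanelSpec:
    """Proteins ranked in the top k under all three measures.

    An empty intersection yields an explicit empty panel with a warning
    (downstream evaluation refuses to run on it).
    """
    t = scores.table
    in_all = (t["rank_lasso"] <= k) & (t["rank_rf"] <= k) & (t["rank_boost"] <= k)
    chosen = t.index[in_all]
    ordered = sorted(chosen, key=lambda prot: (-t.loc[prot, "lasso_pct"], prot))
    if not ordered:
        warnings.warn("consensus panel is empty: the three top-k sets do not "
                      "intersect", stacklevel=2)
    return PanelSpec(proteins=list(ordered), k=k, outcome_contrast=outcome_contrast)


def _make_classifier(name: str, seed: int, n_trees: int, boost_rounds: int):
    if name == "logistic":
        return LogisticRegression(penalty=None, max_iter=1000)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if name == "boosted_trees":
        return XGBClassifier(
            n_estimators=boost_rounds, max_depth=3, learning_rate=0.1,
            nthread=1, random_state=seed, tree_method="exact",
            eval_metric="logloss", base_score=0.5,
        )
    raise ValueError(f"unknown classifier {name!r}")


def evaluate_panel(
    X: pd.DataFrame,
    y,
    iterations: int = 1000,
    split: float = 0.8,
    seed: int = 0,
    classifiers: tuple[str, ...] = ("logistic", "random_forest", "boosted_trees"),
    n_trees: int = 500,
    boost_rounds: int = 200,
) -> dict[str, CVResult]:
    """Repeated stratified 80/20 holdout AUROC for the panel proteins.

    Per iteration each classifier is fit on the training split and scored
    on the test split; the per-iteration AUROCs are summarized by their
    mean and 2.5-97.5 percentile interval, and test-set scores are pooled
    across iterations into one ROC curve per classifier.
    """
    if X.shape[1] == 0:
        raise ValueError("panel is empty; nothing to evaluate")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two subjects per class to split")
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    aucs: dict[str, list[float]] = {c: [] for c in classifiers}
    pooled_scores: dict[str, list[np.ndarray]] = {c: [] for c in classifiers}
    pooled_labels: list[np.ndarray] = []
    for it in range(iterations):
        tr, te = _stratified_split(y, split, rng)
        pooled_labels.append(y[te])
        for name in classifiers:
            clf = _make_classifier(name, seed=int(rng.integers(2**31)),
                                   n_trees=n_trees, boost_rounds=boost_rounds)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xv[tr], y[tr])
                s = clf.predict_proba(Xv[te])[:, 1]
            aucs[name].append(auroc(s, y[te]))
            pooled_scores[name].append(s)
    labels_all = np.concatenate(pooled_labels)
    out = {}
    for name in classifiers:
        arr = np.asarray(aucs[name])
        ci = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
        roc = roc_points(np.concatenate(pooled_scores[name]), labels_all)
        out[name] = CVResult(
            classifier=name, aurocs=arr, mean_auroc=float(arr.mean()),
            ci95=ci, roc=roc,
        )
    return out
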