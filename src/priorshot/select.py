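"""Consensus biomarker selection: LASSO, SVM-RFE, random-forest importance.

Three selectors are run on a (samples x candidate genes) table with binary
labels and their selected lists intersected (Venn consensus):

* L1-penalised logistic regression along a lambda path with K-fold
  cross-validated deviance (``lambda_min`` or ``lambda_1se`` rule).
* SVM-RFE: a linear soft-margin SVM is refit while features with the
  smallest squared weight w_j^2 are eliminated; the surviving subset with
  the best cross-validated accuracy is kept (ties favour the smaller set).
* A bagged forest of CART trees with Gini splitting, scored by out-of-bag
  error, mean decrease in impurity (MDI) and OOB permutation importance.
  The forest is assembled here from individual trees so bootstrap/OOB
  membership is explicit and the importance formulas are computed from the
  fitted tree structures rather than read from a library summary.

Gini importance is reported on two scales: ``mdi`` normalises the impurity
decrease by the bootstrap sample size (values O(1/n) per split), while
``mean_decrease_gini`` is the count-scale sum familiar from R's
randomForest, to which the default selection threshold (> 3) applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .calibrate import roc_auc

__all__ = ["SelectorResult", "lasso_select", "svm_rfe", "rf_importance",
           "consensus_intersect", "auc_screen", "ConsensusSelector"]


@dataclass
class SelectorResult:
    """Outcome of one selector: ordered selected features + diagnostics."""

    method: str
    selected: list[str]
    diagnostics: dict = field(default_factory=dict)


def _check_table(X, y):
    if isinstance(X, pd.DataFrame):
        features = X.columns.tolist()
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        features = [f"f{i}" for i in range(Xv.shape[1])]
    if np.isnan(Xv).any():
        raise ValueError("feature table contains missing values")
    y = np.asarray(pd.Series(y).to_numpy(), dtype=int)
    if Xv.shape[0] != y.size:
        raise ValueError("X and y have different sample counts")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return Xv, y, features


# ---------------------------------------------------------------------- #
# LASSO

def _lambda_path(X, y, n_lambdas=50, ratio=1e-2):
    # glmnet-style: start where the first coefficient would enter; the
    # path stops at ratio*lambda_max, where the fit is near-unpenalised
    r = y - y.mean()
    lam_max = np.abs(X.T @ r).max() / X.shape[0]
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1.05, lam_max * ratio, n_lambdas)


def lasso_select(X, y, folds: int = 10, rule: str = "lambda_min",
                 seed: int = 0, lambdas=None) -> SelectorResult:
    """L1-logistic selection along a cross-validated lambda path.

    The objective per lambda is the penalised logit deviance (solved by
    liblinear with C = 1/lambda); the path's lambda is chosen by K-fold
    cross-validated binomial deviance under ``rule``:

    * ``lambda_min`` — minimiser of the mean CV deviance;
    * ``lambda_1se`` — sparsest lambda within one standard error of it.

    Selected features are those with nonzero coefficients at the chosen
    lambda, ordered by decreasing |coefficient|.
    """
    Xv, y, features = _check_table(X, y)
    if rule not in ("lambda_min", "lambda_1se"):
        raise ValueError(f"unknown rule {rule!r}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} samples for {folds}-fold CV "
            f"(have {counts.tolist()})"
        )
    lambdas = (np.asarray(lambdas, float) if lambdas is not None
               else _lambda_path(Xv, y))

    def fit_at(lam, Xs, ys):
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=2000,
            tol=1e-3,
        ).fit(Xs, ys)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xv, y))
    dev = np.zeros((len(lambdas), folds))
    for li, lam in enumerate(lambdas):
        for fi, (tr, te) in enumerate(splits):
            m = fit_at(lam, Xv[tr], y[tr])
            p = m.predict_proba(Xv[te])[:, 1]
            dev[li, fi] = 2.0 * log_loss(y[te], p, labels=[0, 1])
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(folds)
    i_min = int(mean_dev.argmin())
    if rule == "lambda_min":
        i_sel = i_min
    else:
        ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(ok).min())  # path is ordered large -> small
    final = fit_at(lambdas[i_sel], Xv, y)
    coef = final.coef_.ravel()
    order = np.argsort(-np.abs(coef), kind="stable")
    selected = [features[j] for j in order if coef[j] != 0.0]
    return SelectorResult(
        method="lasso", selected=selected,
        diagnostics={
            "lambdas": lambdas.tolist(), "cv_deviance": mean_dev.tolist(),
            "cv_se": se_dev.tolist(), "lambda_chosen": float(lambdas[i_sel]),
            "rule": rule, "coefficients": dict(zip(features, coef.tolist())),
        },
    )


# ---------------------------------------------------------------------- #
# SVM-RFE

def svm_rfe(X, y, C: float = 1.0, eliminate_per_round: int = 1,
            folds: int = 5, seed: int = 0, min_features: int = 1
            ) -> SelectorResult:
    """Recursive feature elimination ranking features by squared SVM weight.

    Each round fits a linear soft-margin SVM on the remaining features,
    ranks them by w_j^2 and drops the lowest ``eliminate_per_round`` (the
    final round never drops below ``min_features``).  Every visited subset
    is scored by seeded stratified K-fold accuracy; the best-accuracy
    subset is selected, smaller subsets winning ties.
    """
    if C <= 0:
        raise ValueError("C must be > 0")
    Xv, y, features = _check_table(X, y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    remaining = list(range(len(features)))
    eliminated: list[int] = []
    path: list[dict] = []
    rankings: list[dict[str, float]] = []
    while True:
        svc = SVC(kernel="linear", C=C)
        acc = cross_val_score(svc, Xv[:, remaining], y, cv=skf,
                              scoring="accuracy").mean()
        svc.fit(Xv[:, remaining], y)
        w2 = (svc.coef_.ravel() ** 2)
        rankings.append({features[j]: float(w) for j, w in zip(remaining, w2)})
        path.append({"subset": [features[j] for j in remaining],
                     "cv_accuracy": float(acc)})
        if len(remaining) <= min_features:
            break
        n_drop = min(eliminate_per_round, len(remaining) - min_features)
        drop = np.argsort(w2, kind="stable")[:n_drop]
        for j in sorted(drop, reverse=True):
            eliminated.append(remaining.pop(int(j)))
    # best CV accuracy; ties -> smaller subset (scan path backwards)
    best = max(reversed(path), key=lambda p: p["cv_accuracy"])
    return SelectorResult(
        method="svm_rfe", selected=list(best["subset"]),
        diagnostics={
            "path": path, "rankings": rankings, "C": C,
            "elimination_order": [features[j] for j in eliminated],
            "best_cv_accuracy": best["cv_accuracy"],
        },
    )


# ---------------------------------------------------------------------- #
# Random forest

def rf_importance(X, y, n_trees: int = 500, mtry: int | str = "sqrt",
                  seed: int = 0, mdi_threshold: float = 3.0,
                  threshold_mode: str = "gini",
                  fraction_of_max: float = 0.05) -> SelectorResult:
    """Bagged-forest feature importance with native OOB bookkeeping.

    Fits ``n_trees`` CART trees (Gini splitting, ``mtry`` features per
    split) on bootstrap samples; computes the forest OOB error, per-feature
    MDI (impurity decrease weighted by the fraction of samples reaching the
    node, averaged over trees) and OOB permutation importance in the
    difference form ``e_perm - e_orig`` (ratio form in diagnostics).

    Selection: ``threshold_mode="gini"`` keeps features whose count-scale
    MeanDecreaseGini exceeds ``mdi_threshold``; ``"fraction"`` keeps those
    with MDI >= ``fraction_of_max`` of the largest MDI.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    Xv, y, features = _check_table(X, y)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)

    mdi_sum = np.zeros(p)
    mdg_sum = np.zeros(p)
    votes = np.zeros((n, 2))
    fi_diff_sum = np.zeros(p)
    fi_ratio_sum = np.zeros(p)
    n_perm_trees = 0

    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(Xv[boot], y[boot])

        t = tree.tree_
        node_feat = t.feature
        internal = node_feat >= 0
        wn = t.weighted_n_node_samples
        delta = (wn[internal] * t.impurity[internal]
                 - wn[t.children_left[internal]] * t.impurity[t.children_left[internal]]
                 - wn[t.children_right[internal]] * t.impurity[t.children_right[internal]])
        np.add.at(mdg_sum, node_feat[internal], delta)
        np.add.at(mdi_sum, node_feat[internal], delta / n)

        if oob.size:
            pred = tree.predict(Xv[oob])
            votes[oob, pred] += 1.0
            e_orig = float(np.mean(pred != y[oob]))
            # one batched predict over all per-feature permuted copies
            reps = np.repeat(Xv[oob][None, :, :], p, axis=0)
            for j in range(p):
                reps[j, :, j] = rng.permutation(Xv[oob, j])
            perm_pred = tree.predict(reps.reshape(-1, p)).reshape(p, oob.size)
            e_perm = (perm_pred != y[oob]).mean(axis=1)
            fi_diff_sum += e_perm - e_orig
            with np.errstate(divide="ignore", invalid="ignore"):
                fi_ratio_sum += np.where(e_orig > 0, e_perm / e_orig - 1.0, 0.0)
            n_perm_trees += 1

    covered = votes.sum(axis=1) > 0
    if not covered.any():
        warnings.warn("no out-of-bag coverage; OOB error and permutation "
                      "importance are undefined", stacklevel=2)
        oob_error = float("nan")
        fi_diff = np.full(p, np.nan)
        fi_ratio = np.full(p, np.nan)
    else:
        oob_pred = votes.argmax(axis=1)
        oob_error = float(np.mean(oob_pred[covered] != y[covered]))
        fi_diff = fi_diff_sum / n_perm_trees
        fi_ratio = fi_ratio_sum / n_perm_trees

    mdi = mdi_sum / n_trees
    mdg = mdg_sum / n_trees
    if threshold_mode == "gini":
        keep = mdg > mdi_threshold
    elif threshold_mode == "fraction":
        keep = mdi >= fraction_of_max * mdi.max()
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    order = np.argsort(-mdg, kind="stable")
    selected = [features[j] for j in order if keep[j]]
    return SelectorResult(
        method="random_forest", selected=selected,
        diagnostics={
            "oob_error": oob_error,
            "mdi": dict(zip(features, mdi.tolist())),
            "mean_decrease_gini": dict(zip(features, mdg.tolist())),
            "permutation_importance": dict(zip(features, fi_diff.tolist())),
            "permutation_importance_ratio": dict(zip(features, fi_ratio.tolist())),
            "n_trees": n_trees, "threshold_mode": threshold_mode,
            "mdi_threshold": mdi_threshold,
        },
    )


# ---------------------------------------------------------------------- #

def consensus_intersect(a: SelectorResult, b: SelectorResult,
                        c: SelectorResult) -> list[str]:
    """Venn intersection of the three selected lists, in ``a``'s order."""
    common = set(a.selected) & set(b.selected) & set(c.selected)
    return [g for g in a.selected if g in common]


def auc_screen(X, y, genes=None, threshold: float = 0.7) -> pd.DataFrame:
    """Per-gene discriminative screen by direction-aware ROC AUC.

    For each gene the larger of the two direction-specific AUCs is
    reported, with its direction ("up": higher in cases); a gene passes iff
    AUC strictly exceeds ``threshold``.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    _, y, _ = _check_table(X, y)
    genes = X.columns.tolist() if genes is None else list(genes)
    rows = []
    for g in genes:
        auc, _, _ = roc_auc(X[g].to_numpy(), y)
        direction = "up" if auc >= 0.5 else "down"
        best = max(auc, 1.0 - auc)
        rows.append({"gene": g, "auc": best, "direction": direction,
                     "passed": best > threshold})
    return pd.DataFrame(rows).set_index("gene")


class ConsensusSelector(BaseEstimator):
    """Run all three selectors and intersect their gene lists.

    Fitted attributes: ``results_`` (per-method SelectorResult) and
    ``selected_`` (the consensus list, LASSO order).
    """

    def __init__(self, lasso_folds: int = 10, lasso_rule: str = "lambda_min",
                 svm_C: float = 1.0, eliminate_per_round: int = 1,
                 n_trees: int = 500, mdi_threshold: float = 3.0,
                 threshold_mode: str = "gini", random_state: int = 0):
        self.lasso_folds = lasso_folds
        self.lasso_rule = lasso_rule
        self.svm_C = svm_C
        self.eliminate_per_round = eliminate_per_round
        self.n_trees = n_trees
        self.mdi_threshold = mdi_threshold
        self.threshold_mode = threshold_mode
        self.random_state = random_state

    def fit(self, X, y):
        res_l = lasso_select(X, y, folds=self.lasso_folds,
                             rule=self.lasso_rule, seed=self.random_state)
        res_s = svm_rfe(X, y, C=self.svm_C,
                        eliminate_per_round=self.eliminate_per_round,
                        seed=self.random_state)
        res_r = rf_importance(X, y, n_trees=self.n_trees,
                              seed=self.random_state,
                              mdi_threshold=self.mdi_threshold,
                              threshold_mode=self.threshold_mode)
        self.results_ = {"lasso": res_l, "svm_rfe": res_s, "random_forest": res_r}
        self.selected_ = consensus_intersect(res_l, res_s, res_r)
        return self
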