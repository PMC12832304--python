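"""Discrimination, calibration and clinical-utility metrics.

* ``roc_auc``: tie-corrected rank-statistic AUC (probability that a random
  case outscores a random control, ties counted 1/2) plus ROC points.
* ``brier``: mean squared difference between predicted probability and the
  binary outcome.
* ``fit_calibration``: Platt scaling (sigmoid) vs isotonic regression,
  compared by cross-validated Brier score on seeded stratified folds; the
  winner is refit on all data.  Ties go to Platt (the simpler map).
* ``decision_curve``: net benefit NB(p_t) = TP/n - (FP/n) p_t/(1-p_t)
  against treat-all and treat-none policies over a threshold grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = ["CalibrationMap", "DCAResult", "roc_auc", "brier",
           "fit_calibration", "decision_curve"]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be in {0, 1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC via the Mann-Whitney rank statistic; returns (auc, fpr, tpr)."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return float(auc), fpr, tpr


def brier(probs, labels) -> float:
    """Mean squared error between probabilities and binary outcomes."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=int)
    return float(np.mean((p - y) ** 2))


class _PlattMap:
    """Sigmoid score -> probability map fitted by logistic regression."""

    def __init__(self):
        self._lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)

    def fit(self, scores, labels):
        self._lr.fit(np.asarray(scores, float).reshape(-1, 1),
                     np.asarray(labels, int))
        return self

    def predict(self, scores):
        return self._lr.predict_proba(
            np.asarray(scores, float).reshape(-1, 1))[:, 1]

    @property
    def is_monotone_increasing(self) -> bool:
        return bool(self._lr.coef_[0, 0] >= 0)


class _IsotonicMap:
    def __init__(self):
        self._iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                                       out_of_bounds="clip")

    def fit(self, scores, labels):
        self._iso.fit(np.asarray(scores, float), np.asarray(labels, int))
        return self

    def predict(self, scores):
        return self._iso.predict(np.asarray(scores, float))


@dataclass
class CalibrationMap:
    """Monotone score -> probability mapping chosen by cross-validated Brier."""

    method: str                      # "platt" or "isotonic"
    cv_brier: dict[str, float]
    folds: int
    seed: int
    _fitted: object = field(repr=False, default=None)

    def predict(self, scores) -> np.ndarray:
        p = np.clip(self._fitted.predict(scores), 0.0, 1.0)
        return p


def _cv_brier(scores, y, make_map, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.empty_like(scores)
    for tr, te in skf.split(scores.reshape(-1, 1), y):
        m = make_map().fit(scores[tr], y[tr])
        sq_err[te] = (np.clip(m.predict(scores[te]), 0, 1) - y[te]) ** 2
    return float(sq_err.mean())


def fit_calibration(scores, labels, folds: int = 5, seed: int = 0) -> CalibrationMap:
    """Fit Platt and isotonic calibration; keep the lower cross-validated Brier.

    With fewer than two distinct scores isotonic regression is degenerate
    and the method falls back to Platt with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    if s.size < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if np.unique(s).size < 2:
        warnings.warn("fewer than 2 distinct scores; falling back to Platt "
                      "scaling", stacklevel=2)
        fitted = _PlattMap().fit(s, y)
        return CalibrationMap(method="platt", cv_brier={}, folds=folds,
                              seed=seed, _fitted=fitted)
    cv = {
        "platt": _cv_brier(s, y, _PlattMap, folds, seed),
        "isotonic": _cv_brier(s, y, _IsotonicMap, folds, seed),
    }
    method = "isotonic" if cv["isotonic"] < cv["platt"] else "platt"
    fitted = (_IsotonicMap() if method == "isotonic" else _PlattMap()).fit(s, y)
    return CalibrationMap(method=method, cv_brier=cv, folds=folds, seed=seed,
                          _fitted=fitted)


@dataclass
class DCAResult:
    """Net-benefit curves for the model, treat-all and treat-none policies."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "threshold": self.thresholds, "model": self.net_benefit,
            "treat_all": self.treat_all, "treat_none": self.treat_none,
        })


def decision_curve(probs, labels, grid=None) -> DCAResult:
    """Decision-curve analysis over a probability-threshold grid.

    Positives are called at p >= p_t.  Thresholds at exactly 0 or 1 are
    excluded (net benefit undefined) with a warning.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=int)
    grid = np.linspace(0.01, 0.99, 99) if grid is None else np.asarray(grid, float)
    if np.any((grid <= 0) | (grid >= 1)):
        warnings.warn("thresholds outside (0, 1) excluded from the DCA grid",
                      stacklevel=2)
        grid = grid[(grid > 0) & (grid < 1)]
    n = y.size
    prevalence = y.mean()
    nb = np.empty_like(grid)
    ta = np.empty_like(grid)
    for i, t in enumerate(grid):
        w = t / (1 - t)
        called = p >= t
        tp = np.sum(called & (y == 1)) / n
        fp = np.sum(called & (y == 0)) / n
        nb[i] = tp - fp * w
        ta[i] = prevalence - (1 - prevalence) * w
    return DCAResult(thresholds=grid, net_benefit=nb, treat_all=ta,
                     treat_none=np.zeros_like(grid))
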