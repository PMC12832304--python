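"""Episodic 2-way K-shot training and the few-shot relation classifier.

The classifier is an sklearn-style estimator over (samples x latent
features) inputs: ``fit`` runs episodic training with Adam, L2 weight decay
and dropout, checkpointing on validation AUC; ``decision_function`` returns
the raw risk score s(x) = r_{q,1} - r_{q,0} (the binary log-odds under the
temperature-1 softmax over relation scores).

Two inference strategies are provided:

* ``"kshot_ensemble"`` (default): average relation scores over M seeded
  draws of K support samples per class, so the set aggregator sees the
  support size it was trained with.
* ``"full_set"``: one pass with the entire labelled reference as support.

When the query carries sample ids that also occur in the reference, those
reference columns are excluded from that query's support draws, so a
training sample can be scored without comparing against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .relation import RelationNetwork

__all__ = ["Episode", "TrainConfig", "sample_episode", "episode_loss",
           "FewShotRelationClassifier"]


@dataclass
class Episode:
    """Index sets for one training episode (2-way, K-shot, Q queries/class)."""

    support: dict[int, np.ndarray]   # class -> K sample indices
    query: np.ndarray                # query sample indices (both classes)
    query_labels: np.ndarray         # class of each query

    def __post_init__(self):
        sup = np.concatenate(list(self.support.values()))
        if np.intersect1d(sup, self.query).size:
            raise ValueError("support and query index sets overlap")


@dataclass
class TrainConfig:
    """Hyperparameters of episodic training.

    Defaults follow the 2-way 5-shot design: 5 support and 5 query samples
    per class per episode, at most 1000 episodes, validation AUC checked
    every ``eval_every`` episodes with early stopping after ``patience``
    checks without improvement.
    """

    k_shot: int = 5
    queries_per_class: int = 5
    max_episodes: int = 1000
    tau: float = 1.0
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    dropout: float = 0.3
    eval_every: int = 10
    patience: int = 10
    aggregation: str = "sum"
    seed: int = 0

    def __post_init__(self):
        for name in ("k_shot", "queries_per_class", "max_episodes",
                     "eval_every", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")


def sample_episode(y: np.ndarray, k_shot: int, queries_per_class: int,
                   rng: np.random.Generator) -> Episode:
    """Draw a 2-way episode without replacement; support and query disjoint."""
    y = np.asarray(y, dtype=int)
    support: dict[int, np.ndarray] = {}
    q_idx, q_lab = [], []
    need = k_shot + queries_per_class
    for c in (0, 1):
        pool = np.flatnonzero(y == c)
        if pool.size < need:
            raise ValueError(
                f"class {c} has {pool.size} samples but an episode needs "
                f"{need} (K={k_shot} support + {queries_per_class} query)"
            )
        picked = rng.choice(pool, size=need, replace=False)
        support[c] = picked[:k_shot]
        q_idx.append(picked[k_shot:])
        q_lab.append(np.full(queries_per_class, c))
    return Episode(support=support, query=np.concatenate(q_idx),
                   query_labels=np.concatenate(q_lab))


def episode_loss(scores: np.ndarray, labels: np.ndarray, tau: float = 1.0) -> float:
    """Mean cross-entropy of temperature-softmaxed relation scores.

    ``scores``: (Q, 2) relation scores; ``labels``: either integer classes
    (Q,) or one-hot (Q, 2).
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    y = labels.argmax(axis=1) if labels.ndim == 2 else labels.astype(int)
    logits = scores / tau
    logits = logits - logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(scores.shape[0]), y].mean())


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    from .calibrate import roc_auc
    return roc_auc(scores, y)[0]


class FewShotRelationClassifier(BaseEstimator, ClassifierMixin):
    """2-way few-shot relation-network classifier over latent features.

    Parameters
    ----------
    strategy : {"kshot_ensemble", "full_set"}
        Inference-time support construction; see module docstring.
    n_ensemble : int
        Number of seeded support draws for ``kshot_ensemble``.
    val_fraction : float
        Stratified fraction of the fit data held out for early stopping
        when no explicit validation set is passed to ``fit``.
    """

    def __init__(self, k_shot: int = 5, queries_per_class: int = 5,
                 max_episodes: int = 1000, tau: float = 1.0,
                 learning_rate: float = 1e-3, weight_decay: float = 1e-4,
                 dropout: float = 0.3, eval_every: int = 10, patience: int = 10,
                 aggregation: str = "sum", hidden_dim: int = 128,
                 embed_dim: int = 64, phi_hidden: int = 64, rho_hidden: int = 32,
                 strategy: str = "kshot_ensemble", n_ensemble: int = 20,
                 val_fraction: float = 0.25, random_state: int = 0):
        self.k_shot = k_shot
        self.queries_per_class = queries_per_class
        self.max_episodes = max_episodes
        self.tau = tau
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.eval_every = eval_every
        self.patience = patience
        self.aggregation = aggregation
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.phi_hidden = phi_hidden
        self.rho_hidden = rho_hidden
        self.strategy = strategy
        self.n_ensemble = n_ensemble
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    @staticmethod
    def _as_arrays(X, y=None):
        ids = None
        if isinstance(X, pd.DataFrame):
            ids = X.index.astype(str).to_numpy()
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if y is not None:
            y = np.asarray(pd.Series(y).to_numpy(), dtype=int)
            if X.shape[0] != y.shape[0]:
                raise ValueError("X and y have different sample counts")
        return X, y, ids

    def fit(self, X, y, X_val=None, y_val=None):
        X, y, ids = self._as_arrays(X, y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            X_tr, y_tr, ids_tr, X_val, y_val = self._split_validation(X, y, ids, rng)
        else:
            X_tr, y_tr, ids_tr = X, y, ids
            X_val, y_val, _ = self._as_arrays(X_val, y_val)
        if len(np.unique(y_val)) < 2:
            raise ValueError("validation set has a single class; AUC undefined")

        net = RelationNetwork(
            input_dim=X_tr.shape[1], hidden_dim=self.hidden_dim,
            embed_dim=self.embed_dim, phi_hidden=self.phi_hidden,
            rho_hidden=self.rho_hidden, dropout=self.dropout,
            aggregation=self.aggregation,
            seed=int(rng.integers(2**31 - 1)),
        )
        opt = net.make_optimizer(self.learning_rate, self.weight_decay)

        support_full = {c: X_tr[y_tr == c] for c in (0, 1)}
        best_auc, best_state, best_checkpoint = -np.inf, net.get_state(), 0
        stale = 0
        log: list[dict] = []
        losses: list[float] = []
        for ep in range(1, self.max_episodes + 1):
            episode = sample_episode(y_tr, self.k_shot, self.queries_per_class, rng)
            loss, _ = net.episode_forward_backward(
                {c: X_tr[idx] for c, idx in episode.support.items()},
                X_tr[episode.query], episode.query_labels, self.tau, rng,
            )
            opt.step()
            losses.append(loss)
            if ep % self.eval_every == 0:
                h_val = net.encode(X_val)
                h_sup = {c: net.encode(v) for c, v in support_full.items()}
                r = net.relation_scores_from_embeddings(h_val, h_sup)
                val_auc = _auc(r[:, 1] - r[:, 0], y_val)
                log.append({"episode": ep,
                            "mean_loss": float(np.mean(losses[-self.eval_every:])),
                            "val_auc": val_auc})
                if val_auc > best_auc:
                    best_auc, best_state = val_auc, net.get_state()
                    best_checkpoint, stale = len(log), 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        net.set_state(best_state)

        self.network_ = net
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X_tr.shape[1]
        self.support_X_ = X_tr
        self.support_y_ = y_tr
        self.support_ids_ = ids_tr
        self.train_log_ = log
        self.episode_losses_ = losses
        self.best_checkpoint_ = best_checkpoint
        self.best_val_auc_ = best_auc
        return self

    def _split_validation(self, X, y, ids, rng):
        idx_val = []
        for c in (0, 1):
            pool = np.flatnonzero(y == c)
            n_val = max(1, int(round(self.val_fraction * pool.size)))
            idx_val.append(rng.permutation(pool)[:n_val])
        val = np.concatenate(idx_val)
        tr = np.setdiff1d(np.arange(y.size), val)
        ids_tr = ids[tr] if ids is not None else None
        return X[tr], y[tr], ids_tr, X[val], y[val]

    # ------------------------------------------------------------------ #
    def _check_reference(self, reference_X, reference_y, reference_ids):
        if reference_X is None:
            return self.support_X_, self.support_y_, self.support_ids_
        X, y, ids = self._as_arrays(reference_X, reference_y)
        return X, y, ids

    def relation_score_matrix(self, X, reference_X=None, reference_y=None,
                              strategy: str | None = None, seed: int = 0):
        """Per-query relation scores (n, 2) under the chosen strategy."""
        strategy = strategy or self.strategy
        if strategy not in ("full_set", "kshot_ensemble"):
            raise ValueError(f"unknown strategy {strategy!r}")
        Xq, _, q_ids = self._as_arrays(X)
        ref_X, ref_y, ref_ids = self._check_reference(reference_X, reference_y, None)
        for c in (0, 1):
            if not np.any(ref_y == c):
                raise ValueError(f"reference set has no samples of class {c}")
        rng = np.random.default_rng(seed)

        h_q_all = self.network_.encode(Xq)
        scores = np.empty((Xq.shape[0], 2))
        # queries sharing the same exclusion mask can be scored in one batch
        masks = self._exclusion_masks(q_ids, ref_ids, Xq.shape[0], ref_X.shape[0])
        for key in np.unique(masks):
            qsel = masks == key
            keep = np.ones(ref_X.shape[0], dtype=bool)
            if key >= 0:
                keep[key] = False
            scores[qsel] = self._score_batch(
                h_q_all[qsel], ref_X[keep], ref_y[keep], strategy, rng)
        return scores

    def _exclusion_masks(self, q_ids, ref_ids, n_q, n_ref):
        """Per-query index of the reference column to exclude (-1: none)."""
        out = np.full(n_q, -1)
        if q_ids is None or ref_ids is None:
            return out
        pos = {s: i for i, s in enumerate(ref_ids)}
        for i, s in enumerate(q_ids):
            out[i] = pos.get(s, -1)
        return out

    def _score_batch(self, h_q, ref_X, ref_y, strategy, rng):
        net = self.network_
        if strategy == "full_set":
            h_sup = {c: net.encode(ref_X[ref_y == c]) for c in (0, 1)}
            return net.relation_scores_from_embeddings(h_q, h_sup)
        total = np.zeros((h_q.shape[0], 2))
        for _ in range(self.n_ensemble):
            sup = {}
            for c in (0, 1):
                pool = np.flatnonzero(ref_y == c)
                k = min(self.k_shot, pool.size)
                sup[c] = net.encode(ref_X[rng.choice(pool, size=k, replace=False)])
            total += net.relation_scores_from_embeddings(h_q, sup)
        return total / self.n_ensemble

    def decision_function(self, X, reference_X=None, reference_y=None,
                          strategy: str | None = None, seed: int = 0):
        """Raw risk score s(x) = r_{q,1} - r_{q,0} per query."""
        r = self.relation_score_matrix(X, reference_X, reference_y, strategy, seed)
        return r[:, 1] - r[:, 0]

    def predict(self, X, **kwargs):
        r = self.relation_score_matrix(X, **kwargs)
        return self.classes_[r.argmax(axis=1)]

    def predict_proba(self, X, **kwargs):
        """Temperature-softmax of relation scores (uncalibrated)."""
        r = self.relation_score_matrix(X, **kwargs) / self.tau
        r = r - r.max(axis=1, keepdims=True)
        e = np.exp(r)
        return e / e.sum(axis=1, keepdims=True)
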