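"""Relation-style set-to-set comparator over gated latent activities.

Architecture
------------
* Encoder f_theta: L -> 128 (ReLU, dropout 0.3) -> 64 (ReLU); the 64-unit
  layer is the embedding (d = 64).
* Pairwise similarity: Hadamard product m_{q,s} = h_q (*) h_s.
* Deep-Sets relation head: r_{q,c} = rho(agg_{s in S_c} phi(m_{q,s})) with
  phi a 64->64->64 ReLU perceptron, rho a 64->32->1 ReLU perceptron, and
  agg either sum (default) or mean.

Permutation invariance of r_{q,c} in eval mode is exact at the bit level:
the per-class phi outputs are put into a canonical (lexicographic) row
order before summation, so the floating-point reduction order does not
depend on how the support list was presented.
"""

from __future__ import annotations

import numpy as np

from .nn import MLP, Adam, Dropout, Linear, ReLU

__all__ = ["RelationNetwork", "encode", "hadamard_similarity", "relation_scores"]


def hadamard_similarity(h_q: np.ndarray, h_s: np.ndarray) -> np.ndarray:
    """Element-wise product of two equal-length embeddings."""
    h_q = np.asarray(h_q, dtype=float)
    h_s = np.asarray(h_s, dtype=float)
    if h_q.shape != h_s.shape:
        raise ValueError(f"embedding shapes differ: {h_q.shape} vs {h_s.shape}")
    return h_q * h_s


def _canonical_sum(rows: np.ndarray) -> np.ndarray:
    """Sum rows of a 2-D array in lexicographic row order.

    Makes the reduction independent of input row order, so set scores are
    bit-identical under support permutations.
    """
    if rows.shape[0] == 1:
        return rows[0].copy()
    order = np.lexsort(rows.T[::-1])
    return np.add.reduce(rows[order], axis=0)


class RelationNetwork:
    """Encoder + Deep-Sets relation head with explicit forward/backward.

    Parameters default to the reference architecture sizes; all
    widths are exposed so the gradient check can run at toy sizes.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int = 128,
        embed_dim: int = 64,
        phi_hidden: int = 64,
        rho_hidden: int = 32,
        dropout: float = 0.3,
        aggregation: str = "sum",
        seed: int = 0,
    ):
        if aggregation not in ("sum", "mean"):
            raise ValueError(f"aggregation must be 'sum' or 'mean', got {aggregation!r}")
        self.input_dim = input_dim
        self.embed_dim = embed_dim
        self.aggregation = aggregation
        rng = np.random.default_rng(seed)
        self.encoder = MLP([
            Linear(input_dim, hidden_dim, rng), ReLU(), Dropout(dropout),
            Linear(hidden_dim, embed_dim, rng), ReLU(),
        ])
        self.phi = MLP([
            Linear(embed_dim, phi_hidden, rng), ReLU(),
            Linear(phi_hidden, embed_dim, rng),
        ])
        self.rho = MLP([
            Linear(embed_dim, rho_hidden, rng), ReLU(),
            Linear(rho_hidden, 1, rng),
        ])
        # shrink the output layer so a fresh model scores all classes nearly
        # alike (initial episode loss ~ ln 2) while keeping gradients nonzero
        self.rho.layers[-1].W *= 0.05
        self.rho.layers[-1].b *= 0.0
        self._modules = (self.encoder, self.phi, self.rho)

    # ------------------------------------------------------------------ #
    # parameter plumbing
    def params(self):
        out = []
        for m in self._modules:
            out.extend(m.params())
        return out

    def zero_grad(self) -> None:
        for m in self._modules:
            m.zero_grad()

    def get_state(self):
        return [m.get_state() for m in self._modules]

    def set_state(self, state) -> None:
        for m, s in zip(self._modules, state, strict=True):
            m.set_state(s)

    def make_optimizer(self, lr: float, weight_decay: float) -> Adam:
        return Adam(self.params(), lr=lr, weight_decay=weight_decay)

    # ------------------------------------------------------------------ #
    # inference
    def encode(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Embed (n, L) latent vectors to (n, d); deterministic in eval mode."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input has {x.shape[1]} latent features, encoder expects "
                f"{self.input_dim}"
            )
        return self.encoder.forward(x, train=train, rng=rng)

    def relation_scores_from_embeddings(
        self, h_q: np.ndarray, support: dict[int, np.ndarray]
    ) -> np.ndarray:
        """Eval-mode relation scores r_{q,c} for queries vs class support sets.

        ``h_q``: (Q, d) query embeddings; ``support``: class -> (K_c, d)
        support embeddings.  Returns (Q, n_classes) in class order 0, 1.
        """
        h_q = np.atleast_2d(h_q)
        classes = sorted(support)
        scores = np.empty((h_q.shape[0], len(classes)))
        for j, c in enumerate(classes):
            h_s = np.atleast_2d(support[c])
            if h_s.shape[0] == 0:
                raise ValueError(f"empty support set for class {c}")
            for qi in range(h_q.shape[0]):
                m = h_q[qi][None, :] * h_s  # (K, d) Hadamard similarities
                p = self.phi.forward(m, train=False)
                agg = _canonical_sum(p)
                if self.aggregation == "mean":
                    agg = agg / h_s.shape[0]
                scores[qi, j] = self.rho.forward(agg[None, :], train=False)[0, 0]
        return scores

    # ------------------------------------------------------------------ #
    # training
    def episode_forward_backward(
        self,
        support_by_class: dict[int, np.ndarray],
        query_x: np.ndarray,
        query_labels: np.ndarray,
        tau: float,
        rng,
    ) -> tuple[float, np.ndarray]:
        """One episode: forward, cross-entropy loss, full backward pass.

        Inputs are raw (gated-latent) vectors; returns (loss, scores) and
        leaves accumulated gradients on the parameters.  The loss is the
        mean over queries of -log softmax(r_q / tau) at the true class.
        """
        if tau <= 0:
            raise ValueError(f"temperature must be > 0, got {tau}")
        classes = sorted(support_by_class)
        ks = [np.atleast_2d(support_by_class[c]).shape[0] for c in classes]
        Q = np.atleast_2d(query_x).shape[0]
        self.zero_grad()

        # encode queries and all supports in one batch
        batch = np.vstack([np.atleast_2d(query_x)]
                          + [np.atleast_2d(support_by_class[c]) for c in classes])
        H = self.encoder.forward(batch, train=True, rng=rng)
        h_q = H[:Q]
        h_s = {}
        off = Q
        for c, k in zip(classes, ks):
            h_s[c] = H[off:off + k]
            off += k

        # all query-support pairs through phi in one batch
        pair_blocks = [(h_q[:, None, :] * h_s[c][None, :, :]).reshape(-1, self.embed_dim)
                       for c in classes]
        M = np.vstack(pair_blocks)
        P = self.phi.forward(M, train=True, rng=rng)

        # aggregate per (query, class), then rho as one batch of Q * n_classes
        aggs = []
        off = 0
        for c, k in zip(classes, ks):
            block = P[off:off + Q * k].reshape(Q, k, self.embed_dim)
            agg = block.sum(axis=1)
            if self.aggregation == "mean":
                agg = agg / k
            aggs.append(agg)
            off += Q * k
        A = np.vstack(aggs)                       # (n_classes*Q, d)
        R = self.rho.forward(A, train=True, rng=rng)  # (n_classes*Q, 1)
        scores = R.reshape(len(classes), Q).T     # (Q, n_classes)

        # temperature softmax cross-entropy, mean over queries
        logits = scores / tau
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        y = np.asarray(query_labels, dtype=int)
        loss = float(-np.log(probs[np.arange(Q), y]).mean())

        # backward
        d_scores = probs.copy()
        d_scores[np.arange(Q), y] -= 1.0
        d_scores /= tau * Q                        # (Q, n_classes)
        dR = d_scores.T.reshape(-1, 1)
        dA = self.rho.backward(dR)                 # (n_classes*Q, d)
        dP = np.empty_like(P)
        off = 0
        for j, (c, k) in enumerate(zip(classes, ks)):
            d_agg = dA[j * Q:(j + 1) * Q]
            if self.aggregation == "mean":
                d_agg = d_agg / k
            dP[off:off + Q * k] = np.repeat(d_agg[:, None, :], k, axis=1
                                            ).reshape(-1, self.embed_dim)
            off += Q * k
        dM = self.phi.backward(dP)
        dH = np.zeros_like(H)
        off = 0
        for c, k, start in zip(classes, ks, np.cumsum([Q] + ks[:-1])):
            block = dM[off:off + Q * k].reshape(Q, k, self.embed_dim)
            dH[:Q] += (block * h_s[c][None, :, :]).sum(axis=1)
            dH[start:start + k] += (block * h_q[:, None, :]).sum(axis=0)
            off += Q * k
        self.encoder.backward(dH)
        return loss, scores


# ---------------------------------------------------------------------- #
# functional wrappers

def encode(x: np.ndarray, network: RelationNetwork, train_mode: bool = False,
           rng=None) -> np.ndarray:
    """Embed latent vectors with the network's encoder (see RelationNetwork)."""
    return network.encode(x, train=train_mode, rng=rng)


def relation_scores(
    h_q: np.ndarray, support: dict[int, np.ndarray], network: RelationNetwork
) -> np.ndarray:
    """Eval-mode Deep-Sets relation scores for one or more queries."""
    return network.relation_scores_from_embeddings(h_q, support)
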