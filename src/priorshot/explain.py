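"""Additive attribution of the risk score and the gene-level scorecard.

Attribution uses complete-permutation Shapley values over the gated latent
inputs of the risk score s(x), with absent features imputed by the
background mean.  Each sampled permutation contributes a telescoping sum of
score increments, so the efficiency identity

    base + sum_l attribution_l = s(x)

holds exactly per permutation (and hence after averaging), which is what
makes the additive scorecard legitimate on the log-odds scale.
Permutations are drawn antithetically (each with its reversal) to reduce
variance.

Gene-level aggregation shares each LV's attribution among the hub genes in
proportion to their absolute loadings on that LV; LVs with no hub-gene
loading are pooled into an "other" term so additivity is preserved.  Gene
contribution totals are rescaled so the training cohort's range of summed
positive contributions maps linearly onto 0-100 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .latent import GateVector

__all__ = ["shap_attribution", "Scorecard", "gene_scorecard"]


def _as_score_fn(model):
    if callable(model):
        return model
    if hasattr(model, "latent_decision_function"):
        return model.latent_decision_function
    raise TypeError("model must be callable or expose latent_decision_function")


def shap_attribution(model, sample, background, n_permutations: int = 128,
                     seed: int = 0) -> tuple[np.ndarray, float]:
    """Shapley attribution of s(sample) over its latent inputs.

    Parameters
    ----------
    model : callable (n, L) -> (n,) or an object with
        ``latent_decision_function``; evaluated on gated latent vectors.
    sample : (L,) gated latent vector to explain.
    background : (n_b, L) gated latent reference matrix; absent features
        take its column mean.
    n_permutations : number of sampled permutations (antithetic pairs).

    Returns
    -------
    (attributions, base) with ``base + attributions.sum() == s(sample)``
    up to accumulated rounding (well below 1e-6).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    f = _as_score_fn(model)
    x = np.asarray(sample, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background must be nonempty")
    if bg.shape[1] != x.size:
        raise ValueError("background and sample dimensions differ")
    L = x.size
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_permutations // 2):
        p = rng.permutation(L)
        perms.append(p)
        perms.append(p[::-1])
    if n_permutations % 2:
        perms.append(rng.permutation(L))

    bg_mean = bg.mean(axis=0)
    # walk each permutation from the background mean to the sample,
    # evaluating the score after each feature switch (one batched call)
    inputs = np.empty((len(perms), L + 1, L))
    for i, p in enumerate(perms):
        v = bg_mean.copy()
        inputs[i, 0] = v
        for j, feat in enumerate(p):
            v = v.copy()
            v[feat] = x[feat]
            inputs[i, j + 1] = v
    vals = np.asarray(f(inputs.reshape(-1, L)), dtype=float).reshape(len(perms), L + 1)

    attr = np.zeros(L)
    for i, p in enumerate(perms):
        attr[p] += np.diff(vals[i])
    attr /= len(perms)
    base = float(vals[:, 0].mean())  # all rows start at bg_mean; identical
    return attr, base


@dataclass
class Scorecard:
    """Additive gene-level explanation of the risk score.

    ``gene_contributions`` and ``other`` are on the log-odds scale and
    satisfy ``base + other + sum(genes) = s(x)`` per sample.  ``points``
    rescale positive gene contributions so the training cohort spans
    0-100 total points.
    """

    hub_genes: list[str]
    gene_contributions: pd.DataFrame      # samples x hub genes
    other: pd.Series                      # per-sample non-hub LV pool
    base: float
    s_values: pd.Series
    points: pd.DataFrame                  # samples x hub genes, >= 0
    total_points: pd.Series               # in [0, 100] on the training cohort
    point_scale: float
    point_offset: float                   # training minimum of summed positives
    lookup_points: np.ndarray = field(default=None, repr=False)
    lookup_probs: np.ndarray = field(default=None, repr=False)

    def points_for(self, gene_contributions: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
        """Points for new samples; totals clip to [0, 100] with a flag."""
        pos = gene_contributions.clip(lower=0.0)
        pts = pos * self.point_scale
        raw_total = (pos.sum(axis=1) - self.point_offset) * self.point_scale
        clipped = (raw_total < 0) | (raw_total > 100)
        return pts, raw_total.clip(0.0, 100.0), clipped.to_numpy()

    def probability_for_points(self, total_points) -> np.ndarray:
        """Risk probability for a total-points value via the training lookup."""
        if self.lookup_points is None:
            raise ValueError("scorecard was built without a calibration map")
        return np.interp(np.asarray(total_points, float),
                         self.lookup_points, self.lookup_probs)


def gene_scorecard(lv_attr, Z: pd.DataFrame, gate: GateVector, hub_genes,
                   base: float = 0.0, s_values=None,
                   calibration=None) -> Scorecard:
    """Aggregate per-LV attributions into an additive per-gene scorecard.

    Parameters
    ----------
    lv_attr : (n_samples, L) per-LV attributions (DataFrame with LV columns
        or array in Z's column order), typically the training cohort.
    Z : genes x LVs loading matrix (the same prior used for projection).
    gate : the hub-gene gate stored with the model (recorded for
        provenance; attributions are already on gated inputs).
    hub_genes : genes receiving named contributions; each LV's attribution
        is shared in proportion to |Z_gl| over the hub set, and LVs with no
        hub loading are pooled into "other".
    base, s_values : Shapley base value and the per-sample scores; used to
        verify additivity downstream and to build the points -> probability
        lookup when ``calibration`` is given.
    """
    hub = list(dict.fromkeys(hub_genes))
    missing = [g for g in hub if g not in Z.index]
    if missing:
        raise KeyError(f"hub genes absent from loading matrix: {missing}")
    if isinstance(lv_attr, pd.DataFrame):
        if list(lv_attr.columns) != list(Z.columns):
            lv_attr = lv_attr.loc[:, Z.columns]
        A = lv_attr.to_numpy(dtype=float)
        sample_ids = lv_attr.index
    else:
        A = np.atleast_2d(np.asarray(lv_attr, dtype=float))
        sample_ids = pd.RangeIndex(A.shape[0])
    if A.shape[1] != Z.shape[1]:
        raise ValueError("attribution width does not match the number of LVs")

    absZ = Z.loc[hub].abs().to_numpy()            # hub x L
    denom = absZ.sum(axis=0)                      # per-LV hub loading mass
    loaded = denom > 0
    shares = np.zeros_like(absZ)
    shares[:, loaded] = absZ[:, loaded] / denom[loaded]

    contrib = pd.DataFrame(A @ shares.T, index=sample_ids, columns=hub)
    other = pd.Series(A[:, ~loaded].sum(axis=1), index=sample_ids, name="other")
    s_values = pd.Series(
        base + A.sum(axis=1) if s_values is None else np.asarray(s_values, float),
        index=sample_ids, name="s",
    )

    pos = contrib.clip(lower=0.0)
    totals = pos.sum(axis=1)
    t_min, t_max = float(totals.min()), float(totals.max())
    scale = 100.0 / (t_max - t_min) if t_max > t_min else 0.0
    points = pos * scale
    total_points = ((totals - t_min) * scale).clip(0.0, 100.0)

    lookup_points = lookup_probs = None
    if calibration is not None:
        probs = calibration.predict(s_values.to_numpy())
        order = np.argsort(total_points.to_numpy(), kind="stable")
        lookup_points = total_points.to_numpy()[order]
        # enforce a non-decreasing points -> probability chart
        lookup_probs = np.maximum.accumulate(probs[order])

    return Scorecard(
        hub_genes=hub, gene_contributions=contrib, other=other, base=base,
        s_values=s_values, points=points, total_points=total_points,
        point_scale=scale, point_offset=t_min,
        lookup_points=lookup_points, lookup_probs=lookup_probs,
    )
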