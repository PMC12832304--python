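"""Projection onto a fixed pathway-aligned latent space and hub-gene gating.

A frozen gene x LV loading matrix Z (e.g. a MultiPLIER-style prior learned
on a large compendium) defines the latent space.  Per-sample LV activities
are estimated by ridge regression,

    B = argmin_B ||X - Z B||_F^2 + lambda ||B||_F^2
      = (Z'Z + lambda I)^{-1} Z'X,

with Z never refit.  A gate vector derived from the hub-gene rows of Z
re-weights latent channels: alpha_l is the mean absolute loading of the hub
genes on LV l, normalised either to max 1 ("max" mode) or to sum 1 ("l1"),
and the gated activities are B~ = diag(alpha_hat) B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .io import align_to_prior

__all__ = [
    "GateVector",
    "project_to_latent",
    "compute_gate",
    "apply_gate",
    "LatentProjector",
    "HubGeneGate",
]


def project_to_latent(
    X: pd.DataFrame, Z: pd.DataFrame, ridge_lambda: float = 1.0
) -> pd.DataFrame:
    """Ridge-project genes x samples expression onto LVs (LVs x samples out).

    ``X`` and ``Z`` must already share an identical gene index (use
    :func:`priorshot.io.align_to_prior`).  With ``ridge_lambda == 0`` the
    normal equations must be non-singular.
    """
    if ridge_lambda < 0:
        raise ValueError(f"ridge lambda must be >= 0, got {ridge_lambda}")
    if len(X.index) != len(Z.index) or not (X.index == Z.index).all():
        raise ValueError("expression and loadings are not gene-aligned; "
                         "call align_to_prior first")
    Zv = Z.to_numpy()
    G = Zv.T @ Zv + ridge_lambda * np.eye(Z.shape[1])
    rhs = Zv.T @ X.to_numpy()
    try:
        B = scipy.linalg.solve(G, rhs, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise np.linalg.LinAlgError(
            "normal equations are singular; use ridge_lambda > 0"
        ) from None
    return pd.DataFrame(B, index=Z.columns, columns=X.columns)


@dataclass
class GateVector:
    """LV-wise channel weights derived from hub-gene loadings.

    ``raw`` holds alpha (mean |Z_gl| over hub genes, nonnegative);
    ``normalized`` holds alpha-hat under ``norm_mode``.
    """

    raw: pd.Series
    normalized: pd.Series
    norm_mode: str
    hub_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.raw < 0).any():
            raise ValueError("raw gate weights must be nonnegative")


def compute_gate(
    Z: pd.DataFrame, hub_genes, norm_mode: str = "max"
) -> GateVector:
    """Gate weights: alpha_l = mean over hub genes of |Z_gl|, then normalise.

    ``norm_mode="max"`` divides by max(alpha) (entries in [0,1], max exactly
    1); ``"l1"`` divides by the L1 norm (entries on the simplex).
    """
    hub = list(dict.fromkeys(hub_genes))  # dedupe, order-preserving
    if not hub:
        raise ValueError("hub gene set is empty")
    missing = [g for g in hub if g not in Z.index]
    if missing:
        raise KeyError(f"hub genes absent from loading matrix: {missing}")
    if norm_mode not in ("max", "l1"):
        raise ValueError(f"norm_mode must be 'max' or 'l1', got {norm_mode!r}")
    alpha = Z.loc[hub].abs().mean(axis=0)
    denom = alpha.max() if norm_mode == "max" else alpha.sum()
    if denom == 0:
        raise ValueError("all gate weights are zero; gate is undefined")
    return GateVector(raw=alpha, normalized=alpha / denom,
                      norm_mode=norm_mode, hub_genes=hub)


def apply_gate(B: pd.DataFrame, gate: GateVector) -> pd.DataFrame:
    """Multiply each LV row of activities by its normalised gate weight."""
    if len(B.index) != len(gate.normalized.index) or not (
        B.index == gate.normalized.index
    ).all():
        raise ValueError("LV ids of activities and gate do not match")
    return B.mul(gate.normalized, axis=0)


def gate_to_frame(gate: GateVector) -> pd.DataFrame:
    """Serialisable view of a gate (LV id, raw and normalised weight)."""
    return pd.DataFrame({"raw": gate.raw, "normalized": gate.normalized})


class LatentProjector(BaseEstimator, TransformerMixin):
    """Sklearn transformer: samples x genes -> samples x LVs via the prior.

    Parameters
    ----------
    loadings : DataFrame
        Fixed genes x LVs prior; never modified.
    ridge_lambda : float
        Ridge penalty of the projection (applied to standardized genes by
        the surrounding pipeline; default 1.0).
    """

    def __init__(self, loadings: pd.DataFrame, ridge_lambda: float = 1.0):
        self.loadings = loadings
        self.ridge_lambda = ridge_lambda

    def fit(self, X: pd.DataFrame, y=None):
        _, Z = align_to_prior(X.T, self.loadings)
        self.genes_ = Z.index.tolist()
        self.lv_ids_ = Z.columns.tolist()
        self.Z_ = Z
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Xg = X.T.loc[self.genes_]
        B = project_to_latent(Xg, self.Z_, self.ridge_lambda)
        return B.T


class HubGeneGate(BaseEstimator, TransformerMixin):
    """Sklearn transformer applying the hub-gene channel gate to LV activities.

    The gate is computed once from the prior and the hub set at fit time and
    stored with the model; it is never re-derived from data at inference.
    """

    def __init__(self, loadings: pd.DataFrame, hub_genes=(), norm_mode: str = "max"):
        self.loadings = loadings
        self.hub_genes = hub_genes
        self.norm_mode = norm_mode

    def fit(self, X: pd.DataFrame, y=None):
        self.gate_ = compute_gate(self.loadings, list(self.hub_genes),
                                  self.norm_mode)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return apply_gate(X.T, self.gate_).T
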