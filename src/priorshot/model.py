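"""End-to-end diagnostic model: preprocessing, relation classifier, archive.

``train_diagnostic`` wires the full pipeline on a labelled expression
cohort:

    standardize genes (training-derived mean/SD)
      -> ridge-project onto the fixed prior
      -> hub-gene channel gate
      -> episodic few-shot training with validation-AUC early stopping

The fitted :class:`DiagnosticModel` carries everything inference needs —
standardization parameters, the aligned prior, the gate, the network
weights and the labelled support reference — and serialises to a single
versioned ``.npz`` archive (named arrays plus a JSON metadata string).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fewshot import FewShotRelationClassifier, TrainConfig
from .io import StandardizationParams, align_to_prior, standardize_genes
from .latent import GateVector, apply_gate, compute_gate, project_to_latent
from .relation import RelationNetwork

__all__ = ["DiagnosticModel", "CalibratedDiagnostic", "train_diagnostic",
           "predict_diagnostic", "save_model", "load_model"]

SCHEMA_VERSION = "priorshot-model-1"


@dataclass
class DiagnosticModel:
    """A trained prior-informed few-shot diagnostic classifier."""

    standardization: StandardizationParams
    loadings: pd.DataFrame                 # gene-aligned prior (frozen)
    gate: GateVector
    ridge_lambda: float
    classifier: FewShotRelationClassifier
    config: TrainConfig
    hub_genes: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ #
    def transform_expression(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Genes x samples expression -> samples x LVs gated activities."""
        Xs, _ = standardize_genes(expression, self.standardization)
        B = project_to_latent(Xs, self.loadings, self.ridge_lambda)
        return apply_gate(B, self.gate).T

    def latent_decision_function(self, B: np.ndarray) -> np.ndarray:
        """Risk score s(x) on already-gated latent vectors (full-set support)."""
        return self.classifier.decision_function(np.atleast_2d(B),
                                                 strategy="full_set")

    @property
    def train_log(self):
        return self.classifier.train_log_

    # ------------------------------------------------------------------ #
    def save(self, path: str | Path) -> None:
        save_model(self, path)


def train_diagnostic(
    expression: pd.DataFrame,
    labels: pd.Series,
    loadings: pd.DataFrame,
    hub_genes,
    config: TrainConfig | None = None,
    ridge_lambda: float = 1.0,
    norm_mode: str = "max",
    val_fraction: float = 0.25,
) -> DiagnosticModel:
    """Fit the full diagnostic pipeline on a labelled training cohort.

    ``expression`` is genes x samples (log2 scale); ``labels`` a series of
    {0, 1} indexed by sample id covering the expression columns.  A
    stratified ``val_fraction`` of samples is held out for early stopping;
    gene standardization is fitted on the remaining training portion only.
    """
    config = config or TrainConfig()
    labels = labels.loc[expression.columns]
    y = labels.to_numpy(dtype=int)

    rng = np.random.default_rng(config.seed)
    val_idx = []
    for c in (0, 1):
        pool = np.flatnonzero(y == c)
        if pool.size == 0:
            raise ValueError(f"training cohort has no samples of class {c}")
        n_val = max(1, int(round(val_fraction * pool.size)))
        val_idx.append(rng.permutation(pool)[:n_val])
    val_idx = np.concatenate(val_idx)
    tr_idx = np.setdiff1d(np.arange(y.size), val_idx)

    X_aligned, Z = align_to_prior(expression, loadings)
    Xtr, params = standardize_genes(X_aligned.iloc[:, tr_idx])
    Xval, _ = standardize_genes(X_aligned.iloc[:, val_idx], params)
    gate = compute_gate(Z, hub_genes, norm_mode)
    Z = Z.loc[params.mean.index]

    def to_features(Xs: pd.DataFrame) -> pd.DataFrame:
        B = project_to_latent(Xs, Z, ridge_lambda)
        return apply_gate(B, gate).T

    F_tr = to_features(Xtr)
    F_val = to_features(Xval)

    clf = FewShotRelationClassifier(
        k_shot=config.k_shot, queries_per_class=config.queries_per_class,
        max_episodes=config.max_episodes, tau=config.tau,
        learning_rate=config.learning_rate, weight_decay=config.weight_decay,
        dropout=config.dropout, eval_every=config.eval_every,
        patience=config.patience, aggregation=config.aggregation,
        random_state=config.seed,
    )
    clf.fit(F_tr, y[tr_idx], X_val=F_val, y_val=y[val_idx])
    return DiagnosticModel(
        standardization=params, loadings=Z, gate=gate,
        ridge_lambda=ridge_lambda, classifier=clf, config=config,
        hub_genes=list(dict.fromkeys(hub_genes)),
    )


def predict_diagnostic(
    model: DiagnosticModel,
    expression: pd.DataFrame,
    reference: tuple[pd.DataFrame, pd.Series] | None = None,
    strategy: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score new samples; returns per-sample relation scores, s(x) and class.

    ``reference`` optionally replaces the stored support reference with a
    labelled (expression, labels) pair, e.g. an external cohort.
    """
    F = model.transform_expression(expression)
    kwargs: dict = {"strategy": strategy, "seed": seed}
    if reference is not None:
        ref_expr, ref_labels = reference
        ref_F = model.transform_expression(ref_expr)
        kwargs["reference_X"] = ref_F
        kwargs["reference_y"] = ref_labels.loc[ref_expr.columns].to_numpy()
    r = model.classifier.relation_score_matrix(F, **kwargs)
    s = r[:, 1] - r[:, 0]
    return pd.DataFrame(
        {"r_control": r[:, 0], "r_case": r[:, 1], "score": s,
         "predicted_class": (r.argmax(axis=1)).astype(int)},
        index=F.index,
    )


@dataclass
class CalibratedDiagnostic:
    """Trained model plus calibrated risk mapping and gene scorecard."""

    model: DiagnosticModel
    calibration: object                    # calibrate.CalibrationMap
    scorecard: object | None = None        # explain.Scorecard

    def predict_risk(self, expression: pd.DataFrame, strategy=None,
                     seed: int = 0) -> pd.DataFrame:
        out = predict_diagnostic(self.model, expression, strategy=strategy,
                                 seed=seed)
        out["probability"] = self.calibration.predict(out["score"].to_numpy())
        return out


# ---------------------------------------------------------------------- #
# archive format: named numpy arrays + one JSON metadata string

def save_model(model: DiagnosticModel, path: str | Path) -> None:
    clf = model.classifier
    net = clf.network_
    arrays: dict[str, np.ndarray] = {}
    for mi, mod_state in enumerate(net.get_state()):
        for pi, arr in enumerate(mod_state):
            arrays[f"net_{mi}_{pi}"] = arr
    arrays["support_X"] = clf.support_X_
    arrays["support_y"] = clf.support_y_
    if clf.support_ids_ is not None:
        arrays["support_ids"] = np.asarray(clf.support_ids_, dtype=str)
    arrays["std_mean"] = model.standardization.mean.to_numpy()
    arrays["std_sd"] = model.standardization.sd.to_numpy()
    arrays["loadings"] = model.loadings.to_numpy()
    arrays["gate_raw"] = model.gate.raw.to_numpy()
    arrays["gate_normalized"] = model.gate.normalized.to_numpy()
    meta = {
        "schema_version": SCHEMA_VERSION,
        "genes": model.loadings.index.tolist(),
        "lv_ids": model.loadings.columns.tolist(),
        "std_genes": model.standardization.mean.index.tolist(),
        "dropped_genes": model.standardization.dropped_genes,
        "hub_genes": model.hub_genes,
        "norm_mode": model.gate.norm_mode,
        "ridge_lambda": model.ridge_lambda,
        "config": vars(model.config),
        "classifier_params": clf.get_params(),
        "train_log": clf.train_log_,
        "best_checkpoint": clf.best_checkpoint_,
        "best_val_auc": clf.best_val_auc_,
        "net_dims": {
            "input_dim": net.input_dim, "embed_dim": net.embed_dim,
            "aggregation": net.aggregation,
        },
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> DiagnosticModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {meta['schema_version']!r}"
            )
        cfg = TrainConfig(**meta["config"])
        params = StandardizationParams(
            mean=pd.Series(data["std_mean"], index=meta["std_genes"]),
            sd=pd.Series(data["std_sd"], index=meta["std_genes"]),
            dropped_genes=meta["dropped_genes"],
        )
        loadings = pd.DataFrame(data["loadings"], index=meta["genes"],
                                columns=meta["lv_ids"])
        gate = GateVector(
            raw=pd.Series(data["gate_raw"], index=meta["lv_ids"]),
            normalized=pd.Series(data["gate_normalized"], index=meta["lv_ids"]),
            norm_mode=meta["norm_mode"], hub_genes=meta["hub_genes"],
        )
        clf = FewShotRelationClassifier(**meta["classifier_params"])
        net = RelationNetwork(
            input_dim=meta["net_dims"]["input_dim"],
            hidden_dim=meta["classifier_params"]["hidden_dim"],
            embed_dim=meta["net_dims"]["embed_dim"],
            phi_hidden=meta["classifier_params"]["phi_hidden"],
            rho_hidden=meta["classifier_params"]["rho_hidden"],
            dropout=meta["classifier_params"]["dropout"],
            aggregation=meta["net_dims"]["aggregation"],
        )
        state = []
        for mi in range(3):
            mod_state, pi = [], 0
            while f"net_{mi}_{pi}" in data:
                mod_state.append(data[f"net_{mi}_{pi}"])
                pi += 1
            state.append(mod_state)
        net.set_state(state)
        clf.network_ = net
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = meta["net_dims"]["input_dim"]
        clf.support_X_ = data["support_X"]
        clf.support_y_ = data["support_y"]
        clf.support_ids_ = (np.asarray(data["support_ids"], dtype=str)
                            if "support_ids" in data else None)
        clf.train_log_ = meta["train_log"]
        clf.best_checkpoint_ = meta["best_checkpoint"]
        clf.best_val_auc_ = meta["best_val_auc"]
    return DiagnosticModel(
        standardization=params, loadings=loadings, gate=gate,
        ridge_lambda=meta["ridge_lambda"], classifier=clf, config=cfg,
        hub_genes=meta["hub_genes"],
    )
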