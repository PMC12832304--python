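"""Shared fixtures: the synthetic benchmark cohort and a trained model.

The benchmark cohort (1000 genes, 50 LVs, effect size 1.5 SD on three
disease LVs) is generated once per session; 40 samples per class are used
for training (with a stratified validation split inside) and the remaining
32 per class are held out for evaluation.
"""

from __future__ import annotations

import numpy as np
import pytest

import priorshot as ps


@pytest.fixture(scope="session")
def bench_ds() -> ps.SyntheticDataset:
    return ps.make_dataset(ps.SyntheticConfig(n_per_class=72, seed=7))


@pytest.fixture(scope="session")
def bench_split(bench_ds):
    rng = np.random.default_rng(0)
    tr, te = [], []
    for c in (0, 1):
        ids = rng.permutation(bench_ds.labels.index[bench_ds.labels == c].to_numpy())
        tr += list(ids[:40])
        te += list(ids[40:])
    return tr, te


@pytest.fixture(scope="session")
def bench_model(bench_ds, bench_split):
    tr, _ = bench_split
    return ps.train_diagnostic(
        bench_ds.expression[tr], bench_ds.labels[tr], bench_ds.loadings,
        bench_ds.true_hub_genes, config=ps.TrainConfig(seed=1),
    )


@pytest.fixture(scope="session")
def bench_heldout(bench_ds, bench_split, bench_model):
    """(scores, labels) of the held-out cohort under the ensemble strategy."""
    _, te = bench_split
    pred = ps.predict_diagnostic(bench_model, bench_ds.expression[te], seed=2)
    return pred, bench_ds.labels[te].to_numpy()


@pytest.fixture(scope="session")
def bench_calibration(bench_ds, bench_split, bench_model):
    """Calibration fitted on training-cohort scores under the same
    (ensemble) inference strategy used for held-out predictions."""
    tr, _ = bench_split
    F_tr = bench_model.transform_expression(bench_ds.expression[tr])
    scores = bench_model.classifier.decision_function(F_tr, seed=1)
    return ps.fit_calibration(scores, bench_ds.labels[tr].to_numpy(), seed=0), scores


def train_heldout_auc(effect_size: float, *, n_genes=1000, n_lvs=50,
                      genes_per_lv=20, ridge_lambda=1.0, data_seed=7,
                      train_seed=1) -> float:
    """Train on 40/class of a fresh cohort, return held-out AUC on 32/class."""
    cfg = ps.SyntheticConfig(n_genes=n_genes, n_lvs=n_lvs,
                             genes_per_lv=genes_per_lv, n_per_class=72,
                             effect_size=effect_size, seed=data_seed)
    ds = ps.make_dataset(cfg)
    rng = np.random.default_rng(0)
    tr, te = [], []
    for c in (0, 1):
        ids = rng.permutation(ds.labels.index[ds.labels == c].to_numpy())
        tr += list(ids[:40])
        te += list(ids[40:])
    model = ps.train_diagnostic(ds.expression[tr], ds.labels[tr], ds.loadings,
                                ds.true_hub_genes,
                                config=ps.TrainConfig(seed=train_seed),
                                ridge_lambda=ridge_lambda)
    pred = ps.predict_diagnostic(model, ds.expression[te], seed=2)
    return ps.roc_auc(pred["score"].to_numpy(), ds.labels[te].to_numpy())[0]


@pytest.fixture(scope="session")
def delta_aucs():
    """Held-out AUC of the benchmark at increasing latent effect sizes."""
    return {d: train_heldout_auc(d) for d in (0.0, 0.5, 1.0, 1.5)}
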