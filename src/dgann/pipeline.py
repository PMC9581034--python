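"""End-to-end helpers tying simulation, labeling, graphs and training
together; used by the CLI and by the learnability checks."""

from __future__ import annotations

import numpy as np

from .evaluation import ScoredDecoySet
from .graphs import build_graph
from .features import featurize
from .model import Hyper, compile_graph
from .simulate import SimConfig, plant_signal, simulate_target
from .training import TrainConfig, bootstrap_subsets, ensemble_score, train_one

__all__ = ["target_graphs", "synthetic_dataset", "train_ensemble",
           "score_target", "SyntheticExperiment", "run_synthetic_experiment"]


def target_graphs(native, labeled_decoys, edge_cutoff: float = 5.0):
    """Featurized, labeled residue graphs for one simulated target."""
    graphs = []
    for decoy, metrics, _rot, _trans in labeled_decoys:
        g = build_graph(decoy, edge_cutoff=edge_cutoff)
        g = featurize(g, decoy)
        graphs.append(g.with_label(metrics.label))
    return graphs


def synthetic_dataset(cfg: SimConfig):
    """Simulate cfg.n_targets targets and return per-target graph lists."""
    dataset = {}
    for t in range(cfg.n_targets):
        native, labeled = simulate_target(cfg, t)
        graphs = target_graphs(native, labeled)
        if cfg.signal_strength:
            graphs = plant_signal(
                graphs, cfg.signal_strength, cfg.signal_columns, seed=cfg.seed
            )
        dataset[native.target_id] = graphs
    return dataset


def train_ensemble(train_targets, val_targets, dataset, n_subsets, cfg: TrainConfig,
                   hyper: Hyper | None = None):
    """Train one classifier per balanced bootstrap subset."""
    labels = {
        tid: {g.model_id: g.label for g in dataset[tid]} for tid in train_targets
    }
    subsets = bootstrap_subsets(labels, B=n_subsets, seed=cfg.seed)
    by_id = {
        (tid, g.model_id): compile_graph(g)
        for tid in train_targets
        for g in dataset[tid]
    }
    sample_owner = {g.model_id: tid for tid in train_targets for g in dataset[tid]}
    val_graphs = [compile_graph(g) for tid in val_targets for g in dataset[tid]]

    checkpoints, logs = [], []
    for subset in subsets:
        train_graphs = [
            by_id[(sample_owner[sid], sid)] for sid in subset.sample_ids
        ]
        sub_cfg = TrainConfig(**{**cfg.__dict__, "seed": subset.seed})
        params, log = train_one(train_graphs, val_graphs, sub_cfg, hyper=hyper)
        checkpoints.append(params)
        logs.append(log)
    return checkpoints, logs


def score_target(checkpoints, graphs, mode: str = "max") -> ScoredDecoySet:
    scores = np.array(
        [ensemble_score(checkpoints, g, mode=mode) for g in graphs]
    )
    return ScoredDecoySet(
        target_id=graphs[0].target_id,
        model_ids=tuple(g.model_id for g in graphs),
        scores=scores,
        labels=np.array([g.label == "positive" for g in graphs]),
    )


class SyntheticExperiment(dict):
    """Result bundle from :func:`run_synthetic_experiment`."""


def run_synthetic_experiment(
    seed: int,
    n_train: int = 5,
    n_val: int = 1,
    n_test: int = 2,
    decoys_per_target: int = 200,
    positive_fraction: float = 0.05,
    signal_strength: float = 3.0,
    n_subsets: int = 10,
    train_cfg: TrainConfig | None = None,
    hyper: Hyper | None = None,
) -> SyntheticExperiment:
    """Simulate, train a bootstrap ensemble, and score held-out targets."""
    cfg = SimConfig(
        n_targets=n_train + n_val + n_test,
        decoys_per_target=decoys_per_target,
        positive_fraction=positive_fraction,
        signal_strength=signal_strength,
        seed=seed,
    )
    dataset = synthetic_dataset(cfg)
    tids = sorted(dataset)
    train_t, val_t = tids[:n_train], tids[n_train : n_train + n_val]
    test_t = tids[n_train + n_val :]
    # held-out targets must contain positives to be scoreable
    usable_test = [
        t for t in test_t if any(g.label == "positive" for g in dataset[t])
    ]
    train_cfg = train_cfg or TrainConfig(
        seed=seed, max_epochs=40, patience=10, batch_size=64
    )
    checkpoints, logs = train_ensemble(
        train_t, val_t, dataset, n_subsets, train_cfg, hyper=hyper
    )
    scored = {
        mode: [score_target(checkpoints, dataset[t], mode=mode) for t in usable_test]
        for mode in ("max", "mean")
    }
    return SyntheticExperiment(
        dataset=dataset,
        train_targets=train_t,
        val_targets=val_t,
        test_targets=usable_test,
        checkpoints=checkpoints,
        logs=logs,
        scored=scored,
    )
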