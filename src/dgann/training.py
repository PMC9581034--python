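"""Identity-based splitting, bootstrap balancing, training and ensembling.

Targets are clustered by greedy sequence identity (a stand-in for an
external clustering tool) before being dealt into cross-validation folds,
so near-duplicate complexes never straddle a train/test boundary. Each
ensemble member is trained on a balanced bootstrap subset — all positive
decoys plus an equal per-target draw of negatives — with Adam on binary
cross-entropy, early-stopped on the loss over the full imbalanced
validation decoys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .model import (
    CompiledGraph,
    DgannParams,
    Hyper,
    compile_graph,
    forward,
    forward_backward,
    init_params,
)

__all__ = [
    "TargetSplit",
    "BootstrapSubset",
    "TrainConfig",
    "sequence_identity",
    "greedy_identity_cluster",
    "make_splits",
    "bootstrap_subsets",
    "train_one",
    "ensemble_score",
    "Adam",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSplit:
    """Fold index per target plus the train/val/test arrangement per fold."""

    fold_of: dict[str, int]
    arrangements: list[dict[str, list[str]]]  # per fold: train/validation/test

    def check_leakage(self, identity, threshold: float = 0.4) -> None:
        """Assert no cross train/test pair exceeds the identity threshold."""
        for arr in self.arrangements:
            for t in arr["train"]:
                for u in arr["test"]:
                    ident = identity(t, u)
                    if ident >= threshold:
                        raise AssertionError(
                            f"leakage: {t} vs {u} identity {ident:.2f}"
                        )


@dataclass(frozen=True)
class BootstrapSubset:
    index: int
    seed: int
    sample_ids: tuple[str, ...]


@dataclass
class TrainConfig:
    lr: float = 0.001
    decay: float = 0.9  # multiplicative LR decay on validation plateau
    weight_decay: float = 0.0  # alternative reading of "0.9 decay", off by default
    batch_size: int = 256
    patience: int = 30
    max_epochs: int = 500
    seed: int = 0
    plateau_patience: int = 5  # epochs without improvement before LR decay

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.patience, self.max_epochs) < 0:
            raise ValueError("training config values must be non-negative")


# ---------------------------------------------------------------------------
# identity clustering and fold construction


_aligner = None


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / length of the shorter sequence."""
    global _aligner
    if not a or not b:
        raise ValueError("empty sequence")
    if _aligner is None:
        _aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=0,
            open_gap_score=-0.5,
            extend_gap_score=-0.1,
        )
    # cheap 3-mer screen: unrelated sequences short-circuit to 0 identity
    if len(a) >= 6 and len(b) >= 6:
        kmers = {a[i : i + 3] for i in range(len(a) - 2)}
        if not any(b[i : i + 3] in kmers for i in range(len(b) - 2)):
            return 0.0
    score = _aligner.score(a, b)
    matches = max(score, 0.0)
    return matches / min(len(a), len(b))


def greedy_identity_cluster(
    sequences: dict[str, str], threshold: float = 0.4
) -> list[list[str]]:
    """Greedy incremental clustering on pairwise identity.

    Targets are visited by descending sequence length; each joins the first
    cluster whose representative (the longest member) it matches at or
    above the threshold, else it seeds a new cluster. Deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for tid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for target {tid}")
    order = sorted(sequences, key=lambda t: (-len(sequences[t]), t))
    clusters: list[list[str]] = []
    for tid in order:
        for cluster in clusters:
            rep = cluster[0]
            if sequence_identity(sequences[rep], sequences[tid]) >= threshold:
                cluster.append(tid)
                break
        else:
            clusters.append([tid])
    return clusters


def make_splits(
    clusters: list[list[str]], n_folds: int = 5, seed: int = 0
) -> TargetSplit:
    """Deal whole clusters round-robin (by descending size) into folds.

    Per arrangement f: fold f is the test set, fold (f+1) mod n_folds the
    validation set and the rest train.
    """
    if len(clusters) < n_folds:
        raise ValueError(f"need >= {n_folds} clusters, got {len(clusters)}")
    rng = np.random.default_rng(seed)
    ordered = sorted(clusters, key=lambda c: (-len(c), c[0]))
    # random rotation keeps the deal seed-dependent but cluster-atomic
    start = int(rng.integers(n_folds))
    fold_of: dict[str, int] = {}
    for rank, cluster in enumerate(ordered):
        fold = (start + rank) % n_folds
        for tid in cluster:
            fold_of[tid] = fold
    arrangements = []
    for f in range(n_folds):
        val = (f + 1) % n_folds
        arrangements.append(
            {
                "test": sorted(t for t, g in fold_of.items() if g == f),
                "validation": sorted(t for t, g in fold_of.items() if g == val),
                "train": sorted(
                    t for t, g in fold_of.items() if g not in (f, val)
                ),
            }
        )
    return TargetSplit(fold_of=fold_of, arrangements=arrangements)


# ---------------------------------------------------------------------------
# bootstrap balanced subsets


def bootstrap_subsets(
    labels: dict[str, dict[str, str]], B: int = 100, seed: int = 0
) -> list[BootstrapSubset]:
    """B balanced subsets: all positives + per-target negative draws.

    ``labels`` maps target_id -> {sample_id: 'positive'|'negative'}. Each
    subset keeps every positive sample and samples, per target and without
    replacement, as many negatives as that target has positives; if a
    target lacks enough negatives the shortfall is topped up from other
    targets (logged).
    """
    positives, negatives = {}, {}
    for tid, samples in labels.items():
        positives[tid] = sorted(s for s, l in samples.items() if l == "positive")
        negatives[tid] = sorted(s for s, l in samples.items() if l == "negative")
    n_pos = sum(len(v) for v in positives.values())
    if n_pos == 0:
        raise ValueError("no positive samples in training targets")

    subsets = []
    for b in range(B):
        rng = np.random.default_rng(seed + b + 1)
        chosen: list[str] = []
        shortfall = 0
        spare: list[str] = []
        for tid in sorted(labels):
            chosen.extend(positives[tid])
            want = len(positives[tid])
            pool = negatives[tid]
            take = min(want, len(pool))
            if take:
                chosen.extend(rng.choice(pool, size=take, replace=False))
            shortfall += want - take
            spare.extend(pool[take:])
        if shortfall:
            logger.info("subset %d: topping up %d negatives across targets",
                        b + 1, shortfall)
            extra_pool = sorted(set(spare) - set(chosen))
            chosen.extend(rng.choice(extra_pool, size=shortfall, replace=False))
        subsets.append(
            BootstrapSubset(index=b + 1, seed=seed + b + 1,
                            sample_ids=tuple(sorted(chosen)))
        )
    return subsets


# ---------------------------------------------------------------------------
# optimiser and training loop


class Adam:
    """Plain Adam over the named-parameter dict of :class:`DgannParams`."""

    def __init__(self, params: DgannParams, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        flat = params.flat()
        self.m = {k: np.zeros_like(v) for k, v in flat.items()}
        self.v = {k: np.zeros_like(v) for k, v in flat.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        flat = self.params.flat()
        for key, g in grads.items():
            if self.weight_decay and not key.endswith("_b") and key != "fc_b":
                g = g + self.weight_decay * flat[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            self._apply(key, update)

    def _apply(self, key: str, update: np.ndarray) -> None:
        p = self.params
        if key.startswith("W"):
            p.Ws[int(key[1:]) - 1] -= update
        elif key.startswith("a"):
            p.atts[int(key[1:]) - 1] -= update
        elif key == "conv_w":
            p.conv_w -= update
        elif key == "conv_b":
            p.conv_b -= update
        elif key == "fc_w":
            p.fc_w -= update
        elif key == "fc_b":
            p.fc_b -= float(update[0])


def _mean_bce(graphs: list[CompiledGraph], params: DgannParams) -> float:
    eps = 1e-12
    total = 0.0
    for cg in graphs:
        p = forward(cg, params)
        y = cg.label
        total += -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return total / len(graphs)


def train_one(
    train_graphs,
    val_graphs,
    cfg: TrainConfig,
    hyper: Hyper | None = None,
):
    """Train one classifier; returns (best params, training log).

    ``train_graphs``/``val_graphs`` may be :class:`ResidueGraph` or
    pre-compiled graphs; labels must be set. Early stopping restores the
    checkpoint with the best validation BCE.
    """
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be non-empty")
    train_cg = [g if isinstance(g, CompiledGraph) else compile_graph(g)
                for g in train_graphs]
    val_cg = [g if isinstance(g, CompiledGraph) else compile_graph(g)
              for g in val_graphs]
    for cg in train_cg + val_cg:
        if np.isnan(cg.label):
            raise ValueError("all graphs must be labeled for training")

    hyper = hyper or Hyper()
    rng = np.random.default_rng(cfg.seed)
    params = init_params(hyper, rng)
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    best = params.copy()
    best_val = _mean_bce(val_cg, params)
    best_epoch = 0
    since_lr_drop = 0
    log = {"epochs": [], "initial_val_bce": best_val, "seed": cfg.seed}

    n = len(train_cg)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            grads_sum = None
            for idx in batch:
                cg = train_cg[idx]
                _, loss, grads = forward_backward(cg, params, cg.label, rng=rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"divergence (NaN loss) at epoch {epoch}")
                epoch_loss += loss
                if grads_sum is None:
                    grads_sum = grads
                else:
                    for key in grads_sum:
                        grads_sum[key] += grads[key]
            if cfg.lr > 0:
                for key in grads_sum:
                    grads_sum[key] /= len(batch)
                opt.step(grads_sum)
        val_bce = _mean_bce(val_cg, params)
        log["epochs"].append(
            {"epoch": epoch, "train_bce": epoch_loss / n, "val_bce": val_bce,
             "lr": opt.lr}
        )
        if val_bce < best_val - 1e-9:
            best_val = val_bce
            best = params.copy()
            best_epoch = epoch
            since_lr_drop = 0
        else:
            since_lr_drop += 1
            if since_lr_drop >= cfg.plateau_patience:
                opt.lr *= cfg.decay
                since_lr_drop = 0
        if epoch - best_epoch >= cfg.patience:
            break

    log["best_epoch"] = best_epoch
    log["best_val_bce"] = best_val
    return best, log


def ensemble_score(checkpoints, graph, mode: str = "max") -> float:
    """Aggregate per-classifier probabilities by mean or max."""
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    if mode not in ("mean", "max"):
        raise ValueError(f"unknown ensemble mode {mode!r}")
    cg = graph if isinstance(graph, CompiledGraph) else compile_graph(graph)
    scores = [forward(cg, p) for p in checkpoints]
    return float(np.mean(scores) if mode == "mean" else np.max(scores))
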