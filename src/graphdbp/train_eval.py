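"""Training, evaluation metrics, and the experiment harness.

Training minimizes two-class cross-entropy by mini-batch gradient
descent with the Adam optimizer (defaults: 1000 epochs, batch 128,
learning rate 0.001).  Evaluation reports sensitivity (SN), specificity
(SP), accuracy (ACC) and the Matthews correlation coefficient (MCC)
from the confusion counts:

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

When an MCC denominator factor vanishes, MCC is reported as 0 and
flagged undefined; likewise an SN or SP with an empty class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .gcn_model import (
    ModelConfig,
    ModelParams,
    _forward_cache,
    backward,
    forward,
    init_params,
    predict,
)
from .graph_build import ProteinGraph


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults follow the published protocol."""

    epochs: int = 1000
    batch_size: int = 128
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    validation_fraction: float = 0.1
    early_stop_patience: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvalMetrics:
    """SN/SP/ACC in [0,1], MCC in [-1,1]; ``undefined`` lists any metric
    whose denominator vanished (reported as 0 by convention)."""

    SN: float
    SP: float
    ACC: float
    MCC: float
    counts: ConfusionCounts
    undefined: Tuple[str, ...] = ()

    def as_dict(self) -> Dict[str, float]:
        return {
            "sn": self.SN, "sp": self.SP, "acc": self.ACC, "mcc": self.MCC,
            "tp": self.counts.TP, "tn": self.counts.TN,
            "fp": self.counts.FP, "fn": self.counts.FN,
        }


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """2×2 cross-tabulation of binary predictions against labels."""
    if len(predictions) != len(labels):
        raise ValueError(f"{len(predictions)} predictions vs {len(labels)} labels")
    tp = tn = fp = fn = 0
    for p, y in zip(predictions, labels):
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def compute_metrics(counts: ConfusionCounts) -> EvalMetrics:
    """SN, SP, ACC and MCC from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated samples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    undefined = []
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn, undefined = 0.0, undefined + ["SN"]
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp, undefined = 0.0, undefined + ["SP"]
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc, undefined = 0.0, undefined + ["MCC"]
    return EvalMetrics(SN=sn, SP=sp, ACC=acc, MCC=mcc, counts=counts,
                       undefined=tuple(undefined))


def stratified_split(labels: Sequence[int], fraction: float,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of a (1-fraction, fraction) split stratified by class."""
    labels = np.asarray(labels)
    held, kept = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_held = int(round(fraction * len(idx)))
        held.extend(idx[:n_held])
        kept.extend(idx[n_held:])
    return np.sort(np.array(kept, dtype=int)), np.sort(np.array(held, dtype=int))


@dataclass
class TrainResult:
    params: ModelParams
    history: List[Dict[str, float]]
    best_epoch: int
    val_ids: Tuple[str, ...]


def _check_labeled_two_class(graphs: Sequence[ProteinGraph]) -> None:
    labels = {g.label for g in graphs}
    if None in labels:
        raise ValueError("all training graphs must be labeled")
    if labels != {0, 1}:
        raise ValueError(f"training requires both classes, got labels {sorted(labels)}")


def train(graphs: Sequence[ProteinGraph], model_config: Optional[ModelConfig] = None,
          train_config: Optional[TrainConfig] = None) -> TrainResult:
    """Fit the classifier by Adam on mini-batch cross-entropy.

    A stratified ``validation_fraction`` of the graphs is held aside for
    epoch selection; the returned parameters are those of the best
    validation-MCC epoch (the final epoch when the fraction is 0).
    Fully reproducible from ``train_config.seed`` on one thread.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if len(graphs) < 2:
        raise ValueError("need at least 2 graphs to train")
    _check_labeled_two_class(graphs)

    rng = np.random.default_rng(train_config.seed)
    labels = [g.label for g in graphs]
    if train_config.validation_fraction > 0:
        train_idx, val_idx = stratified_split(labels, train_config.validation_fraction, rng)
        if len(train_idx) == 0 or len({graphs[i].label for i in train_idx}) < 2:
            raise ValueError("validation split left fewer than two training classes")
    else:
        train_idx, val_idx = np.arange(len(graphs)), np.array([], dtype=int)
    train_graphs = [graphs[i] for i in train_idx]
    val_graphs = [graphs[i] for i in val_idx]

    params = init_params(model_config, seed=int(rng.integers(2**31)))
    # Adam state, one slot per parameter array.
    m_state = [np.zeros_like(a) for a in params.flat()]
    v_state = [np.zeros_like(a) for a in params.flat()]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    keep = 1.0 - model_config.dropout
    hidden_width = model_config.fc_dims[1]

    history: List[Dict[str, float]] = []
    # Epoch selection: best validation MCC, ties broken by lower validation
    # cross-entropy (a small validation set saturates MCC long before the
    # model converges, so MCC alone would freeze a barely-trained epoch).
    best_key, best_epoch, best_params = (-np.inf, -np.inf), 0, params.copy()
    stall = 0

    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(len(train_graphs))
        epoch_loss = 0.0
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start:start + train_config.batch_size]
            acc_grads = None
            for gi in batch:
                g = train_graphs[gi]
                mask = None
                if model_config.dropout > 0:
                    mask = (rng.random(hidden_width) < keep).astype(float) / keep
                cache = _forward_cache(g, params, model_config, dropout_mask=mask)
                loss, grads = backward(cache, g.label, params, model_config)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} on graph {g.id!r}"
                    )
                epoch_loss += loss
                if acc_grads is None:
                    acc_grads = grads
                else:
                    for a, b in zip(acc_grads.flat(), grads.flat()):
                        a += b
            # Adam step on the batch-mean gradient.
            t += 1
            scale = 1.0 / len(batch)
            for slot, (p_arr, g_arr) in enumerate(zip(params.flat(), acc_grads.flat())):
                g_mean = g_arr * scale
                m_state[slot] = beta1 * m_state[slot] + (1 - beta1) * g_mean
                v_state[slot] = beta2 * v_state[slot] + (1 - beta2) * g_mean**2
                m_hat = m_state[slot] / (1 - beta1**t)
                v_hat = v_state[slot] / (1 - beta2**t)
                p_arr -= train_config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        row = {"epoch": epoch, "train_loss": epoch_loss / len(train_graphs)}
        if val_graphs:
            val_metrics, val_probs = evaluate(params, val_graphs, model_config)
            val_loss = -float(np.mean([
                np.log(max(val_probs[g.id] if g.label == 1 else 1 - val_probs[g.id],
                           1e-300))
                for g in val_graphs
            ]))
            row.update(val_mcc=val_metrics.MCC, val_acc=val_metrics.ACC,
                       val_loss=val_loss)
            key = (val_metrics.MCC, -val_loss)
            if key > best_key:
                best_key, best_epoch, best_params = key, epoch, params.copy()
                stall = 0
            else:
                stall += 1
                if (train_config.early_stop_patience is not None
                        and stall >= train_config.early_stop_patience):
                    history.append(row)
                    break
        history.append(row)

    if not val_graphs:
        best_params, best_epoch = params, train_config.epochs
    return TrainResult(params=best_params, history=history, best_epoch=best_epoch,
                       val_ids=tuple(g.id for g in val_graphs))


def evaluate(params: ModelParams, graphs: Sequence[ProteinGraph],
             model_config: Optional[ModelConfig] = None
             ) -> Tuple[EvalMetrics, Dict[str, float]]:
    """Inference-mode metrics plus per-protein positive-class probabilities."""
    model_config = model_config or ModelConfig()
    if any(g.label is None for g in graphs):
        raise ValueError("evaluation requires labeled graphs")
    probs = {g.id: forward(g, params, model_config, training_mode=False) for g in graphs}
    preds = [predict(probs[g.id], model_config.classification_threshold) for g in graphs]
    counts = confusion(preds, [g.label for g in graphs])
    return compute_metrics(counts), probs


def _split_dataset(graphs: Sequence[ProteinGraph], test_fraction: float,
                   seed: int) -> Tuple[List[ProteinGraph], List[ProteinGraph]]:
    rng = np.random.default_rng(seed)
    train_idx, test_idx = stratified_split([g.label for g in graphs], test_fraction, rng)
    return [graphs[i] for i in train_idx], [graphs[i] for i in test_idx]


def sweep_dropout(graphs: Sequence[ProteinGraph],
                  values: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
                  train_config: Optional[TrainConfig] = None,
                  model_config: Optional[ModelConfig] = None,
                  test_fraction: float = 0.25) -> List[Dict]:
    """Train/evaluate once per dropout value on one fixed stratified split.

    Every row shares the identical split and optimizer seed, so rows
    differ only in the dropout probability.
    """
    train_config = train_config or TrainConfig()
    base = model_config or ModelConfig()
    train_set, test_set = _split_dataset(graphs, test_fraction, train_config.seed)
    split_ids = tuple(sorted(g.id for g in test_set))
    rows = []
    for value in values:
        cfg = ModelConfig(
            conv_dims=base.conv_dims, fc_dims=base.fc_dims, dropout=value,
            activation=base.activation, pooling=base.pooling,
            classification_threshold=base.classification_threshold,
            use_bias=base.use_bias,
        )
        result = train(train_set, cfg, train_config)
        metrics, _ = evaluate(result.params, test_set, cfg)
        rows.append({"dropout": value, "metrics": metrics, "test_ids": split_ids})
    return rows


def holdout_experiment(graphs: Sequence[ProteinGraph],
                       model_config: Optional[ModelConfig] = None,
                       train_config: Optional[TrainConfig] = None,
                       test_fraction: float = 0.25
                       ) -> Tuple[EvalMetrics, TrainResult]:
    """Single stratified train/test split, train, evaluate on the held-out set.

    The building block of the recovery and null experiments: the test
    fraction never participates in training or epoch selection.
    """
    train_config = train_config or TrainConfig()
    model_config = model_config or ModelConfig()
    train_set, test_set = _split_dataset(graphs, test_fraction, train_config.seed)
    result = train(train_set, model_config, train_config)
    metrics, _ = evaluate(result.params, test_set, model_config)
    return metrics, result


def ablate_pssm(graphs: Sequence[ProteinGraph],
                train_config: Optional[TrainConfig] = None,
                model_config: Optional[ModelConfig] = None,
                test_fraction: float = 0.25) -> Dict[str, EvalMetrics]:
    """Paired runs with and without the PPM feature block.

    Both arms share the split and the seed; the "without" arm zeroes
    feature columns 21–41 in every graph (width stays 54, so the
    architecture is identical).
    """
    from .features import N_ONE_HOT, N_PPM

    train_config = train_config or TrainConfig()
    model_config = model_config or ModelConfig()
    results: Dict[str, EvalMetrics] = {}
    for arm, strip in (("with_pssm", False), ("without_pssm", True)):
        if strip:
            arm_graphs = []
            for g in graphs:
                feats = g.features.copy()
                feats[:, N_ONE_HOT:N_ONE_HOT + N_PPM] = 0.0
                arm_graphs.append(ProteinGraph(id=g.id, features=feats,
                                               adjacency=g.adjacency, label=g.label))
        else:
            arm_graphs = list(graphs)
        train_set, test_set = _split_dataset(arm_graphs, test_fraction, train_config.seed)
        result = train(train_set, model_config, train_config)
        metrics, _ = evaluate(result.params, test_set, model_config)
        results[arm] = metrics
    return results
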