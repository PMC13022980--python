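"""Hyperparameter search: IWO over the backbone/training space.

A candidate is a point in the eight-dimensional space of learning rate,
weight decay, batch size, width multiplier, depthwise kernel, embedding
dimension, head count, and attention dropout.  Each candidate is scored by a
short head-training run on synthetic data and the composite fitness

    F = alpha * (1 - ValAccuracy) + beta * ValLoss + gamma * FLOPs / FLOPs_max

(lower is better), which trades discriminative quality against the
candidate feature extractor's computational cost.  ``FLOPs_max`` is the
analytic FLOP count of the largest configuration in the space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import (BackboneConfig, count_params_flops, extract_features,
                       init_backbone_weights)
from .ckan import CkanConfig, evaluate_head, train_head
from .iwo import Dimension, IWOConfig, OptimizeResult, SearchSpace, optimize

__all__ = [
    "FitnessWeights", "CandidateResult", "table_search_space",
    "max_flops_in_space", "fitness_score", "decode_candidate",
    "evaluate_candidate", "run_search",
]


def table_search_space(input_size: int = 224) -> SearchSpace:
    """The tuned-by-IWO hyperparameter space (batch-size menu {16, 32})."""
    return SearchSpace([
        Dimension("learning_rate", 1e-5, 1e-2, kind="log"),
        Dimension("weight_decay", 1e-6, 1e-3, kind="log"),
        Dimension("batch_size", kind="categorical", menu=(16, 32)),
        Dimension("width_multiplier", kind="categorical", menu=(0.5, 0.75, 1.0)),
        Dimension("depthwise_kernel", kind="categorical", menu=(3, 5)),
        Dimension("embed_dim", kind="categorical", menu=(128, 256, 384)),
        Dimension("n_heads", kind="categorical", menu=(4, 8)),
        Dimension("attention_dropout", 0.0, 0.3),
    ])


def max_flops_in_space(input_size: int = 224) -> int:
    """Analytic FLOPs of the most expensive configuration in the space."""
    cfg = BackboneConfig(width_multiplier=1.0, depthwise_kernel=5,
                         embed_dim=384, n_heads=8, input_size=input_size)
    return count_params_flops(cfg)[1]


@dataclass(frozen=True)
class FitnessWeights:
    """Trade-off weights of the composite fitness (accuracy-dominant)."""

    alpha: float = 0.6
    beta: float = 0.3
    gamma: float = 0.1
    flops_max: float = field(default_factory=max_flops_in_space)

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be nonnegative")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ValueError("at least one weight must be positive")
        if self.flops_max <= 0:
            raise ValueError("flops_max must be positive")


def fitness_score(val_accuracy: float, val_loss: float, flops: float,
                  weights: FitnessWeights) -> float:
    """``alpha (1 - acc) + beta loss + gamma flops/flops_max``; lower is better."""
    if not (np.isfinite(val_accuracy) and np.isfinite(val_loss)
            and np.isfinite(flops)):
        raise ValueError("fitness inputs must be finite")
    if min(val_accuracy, val_loss, flops) < 0:
        raise ValueError("fitness inputs must be nonnegative")
    ratio = flops / weights.flops_max
    if ratio > 1.0:
        warnings.warn(f"candidate FLOPs exceed flops_max (ratio {ratio:.2f})")
    return (weights.alpha * (1.0 - val_accuracy)
            + weights.beta * val_loss + weights.gamma * ratio)


@dataclass(frozen=True)
class CandidateResult:
    """Outcome of evaluating one search-space point."""

    backbone: BackboneConfig
    learning_rate: float
    weight_decay: float
    batch_size: int
    val_accuracy: float
    val_loss: float
    flops: int
    fitness: float
    diverged: bool = False


def decode_candidate(position: np.ndarray, space: SearchSpace,
                     input_size: int = 224) -> dict:
    """Decode a raw position into backbone + training hyperparameters."""
    cand = space.decode(position)
    cand["backbone"] = BackboneConfig(
        width_multiplier=cand.pop("width_multiplier"),
        depthwise_kernel=cand.pop("depthwise_kernel"),
        embed_dim=cand.pop("embed_dim"),
        n_heads=cand.pop("n_heads"),
        attention_dropout=cand.pop("attention_dropout"),
        input_size=input_size)
    return cand


@dataclass(frozen=True)
class SearchData:
    """Pre-split [-1, 1] images and labels for candidate evaluation."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray


def evaluate_candidate(position: np.ndarray, space: SearchSpace,
                       data: SearchData, weights: FitnessWeights,
                       budget_epochs: int = 3, seed: int = 0,
                       head_cfg: CkanConfig | None = None,
                       input_size: int = 224) -> CandidateResult:
    """Build, briefly train and score one candidate; deterministic given seed.

    The backbone runs with fixed seeded weights; ``budget_epochs`` of head
    training on the training split produce the validation accuracy and
    cross-entropy loss entering the fitness together with the candidate's
    analytic FLOPs.  A NaN training loss flags the candidate as diverged
    with infinite fitness.
    """
    cand = decode_candidate(position, space, input_size)
    bb_cfg: BackboneConfig = cand["backbone"]
    head_cfg = head_cfg or CkanConfig()
    bb_weights = init_backbone_weights(bb_cfg, seed)
    feats_train = extract_features(data.train_images, bb_cfg, bb_weights)
    feats_val = extract_features(data.val_images, bb_cfg, bb_weights)
    flops = count_params_flops(bb_cfg, head_cfg)[1]

    if budget_epochs > 0:
        params, history = train_head(
            feats_train, data.train_labels, head_cfg,
            epochs=budget_epochs, lr=cand["learning_rate"],
            weight_decay=cand["weight_decay"],
            batch_size=int(cand["batch_size"]),
            patience=budget_epochs, seed=seed)
        diverged = not np.isfinite(history["train_loss"][-1])
    else:
        from .ckan import init_head_params
        params = init_head_params(head_cfg, seed=seed)
        diverged = False
    val_loss, val_acc = evaluate_head(feats_val, data.val_labels,
                                      head_cfg, params)
    if diverged or not np.isfinite(val_loss):
        return CandidateResult(bb_cfg, cand["learning_rate"],
                               cand["weight_decay"], int(cand["batch_size"]),
                               0.0, float("inf"), flops, float("inf"),
                               diverged=True)
    fitness = fitness_score(val_acc, val_loss, flops, weights)
    return CandidateResult(bb_cfg, cand["learning_rate"],
                           cand["weight_decay"], int(cand["batch_size"]),
                           val_acc, val_loss, flops, fitness)


def run_search(space: SearchSpace, iwo_cfg: IWOConfig,
               weights: FitnessWeights, data: SearchData,
               budget_epochs: int = 3, seed: int = 0,
               input_size: int = 224,
               out_dir: str | Path | None = None
               ) -> tuple[CandidateResult, OptimizeResult]:
    """IWO-minimize the candidate fitness; returns champion + trace.

    The per-iteration best-fitness trace is monotone non-increasing and,
    when ``out_dir`` is given, written to ``trace.csv`` along with the
    champion configuration in ``champion.yaml``.
    """
    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        key = np.round(position, 12).tobytes()
        if key not in cache:
            cache[key] = evaluate_candidate(
                position, space, data, weights, budget_epochs=budget_epochs,
                seed=seed, input_size=input_size).fitness
        return cache[key]

    result = optimize(objective, space, iwo_cfg)
    champion = evaluate_candidate(result.best_position, space, data, weights,
                                  budget_epochs=budget_epochs, seed=seed,
                                  input_size=input_size)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.history_frame().to_csv(out_dir / "trace.csv", index=False)
        import json

        import yaml
        from dataclasses import asdict
        champ = asdict(champion)
        champ["backbone"] = asdict(champion.backbone)
        champ = json.loads(json.dumps(champ, default=float))  # native types
        (out_dir / "champion.yaml").write_text(yaml.safe_dump(champ))
    return champion, result
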