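"""Simulator of the hierarchical cloud-edge feedback retraining loop.

Edge nodes classify incoming cases; predictions whose confirmed truth
disagrees are sent back to the cloud, appended to the cloud dataset, and the
cloud model is warm-start retrained and redeployed. Each round logs the
per-edge error counts, the growing dataset size, held-out accuracy of the
freshly retrained model, and the mean hop delay implied by the edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf
from .edge_planner import delay
from .synthetic_data import GeneratorConfig, LabeledImage, generate_dataset


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LoopConfig:
    rounds: int = 5
    cases_per_round: int = 20  # per edge
    n_edges: int = 2
    initial_cobra: int = 60
    initial_other: int = 60
    holdout_per_class: int = 30
    retrain_epochs: int = 5  # warm-start epochs per round
    retrain_enabled: bool = True
    confirmation_lag: int = 0  # rounds before truth is revealed
    train_config: clf.TrainConfig = field(
        default_factory=lambda: clf.TrainConfig(epochs=10, input_side=32))
    generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(image_size=32))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise SimulationError("rounds must be >= 1")
        if self.cases_per_round < 0:
            raise SimulationError("cases per round must be >= 0")
        if self.n_edges < 1:
            raise SimulationError("need at least one edge node")
        if self.confirmation_lag < 0:
            raise SimulationError("confirmation lag must be >= 0")


@dataclass
class RoundLog:
    round_index: int
    edge_errors: list[int]
    dataset_size: int
    accuracy: float
    mean_delay: float


def simulate_round(model: clf.TinyCNN, stream: list[LabeledImage],
                   seed: int = 0) -> tuple[list[str], list[LabeledImage]]:
    """Classify a stream of cases at one edge and collect the wrong ones.

    Returns the predictions and the misclassified cases carrying their
    confirmed true labels. Deterministic: inference has no randomness and the
    seed is kept only for interface symmetry with future confirmation models.
    """
    if not getattr(model, "trained", False):
        raise SimulationError("model must be trained before edge deployment")
    if not stream:
        return [], []
    predictions, _ = clf.predict(model, stream)
    missed = [case for case, pred in zip(stream, predictions)
              if case.label != pred]
    return predictions, missed


def feedback_update(cloud_dataset: list[LabeledImage],
                    misclassified: list[LabeledImage]) -> list[LabeledImage]:
    """Append misclassified cases (with confirmed labels) to the cloud set."""
    return list(cloud_dataset) + list(misclassified)


def run_loop(config: LoopConfig) -> list[RoundLog]:
    """Run the full feedback loop and return one log per round.

    The held-out evaluation set is generated up front from a dedicated seed
    and never enters the cloud dataset, so the accuracy trajectory measures
    generalization of each retrained model without leakage.
    """
    master = np.random.default_rng(config.seed)
    data_seed, holdout_seed, train_seed = master.integers(0, 2 ** 31 - 1, 3)

    cloud = generate_dataset(config.initial_cobra, config.initial_other,
                             config.generator, int(data_seed))
    holdout = generate_dataset(config.holdout_per_class,
                               config.holdout_per_class,
                               config.generator, int(holdout_seed))

    base_cfg = config.train_config
    model = clf.build_model(base_cfg)
    all_indices = {"train": list(range(len(cloud))), "val": [], "test": []}
    clf.train(model, cloud, clf.TrainConfig(
        epochs=base_cfg.epochs, learning_rate=base_cfg.learning_rate,
        epsilon=base_cfg.epsilon, batch_size=base_cfg.batch_size,
        backbone=base_cfg.backbone, seed=int(train_seed),
        split=base_cfg.split, input_side=base_cfg.input_side),
        splits=all_indices)

    logs: list[RoundLog] = []
    mean_delay = delay(config.n_edges)
    pending: list[list[LabeledImage]] = []  # confirmation-lag queue
    for r in range(config.rounds):
        round_rng = np.random.default_rng(config.seed + 1000 * (r + 1))
        edge_errors = []
        round_missed: list[LabeledImage] = []
        for edge in range(config.n_edges):
            n_cobra = int(round_rng.binomial(config.cases_per_round, 0.5))
            stream = generate_dataset(
                n_cobra, config.cases_per_round - n_cobra, config.generator,
                int(round_rng.integers(0, 2 ** 31 - 1)))
            _, missed = simulate_round(model, stream, seed=edge)
            edge_errors.append(len(missed))
            round_missed.extend(missed)

        pending.append(round_missed)
        confirmed: list[LabeledImage] = []
        if len(pending) > config.confirmation_lag:
            confirmed = pending.pop(0)
            cloud = feedback_update(cloud, confirmed)
        # retrain only when new confirmed cases arrived; with an empty
        # feedback stream the deployed model must stay frozen
        if config.retrain_enabled and config.retrain_epochs > 0 and confirmed:
            splits = {"train": list(range(len(cloud))), "val": [], "test": []}
            clf.train(model, cloud, clf.TrainConfig(
                epochs=config.retrain_epochs,
                learning_rate=base_cfg.learning_rate,
                epsilon=base_cfg.epsilon, batch_size=base_cfg.batch_size,
                backbone=base_cfg.backbone,
                seed=int(train_seed) + r + 1,
                split=base_cfg.split, input_side=base_cfg.input_side),
                splits=splits)

        preds, _ = clf.predict(model, holdout)
        acc = float(np.mean([p == h.label for p, h in zip(preds, holdout)]))
        logs.append(RoundLog(round_index=r, edge_errors=edge_errors,
                             dataset_size=len(cloud), accuracy=acc,
                             mean_delay=mean_delay))
    return logs
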