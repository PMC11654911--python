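"""Multi-objective fitness and the channel-search harness.

A candidate x in [-0.5, 0.5]^43 decodes to a channel plan; its quality is a
weighted blend of segmentation accuracy and model cost:

    fit_i = 0.6 * mIoU_i + 0.1 * P_i + 0.3 * f_i
    P_i   = 1 - params_i / sum(params)   over a comparison pool
    f_i   = 1 - flops_i  / sum(flops)

P_i and f_i are population-relative, so fitness values are only comparable
within one pool.  The search therefore freezes the normalization pool at the
initial population: every candidate in the run is scored against the same cost
sums, which restores a total order, makes the elitist best-fitness sequence
genuinely non-decreasing, and keeps the population-relative spirit (the sums
come from the same seeded run).  Re-normalizing over each generation's
population instead makes the archived best's fitness drift as the pool
changes, so the reported best can decrease without any real regression.

``evaluate_candidate`` trains the decoded network briefly (AdamW, focal+dice
loss) and measures mIoU on the validation split; parameter and FLOP counts
come from the architecture table and are exact.  A candidate whose training
diverges (non-finite loss) scores mIoU = 0 with a warning instead of aborting
the search.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import optimizer as opt
from .encoding import ChannelPlan, ReductionReport, decode_channels, summarize_plan
from .losses import segmentation_loss_and_grad
from .metrics import confusion, metrics_from_confusion
from .model import SegmentationNet, count_flops, count_parameters, reference_spec
from .synthdata import LodgingScene

__all__ = [
    "ObjectiveRecord",
    "FitnessWeights",
    "TrainConfig",
    "SearchResult",
    "fitness_components",
    "fitness",
    "scenes_to_arrays",
    "train_network",
    "validation_miou",
    "evaluate_candidate",
    "channel_search",
]


@dataclass(frozen=True)
class ObjectiveRecord:
    """Raw objectives of one evaluated candidate."""

    miou: float
    params: int
    flops: float
    plan: ChannelPlan

    def __post_init__(self) -> None:
        if not (np.isfinite(self.miou) and self.params > 0 and self.flops > 0):
            raise ValueError("objective record requires finite mIoU and positive costs")


@dataclass(frozen=True)
class FitnessWeights:
    w_miou: float = 0.6
    w_params: float = 0.1
    w_flops: float = 0.3

    def __post_init__(self) -> None:
        if abs(self.w_miou + self.w_params + self.w_flops - 1.0) > 1e-9:
            raise ValueError("fitness weights must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    """Per-candidate training budget (desk-scale defaults).

    The full-scale schedule (500 epochs, batch 4) is retained in run
    configurations for completeness; searches evaluate candidates with the
    short budget below.
    """

    epochs: int = 3
    batch_size: int = 4
    lr: float = 1.5e-3
    weight_decay: float = 5e-5
    w_focal: float = 1.0
    w_dice: float = 1.0
    gamma: float = 2.0


def fitness_components(records: list[ObjectiveRecord]) -> list[tuple[float, float]]:
    """(P_i, f_i) per record, normalized over the given comparison pool."""
    if len(records) < 2:
        raise ValueError("pool must contain at least 2 records to normalize")
    sum_p = float(sum(r.params for r in records))
    sum_f = float(sum(r.flops for r in records))
    return [(1.0 - r.params / sum_p, 1.0 - r.flops / sum_f) for r in records]


def fitness(
    record: ObjectiveRecord,
    components: tuple[float, float],
    weights: FitnessWeights = FitnessWeights(),
) -> float:
    p_i, f_i = components
    return weights.w_miou * record.miou + weights.w_params * p_i + weights.w_flops * f_i


def scenes_to_arrays(scenes: list[LodgingScene]) -> tuple[np.ndarray, np.ndarray]:
    """Stack scenes into model inputs (B, 3, H, W) and labels (B, H, W).

    Each image is standardized per channel to zero mean, unit variance (the
    usual preprocessing for short training budgets); using per-image statistics
    keeps the transform leakage-free between splits.
    """
    images = np.stack([s.image for s in scenes]).astype(np.float32) / 255.0
    images = images.transpose(0, 3, 1, 2)
    mean = images.mean(axis=(2, 3), keepdims=True)
    std = images.std(axis=(2, 3), keepdims=True) + 1e-6
    images = (images - mean) / std
    masks = np.stack([s.mask for s in scenes]).astype(np.int64)
    return np.ascontiguousarray(images), masks


def train_network(
    net: SegmentationNet,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    seed: int = 0,
) -> list[float]:
    """Mini-batch AdamW training; returns the per-step loss trace."""
    rng = np.random.default_rng(seed)
    optim = net.make_optimizer(lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = images.shape[0]
    losses: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            optim.zero_grad()
            logits = net.forward(images[idx])
            loss, dlogits = segmentation_loss_and_grad(
                logits, labels[idx], cfg.w_focal, cfg.w_dice, cfg.gamma
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss {loss}")
            net.backward(dlogits)
            optim.step()
            losses.append(loss)
    return losses


def validation_miou(
    net: SegmentationNet, images: np.ndarray, labels: np.ndarray, batch_size: int = 4
) -> float:
    """mIoU over the validation split, confusion accumulated across batches."""
    cm = None
    for start in range(0, images.shape[0], batch_size):
        pred = net.predict(images[start : start + batch_size])
        part = confusion(pred, labels[start : start + batch_size], 4)
        cm = part if cm is None else cm + part
    return float(metrics_from_confusion(cm).miou)


def evaluate_candidate(
    x: np.ndarray,
    base_plan: ChannelPlan,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    flops_hw: tuple[int, int] | None = None,
) -> ObjectiveRecord:
    """Decode, build, briefly train, and score one candidate."""
    plan = decode_channels(np.asarray(x, dtype=float), base_plan)
    spec = reference_spec(plan)
    hw = flops_hw or train_data[0].shape[2:]
    params = count_parameters(spec)
    flops = count_flops(spec, hw)
    net = SegmentationNet(plan, seed=seed)
    try:
        train_network(net, train_data[0], train_data[1], cfg, seed=seed)
        miou = validation_miou(net, val_data[0], val_data[1], cfg.batch_size)
    except FloatingPointError as err:
        warnings.warn(f"candidate training diverged ({err}); scoring mIoU = 0")
        miou = 0.0
    return ObjectiveRecord(miou=miou, params=params, flops=flops, plan=plan)


def evaluate_plan_metrics(
    plan: ChannelPlan,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    flops_hw: tuple[int, int] | None = None,
) -> dict:
    """Train a plan and report the full metric block (PA/MPA/mIoU/params/FLOPs)."""
    spec = reference_spec(plan)
    hw = flops_hw or train_data[0].shape[2:]
    net = SegmentationNet(plan, seed=seed)
    train_network(net, train_data[0], train_data[1], cfg, seed=seed)
    cm = None
    for start in range(0, val_data[0].shape[0], cfg.batch_size):
        pred = net.predict(val_data[0][start : start + cfg.batch_size])
        part = confusion(pred, val_data[1][start : start + cfg.batch_size], 4)
        cm = part if cm is None else cm + part
    report = metrics_from_confusion(cm)
    return {
        "PA_pct": 100.0 * report.pa,
        "MPA_pct": 100.0 * report.mpa,
        "mIoU_pct": 100.0 * report.miou,
        "params_M": count_parameters(spec) / 1e6,
        "FLOPs_G": count_flops(spec, hw) / 1e9,
    }


@dataclass
class SearchResult:
    best_plan: ChannelPlan
    best_record: ObjectiveRecord
    best_fitness: float
    report: ReductionReport
    history: list[dict]
    baseline_record: ObjectiveRecord | None = None


class _PooledObjective:
    """Scores candidates against the current pool's cost sums."""

    def __init__(self, evaluate, weights: FitnessWeights):
        self.evaluate = evaluate
        self.weights = weights
        self.sum_params = 1.0
        self.sum_flops = 1.0
        self.n_evals = 0

    def set_pool(self, records: list[ObjectiveRecord]) -> None:
        self.sum_params = float(sum(r.params for r in records))
        self.sum_flops = float(sum(r.flops for r in records))

    def score(self, record: ObjectiveRecord) -> float:
        p_i = 1.0 - record.params / self.sum_params
        f_i = 1.0 - record.flops / self.sum_flops
        return fitness(record, (p_i, f_i), self.weights)

    def __call__(self, x: np.ndarray) -> tuple[float, ObjectiveRecord]:
        record = self.evaluate(x, self.n_evals)
        self.n_evals += 1
        return self.score(record), record


def channel_search(
    base_plan: ChannelPlan,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    n: int = 8,
    iters: int = 10,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    weights: FitnessWeights = FitnessWeights(),
    flops_hw: tuple[int, int] | None = None,
) -> SearchResult:
    """AFOA-APOM search over [-0.5, 0.5]^43 for the best channel plan.

    Per-candidate training seeds derive deterministically from (seed,
    evaluation index), so a (seed, config) pair reproduces the whole run.
    """
    dim = len(base_plan)
    space = opt.SearchSpace.cube(dim, -0.5, 0.5)
    params = opt.StrategyParams(maxg=max(iters, 1), seed=seed)

    def evaluate(x: np.ndarray, eval_index: int) -> ObjectiveRecord:
        cand_seed = (seed * 1000003 + eval_index) % (2**31)
        return evaluate_candidate(
            x, base_plan, train_data, val_data, cfg, seed=cand_seed, flops_hw=flops_hw
        )

    pooled = _PooledObjective(evaluate, weights)
    # bootstrap: evaluate the initial population raw, then freeze the pool
    state = opt.init_population(space, n, lambda x: (0.0, evaluate(x, _bump(pooled))), params)
    pooled.set_pool([ind.record for ind in state.population])
    for ind in state.population:
        ind.fitness = pooled.score(ind.record)
        ind.memory_fitness = ind.fitness
    best_ix = int(np.argmax([ind.fitness for ind in state.population]))
    state.global_best = copy.deepcopy(state.population[best_ix])

    history: list[dict] = [_history_entry(0, state, {})]
    for _ in range(iters):
        opt.step(state, pooled, space, params)
        history.append(_history_entry(state.iteration, state, state.history[-1]["strategy_counts"]))

    best = state.global_best
    return SearchResult(
        best_plan=best.record.plan,
        best_record=best.record,
        best_fitness=float(best.fitness),
        report=summarize_plan(best.record.plan),
        history=history,
    )


def _bump(pooled: _PooledObjective) -> int:
    ix = pooled.n_evals
    pooled.n_evals += 1
    return ix


def _history_entry(iteration: int, state: opt.OptimizerState, counts: dict) -> dict:
    rec = state.global_best.record
    return {
        "iteration": iteration,
        "best_fitness": float(state.global_best.fitness),
        "best_miou": float(rec.miou),
        "best_params": int(rec.params),
        "best_flops": float(rec.flops),
        "strategy_counts": dict(counts),
        "n_evals": state.n_evals,
    }
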