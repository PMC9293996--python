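"""Multi-model training by successive halving.

Neural-network training is not repeatable across seeds: differently
initialized runs of the same architecture end at different quality. To
reduce the chance of shipping a subpar model, a fixed successive-halving
bracket trains several differently seeded runs concurrently and eliminates
the worse half at fixed iteration milestones, judged by validation Jaccard
measured at the shared milestone (equal budget for every competitor). The
default bracket starts 16 runs and halves at 5k, 10k, 20k and 40k
iterations; the survivor trains to 80k. Its total budget is 240k iterations,
exactly three times a single 80k training. No hyper-parameters are searched;
runs differ only in their random seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .config import NetworkConfig, ScheduleConfig, TrainConfig
from .nn import AUNet
from .train import Case, Trainer

log = logging.getLogger("hepaseg")


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered stages of (surviving run count, cumulative iteration milestone)."""

    stages: tuple[tuple[int, int], ...] = (
        (16, 5_000), (8, 10_000), (4, 20_000), (2, 40_000), (1, 80_000))

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        counts = [n for n, _ in self.stages]
        miles = [m for _, m in self.stages]
        if counts[-1] != 1:
            raise ValueError("the last stage must keep exactly one run")
        if any(a <= b for a, b in zip(counts, counts[1:])):
            raise ValueError("run counts must be strictly decreasing")
        if any(a >= b for a, b in zip(miles, miles[1:])):
            raise ValueError("milestones must be strictly increasing")
        if any(n < 1 or m < 1 for n, m in self.stages):
            raise ValueError("counts and milestones must be positive")

    @property
    def initial_runs(self) -> int:
        return self.stages[0][0]

    @classmethod
    def from_config(cls, cfg: ScheduleConfig) -> "TrainingSchedule":
        return cls(tuple(cfg.stages))

    @classmethod
    def parse(cls, text: str) -> "TrainingSchedule":
        """Parse '16@5000,8@10000,...' into a schedule."""
        stages = []
        for part in text.split(","):
            n, m = part.strip().split("@")
            stages.append((int(n), int(m)))
        return cls(tuple(stages))


def total_iterations(s: TrainingSchedule) -> int:
    """Total iterations summed over all runs of the bracket."""
    total = 0
    prev = 0
    for count, milestone in s.stages:
        total += count * (milestone - prev)
        prev = milestone
    return total


@dataclass
class RunRecord:
    """Per-run bookkeeping of one successive-halving competitor."""

    run_id: int
    seed: int
    iterations: int = 0
    history: list[tuple[int, float]] = field(default_factory=list)
    alive: bool = True
    eliminated_at: int | None = None
    failed: bool = False

    def jaccard_at(self, milestone: int) -> float:
        if self.failed:
            return -np.inf     # failed runs are eliminated first
        for it, j in self.history:
            if it == milestone:
                return j
        raise KeyError(f"run {self.run_id}: no validation at milestone {milestone}")


def select_survivors(records: list[RunRecord], keep: int, milestone: int) -> list[int]:
    """Keep the runs with the highest validation Jaccard at the milestone.

    Ties are broken toward the lower run id. Eliminated runs are marked dead
    with their elimination milestone. ``keep`` >= number of alive runs is a
    no-op with a warning.
    """
    alive = [r for r in records if r.alive]
    if any(not r.failed and r.iterations < milestone for r in alive):
        raise ValueError(f"not all alive runs have reached milestone {milestone}")
    if keep >= len(alive):
        log.warning("select_survivors: keep=%d >= alive=%d, nothing to eliminate",
                    keep, len(alive))
        return [r.run_id for r in alive]
    ranked = sorted(alive, key=lambda r: (-r.jaccard_at(milestone), r.run_id))
    survivors = {r.run_id for r in ranked[:keep]}
    for r in alive:
        if r.run_id not in survivors:
            r.alive = False
            r.eliminated_at = milestone
            r.iterations = milestone
    return sorted(survivors)


def run_multi_model(cases: list[Case], val_cases: list[Case],
                    network_cfg: NetworkConfig, train_cfg: TrainConfig,
                    schedule: TrainingSchedule,
                    augment_cfg: AugmentConfig | None = None,
                    base_seed: int = 0, workers: int = 1,
                    ) -> tuple[Trainer, list[RunRecord]]:
    """Run the full successive-halving bracket; returns the surviving trainer
    (restored to its best checkpoint) and the complete run-record table.

    Stage-1 runs use seeds ``base_seed + run_id`` for both weight
    initialization and patch order. Execution is sequential and fully
    deterministic; ``workers`` is accepted for interface compatibility and
    never changes results (runs are independent between milestones). A run
    failing with a non-finite loss is recorded as failed and eliminated at
    the next selection.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    n_runs = schedule.initial_runs
    records = [RunRecord(run_id=i, seed=base_seed + i) for i in range(n_runs)]
    trainers: dict[int, Trainer] = {}
    for i in range(n_runs):
        net = AUNet(network_cfg, seed=base_seed + i)
        trainers[i] = Trainer(net, cases, val_cases, train_cfg, augment_cfg,
                              seed=base_seed + i)

    for stage_idx, (count, milestone) in enumerate(schedule.stages):
        for rec in records:
            if not rec.alive or rec.failed:
                continue
            trainer = trainers[rec.run_id]
            try:
                trainer.run(milestone)
            except RuntimeError as exc:
                log.error("run %d failed: %s; penalized at next selection",
                          rec.run_id, exc)
                rec.failed = True
                rec.iterations = trainer.state.iteration
                rec.history = list(trainer.state.history)
                continue
            rec.iterations = trainer.state.iteration
            rec.history = list(trainer.state.history)
        if stage_idx + 1 < len(schedule.stages):
            keep = schedule.stages[stage_idx + 1][0]
            select_survivors(records, keep, milestone)
            for rec in records:
                if not rec.alive and rec.run_id in trainers:
                    del trainers[rec.run_id]   # free eliminated runs

    (winner_id,) = [r.run_id for r in records if r.alive]
    winner = trainers[winner_id]
    winner.restore_best()
    return winner, records


def records_table(records: list[RunRecord]) -> pd.DataFrame:
    """Record table as a DataFrame (one row per run and milestone)."""
    rows = []
    for r in records:
        for it, j in r.history:
            rows.append({"run_id": r.run_id, "seed": r.seed, "iteration": it,
                         "val_jaccard": j, "alive": r.alive,
                         "eliminated_at": r.eliminated_at})
    return pd.DataFrame(rows)
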