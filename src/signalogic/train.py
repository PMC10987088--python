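"""Genetic-algorithm training of gate selections against perturbation data.

Each individual is a bitstring over the scaffold's gates. Fitness is
the simulation mean squared error plus unresolved and size penalties
(see :mod:`signalogic.boolean_core`). Many independent GA runs produce
a *model family*; the per-gate selection frequency across the family is
the edge-confidence measure, and gates above a confidence threshold
form the high-confidence submodel used for phenotype analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .boolean_core import FitnessEvaluator, FitnessResult, LogicModel
from .dataprep import ExperimentalDesign, NormalizedDataset
from .preprocess import ScaffoldModel


@dataclass(frozen=True)
class GAParams:
    """Hyperparameters of one GA run.

    Defaults are sized so a hundred runs on a ~30-node scaffold finish
    in minutes; all are configurable.
    """

    population: int = 50
    generations: int = 200
    mutation_prob: float = 0.01
    elitism: int = 2
    tournament: int = 3
    stall_limit: int = 50
    crossover_prob: float = 0.7
    seed: int = 0
    theta_size: float = 1e-4
    theta_na: float = 1.0

    def __post_init__(self) -> None:
        if min(self.population, self.generations, self.elitism,
               self.tournament, self.stall_limit) <= 0:
            raise ValueError("GA sizes must be positive")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must be in [0, 1]")


@dataclass
class FamilyMember:
    selection: tuple[int, ...]
    fitness: FitnessResult
    seed: int


@dataclass
class ModelFamily:
    """Best-of-run models sorted by total fitness (ascending)."""

    scaffold: ScaffoldModel
    members: list[FamilyMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members.sort(key=lambda m: m.fitness.total)

    def __len__(self) -> int:
        return len(self.members)

    def totals(self) -> list[float]:
        return [m.fitness.total for m in self.members]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "selection": list(m.selection),
                "seed": m.seed,
                "mse": m.fitness.mse,
                "na_penalty": m.fitness.na_penalty,
                "size_penalty": m.fitness.size_penalty,
                "total": m.fitness.total,
                "n_points": m.fitness.n_points,
            }
            for m in self.members
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class EdgeConfidence:
    """Per-gate selection frequency across a model family."""

    frequencies: tuple[float, ...]

    def __getitem__(self, i: int) -> float:
        return self.frequencies[i]

    def to_tsv(self, scaffold: ScaffoldModel, path: str | Path) -> None:
        lines = ["gate\tfrequency"]
        for g, f in zip(scaffold.gates, self.frequencies):
            lines.append(f"{g.label()}\t{f:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def ga_optimize(
    scaffold: ScaffoldModel,
    dataset: NormalizedDataset,
    design: ExperimentalDesign,
    params: GAParams = GAParams(),
    evaluator: FitnessEvaluator | None = None,
) -> tuple[tuple[int, ...], FitnessResult]:
    """One GA run; returns the best selection ever evaluated.

    Deterministic given ``params.seed``. Initial population: random
    bitstrings at 50% density plus one all-ones individual, so the full
    scaffold is always evaluated. Selection is tournament; elites are
    carried over unchanged; the run stops early after ``stall_limit``
    generations without improvement.
    """
    if scaffold.n_gates == 0:
        raise ValueError("cannot optimize an empty scaffold")
    ev = evaluator or FitnessEvaluator(
        scaffold, dataset, design,
        theta_size=params.theta_size, theta_na=params.theta_na,
    )
    rng = np.random.default_rng(params.seed)
    n = scaffold.n_gates
    pop = [tuple(map(int, rng.integers(0, 2, n)))
           for _ in range(params.population - 1)]
    pop.append((1,) * n)

    def fit(ind: tuple[int, ...]) -> float:
        return ev(ind).total

    scores = [fit(ind) for ind in pop]
    best_i = int(np.argmin(scores))
    best, best_score = pop[best_i], scores[best_i]
    stall = 0
    for _ in range(params.generations):
        order = np.argsort(scores, kind="stable")
        elites = [pop[i] for i in order[: params.elitism]]
        children: list[tuple[int, ...]] = list(elites)
        while len(children) < params.population:
            idx = rng.integers(0, len(pop), params.tournament)
            p1 = pop[min(idx, key=lambda i: scores[i])]
            idx = rng.integers(0, len(pop), params.tournament)
            p2 = pop[min(idx, key=lambda i: scores[i])]
            if rng.random() < params.crossover_prob:
                mask = rng.integers(0, 2, n)
                child = tuple(
                    int(a if m else b) for a, b, m in zip(p1, p2, mask)
                )
            else:
                child = p1
            flips = rng.random(n) < params.mutation_prob
            if flips.any():
                child = tuple(
                    int(b ^ 1) if f else b for b, f in zip(child, flips)
                )
            children.append(child)
        pop = children
        scores = [fit(ind) for ind in pop]
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score:
            best, best_score = pop[gen_best], scores[gen_best]
            stall = 0
        else:
            stall += 1
            if stall >= params.stall_limit:
                break
    return best, ev(best)


def build_family(
    scaffold: ScaffoldModel,
    dataset: NormalizedDataset,
    design: ExperimentalDesign,
    n_runs: int = 100,
    keep: int = 20,
    base_seed: int = 0,
    params: GAParams = GAParams(),
) -> ModelFamily:
    """Run the GA ``n_runs`` times (seeds base_seed..base_seed+n_runs-1)
    and keep the ``keep`` lowest-fitness results.

    The study-scale configuration is ``n_runs=1000, keep=100``; the
    default is a desk-scale 100/20.
    """
    if n_runs < keep:
        raise ValueError("n_runs must be >= keep")
    ev = FitnessEvaluator(
        scaffold, dataset, design,
        theta_size=params.theta_size, theta_na=params.theta_na,
    )
    members = []
    for i in range(n_runs):
        seed = base_seed + i
        sel, fr = ga_optimize(
            scaffold, dataset, design,
            params=replace(params, seed=seed), evaluator=ev,
        )
        members.append(FamilyMember(selection=sel, fitness=fr, seed=seed))
    members.sort(key=lambda m: m.fitness.total)
    return ModelFamily(scaffold=scaffold, members=members[:keep])


def edge_frequencies(family: ModelFamily) -> EdgeConfidence:
    """Fraction of family models selecting each gate."""
    if not family.members:
        raise ValueError("empty family")
    n = family.scaffold.n_gates
    counts = np.zeros(n)
    for m in family.members:
        counts += np.asarray(m.selection)
    return EdgeConfidence(tuple(counts / len(family.members)))


def select_best(family: ModelFamily) -> LogicModel:
    """Lowest total fitness; ties broken by fewer selected gates, then
    lexicographically smallest bitstring."""
    if not family.members:
        raise ValueError("empty family")
    best = min(
        family.members,
        key=lambda m: (m.fitness.total, sum(m.selection), m.selection),
    )
    return LogicModel(family.scaffold, best.selection)


def high_confidence_submodel(
    best: LogicModel, conf: EdgeConfidence, threshold: float = 0.4
) -> LogicModel:
    """Restrict ``best`` to gates with family frequency strictly above
    ``threshold`` (the display/phenotype-analysis model)."""
    if len(conf.frequencies) != best.scaffold.n_gates:
        raise ValueError("confidence does not cover the scaffold")
    sel = tuple(
        b if conf.frequencies[i] > threshold else 0
        for i, b in enumerate(best.selection)
    )
    if not any(sel):
        import logging

        logging.getLogger(__name__).warning(
            "high-confidence submodel is empty at threshold %.2f", threshold
        )
    return LogicModel(best.scaffold, sel)
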