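"""Synchronous Boolean simulation, steady states, and model fitness.

A logic model is a scaffold (candidate AND gates) plus a selection
bitstring saying which gates are active. Under a clamp condition the
network is updated synchronously: every node simultaneously becomes the
OR over its selected gates, each gate the AND of its literals (+1 input
must be 1, -1 input must be 0). Clamped nodes are re-forced to their
clamp value every step; nodes with no selected gate hold their value.
The trajectory either reaches a fixpoint or enters a cycle; nodes that
vary within a cycle are reported as :data:`UNRESOLVED`.

Implementation note: states are packed as Python-int bitmasks with one
bit per condition, so all conditions of a training design advance in a
single synchronous pass. This is what makes genetic-algorithm training
(thousands of fitness evaluations) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataprep import ExperimentalDesign, NormalizedDataset
from .preprocess import Gate, ScaffoldModel


class _Unresolved:
    """Singleton marker for nodes oscillating at steady state."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNRESOLVED"


UNRESOLVED = _Unresolved()


@dataclass(frozen=True)
class ClampCondition:
    """Nodes forced ON (stimuli, constitutive receptors) or OFF (drugged)."""

    name: str
    clamp_on: frozenset[str] = frozenset()
    clamp_off: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.clamp_on & self.clamp_off
        if overlap:
            raise ValueError(f"nodes clamped both on and off: {sorted(overlap)}")


@dataclass
class LogicModel:
    """A scaffold plus the gate-selection bitstring."""

    scaffold: ScaffoldModel
    selection: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.selection) != self.scaffold.n_gates:
            raise ValueError(
                f"selection length {len(self.selection)} != "
                f"{self.scaffold.n_gates} gates"
            )
        self.selection = tuple(int(bool(b)) for b in self.selection)

    @property
    def nodes(self) -> list[str]:
        return self.scaffold.species

    @property
    def selected_gates(self) -> list[Gate]:
        return [g for g, b in zip(self.scaffold.gates, self.selection) if b]

    @property
    def n_selected(self) -> int:
        return sum(self.selection)

    @classmethod
    def full(cls, scaffold: ScaffoldModel) -> "LogicModel":
        return cls(scaffold, (1,) * scaffold.n_gates)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "species": self.scaffold.species,
            "gates": [
                {
                    "output": g.output,
                    "inputs": [[n, s] for n, s in g.inputs],
                    "provenance": g.provenance,
                }
                for g in self.scaffold.gates
            ],
            "selection": list(self.selection),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "LogicModel":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        scaffold = ScaffoldModel(
            species=list(payload["species"]),
            gates=[
                Gate(
                    output=g["output"],
                    inputs=tuple((n, int(s)) for n, s in g["inputs"]),
                    provenance=g.get("provenance", "curated"),
                )
                for g in payload["gates"]
            ],
        )
        return cls(scaffold, tuple(payload["selection"]))


@dataclass
class SteadyState:
    """Node values at the end of a synchronous simulation.

    ``converged`` is True iff a fixpoint was reached; ``cycle_period``
    is set (> 1) when the trajectory entered a limit cycle, in which
    case nodes varying within the cycle are :data:`UNRESOLVED` and
    constant ones keep their value. If ``max_iter`` ran out with
    neither, every non-clamped node is UNRESOLVED and ``converged`` is
    False with ``cycle_period`` None.
    """

    values: dict[str, object]
    iterations: int
    converged: bool
    cycle_period: int | None = None

    def __getitem__(self, node: str):
        return self.values[node]

    def resolved(self) -> dict[str, int]:
        return {n: v for n, v in self.values.items() if v is not UNRESOLVED}


@dataclass
class FitnessResult:
    """Decomposed fitness of a model against the normalized dataset."""

    mse: float
    n_points: int
    na_penalty: float
    size_penalty: float

    @property
    def total(self) -> float:
        return self.mse + self.na_penalty + self.size_penalty


# ---------------------------------------------------------------------------
# compiled engine


class CompiledScaffold:
    """Index-based view of a scaffold for the bitmask engine."""

    def __init__(self, scaffold: ScaffoldModel):
        self.scaffold = scaffold
        self.species = list(scaffold.species)
        self.index = {n: i for i, n in enumerate(self.species)}
        self.gates: list[tuple[int, tuple[int, ...], tuple[int, ...]]] = []
        for g in scaffold.gates:
            pos = tuple(self.index[n] for n, s in g.inputs if s > 0)
            neg = tuple(self.index[n] for n, s in g.inputs if s < 0)
            self.gates.append((self.index[g.output], pos, neg))

    def masks(self, clamps: Sequence[ClampCondition]) -> tuple[list[int], list[int]]:
        """Per-node ON/OFF bitmasks over a list of clamp conditions."""
        n = len(self.species)
        on = [0] * n
        off = [0] * n
        for c, clamp in enumerate(clamps):
            bit = 1 << c
            for name in clamp.clamp_on:
                if name in self.index:
                    on[self.index[name]] |= bit
            for name in clamp.clamp_off:
                if name in self.index:
                    off[self.index[name]] |= bit
        return on, off


def _run_masked(
    compiled: CompiledScaffold,
    selection: Sequence[int],
    on: Sequence[int],
    off: Sequence[int],
    init: Sequence[int],
    n_cond: int,
    max_iter: int,
) -> tuple[list[int], list[int], int, bool, int | None]:
    """Bitmask simulation over ``n_cond`` parallel clamp conditions.

    Returns (values, unresolved_masks, iterations, fixpoint, period):
    per-node ints whose bit c is the state / unresolved flag in
    condition c.
    """
    full = (1 << n_cond) - 1
    n = len(compiled.species)
    gates_by_node: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = [
        [] for _ in range(n)
    ]
    for (out, pos, neg), sel in zip(compiled.gates, selection):
        if sel:
            gates_by_node[out].append((pos, neg))
    keep = [full ^ (on[i] | off[i]) for i in range(n)]
    state = [((init[i] & keep[i]) | on[i]) & full for i in range(n)]

    history: dict[tuple[int, ...], int] = {tuple(state): 0}
    traj: list[list[int]] = [list(state)]
    for t in range(1, max_iter + 1):
        new = []
        for i in range(n):
            gl = gates_by_node[i]
            if not gl:
                v = state[i]
            else:
                v = 0
                for pos, neg in gl:
                    g = full
                    for j in pos:
                        g &= state[j]
                    for j in neg:
                        g &= full ^ state[j]
                    v |= g
            new.append((v & keep[i]) | on[i])
        state = new
        key = tuple(state)
        if key in history:
            t0 = history[key]
            period = t - t0
            if period == 1:
                return state, [0] * n, t, True, None
            cyc = traj[t0:]
            or_m = [0] * n
            and_m = [full] * n
            for s in cyc:
                for i in range(n):
                    or_m[i] |= s[i]
                    and_m[i] &= s[i]
            unres = [or_m[i] & (full ^ and_m[i]) for i in range(n)]
            values = [and_m[i] for i in range(n)]
            return values, unres, t, False, period
        history[key] = t
        traj.append(list(state))
    # no fixpoint, no cycle within budget: everything non-clamped unresolved
    unres = [keep[i] for i in range(n)]
    values = [on[i] for i in range(n)]
    return values, unres, max_iter, False, None


def simulate_conditions(
    model: LogicModel,
    clamps: Sequence[ClampCondition],
    initial: Mapping[str, int] | None = None,
    max_iter: int = 100,
    compiled: CompiledScaffold | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool, int | None]:
    """Simulate all ``clamps`` in parallel.

    Returns (values, unresolved, iterations, fixpoint, period) where
    ``values`` is a float array (n_conditions, n_nodes) of 0/1 with NaN
    at unresolved entries and ``unresolved`` the boolean mask.
    """
    comp = compiled or CompiledScaffold(model.scaffold)
    n_cond = len(clamps)
    n = len(comp.species)
    on, off = comp.masks(clamps)
    full = (1 << n_cond) - 1
    init = [0] * n
    if initial:
        for name, v in initial.items():
            if name in comp.index and v:
                init[comp.index[name]] = full
    vals, unres, iters, fix, period = _run_masked(
        comp, model.selection, on, off, init, n_cond, max_iter
    )
    out = np.zeros((n_cond, n), dtype=float)
    mask = np.zeros((n_cond, n), dtype=bool)
    for i in range(n):
        for c in range(n_cond):
            bit = 1 << c
            if unres[i] & bit:
                out[c, i] = np.nan
                mask[c, i] = True
            else:
                out[c, i] = 1.0 if vals[i] & bit else 0.0
    return out, mask, iters, fix, period


def simulate_synchronous(
    model: LogicModel,
    condition: ClampCondition,
    initial: Mapping[str, int] | None = None,
    max_iter: int = 100,
) -> SteadyState:
    """Synchronous steady state of ``model`` under one clamp condition."""
    unknown = (condition.clamp_on | condition.clamp_off) - set(model.nodes)
    if unknown:
        raise ValueError(f"clamp refers to unknown nodes: {sorted(unknown)}")
    vals, mask, iters, fix, period = simulate_conditions(
        model, [condition], initial=initial, max_iter=max_iter
    )
    values: dict[str, object] = {}
    for i, name in enumerate(model.nodes):
        values[name] = UNRESOLVED if mask[0, i] else int(vals[0, i])
    return SteadyState(values=values, iterations=iters, converged=fix,
                       cycle_period=period)


def training_clamps(design: ExperimentalDesign,
                    species: Iterable[str]) -> list[ClampCondition]:
    """Clamp conditions for the training design.

    Stimuli present in a condition are clamped ON, drug targets OFF,
    and constitutive receptors ON unless inhibited. Clamps are
    restricted to nodes present in ``species``.
    """
    sp = set(species)
    clamps = []
    for cond in design.conditions:
        on = (set(cond.stimuli_on) | (set(design.constitutive) - set(cond.inhibited)))
        off = set(cond.inhibited)
        clamps.append(
            ClampCondition(cond.name, frozenset(on & sp), frozenset(off & sp))
        )
    return clamps


class FitnessEvaluator:
    """Precompiled, cached fitness of gate selections against a dataset.

    Shared by the trainer so that repeated evaluations of the same
    bitstring (frequent once a GA population converges) cost a
    dictionary lookup.
    """

    def __init__(
        self,
        scaffold: ScaffoldModel,
        dataset: NormalizedDataset,
        design: ExperimentalDesign,
        theta_size: float = 1e-4,
        theta_na: float = 1.0,
        max_iter: int = 100,
    ):
        self.scaffold = scaffold
        self.compiled = CompiledScaffold(scaffold)
        self.design = design
        self.theta_size = theta_size
        self.theta_na = theta_na
        self.max_iter = max_iter

        missing = [s for s in design.sentinel_nodes()
                   if s in dataset.analytes and s not in self.compiled.index]
        if missing:
            raise ValueError(f"sentinels not in model: {missing}")
        self.sentinels = [s for s in design.sentinel_nodes()
                          if s in dataset.analytes]
        if not self.sentinels:
            raise ValueError("no measured sentinel maps to the dataset")
        self.sent_idx = [self.compiled.index[s] for s in self.sentinels]
        cond_names = [c.name for c in design.conditions]
        self.data = dataset.t1.loc[cond_names, self.sentinels].to_numpy(dtype=float)
        if not np.isfinite(self.data).any():
            raise ValueError("all data cells are masked; nothing to fit")
        self.n_cond = len(cond_names)
        self.clamps = training_clamps(design, scaffold.species)
        self.on, self.off = self.compiled.masks(self.clamps)
        self.total_inputs = scaffold.total_inputs
        self.arities = [g.arity for g in scaffold.gates]
        self._cache: dict[tuple[int, ...], FitnessResult] = {}

    def __call__(self, selection: Sequence[int]) -> FitnessResult:
        key = tuple(int(b) for b in selection)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = len(self.compiled.species)
        vals, unres, _, _, _ = _run_masked(
            self.compiled, key, self.on, self.off, [0] * n,
            self.n_cond, self.max_iter,
        )
        sse = 0.0
        n_points = 0
        n_na = 0
        for c in range(self.n_cond):
            bit = 1 << c
            row = self.data[c]
            for k, i in enumerate(self.sent_idx):
                d = row[k]
                if not np.isfinite(d):
                    continue
                n_points += 1
                if unres[i] & bit:
                    n_na += 1
                else:
                    sim = 1.0 if vals[i] & bit else 0.0
                    sse += (sim - d) ** 2
        sel_inputs = sum(a for a, b in zip(self.arities, key) if b)
        size_pen = self.theta_size * (
            sel_inputs / self.total_inputs if self.total_inputs else 0.0
        )
        result = FitnessResult(
            mse=sse / n_points if n_points else 0.0,
            n_points=n_points,
            na_penalty=(self.theta_na * n_na / n_points) if n_points else 0.0,
            size_penalty=size_pen,
        )
        self._cache[key] = result
        return result


def mse_fitness(
    model: LogicModel,
    dataset: NormalizedDataset,
    design: ExperimentalDesign,
    theta_size: float = 1e-4,
    theta_na: float = 1.0,
) -> FitnessResult:
    """Fitness of one model: mean squared deviation of simulated steady
    states from the normalized T1 values, plus unresolved-prediction and
    model-size penalties."""
    return FitnessEvaluator(
        model.scaffold, dataset, design,
        theta_size=theta_size, theta_na=theta_na,
    )(model.selection)


def activity_modulation(
    state_t1: Mapping[str, object], baseline_t0: Mapping[str, object]
) -> dict[str, float | None]:
    """Per-node activity change T1 - T0 clipped to [-1, 1].

    Family-averaged states may be fractional. Nodes UNRESOLVED in
    either state are masked (None).
    """
    if set(state_t1) != set(baseline_t0):
        raise ValueError("states must cover the same nodes")
    out: dict[str, float | None] = {}
    for node, v1 in state_t1.items():
        v0 = baseline_t0[node]
        if v1 is UNRESOLVED or v0 is UNRESOLVED:
            out[node] = None
        else:
            out[node] = float(np.clip(float(v1) - float(v0), -1.0, 1.0))
    return out
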