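"""PKN -> trainable AND/OR hypergraph scaffold.

Three stages, mirroring standard logic-model preprocessing:

* *compression* removes nodes that are neither measured nor targeted
  nor phenotypes, bypassing pass-through nodes with sign-product edges;
* *expansion* connects each remaining node to every combination of its
  upstream regulators with AND gates (OR is implicit across a node's
  gates);
* *imputation* adds data-derived candidate edges from strong
  correlations between analyte profiles in the perturbation data.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataprep import ExperimentalDesign, NormalizedDataset
from .network_io import CausalEdge, CausalNetwork, NodeSpec

logger = logging.getLogger(__name__)

#: Compression bypasses a pass-through node only when reconnecting its
#: neighbors adds at most this many edges; larger hubs are retained to
#: avoid quadratic edge blow-up.
MAX_BYPASS_FANPRODUCT = 4


@dataclass(frozen=True)
class Gate:
    """AND-of-literals hyperedge regulating one node.

    The gate fires iff every +1 input is 1 and every -1 input is 0.
    A node's update value is the OR over its selected gates.
    """

    output: str
    inputs: tuple[tuple[str, int], ...]
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if len(self.inputs) < 1:
            raise ValueError("gate arity must be >= 1")
        if len({n for n, _ in self.inputs}) != len(self.inputs):
            raise ValueError("gate inputs must be unique nodes")
        for _, s in self.inputs:
            if s not in (1, -1):
                raise ValueError("gate input sign must be +1 or -1")

    @property
    def arity(self) -> int:
        return len(self.inputs)

    def label(self) -> str:
        lits = "^".join(("" if s > 0 else "!") + n for n, s in self.inputs)
        return f"{lits}->{self.output}"


@dataclass
class ScaffoldModel:
    """Species nodes plus candidate gates; the logic-model search space."""

    species: list[str]
    gates: list[Gate]
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sp = set(self.species)
        for g in self.gates:
            if g.output not in sp:
                raise ValueError(f"gate output {g.output!r} not a species")
            for n, _ in g.inputs:
                if n not in sp:
                    raise ValueError(f"gate input {n!r} not a species")
        if not self.provenance:
            self.provenance = {i: g.provenance for i, g in enumerate(self.gates)}

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    @property
    def n_and_nodes(self) -> int:
        """Gates with arity >= 2, counted as AND operator pseudo-nodes."""
        return sum(1 for g in self.gates if g.arity >= 2)

    @property
    def total_inputs(self) -> int:
        return sum(g.arity for g in self.gates)

    def gates_for(self, node: str) -> list[int]:
        return [i for i, g in enumerate(self.gates) if g.output == node]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "gates": [
                {
                    "output": g.output,
                    "inputs": [[n, s] for n, s in g.inputs],
                    "provenance": g.provenance,
                }
                for g in self.gates
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaffoldModel":
        payload = json.loads(Path(path).read_text())
        gates = [
            Gate(
                output=g["output"],
                inputs=tuple((n, int(s)) for n, s in g["inputs"]),
                provenance=g.get("provenance", "curated"),
            )
            for g in payload["gates"]
        ]
        return cls(species=list(payload["species"]), gates=gates)

    def to_sif(self, path: str | Path) -> None:
        """Export with AND gates materialized as ``and<k>`` pseudo-nodes."""
        lines = []
        k = 0
        for g in self.gates:
            if g.arity == 1:
                (n, s), = g.inputs
                lines.append(f"{n}\t{s}\t{g.output}")
            else:
                k += 1
                andname = f"and{k}"
                for n, s in g.inputs:
                    lines.append(f"{n}\t{s}\t{andname}")
                lines.append(f"{andname}\t1\t{g.output}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _protected_nodes(net: CausalNetwork, design: ExperimentalDesign) -> set[str]:
    protected = set(design.cue_nodes()) | set(design.sentinel_nodes())
    protected |= set(design.constitutive)
    protected |= {
        n for n, spec in net.nodes.items()
        if spec.category in ("phenotype", "stimulus") or spec.is_measured
        or spec.is_targeted
    }
    return protected


def compress(net: CausalNetwork, design: ExperimentalDesign) -> CausalNetwork:
    """Remove unmeasured, untargeted pass-through nodes from the PKN.

    A non-designated node with both in- and out-edges is bypassed by
    connecting each (upstream, downstream) pair with the sign product of
    the two traversed edges; non-designated sources and sinks are
    deleted outright. Iterates to fixpoint. Nodes with self-loops are
    never bypassed, and hubs whose bypass would add more than
    ``MAX_BYPASS_FANPRODUCT`` edges are retained.
    """
    protected = _protected_nodes(net, design)
    edges = {(e.source, e.target): e.sign for e in net.edges}
    # parallel edges with opposite signs are kept as a pair
    multi: set[tuple[str, str, int]] = {(e.source, e.target, e.sign) for e in net.edges}
    nodes = dict(net.nodes)

    def in_edges(n: str) -> list[tuple[str, str, int]]:
        return [e for e in multi if e[1] == n]

    def out_edges(n: str) -> list[tuple[str, str, int]]:
        return [e for e in multi if e[0] == n]

    changed = True
    while changed:
        changed = False
        for name in sorted(set(nodes) - protected):
            ins = [e for e in in_edges(name) if e[0] != name]
            outs = [e for e in out_edges(name) if e[1] != name]
            has_self_loop = any(e[0] == e[1] == name for e in multi)
            if has_self_loop:
                continue
            if not ins or not outs:
                # dangling: remove node and its incident edges
                for e in in_edges(name) + out_edges(name):
                    multi.discard(e)
                del nodes[name]
                changed = True
                continue
            if len(ins) * len(outs) > MAX_BYPASS_FANPRODUCT:
                continue
            for (u, _, s1) in ins:
                for (_, v, s2) in outs:
                    if u == v:
                        continue  # would create a self-loop; drop
                    multi.add((u, v, s1 * s2))
            for e in in_edges(name) + out_edges(name):
                multi.discard(e)
            del nodes[name]
            changed = True

    out_edges_list = sorted(multi)
    return CausalNetwork(
        nodes=nodes,
        edges=[CausalEdge(u, v, s) for u, v, s in out_edges_list],
    )


def expand(net: CausalNetwork, max_gate_inputs: int = 2) -> ScaffoldModel:
    """Build the AND/OR gate scaffold from a (compressed) network.

    For every node with regulator set R: one arity-1 gate per regulator
    plus one AND gate per subset of R of size 2..min(|R|,
    ``max_gate_inputs``). Gate ordering is deterministic
    (lexicographic). Gate count for k regulators is therefore
    ``k + sum_{j=2..min(k,m)} C(k, j)``.
    """
    if max_gate_inputs < 2:
        raise ValueError("max_gate_inputs must be >= 2")
    prov_by_edge = {
        (e.source, e.target, e.sign): e.provenance for e in net.edges
    }
    gates: list[Gate] = []
    for node in sorted(net.nodes):
        regs = net.regulators(node)
        regs = [r for r in regs if r[0] != node]  # self-loops not expanded
        for n, s in regs:
            gates.append(Gate(node, ((n, s),),
                              provenance=prov_by_edge.get((n, node, s), "curated")))
        top = min(len(regs), max_gate_inputs)
        for j in range(2, top + 1):
            for combo in itertools.combinations(regs, j):
                names = [n for n, _ in combo]
                if len(set(names)) < len(names):
                    continue  # same regulator with both signs: no AND
                prov = (
                    "data-derived"
                    if any(
                        prov_by_edge.get((n, node, s)) == "data-derived"
                        for n, s in combo
                    )
                    else "curated"
                )
                gates.append(Gate(node, tuple(combo), provenance=prov))
    return ScaffoldModel(species=sorted(net.nodes), gates=gates)


def impute_data_edges(
    net: CausalNetwork,
    dataset: NormalizedDataset,
    design: ExperimentalDesign,
    r_threshold: float = 0.75,
) -> list[CausalEdge]:
    """Propose data-derived edges from strong profile correlations.

    For each ordered pair of measured analytes (u, v) with no existing
    directed edge u->v, the Pearson correlation of their normalized T1
    profiles across conditions is computed; |r| >= ``r_threshold`` adds
    a candidate edge signed by the correlation. Cue on/off vectors are
    screened against analyte profiles under the same rule. Constant
    profiles are skipped.
    """
    if len(dataset.conditions) < 4:
        raise ValueError("imputation needs at least 4 conditions")
    t1 = dataset.t1
    analytes = [a for a in dataset.analytes if a in net.nodes]

    profiles: dict[str, np.ndarray] = {}
    for a in analytes:
        profiles[a] = t1[a].to_numpy(dtype=float)
    cue_vectors: dict[str, np.ndarray] = {}
    for cue in design.cue_nodes():
        if cue not in net.nodes:
            continue
        vec = []
        for cond in design.conditions:
            on = cue in cond.stimuli_on or (
                cue in design.constitutive and cue not in cond.inhibited
            )
            off = cue in cond.inhibited
            vec.append(1.0 if on and not off else 0.0)
        cue_vectors[cue] = np.asarray(vec)

    def corr(x: np.ndarray, y: np.ndarray) -> float | None:
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 4:
            return None
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return None  # constant profile
        return float(np.corrcoef(xs, ys)[0, 1])

    imputed: list[CausalEdge] = []
    for u, v in itertools.permutations(analytes, 2):
        if net.has_edge(u, v):
            continue
        r = corr(profiles[u], profiles[v])
        if r is not None and abs(r) >= r_threshold:
            imputed.append(CausalEdge(u, v, 1 if r > 0 else -1,
                                      provenance="data-derived"))
    for cue, vec in cue_vectors.items():
        for a in analytes:
            if cue == a or net.has_edge(cue, a):
                continue
            r = corr(vec, profiles[a])
            if r is not None and abs(r) >= r_threshold:
                imputed.append(CausalEdge(cue, a, 1 if r > 0 else -1,
                                          provenance="data-derived"))
    logger.info("imputation proposed %d data-derived edges", len(imputed))
    return imputed


def add_edges(net: CausalNetwork, edges: Iterable[CausalEdge]) -> CausalNetwork:
    """Return a network with ``edges`` merged in (duplicates collapsed)."""
    existing = net.edge_set()
    merged = list(net.edges)
    nodes = dict(net.nodes)
    for e in edges:
        if (e.source, e.target, e.sign) in existing:
            continue
        existing.add((e.source, e.target, e.sign))
        merged.append(e)
        for name in (e.source, e.target):
            nodes.setdefault(name, NodeSpec(name))
    return CausalNetwork(nodes=nodes, edges=merged)
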