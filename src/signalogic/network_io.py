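"""Causal network I/O: SIF and SIGNOR-style tables, regulator tables, validation.

A causal network is a signed directed graph: nodes are proteins,
complexes, stimuli, small molecules, or phenotypes; each edge carries a
sign (+1 activating, -1 inhibitory) and a provenance tag (``curated``
from the literature-derived PKN, or ``data-derived`` when imputed from
perturbation-data correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NODE_CATEGORIES = frozenset(
    {"protein", "complex", "stimulus", "small-molecule", "phenotype"}
)

#: SIGNOR effect vocabulary -> sign. Prefix match: "up-regulates activity"
#: etc. all map to +1. Ambiguous effects (plain "regulates", complex
#: formation) are rejected.
_EFFECT_PREFIXES = (("down-regulates", -1), ("up-regulates", 1))
_NUMERIC_SIGNS = {"1": 1, "+1": 1, "-1": -1, "−1": -1}


class NetworkParseError(ValueError):
    """Raised for malformed causal-table rows; carries the line number."""


@dataclass(frozen=True)
class NodeSpec:
    """A network node with its experimental designation.

    ``is_measured`` marks sentinel analytes, ``is_targeted`` marks cues
    (stimulated or drug-inhibited nodes).
    """

    name: str
    category: str = "protein"
    is_measured: bool = False
    is_targeted: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("node name must be nonempty")
        if self.category not in NODE_CATEGORIES:
            raise ValueError(
                f"unknown node category {self.category!r}; "
                f"expected one of {sorted(NODE_CATEGORIES)}"
            )


@dataclass(frozen=True)
class CausalEdge:
    """Signed directed interaction ``source -> target``."""

    source: str
    target: str
    sign: int
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if self.provenance not in ("curated", "data-derived"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class CausalNetwork:
    """Signed directed graph of causal regulations (the PKN)."""

    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[CausalEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} not in nodes")
        for spec in self.nodes.values():
            if spec.category == "phenotype" and any(
                e.source == spec.name for e in self.edges
            ):
                raise ValueError(
                    f"phenotype node {spec.name!r} must have no outgoing edges"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(e.source, e.target, e.sign) for e in self.edges}

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def regulators(self, node: str) -> list[tuple[str, int]]:
        """Upstream (source, sign) pairs of ``node``, deduplicated, sorted."""
        return sorted({(e.source, e.sign) for e in self.edges if e.target == node})

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for name, spec in sorted(self.nodes.items()):
            g.add_node(name, **{
                "category": spec.category,
                "is_measured": spec.is_measured,
                "is_targeted": spec.is_targeted,
            })
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, provenance=e.provenance)
        return g

    def with_designations(
        self,
        measured: Iterable[str] = (),
        targeted: Iterable[str] = (),
        categories: Mapping[str, str] | None = None,
    ) -> "CausalNetwork":
        """Return a copy with measured/targeted flags and categories set."""
        measured, targeted = set(measured), set(targeted)
        categories = dict(categories or {})
        nodes = {
            name: replace(
                spec,
                is_measured=name in measured,
                is_targeted=name in targeted,
                category=categories.get(name, spec.category),
            )
            for name, spec in self.nodes.items()
        }
        return CausalNetwork(nodes=nodes, edges=list(self.edges))


@dataclass(frozen=True)
class RegulatorEntry:
    node: str
    phenotype: str
    sign: int


@dataclass
class PhenotypeRegulatorTable:
    """(node, phenotype, sign) annotations linking proteins to phenotypes.

    Restricted to the apoptosis and proliferation phenotypes; sign +1
    marks an activator of the phenotype, -1 an inhibitor.
    """

    entries: list[RegulatorEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for e in self.entries:
            key = (e.node, e.phenotype)
            if key in seen and seen[key] != e.sign:
                raise ValueError(
                    f"conflicting signs for {key}: {seen[key]} vs {e.sign}"
                )
            seen[key] = e.sign
        # collapse exact duplicates
        uniq: dict[tuple[str, str], RegulatorEntry] = {}
        for e in self.entries:
            uniq.setdefault((e.node, e.phenotype), e)
        self.entries = list(uniq.values())

    def for_phenotype(self, phenotype: str) -> dict[str, int]:
        return {e.node: e.sign for e in self.entries if e.phenotype == phenotype}


@dataclass
class ValidationReport:
    """Structural check of a network against an experimental design."""

    dead_inputs: list[str] = field(default_factory=list)
    unreachable_readouts: list[str] = field(default_factory=list)
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.dead_inputs or self.unreachable_readouts or self.isolated_nodes)


def _parse_sign(token: str, line_no: int) -> int:
    token = token.strip()
    if token in _NUMERIC_SIGNS:
        return _NUMERIC_SIGNS[token]
    low = token.lower()
    for prefix, sign in _EFFECT_PREFIXES:
        if low.startswith(prefix):
            return sign
    raise NetworkParseError(
        f"line {line_no}: unknown effect {token!r}; accepted: "
        "'up-regulates*' (+1), 'down-regulates*' (-1), numeric 1 / -1"
    )


def read_causal_table(path: str | Path, dialect: str = "three-column-sif") -> CausalNetwork:
    """Read a causal interaction table into a :class:`CausalNetwork`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"three-column-sif"``: whitespace/tab-separated ``source sign
        target`` rows, no header. ``"signor-tsv"``: tab-separated with a
        header naming at least ENTITYA, EFFECT, ENTITYB (extra columns
        ignored).

    Duplicate identical rows are collapsed; row order is irrelevant.
    """
    path = Path(path)
    if dialect not in ("three-column-sif", "signor-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: list[CausalEdge] = []
    seen: set[tuple[str, str, int]] = set()
    nodes: dict[str, NodeSpec] = {}

    with open(path) as fh:
        lines = fh.read().splitlines()

    col_idx = {"source": 0, "sign": 1, "target": 2}
    start = 0
    sep = None
    if dialect == "signor-tsv":
        if not lines:
            raise NetworkParseError("line 1: empty SIGNOR table (header required)")
        header = [c.strip().upper() for c in lines[0].split("\t")]
        try:
            col_idx = {
                "source": header.index("ENTITYA"),
                "sign": header.index("EFFECT"),
                "target": header.index("ENTITYB"),
            }
        except ValueError as exc:
            raise NetworkParseError(
                "line 1: SIGNOR header must contain ENTITYA, EFFECT, ENTITYB"
            ) from exc
        start = 1
        sep = "\t"

    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(sep) if sep else line.split()
        needed = max(col_idx.values()) + 1
        if len(fields) < needed:
            raise NetworkParseError(
                f"line {i}: expected at least {needed} columns, got {len(fields)}"
            )
        source = fields[col_idx["source"]].strip()
        target = fields[col_idx["target"]].strip()
        if not source or not target:
            raise NetworkParseError(f"line {i}: empty entity name")
        sign = _parse_sign(fields[col_idx["sign"]], i)
        key = (source, target, sign)
        for name in (source, target):
            nodes.setdefault(name, NodeSpec(name))
        if key in seen:
            continue
        seen.add(key)
        edges.append(CausalEdge(source, target, sign))

    edges.sort(key=lambda e: (e.source, e.target, e.sign))
    return CausalNetwork(nodes=nodes, edges=edges)


def write_sif(net: CausalNetwork, path: str | Path) -> None:
    """Write ``net`` as tab-separated SIF (``source<TAB>sign<TAB>target``).

    The written file round-trips through :func:`read_causal_table`:
    isolated nodes are appended as single-column rows so node sets are
    preserved exactly.
    """
    path = Path(path)
    connected = {e.source for e in net.edges} | {e.target for e in net.edges}
    with open(path, "w") as fh:
        for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign)):
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
        for name in sorted(set(net.nodes) - connected):
            fh.write(f"{name}\n")


def read_sif(path: str | Path) -> CausalNetwork:
    """Read SIF written by :func:`write_sif` (tolerates isolated-node rows)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    nodes: dict[str, NodeSpec] = {}
    edges: list[CausalEdge] = []
    seen: set[tuple[str, str, int]] = set()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) == 1:
            nodes.setdefault(fields[0], NodeSpec(fields[0]))
            continue
        if len(fields) < 3:
            raise NetworkParseError(f"line {i}: expected source sign target")
        source, target = fields[0], fields[2]
        sign = _parse_sign(fields[1], i)
        for name in (source, target):
            nodes.setdefault(name, NodeSpec(name))
        key = (source, target, sign)
        if key not in seen:
            seen.add(key)
            edges.append(CausalEdge(source, target, sign))
    edges.sort(key=lambda e: (e.source, e.target, e.sign))
    return CausalNetwork(nodes=nodes, edges=edges)


def read_regulator_table(path: str | Path) -> PhenotypeRegulatorTable:
    """Read a TSV of (node, phenotype, effect) phenotype regulators.

    Only apoptosis and proliferation rows are kept; rows for other
    phenotypes are dropped with a logged count. A header row is
    tolerated (detected by a non-numeric effect field named 'effect' or
    'sign').
    """
    path = Path(path)
    entries: list[RegulatorEntry] = []
    dropped = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3 or not fields[2]:
            raise NetworkParseError(
                f"line {i}: expected node<TAB>phenotype<TAB>effect"
            )
        if i == 1 and fields[2].lower() in ("effect", "sign"):
            continue
        node, phenotype, effect = fields[0], fields[1].lower(), fields[2]
        sign = _parse_sign(effect, i)
        if phenotype not in ("apoptosis", "proliferation"):
            dropped += 1
            continue
        entries.append(RegulatorEntry(node, phenotype, sign))
    if dropped:
        logger.info("read_regulator_table: dropped %d rows with other phenotypes", dropped)
    return PhenotypeRegulatorTable(entries=entries)


def validate_network(net: CausalNetwork, design) -> ValidationReport:
    """Check that every cue can, in principle, modulate some sentinel.

    ``design`` is an :class:`~signalogic.dataprep.ExperimentalDesign`
    (anything exposing ``cue_nodes()`` and ``sentinel_nodes()``). The
    report flags cues with no directed path to any sentinel ("dead
    inputs"), sentinels unreachable from every cue, and isolated nodes.
    """
    cues = list(design.cue_nodes())
    sentinels = list(design.sentinel_nodes())
    for name in cues + sentinels:
        if name not in net.nodes:
            raise ValueError(f"design node {name!r} not in network")
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((e.source, e.target) for e in net.edges)

    report = ValidationReport()
    sentinel_set = set(sentinels)
    reachable_union: set[str] = set()
    for cue in cues:
        # a cue that is itself measured modulates its own readout
        reach = nx.descendants(g, cue) | {cue}
        reachable_union |= reach
        if not (reach & sentinel_set):
            report.dead_inputs.append(cue)
    for s in sentinels:
        if s not in reachable_union:
            report.unreachable_readouts.append(s)
    for name in sorted(net.nodes):
        if g.in_degree(name) == 0 and g.out_degree(name) == 0:
            report.isolated_nodes.append(name)
    return report
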