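"""Phenotype scoring and the in silico combinatorial knockout screen.

Trained models are interrogated under three kinds of clamp conditions:
*untreated* (all receptors ON, the malignant state), *FLT3i* (FLT3
forced OFF, mimicking a tyrosine-kinase inhibitor), and *FLT3i+<X>KO*
(FLT3 and a second target both OFF, a candidate combination therapy).
Apoptosis and proliferation levels are inferred from the states of
*endpoint regulators*: nodes annotated as phenotype activators or
inhibitors that are terminal in the high-confidence model. A knockout
is a *rescue hit* for a resistant model when it brings both phenotype
scores down to the sensitive model's FLT3i-treated levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .boolean_core import (
    UNRESOLVED,
    ClampCondition,
    LogicModel,
    SteadyState,
    simulate_synchronous,
)
from .network_io import PhenotypeRegulatorTable

logger = logging.getLogger(__name__)

DEFAULT_RECEPTORS = ("FLT3", "IGF1R", "TNFR")

#: Kinases screened in combination with FLT3 inhibition.
DEFAULT_KO_TARGETS = (
    "ERK1/2", "MEK1/2", "GSK3A/B", "IGF1R", "JNK",
    "KRAS", "MTOR", "PDPK1", "PI3K", "p38",
)

#: Complex drug targets clamp every member node.
DEFAULT_COMPLEX_MEMBERS: dict[str, tuple[str, ...]] = {
    "ERK1/2": ("ERK1", "ERK2"),
    "MEK1/2": ("MEK1", "MEK2"),
    "GSK3A/B": ("GSK3A", "GSK3B"),
}


@dataclass
class PhenotypeScores:
    """Proliferation-activation and apoptosis-inhibition levels.

    Both are normalized sums of endpoint-regulator states in [-1, 1];
    apoptosis inhibition is the *negative* of the apoptosis score so
    that high values read as tumor-like (apoptosis suppressed). A score
    is None when the phenotype has no endpoint regulators.
    """

    proliferation_activation: float | None
    apoptosis_inhibition: float | None
    regulator_states: dict[str, dict[str, float]] = field(default_factory=dict)

    def defined(self) -> bool:
        return (
            self.proliferation_activation is not None
            and self.apoptosis_inhibition is not None
        )


@dataclass
class ScreenRow:
    condition: str
    scores: PhenotypeScores
    skipped: bool = False


@dataclass
class ScreenResult:
    rows: list[ScreenRow]
    skipped_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.condition for r in self.rows]
        if len(names) != len(set(names)):
            raise ValueError("screen condition names must be unique")

    def scores_for(self, condition: str) -> PhenotypeScores:
        for r in self.rows:
            if r.condition == condition:
                return r.scores
        raise KeyError(condition)

    def to_tsv(self, path: str | Path,
               rescue: Sequence[str] = ()) -> None:
        hits = set(rescue)
        lines = ["condition\tproliferation_activation\tapoptosis_inhibition\trescue_flag"]
        for r in self.rows:
            p = r.scores.proliferation_activation
            a = r.scores.apoptosis_inhibition
            target = r.condition.removeprefix("FLT3i+").removesuffix("KO")
            flag = int(r.condition.startswith("FLT3i+") and target in hits)
            lines.append(
                f"{r.condition}\t"
                f"{'NA' if p is None else f'{p:.4f}'}\t"
                f"{'NA' if a is None else f'{a:.4f}'}\t{flag}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def endpoint_regulators(
    model_hc: LogicModel, regtable: PhenotypeRegulatorTable
) -> dict[str, dict[str, int]]:
    """Endpoint phenotype regulators of the high-confidence model.

    A node qualifies for a phenotype iff it is annotated for it in
    ``regtable`` and feeds no selected gate (a terminal effector of the
    retained network). Returns {phenotype: {node: sign}}.
    """
    has_outgoing = set()
    for g in model_hc.selected_gates:
        for n, _ in g.inputs:
            has_outgoing.add(n)
    nodes = set(model_hc.nodes)
    out: dict[str, dict[str, int]] = {}
    for phenotype in ("apoptosis", "proliferation"):
        annotated = regtable.for_phenotype(phenotype)
        out[phenotype] = {
            n: s for n, s in annotated.items()
            if n in nodes and n not in has_outgoing
        }
        if not out[phenotype]:
            logger.warning("no endpoint regulators for %s; score undefined",
                           phenotype)
    return out


def phenotype_scores(
    state: SteadyState | Mapping[str, object],
    endpoints: Mapping[str, Mapping[str, int]],
) -> PhenotypeScores:
    """Integrate endpoint states into phenotype levels.

    raw(phenotype) = sum over activator endpoints of state - sum over
    inhibitor endpoints of state, normalized by the endpoint count
    (equal weight for activators and inhibitors). UNRESOLVED endpoint
    states contribute 0.5 (neutral).
    """
    values = state.values if isinstance(state, SteadyState) else state

    def level(phenotype: str) -> tuple[float | None, dict[str, float]]:
        eps = endpoints.get(phenotype, {})
        if not eps:
            return None, {}
        raw = 0.0
        states = {}
        for node, sign in eps.items():
            v = values.get(node, 0)
            x = 0.5 if v is UNRESOLVED else float(v)
            states[node] = x
            raw += sign * x
        return raw / len(eps), states

    prolif, prolif_states = level("proliferation")
    apo, apo_states = level("apoptosis")
    return PhenotypeScores(
        proliferation_activation=prolif,
        apoptosis_inhibition=None if apo is None else -apo,
        regulator_states={"proliferation": prolif_states, "apoptosis": apo_states},
    )


def _condition_clamps(
    name: str,
    receptors: Sequence[str],
    model_nodes: set[str],
    complex_members: Mapping[str, Sequence[str]],
    extra_on: Mapping[str, int] | None = None,
) -> ClampCondition:
    receptors = [r for r in receptors if r in model_nodes]
    off: set[str] = set()
    if name == "untreated":
        pass
    elif name == "FLT3i":
        off = {"FLT3"}
    elif name.startswith("FLT3i+") and name.endswith("KO"):
        target = name[len("FLT3i+"):-len("KO")]
        members = complex_members.get(target, (target,))
        resolved = [m for m in members if m in model_nodes]
        if not resolved:
            raise KeyError(target)
        off = {"FLT3", *resolved}
    else:
        raise ValueError(f"unknown screen condition {name!r}")
    off &= model_nodes
    on = set(receptors) - off
    if extra_on:
        for node, v in extra_on.items():
            if node not in model_nodes:
                continue
            if node in off or node in on:
                logger.info(
                    "condition %s overrides patient clamp on %s", name, node
                )
                continue
            (on if v else off).add(node)
    return ClampCondition(name, frozenset(on), frozenset(off))


def run_condition(
    model: LogicModel,
    name: str,
    endpoints: Mapping[str, Mapping[str, int]],
    receptors: Sequence[str] = DEFAULT_RECEPTORS,
    complex_members: Mapping[str, Sequence[str]] | None = None,
    patient_clamps: Mapping[str, int] | None = None,
    max_iter: int = 100,
) -> tuple[SteadyState, PhenotypeScores]:
    """Simulate one screen condition and score the phenotypes.

    ``name`` is ``untreated``, ``FLT3i``, or ``FLT3i+<target>KO``.
    Optional ``patient_clamps`` (gene -> 0/1) are applied in addition;
    condition clamps win on conflict (a drugged gain-of-function gene
    is still OFF under its inhibitor).
    """
    members = dict(DEFAULT_COMPLEX_MEMBERS if complex_members is None
                   else complex_members)
    nodes = set(model.nodes)
    clamp = _condition_clamps(name, receptors, nodes, members,
                              extra_on=patient_clamps)
    state = simulate_synchronous(model, clamp, max_iter=max_iter)
    return state, phenotype_scores(state, endpoints)


def ko_screen(
    model: LogicModel,
    endpoints: Mapping[str, Mapping[str, int]],
    targets: Sequence[str] = DEFAULT_KO_TARGETS,
    receptors: Sequence[str] = DEFAULT_RECEPTORS,
    complex_members: Mapping[str, Sequence[str]] | None = None,
    patient_clamps: Mapping[str, int] | None = None,
) -> ScreenResult:
    """Screen untreated, FLT3i, and FLT3i+<target>KO for every target.

    Targets that resolve to no model node are reported in
    ``skipped_targets`` and omitted from the rows.
    """
    rows: list[ScreenRow] = []
    skipped: list[str] = []
    for name in ("untreated", "FLT3i"):
        _, scores = run_condition(
            model, name, endpoints, receptors=receptors,
            complex_members=complex_members, patient_clamps=patient_clamps,
        )
        rows.append(ScreenRow(name, scores))
    for target in targets:
        name = f"FLT3i+{target}KO"
        try:
            _, scores = run_condition(
                model, name, endpoints, receptors=receptors,
                complex_members=complex_members, patient_clamps=patient_clamps,
            )
        except KeyError:
            skipped.append(target)
            continue
        rows.append(ScreenRow(name, scores))
    if skipped:
        logger.info("ko_screen skipped unresolvable targets: %s", skipped)
    return ScreenResult(rows=rows, skipped_targets=skipped)


def rescue_hits(
    resistant_screen: ScreenResult,
    sensitive_reference: PhenotypeScores,
    epsilon: float = 0.0,
) -> list[str]:
    """Knockouts that restore drug sensitivity in the resistant model.

    A target is a hit iff its FLT3i+KO condition pushes *both*
    apoptosis inhibition and proliferation activation down to the
    sensitive model's FLT3i levels (<= reference + epsilon).
    """
    if not sensitive_reference.defined():
        raise ValueError("sensitive reference scores are undefined")
    ref_a = sensitive_reference.apoptosis_inhibition
    ref_p = sensitive_reference.proliferation_activation
    hits = []
    for row in resistant_screen.rows:
        if not (row.condition.startswith("FLT3i+") and row.condition.endswith("KO")):
            continue
        target = row.condition[len("FLT3i+"):-len("KO")]
        s = row.scores
        if not s.defined():
            logger.warning("target %s has undefined scores; excluded", target)
            continue
        if (s.apoptosis_inhibition <= ref_a + epsilon
                and s.proliferation_activation <= ref_p + epsilon):
            hits.append(target)
    return hits
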