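"""Patient-specific simulations on trained genotype models.

FLT3-ITD insertion sites classify each patient as JMD (juxtamembrane
domain), TKD (first tyrosine-kinase domain), or mixed JMD+TKD; JMD and
JMD+TKD patients are simulated on the TKI-sensitive (JMD) cell model,
TKD patients on the resistant (TKD) model. Annotated variants are
binarized into node clamps (gain-of-function -> 1, loss-of-function ->
0) and the condition panel of the knockout screen is replayed with the
patient clamps applied underneath.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boolean_core import LogicModel
from .phenotype_screen import (
    DEFAULT_KO_TARGETS,
    DEFAULT_RECEPTORS,
    PhenotypeScores,
    ScreenResult,
    ko_screen,
)

logger = logging.getLogger(__name__)

#: Default first residue of the TKD1 domain: insertions before it are
#: juxtamembrane (the study's exemplars are aa 598 JMD, aa 613 TKD1).
JMD_TKD_BOUNDARY = 610

_GOF = {"gain-of-function", "likely gain-of-function"}
_LOF = {"loss-of-function", "likely loss-of-function"}
_DROPPED = {"unknown", "inconclusive", "likely neutral", "switch-of-function"}


@dataclass
class PatientProfile:
    patient_id: str
    variants: list[tuple[str, str]] = field(default_factory=list)
    itd_sites: list[int] = field(default_factory=list)
    expression: dict[str, float] | None = None


@dataclass(frozen=True)
class ITDCall:
    """FLT3-ITD insertion-domain class."""

    cls: str  # "JMD" | "TKD" | "JMD+TKD"

    def __post_init__(self) -> None:
        if self.cls not in ("JMD", "TKD", "JMD+TKD"):
            raise ValueError(f"unknown ITD class {self.cls!r}")


def classify_itd(itd_sites: Iterable[int],
                 jmd_tkd_boundary: int = JMD_TKD_BOUNDARY) -> ITDCall:
    """Classify insertion amino-acid positions against the domain boundary.

    Sites strictly below the boundary are JMD insertions, sites at or
    above it TKD insertions; a patient with both kinds is JMD+TKD.
    """
    sites = sorted(set(int(s) for s in itd_sites))
    if not sites:
        raise ValueError("patient has no ITD insertion sites")
    if any(s <= 0 for s in sites):
        raise ValueError("insertion sites must be positive residue numbers")
    jmd = any(s < jmd_tkd_boundary for s in sites)
    tkd = any(s >= jmd_tkd_boundary for s in sites)
    if jmd and tkd:
        return ITDCall("JMD+TKD")
    return ITDCall("JMD" if jmd else "TKD")


def binarize_mutations(
    variants: Sequence[tuple[str, str]],
    model_nodes: Iterable[str] | None = None,
    alias: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Binarize annotated variants into node clamps.

    Gain-of-function and likely gain-of-function -> 1; loss-of-function
    and likely loss-of-function -> 0. Variants annotated Unknown,
    Inconclusive, Likely Neutral, or Switch-of-function are dropped.
    Unrecognized effect strings raise, listing the vocabulary. With
    ``model_nodes`` given, genes absent from the model (after applying
    the explicit ``alias`` gene->node map) are reported and ignored.
    """
    alias = dict(alias or {})
    clamps: dict[str, int] = {}
    ignored: list[str] = []
    for gene, effect in variants:
        eff = effect.strip().lower()
        if eff in _DROPPED:
            continue
        if eff in _GOF:
            value = 1
        elif eff in _LOF:
            value = 0
        else:
            raise ValueError(
                f"unrecognized MUTATION_EFFECT {effect!r} for {gene}; expected "
                "one of Gain-of-function, Likely Gain-of-function, "
                "Loss-of-function, Likely Loss-of-function, Unknown, "
                "Inconclusive, Likely Neutral, Switch-of-function"
            )
        node = alias.get(gene, gene)
        if model_nodes is not None and node not in set(model_nodes):
            ignored.append(gene)
            continue
        if node in clamps and clamps[node] != value:
            logger.warning("conflicting clamps for %s; keeping first (%d)",
                           node, clamps[node])
            continue
        clamps[node] = value
    if ignored:
        logger.info("genes absent from the model, ignored: %s", sorted(set(ignored)))
    return clamps


def match_model(call: ITDCall, models: Mapping[str, LogicModel]) -> LogicModel:
    """Pick the cell-line model for a patient's ITD class.

    JMD and JMD+TKD patients map to the JMD model (the JMD insertion is
    dominant); TKD patients to the TKD model. ``models`` must supply
    both under keys "JMD" and "TKD".
    """
    for key in ("JMD", "TKD"):
        if key not in models:
            raise ValueError(f"missing {key} model")
    return models["JMD"] if call.cls in ("JMD", "JMD+TKD") else models["TKD"]


def simulate_patient(
    model: LogicModel,
    clamps: Mapping[str, int],
    endpoints: Mapping[str, Mapping[str, int]],
    condition_panel: Sequence[str] | None = None,
    receptors: Sequence[str] = DEFAULT_RECEPTORS,
) -> ScreenResult:
    """Replay the screen condition panel with patient clamps underneath.

    ``condition_panel`` defaults to untreated + FLT3i + the ten
    FLT3i+<target>KO combinations. Condition clamps take precedence
    over patient clamps on conflict.
    """
    if condition_panel is None:
        targets: Sequence[str] = DEFAULT_KO_TARGETS
    else:
        targets = [
            c[len("FLT3i+"):-len("KO")]
            for c in condition_panel
            if c.startswith("FLT3i+") and c.endswith("KO")
        ]
    result = ko_screen(
        model, endpoints, targets=targets, receptors=receptors,
        patient_clamps=dict(clamps),
    )
    if condition_panel is not None:
        keep = set(condition_panel)
        result = ScreenResult(
            rows=[r for r in result.rows if r.condition in keep],
            skipped_targets=result.skipped_targets,
        )
    return result


def patient_score_table(
    screens: Mapping[str, ScreenResult]
) -> pd.DataFrame:
    """Long-format per-patient score matrix (patient, condition, scores)."""
    rows = []
    for pid, screen in screens.items():
        for r in screen.rows:
            rows.append((
                pid, r.condition,
                r.scores.proliferation_activation,
                r.scores.apoptosis_inhibition,
            ))
    return pd.DataFrame(
        rows,
        columns=["patient", "condition",
                 "proliferation_activation", "apoptosis_inhibition"],
    )


def expression_zscores(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-patient z-scores of a genes x patients expression matrix.

    Each column is centered by that patient's mean and scaled by the
    sample standard deviation of that patient's values. Columns with
    zero spread raise.
    """
    if expression.shape[0] < 2:
        raise ValueError("need at least two genes per patient")
    mat = expression.astype(float)
    sd = mat.std(axis=0, ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ValueError(f"constant expression column(s): {bad}")
    return (mat - mat.mean(axis=0)) / sd


def read_variant_table(path) -> dict[str, list[tuple[str, str]]]:
    """Read a TSV with columns patient, gene, MUTATION_EFFECT."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("patient", "gene", "mutation_effect"):
        if needed not in cols:
            raise ValueError(f"variant table missing column {needed!r}")
    out: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(getattr(r, cols["patient"])), []).append(
            (str(getattr(r, cols["gene"])), str(getattr(r, cols["mutation_effect"])))
        )
    return out


def read_itd_sites(path) -> dict[str, list[int]]:
    """Read a TSV with columns patient, insertion_aa."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("patient", "insertion_aa"):
        if needed not in cols:
            raise ValueError(f"ITD table missing column {needed!r}")
    out: dict[str, list[int]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(getattr(r, cols["patient"])), []).append(
            int(getattr(r, cols["insertion_aa"]))
        )
    return out
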