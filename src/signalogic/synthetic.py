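"""Ground-truth generators and recovery metrics.

``make_truth`` draws a layered signed network shaped like the study
system: two stimulus-gated receptors plus a constitutively active
FLT3-like receptor feed a layer of inhibitable kinases and measured
sentinels; a known gate selection over the expanded scaffold (truth
gates plus degree-preserving decoy edges) is the recovery target.
``simulate_dataset`` turns steady states of the truth model into
MFI-scale raw bead-array measurements with multiplicative log-normal
noise, a loading-control channel, bead counts and replicates, so the
whole pipeline (bead filter through GA training) can be exercised and
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boolean_core import ClampCondition, LogicModel, simulate_conditions, training_clamps
from .dataprep import ExperimentalDesign, RawMeasurement, enumerate_design
from .network_io import (
    CausalEdge,
    CausalNetwork,
    NodeSpec,
    PhenotypeRegulatorTable,
    RegulatorEntry,
    validate_network,
)
from .preprocess import Gate, ScaffoldModel, add_edges, expand

LOADING_CONTROL = "b-Tubulin"


@dataclass
class SyntheticTruth:
    """A known-model instance of the full study setup."""

    pkn: CausalNetwork
    truth_model: LogicModel  # selection over the distractor scaffold
    design: ExperimentalDesign
    regtable: PhenotypeRegulatorTable
    noise_sd: float
    seed: int

    @property
    def scaffold(self) -> ScaffoldModel:
        return self.truth_model.scaffold

    @property
    def truth_selection(self) -> tuple[int, ...]:
        return self.truth_model.selection


def _draw_network(
    rng: np.random.Generator,
    n_nodes: int,
    n_stimuli: int,
    n_inhibitable: int,
    n_sentinels: int | None,
):
    """One wiring attempt; returns (nodes, edges, truth gates, design pieces)."""
    if n_stimuli != 2:
        stimuli = [f"STIM{i + 1}" for i in range(n_stimuli)]
        receptors = ["FLT3"] + [f"R{i + 1}" for i in range(n_stimuli)]
    else:
        stimuli = ["IGF1", "TNFa"]
        receptors = ["FLT3", "IGF1R", "TNFR"]
    n_down = n_nodes - len(stimuli) - len(receptors)
    if n_down < 2:
        raise ValueError("n_nodes too small for the layered layout")
    downstream = [f"K{i + 1}" for i in range(n_down)]

    edges: list[tuple[str, str, int]] = []
    for stim, rec in zip(stimuli, receptors[1:]):
        edges.append((stim, rec, 1))

    order = {n: i for i, n in enumerate(receptors + downstream)}
    truth_gates: dict[str, list[tuple[tuple[str, int], ...]]] = {}

    # guarantee each receptor drives something
    forced = {downstream[i % n_down]: receptors[i] for i in range(len(receptors))}
    for j, node in enumerate(downstream):
        pool = receptors + downstream[:j]
        regs: list[tuple[str, int]] = []
        if node in forced:
            regs.append((forced[node], 1))
        n_regs = 1 if rng.random() < 0.7 else 2
        while len(regs) < n_regs:
            cand = pool[int(rng.integers(0, len(pool)))]
            if any(r[0] == cand for r in regs):
                if len(pool) <= len(regs):
                    break
                continue
            sign = 1 if rng.random() < 0.8 else -1
            regs.append((cand, sign))
        for src, sign in regs:
            edges.append((src, node, sign))
        if len(regs) == 1:
            truth_gates[node] = [tuple(regs)]
        else:
            # coin flip: AND of both regulators, or OR of the singles
            if rng.random() < 0.5:
                truth_gates[node] = [tuple(sorted(regs))]
            else:
                truth_gates[node] = [(r,) for r in regs]
    for stim, rec in zip(stimuli, receptors[1:]):
        truth_gates[rec] = [((stim, 1),)]

    if n_sentinels is None:
        n_sentinels = n_down
    sentinels = downstream[-n_sentinels:] if n_sentinels <= n_down else downstream

    inhibitable = ["FLT3"] + downstream[: max(0, n_inhibitable - 1)]
    return stimuli, receptors, downstream, edges, truth_gates, sentinels, inhibitable, order


def _build_design(
    stimuli: Sequence[str],
    receptors: Sequence[str],
    inhibitable: Sequence[str],
    sentinels: Sequence[str],
    edges: Sequence[tuple[str, str, int]],
) -> ExperimentalDesign:
    """Branch assignment mirrors the study: a kinase joins the branch of
    the stimulated receptor it descends from; the last kinase of the
    larger branch is (like GSK3i) not paired with FLT3 inhibition."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_edges_from((u, v) for u, v, _ in edges)
    branch_of: dict[str, list[str]] = {s: [] for s in stimuli}
    alternator = 0
    for k in inhibitable:
        if k == "FLT3":
            continue
        assigned = None
        for stim, rec in zip(stimuli, receptors[1:]):
            if rec in g and k in g and nx.has_path(g, rec, k):
                assigned = stim
                break
        if assigned is None:
            assigned = stimuli[alternator % len(stimuli)]
            alternator += 1
        branch_of[assigned].append(k)

    targets = {"FLT3i": "FLT3"}
    branches: dict[str, list[str]] = {}
    for stim in stimuli:
        drugs = []
        for k in branch_of[stim]:
            drug = f"{k}i"
            targets[drug] = k
            drugs.append(drug)
        branches[stim] = drugs
    combos = [d for drugs in branches.values() for d in drugs]
    largest = max(branches.values(), key=len, default=[])
    if len(largest) >= 2:
        combos = [d for d in combos if d != largest[-1]]
    return enumerate_design(
        stimulus_branches=branches,
        inhibitor_targets=targets,
        flt3i_combos=combos,
        sentinels={s: 1 for s in sentinels},
        constitutive=("FLT3",),
    )


def make_truth(
    n_nodes: int = 12,
    n_stimuli: int = 2,
    n_inhibitable: int = 7,
    n_sentinels: int | None = None,
    n_phenotype_regs: int = 4,
    seed: int = 0,
    n_decoys: int | None = None,
    max_attempts: int = 50,
) -> SyntheticTruth:
    """Draw a ground-truth logic model with its experimental design.

    The wiring is redrawn (deterministically, from the seed) until the
    network validates against its design, the truth model reaches
    resolved steady states for >= 90% of (condition, sentinel) cells,
    and every sentinel profile varies across conditions — a degenerate
    readout could never be normalized or recovered.
    """
    master = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_attempts):
        rng = np.random.default_rng(master.integers(0, 2**31))
        try:
            (stimuli, receptors, downstream, edges, truth_gates,
             sentinels, inhibitable, order) = _draw_network(
                rng, n_nodes, n_stimuli, n_inhibitable, n_sentinels
            )
        except ValueError:
            raise
        design = _build_design(stimuli, receptors, inhibitable, sentinels, edges)

        nodes = {
            n: NodeSpec(
                n,
                category="stimulus" if n in stimuli else "protein",
                is_measured=n in sentinels,
                is_targeted=(n in stimuli) or (n in inhibitable),
            )
            for n in stimuli + receptors + downstream
        }
        pkn = CausalNetwork(
            nodes=nodes, edges=[CausalEdge(u, v, s) for u, v, s in edges]
        )
        report = validate_network(pkn, design)
        if not report.ok:
            last_err = f"invalid network: {report}"
            continue

        # degree-preserving decoy edges: rewire an existing edge's target
        # to a deeper node, keeping the DAG
        n_dec = max(2, len(edges) // 4) if n_decoys is None else n_decoys
        existing = {(u, v) for u, v, _ in edges}
        decoys: list[CausalEdge] = []
        tries = 0
        species_ordered = receptors + downstream
        while len(decoys) < n_dec and tries < 200:
            tries += 1
            u, v, s = edges[int(rng.integers(0, len(edges)))]
            if u in stimuli:
                continue
            deeper = [w for w in species_ordered if order[w] > order[u]]
            if not deeper:
                continue
            w = deeper[int(rng.integers(0, len(deeper)))]
            if w == u or (u, w) in existing:
                continue
            existing.add((u, w))
            decoys.append(CausalEdge(u, w, s, provenance="curated"))
        scaffold_net = add_edges(pkn, decoys)
        # stimuli feed receptors directly; exclude them from the trainable
        # scaffold the same way compression removes pure inputs
        scaffold = expand(scaffold_net, max_gate_inputs=2)

        truth_sel = []
        wanted = {
            (out, tuple(sorted(g))) for out, gs in truth_gates.items() for g in gs
        }
        for g in scaffold.gates:
            key = (g.output, tuple(sorted(g.inputs)))
            truth_sel.append(1 if key in wanted else 0)
        want_n = len(wanted)
        if sum(truth_sel) != want_n:
            last_err = "truth gates not all present in scaffold"
            continue
        truth_model = LogicModel(scaffold, tuple(truth_sel))

        # resolvedness + informativeness check (noise-free simulation)
        clamps = training_clamps(design, scaffold.species)
        vals, unres, _, _, _ = simulate_conditions(truth_model, clamps)
        comp_idx = {n: i for i, n in enumerate(scaffold.species)}
        sent_cols = vals[:, [comp_idx[s] for s in sentinels]]
        frac_resolved = 1.0 - np.isnan(sent_cols).mean()
        if frac_resolved < 0.9:
            last_err = "too many unresolved cells"
            continue
        constant = [
            s for k, s in enumerate(sentinels)
            if np.nanmax(sent_cols[:, k]) == np.nanmin(sent_cols[:, k])
        ]
        if constant:
            last_err = f"constant sentinel profiles: {constant}"
            continue

        regs = []
        pool = list(reversed(downstream))[: max(n_phenotype_regs, 0)]
        for i, node in enumerate(pool):
            phenotype = "apoptosis" if i % 2 == 0 else "proliferation"
            sign = 1 if i < 2 else -1
            regs.append(RegulatorEntry(node, phenotype, sign))
        return SyntheticTruth(
            pkn=pkn,
            truth_model=truth_model,
            design=design,
            regtable=PhenotypeRegulatorTable(entries=regs),
            noise_sd=0.0,
            seed=seed,
        )
    raise RuntimeError(f"could not draw a valid truth in {max_attempts} attempts "
                       f"(last: {last_err})")


def simulate_dataset(
    truth: SyntheticTruth,
    replicates: int = 3,
    noise_sd: float = 0.05,
    bead_mean: int = 120,
    low_bead_rate: float = 0.02,
    seed: int = 0,
) -> list[RawMeasurement]:
    """Raw bead-array measurements from the truth model's steady states.

    Sentinel states {0, 1} map to MFI through a per-analyte affine
    range (low point 500-2000, high point 8000-20000 units) and are
    multiplied by log-normal noise exp(N(0, noise_sd)). A loading
    control channel is emitted per well with its own noise; bead counts
    are Poisson around ``bead_mean`` with a ``low_bead_rate`` fraction
    forced below the 50-bead filter. T0 rows derive from the
    unstimulated baseline (constitutive receptors only).
    """
    rng = np.random.default_rng(seed)
    design = truth.design
    sentinels = design.sentinel_nodes()
    clamps = training_clamps(design, truth.scaffold.species)
    baseline = ClampCondition(
        "T0", frozenset(set(design.constitutive) & set(truth.scaffold.species)),
        frozenset(),
    )
    vals, unres, _, _, _ = simulate_conditions(truth.truth_model, list(clamps) + [baseline])
    idx = {n: i for i, n in enumerate(truth.scaffold.species)}
    sent_idx = [idx[s] for s in sentinels]
    t1_states = vals[:-1][:, sent_idx]
    t0_state = vals[-1][sent_idx]

    lo = rng.uniform(500.0, 2000.0, len(sentinels))
    hi = rng.uniform(8000.0, 20000.0, len(sentinels))
    tub_base = 5000.0

    rows: list[RawMeasurement] = []
    for c, cond in enumerate(design.conditions):
        for rep in range(1, replicates + 1):
            for tp, states in (("T0", t0_state), ("T1", t1_states[c])):
                for k, analyte in enumerate(sentinels):
                    s = states[k]
                    x = 0.5 if np.isnan(s) else float(s)
                    mfi = (lo[k] + x * (hi[k] - lo[k])) * float(
                        np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                    )
                    rows.append(RawMeasurement(cond.name, analyte, rep, tp,
                                               mfi, 0))
                mfi_tub = tub_base * float(
                    np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                )
                rows.append(RawMeasurement(cond.name, LOADING_CONTROL, rep, tp,
                                           mfi_tub, 0))
    beads = rng.poisson(bead_mean, len(rows)).astype(int)
    beads[beads < 50] = 50  # dropout is governed by low_bead_rate alone
    low = rng.random(len(rows)) < low_bead_rate
    beads[low] = rng.integers(1, 50, low.sum())
    rows = [
        RawMeasurement(m.condition, m.analyte, m.replicate, m.timepoint,
                       m.mfi, int(b))
        for m, b in zip(rows, beads)
    ]
    return rows


def recovery_report(
    truth: SyntheticTruth,
    conf,
    threshold: float = 0.4,
) -> dict[str, float]:
    """Precision/recall/F1 of {gate frequency > threshold} vs truth gates."""
    pred = {i for i, f in enumerate(conf.frequencies) if f > threshold}
    true = {i for i, b in enumerate(truth.truth_selection) if b}
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_pred": float(len(pred)), "n_true": float(len(true))}


def demo_model_pair() -> tuple[LogicModel, LogicModel, PhenotypeRegulatorTable]:
    """Fixed sensitive/resistant demo models for the rescue screen.

    Both are small hand-built logic models sharing the receptor layer;
    the resistant one adds a TNFR->JNK->STAT5 bypass that keeps the
    survival axis on under FLT3 inhibition, so knocking out JNK (and
    only JNK) restores the sensitive model's treated phenotype. They
    are synthetic stand-ins for trained genotype-specific models, built
    so the combinatorial screen has a deterministic worked example.
    """
    species = ["BCL2", "CASP3", "FLT3", "IGF1R", "JNK", "RPS6", "STAT5", "TNFR"]
    common = [
        Gate("JNK", (("TNFR", 1),)),
        Gate("STAT5", (("FLT3", 1),)),
        Gate("RPS6", (("STAT5", 1),)),
        Gate("CASP3", (("STAT5", -1),)),
        Gate("BCL2", (("STAT5", 1),)),
    ]
    bypass = Gate("STAT5", (("JNK", 1),))
    sensitive = LogicModel(
        ScaffoldModel(species=species, gates=list(common)),
        (1,) * len(common),
    )
    resistant = LogicModel(
        ScaffoldModel(species=species, gates=list(common) + [bypass]),
        (1,) * (len(common) + 1),
    )
    regtable = PhenotypeRegulatorTable(entries=[
        RegulatorEntry("RPS6", "proliferation", 1),
        RegulatorEntry("CASP3", "apoptosis", 1),
        RegulatorEntry("BCL2", "apoptosis", -1),
    ])
    return sensitive, resistant, regtable
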