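"""From raw plate measurements to the normalized 0-1 training matrix.

The processing chain mirrors a multiplexed bead-array (Luminex/xMAP)
perturbation experiment:

1. drop measurements with fewer than 50 detected beads (technically
   unreliable wells),
2. divide each analyte's median fluorescence intensity (MFI) by the
   loading-control channel of the same well,
3. take the median (and sample SD) across the biological replicates,
4. rescale each analyte to (0, 1) with a per-analyte Hill function whose
   parameters are derived in closed form so that the observed minimum
   maps to 0.001 and the observed maximum to 0.999.

The rescaled matrix is serialized as MIDAS (TR:/DA:/DV: columns), the
interchange format consumed by logic-model trainers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MIN_BEADS_DEFAULT = 50
LOADING_CONTROL_DEFAULT = "b-Tubulin"

#: Target extremes of the Hill rescaling: observed minimum -> MIN_T,
#: observed maximum -> MAX_T.
MIN_T = 0.001
MAX_T = 0.999

#: Default cue wiring of the 16-condition study design: each stimulus
#: activates one signaling branch and is paired with the inhibitors of
#: the kinases in that branch.
DEFAULT_STIMULUS_BRANCHES: dict[str, tuple[str, ...]] = {
    "TNFa": ("p38i", "JNKi"),
    "IGF1": ("PI3Ki", "mTORi", "MEKi", "GSK3i"),
}
DEFAULT_INHIBITOR_TARGETS: dict[str, str] = {
    "FLT3i": "FLT3",
    "p38i": "p38",
    "JNKi": "JNK",
    "PI3Ki": "PI3K",
    "mTORi": "mTOR",
    "MEKi": "MEK1/2",
    "GSK3i": "GSK3",
}
#: Branch inhibitors that are also tested in combination with the FLT3
#: inhibitor. GSK3i is tested only without it.
DEFAULT_FLT3I_COMBOS: tuple[str, ...] = ("p38i", "JNKi", "PI3Ki", "mTORi", "MEKi")

#: Sentinel analytes and the functional role of the measured
#: phosphosite (+1 the site activates the protein, -1 it inhibits it).
DEFAULT_SENTINELS: dict[str, int] = {
    "CREB1": 1,
    "ERK1/2": 1,
    "JNK": 1,
    "p38": 1,
    "STAT3": 1,
    "STAT5": 1,
    "p70S6K": 1,
    "RPS6": 1,
    "MTOR": 1,
    "IGF1R": 1,
    "PTEN": -1,
    "TSC2": -1,
    "GSK3A": -1,
    "GSK3B": -1,
}


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a set of stimuli plus inhibited targets."""

    name: str
    stimuli_on: frozenset[str] = frozenset()
    inhibited: frozenset[str] = frozenset()

    @staticmethod
    def build(stimuli_on: Iterable[str], inhibited_drugs: Iterable[str],
              targets: Mapping[str, str]) -> "Condition":
        """Name encodes membership: drugs first (FLT3i leading), then stimuli."""
        drugs = list(inhibited_drugs)
        ordered = [d for d in ("FLT3i",) if d in drugs]
        ordered += [d for d in drugs if d != "FLT3i"]
        parts = ordered + sorted(stimuli_on)
        name = "+".join(parts) if parts else "control"
        return Condition(
            name=name,
            stimuli_on=frozenset(stimuli_on),
            inhibited=frozenset(targets[d] for d in drugs),
        )


@dataclass
class ExperimentalDesign:
    """Cues (stimuli and drug-inhibited targets) and sentinel readouts.

    ``constitutive`` lists receptors that are active in every condition
    unless drug-inhibited (an internal-tandem-duplicated FLT3 receptor
    signals without ligand, so the FLT3i/no-FLT3i contrast is the only
    way to switch it off).
    """

    conditions: list[Condition]
    stimuli: tuple[str, ...]
    inhibitors: dict[str, str]
    sentinels: dict[str, int]
    constitutive: frozenset[str] = frozenset({"FLT3"})

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(names) != len(set(names)):
            raise ValueError("condition names must be unique")
        for s in self.sentinels.values():
            if s not in (1, -1):
                raise ValueError("sentinel activity annotation must be +1 or -1")

    def cue_nodes(self) -> list[str]:
        """Stimulus nodes plus drug-target nodes, in deterministic order."""
        seen: dict[str, None] = {}
        for s in self.stimuli:
            seen.setdefault(s)
        for t in self.inhibitors.values():
            seen.setdefault(t)
        return list(seen)

    def sentinel_nodes(self) -> list[str]:
        return list(self.sentinels)

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)


def enumerate_design(
    stimulus_branches: Mapping[str, Sequence[str]] | None = None,
    inhibitor_targets: Mapping[str, str] | None = None,
    flt3i_combos: Sequence[str] | None = None,
    sentinels: Mapping[str, int] | None = None,
    constitutive: Iterable[str] = ("FLT3",),
) -> ExperimentalDesign:
    """Enumerate the condition panel of the perturbation experiment.

    With the default arguments this reproduces the study's 16
    conditions: FLT3i alone; FLT3i plus each stimulus; FLT3i plus each
    FLT3i-paired branch inhibitor plus its stimulus; each stimulus
    alone; and each branch inhibitor plus its stimulus.

    An empty ``stimulus_branches`` with no inhibitors yields an empty
    design (zero conditions).
    """
    branches = (
        dict(DEFAULT_STIMULUS_BRANCHES)
        if stimulus_branches is None
        else {k: list(v) for k, v in stimulus_branches.items()}
    )
    targets = dict(
        DEFAULT_INHIBITOR_TARGETS if inhibitor_targets is None else inhibitor_targets
    )
    combos = tuple(DEFAULT_FLT3I_COMBOS if flt3i_combos is None else flt3i_combos)
    sent = dict(DEFAULT_SENTINELS if sentinels is None else sentinels)

    all_drugs = set(targets)
    for stim, drugs in branches.items():
        for d in drugs:
            if d not in all_drugs:
                raise ValueError(f"branch inhibitor {d!r} has no declared target")
    for d in combos:
        if d not in all_drugs:
            raise ValueError(f"FLT3i-combo inhibitor {d!r} has no declared target")

    conditions: list[Condition] = []
    empty_design = not branches and not targets

    def add(stimuli_on: Iterable[str], drugs: Iterable[str]) -> None:
        conditions.append(Condition.build(stimuli_on, drugs, targets))

    has_flt3i = "FLT3i" in targets
    if has_flt3i:
        add((), ["FLT3i"])
        for stim in branches:
            add([stim], ["FLT3i"])
        for stim, drugs in branches.items():
            for d in drugs:
                if d in combos:
                    add([stim], ["FLT3i", d])
    for stim in branches:
        add([stim], [])
    for stim, drugs in branches.items():
        for d in drugs:
            add([stim], [d])

    return ExperimentalDesign(
        conditions=conditions,
        stimuli=tuple(branches),
        inhibitors=targets,
        sentinels=sent,
        constitutive=frozenset(constitutive) if not empty_design else frozenset(),
    )


# ---------------------------------------------------------------------------
# raw measurements


@dataclass(frozen=True)
class RawMeasurement:
    """One well x analyte readout from the bead array."""

    condition: str
    analyte: str
    replicate: int
    timepoint: str  # "T0" | "T1"
    mfi: float
    beads: int

    def __post_init__(self) -> None:
        if self.timepoint not in ("T0", "T1"):
            raise ValueError(f"timepoint must be T0 or T1, got {self.timepoint!r}")
        if self.beads < 0:
            raise ValueError("bead count cannot be negative")
        if self.beads > 0 and not self.mfi > 0:
            raise ValueError("MFI must be positive when beads were detected")


def raw_to_frame(raw: Iterable[RawMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.condition, m.analyte, m.replicate, m.timepoint, m.mfi, m.beads)
            for m in raw
        ],
        columns=["condition", "analyte", "replicate", "timepoint", "mfi", "beads"],
    )


def frame_to_raw(df: pd.DataFrame) -> list[RawMeasurement]:
    return [
        RawMeasurement(
            condition=str(r.condition),
            analyte=str(r.analyte),
            replicate=int(r.replicate),
            timepoint=str(r.timepoint),
            mfi=float(r.mfi),
            beads=int(r.beads),
        )
        for r in df.itertuples(index=False)
    ]


def filter_bead_counts(
    raw: Sequence[RawMeasurement], min_beads: int = MIN_BEADS_DEFAULT
) -> tuple[list[RawMeasurement], list[RawMeasurement]]:
    """Split measurements into (kept, excluded) by detected bead count.

    A measurement is kept iff ``beads >= min_beads``; only counts
    strictly below the threshold are excluded.
    """
    kept: list[RawMeasurement] = []
    excluded: list[RawMeasurement] = []
    for m in raw:
        if m.beads < 0:
            raise ValueError("bead count cannot be negative")
        (kept if m.beads >= min_beads else excluded).append(m)
    return kept, excluded


def normalize_loading(
    raw: Sequence[RawMeasurement],
    control_analyte: str = LOADING_CONTROL_DEFAULT,
) -> pd.DataFrame:
    """Divide each analyte MFI by the loading-control MFI of its well.

    Returns a long frame with columns condition, analyte, replicate,
    timepoint, value, masked, reason. Wells whose control is absent
    (e.g. removed by the bead filter) have all their analytes masked
    with reason ``missing``. The control channel itself is removed from
    the downstream analytes.
    """
    df = raw_to_frame(raw)
    controls = (
        df[df.analyte == control_analyte]
        .set_index(["condition", "replicate", "timepoint"])["mfi"]
    )
    rows = []
    for r in df[df.analyte != control_analyte].itertuples(index=False):
        key = (r.condition, r.replicate, r.timepoint)
        if key in controls.index:
            rows.append((*key[:1], r.analyte, key[1], key[2],
                         r.mfi / float(controls.loc[key]), False, ""))
        else:
            rows.append((r.condition, r.analyte, r.replicate, r.timepoint,
                         np.nan, True, "missing"))
    return pd.DataFrame(
        rows,
        columns=["condition", "analyte", "replicate", "timepoint",
                 "value", "masked", "reason"],
    )


def aggregate_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Median and sample SD over unmasked replicates per condition x analyte x timepoint.

    SD uses the n-1 convention and is NaN for a single replicate. Cells
    with zero unmasked replicates are masked, carrying the replicate
    reason (``low-beads`` wins over ``missing`` when both occurred).
    """
    out = []
    values = values.assign(masked=values.masked.astype(bool))
    grouped = values.groupby(["condition", "analyte", "timepoint"], sort=True)
    for (cond, analyte, tp), grp in grouped:
        ok = grp[~grp.masked]
        if len(ok) == 0:
            reasons = set(grp.reason)
            reason = "low-beads" if "low-beads" in reasons else "missing"
            out.append((cond, analyte, tp, np.nan, np.nan, 0, True, reason))
        else:
            med = float(ok.value.median())
            sd = float(ok.value.std(ddof=1)) if len(ok) > 1 else np.nan
            out.append((cond, analyte, tp, med, sd, len(ok), False, ""))
    return pd.DataFrame(
        out,
        columns=["condition", "analyte", "timepoint", "median", "sd",
                 "n_replicates", "masked", "reason"],
    )


# ---------------------------------------------------------------------------
# Hill rescaling


@dataclass(frozen=True)
class HillParams:
    """Closed-form Hill rescaling y = x^n / (K + x^n) for one analyte.

    Parameters are derived from the observed extremes so that
    ``y(min_s) = MIN_T`` and ``y(max_s) = MAX_T``: with b = max_s/min_s,

        n = log(((1 - MIN_T) * MAX_T) / ((1 - MAX_T) * MIN_T)) / log(b)
        K = ((1 - MAX_T) / MAX_T) * max_s ** n
    """

    analyte: str
    n: float
    K: float
    min_s: float
    max_s: float
    min_t: float = MIN_T
    max_t: float = MAX_T

    @property
    def b(self) -> float:
        return self.max_s / self.min_s


def fit_hill_params(
    analyte: str,
    values: Iterable[float],
    min_t: float = MIN_T,
    max_t: float = MAX_T,
) -> HillParams:
    """Derive per-analyte Hill parameters from its observed value range."""
    vals = [float(v) for v in values if not (isinstance(v, float) and math.isnan(v))]
    if any(v <= 0 for v in vals):
        raise ValueError(f"{analyte}: nonpositive value in Hill fit")
    if len(vals) < 2:
        raise ValueError(f"{analyte}: need at least two values")
    min_s, max_s = min(vals), max(vals)
    if max_s == min_s:
        raise ValueError(f"{analyte}: degenerate analyte (constant profile)")
    b = max_s / min_s
    n = math.log(((1 - min_t) * max_t) / ((1 - max_t) * min_t)) / math.log(b)
    K = ((1 - max_t) / max_t) * max_s**n
    return HillParams(analyte=analyte, n=n, K=K, min_s=min_s, max_s=max_s,
                      min_t=min_t, max_t=max_t)


def apply_hill(params: HillParams, x: float) -> float:
    """Evaluate y = x^n / (K + x^n); strictly increasing for x > 0."""
    if not x > 0:
        raise ValueError("Hill rescaling is defined for x > 0 only")
    xn = x**params.n
    return xn / (params.K + xn)


# ---------------------------------------------------------------------------
# normalized dataset


@dataclass
class NormalizedDataset:
    """Conditions x analytes matrices of Hill-normalized values.

    ``t1``/``t0`` hold values in [0, 1] (NaN = masked); ``sd`` the
    replicate spread of the loading-normalized values at T1; ``reasons``
    the mask reason per masked (condition, analyte) cell at T1.
    """

    t1: pd.DataFrame
    t0: pd.DataFrame
    sd: pd.DataFrame
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)
    hill: dict[str, HillParams] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.t1.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.t1.columns)

    def modulation(self) -> pd.DataFrame:
        """Activity modulation T1 - T0 per cell, clipped to [-1, 1]."""
        return (self.t1 - self.t0).clip(-1.0, 1.0)


def normalize_pipeline(
    raw: Sequence[RawMeasurement],
    design: ExperimentalDesign,
    min_beads: int = MIN_BEADS_DEFAULT,
    control_analyte: str = LOADING_CONTROL_DEFAULT,
) -> NormalizedDataset:
    """Full chain: bead filter -> loading normalization -> replicate
    aggregation -> per-analyte Hill rescaling (T0 and T1 pooled).
    """
    kept, excluded = filter_bead_counts(raw, min_beads=min_beads)
    norm = normalize_loading(kept, control_analyte=control_analyte)
    # re-attach bead-excluded wells as masked rows so reasons propagate
    if excluded:
        extra = pd.DataFrame(
            [
                (m.condition, m.analyte, m.replicate, m.timepoint, np.nan,
                 True, "low-beads")
                for m in excluded
                if m.analyte != control_analyte
            ],
            columns=norm.columns,
        )
        norm = pd.concat([norm, extra], ignore_index=True)
    agg = aggregate_replicates(norm)

    cond_order = [c.name for c in design.conditions]
    analytes = sorted(agg.analyte.unique())
    hill: dict[str, HillParams] = {}
    for analyte in analytes:
        pooled = agg[(agg.analyte == analyte) & ~agg.masked]["median"]
        if len(pooled) == 0:
            continue  # fully masked analyte: stays NaN in the matrices
        hill[analyte] = fit_hill_params(analyte, pooled)

    def matrix(tp: str, col: str = "median", rescale: bool = True) -> pd.DataFrame:
        m = pd.DataFrame(index=cond_order, columns=analytes, dtype=float)
        sub = agg[agg.timepoint == tp]
        for r in sub.itertuples(index=False):
            if r.condition not in m.index:
                continue
            v = getattr(r, col)
            if rescale and not r.masked and r.analyte in hill:
                v = apply_hill(hill[r.analyte], v)
            m.loc[r.condition, r.analyte] = v if not r.masked else np.nan
        return m

    reasons = {
        (r.condition, r.analyte): r.reason
        for r in agg[(agg.timepoint == "T1") & agg.masked].itertuples(index=False)
    }
    return NormalizedDataset(
        t1=matrix("T1"),
        t0=matrix("T0"),
        sd=matrix("T1", col="sd", rescale=False),
        reasons=reasons,
        hill=hill,
    )


# ---------------------------------------------------------------------------
# MIDAS serialization


def to_midas(dataset: NormalizedDataset, design: ExperimentalDesign,
             path: str | Path, t1_label: int = 90) -> None:
    """Write the normalized dataset as a MIDAS CSV.

    One row per condition x timepoint; TR: columns encode cues (0/1,
    inhibitors carry an ``i`` suffix), DA: columns the acquisition time
    (0 or ``t1_label``), DV: columns the normalized value (``NA`` when
    masked).
    """
    drug_by_target = {t: d for d, t in design.inhibitors.items()}
    tr_cols = [f"TR:{s}" for s in design.stimuli] + [
        f"TR:{d}" for d in design.inhibitors
    ]
    analytes = dataset.analytes
    rows = []
    for cond in design.conditions:
        for tp, label, matrix in (("T0", 0, dataset.t0), ("T1", t1_label, dataset.t1)):
            row: dict[str, object] = {}
            for s in design.stimuli:
                row[f"TR:{s}"] = int(s in cond.stimuli_on)
            for d, target in design.inhibitors.items():
                row[f"TR:{d}"] = int(target in cond.inhibited)
            for a in analytes:
                row[f"DA:{a}"] = label
                v = matrix.loc[cond.name, a]
                if pd.notna(v) and not (0.0 <= float(v) <= 1.0):
                    raise ValueError(
                        f"{cond.name}/{a}: value {v} outside [0, 1]"
                    )
                row[f"DV:{a}"] = float(v) if pd.notna(v) else np.nan
            rows.append(row)
    cols = tr_cols + [f"DA:{a}" for a in analytes] + [f"DV:{a}" for a in analytes]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, na_rep="NA")


def read_midas(path: str | Path, design: ExperimentalDesign,
               t1_label: int = 90) -> NormalizedDataset:
    """Read a MIDAS CSV written by :func:`to_midas` back into matrices.

    Rows are matched to design conditions through the TR: columns.
    """
    df = pd.read_csv(path)
    analytes = sorted(c[3:] for c in df.columns if c.startswith("DV:"))
    cond_order = [c.name for c in design.conditions]

    def cond_key(cond: Condition) -> tuple:
        key = tuple(int(s in cond.stimuli_on) for s in design.stimuli) + tuple(
            int(t in cond.inhibited) for t in design.inhibitors.values()
        )
        return key

    key_to_name = {cond_key(c): c.name for c in design.conditions}
    t0 = pd.DataFrame(index=cond_order, columns=analytes, dtype=float)
    t1 = pd.DataFrame(index=cond_order, columns=analytes, dtype=float)
    for _, row in df.iterrows():
        key = tuple(int(row[f"TR:{s}"]) for s in design.stimuli) + tuple(
            int(row[f"TR:{d}"]) for d in design.inhibitors
        )
        name = key_to_name[key]
        for a in analytes:
            target = t0 if int(row[f"DA:{a}"]) == 0 else t1
            target.loc[name, a] = row[f"DV:{a}"]
    sd = pd.DataFrame(np.nan, index=cond_order, columns=analytes)
    return NormalizedDataset(t1=t1, t0=t0, sd=sd)
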