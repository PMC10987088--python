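"""Simulator semantics checked against a naive trajectory oracle."""

import numpy as np
import pytest

from signalogic.boolean_core import (
    UNRESOLVED,
    ClampCondition,
    LogicModel,
    activity_modulation,
    mse_fitness,
    simulate_synchronous,
)
from signalogic.preprocess import Gate, ScaffoldModel


def naive_steady_state(model, clamp, initial=None, max_iter=100):
    """Independent oracle: dict-based step-by-step trajectory enumeration."""
    state = {n: 0 for n in model.nodes}
    if initial:
        state.update(initial)
    for n in clamp.clamp_on:
        state[n] = 1
    for n in clamp.clamp_off:
        state[n] = 0
    gates_by_node = {}
    for g, b in zip(model.scaffold.gates, model.selection):
        if b:
            gates_by_node.setdefault(g.output, []).append(g)
    traj = [dict(state)]
    for _ in range(max_iter):
        new = {}
        for n in model.nodes:
            gates = gates_by_node.get(n)
            if not gates:
                new[n] = state[n]
            else:
                new[n] = int(any(
                    all((state[i] == 1) if s > 0 else (state[i] == 0)
                        for i, s in g.inputs)
                    for g in gates
                ))
        for x in clamp.clamp_on:
            new[x] = 1
        for x in clamp.clamp_off:
            new[x] = 0
        if new in traj:
            start = traj.index(new)
            cycle = traj[start:]
            if len(cycle) == 1:
                return dict(new), True
            values = {}
            for n in model.nodes:
                seen = {s[n] for s in cycle}
                values[n] = seen.pop() if len(seen) == 1 else UNRESOLVED
            return values, False
        state = new
        traj.append(dict(state))
    clamped = clamp.clamp_on | clamp.clamp_off
    return {n: (state[n] if n in clamped else UNRESOLVED)
            for n in model.nodes}, False


def random_instance(rng):
    n_nodes = int(rng.integers(3, 11))
    names = [f"N{i}" for i in range(n_nodes)]
    n_gates = int(rng.integers(1, 2 * n_nodes))
    gates = []
    for _ in range(n_gates):
        out = names[int(rng.integers(0, n_nodes))]
        arity = int(rng.integers(1, 3))
        inputs = rng.choice(n_nodes, size=arity, replace=False)
        gates.append(Gate(out, tuple(
            (names[i], int(rng.choice([1, -1]))) for i in inputs
        )))
    selection = tuple(int(b) for b in rng.integers(0, 2, len(gates)))
    model = LogicModel(ScaffoldModel(species=names, gates=gates), selection)
    k_on = int(rng.integers(0, 3))
    k_off = int(rng.integers(0, 3))
    picks = list(rng.permutation(names))
    clamp = ClampCondition(
        "rnd", frozenset(picks[:k_on]), frozenset(picks[k_on:k_on + k_off])
    )
    initial = {n: int(rng.integers(0, 2)) for n in names}
    return model, clamp, initial


class TestSimulatorSemantics:
    def test_chain_activation_fixpoint(self):
        sc = ScaffoldModel(
            species=["A", "B", "C"],
            gates=[Gate("B", (("A", 1),)), Gate("C", (("B", 1),))],
        )
        st = simulate_synchronous(
            LogicModel.full(sc), ClampCondition("on", frozenset({"A"}))
        )
        assert st.converged
        assert st.iterations <= 3
        assert (st["A"], st["B"], st["C"]) == (1, 1, 1)

    def test_negative_feedback_period_four_cycle(self):
        """A->B with B -| A from (A=1, B=0) walks (1,0)->(1,1)->(0,1)->(0,0)."""
        sc = ScaffoldModel(
            species=["A", "B"],
            gates=[Gate("B", (("A", 1),)), Gate("A", (("B", -1),))],
        )
        st = simulate_synchronous(
            LogicModel.full(sc), ClampCondition("free"),
            initial={"A": 1, "B": 0},
        )
        assert st.cycle_period == 4
        assert st["A"] is UNRESOLVED and st["B"] is UNRESOLVED

    def test_all_nodes_clamped_immediate_fixpoint(self):
        sc = ScaffoldModel(species=["A", "B"], gates=[Gate("B", (("A", 1),))])
        st = simulate_synchronous(
            LogicModel.full(sc),
            ClampCondition("all", frozenset({"A"}), frozenset({"B"})),
        )
        assert st.converged and st.iterations == 1
        assert (st["A"], st["B"]) == (1, 0)

    def test_unknown_clamp_node_errors(self):
        sc = ScaffoldModel(species=["A"], gates=[Gate("A", (("A", 1),))])
        with pytest.raises(ValueError, match="ghost"):
            simulate_synchronous(LogicModel.full(sc),
                                 ClampCondition("x", frozenset({"ghost"})))

    def test_fixpoint_is_verified_by_reapplication(self, small_truth):
        from signalogic.boolean_core import training_clamps

        model = small_truth.truth_model
        for clamp in training_clamps(small_truth.design, model.nodes):
            st = simulate_synchronous(model, clamp)
            assert st.converged
            again = simulate_synchronous(
                model, clamp, initial={n: v for n, v in st.values.items()}
            )
            assert again.values == st.values
            assert again.iterations == 1

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            model, clamp, initial = random_instance(rng)
            st = simulate_synchronous(model, clamp, initial=initial)
            expected, fixpoint = naive_steady_state(model, clamp, initial)
            assert st.values == expected
            assert st.converged == fixpoint

    def test_clamped_nodes_constant_throughout(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model, clamp, initial = random_instance(rng)
            st = simulate_synchronous(model, clamp, initial=initial)
            for n in clamp.clamp_on:
                assert st[n] == 1
            for n in clamp.clamp_off:
                assert st[n] == 0


class TestFitness:
    def test_perfect_model_zero_mse(self, small_truth, noisefree_dataset):
        fr = mse_fitness(small_truth.truth_model, noisefree_dataset,
                         small_truth.design, theta_size=0.0)
        # noise-free data are exactly 0.001/0.999, so the squared error
        # floor per cell is at most 0.001**2
        assert fr.mse <= 1e-6 + 1e-12
        assert fr.na_penalty == 0.0

    def test_single_cell_arithmetic(self):
        import pandas as pd

        from signalogic.dataprep import NormalizedDataset, enumerate_design

        sc = ScaffoldModel(species=["FLT3", "S"], gates=[Gate("S", (("FLT3", 1),))])
        design = enumerate_design(
            stimulus_branches={}, inhibitor_targets={"FLT3i": "FLT3"},
            flt3i_combos=(), sentinels={"S": 1},
        )
        design.conditions[:] = [design.conditions[0]]  # FLT3i only
        t1 = pd.DataFrame({"S": [0.5]}, index=["FLT3i"])
        ds = NormalizedDataset(t1=t1, t0=t1 * np.nan, sd=t1 * np.nan)
        fr = mse_fitness(LogicModel.full(sc), ds, design, theta_size=0.0)
        # FLT3 clamped off -> S predicted 0, data 0.5
        assert fr.mse == pytest.approx(0.25)
        assert fr.n_points == 1

    def test_masked_cells_excluded_and_order_invariant(self, small_truth):
        from signalogic.dataprep import normalize_pipeline
        from signalogic.synthetic import simulate_dataset

        raw = simulate_dataset(small_truth, noise_sd=0.05, low_bead_rate=0.3,
                               seed=9)
        ds = normalize_pipeline(raw, small_truth.design)
        n_unmasked = int(ds.t1.notna().sum().sum())
        fr = mse_fitness(small_truth.truth_model, ds, small_truth.design)
        assert fr.n_points == n_unmasked

        import copy

        design2 = copy.deepcopy(small_truth.design)
        design2.conditions.reverse()
        fr2 = mse_fitness(small_truth.truth_model, ds, design2)
        assert fr2.mse == pytest.approx(fr.mse, abs=1e-12)

    def test_deselecting_wrong_gate_never_hurts(self):
        """On a constructed instance, dropping a wrong-prediction gate
        cannot increase the error."""
        import pandas as pd

        from signalogic.dataprep import NormalizedDataset, enumerate_design

        sc = ScaffoldModel(
            species=["FLT3", "S"],
            gates=[Gate("S", (("FLT3", 1),)), Gate("S", (("FLT3", -1),))],
        )
        design = enumerate_design(
            stimulus_branches={}, inhibitor_targets={"FLT3i": "FLT3"},
            flt3i_combos=(), sentinels={"S": 1},
        )
        t1 = pd.DataFrame({"S": [0.001]}, index=["FLT3i"])
        design.conditions[:] = [design.conditions[0]]
        ds = NormalizedDataset(t1=t1, t0=t1 * np.nan, sd=t1 * np.nan)
        with_wrong = mse_fitness(LogicModel(sc, (1, 1)), ds, design,
                                 theta_size=0.0)
        without = mse_fitness(LogicModel(sc, (1, 0)), ds, design,
                              theta_size=0.0)
        assert without.mse <= with_wrong.mse


class TestModulation:
    @pytest.mark.parametrize("t1,t0,expected", [
        (1, 0, 1.0), (1, 1, 0.0), (0.3, 0.8, -0.5),
    ])
    def test_difference_and_clip(self, t1, t0, expected):
        out = activity_modulation({"X": t1}, {"X": t0})
        assert out["X"] == pytest.approx(expected)

    def test_unresolved_masked(self):
        out = activity_modulation({"X": UNRESOLVED}, {"X": 1})
        assert out["X"] is None
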