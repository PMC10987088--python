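import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signalogic.dataprep import NormalizedDataset, enumerate_design
from signalogic.network_io import CausalEdge, CausalNetwork, NodeSpec
from signalogic.preprocess import (
    Gate,
    ScaffoldModel,
    add_edges,
    compress,
    expand,
    impute_data_edges,
)


def _net(edges, measured=(), targeted=(), categories=None):
    names = {n for e in edges for n in (e[0], e[1])}
    net = CausalNetwork(
        nodes={n: NodeSpec(n) for n in names},
        edges=[CausalEdge(u, v, s) for u, v, s in edges],
    )
    return net.with_designations(measured=measured, targeted=targeted,
                                 categories=categories)


def _design(cues=(), sentinels=()):
    """Minimal design stub: compression only reads the designations."""

    class D:
        constitutive = frozenset()

        def cue_nodes(self):
            return list(cues)

        def sentinel_nodes(self):
            return list(sentinels)

    return D()


class TestCompress:
    def test_chain_collapse_positive(self):
        net = _net([("A", "B", 1), ("B", "C", 1)], measured=["C"], targeted=["A"])
        out = compress(net, _design(["A"], ["C"]))
        assert out.edge_set() == {("A", "C", 1)}

    def test_sign_product_of_double_inhibition(self):
        net = _net([("A", "B", -1), ("B", "C", -1)], measured=["C"], targeted=["A"])
        out = compress(net, _design(["A"], ["C"]))
        assert out.edge_set() == {("A", "C", 1)}

    def test_dangling_sink_deleted(self):
        net = _net([("A", "B", 1)], targeted=["A"])
        out = compress(net, _design(["A"], []))
        assert "B" not in out.nodes
        assert out.n_edges == 0

    def test_designated_nodes_never_removed(self):
        net = _net([("A", "B", 1), ("B", "C", 1)],
                   measured=["B", "C"], targeted=["A"])
        out = compress(net, _design(["A"], ["B", "C"]))
        assert set(out.nodes) == {"A", "B", "C"}

    def test_phenotype_nodes_protected(self):
        net = _net([("A", "B", 1), ("B", "apoptosis", 1)],
                   targeted=["A"], categories={"apoptosis": "phenotype"})
        out = compress(net, _design(["A"], []))
        assert "apoptosis" in out.nodes
        assert out.edge_set() == {("A", "apoptosis", 1)}

    def test_reachability_sign_preserved(self, small_truth):
        """Any signed cue->sentinel path of the PKN survives compression."""
        import networkx as nx

        net = small_truth.pkn
        design = small_truth.design
        out = compress(net, design)

        def signed_paths(n):
            g = nx.DiGraph()
            for e in n.edges:
                if g.has_edge(e.source, e.target):
                    g[e.source][e.target]["signs"].add(e.sign)
                else:
                    g.add_edge(e.source, e.target, signs={e.sign})
            reach = {}
            for cue in design.cue_nodes():
                if cue not in g:
                    continue
                for sent in design.sentinel_nodes():
                    if sent not in g:
                        continue
                    for path in nx.all_simple_paths(g, cue, sent, cutoff=8):
                        sign_sets = [g[a][b]["signs"]
                                     for a, b in zip(path, path[1:])]
                        for combo in _products(sign_sets):
                            reach.setdefault((cue, sent), set()).add(combo)
            return reach

        def _products(sets):
            out = {1}
            for s in sets:
                out = {a * b for a in out for b in s}
            return out

        before = signed_paths(net)
        after = signed_paths(out)
        for key, signs in before.items():
            assert signs <= after.get(key, set()), key


class TestExpand:
    def test_two_activators_max_two(self):
        net = _net([("A", "C", 1), ("B", "C", 1)])
        scaffold = expand(net, max_gate_inputs=2)
        c_gates = [scaffold.gates[i] for i in scaffold.gates_for("C")]
        assert len(c_gates) == 3
        assert scaffold.n_and_nodes == 1

    def test_mixed_sign_and_gate_semantics(self):
        net = _net([("A", "C", 1), ("B", "C", -1)])
        scaffold = expand(net, max_gate_inputs=2)
        and_gates = [g for g in scaffold.gates if g.arity == 2]
        assert and_gates == [Gate("C", (("A", 1), ("B", -1)))]

    def test_single_regulator_single_gate(self):
        net = _net([("A", "C", 1)])
        scaffold = expand(net)
        assert scaffold.n_gates == 1
        assert scaffold.n_and_nodes == 0

    @settings(max_examples=20, derandomize=True)
    @given(k=st.integers(min_value=1, max_value=6),
           m=st.integers(min_value=2, max_value=4))
    def test_gate_count_formula(self, k, m):
        edges = [(f"R{i}", "X", 1) for i in range(k)]
        scaffold = expand(_net(edges), max_gate_inputs=m)
        expected = k + sum(math.comb(k, j) for j in range(2, min(k, m) + 1))
        assert scaffold.n_gates == expected


class TestImpute:
    @staticmethod
    def _dataset(profiles: dict[str, list[float]]):
        conds = [f"c{i}" for i in range(len(next(iter(profiles.values()))))]
        t1 = pd.DataFrame(profiles, index=conds, dtype=float)
        return NormalizedDataset(t1=t1, t0=t1 * np.nan, sd=t1 * np.nan)

    @staticmethod
    def _design(sentinels):
        return enumerate_design(
            stimulus_branches={}, inhibitor_targets={}, flt3i_combos=(),
            sentinels={s: 1 for s in sentinels}, constitutive=(),
        )

    def test_identical_profiles_add_positive_edge(self):
        ds = self._dataset({"X": [0.1, 0.9, 0.1, 0.9],
                            "Y": [0.1, 0.9, 0.1, 0.9]})
        # design has no conditions; use the dataset's own index as conditions
        design = self._design(["X", "Y"])
        net = _net([("X", "Z", 1), ("Z", "Y", 1)])
        edges = impute_data_edges(net, ds, design)
        assert ("X", "Y", 1) in {(e.source, e.target, e.sign) for e in edges}
        assert all(e.provenance == "data-derived" for e in edges)

    def test_anticorrelated_profiles_add_negative_edge(self):
        ds = self._dataset({"X": [0.1, 0.9, 0.2, 0.8],
                            "Y": [0.9, 0.1, 0.8, 0.2]})
        net = _net([("X", "Z", 1), ("Z", "Y", 1)])
        edges = impute_data_edges(net, ds, self._design(["X", "Y"]))
        assert ("X", "Y", -1) in {(e.source, e.target, e.sign) for e in edges}

    def test_weak_correlation_below_threshold_skipped(self):
        ds = self._dataset({"X": [0.1, 0.9, 0.1, 0.9, 0.5],
                            "Y": [0.4, 0.5, 0.6, 0.4, 0.6]})
        net = _net([("X", "Z", 1), ("Z", "Y", 1)])
        assert impute_data_edges(net, ds, self._design(["X", "Y"])) == []

    def test_existing_edge_not_duplicated(self):
        ds = self._dataset({"X": [0.1, 0.9, 0.1, 0.9],
                            "Y": [0.1, 0.9, 0.1, 0.9]})
        net = _net([("X", "Y", 1)])
        edges = impute_data_edges(net, ds, self._design(["X", "Y"]))
        assert ("X", "Y", 1) not in {(e.source, e.target, e.sign) for e in edges}

    def test_imputation_is_superset_operation(self):
        """All curated gates survive when imputed edges enter expansion."""
        net = _net([("X", "Z", 1), ("Z", "Y", 1)])
        base = expand(net)
        ds = self._dataset({"X": [0.1, 0.9, 0.1, 0.9],
                            "Y": [0.1, 0.9, 0.1, 0.9]})
        merged = add_edges(net, impute_data_edges(net, ds, self._design(["X", "Y"])))
        grown = expand(merged)
        base_keys = {(g.output, g.inputs) for g in base.gates}
        grown_keys = {(g.output, g.inputs) for g in grown.gates}
        assert base_keys <= grown_keys


class TestScaffoldSerialization:
    def test_json_round_trip(self, tmp_path, small_truth):
        scaffold = small_truth.scaffold
        p = tmp_path / "scaffold.json"
        scaffold.to_json(p)
        back = ScaffoldModel.from_json(p)
        assert back.species == scaffold.species
        assert back.gates == scaffold.gates

    def test_sif_export_materializes_and_nodes(self, tmp_path):
        scaffold = ScaffoldModel(
            species=["A", "B", "C"],
            gates=[Gate("C", (("A", 1), ("B", -1)))],
        )
        p = tmp_path / "scaffold.sif"
        scaffold.to_sif(p)
        text = p.read_text()
        assert "and1" in text
        assert "A\t1\tand1" in text and "B\t-1\tand1" in text
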