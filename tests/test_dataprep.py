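import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signalogic.dataprep import (
    RawMeasurement,
    aggregate_replicates,
    apply_hill,
    enumerate_design,
    filter_bead_counts,
    fit_hill_params,
    normalize_loading,
    normalize_pipeline,
    read_midas,
    to_midas,
)

PRINTED_CONDITIONS = {
    "FLT3i", "FLT3i+IGF1", "FLT3i+TNFa", "FLT3i+p38i+TNFa", "FLT3i+JNKi+TNFa",
    "FLT3i+PI3Ki+IGF1", "FLT3i+mTORi+IGF1", "FLT3i+MEKi+IGF1", "IGF1", "TNFa",
    "p38i+TNFa", "JNKi+TNFa", "PI3Ki+IGF1", "mTORi+IGF1", "MEKi+IGF1",
    "GSK3i+IGF1",
}


class TestEnumerateDesign:
    def test_default_panel_is_the_sixteen_printed_conditions(self):
        design = enumerate_design()
        assert len(design.conditions) == 16
        assert {c.name for c in design.conditions} == PRINTED_CONDITIONS

    def test_gsk3_is_not_paired_with_flt3_inhibition(self):
        names = {c.name for c in enumerate_design().conditions}
        assert "GSK3i+IGF1" in names
        assert "FLT3i+JNKi+TNFa" in names
        assert "FLT3i+GSK3i+IGF1" not in names

    def test_condition_membership_encoding(self):
        design = enumerate_design()
        cond = design.condition("FLT3i+PI3Ki+IGF1")
        assert cond.stimuli_on == frozenset({"IGF1"})
        assert cond.inhibited == frozenset({"FLT3", "PI3K"})

    def test_empty_spec_yields_empty_design(self):
        design = enumerate_design(stimulus_branches={}, inhibitor_targets={},
                                  flt3i_combos=(), sentinels={})
        assert design.conditions == []

    def test_unknown_drug_in_branch_errors(self):
        with pytest.raises(ValueError, match="no declared target"):
            enumerate_design(stimulus_branches={"IGF1": ["ghosti"]})


def _m(beads, mfi=100.0, analyte="X", cond="c1", rep=1, tp="T1"):
    return RawMeasurement(cond, analyte, rep, tp, mfi, beads)


class TestBeadFilter:
    @pytest.mark.parametrize("beads,kept", [(50, True), (49, False), (0, False)])
    def test_boundary_at_fifty(self, beads, kept):
        k, e = filter_bead_counts([_m(beads, mfi=100.0 if beads else 0.0)])
        assert (len(k), len(e)) == ((1, 0) if kept else (0, 1))

    def test_empty_input(self):
        assert filter_bead_counts([]) == ([], [])

    def test_negative_beads_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            _m(-1)


class TestLoadingNormalization:
    def test_ratio(self):
        rows = [_m(100, mfi=3000.0, analyte="X"),
                _m(100, mfi=1500.0, analyte="ctrl")]
        norm = normalize_loading(rows, control_analyte="ctrl")
        assert norm.value.tolist() == [2.0]

    def test_missing_control_masks_whole_well(self):
        rows = [_m(100, analyte="X"), _m(100, analyte="Y")]
        norm = normalize_loading(rows, control_analyte="ctrl")
        assert norm.masked.all()
        assert set(norm.reason) == {"missing"}

    def test_control_channel_removed_downstream(self):
        rows = [_m(100, analyte="X"), _m(100, analyte="ctrl")]
        norm = normalize_loading(rows, control_analyte="ctrl")
        assert set(norm.analyte) == {"X"}


class TestAggregateReplicates:
    def test_median_and_sample_sd(self):
        rows = [_m(100, mfi=v, rep=r, analyte="X")
                for r, v in ((1, 1000.0), (2, 3000.0))]
        rows.append(_m(100, mfi=1000.0, rep=1, analyte="ctrl"))
        rows.append(_m(100, mfi=1000.0, rep=2, analyte="ctrl"))
        agg = aggregate_replicates(normalize_loading(rows, "ctrl"))
        row = agg.iloc[0]
        assert row["median"] == 2.0
        assert row["sd"] == pytest.approx(math.sqrt(2))

    def test_single_replicate_sd_masked(self):
        norm = normalize_loading(
            [_m(100, analyte="X"), _m(100, analyte="ctrl")], "ctrl"
        )
        agg = aggregate_replicates(norm)
        assert agg.iloc[0]["median"] == 1.0
        assert np.isnan(agg.iloc[0]["sd"])

    def test_zero_unmasked_replicates_masks_cell(self):
        norm = normalize_loading([_m(100, analyte="X")], "ctrl")
        agg = aggregate_replicates(norm)
        assert bool(agg.iloc[0]["masked"])


class TestHill:
    def test_worked_closed_form_n2_k999(self):
        p = fit_hill_params("x", range(1, 1000))
        assert p.n == pytest.approx(2.0, abs=1e-12)
        assert p.K == pytest.approx(999.0, rel=1e-12)

    def test_half_saturation_point(self):
        p = fit_hill_params("x", [1.0, 999.0])
        assert apply_hill(p, p.K ** (1 / p.n)) == pytest.approx(0.5)

    def test_degenerate_and_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_hill_params("x", [2.0, 2.0])
        with pytest.raises(ValueError, match="nonpositive"):
            fit_hill_params("x", [-1.0, 2.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=2,
                 max_size=20, unique=True),
    )
    def test_boundary_conditions_and_monotonicity(self, values):
        if max(values) / min(values) < 1.001:
            return
        p = fit_hill_params("x", values)
        assert apply_hill(p, p.max_s) == pytest.approx(0.999, abs=1e-9)
        assert apply_hill(p, p.min_s) == pytest.approx(0.001, abs=1e-9)
        xs = sorted(values)
        ys = [apply_hill(p, x) for x in xs]
        assert all(a < b for a, b in zip(ys, ys[1:]))


class TestPipelineAndMidas:
    def test_values_land_in_hill_range_with_extremes(self, small_truth,
                                                     noisefree_dataset):
        ds = noisefree_dataset
        vals = ds.t1.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0.001 - 1e-12) & (vals <= 0.999 + 1e-12)).all()
        for analyte in ds.analytes:
            pooled = np.concatenate([ds.t1[analyte].dropna(),
                                     ds.t0[analyte].dropna()])
            assert pooled.min() == pytest.approx(0.001, abs=1e-9)
            assert pooled.max() == pytest.approx(0.999, abs=1e-9)

    def test_midas_round_trip(self, small_truth, noisefree_dataset, tmp_path):
        path = tmp_path / "data.csv"
        to_midas(noisefree_dataset, small_truth.design, path)
        back = read_midas(path, small_truth.design)
        np.testing.assert_allclose(
            back.t1.to_numpy(float), noisefree_dataset.t1.to_numpy(float),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            back.t0.to_numpy(float), noisefree_dataset.t0.to_numpy(float),
            atol=1e-12,
        )

    def test_midas_treatment_encoding(self, small_truth, noisefree_dataset,
                                      tmp_path):
        import pandas as pd

        path = tmp_path / "data.csv"
        design = small_truth.design
        to_midas(noisefree_dataset, design, path)
        df = pd.read_csv(path)
        # FLT3i-only condition row at T1: FLT3i on, stimuli off
        row = df[(df["TR:FLT3i"] == 1)
                 & (df[[f"TR:{s}" for s in design.stimuli]].sum(axis=1) == 0)]
        assert len(row) >= 1
        drugs = [d for d in design.inhibitors if d != "FLT3i"]
        assert (row[[f"TR:{d}" for d in drugs]].to_numpy() == 0).all()

    def test_masked_cells_written_as_na(self, small_truth, tmp_path):
        from signalogic.synthetic import simulate_dataset

        raw = simulate_dataset(small_truth, noise_sd=0.0, low_bead_rate=0.3,
                               seed=11)
        ds = normalize_pipeline(raw, small_truth.design)
        assert ds.t1.isna().any().any()
        path = tmp_path / "masked.csv"
        to_midas(ds, small_truth.design, path)
        assert "NA" in path.read_text()

    def test_pipeline_commutes_with_condition_reordering(self, small_truth):
        from signalogic.synthetic import simulate_dataset

        raw = simulate_dataset(small_truth, noise_sd=0.05, seed=5)
        ds1 = normalize_pipeline(raw, small_truth.design)
        ds2 = normalize_pipeline(list(reversed(raw)), small_truth.design)
        np.testing.assert_allclose(ds1.t1.to_numpy(float),
                                   ds2.t1.to_numpy(float), atol=1e-12)
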