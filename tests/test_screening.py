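import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.weightstats import ttest_ind as sm_ttest_ind

from episcreen.pools import build_matrix, decode
from episcreen.screening import (
    PositivityCall,
    ScreenConfig,
    WellTableError,
    call_pools,
    call_stimulus,
    calls_to_frame,
    confirm_peptides,
    qc_plate,
    two_stage_screen,
)
from episcreen.simulate import SimulationConfig, simulate_peptide_plate, simulate_pool_plate


def _wells(treated, control, stimulus="pool:1", allele="H2-Kd"):
    rows = []
    for i, spots in enumerate(treated):
        rows.append((allele, f"T{i}", "treated", stimulus, spots))
    for i, spots in enumerate(control):
        rows.append((allele, f"C{i}", "control", stimulus, spots))
    return pd.DataFrame(
        rows, columns=["allele", "mouse_id", "group", "stimulus", "spots"]
    )


class TestCallStimulus:
    def test_strong_response_is_positive_and_p_matches_oracle(self):
        treated, control = [200, 220, 210, 190], [5, 8, 6, 7]
        call = call_stimulus(_wells(treated, control))
        assert call.positive and call.passes_floor
        # independent equal-variance t test implementation
        _, p_oracle, _ = sm_ttest_ind(
            np.array(treated, float), np.array(control, float), usevar="pooled"
        )
        assert call.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_welch_variant_matches_oracle(self):
        treated, control = [200, 260, 210, 190, 330], [5, 8, 6, 7]
        call = call_stimulus(_wells(treated, control), ScreenConfig(welch=True))
        _, p_oracle, _ = sm_ttest_ind(
            np.array(treated, float), np.array(control, float), usevar="unequal"
        )
        assert call.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_identical_groups_not_positive(self):
        call = call_stimulus(_wells([70, 80, 90, 100], [70, 80, 90, 100]))
        assert not call.positive

    def test_floor_rule_blocks_significant_but_weak_response(self):
        call = call_stimulus(_wells([55, 58, 57, 56], [5, 6, 5, 7]))
        assert call.p_value < 0.05
        assert not call.passes_floor
        assert not call.positive

    def test_small_group_is_indeterminate_never_positive(self):
        call = call_stimulus(_wells([500], [5, 6, 5, 7]))
        assert call.indeterminate and not call.positive

    def test_treated_below_control_not_positive(self):
        call = call_stimulus(_wells([60, 62, 61, 63], [200, 210, 220, 205]))
        assert not call.positive

    def test_negative_counts_rejected(self):
        with pytest.raises(WellTableError, match="negative"):
            call_stimulus(_wells([-1, 5], [5, 6]))


class TestQC:
    def _plate(self, pc_mean, nc_mean):
        rows = []
        for group in ("control", "treated"):
            for i in range(3):
                rows.append((group, f"{group}{i}", "NC", nc_mean + i))
                rows.append((group, f"{group}{i}", "PC", pc_mean + i))
        return pd.DataFrame(rows, columns=["group", "mouse_id", "stimulus", "spots"]).assign(
            allele="H2-Kd"
        )

    def test_wide_separation_passes(self):
        assert qc_plate(self._plate(400, 5)).passed

    def test_low_positive_control_fails(self):
        report = qc_plate(self._plate(30, 5))
        assert not report.passed
        assert any("positive control below floor" in f for f in report.failures)

    def test_missing_negative_control_fails(self):
        plate = self._plate(400, 5)
        report = qc_plate(plate[plate["stimulus"] != "NC"])
        assert not report.passed
        assert any("missing negative control" in f for f in report.failures)

    def test_high_background_fails(self):
        report = qc_plate(self._plate(400, 90))
        assert any("background" in f for f in report.failures)


class TestCallPools:
    def test_planted_pools_recovered_exactly(self, make_panel):
        design = build_matrix(make_panel(50))
        planted_ids = {"N6", "N7", "N8", "N16", "N25"}  # rows 1-4, cols {1,2,4,6,7}
        config = SimulationConfig(seed=11, true_epitopes=frozenset(planted_ids))
        wells = simulate_pool_plate(config, design)
        calls, positive = call_pools(wells, design)
        expected = set()
        for cid in planted_ids:
            row, col = design.pools_of(cid)
            expected |= {row, col}
        assert positive == expected
        assert len(calls) == 14

    def test_pool_without_wells_is_indeterminate(self, make_panel):
        design = build_matrix(make_panel(50))
        config = SimulationConfig(seed=3, true_epitopes=frozenset({"N1"}))
        wells = simulate_pool_plate(config, design)
        wells = wells[wells["stimulus"] != "pool:14"]
        calls, _ = call_pools(wells, design)
        by_stim = {c.stimulus: c for c in calls}
        assert by_stim["pool:14"].indeterminate

    def test_all_pools_planted_all_positive(self, make_panel):
        design = build_matrix(make_panel(50))
        config = SimulationConfig(
            seed=5, true_epitopes=frozenset(design.candidate_order)
        )
        wells = simulate_pool_plate(config, design)
        _, positive = call_pools(wells, design)
        assert positive == set(design.pool_ids)

    def test_null_plates_stay_silent(self, make_panel):
        # the 60-count floor suppresses false pool calls under the null
        design = build_matrix(make_panel(50))
        hits = 0
        for seed in range(100):
            wells = simulate_pool_plate(SimulationConfig(seed=seed), design)
            _, positive = call_pools(wells, design)
            hits += bool(positive)
        assert hits == 0

    def test_bh_correction_weakly_conservative(self, make_panel):
        design = build_matrix(make_panel(50))
        config = SimulationConfig(seed=21, true_epitopes=frozenset({"N1", "N9"}))
        wells = simulate_pool_plate(config, design)
        _, raw_positive = call_pools(wells, design, ScreenConfig())
        _, bh_positive = call_pools(wells, design, ScreenConfig(multiplicity="bh"))
        assert bh_positive <= raw_positive


class TestConfirmAndTwoStage:
    def test_planted_candidates_confirmed(self):
        planted = ("N6", "P16")
        candidates = ("N6", "N7", "P16", "P20")
        config = SimulationConfig(seed=9, true_epitopes=frozenset(planted))
        wells = simulate_peptide_plate(config, candidates, "H2-Kd")
        calls, confirmed = confirm_peptides(wells, candidates)
        assert tuple(confirmed) == planted
        assert len(calls) == len(candidates)

    def test_candidate_without_wells_left_unconfirmed(self):
        config = SimulationConfig(seed=9, true_epitopes=frozenset({"N6"}))
        wells = simulate_peptide_plate(config, ("N6",), "H2-Kd")
        with pytest.warns(UserWarning, match="no wells"):
            calls, confirmed = confirm_peptides(wells, ("N6", "N7"))
        assert confirmed == ["N6"]
        assert calls[1].indeterminate

    def test_zero_candidates(self):
        wells = simulate_peptide_plate(SimulationConfig(seed=1), (), "H2-Kd")
        calls, confirmed = confirm_peptides(wells, ())
        assert calls == [] and confirmed == []

    def test_effect_below_floor_never_confirms(self):
        config = SimulationConfig(
            seed=13, effect_mean=40.0, true_epitopes=frozenset({"N6"}), potency_spread=0.0
        )
        wells = simulate_peptide_plate(config, ("N6",), "H2-Kd")
        _, confirmed = confirm_peptides(wells, ("N6",))
        assert confirmed == []

    def test_two_stage_screen_confirmed_subset_of_decoded(self, make_panel):
        design = build_matrix(make_panel(50))
        planted = frozenset({"N6", "N16", "N25"})
        pool_wells = simulate_pool_plate(
            SimulationConfig(seed=31, true_epitopes=planted), design
        )
        _, positive = call_pools(pool_wells, design)
        decoded = decode(design, positive).candidates
        pep_wells = simulate_peptide_plate(
            SimulationConfig(seed=32, true_epitopes=planted), decoded, "H2-Kd"
        )
        result = two_stage_screen(pool_wells, pep_wells, design)
        assert set(result.confirmed) == planted
        assert set(result.confirmed) <= set(result.deconvolution.candidates)
        assert set(result.deconvolution.candidates) <= set(design.candidate_order)

    def test_stage_separation_without_peptide_wells(self, make_panel):
        design = build_matrix(make_panel(50))
        planted = frozenset({"N6"})
        pool_wells = simulate_pool_plate(
            SimulationConfig(seed=41, true_epitopes=planted), design
        )
        result = two_stage_screen(pool_wells, None, design)
        assert result.confirmed == ()
        assert len(result.deconvolution.candidates) >= 1


def test_calls_frame_shape():
    call = PositivityCall(
        stimulus="pool:1",
        mean_treated=100.0,
        mean_control=5.0,
        p_value=0.01,
        passes_floor=True,
        positive=True,
        n_treated=6,
        n_control=4,
    )
    frame = calls_to_frame([call])
    assert list(frame["stimulus"]) == ["pool:1"]
    assert bool(frame["positive"][0])
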