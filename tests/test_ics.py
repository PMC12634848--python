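import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcreen.ics import (
    GATE_COMBINATIONS,
    compare_routes,
    correlate_assays,
    epitope_composition,
    ifng_frequency,
    polyfunction_gates,
    round_frequency,
)
from episcreen.simulate import ICSEffectConfig, SimulationConfig, simulate_ics


class TestFrequency:
    @pytest.mark.parametrize(
        "positive, total, expected",
        [(0, 1000, 0.0), (50, 1000, 5.0), (467, 1005, 46.47)],
    )
    def test_percentage_with_reporting_convention(self, positive, total, expected):
        assert round_frequency(ifng_frequency(positive, total)) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ifng_frequency(5, 0)

    def test_positive_above_total_rejected(self):
        with pytest.raises(ValueError):
            ifng_frequency(11, 10)


class TestCorrelation:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate_assays(x, [2 * v for v in x]).r == pytest.approx(1.0)
        assert correlate_assays(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0, 4.0])
        result = correlate_assays(x, y)
        # closed-form product-moment estimate and t-based two-sided p
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t = r_oracle * np.sqrt((len(x) - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), len(x) - 2)
        assert result.r == pytest.approx(r_oracle, abs=1e-12)
        assert result.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert result.n == 11

    def test_symmetric_and_affine_invariant(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [2.0, 3.0, 7.0, 9.0, 1.0]
        forward = correlate_assays(x, y).r
        assert correlate_assays(y, x).r == pytest.approx(forward, abs=1e-12)
        rescaled = correlate_assays([3 * v + 10 for v in x], y).r
        assert rescaled == pytest.approx(forward, abs=1e-12)

    def test_zero_variance_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="zero variance"):
            result = correlate_assays([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not result.defined and np.isnan(result.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate_assays([1.0, 2.0], [1.0, 2.0])


def _ics_table(stimuli, routes=("iv", "it"), n=6, effects=None, seed=0):
    effects = effects or ICSEffectConfig()
    config = SimulationConfig(seed=seed, n_treated=n, n_control=4)
    return simulate_ics(config, effects, stimuli, tissues=("spleen",), routes=routes)


class TestCompareRoutes:
    def test_identical_distributions_flag_at_most_alpha_rate(self):
        # type-I behaviour: with no route effect, significant contrasts appear
        # at most at roughly the nominal rate
        effects = ICSEffectConfig(route_multipliers={"iv": 1.0, "it": 1.0}, noise_cv=0.3)
        total, flagged = 0, 0
        for seed in range(30):
            table = _ics_table(["e1", "e2", "e3"], effects=effects, seed=seed)
            _, contrasts = compare_routes(table, ["e1", "e2", "e3"])
            total += len(contrasts)
            flagged += int(contrasts["significant"].sum())
        assert total == 90
        # nominal 5%; allow ~3 binomial standard errors of slack
        assert flagged / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_planted_iv_advantage_detected_on_exactly_eight(self):
        stimuli = [f"e{i}" for i in range(1, 12)]
        boosted = stimuli[:8]
        effects = ICSEffectConfig(
            route_multipliers={"iv": 1.0, "it": 1.0},
            stimulus_route_multipliers={s: {"iv": 3.0} for s in boosted},
            noise_cv=0.1,
            baseline_freq=1.0,
        )
        table = _ics_table(stimuli, n=8, effects=effects, seed=4)
        # family-adjusted alpha over the 11 stimuli
        _, contrasts = compare_routes(table, stimuli, alpha=0.005)
        iv_it = contrasts[contrasts[["route_a", "route_b"]].apply(set, axis=1) == {"it", "iv"}]
        significant = set(iv_it.loc[iv_it["significant"], "stimulus"])
        assert significant == set(boosted)

    def test_adjusted_p_values_match_independent_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for route, shift in (("iv", 0.0), ("it", 1.0), ("untreated", 0.5)):
            for i, value in enumerate(rng.normal(shift, 1.0, size=6)):
                rows.append(("m%d" % i, "spleen", route, "e1", value))
        table = pd.DataFrame(
            rows, columns=["mouse_id", "tissue", "route", "stimulus", "freq_ifng"]
        )
        _, contrasts = compare_routes(table, ["e1"])
        groups = {
            route: table.loc[table["route"] == route, "freq_ifng"].to_numpy()
            for route in ("it", "iv", "untreated")
        }
        oracle = stats.tukey_hsd(groups["it"], groups["iv"], groups["untreated"])
        keys = {("it", "iv"): (0, 1), ("it", "untreated") : (0, 2), ("iv", "untreated"): (1, 2)}
        for _, row in contrasts.iterrows():
            i, j = keys[(row["route_a"], row["route_b"])]
            assert row["p_adj"] == pytest.approx(oracle.pvalue[i, j], abs=1e-8)

    def test_missing_route_skipped_with_warning(self):
        table = _ics_table(["e1"], routes=("iv",))
        with pytest.warns(UserWarning, match="fewer than two routes"):
            _, contrasts = compare_routes(table, ["e1"])
        assert contrasts.empty


class TestComposition:
    def _table(self, means, nc=0.0):
        rows = [("m1", "spleen", "iv", "NC", nc), ("m2", "spleen", "iv", "NC", nc)]
        for stim, mean in means.items():
            rows.append(("m1", "spleen", "iv", stim, mean))
            rows.append(("m2", "spleen", "iv", stim, mean))
        return pd.DataFrame(
            rows, columns=["mouse_id", "tissue", "route", "stimulus", "freq_ifng"]
        )

    def test_normalisation(self):
        summary = epitope_composition(self._table({"A": 2.0, "B": 2.0, "C": 1.0}), ["A", "B", "C"])
        assert summary.proportions == pytest.approx({"A": 0.4, "B": 0.4, "C": 0.2})
        assert sum(summary.proportions.values()) == pytest.approx(1.0)

    def test_single_epitope(self):
        summary = epitope_composition(self._table({"A": 3.0}), ["A"])
        assert summary.proportions["A"] == pytest.approx(1.0)

    def test_background_clamped_before_normalising(self):
        summary = epitope_composition(
            self._table({"A": 0.5, "B": 3.0}, nc=1.0), ["A", "B"]
        )
        assert summary.means["A"] == 0.0
        assert summary.proportions["B"] == pytest.approx(1.0)

    def test_all_zero_signal_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            summary = epitope_composition(self._table({"A": 0.5}, nc=1.0), ["A"])
        assert not summary.defined


class TestGates:
    def _counts(self, mapping, total=1000):
        counts = {combo: 0 for combo in GATE_COMBINATIONS}
        used = 0
        for combo, n in mapping.items():
            counts[combo] = n
            used += n
        counts[(False, False, False)] += total - used
        return counts

    def test_hand_built_counts(self):
        # markers ordered (IFNg, TNFa, CD107a)
        counts = self._counts({(True, False, False): 50, (True, False, True): 25})
        summary = polyfunction_gates(counts, 1000)
        assert summary.frequency_of(IFNg=True) == pytest.approx(5.0)
        assert summary.frequency_of(IFNg=True, CD107a=True) == pytest.approx(2.5)
        assert sum(summary.frequencies.values()) == pytest.approx(100.0, abs=1e-9)

    def test_tnfa_negative_input_has_zero_triple_positive(self):
        counts = self._counts(
            {(True, False, False): 40, (False, False, True): 30, (True, False, True): 20}
        )
        summary = polyfunction_gates(counts)
        assert summary.triple_positive == 0.0
        assert summary.double_positive == pytest.approx(2.0)

    def test_all_null_combination(self):
        summary = polyfunction_gates(self._counts({}))
        assert summary.single_positive == 0.0
        assert summary.double_positive == 0.0
        assert summary.triple_positive == 0.0

    def test_counts_must_sum_to_total(self):
        counts = self._counts({(True, True, True): 10})
        with pytest.raises(ValueError, match="sum"):
            polyfunction_gates(counts, 999)

    def test_missing_combination_rejected(self):
        counts = {c: 1 for c in GATE_COMBINATIONS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            polyfunction_gates(counts)
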