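"""Design orchestration, Welch/ANOVA/Tukey statistics, delay invariance."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hfire_bench.experiment import (
    DesignSpec,
    delay_invariance_report,
    oneway_anova_tukey,
    ramp_memory_test,
    run_design,
    significance_markers,
    welch_t_test,
)
from hfire_bench.geometry import PlateGeometry
from hfire_bench.waveforms import BurstProtocol

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


class TestWelch:
    def test_identical_groups_t0_p1(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t_test(x, list(x))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        assert welch_t_test(x, y).statistic == pytest.approx(-welch_t_test(y, x).statistic)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 2, 13)  # unequal n and variance
        res = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_type_i_error_calibrated(self):
        """Null simulation: empirical alpha in [0.03, 0.07] at alpha=0.05."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1500
        for _ in range(n_sim):
            if welch_t_test(rng.normal(0, 1, 8), rng.normal(0, 1, 8)).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestAnovaTukey:
    def test_identical_groups_f0(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = oneway_anova_tukey([g, list(g), list(g)])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_pooled_t_squared(self):
        x, y = [1.0, 2.0, 3.5, 4.0], [2.0, 3.0, 4.5, 6.0]
        res = oneway_anova_tukey([x, y])
        t_pooled = sps.ttest_ind(x, y, equal_var=True).statistic
        assert res.statistic == pytest.approx(t_pooled**2, rel=1e-10)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 8), (0.8, 10), (0.3, 7)]]
        res = oneway_anova_tukey(groups)
        f_ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f_ref.statistic, abs=1e-8)
        assert res.p_value == pytest.approx(f_ref.pvalue, abs=1e-8)
        tukey_ref = sps.tukey_hsd(*groups)
        for _, row in res.pairwise.iterrows():
            i, j = int(row.group_a), int(row.group_b)
            assert row.p_adj == pytest.approx(tukey_ref.pvalue[i, j], abs=1e-8)

    def test_pairwise_table_covers_all_pairs(self):
        rng = np.random.default_rng(0)
        res = oneway_anova_tukey([rng.normal(0, 1, 5) for _ in range(4)])
        assert len(res.pairwise) == 6  # k(k-1)/2 for k=4

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_tukey([[1.0, 1.0], [2.0, 2.0]])

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 1500
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            if oneway_anova_tukey(groups).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestSignificanceMarkers:
    def test_thresholds(self):
        assert significance_markers(0.2) == "ns"
        assert significance_markers(0.03) == "*"
        assert significance_markers(0.004) == "**"
        assert significance_markers(5e-4) == "***"
        assert significance_markers(5e-5) == "****"


@pytest.fixture
def small_design(plate):
    """Scaled-down factorial: 2 pulse widths x 2 delays, 3 levels, n=4."""
    return DesignSpec(
        pulse_widths_us=(1.0, 10.0),
        delays_us=(1.0, 10.0),
        geometry=plate,
        levels=(100.0, 500.0, 2000.0),
        n_replicates=4,
        base_seed=17,
        sampling_period_ns=10.0,
        ontime_us=20.0,
    )


class TestRunDesign:
    def test_row_count_and_keys(self, small_design, potato):
        table = run_design(small_design, potato)
        assert len(table) == 2 * 2 * 4 * 3  # waveforms x replicates x levels
        keys = table[["waveform", "replicate", "level_v_per_cm"]]
        assert not keys.duplicated().any()

    def test_deterministic_given_base_seed(self, small_design, potato):
        a = run_design(small_design, potato)
        b = run_design(small_design, potato)
        pd.testing.assert_frame_equal(a, b)

    def test_plate_thickness_recorded_and_varies(self, small_design, potato):
        table = run_design(small_design, potato)
        assert "thickness_m" in table.columns
        per_rep = table.groupby(["waveform", "replicate"])["thickness_m"].first()
        assert per_rep.std() > 0
        assert np.allclose(per_rep.mean(), 0.006, atol=5e-4)


class TestDelayInvariance:
    def test_null_generator_cells_mostly_non_significant(self, plate, potato):
        design = DesignSpec(
            pulse_widths_us=(1.0,),
            delays_us=(1.0, 10.0, 100.0),
            geometry=plate,
            levels=(100.0, 2000.0),
            n_replicates=8,
            base_seed=23,
            sampling_period_ns=10.0,
            ontime_us=20.0,
        )
        cells, summary = delay_invariance_report(run_design(design, potato))
        assert summary["n_cells"] == 2
        assert summary["missing_cells"] == []
        # single realization: with alpha=0.05 both cells are overwhelmingly
        # likely to be null; the seeded outcome is deterministic
        assert summary["n_significant"] == 0

    def test_injected_delay_effect_detected(self, plate, potato):
        biased = replace(potato, delay_effect_frac_at_100us=0.10)
        design = DesignSpec(
            pulse_widths_us=(1.0,),
            delays_us=(1.0, 10.0, 100.0),
            geometry=plate,
            levels=(2000.0,),
            n_replicates=8,
            base_seed=23,
            sampling_period_ns=10.0,
            ontime_us=20.0,
        )
        cells, summary = delay_invariance_report(run_design(design, biased))
        assert summary["n_significant"] == 1

    def test_current_response_also_testable(self, plate, potato):
        design = DesignSpec(
            pulse_widths_us=(1.0,),
            delays_us=(1.0, 100.0),
            geometry=plate,
            levels=(100.0,),
            n_replicates=4,
            base_seed=5,
            sampling_period_ns=10.0,
            ontime_us=20.0,
        )
        cells, _ = delay_invariance_report(run_design(design, potato), response="I")
        assert {"F", "p", "significant"} <= set(cells.columns)

    def test_single_delay_group_reported_missing(self, plate, potato):
        design = DesignSpec(
            pulse_widths_us=(1.0,),
            delays_us=(10.0,),
            geometry=plate,
            levels=(100.0,),
            n_replicates=4,
            base_seed=5,
            sampling_period_ns=10.0,
            ontime_us=20.0,
        )
        cells, summary = delay_invariance_report(run_design(design, potato))
        assert summary["n_cells"] == 0
        assert summary["missing_cells"] == [(1.0, 100.0)]


class TestRampMemory:
    @pytest.fixture
    def protocol(self):
        return BurstProtocol.from_label("10-1-10-1", cycles=2, sampling_period_ns=10.0)

    def test_null_no_significant_difference(self, plate, potato, protocol):
        results = ramp_memory_test(
            target_levels=[1000.0, 2000.0],
            params=potato,
            geometry=plate,
            protocol=protocol,
            ramp_levels=[500.0, 1000.0, 1500.0, 2000.0],
            n=8,
            seed=31,
        )
        assert set(results) == {1000.0, 2000.0}
        assert all(r.p_value > 0.05 for r in results.values())

    def test_injected_memory_detected(self, plate, potato, protocol):
        results = ramp_memory_test(
            target_levels=[2000.0],
            params=potato,
            geometry=plate,
            protocol=protocol,
            ramp_levels=[500.0, 1000.0, 1500.0, 2000.0],
            n=8,
            seed=31,
            memory_frac=-0.2,
        )
        assert results[2000.0].p_value < 0.05
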