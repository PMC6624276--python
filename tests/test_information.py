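"""The information statistic: limiting cases, oracle agreement, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fateinfo import (
    SimulationConfig,
    bin_sensitivity,
    binary_entropy,
    covariate_information,
    information_trace,
    mi_at_time,
    mi_oracle,
    permutation_test,
    rank_and_bin,
    simulate_experiment,
)
from helpers import build_experiment, rank_order_experiment


class TestBinaryEntropy:
    def test_half_is_one_bit(self):
        assert binary_entropy(0.5) == 1.0

    def test_degenerate_is_zero(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0

    def test_quarter(self):
        assert binary_entropy(0.25) == pytest.approx(0.8112781244591328, abs=1e-15)

    def test_symmetry_and_bound(self):
        p = np.linspace(0, 1, 101)
        h = binary_entropy(p)
        np.testing.assert_allclose(h, h[::-1], atol=1e-12)
        assert np.all(h <= 1.0)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            binary_entropy(bad)


class TestMiAtTime:
    def _equal_bins(self, n_bins, per_bin):
        return np.repeat(np.arange(n_bins), per_bin)

    def test_half_dead_by_bin_is_one_bit(self):
        """Five bins fully dead, five fully alive: the theoretical maximum."""
        bins = self._equal_bins(10, 10)
        states = bins < 5
        assert mi_at_time(states, bins) == 1.0

    def test_all_alive_and_all_dead_are_zero(self):
        bins = self._equal_bins(10, 10)
        assert mi_at_time(np.zeros(100, bool), bins) == 0.0
        assert mi_at_time(np.ones(100, bool), bins) == 0.0

    def test_uniform_death_is_exactly_zero(self):
        """Every bin 30% dead: fate unrelated to the covariate."""
        states = np.tile(np.arange(10) < 3, 10)
        bins = self._equal_bins(10, 10)
        assert mi_at_time(states, bins) == 0.0

    def test_hand_computed_mixed_case(self):
        """Dead counts (10,10,10,10,10,5,0,0,0,0) -> H(0.55) - 0.1*H(0.5)."""
        counts = [10] * 5 + [5] + [0] * 4
        bins = self._equal_bins(10, 10)
        states = np.concatenate([np.arange(10) < c for c in counts])
        expected = 0.8927744539878083
        assert mi_at_time(states, bins) == pytest.approx(expected, abs=1e-12)
        assert mi_oracle(states, bins) == pytest.approx(expected, abs=1e-12)

    def test_upper_bounds(self):
        rng = np.random.default_rng(0)
        bins = self._equal_bins(10, 10)
        for _ in range(50):
            states = rng.random(100) < rng.random()
            mi = mi_at_time(states, bins)
            assert mi <= binary_entropy(states.mean()) + 1e-12
            assert mi <= 1.0 + 1e-12

    @given(
        n_bins=st.integers(2, 10),
        per_bin=st.integers(2, 20),
        seed=st.integers(0, 2**16),
    )
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_oracle_equivalence_for_equal_bins(self, n_bins, per_bin, seed):
        """The averaged-entropy form is the plug-in MI when bins are equal."""
        rng = np.random.default_rng(seed)
        bins = self._equal_bins(n_bins, per_bin)
        states = rng.random(n_bins * per_bin) < rng.random()
        assert mi_at_time(states, bins) == pytest.approx(
            mi_oracle(states, bins), abs=1e-12
        )
        assert mi_at_time(states, bins) >= -1e-12

    @given(seed=st.integers(0, 2**16))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_alive_dead_relabeling_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        bins = self._equal_bins(5, 8)
        states = rng.random(40) < 0.4
        assert mi_at_time(states, bins) == pytest.approx(
            mi_at_time(~states, bins), abs=1e-12
        )

    def test_unequal_bins_documented_divergence(self):
        """With unequal bins the 1/n average is not the plug-in MI."""
        bins = np.array([0] * 30 + [1] * 10)
        states = np.array([True] * 15 + [False] * 25)
        assert mi_at_time(states, bins) != pytest.approx(
            mi_oracle(states, bins), abs=1e-6
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(Exception, match="length"):
            mi_at_time(np.zeros(5, bool), np.zeros(4, int))


class TestInformationTrace:
    def test_rank_order_death_peaks_at_one_bit_at_half_death(self):
        """Proportional death: parabolic arc peaking at 1.0 bit."""
        exp = rank_order_experiment(100)
        trace = information_trace(exp, rank_and_bin(exp, n_bins=10))
        assert trace.peak_bits == 1.0
        assert trace.peak_time == 250.0  # frame where 50 of 100 cells are dead
        # rise and fall through the decile-complete frames
        decile_frames = np.searchsorted(exp.time_grid, 50.0 * np.arange(1, 10))
        arc = trace.info_bits[decile_frames]
        assert np.all(np.diff(arc[:5]) > 0)
        assert np.all(np.diff(arc[4:]) < 0)
        assert trace.info_bits[0] == 0.0
        assert trace.info_bits[-1] == 0.0

    def test_trace_bounded_and_nonnegative(self, strong_experiment):
        trace = information_trace(
            strong_experiment, rank_and_bin(strong_experiment, n_bins=10)
        )
        assert np.all(trace.info_bits >= 0)
        assert np.all(trace.info_bits <= 1.0)
        assert trace.peak_bits == trace.info_bits.max()

    def test_null_link_peak_below_permutation_null(self, null_experiment):
        result = permutation_test(null_experiment, seed=17)
        assert not result.exceeds_null

    def test_peak_tie_reports_earliest_frame(self):
        """Alternating-bin deaths give a symmetric trace; tie goes to the earlier frame."""
        exp = build_experiment([5.0, 10.0, 15.0, 20.0])
        bins = rank_and_bin(exp, n_bins=2)
        from fateinfo import BinAssignment

        alternating = BinAssignment(
            2, {"c0000": 0, "c0001": 1, "c0002": 0, "c0003": 1}, "custom"
        )
        trace = information_trace(exp, alternating)
        assert trace.info_bits[1] == pytest.approx(trace.info_bits[3], abs=1e-12)
        assert trace.peak_time == 5.0

    def test_trace_depends_only_on_bin_membership(self, strong_experiment):
        """Monotone transform of fluorescence leaves the trace unchanged."""
        from dataclasses import replace

        transformed = type(strong_experiment).from_records(
            [
                replace(c, initial_fluorescence=np.log(c.initial_fluorescence))
                for c in strong_experiment.cells
            ],
            strong_experiment.time_grid,
        )
        a = information_trace(strong_experiment, rank_and_bin(strong_experiment))
        b = information_trace(transformed, rank_and_bin(transformed))
        np.testing.assert_array_equal(a.info_bits, b.info_bits)

    def test_signal_recovery_over_seeds(self):
        """Strong-link peaks all exceed the null's 95th percentile over 20 seeds."""
        strong_peaks, null_peaks, null_q95s = [], [], []
        for s in range(20):
            strong = simulate_experiment(SimulationConfig(seed=300 + s))
            null = simulate_experiment(
                SimulationConfig(link_shape="none", seed=300 + s)
            )
            strong_peaks.append(
                information_trace(strong, rank_and_bin(strong)).peak_bits
            )
            null_peaks.append(information_trace(null, rank_and_bin(null)).peak_bits)
            null_q95s.append(
                permutation_test(null, n_permutations=50, seed=400 + s).null_q95
            )
        assert np.mean(strong_peaks) > np.mean(null_peaks)
        assert all(p > q for p, q in zip(strong_peaks, null_q95s))


class TestCovariateInformation:
    def test_fluorescence_covariate_matches_direct_trace(self, strong_experiment):
        direct = information_trace(
            strong_experiment, rank_and_bin(strong_experiment, n_bins=10)
        )
        via = covariate_information(strong_experiment, "initial_fluorescence", 10)
        np.testing.assert_array_equal(direct.info_bits, via.info_bits)

    def test_growth_rate_predicts_fate_when_coupled(self):
        cfg = SimulationConfig(link_shape="none", growth_death_coupling=120.0, seed=11)
        exp = simulate_experiment(cfg)
        result = permutation_test(exp, covariate="growth_rate", seed=23)
        assert result.exceeds_null

    def test_uncoupled_size_stays_within_null(self):
        cfg = SimulationConfig(seed=11)  # size_death_coupling = 0
        exp = simulate_experiment(cfg)
        result = permutation_test(exp, covariate="initial_size", seed=23)
        assert not result.exceeds_null


class TestBinSensitivity:
    def test_strong_exceeds_null_at_every_bin_count(
        self, strong_experiment, null_experiment
    ):
        strong = bin_sensitivity(strong_experiment, [5, 10, 20])
        null = bin_sensitivity(null_experiment, [5, 10, 20])
        for k in (5, 10, 20):
            assert strong[k] > null[k]

    def test_single_bin_carries_no_information(self, strong_experiment):
        trace = covariate_information(strong_experiment, "initial_fluorescence", 1)
        assert np.all(trace.info_bits == 0.0)

    def test_one_cell_per_bin_noise_free_peak_is_one_bit(self):
        exp = rank_order_experiment(100)
        peaks = bin_sensitivity(exp, [100])
        assert peaks[100] == 1.0
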