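import numpy as np
import pytest

from ltccmicro import patch
from ltccmicro.markov import two_state_for_po, two_state_spec
from ltccmicro.protocols import iv_step_potentials
from ltccmicro.synth import SweepGenConfig, gen_iv_dataset, gen_sweep_set


# ---------------------------------------------------------------------------
# Idealization
# ---------------------------------------------------------------------------

class TestIdealization:
    fs = 10_000.0

    def test_flat_noisy_baseline_idealizes_to_zero(self):
        rng = np.random.default_rng(0)
        sweep = rng.normal(0.0, 0.12, size=11_500)  # SD = amplitude/10
        path = patch.idealize_sweep(sweep, -1.2, self.fs)
        assert np.all(path == 0)

    def test_noiseless_sweeps_recover_truth_exactly(self):
        cfg = SweepGenConfig(n_sweeps=10, gating=two_state_spec(0.2, 0.6),
                             noise_sd=0.0, seed=1)
        ss = gen_sweep_set(cfg)
        ideal, excluded = patch.idealize_sweep_set(ss, min_event_ms=0.0)
        assert excluded == []
        np.testing.assert_array_equal(ideal, ss.truth_state)

    def test_recovery_at_snr_six(self):
        """Per-sweep open fractions recovered within 0.02 at SNR 6."""
        cfg = SweepGenConfig(n_sweeps=30, gating=two_state_for_po(0.10),
                             noise_sd=0.2, seed=2)  # 1.2 pA / 0.2 pA = SNR 6
        ss = gen_sweep_set(cfg)
        ideal, _ = patch.idealize_sweep_set(ss)
        a, b = ss.step_window()
        est = ideal[:, a:b].mean(axis=1)
        truth = ss.true_sweep_open_fractions()
        assert np.abs(est - truth).max() <= 0.02

    def test_baseline_drift_rejected(self):
        drift = np.linspace(0.0, 1.5, 11_500)  # > unitary amplitude of drift
        with pytest.raises(ValueError, match="drift"):
            patch.idealize_sweep(drift, -1.2, self.fs)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            patch.idealize_sweep(np.zeros(100), 0.0, self.fs)


class TestChannelCounting:
    def test_single_level_means_one_channel(self):
        ideal = np.zeros((5, 100), dtype=int)
        ideal[2, 40:60] = 1
        assert patch.count_channel_levels(ideal) == 1

    def test_empty_recording_counts_zero(self):
        assert patch.count_channel_levels(np.zeros((5, 100), dtype=int)) == 0
        assert patch.count_channel_levels(np.empty((0, 0), dtype=int)) == 0

    def test_counter_is_lower_bound_and_exact_for_long_records(self):
        """Max simultaneous level never exceeds the true channel count and
        reaches it given enough recording."""
        short = gen_sweep_set(SweepGenConfig(
            n_sweeps=2, n_channels=3, gating=two_state_spec(0.05, 0.95),
            noise_sd=0.0, seed=3))
        long = gen_sweep_set(SweepGenConfig(
            n_sweeps=150, n_channels=3, gating=two_state_spec(0.3, 0.7),
            noise_sd=0.0, seed=3))
        assert patch.count_channel_levels(short.truth_state) <= 3
        assert patch.count_channel_levels(long.truth_state) == 3


class TestOpenProbability:
    def test_all_closed_gives_zero(self):
        ideal = np.zeros((20, 1000), dtype=int)
        assert patch.estimate_open_probability(ideal, 1, (0, 1000)) == 0.0

    def test_always_open_gives_one(self):
        ideal = np.ones((20, 1000), dtype=int)
        assert patch.estimate_open_probability(ideal, 1, (0, 1000)) == 1.0

    def test_protocol_floor_of_twenty_sweeps(self):
        ideal = np.zeros((19, 1000), dtype=int)
        with pytest.raises(ValueError, match="20"):
            patch.estimate_open_probability(ideal, 1, (0, 1000))

    def test_npo_divided_by_channel_count(self):
        ideal = np.ones((20, 1000), dtype=int) * 2  # two channels always open
        assert patch.estimate_open_probability(ideal, 2, (0, 1000)) == 1.0

    def test_parameter_recovery_control_po(self):
        """A 50-sweep synthetic seal at the control TT Po (0.057) is
        recovered within Monte-Carlo error."""
        cfg = SweepGenConfig(n_sweeps=50, gating=two_state_for_po(0.057),
                             noise_sd=0.15, seed=4)
        ss = gen_sweep_set(cfg)
        ideal, _ = patch.idealize_sweep_set(ss)
        po = patch.estimate_open_probability(ideal, 1, ss.step_window(), ss.sampling_rate)
        assert po == pytest.approx(ss.true_po(), abs=0.006)


class TestSealArea:
    def test_mean_resistance_maps_to_tabulated_mean_area(self):
        """27.78 MΩ (the mean pipette resistance) gives the grand-mean
        area per seal, 43.56 µm² / 304 seals = 0.1433 µm²."""
        assert patch.seal_area_from_resistance(27.78) == pytest.approx(0.1433, abs=0.001)

    def test_inverse_square_law(self):
        a1 = patch.seal_area_from_resistance(10.0)
        assert patch.seal_area_from_resistance(20.0) == pytest.approx(a1 / 4)

    def test_vanishes_at_large_resistance(self):
        assert patch.seal_area_from_resistance(1e6) < 1e-9

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            patch.seal_area_from_resistance(0.0)


class TestConductanceFit:
    def test_noiseless_line_recovered_exactly(self):
        iv = gen_iv_dataset(20.0, 60.0, iv_step_potentials(), noise_sd=0.0)
        fit = patch.fit_unitary_conductance(iv)
        assert fit.slope == pytest.approx(20.0, abs=1e-9)
        assert fit.reversal_estimate == pytest.approx(60.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_bayk_conductance(self):
        """24.94 pS recovered within ±0.4 from noisy protocol I-V data."""
        iv = gen_iv_dataset(24.94, 60.0, iv_step_potentials(),
                            noise_sd=0.05, n_repeats=50, seed=5)
        fit = patch.fit_unitary_conductance(iv)
        assert fit.slope == pytest.approx(24.94, abs=0.4)

    def test_point_order_invariance(self):
        iv = gen_iv_dataset(18.0, 55.0, iv_step_potentials(), noise_sd=0.1, seed=6)
        perm = np.random.default_rng(0).permutation(iv.voltages.size)
        shuffled = type(iv)(voltages=iv.voltages[perm], amplitudes=iv.amplitudes[perm])
        a = patch.fit_unitary_conductance(iv)
        b = patch.fit_unitary_conductance(shuffled)
        assert a.slope == pytest.approx(b.slope)

    def test_too_few_points_rejected(self):
        iv = gen_iv_dataset(20.0, 60.0, [-36.7, -6.7], noise_sd=0.0)
        with pytest.raises(ValueError):
            patch.fit_unitary_conductance(iv)


# ---------------------------------------------------------------------------
# Aggregation against the recordings table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def table1():
    return {(s.group, s.microdomain): s for s in patch.table1_from_counts()}


class TestGroupSummaries:
    def test_control_tt_row(self, table1):
        s = table1[("Control", "TT")]
        row = s.as_row()
        assert row["occurrence_pct"] == 25.8
        assert row["density_per_um2"] == 3.94
        assert row["mean_channels_per_active_seal"] == 1.63

    def test_icm_crest_row(self, table1):
        s = table1[("ICM", "Crest")]
        assert s.occurrence == pytest.approx(25.0)
        assert round(s.density, 1) == 2.7
        assert s.mean_channels_per_active_seal == pytest.approx(1.8)

    def test_inactive_stratum(self):
        rec = patch.SealRecord("s1", "Control", "TT", 27.78)
        s = patch.summarize_group([rec], "Control", "TT")
        assert s.occurrence == 0.0
        assert s.density == 0.0
        assert s.mean_channels_per_active_seal is None

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            patch.summarize_group([], "Control", "TT")

    def test_every_table_row_occurrence_consistent(self, table1):
        """Computed occurrences match the printed percentages (half-up to
        one decimal) except the two known truncated rows."""
        truncated = {("DCM+LVAD", "TT"), ("BayK", "TT")}
        counts = patch.load_table1_counts()
        for _, row in counts.iterrows():
            s = table1[(row["group"], row["microdomain"])]
            printed = float(row["printed_occurrence_pct"])
            diff = abs(s.as_row()["occurrence_pct"] - printed)
            if (row["group"], row["microdomain"]) in truncated:
                assert diff <= 0.101
            else:
                assert diff < 0.051


class TestPooling:
    def test_failing_crest_pool_matches_reported_statistics(self):
        pool = patch.failing_crest_pool()
        assert round(pool.occurrence, 1) == 28.7
        assert round(pool.density, 2) == 2.36
        assert round(pool.mean_channels_per_active_seal, 2) == 1.45

    def test_pooling_idempotent_on_ratios(self, table1):
        s = table1[("DCM", "Crest")]
        pooled = patch.pool_groups([s])
        assert pooled.occurrence == s.occurrence
        assert pooled.density == s.density

    def test_pooling_order_invariant_and_associative(self, table1):
        rows = [table1[(g, "Crest")] for g in ("ICM", "ICM+LVAD", "DCM", "DCM+LVAD")]
        a = patch.pool_groups(rows)
        b = patch.pool_groups(list(reversed(rows)))
        c = patch.pool_groups([patch.pool_groups(rows[:2]), patch.pool_groups(rows[2:])],
                              label="pooled")
        assert a.density == pytest.approx(b.density) == pytest.approx(c.density)
        assert a.occurrence == pytest.approx(b.occurrence) == pytest.approx(c.occurrence)

    def test_mixed_microdomains_need_override(self, table1):
        rows = [table1[("ICM", "TT")], table1[("ICM", "Crest")]]
        with pytest.raises(ValueError):
            patch.pool_groups(rows)
        pooled = patch.pool_groups(rows, allow_mixed_microdomains=True)
        assert pooled.microdomain == "mixed"

    def test_pooled_ratios_from_summed_counts_not_mean_of_ratios(self, table1):
        rows = [table1[(g, "Crest")] for g in ("ICM", "ICM+LVAD", "DCM", "DCM+LVAD")]
        pooled = patch.pool_groups(rows)
        mean_of_ratios = np.mean([r.density for r in rows])
        assert pooled.density != pytest.approx(mean_of_ratios, abs=1e-3)


class TestEndToEndSeal:
    def test_analyze_seal_pipeline(self):
        cfg = SweepGenConfig(n_sweeps=25, gating=two_state_for_po(0.1),
                             noise_sd=0.15, seed=7)
        ss = gen_sweep_set(cfg)
        rec = patch.analyze_seal(ss, "seal1", "ICM", "TT", 27.78)
        assert rec.has_activity
        assert rec.n_channels == 1
        assert rec.po == pytest.approx(ss.true_po(), abs=0.02)
        assert rec.area == pytest.approx(patch.seal_area_from_resistance(27.78))

    def test_reported_stats_fixture_loads(self):
        df = patch.load_reported_group_stats()
        po_icm = df[(df.quantity == "po") & (df.group == "ICM")].value.iloc[0]
        assert po_icm == 0.102
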