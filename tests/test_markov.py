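import numpy as np
import pytest

from ltccmicro import markov as mk


@pytest.fixture(scope="module")
def ltcc_unphos():
    return mk.anchored_ltcc_spec()


@pytest.fixture(scope="module")
def ltcc_pka():
    return mk.anchored_ltcc_spec(phospho=mk.pka_variant())


class TestStateSpace:
    def test_base_model_has_32_states(self, ltcc_unphos):
        assert len(ltcc_unphos.gates) == 5
        assert ltcc_unphos.n_states == 32

    def test_pka_expansion_has_64_states(self, ltcc_pka):
        assert ltcc_pka.n_states == 64

    def test_single_gate_stationary_closed_form(self):
        spec = mk.two_state_spec(0.1, 0.9)
        assert mk.stationary_po(spec, 0.0, 1.0) == pytest.approx(0.1)

    def test_exactly_one_conducting_state_per_half(self, ltcc_pka):
        Q, conducting = mk.generator_matrix(ltcc_pka, -6.7, 1.0)
        assert conducting.sum() == 2  # all-permissive state in each phospho half

    def test_generator_rows_sum_to_zero(self, ltcc_pka):
        Q, _ = mk.generator_matrix(ltcc_pka, -6.7, 1.0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_transitions_only_between_single_gate_neighbours(self, ltcc_unphos):
        Q, _ = mk.generator_matrix(ltcc_unphos, -6.7, 1.0)
        n = Q.shape[0]
        for i in range(n):
            for j in range(n):
                if i != j and Q[i, j] != 0.0:
                    assert bin(i ^ j).count("1") == 1


class TestDeterministicCompanion:
    def test_occupancy_stays_normalized(self, ltcc_unphos):
        _, occ = mk.occupancy_ode(ltcc_unphos, -6.7, 1.0, duration_ms=200.0)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-8)

    def test_occupancy_converges_to_gate_product(self, ltcc_unphos):
        # the slow VDI gate relaxes over ~13 s at −6.7 mV: integrate well past it
        _, occ = mk.occupancy_ode(ltcc_unphos, -6.7, 1.0, duration_ms=200_000.0)
        _, conducting = mk.generator_matrix(ltcc_unphos, -6.7, 1.0)
        po_ode = occ[-1][conducting].sum()
        assert po_ode == pytest.approx(mk.stationary_po(ltcc_unphos, -6.7, 1.0), rel=1e-4)


class TestEnsembleSimulation:
    def test_zero_conducting_rate_gives_zero_po(self):
        spec = mk.two_state_spec(0.0, 0.9)
        res = mk.simulate_channel_ensemble(spec, -6.7, 1.0, 200, 1.0, seed=1)
        assert res.po_estimate == 0.0
        assert res.warnings == []

    def test_two_state_po_within_three_se(self):
        spec = mk.two_state_spec(0.1, 0.9)
        res = mk.simulate_channel_ensemble(spec, -6.7, 1.0, 1000, 1.0, seed=2)
        assert abs(res.po_estimate - 0.1) <= max(3 * res.po_se, 0.003)

    @pytest.mark.parametrize("voltage", [-20.0, -6.7, 0.0, 10.0])
    def test_markov_hh_equivalence(self, ltcc_unphos, voltage):
        """Ensemble open fraction agrees with the deterministic product of
        gate open probabilities (Hodgkin-Huxley equivalence)."""
        res = mk.simulate_channel_ensemble(ltcc_unphos, voltage, 1.0, 1000, 2.0, seed=3)
        oracle = mk.stationary_po(ltcc_unphos, voltage, 1.0)
        assert abs(res.po_estimate - oracle) <= max(3 * res.po_se, 0.004)

    def test_phospho_doubling_with_identity_kinetics_is_neutral(self):
        """64 states with identity modifiers and current factor 1 leave the
        ensemble Po unchanged (symmetry)."""
        base = mk.anchored_ltcc_spec()
        neutral = mk.anchored_ltcc_spec(
            phospho=mk.PhosphoVariant(kind="PKA", current_factor=1.0, kinetic_modifiers={})
        )
        kw = dict(voltage=-6.7, ca=1.0, n_channels=500, duration=1.0, seed=4)
        a = mk.simulate_channel_ensemble(base, **kw)
        b = mk.simulate_channel_ensemble(neutral, phosphorylated=True, **kw)
        assert a.po_estimate == pytest.approx(b.po_estimate, abs=1e-12)

    def test_reproducible_under_seed(self, ltcc_unphos):
        kw = dict(voltage=-6.7, ca=1.0, n_channels=100, duration=1.0, seed=5)
        a = mk.simulate_channel_ensemble(ltcc_unphos, **kw)
        b = mk.simulate_channel_ensemble(ltcc_unphos, **kw)
        np.testing.assert_array_equal(a.per_channel_open_fraction, b.per_channel_open_fraction)

    def test_frozen_gate_warns(self):
        spec = mk.two_state_spec(0.0, 0.0)
        res = mk.simulate_channel_ensemble(spec, -6.7, 1.0, 10, 1.0, seed=6)
        assert res.warnings


class TestCalibration:
    def test_boundary_targets(self, ltcc_unphos, ltcc_pka):
        po_u = mk.stationary_po(ltcc_unphos, -6.7, 1.0)
        po_p = mk.stationary_po(ltcc_pka, -6.7, 1.0, phosphorylated=True)
        f0, _ = mk.calibrate_phospho_fraction(ltcc_unphos, ltcc_pka, po_u,
                                              n_channels=300, seed=7, duration=5.0, tol=5e-3)
        f1, _ = mk.calibrate_phospho_fraction(ltcc_unphos, ltcc_pka, po_p,
                                              n_channels=300, seed=7, duration=5.0, tol=5e-3)
        assert f0 <= 0.1
        assert f1 >= 0.9

    def test_out_of_range_targets_clamp_with_flag(self, ltcc_unphos, ltcc_pka):
        f_lo, flag_lo = mk.calibrate_phospho_fraction(
            ltcc_unphos, ltcc_pka, 0.001, n_channels=200, seed=8, duration=5.0)
        f_hi, flag_hi = mk.calibrate_phospho_fraction(
            ltcc_unphos, ltcc_pka, 0.5, n_channels=200, seed=8, duration=5.0)
        assert (f_lo, flag_lo) == (0.0, "below_range")
        assert (f_hi, flag_hi) == (1.0, "above_range")

    def test_monotone_in_target(self, ltcc_unphos, ltcc_pka):
        targets = [0.065, 0.08, 0.095, 0.11, 0.12]
        fs = [
            mk.calibrate_phospho_fraction(ltcc_unphos, ltcc_pka, tp,
                                          n_channels=500, seed=9, duration=5.0)[0]
            for tp in targets
        ]
        assert all(b >= a for a, b in zip(fs, fs[1:]))

    def test_invalid_tolerance(self, ltcc_unphos, ltcc_pka):
        with pytest.raises(ValueError):
            mk.calibrate_phospho_fraction(ltcc_unphos, ltcc_pka, 0.1, tol=0.0)


class TestUnitaryCurrent:
    def test_zero_at_reversal(self, ltcc_unphos):
        assert mk.unitary_current(ltcc_unphos, ltcc_unphos.reversal) == 0.0

    def test_ohmic_value(self):
        spec = mk.two_state_spec(0.1, 0.9, unitary_conductance=20.0, reversal=60.0)
        assert mk.unitary_current(spec, -6.7) == pytest.approx(-1.334)

    def test_pka_multiplies_by_current_factor(self):
        base = mk.anchored_ltcc_spec(unitary_conductance=20.0)
        pka = mk.anchored_ltcc_spec(phospho=mk.pka_variant(), unitary_conductance=20.0)
        for v in (-30.0, -6.7, 0.0, 20.0):
            assert mk.unitary_current(pka, v) == pytest.approx(2.5 * mk.unitary_current(base, v))


class TestSerialization:
    def test_json_roundtrip(self, ltcc_pka):
        back = mk.MarkovSpec.from_json(ltcc_pka.to_json())
        assert back == ltcc_pka

    def test_anchoring_hits_measured_control_po(self):
        spec = mk.anchored_ltcc_spec(po_anchor=0.057)
        assert mk.stationary_po(spec, -6.7, mk.CA_TT_UM) == pytest.approx(0.057, abs=1e-9)
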