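import numpy as np
import pytest

from ltccmicro import myocyte as myo
from ltccmicro import ord_model as om


class TestConstructionEquations:
    def test_ttd_is_arithmetic_mean(self):
        assert myo.compute_ttd(1.0, 1.0) == 1.0
        assert myo.compute_ttd(0.0, 0.0) == 0.0
        assert myo.compute_ttd(0.637, 0.663) == pytest.approx(0.65)
        assert myo.compute_ttd(0.4, 0.8) == pytest.approx(0.6)

    def test_ttd_rejects_negative_ratios(self):
        with pytest.raises(ValueError):
            myo.compute_ttd(-0.1, 0.5)

    def test_icm_occurrence_ratio(self):
        """ICM TT/crest occurrences 20%/25% give channel ratio 0.8 and a
        TT fraction of ~0.45."""
        ratio, f_tt = myo.domain_fraction_from_occurrence(20.0, 25.0)
        assert ratio == pytest.approx(0.8)
        assert f_tt == pytest.approx(0.8 / 1.8)
        assert f_tt == pytest.approx(0.45, abs=0.01)

    def test_equal_occurrences_split_evenly(self):
        ratio, f_tt = myo.domain_fraction_from_occurrence(10.0, 10.0)
        assert ratio == 1.0
        assert f_tt == 0.5

    def test_zero_crest_occurrence_rejected(self):
        with pytest.raises(ValueError):
            myo.domain_fraction_from_occurrence(20.0, 0.0)


class TestVariantBuilders:
    def test_control_definition(self):
        c = myo.build_cell_variant("control")
        assert c.ttd == 1.0
        assert c.pka_fraction == 0.0
        assert c.camkii_crest == 0.0
        assert c.hf_remodeling == myo.HFRemodeling.none()

    def test_icm_parameters(self):
        c = myo.build_cell_variant("ICM")
        assert (c.ttd, round(c.f_tt, 2), c.pka_fraction) == (0.65, 0.44, 0.7)

    def test_dcm_parameters(self):
        c = myo.build_cell_variant("DCM")
        assert c.camkii_crest == 1.0
        assert c.f_tt == pytest.approx(0.451, abs=0.001)

    def test_pka_block_neutralizes_phospho_current_factor(self):
        c = myo.build_cell_variant("ICM", pka_block=True)
        assert c.pka_fraction == 0.7  # structure unchanged
        p = c.to_vector()
        assert p[om.P.PKA_CURRENT_FACTOR] == 1.0
        assert p[om.P.PKA_ACT_SHIFT] == 0.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            myo.build_cell_variant("HCM")

    def test_inconsistent_f_tt_rejected(self):
        with pytest.raises(ValueError):
            myo.CellParams(variant="control", f_tt=0.9, ratio_tt_crest=1.0)


class TestVoltageClamp:
    def test_component_conservation(self, clamp_results):
        """Total I_CaL is the sum of TT and crest components everywhere."""
        r = clamp_results["ICM"]
        np.testing.assert_allclose(r.i_cal_total, r.i_cal_tt + r.i_cal_crest, atol=1e-9)

    def test_correction_factor_is_identity_for_control(self, control_variant):
        out = myo.compute_current_correction(control_variant, control_variant)
        assert out.correction_factor == pytest.approx(1.0, abs=0.01)

    def test_corrected_peaks_match_control_within_one_percent(self, clamp_results):
        ref = clamp_results["control"].peak()
        for key in ("ICM", "DCM"):
            assert clamp_results[key].peak() / ref == pytest.approx(1.0, abs=0.011)

    def test_decay_ordering_control_icm_dcm(self, clamp_results):
        """Whole-cell current decay: control fastest, DCM slowest."""
        d = {k: clamp_results[k].decay_metric() for k in ("control", "ICM", "DCM")}
        assert d["control"] < d["ICM"] < d["DCM"]

    def test_tt_component_decay_similar_across_variants(self, clamp_results):
        ref = clamp_results["control"].decay_metric("tt")
        for key in ("ICM", "DCM"):
            assert clamp_results[key].decay_metric("tt") == pytest.approx(ref, rel=0.15)

    def test_crest_decays_slower_than_tt_in_every_variant(self, clamp_results):
        for key in ("control", "ICM", "DCM"):
            r = clamp_results[key]
            assert r.decay_metric("crest") > r.decay_metric("tt")

    def test_short_step_rejected(self, control_variant):
        with pytest.raises(ValueError):
            myo.run_voltage_clamp(control_variant, step_ms=200.0)

    def test_deterministic(self, control_variant):
        a = myo.run_voltage_clamp(control_variant)
        b = myo.run_voltage_clamp(control_variant)
        np.testing.assert_array_equal(a.i_cal_total, b.i_cal_total)


class TestControlRecovery:
    def test_disease_builder_with_healthy_knobs_recovers_control(self, control_variant):
        """Setting ttd = 1, the control TT fraction and no phosphorylation
        inside the ICM builder reproduces the control clamp trace."""
        ctrl_ratio, ctrl_f = myo.domain_fraction_from_occurrence(*myo.CONTROL_OCCURRENCE)
        pseudo = myo.CellParams(
            variant="ICM", ttd=1.0, f_tt=ctrl_f, ratio_tt_crest=ctrl_ratio,
            pka_fraction=0.0, camkii_crest=0.0,
            hf_remodeling=myo.HFRemodeling.none(),
        )
        a = myo.run_voltage_clamp(control_variant)
        b = myo.run_voltage_clamp(pseudo)
        np.testing.assert_allclose(a.i_cal_total, b.i_cal_total, atol=1e-12)


class TestAPDMeasurement:
    def _square_pulse(self, width_ms=200.0):
        t = np.arange(0.0, 500.0, 0.5)
        v = np.full_like(t, -85.0)
        v[(t >= 10.0) & (t < 10.0 + width_ms)] = 20.0
        return t, v

    def test_square_pulse_apd_equals_width(self):
        t, v = self._square_pulse(200.0)
        apd = myo.measure_apd(t, v, (0.0, 500.0))
        assert apd == pytest.approx(200.0, abs=2.0)

    def test_apd_monotone_in_level(self):
        t, v = self._square_pulse(150.0)
        v = v - np.linspace(0, 20, v.size)  # slight ramp for distinct crossings
        apd90 = myo.measure_apd(t, v, (0.0, 500.0), level=90.0)
        apd100 = myo.measure_apd(t, v, (0.0, 500.0), level=100.0)
        assert apd100 >= apd90

    def test_non_repolarizing_beat_flagged(self):
        t = np.arange(0.0, 300.0, 0.5)
        v = np.where(t < 10.0, -85.0, 10.0)  # never repolarizes
        assert np.isnan(myo.measure_apd(t, v, (0.0, 300.0)))


class TestEADDetection:
    def _ap(self, bump=False):
        t = np.arange(0.0, 600.0, 0.5)
        v = -85.0 + 120.0 * np.exp(-t / 150.0)
        v[t < 2.0] = -85.0 + 60.0 * t[t < 2.0]  # upstroke
        if bump:
            # plateau bump, steep enough to outpace the decay, above −40 mV
            sel = (t > 60.0) & (t < 100.0)
            v[sel] += 15.0 * np.sin(np.pi * (t[sel] - 60.0) / 40.0)
        return t, v

    def test_monotone_repolarization_has_no_events(self):
        t, v = self._ap(bump=False)
        assert myo.detect_eads(t, v, np.array([0.0])) == []

    def test_injected_plateau_bump_is_one_event(self):
        t, v = self._ap(bump=True)
        events = myo.detect_eads(t, v, np.array([0.0]))
        assert len(events) == 1
        assert events[0].amplitude >= 2.0

    def test_ikr_block_positive_control(self):
        """Deep rapid-delayed-rectifier block at slow (0.25 Hz) pacing is
        the classical EAD positive control."""
        c = myo.CellParams(
            variant="control",
            hf_remodeling=myo.HFRemodeling(
                serca=1.0, ncx=1.0, gk1=1.0, gto=1.0, gnal=1.0, gks=1.0, jrel=1.0,
                gkr=0.1,
            ),
        )
        from ltccmicro.protocols import PacingProtocol

        res = myo.run_pacing(
            c,
            pacing=PacingProtocol(n_initial_beats=2, n_skipped_beats=0,
                                  n_resumed_beats=1, cycle_length=4000.0),
            prepace_beats=10,
        )
        assert res.n_eads >= 1
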