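import numpy as np
import pandas as pd
import pytest

from circaretina.classification import classify_session, responsiveness_test
from circaretina.rhythms import cosinor_fit
from circaretina.erg import a_wave_amplitude, b_wave_amplitude, average_replicates
from circaretina.spikes import mean_rate
from circaretina.synthetic import (
    DEFAULT_MODELS,
    EffectTable,
    RgcKineticModel,
    contrast_response,
    default_cohort,
    expression_to_ct,
    simulate_erg,
    simulate_expression,
    simulate_session,
    simulate_unit,
    study_effects,
)
from circaretina.rhythms import delta_delta_ct


class TestSpikes:
    def test_same_seed_identical_sessions(self, ct100_protocol):
        counts = {"ON_sust": 3, "OFF_trans": 3, "ONOFF": 3}
        a, _ = simulate_session(counts=counts, protocol=ct100_protocol, seed=9)
        b, _ = simulate_session(counts=counts, protocol=ct100_protocol, seed=9)
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.times, ub.times)

    def test_zero_gain_population_is_null(self, ct100_protocol, rng):
        """With no evoked component the responsiveness filter keeps only
        ~alpha of units."""
        model = RgcKineticModel("ON_sust", baseline_rate=2.0, peak_gain=0.0)
        spont = ct100_protocol.spontaneous_window()
        block = ct100_protocol.block_window(100.0)
        kept = 0
        n = 150
        for _ in range(n):
            t = simulate_unit(model, ct100_protocol, rng)
            g = t[(t >= spont[0]) & (t < spont[1])]
            f = t[(t >= block[0]) & (t < block[1])]
            keep, _, _ = responsiveness_test(np.diff(g), np.diff(f))
            kept += keep
        assert kept <= 0.12 * n

    def test_spontaneous_rate_matches_parameter(self, ct100_protocol, rng):
        model = DEFAULT_MODELS["ON_sust"]
        spont = ct100_protocol.spontaneous_window()
        rates = [
            mean_rate(simulate_unit(model, ct100_protocol, rng), window=spont)
            for _ in range(80)
        ]
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - model.baseline_rate) < 4 * se + 1e-9

    def test_high_gain_on_unit_classified_on(self, ct100_protocol):
        sess, truth = simulate_session(
            counts={"ON_sust": 10}, protocol=ct100_protocol, seed=5
        )
        rows = pd.DataFrame(classify_session(sess))
        assert (rows["label"] == "ON").all()

    def test_injected_gain_scales_evoked_rate(self, ct100_protocol):
        effects = EffectTable(peak_gain_factor={("cKO", 18): 2.0})
        assert effects.gain("cKO", 18) == 2.0
        assert effects.gain("Ctrl", 18) == 1.0
        assert effects.gain("cKO", 0) == 1.0

    def test_refractory_option_enforces_dead_time(self, ct100_protocol, rng):
        model = RgcKineticModel("ON_trans", baseline_rate=5.0, peak_gain=300.0)
        t = simulate_unit(model, ct100_protocol, rng, refractory=0.0015)
        assert np.all(np.diff(t) >= 0.0015 - 1e-12)

    def test_contrast_response_shape(self):
        assert contrast_response(0.0) == 0.0
        assert contrast_response(30.0) == pytest.approx(0.5)
        assert contrast_response(100.0) < 1.0


class TestExpression:
    def test_noiseless_expression_recovered_exactly(self):
        df = simulate_expression(baseline=2.0, amplitude=0.7, acrophase=10.0,
                                 sigma=0.0, seed=1)
        fit = cosinor_fit(df["zt"].to_numpy(float), df["value"].to_numpy())
        assert fit.baseline == pytest.approx(2.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.7, abs=1e-9)
        assert fit.acrophase == pytest.approx(10.0, abs=1e-9)

    def test_flat_gene_mostly_called_flat(self):
        flat = 0
        n = 200
        for i in range(n):
            df = simulate_expression(amplitude=0.0, sigma=0.1, seed=i)
            fit = cosinor_fit(df["zt"].to_numpy(float), df["value"].to_numpy())
            flat += fit.selected_model == "flat"
        assert flat >= 0.85 * n

    def test_deterministic_per_seed(self):
        a = simulate_expression(seed=3)
        b = simulate_expression(seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_ct_representation_roundtrip(self):
        expr = simulate_expression(seed=4, genotype="Ctrl")
        # anchor: make the Ctrl ZT0 mean the delta-delta-Ct reference
        ct = expression_to_ct(expr)
        ref_dct = ct.loc[(ct["genotype"] == "Ctrl") & (ct["zt"] == 0),
                         "ct_target"].mean() - 18.0
        out = delta_delta_ct(ct, reference=ref_dct)
        ratio = out["fold"] / out["value"]
        assert np.allclose(ratio, ratio.iloc[0])


class TestErgGenerator:
    def test_noise_free_roundtrip_is_exact(self):
        tr = simulate_erg(150.0, 300.0, noise_sd=0.0)
        assert a_wave_amplitude(tr).amplitude == pytest.approx(150.0, abs=1e-12)
        assert b_wave_amplitude(tr).amplitude == pytest.approx(300.0, abs=1e-12)

    def test_invalid_amplitude_order_rejected(self):
        with pytest.raises(ValueError):
            simulate_erg(200.0, 100.0)

    def test_replicate_averaging_recovers_amplitudes(self):
        """20-replicate averages of noisy traces stay within +-5 uV of the
        generating amplitudes in >=95% of seeds."""
        ok = 0
        n = 60
        for i in range(n):
            reps = [simulate_erg(150.0, 300.0, noise_sd=5.0, seed=1000 * i + j)
                    for j in range(20)]
            mean_tr = average_replicates(reps)
            da = abs(a_wave_amplitude(mean_tr).amplitude - 150.0)
            db = abs(b_wave_amplitude(mean_tr).amplitude - 300.0)
            ok += da <= 5.0 and db <= 5.0
        assert ok >= 0.95 * n


class TestCohort:
    def test_cohort_grid_and_determinism(self):
        counts = {"ON_sust": 3, "OFF_sust": 2, "ONOFF": 2}
        s1, t1 = default_cohort(seed=11, counts=counts,
                                protocol_kwargs={"contrasts": [100.0],
                                                 "spont_dur": 30.0})
        s2, t2 = default_cohort(seed=11, counts=counts,
                                protocol_kwargs={"contrasts": [100.0],
                                                 "spont_dur": 30.0})
        assert len(s1) == 2 * 4 * 2 * 2  # genotypes x ZTs x retinae x regimes
        pd.testing.assert_frame_equal(t1, t2)
        for a, b in zip(s1, s2):
            assert (a.genotype, a.zt, a.regime, a.retina_id) == (
                b.genotype, b.zt, b.regime, b.retina_id)
            for ua, ub in zip(a.units, b.units):
                np.testing.assert_array_equal(ua.times, ub.times)

    def test_same_retina_appears_in_both_regimes(self):
        counts = {"ON_sust": 2, "OFF_sust": 2, "ONOFF": 2}
        sessions, _ = default_cohort(seed=1, counts=counts,
                                     protocol_kwargs={"contrasts": [100.0],
                                                      "spont_dur": 30.0})
        by_retina = {}
        for s in sessions:
            by_retina.setdefault(s.retina_id, set()).add(s.regime)
        assert all(v == {"mesopic", "photopic"} for v in by_retina.values())

    def test_study_effects_switch_probabilities_valid(self):
        eff = study_effects()
        assert eff.gain("cKO", 18) == 1.5
        p = eff.p_switch("OFF_sust", "cKO", 0, "photopic")
        assert 0.0 < p <= 1.0
        assert eff.p_switch("ON_sust", "Ctrl", 6, "mesopic") == 0.0
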