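import numpy as np
import pandas as pd
import pytest

from circaretina.classification import (
    NA,
    OFF,
    ON,
    ONOFF,
    TemplateLibrary,
    classify_polarity,
    classify_session,
    default_templates,
    rate_floor_filter,
    responsiveness_test,
)
from circaretina.spikes import (
    CDF_GRID,
    CumulativeCycleDistribution,
    SpikeTrain,
    cumulative_cycle_distribution,
)
from circaretina.synthetic import simulate_session

from oracles import ks_pvalue_brute, ks_statistic_brute


def _cdf(values):
    return CumulativeCycleDistribution(CDF_GRID.copy(), np.asarray(values, float),
                                       n_spikes=100)


class TestDefaultTemplates:
    def test_boundary_values_at_black_onset(self):
        lib = default_templates()
        by_name = {t.name: t for t in lib.templates}
        at_1 = np.searchsorted(CDF_GRID, 1.0)
        assert by_name["on_sustained"].values[at_1] == pytest.approx(1.0)
        assert by_name["off_sustained"].values[at_1] == pytest.approx(0.0)
        assert by_name["onoff_symmetric"].values[at_1] == pytest.approx(0.5)

    def test_every_template_is_a_cdf(self):
        for t in default_templates().templates:
            assert np.all(np.diff(t.values) >= -1e-12)
            assert t.values[-1] == pytest.approx(1.0)
            assert t.values[0] >= 0.0

    def test_library_json_roundtrip(self):
        lib = default_templates()
        restored = TemplateLibrary.from_json(lib.to_json())
        assert restored.theta == lib.theta
        for a, b in zip(lib.templates, restored.templates):
            assert a.name == b.name and a.cell_class == b.cell_class
            np.testing.assert_allclose(a.values, b.values)


class TestClassifyPolarity:
    def test_exact_template_match_distance_zero(self):
        lib = default_templates()
        off = next(t for t in lib.templates if t.name == "off_sustained")
        call = classify_polarity(_cdf(off.values), lib, unit_id="x")
        assert call.label == OFF
        assert call.distance == pytest.approx(0.0)
        assert call.best_template == "off_sustained"

    def test_diagonal_curve_distance_and_call(self):
        """A unit firing uniformly over the whole cycle sits far from all
        canonical curves; verify the sup-norm minimum with a direct
        computation and that the strict >theta rule then yields NA."""
        lib = default_templates()
        diag = CDF_GRID / 2.0
        oracle = min(float(np.max(np.abs(t.values - diag))) for t in lib.templates)
        call = classify_polarity(_cdf(diag), lib)
        assert call.distance == pytest.approx(oracle)
        expected = NA if oracle > lib.theta else call.label
        assert call.label == expected
        assert call.label == NA  # oracle distance ~0.31 for this library

    def test_burst_at_black_onset_matches_off_transient(self):
        """A kinetically realistic (80 ms) burst at the black onset is
        called OFF via the OFF-transient template.  An idealized
        instantaneous step is too far in sup-norm from every canonical
        curve (independently computed distances; the nearest is the
        symmetric ON-OFF template at 0.5), so the strict theta rule
        leaves it NA."""
        lib = default_templates()
        step = (CDF_GRID > 1.0).astype(float)
        dists = {t.name: float(np.max(np.abs(t.values - step))) for t in lib.templates}
        best = min(dists, key=dists.get)
        call = classify_polarity(_cdf(step), lib)
        assert call.best_template == best
        assert call.distance == pytest.approx(dists[best])
        assert dists[best] > lib.theta and call.label == NA

        rng = np.random.default_rng(0)
        burst = 1.0 + np.minimum(rng.exponential(0.08, 400), 0.999)
        realistic = classify_polarity(cumulative_cycle_distribution(burst), lib)
        assert realistic.label == OFF
        assert realistic.best_template == "off_transient"

    def test_boundary_distance_is_not_na(self):
        """distance == theta keeps the match; NA needs strictly > theta."""
        from circaretina.classification import Template

        t = CDF_GRID
        on = np.clip(t, 0.0, 1.0)
        off = np.clip(t - 1.0, 0.0, 1.0)
        lib = TemplateLibrary(
            [Template("on", ON, on), Template("onoff", ONOFF, t / 2.0),
             Template("off", OFF, off)],
            theta=0.25,
        )
        # curve exactly 0.25 away (sup-norm) from the ON template
        curve = 0.75 * on + 0.25 * off
        call = classify_polarity(_cdf(curve), lib)
        assert call.distance == 0.25
        assert call.label == ON  # boundary kept as a match

    def test_duplication_invariance_exact(self, rng):
        lib = default_templates()
        phases = np.sort(rng.uniform(0, 1, 80))  # ON-ish
        a = classify_polarity(cumulative_cycle_distribution(phases), lib)
        b = classify_polarity(
            cumulative_cycle_distribution(np.concatenate([phases, phases])), lib
        )
        assert (a.label, a.best_template, a.distance) == (
            b.label, b.best_template, b.distance,
        )

    def test_curve_on_foreign_grid_is_resampled(self):
        lib = default_templates()
        coarse = np.linspace(0.05, 2.0, 40)
        curve = CumulativeCycleDistribution(coarse, np.clip(coarse, 0, 1) / 1.0, 50)
        call = classify_polarity(curve, lib)
        assert call.label == ON


class TestResponsiveness:
    def test_identical_samples_not_kept(self):
        isi = np.linspace(0.01, 1.0, 40)
        keep, d, p = responsiveness_test(isi, isi.copy())
        assert d == pytest.approx(0.0)
        assert not keep

    def test_disjoint_supports_kept(self, rng):
        a = rng.uniform(0.0, 0.5, 50)
        b = rng.uniform(1.0, 1.5, 50)
        keep, d, p = responsiveness_test(a, b)
        assert d == pytest.approx(1.0)
        assert keep

    @pytest.mark.parametrize(
        "a, b",
        [
            ([0.1, 0.2, 0.35, 0.9], [0.15, 0.4, 0.5, 0.8]),
            ([0.05, 0.06, 0.07, 0.5], [0.3, 0.31, 0.6, 0.9]),
        ],
    )
    def test_small_sample_matches_enumeration_oracle(self, a, b):
        keep, d, p = responsiveness_test(np.array(a), np.array(b))
        assert d == pytest.approx(ks_statistic_brute(a, b))
        assert p == pytest.approx(ks_pvalue_brute(a, b), abs=1e-12)

    def test_insufficient_isis_raise(self):
        with pytest.raises(ValueError):
            responsiveness_test(np.array([0.1]), np.array([0.2, 0.3]))


class TestRateFloor:
    def test_threshold_is_inclusive(self, ct100_protocol):
        spont = ct100_protocol.spontaneous_window()
        dur = spont[1] - spont[0]

        def unit(n, uid):
            return SpikeTrain(uid, np.linspace(spont[0] + 0.1, spont[1] - 0.1, n))

        from circaretina.spikes import RecordingSession

        sess = RecordingSession(
            "Ctrl", 0, "mesopic", "r", ct100_protocol,
            [unit(int(0.05 * dur), "low"), unit(int(0.1 * dur), "edge"),
             unit(int(2 * dur), "high")],
        )
        kept = {u.unit_id for u in rate_floor_filter(sess)}
        assert kept == {"edge", "high"}


def test_classify_session_pipeline_ordering(small_session):
    """Every polarity call comes from a unit that passed both gates, and
    every unit appears exactly once with a label or a drop reason."""
    session, truth = small_session
    rows = pd.DataFrame(classify_session(session))
    assert len(rows) == len(session.units)
    called = rows[rows["label"] != NA]
    assert (called["drop_reason"] == "").all()
    merged = rows.merge(truth, on="unit_id")
    good = merged[merged["drop_reason"] == ""]
    assert (good["label"] == good["true_polarity"]).mean() >= 0.9
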