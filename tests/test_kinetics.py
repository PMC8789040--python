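"""1:1 Langmuir closed forms, referencing, global fitting and selectivity."""

import numpy as np
import pandas as pd
import pytest

from pdselex.kinetics import (
    KineticFitResults,
    LangmuirModel,
    LangmuirParams,
    Sensorgram,
    aggregate_replicates,
    double_reference,
    kd_from_rates,
    langmuir_association,
    langmuir_dissociation,
    orthogonality_matrix,
    selectivity,
    simulate_sensorgrams,
)


class TestClosedForms:
    def test_association_starts_at_zero(self):
        assert langmuir_association(0.0, 1e-9, 1e7, 1e-4, 100.0) == 0.0

    def test_association_half_saturation_at_kd(self):
        params = LangmuirParams(1e7, 1e-4, 100.0)
        plateau = langmuir_association(1e9, params.k_d, params.k_on,
                                       params.k_off, params.r_max)
        assert plateau == pytest.approx(50.0, rel=1e-9)

    def test_association_frozen_value(self):
        """Independent evaluation of the closed form at the model pair's
        measured rates (k_on 1.41e7, k_off 2.77e-4, C 1 nM, R_max 100,
        t 100 s)."""
        value = langmuir_association(100.0, 1e-9, 1.41e7, 2.77e-4, 100.0)
        assert value == pytest.approx(74.78351667585369, rel=1e-12)

    def test_association_high_concentration_limit(self):
        k_on, k_off, r_max = 1e6, 1e-4, 50.0
        conc = 1000 * (k_off / k_on)
        t = np.linspace(0, 50, 40)
        full = langmuir_association(t, conc, k_on, k_off, r_max)
        limit = r_max * (1 - np.exp(-conc * k_on * t))
        np.testing.assert_allclose(full, limit, rtol=2e-3)

    def test_dissociation_initial_and_half_life(self):
        assert langmuir_dissociation(5.0, 80.0, 1e-3, t0=5.0) == 80.0
        half = langmuir_dissociation(5.0 + np.log(2) / 1e-3, 80.0, 1e-3, t0=5.0)
        assert half == pytest.approx(40.0, rel=1e-12)

    def test_dissociation_frozen_window(self):
        # k_off 2.77e-4 over a 420 s window decays by exp(-0.11634)
        out = langmuir_dissociation(420.0, 1.0, 2.77e-4, t0=0.0)
        assert out == pytest.approx(0.8901725131851866, rel=1e-12)


class TestKdFromRates:
    def test_printed_rates_reproduce_printed_kd(self):
        # mean rates 2.00e7 / 1.36e-4 give 6.80e-12, matching the printed
        # (6.82 +/- 0.98)e-12 within rounding
        assert kd_from_rates(2.00e7, 1.36e-4) == pytest.approx(6.82e-12, rel=0.01)

    def test_simple_values(self):
        assert kd_from_rates(1e7, 1e-4) == pytest.approx(1e-11)
        assert kd_from_rates(3.0, 3.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kd_from_rates(0.0, 1e-4)
        with pytest.raises(ValueError):
            kd_from_rates(1e7, -1.0)


class TestSimulateSensorgrams:
    def test_noiseless_matches_closed_form(self):
        params = LangmuirParams(1e7, 1e-3, 100.0)
        (sg,) = simulate_sensorgrams(params, [1e-9], t_assoc=100, t_diss=300)
        predicted = sg.predict(params.k_on, params.k_off, params.r_max)
        np.testing.assert_allclose(sg.response, predicted, atol=1e-12)

    def test_seeded_reproducibility(self):
        params = LangmuirParams(1e7, 1e-3, 100.0)
        curves = []
        for _ in range(2):
            rng = np.random.default_rng(4)
            out = simulate_sensorgrams(params, [1e-9, 1e-8], noise_sd=1.0,
                                       rng=rng)
            curves.append(np.concatenate([sg.response for sg in out]))
        np.testing.assert_array_equal(curves[0], curves[1])

    def test_drift_is_linear_offset(self):
        params = LangmuirParams(1e7, 1e-3, 100.0)
        (flat,) = simulate_sensorgrams(params, [1e-9])
        (drifted,) = simulate_sensorgrams(params, [1e-9], drift_slope=0.01)
        delta = drifted.response - flat.response
        np.testing.assert_allclose(np.diff(delta), 0.01, atol=1e-12)


class TestDoubleReference:
    def _sg(self, values, conc=1e-9):
        t = np.arange(-5.0, 5.0)
        return Sensorgram(conc, t, np.full_like(t, values, dtype=float), 2.0)

    def test_identical_inputs_cancel(self):
        sg = self._sg(7.0)
        out = double_reference(sg, sg, sg, sg)
        np.testing.assert_array_equal(out.response, 0.0)

    def test_zero_blanks_reduce_to_reference_subtraction(self):
        out = double_reference(self._sg(5.0), self._sg(2.0),
                               self._sg(0.0), self._sg(0.0))
        np.testing.assert_array_equal(out.response, 3.0)

    def test_common_mode_offset_invariance(self):
        base = double_reference(self._sg(5.0), self._sg(2.0),
                                self._sg(1.0), self._sg(0.5))
        shifted = double_reference(self._sg(5.0 + 11.0), self._sg(2.0 + 11.0),
                                   self._sg(1.0), self._sg(0.5))
        np.testing.assert_allclose(base.response, shifted.response)

    def test_mismatched_grids_rejected(self):
        a = self._sg(1.0)
        t = np.arange(-4.0, 6.0)
        b = Sensorgram(1e-9, t, np.zeros_like(t), 2.0)
        with pytest.raises(ValueError, match="time grid"):
            double_reference(a, a, b, a)


class TestGlobalFit:
    def test_noiseless_recovery(self):
        true = LangmuirParams(2.00e7, 1.36e-4, 100.0)
        concs = np.geomspace(0.3, 30, 5) * true.k_d
        sgs = simulate_sensorgrams(true, concs, t_assoc=200, t_diss=1500, dt=2)
        fit = LangmuirModel(sgs).fit()
        assert fit.converged and not fit.no_binding
        assert fit.k_on == pytest.approx(true.k_on, rel=1e-3)
        assert fit.k_off == pytest.approx(true.k_off, rel=1e-3)
        assert fit.r_max == pytest.approx(true.r_max, rel=1e-3)

    def test_kd_is_exact_quotient_of_fit(self):
        true = LangmuirParams(1e6, 1e-3, 50.0)
        sgs = simulate_sensorgrams(true, [1e-9, 1e-8], t_assoc=100, t_diss=420)
        fit = LangmuirModel(sgs).fit()
        assert fit.k_d == fit.k_off / fit.k_on  # bit-for-bit

    def test_flat_zero_signal_flags_no_binding(self):
        t = np.arange(-10.0, 520.0)
        sgs = [Sensorgram(c, t, np.zeros_like(t), 100.0)
               for c in (1e-9, 1e-8, 1e-7)]
        fit = LangmuirModel(sgs).fit()
        assert fit.no_binding

    def test_flat_noise_flags_no_binding(self, rng):
        t = np.arange(-10.0, 520.0)
        sgs = [Sensorgram(c, t, rng.normal(0, 0.5, t.shape), 100.0)
               for c in (1e-9, 1e-8, 1e-7)]
        assert LangmuirModel(sgs).fit().no_binding

    def test_per_curve_mode_returns_list(self):
        true = LangmuirParams(1e6, 1e-3, 50.0)
        sgs = simulate_sensorgrams(true, [1e-9, 1e-8])
        fits = LangmuirModel(sgs).fit(global_fit=False)
        assert isinstance(fits, list) and len(fits) == 2

    def test_summary_mentions_parameters(self):
        true = LangmuirParams(1e6, 1e-3, 50.0)
        sgs = simulate_sensorgrams(true, [1e-8])
        text = LangmuirModel(sgs).fit().summary()
        assert "k_on" in text and "K_D" in text


def _fit_result(k_on, k_off, no_binding=False):
    sg = Sensorgram(1e-9, np.arange(0.0, 10.0), np.zeros(10), 5.0)
    return KineticFitResults(
        model=LangmuirModel([sg]), params=LangmuirParams(k_on, k_off, 100.0),
        stderr={}, rss=0.0, converged=True, no_binding=no_binding,
        noise_sd=0.0, nfev=1,
    )


class TestReplicateAggregation:
    def test_identical_replicates_zero_sd(self):
        summary = aggregate_replicates([_fit_result(1e7, 1e-4)] * 2)
        assert summary.k_on_sd == 0.0 and summary.k_d_sd == 0.0

    def test_kd_mean_of_ratios(self):
        fits = [_fit_result(1e7, 2e-4), _fit_result(1e7, 2.3e-4)]
        summary = aggregate_replicates(fits)
        assert summary.k_d_mean == pytest.approx(2.15e-11, rel=1e-12)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        """Replicates consistent with the model pair's printed means and SDs
        reproduce the printed K_D (2.13e-11) even though the ratio of the
        mean rates is 1.96e-11."""
        a = 1.11e7 / np.sqrt(2)  # sample SD of {m+a, m-a} is a*sqrt(2)
        b = 1.75e-4 / np.sqrt(2)
        fits = [_fit_result(1.41e7 + a, 2.77e-4 + b),
                _fit_result(1.41e7 - a, 2.77e-4 - b)]
        summary = aggregate_replicates(fits)
        assert summary.k_on_mean == pytest.approx(1.41e7, rel=1e-12)
        assert summary.k_off_mean == pytest.approx(2.77e-4, rel=1e-12)
        assert summary.k_d_mean == pytest.approx(2.13e-11, rel=0.01)
        ratio_of_means = summary.k_off_mean / summary.k_on_mean
        assert ratio_of_means == pytest.approx(1.96e-11, rel=0.01)
        assert summary.k_d_mean != pytest.approx(ratio_of_means, rel=0.05)

    def test_rejects_single_or_no_binding(self):
        with pytest.raises(ValueError):
            aggregate_replicates([_fit_result(1e7, 1e-4)])
        with pytest.raises(ValueError, match="no-binding"):
            aggregate_replicates([_fit_result(1e7, 1e-4),
                                  _fit_result(1e7, 1e-4, no_binding=True)])


PAPER_KDS = pd.DataFrame(
    {
        "LS4": {"CS1": 6.82e-12, "CS2": 1.14e-7},
        "LS12": {"CS1": 2.75e-8, "CS2": 7.24e-12},
        "L7Ae": {"CS1": 1.49e-9, "CS2": 5.71e-12},
    }
)


class TestSelectivity:
    def test_printed_folds(self):
        assert selectivity(2.75e-8, 6.82e-12) == 4030.0
        assert selectivity(1.49e-9, 6.82e-12) == 218.0
        assert selectivity(1.14e-7, 5.71e-12) == 20000.0

    def test_identity(self):
        assert selectivity(3.3e-9, 3.3e-9) == 1.0


class TestOrthogonalityMatrix:
    def test_forced_two_by_two(self):
        table = pd.DataFrame({"P1": {"R1": 1e-11, "R2": 1e-7},
                              "P2": {"R1": 1e-7, "R2": 1e-11}})
        sel, proposals = orthogonality_matrix(
            table, {"R1": "P1", "R2": "P2"}, selectivity_min=4000
        )
        assert sel.loc["R1", "P2"] == pytest.approx(1e4)
        assert proposals == [(("R1", "P1"), ("R2", "P2"))]

    def test_printed_kds_orthogonal_pairs(self):
        sel, proposals = orthogonality_matrix(
            PAPER_KDS, {"CS1": "LS4", "CS2": "LS12"}, selectivity_min=4000
        )
        # CS2 cannot discriminate LS12 from L7Ae (ratio ~1.3)...
        assert sel.loc["CS2", "L7Ae"] == pytest.approx(5.71e-12 / 7.24e-12,
                                                       rel=0.01)
        # ...but the two selected pairs are mutually orthogonal
        assert proposals == [(("CS1", "LS4"), ("CS2", "LS12"))]
        assert min(sel.loc["CS1", "LS12"], sel.loc["CS2", "LS4"]) > 4000

    def test_oriented_entries_at_least_one(self):
        sel, _ = orthogonality_matrix(PAPER_KDS, {"CS1": "LS4", "CS2": "LS12"})
        assert sel.loc["CS1", "LS4"] == 1.0
        assert sel.loc["CS2", "LS12"] == 1.0

    def test_no_binding_entries_floored(self):
        table = pd.DataFrame({"P1": {"R1": 1e-11}, "P2": {"R1": np.nan}})
        sel, _ = orthogonality_matrix(table, {"R1": "P1"}, nb_floor_kd=1e-6)
        assert sel.loc["R1", "P2"] == pytest.approx(1e5)
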