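"""Two-state melting models, van't Hoff derivation, and curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m6afold.errors import ValidationError
from m6afold.melt import (MeltingCurve, R_KCAL, T37_K, delta_delta,
                          derive_thermo, fit_melting, fit_melting_replicates,
                          fraction_folded_duplex, fraction_folded_hairpin)
from m6afold.simulate import GeneratorSpec, gen_melting_curve


class TestModelFunctions:
    @pytest.mark.parametrize("fn", [fraction_folded_duplex,
                                    fraction_folded_hairpin])
    @pytest.mark.parametrize("dh", [-20.0, -45.0, -80.0])
    def test_half_folded_at_tm(self, fn, dh):
        assert fn(330.0, 330.0, dh) == pytest.approx(0.5)

    @pytest.mark.parametrize("fn", [fraction_folded_duplex,
                                    fraction_folded_hairpin])
    def test_limits(self, fn):
        assert fn(2000.0, 330.0, -45.0) < 1e-6
        assert fn(100.0, 330.0, -45.0) > 1 - 1e-6

    def test_duplex_value_matches_direct_arithmetic(self):
        # independent evaluation of the root form of the duplex isotherm
        T, tm, dh = 320.0, 330.0, -40.0
        e = np.exp((1 / tm - 1 / T) * dh / R_KCAL)
        expected = (1 + 4 * e - np.sqrt(1 + 8 * e)) / (4 * e)
        assert fraction_folded_duplex(T, tm, dh) == pytest.approx(expected, rel=1e-12)

    def test_hairpin_value_matches_direct_arithmetic(self):
        T, tm, dh = 335.0, 330.0, -45.0
        x = (1 / tm - 1 / T) * dh / R_KCAL
        expected = np.exp(x) / (1 + np.exp(x))
        assert fraction_folded_hairpin(T, tm, dh) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=-120, max_value=-5),
           st.floats(min_value=290, max_value=370))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_for_folding_enthalpy(self, dh, tm):
        T = np.linspace(280.0, 380.0, 101)
        for fn in (fraction_folded_duplex, fraction_folded_hairpin):
            y = fn(T, tm, dh)
            assert np.all(np.diff(y) <= 1e-12)
            assert np.all((y >= 0) & (y <= 1))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValidationError):
            fraction_folded_hairpin(-1.0, 330.0, -45.0)
        with pytest.raises(ValidationError):
            fraction_folded_duplex(300.0, 0.0, -45.0)


class TestDeriveThermo:
    def test_hairpin_hand_arithmetic(self):
        p = derive_thermo({"tm": 330.0, "dh": -45.0}, "hairpin", t_eval=310.15)
        assert p.ds == pytest.approx(-45.0 / 330.0)           # -0.136364
        assert p.ds == pytest.approx(-0.136364, abs=1e-6)
        assert p.dg == pytest.approx(-2.71, abs=0.01)

    def test_duplex_hand_arithmetic(self):
        p = derive_thermo({"tm": 330.0, "dh": -40.0}, "duplex", ct=3e-6,
                          t_eval=310.15)
        assert p.ds == pytest.approx(-40.0 / 330.0 - R_KCAL * np.log(1.5e-6))
        assert p.dg == pytest.approx(-10.67, abs=0.01)

    def test_hairpin_dg_zero_at_tm(self):
        p = derive_thermo({"tm": 341.2, "dh": -37.0}, "hairpin", t_eval=341.2)
        assert p.dg == pytest.approx(0.0, abs=1e-12)

    def test_duplex_dg_at_tm_is_concentration_term(self):
        tm, ct = 330.0, 3e-6
        p = derive_thermo({"tm": tm, "dh": -60.0}, "duplex", ct=ct, t_eval=tm)
        assert p.dg == pytest.approx(R_KCAL * tm * np.log(ct / 2.0))

    def test_duplex_requires_ct(self):
        with pytest.raises(ValidationError):
            derive_thermo({"tm": 330.0, "dh": -40.0}, "duplex")

    def test_gibbs_identity(self):
        p = derive_thermo({"tm": 320.0, "dh": -50.0}, "hairpin", t_eval=300.0)
        assert p.dg == pytest.approx(p.dh - 300.0 * p.ds)


class TestFitting:
    def test_exact_recovery_on_noise_free_curve(self):
        curve = gen_melting_curve(GeneratorSpec(0, 1, 0.0), "hairpin",
                                  tm=330.0, dh=-45.0)
        fit = fit_melting(curve, "hairpin")
        assert fit.tm == pytest.approx(330.0, rel=1e-6)
        assert fit.dh == pytest.approx(-45.0, rel=1e-6)

    def test_exact_recovery_duplex(self):
        curve = gen_melting_curve(GeneratorSpec(0, 1, 0.0), "duplex",
                                  tm=325.0, dh=-60.0, ct=3e-6)
        fit = fit_melting(curve, "duplex")
        assert fit.tm == pytest.approx(325.0, rel=1e-6)
        assert fit.dh == pytest.approx(-60.0, rel=1e-6)

    def test_noisy_recovery_statistics(self):
        """Monte-Carlo parameter recovery under the standard noise level."""
        errs_tm, errs_dh = [], []
        for i in range(60):
            curve = gen_melting_curve(GeneratorSpec(500 + i, 1, 0.01),
                                      "hairpin", tm=330.0, dh=-45.0)
            fit = fit_melting(curve, "hairpin")
            errs_tm.append(abs(fit.tm - 330.0))
            errs_dh.append(abs(fit.dh + 45.0) / 45.0)
        assert np.mean(errs_tm) < 0.5
        assert np.mean(errs_dh) < 0.05

    def test_absorbance_baseline_fit(self):
        curve = gen_melting_curve(GeneratorSpec(1, 1, 0.0), "hairpin",
                                  tm=330.0, dh=-45.0)
        # synthetic absorbance: sloped folded/unfolded baselines
        T, f = curve.temperature, curve.signal
        absb = (0.5 + 1e-4 * T) * f + (0.9 + 2e-4 * T) * (1 - f)
        ab_curve = MeltingCurve(T, absb, signal_kind="absorbance")
        fit = fit_melting(ab_curve, "hairpin", baseline_mode="linear")
        assert fit.tm == pytest.approx(330.0, abs=0.2)
        assert fit.dh == pytest.approx(-45.0, rel=0.05)

    def test_absorbance_without_baseline_rejected(self):
        curve = gen_melting_curve(GeneratorSpec(1, 1, 0.0), "hairpin",
                                  tm=330.0, dh=-45.0)
        bad = MeltingCurve(curve.temperature, curve.signal,
                           signal_kind="absorbance")
        with pytest.raises(ValidationError):
            fit_melting(bad, "hairpin", baseline_mode="none")

    def test_fraction_out_of_range_rejected(self):
        T = np.linspace(288, 368, 81)
        with pytest.raises(ValidationError):
            fit_melting(MeltingCurve(T, np.linspace(-0.3, 1.2, 81)), "hairpin")

    def test_replicate_uncertainty(self):
        curves = [gen_melting_curve(GeneratorSpec(i, 1, 0.01), "hairpin",
                                    tm=330.0, dh=-45.0) for i in range(4)]
        fit = fit_melting_replicates(curves, "hairpin")
        assert fit.uncertainty["tm"] > 0
        assert fit.uncertainty["dg"] > 0

    def test_bootstrap_uncertainty_seeded(self):
        curve = gen_melting_curve(GeneratorSpec(9, 1, 0.01), "hairpin",
                                  tm=330.0, dh=-45.0)
        a = fit_melting(curve, "hairpin", n_bootstrap=50, seed=1)
        b = fit_melting(curve, "hairpin", n_bootstrap=50, seed=1)
        assert a.uncertainty == b.uncertainty
        assert a.uncertainty["tm"] > 0


class TestDeltaDelta:
    def _p(self, tm, dh, t_eval=T37_K):
        return derive_thermo({"tm": tm, "dh": dh}, "hairpin", t_eval=t_eval)

    def test_identity_gives_zero(self):
        p = self._p(330.0, -45.0)
        r = delta_delta(p, p)
        assert (r.ddg, r.ddh, r.dds) == (0.0, 0.0, 0.0)

    def test_sign_convention_stabilizing(self):
        # ΔG −3.0 vs −2.1 → −0.9 (methylation stabilizes)
        import dataclasses
        a = dataclasses.replace(self._p(330.0, -45.0), dg=-3.0)
        b = dataclasses.replace(self._p(330.0, -45.0), dg=-2.1)
        assert delta_delta(a, b).ddg == pytest.approx(-0.9)

    def test_sign_convention_destabilizing(self):
        import dataclasses
        a = dataclasses.replace(self._p(330.0, -45.0), dg=-4.0)
        b = dataclasses.replace(self._p(330.0, -45.0), dg=-4.6)
        assert delta_delta(a, b).ddg == pytest.approx(+0.6)

    def test_swap_negates(self):
        a, b = self._p(332.0, -48.0), self._p(328.0, -43.0)
        r1, r2 = delta_delta(a, b), delta_delta(b, a)
        assert r1.ddg == pytest.approx(-r2.ddg)
        assert r1.ddh == pytest.approx(-r2.ddh)
        assert r1.dds == pytest.approx(-r2.dds)

    def test_mismatched_models_rejected(self):
        h = self._p(330.0, -45.0)
        d = derive_thermo({"tm": 330.0, "dh": -45.0}, "duplex", ct=3e-6)
        with pytest.raises(ValidationError):
            delta_delta(h, d)

    def test_mismatched_temperature_rejected(self):
        with pytest.raises(ValidationError):
            delta_delta(self._p(330.0, -45.0),
                        self._p(330.0, -45.0, t_eval=298.15))

    def test_uncertainty_quadrature(self):
        import dataclasses
        a = dataclasses.replace(self._p(330.0, -45.0),
                                uncertainty={"dg": 0.3, "dh": 1.0, "ds": 0.01})
        b = dataclasses.replace(self._p(329.0, -44.0),
                                uncertainty={"dg": 0.4, "dh": 1.0, "ds": 0.01})
        r = delta_delta(a, b)
        assert r.uncertainty["ddg"] == pytest.approx(0.5)
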