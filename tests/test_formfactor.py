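"""Form-factor engine: analytic amplitude vs. quadrature, intensities,
and the form-factor (non-)additivity comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdpfit.bilayer import build_unit_cell
from sdpfit.composition import default_peptides
from sdpfit.formfactor import (
    FormFactor,
    ProbeError,
    average_form_factors,
    contrast_profile,
    form_factor_analytic,
    form_factor_discrepancy,
    intensity,
)
from sdpfit.simulate import build_truth_model, system_recipe

from test_bilayer import random_params

Q = np.geomspace(0.01, 0.9, 80)

# quadrature grid: midpoint rule on a fine half-grid, spectrally accurate
# for the smooth SDP profiles
_DZ = 0.01
_ZQ = np.arange(0.0, 60.0, _DZ) + _DZ / 2


def transform_oracle(model, probe, x_D, q=Q):
    """Numerical cosine transform of the real-space contrast profile."""
    cp = contrast_profile(model, probe, x_D, _ZQ)
    return 2.0 * np.array([np.sum(cp.drho * np.cos(qi * _ZQ)) * _DZ for qi in q])


CONTRASTS = [("xray", 0.0), ("neutron", 1.0), ("neutron", 0.75), ("neutron", 0.5)]


class TestAnalyticVsQuadrature:
    @pytest.mark.parametrize("probe,x_D", CONTRASTS)
    @pytest.mark.parametrize("system", ["pure", "mixture"])
    def test_shipped_systems(self, system, probe, x_D):
        model = build_truth_model(system_recipe(system))
        ff = form_factor_analytic(model, probe, x_D, Q)
        F_num = transform_oracle(model, probe, x_D)
        scale = np.max(np.abs(F_num))
        np.testing.assert_allclose(ff.F, F_num, atol=1e-6 * scale)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_randomised_models(self, seed):
        rng = np.random.default_rng(seed)
        peptides = [default_peptides()["L18W-PGLa"]] if seed % 2 else []
        model = build_unit_cell(
            peptides=peptides, PL_ratio=0.005 if peptides else 0.0,
            params=random_params(rng))
        probe, x_D = CONTRASTS[seed % len(CONTRASTS)]
        ff = form_factor_analytic(model, probe, x_D, Q)
        F_num = transform_oracle(model, probe, x_D)
        np.testing.assert_allclose(ff.F, F_num, atol=1e-6 * np.max(np.abs(F_num)))


class TestContrastProfile:
    def test_far_field_vanishes(self, pure_model):
        cp = contrast_profile(pure_model, "xray", 0.0, np.array([50.0, 60.0]))
        assert np.all(np.abs(cp.drho) < 1e-12)

    def test_xray_headgroup_maximum_near_phosphate(self, pure_model):
        z = np.linspace(0, 30, 1501)
        cp = contrast_profile(pure_model, "xray", 0.0, z)
        z_peak = z[np.argmax(cp.drho)]
        z_po4 = pure_model.component("PO4").z_c
        assert abs(z_peak - z_po4) < 1.0

    def test_solvent_matched_group_drops_out(self, pure_model):
        """At the D2O fraction where phosphate matches the solvent SLD, the
        PO4 term vanishes from the neutron contrast profile."""
        from sdpfit.bilayer import volume_probability
        from sdpfit.composition import Solvent, neutron_sld

        po4 = pure_model.component("PO4").group
        # solve affine solvent SLD(x) = constant PO4 SLD (no labile H)
        lo, hi = Solvent(0.0).neutron_sld, Solvent(1.0).neutron_sld
        x_match = (neutron_sld(po4, Solvent(0.5)) - lo) / (hi - lo)
        assert 0 < x_match < 1
        solvent = Solvent(x_match)
        assert neutron_sld(po4, solvent) == pytest.approx(
            solvent.neutron_sld, rel=1e-9)
        z = np.linspace(0, 40, 401)
        cp = contrast_profile(pure_model, "neutron", x_match, z)
        prof = volume_probability(pure_model, z)
        from sdpfit.formfactor import group_sld

        manual = np.zeros_like(z)
        for name, arr in prof.components.items():
            if name == "PO4":
                continue
            g = (pure_model.ch2 if name == "CH2"
                 else pure_model.component(name).group)
            manual += arr * (group_sld(g, "neutron", solvent)
                             - solvent.neutron_sld)
        np.testing.assert_allclose(cp.drho, manual, atol=1e-12)

    def test_low_q_limit_is_integrated_contrast(self, pure_model):
        q_small = np.array([1e-4])
        ff = form_factor_analytic(pure_model, "xray", 0.0, q_small)
        cp = contrast_profile(pure_model, "xray", 0.0, _ZQ)
        expected = 2.0 * np.sum(cp.drho) * _DZ
        assert ff.F[0] == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_q_rejected(self, pure_model):
        with pytest.raises(ValueError):
            form_factor_analytic(pure_model, "xray", 0.0, np.array([0.0, 0.1]))

    def test_unknown_probe_rejected(self, pure_model):
        with pytest.raises(ProbeError):
            contrast_profile(pure_model, "electron", 0.0, _ZQ[:10])


class TestIntensity:
    def test_scale_linearity(self, pure_model):
        ff = form_factor_analytic(pure_model, "xray", 0.0, Q)
        i1 = intensity(ff, scale=1.0, background=0.1)
        i2 = intensity(ff, scale=2.0, background=0.1)
        np.testing.assert_allclose(i2 - 0.1, 2 * (i1 - 0.1), rtol=1e-12)

    def test_background_floor(self, pure_model):
        ff = form_factor_analytic(pure_model, "xray", 0.0, Q)
        assert np.all(intensity(ff, 1.0, 0.05) >= 0.05)

    def test_form_factor_zeros_make_minima(self, pure_model):
        q = np.linspace(0.05, 0.6, 4000)
        ff = form_factor_analytic(pure_model, "xray", 0.0, q)
        I = intensity(ff, 1.0, 0.0)
        signs = np.sign(ff.F)
        crossings = np.where(np.diff(signs) != 0)[0]
        assert crossings.size > 0
        for i in crossings:
            lo = max(i - 50, 0)
            hi = min(i + 50, q.size - 1)
            assert I[lo : hi + 1].min() <= I[lo] and I[lo : hi + 1].min() <= I[hi]

    def test_nonpositive_scale_rejected(self, pure_model):
        ff = form_factor_analytic(pure_model, "xray", 0.0, Q)
        with pytest.raises(ValueError):
            intensity(ff, scale=0.0)


class TestSmearing:
    def test_zero_width_is_identity(self, pure_model):
        from sdpfit.formfactor import smear_gaussian

        ff = form_factor_analytic(pure_model, "neutron", 1.0, Q)
        I = intensity(ff)
        np.testing.assert_array_equal(smear_gaussian(Q, I, 0.0), I)

    def test_constant_curve_unchanged(self):
        from sdpfit.formfactor import smear_gaussian

        q = np.linspace(0.05, 0.4, 200)
        I = np.full_like(q, 3.7)
        np.testing.assert_allclose(smear_gaussian(q, I, 0.04), I, rtol=1e-12)

    def test_smearing_fills_sharp_minima(self, pure_model):
        from sdpfit.formfactor import smear_gaussian

        q = np.linspace(0.05, 0.5, 2000)
        ff = form_factor_analytic(pure_model, "neutron", 1.0, q)
        I = intensity(ff)
        sm = smear_gaussian(q, I, 0.04)
        assert sm.min() > I.min()


class TestAveraging:
    def test_average_of_identical_is_identity(self, pure_model):
        ff = form_factor_analytic(pure_model, "xray", 0.0, Q)
        avg = average_form_factors(ff, ff)
        np.testing.assert_allclose(avg.F, ff.F, rtol=1e-15)

    def test_degenerate_weights_select_one(self, pure_model, pgla_model):
        fa = form_factor_analytic(pure_model, "xray", 0.0, Q)
        fb = form_factor_analytic(pgla_model, "xray", 0.0, Q)
        avg = average_form_factors(fa, fb, weights=(1.0, 0.0))
        np.testing.assert_allclose(avg.F, fa.F, rtol=1e-15)

    def test_mismatched_grids_rejected(self, pure_model):
        fa = form_factor_analytic(pure_model, "xray", 0.0, Q)
        fb = form_factor_analytic(pure_model, "xray", 0.0, Q[:-1])
        with pytest.raises(ProbeError):
            average_form_factors(fa, fb)

    def test_single_peptide_average_differs_from_mixture(self):
        """Averaging the two single-peptide form factors does not reproduce
        the equimolar-mixture model (the non-interaction null hypothesis)."""
        f_pgla = form_factor_analytic(
            build_truth_model(system_recipe("L18W-PGLa")), "xray", 0.0, Q)
        f_mg2a = form_factor_analytic(
            build_truth_model(system_recipe("MG2a")), "xray", 0.0, Q)
        f_mix = form_factor_analytic(
            build_truth_model(system_recipe("mixture")), "xray", 0.0, Q)
        avg = average_form_factors(f_pgla, f_mg2a)
        assert form_factor_discrepancy(avg, f_mix) > 1e-4
        assert form_factor_discrepancy(f_mix, f_mix) == 0.0
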