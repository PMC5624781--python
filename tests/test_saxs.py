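"""Debye scattering, Guinier, P(r)/IFT, Porod and chi-square processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ubconj as u
from ubconj import synthetic as syn
from ubconj.saxs import (
    ScatteringCurve,
    chi2_with_scale,
    debye_curve_from_structure,
    ift_pofr,
    pofr_from_model,
    porod_volume,
    read_dat,
    write_dat,
)

SPHERE_RG = np.sqrt(3 / 5) * 20.0  # 15.4919 A for R = 20 A


def brute_force_debye(coords, qgrid):
    """Independent O(n^2) Debye oracle."""
    n = len(coords)
    I = np.full(len(qgrid), float(n))
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(coords[i] - coords[j])
            x = qgrid * r
            with np.errstate(invalid="ignore"):
                term = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
            I += 2 * term
    return I


class TestDebye:
    def test_two_beads_closed_form(self):
        coords = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        q = np.linspace(0.0, 0.5, 20)
        c = debye_curve_from_structure(coords, q, exact=True)
        x = q * 7.0
        expected = 2 + 2 * np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1, x))
        assert np.allclose(c.I, expected, atol=1e-9)
        assert c.I[0] == pytest.approx(4.0)

    def test_forward_intensity_is_n_squared(self):
        coords = np.random.default_rng(0).normal(size=(30, 3)) * 10
        c = debye_curve_from_structure(coords, np.array([0.0]))
        assert c.I[0] == pytest.approx(900.0, rel=1e-9)

    @settings(deadline=None, max_examples=5)
    @given(st.integers(min_value=0, max_value=1000))
    def test_histogram_path_matches_brute_force(self, seed):
        coords = np.random.default_rng(seed).normal(scale=12, size=(120, 3))
        q = np.linspace(0.002, 0.5, 40)
        hist = debye_curve_from_structure(coords, q, bin_width=0.5)
        brute = brute_force_debye(coords, q)
        assert np.max(np.abs(hist.I / brute - 1)) < 0.005

    def test_empty_qgrid(self):
        with pytest.raises(ValueError):
            debye_curve_from_structure(np.zeros((3, 3)), np.array([]))


class TestGuinier:
    def test_sphere_with_noise(self):
        q = np.linspace(0.0005, 0.15, 300)
        errs = []
        for s in range(5):
            sph = syn.make_sphere_curve(20.0, i0=100.0, qgrid=q)
            I, sig = syn.NoiseModel(c=0.01, seed=s).apply(q, sph.I)
            g = u.guinier_fit(ScatteringCurve(q, I, sig))
            assert g.success
            errs.append(abs(g.rg / SPHERE_RG - 1))
        assert np.median(errs) < 0.02

    def test_noise_free_rigid_body_within_one_percent(self):
        body = syn.make_dummy_rigid_body(200, 20.0, seed=5)
        cv = u.debye_curve(body, syn.default_qgrid(0.3, 200), exact=True)
        g = u.guinier_fit(cv, qrg_limit=1.0)
        assert g.rg == pytest.approx(20.0, rel=0.01)

    def test_gaussian_chain_small_q_limit(self):
        ch = syn.make_gaussian_chain_curve(25.0, qgrid=syn.default_qgrid(0.2, 300))
        g = u.guinier_fit(ch, qrg_limit=0.5)
        assert g.rg == pytest.approx(25.0, rel=0.01)

    def test_scale_equivariance(self):
        a = u.guinier_fit(syn.make_sphere_curve(20.0, i0=1.0))
        b = u.guinier_fit(syn.make_sphere_curve(20.0, i0=10.0))
        assert a.rg == pytest.approx(b.rg, rel=1e-12)
        assert b.i0 / a.i0 == pytest.approx(10.0, rel=1e-9)

    def test_failure_result_not_exception(self):
        flat = ScatteringCurve(np.linspace(0.01, 0.1, 20), np.ones(20))
        g = u.guinier_fit(flat)
        assert not g.success and g.message


class TestPofR:
    def test_two_beads_single_bin(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        p = pofr_from_model(coords, bin_width=1.0)
        assert p.dmax == pytest.approx(10.0)
        nz = np.flatnonzero(p.p)
        assert len(nz) == 1 and abs(p.r[nz[0]] - 10.0) <= 0.5

    def test_rg_matches_geometry_within_half_bin(self, small_pool):
        conf = small_pool.conformers[0]
        p = pofr_from_model(conf, bin_width=1.0)
        assert abs(p.rg - conf.rg) < 0.5

    def test_sphere_distance_distribution_shape(self):
        # p(r) of a uniform ball: p(x) = 3x^2 - 9x^3/4 + 3x^5/16, x = r/R in [0,2]
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(3000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 20.0 * rng.uniform(size=(3000, 1)) ** (1 / 3)
        p = pofr_from_model(pts, bin_width=1.0)
        x = p.r / 20.0
        analytic = 3 * x**2 - (9 / 4) * x**3 + (3 / 16) * x**5
        analytic[x > 2] = 0
        analytic /= np.trapezoid(analytic, p.r)
        empirical = p.p / np.trapezoid(p.p, p.r)
        assert p.dmax == pytest.approx(40.0, abs=1.5)
        assert np.max(np.abs(empirical - analytic)) < 0.1 * analytic.max()


class TestIFT:
    def test_sphere_dmax_and_rg(self):
        q = syn.default_qgrid(0.35, 150)
        sph = syn.make_sphere_curve(20.0, i0=100.0, qgrid=q)
        curve = ScatteringCurve(q, sph.I, 0.01 * np.abs(sph.I) + 1e-8)
        p = ift_pofr(curve, np.arange(30.0, 60.1, 2.0))
        assert abs(p.dmax - 40.0) <= 2.0  # within one grid step
        assert p.rg == pytest.approx(SPHERE_RG, rel=0.02)
        assert np.all(p.p >= 0) and p.p[0] == 0

    def test_conformer_curve_recovery(self, small_pool):
        conf = small_pool.conformers[1]
        q = syn.default_qgrid(0.4, 160)
        cv = u.debye_curve(conf, q)
        I, sig = syn.NoiseModel(c=0.01, seed=9).apply(q, cv.I)
        p = ift_pofr(ScatteringCurve(q, I, sig), np.arange(50.0, 100.1, 2.0))
        assert p.rg == pytest.approx(conf.rg, rel=0.03)

    def test_deterministic(self):
        q = syn.default_qgrid(0.3, 80)
        sph = syn.make_sphere_curve(15.0, qgrid=q)
        curve = ScatteringCurve(q, sph.I, 0.01 * np.abs(sph.I) + 1e-9)
        a = ift_pofr(curve, [25.0, 30.0, 35.0])
        b = ift_pofr(curve, [25.0, 30.0, 35.0])
        assert a.dmax == b.dmax and np.array_equal(a.p, b.p)

    def test_requires_sigma(self):
        sph = syn.make_sphere_curve(15.0)
        with pytest.raises(ValueError):
            ift_pofr(sph, [30.0])


class TestPorod:
    def test_sphere_volume(self):
        curve = syn.make_sphere_curve(20.0, qgrid=syn.default_qgrid(0.6, 600))
        res = porod_volume(curve, 1.0)
        assert res.volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.10)

    def test_scale_invariance(self):
        curve = syn.make_sphere_curve(20.0, qgrid=syn.default_qgrid(0.6, 600))
        v1 = porod_volume(curve, 1.0).volume
        v2 = porod_volume(curve.scaled(2.0), 2.0).volume
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_truncation_with_tail_extrapolation(self):
        full = porod_volume(syn.make_sphere_curve(20.0, qgrid=syn.default_qgrid(0.6, 600)), 1.0)
        trunc = porod_volume(syn.make_sphere_curve(20.0, qgrid=syn.default_qgrid(0.4, 400)), 1.0)
        assert abs(trunc.volume / full.volume - 1) < 0.05


class TestPorodDebyeVerdict:
    def test_sphere_is_rigid(self):
        v = u.porod_debye_verdict(syn.make_sphere_curve(20.0))
        assert v.plateau and not v.flexible

    def test_gaussian_chain_is_flexible(self):
        v = u.porod_debye_verdict(syn.make_gaussian_chain_curve(20.0))
        assert v.flexible

    def test_equal_mixture_is_flexible(self):
        sph = syn.make_sphere_curve(20.0, i0=1.0)
        ch = syn.make_gaussian_chain_curve(20.0, i0=1.0)
        mix = ScatteringCurve(sph.q, 0.5 * sph.I + 0.5 * ch.I)
        assert u.porod_debye_verdict(mix).flexible

    def test_region_outside_data(self):
        short = syn.make_sphere_curve(20.0, qgrid=np.linspace(0.001, 0.05, 50))
        with pytest.raises(ValueError):
            u.porod_debye_verdict(short)


class TestChi2:
    def test_exact_multiple(self):
        c = syn.make_sphere_curve(18.0)
        exp = ScatteringCurve(c.q, 3.7 * c.I, np.ones_like(c.q))
        s, chi2 = chi2_with_scale(c, exp)
        assert s == pytest.approx(3.7, rel=1e-12)
        assert chi2 < 1e-12

    def test_gaussian_noise_gives_unit_chi2(self):
        c = syn.make_sphere_curve(18.0, i0=100.0)
        sig = 0.01 * c.I
        rng = np.random.default_rng(2)
        exp = ScatteringCurve(c.q, c.I + rng.normal(scale=sig), sig)
        _, chi2 = chi2_with_scale(c, exp)
        assert abs(chi2 - 1.0) < 3 / np.sqrt(len(c.q))

    @settings(deadline=None, max_examples=10)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scaled_self_is_perfect_fit(self, a):
        c = syn.make_sphere_curve(12.0, qgrid=np.linspace(0.01, 0.3, 60))
        exp = ScatteringCurve(c.q, a * c.I, 0.01 * a * c.I)
        s, chi2 = chi2_with_scale(c, exp)
        assert s == pytest.approx(a, rel=1e-9)
        assert chi2 < 1e-15

    def test_grid_mismatch_error(self):
        c = syn.make_sphere_curve(12.0, qgrid=np.linspace(0.05, 0.2, 30))
        exp = ScatteringCurve(np.linspace(0.01, 0.3, 30), np.ones(30), np.ones(30))
        with pytest.raises(ValueError):
            chi2_with_scale(c, exp)


def test_dat_round_trip(tmp_path):
    c = syn.make_sphere_curve(10.0, i0=5.0)
    curve = ScatteringCurve(c.q, c.I, 0.01 * c.I, label="sphere")
    path = tmp_path / "curve.dat"
    path.write_text(write_dat(curve))
    back = read_dat(str(path))
    assert np.allclose(back.q, curve.q, rtol=1e-5)
    assert np.allclose(back.I, curve.I, rtol=1e-5)
    assert np.allclose(back.sigma, curve.sigma, rtol=1e-5)
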