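"""Guinier, cross-section Rg, Porod volume and volume of correlation
against closed forms and coordinate-space oracles."""

import numpy as np
import pytest

from husaxs.invariants import (
    GuinierError,
    cross_section_rg,
    guinier_fit,
    normalize_pr,
    porod_volume,
    volume_of_correlation,
)
from husaxs.pddf import PDDF
from husaxs.profiles import ScatteringProfile

from conftest import sphere_intensity


@pytest.mark.parametrize("radius", [5.0, 10.0, 20.0, 50.0])
def test_guinier_rg_matches_sphere_closed_form(qgrid, radius):
    """Rg = √(3/5)·R for a uniform sphere, within 1 %."""
    prof = ScatteringProfile(qgrid, sphere_intensity(qgrid, radius))
    res = guinier_fit(prof)
    assert res.rg == pytest.approx(np.sqrt(3 / 5) * radius, rel=0.01)
    assert res.qmax_rg <= 1.3 * (1 + 1e-6)
    assert res.i0 == pytest.approx(1.0, rel=0.02)


def test_guinier_respects_qrg_limit_on_noisy_data(qgrid):
    from husaxs.synthetic import simulate_profile

    for seed in range(5):
        prof = simulate_profile(
            ScatteringProfile(qgrid, sphere_intensity(qgrid, 20.0)), 0.01, seed, qgrid)
        res = guinier_fit(prof)
        assert res.qmax_rg <= 1.3 * (1 + 1e-6)
        assert res.rg == pytest.approx(np.sqrt(3 / 5) * 20, rel=0.05)


def test_guinier_rg_of_duplex_matches_coordinate_rg(duplex, duplex_profile):
    """Reciprocal-space Rg of the 80 bp duplex vs brute-force bead Rg."""
    res = guinier_fit(duplex_profile)
    assert res.rg == pytest.approx(duplex.rg(), rel=0.02)


def test_guinier_fails_without_admissible_window():
    q = np.linspace(0.05, 0.3, 40)
    # steep decay: Rg so large that even 5 points violate qmax·Rg <= 1.3
    prof = ScatteringProfile(q, np.exp(-q ** 2 * 200 ** 2 / 3))
    with pytest.raises(GuinierError):
        guinier_fit(prof)


def test_cross_section_rg_of_cylinder_closed_form(qgrid):
    """Infinite cylinder of radius R: Rc = R/√2, within 3 %."""
    from scipy.special import j1

    radius = 10.0
    intensity = (1 / qgrid) * (2 * j1(qgrid * radius) / (qgrid * radius)) ** 2
    rc = cross_section_rg(ScatteringProfile(qgrid, intensity), (0.02, 0.10))
    assert rc == pytest.approx(radius / np.sqrt(2), rel=0.03)


def test_cross_section_rg_of_duplex_matches_coordinate_oracle(duplex, duplex_profile):
    """Rc of the duplex vs brute-force weighted radial spread about its axis.

    The window starts at q ≈ 4·(2π/L): below that the finite rod length
    still bends ln(qI) and the modified Guinier slope is biased.
    """
    w = duplex.weights / duplex.weights.sum()
    centre = w @ duplex.beads
    xy = duplex.beads[:, :2] - centre[:2]
    rc_coord = np.sqrt(np.sum(w * np.sum(xy ** 2, axis=1)))
    rc = cross_section_rg(duplex_profile, (0.05, 0.12))
    assert rc == pytest.approx(rc_coord, rel=0.05)


def test_cross_section_rg_rejects_non_rodlike_data(qgrid):
    flat = ScatteringProfile(qgrid, np.ones_like(qgrid))
    with pytest.raises(ValueError):
        cross_section_rg(flat, (0.05, 0.15))


def test_porod_volume_of_sphere(sphere20_profile):
    res = guinier_fit(sphere20_profile)
    vp = porod_volume(sphere20_profile, res)
    assert vp == pytest.approx(4 / 3 * np.pi * 20 ** 3, rel=0.10)


def test_porod_volume_of_duplex_vs_bead_sphere_sum(duplex, duplex_profile):
    """Vp within 25 % of the summed per-bead volumes (loose, documented).

    Each of the two beads per nucleotide is assigned half the nucleotide
    partial volume (~534 Å³), the standard crystallographic value.
    """
    vol_oracle = len(duplex) * 534.0 / 2.0
    vp = porod_volume(duplex_profile, guinier_fit(duplex_profile))
    assert vp == pytest.approx(vol_oracle, rel=0.25)


def test_invariants_are_scale_invariant(sphere20_profile, qgrid):
    scaled = ScatteringProfile(qgrid, 7.25 * sphere20_profile.intensity)
    g1, g2 = guinier_fit(sphere20_profile), guinier_fit(scaled)
    assert porod_volume(scaled, g2) == pytest.approx(porod_volume(sphere20_profile, g1), rel=1e-9)
    assert volume_of_correlation(scaled, g2) == pytest.approx(
        volume_of_correlation(sphere20_profile, g1), rel=1e-9)


def test_vc_matches_fine_grid_quadrature(sphere20_profile, qgrid):
    g = guinier_fit(sphere20_profile)
    vc = volume_of_correlation(sphere20_profile, g)
    qf = np.geomspace(qgrid[0], qgrid[-1], 10 * len(qgrid))
    head_q = np.linspace(0, qgrid[0], 513)
    head = np.trapezoid(head_q * g.i0 * np.exp(-(head_q * g.rg) ** 2 / 3), head_q)
    oracle = g.i0 / (head + np.trapezoid(qf * sphere_intensity(qf, 20.0), qf))
    assert vc == pytest.approx(oracle, rel=0.005)


def test_vc_truncation_sensitivity_is_small(qgrid):
    """Cutting the sphere curve at q = 0.35 Å⁻¹ moves Vc by < 5 %."""
    q_ext = np.geomspace(qgrid[0], 1.0, 1200)
    full = ScatteringProfile(q_ext, sphere_intensity(q_ext, 20.0))
    cut = full.slice(q_ext[0], 0.35)
    vc_full = volume_of_correlation(full, guinier_fit(full))
    vc_cut = volume_of_correlation(cut, guinier_fit(cut))
    assert abs(vc_cut / vc_full - 1) < 0.05


def test_normalize_pr_scales_to_vc_and_is_idempotent():
    r = np.linspace(0, 10, 101)
    p = np.where(r <= 10, 0.2 * np.ones_like(r), 0.0)   # integral 2
    pd = PDDF(r=r, p=p, dmax=10.0)
    out = normalize_pr(pd, 4.0)
    assert np.allclose(out.p, 2 * p)
    again = normalize_pr(out, 4.0)
    assert np.allclose(again.p, out.p)
    rng = np.random.default_rng(0)
    for _ in range(10):
        pr = PDDF(r=r, p=rng.uniform(0.0, 1.0, r.size), dmax=10.0)
        vc = float(rng.uniform(0.5, 50))
        assert np.trapezoid(normalize_pr(pr, vc).p, r) == pytest.approx(vc, rel=1e-6)
    with pytest.raises(ValueError):
        normalize_pr(PDDF(r=r, p=np.zeros_like(r), dmax=10.0), 4.0)
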