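"""Lamellar-stack Caillé intensity: structure/form factors, polydispersity
quadrature, and bounded fitting."""

import numpy as np
import pytest

from husaxs.lamellar import (
    LamellarFitError,
    LamellarModel,
    caille_structure_factor,
    fit_lamellar,
    lamellar_form_factor,
    lamellar_form_factor_headtail,
    lamellar_intensity,
)
from husaxs.profiles import ScatteringProfile
from husaxs.synthetic import default_qgrid, simulate_profile


def naive_caille(q, d, n_plates, eta):
    """Scalar double-loop oracle for S(q)."""
    out = []
    for qq in np.atleast_1d(q):
        s = 1.0
        for n in range(1, n_plates):
            damp = np.exp(-qq ** 2 * d ** 2 * eta
                          * (np.log(np.pi * n) + np.euler_gamma) / (4 * np.pi ** 2))
            s += 2.0 * (1 - n / n_plates) * np.cos(qq * d * n) * damp
        out.append(s)
    return np.array(out)


def test_single_plate_has_unit_structure_factor(qgrid):
    assert np.allclose(caille_structure_factor(qgrid, 60.0, 1, 0.3), 1.0)


@pytest.mark.parametrize("n_plates", [2, 5, 20, 40])
def test_ordered_stack_bragg_amplitude_equals_plate_count(n_plates):
    """At η = 0 and q* = 2π/d the sum telescopes to S = N exactly."""
    s = caille_structure_factor(np.array([2 * np.pi / 60.0]), 60.0, n_plates, 0.0)
    assert s[0] == pytest.approx(n_plates, abs=1e-9)


def test_vectorized_caille_matches_scalar_loop():
    rng = np.random.default_rng(17)
    for _ in range(5):
        q = rng.uniform(0.01, 0.4, 6)
        d = float(rng.uniform(20, 90))
        n = int(rng.integers(2, 9))
        eta = float(rng.uniform(0, 0.6))
        assert np.allclose(caille_structure_factor(q, d, n, eta),
                           naive_caille(q, d, n, eta), atol=1e-12)


def test_slab_form_factor_limits():
    q = np.array([1e-6])
    assert lamellar_form_factor(q, 20.0)[0] == pytest.approx(400.0, rel=1e-9)
    # first zero at q = 2π/δ
    assert lamellar_form_factor(np.array([2 * np.pi / 20.0]), 20.0)[0] == pytest.approx(0.0, abs=1e-12)


def test_headtail_with_equal_contrast_reduces_to_slab(qgrid):
    ht = lamellar_form_factor_headtail(qgrid, delta_head=4.0, delta_tail=6.0,
                                       rho_head=2.5, rho_tail=2.5)
    slab = 2.5 ** 2 * lamellar_form_factor(qgrid, 2 * (4.0 + 6.0))
    assert np.allclose(ht, slab, rtol=1e-12)


def test_intensity_composes_p_s_and_prefactor(qgrid):
    model = LamellarModel(d=60.0, delta=20.0, n_plates=10, eta=0.2,
                          scale=3.0, background=0.5)
    p = lamellar_form_factor(qgrid, 20.0)
    s = caille_structure_factor(qgrid, 60.0, 10, 0.2)
    expected = 3.0 * 2 * np.pi * p * s / (qgrid ** 2 * 20.0) + 0.5
    assert np.allclose(lamellar_intensity(qgrid, model).intensity, expected, rtol=1e-12)
    with pytest.raises(ValueError):
        lamellar_intensity(np.array([0.0, 0.1]), model)


def test_zero_polydispersity_equals_single_thickness(qgrid):
    a = LamellarModel(d=60.0, delta=20.0, n_plates=10, eta=0.1, poly_delta=0.0)
    b = LamellarModel(d=60.0, delta=20.0, n_plates=10, eta=0.1, poly_delta=1e-12)
    ia = lamellar_intensity(qgrid, a).intensity
    ib = lamellar_intensity(qgrid, b).intensity
    assert np.allclose(ia, ib, rtol=1e-6)


def test_polydispersity_quadrature_matches_monte_carlo(qgrid):
    """15-node ±2σ quadrature vs a 10⁵-sample seeded MC average (< 0.5 %)."""
    model = LamellarModel(d=60.0, delta=20.0, n_plates=10, eta=0.2, poly_delta=0.15)
    iq = lamellar_intensity(qgrid, model).intensity
    sigma = 0.15 * 20.0
    rng = np.random.default_rng(123)
    draws = rng.normal(20.0, sigma, 300_000)
    draws = draws[np.abs(draws - 20.0) <= 2 * sigma][:100_000]
    pavg = np.zeros_like(qgrid)
    for chunk in np.array_split(draws, 50):
        pavg += ((2 * np.sin(qgrid[:, None] * chunk[None, :] / 2) / qgrid[:, None]) ** 2).sum(axis=1)
    pavg /= len(draws)
    s = caille_structure_factor(qgrid, 60.0, 10, 0.2)
    imc = 2 * np.pi * pavg * s / (qgrid ** 2 * 20.0)
    assert np.max(np.abs(iq / imc - 1)) < 0.005


def test_model_invariants_enforced():
    with pytest.raises(ValueError):
        LamellarModel(d=60.0, delta=70.0)            # delta >= d
    with pytest.raises(ValueError):
        LamellarModel(d=60.0, eta=0.9)               # eta above Caille bound
    with pytest.raises(ValueError):
        LamellarModel(d=60.0, n_plates=0)
    with pytest.raises(ValueError):
        LamellarModel(d=60.0, poly_delta=0.7)


def test_bragg_amplitude_and_peak_width_monotone_in_eta():
    qstar = 2 * np.pi / 60.0
    amps = [caille_structure_factor(np.array([qstar]), 60.0, 20, e)[0]
            for e in (0.02, 0.1, 0.3, 0.5, 0.8)]
    assert all(np.diff(amps) < 0)

    def fwhm(eta):
        q = np.linspace(0.08, 0.13, 2001)
        i = lamellar_intensity(q, LamellarModel(d=60.0, delta=20.0, n_plates=20, eta=eta)).intensity
        y = i - np.interp(q, [q[0], q[-1]], [i[0], i[-1]])
        j = int(np.argmax(y))
        half = y[j] / 2
        left = q[:j][np.nonzero(y[:j] < half)[0][-1]]
        right = q[j:][np.nonzero(y[j:] < half)[0][0]]
        return right - left

    widths = [fwhm(e) for e in (0.02, 0.1, 0.3, 0.8)]
    assert all(np.diff(widths) > 0)


def test_self_fit_of_noiseless_curve_recovers_parameters():
    truth = LamellarModel(d=60.0, delta=20.0, n_plates=20, eta=0.1, poly_delta=0.05)
    prof = simulate_profile(truth, 0.0, 1)
    fit = fit_lamellar(prof, init=truth, n_grid=(20,))
    assert fit.reduced_chi2 < 1e-3
    assert fit.model.d == pytest.approx(60.0, rel=1e-3)
    assert fit.model.delta == pytest.approx(20.0, rel=1e-3)
    assert fit.model.eta == pytest.approx(0.1, rel=1e-3)


@pytest.mark.parametrize("d", [42.0, 60.0, 70.0])
def test_spacing_recovery_under_noise(d):
    """d recovered within 2 % for ≥ 18/20 seeds at 2 % noise."""
    hits = 0
    for seed in range(20):
        truth = LamellarModel(d=d, delta=20.0, n_plates=20, eta=0.1, poly_delta=0.05)
        prof = simulate_profile(truth, 0.02, 1000 + seed)
        fit = fit_lamellar(prof)
        hits += abs(fit.model.d / d - 1) <= 0.02
    assert hits >= 18


def test_eta_recovery_median_within_20_percent():
    recovered = []
    for seed in range(10):
        truth = LamellarModel(d=60.0, delta=20.0, n_plates=20, eta=0.2, poly_delta=0.05)
        prof = simulate_profile(truth, 0.01, 2000 + seed)
        recovered.append(fit_lamellar(prof).model.eta)
    assert abs(np.median(recovered) / 0.2 - 1) < 0.2


def test_eta_bound_respected_and_flagged(qgrid):
    """Data made with super-bound disorder pins the fit at η = 0.8."""
    s = caille_structure_factor(qgrid, 60.0, 20, 1.6)
    p = lamellar_form_factor(qgrid, 20.0)
    ideal = ScatteringProfile(qgrid, 2 * np.pi * p * s / (qgrid ** 2 * 20.0))
    prof = simulate_profile(ideal, 0.01, 9, qgrid)
    fit = fit_lamellar(prof, init=LamellarModel(d=60.0, delta=20.0, n_plates=20, eta=0.5),
                       n_grid=(20,))
    assert fit.model.eta <= 0.8
    assert fit.at_bound


def test_fit_requires_peak_or_init(qgrid):
    featureless = ScatteringProfile(qgrid, qgrid ** -1.0, 0.01 * qgrid ** -1.0)
    with pytest.raises(LamellarFitError):
        fit_lamellar(featureless)
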