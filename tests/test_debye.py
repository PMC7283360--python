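"""Debye-formula profiles, scale fitting and minimal-ensemble selection."""

import numpy as np
import pytest

from husaxs.debye import debye_intensity, fit_scale, minimal_ensemble
from husaxs.models import BuildSpec, build_pool
from husaxs.profiles import AtomisticModel, ScatteringProfile
from husaxs.synthetic import simulate_profile

from conftest import grid_sphere, sphere_intensity


def test_two_bead_closed_form():
    m = AtomisticModel(np.array([[0.0, 0, 0], [10.0, 0, 0]]), np.ones(2))
    q = np.linspace(0.01, 0.5, 100)
    i = debye_intensity(m, q).intensity
    expected = 2 + 2 * np.sin(10 * q) / (10 * q)
    assert np.allclose(i, expected, rtol=1e-12)
    # normalized form quoted as (2 + 2 sin(10q)/(10q))/4 relative to I(0)
    assert np.allclose(i / 4.0, expected / 4.0)


def test_low_q_limit_is_total_weight_squared():
    rng = np.random.default_rng(2)
    m = AtomisticModel(rng.uniform(-5, 5, (30, 3)), rng.uniform(0.5, 3.0, 30))
    i0 = debye_intensity(m, np.array([1e-6])).intensity[0]
    assert i0 == pytest.approx(m.weights.sum() ** 2, rel=1e-6)
    with pytest.raises(ValueError):
        debye_intensity(m, np.array([0.0, 0.1]))


def test_bead_sphere_matches_analytic_form_factor():
    """Grid-filled sphere vs [3(sin x − x cos x)/x³]² within 1 % to qR = 4."""
    model = grid_sphere(radius=20.0, spacing=1.5)
    q = np.linspace(0.01, 4 / 20.0, 30)
    i = debye_intensity(model, q).intensity / model.weights.sum() ** 2
    assert np.max(np.abs(i / sphere_intensity(q, 20.0) - 1)) < 0.01


def test_histogram_acceleration_agrees_with_exact_sum(qgrid):
    from husaxs.synthetic import filament_model

    m = filament_model()
    exact = debye_intensity(m, qgrid, exact=True).intensity
    hist = debye_intensity(m, qgrid, exact=False).intensity
    assert np.max(np.abs(hist / exact - 1)) < 0.003


def test_fit_scale_exact_linear_recovery(duplex_profile, qgrid):
    data = ScatteringProfile(qgrid, 3.5 * duplex_profile.intensity + 0.1,
                             np.ones_like(qgrid))
    scale, background, chi = fit_scale(duplex_profile, data)
    assert scale == pytest.approx(3.5, rel=1e-9)
    assert background == pytest.approx(0.1, rel=1e-4)
    assert chi < 1e-6


def test_fit_scale_chi_near_unity_for_unit_noise(duplex_profile, qgrid):
    chis = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        data = ScatteringProfile(qgrid, duplex_profile.intensity + rng.normal(0, 1, len(qgrid)),
                                 np.ones_like(qgrid))
        chis.append(fit_scale(duplex_profile, data)[2])
    assert np.mean(chis) == pytest.approx(1.0, abs=0.15)


def test_fit_scale_sigma_rescaling_identity(duplex_profile, qgrid):
    rng = np.random.default_rng(6)
    data = ScatteringProfile(qgrid,
                             2.0 * duplex_profile.intensity + 5.0 + rng.normal(0, 1, len(qgrid)),
                             np.full(len(qgrid), 1.0))
    s1, _, chi1 = fit_scale(duplex_profile, data)
    data2 = ScatteringProfile(qgrid, data.intensity, np.full(len(qgrid), 3.0))
    s2, _, chi2 = fit_scale(duplex_profile, data2)
    assert s2 == pytest.approx(s1, rel=1e-9)
    assert chi2 == pytest.approx(chi1 / 3.0, rel=1e-6, abs=1e-9)


def test_fit_scale_needs_overlap(duplex_profile):
    q = np.linspace(0.5, 0.6, 20)
    far = ScatteringProfile(q, np.ones(20), np.ones(20))
    with pytest.raises(ValueError):
        fit_scale(duplex_profile, far)


@pytest.fixture(scope="module")
def hu_pool_profiles(qgrid):
    pool = build_pool(BuildSpec(n_bp=80), [0, 2, 4, 8])
    return [debye_intensity(m, qgrid) for m in pool]


def test_ensemble_identity_member(hu_pool_profiles, qgrid):
    data = simulate_profile(
        ScatteringProfile(qgrid, hu_pool_profiles[2].intensity), 0.005, 3, qgrid)
    ens = minimal_ensemble(hu_pool_profiles, data)
    assert ens.size == 1
    assert ens.member_ids == [2]
    assert ens.weights[0] == pytest.approx(1.0)
    assert ens.chi < 1.5


def test_single_member_pool(hu_pool_profiles, qgrid):
    data = ScatteringProfile(qgrid, hu_pool_profiles[0].intensity,
                             0.01 * hu_pool_profiles[0].intensity)
    ens = minimal_ensemble(hu_pool_profiles[:1], data)
    assert ens.size == 1 and ens.weights[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        minimal_ensemble([], data)


def test_two_state_mixture_recovery(hu_pool_profiles, qgrid):
    """50/50 mixture of bare and saturated duplex recovered within ±0.1."""
    mix = ScatteringProfile(qgrid, 0.5 * hu_pool_profiles[0].intensity
                            + 0.5 * hu_pool_profiles[3].intensity)
    data = simulate_profile(mix, 0.01, 5, qgrid)
    ens = minimal_ensemble(hu_pool_profiles, data)
    assert ens.size == 2
    assert sorted(ens.member_ids) == [0, 3]
    for w in ens.weights:
        assert w == pytest.approx(0.5, abs=0.1)
    assert ens.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_three_state_mixture_recovery_median(hu_pool_profiles, qgrid):
    truth = np.array([0.5, 0.3, 0.2])
    members = [0, 1, 3]
    mix = ScatteringProfile(qgrid, sum(t * hu_pool_profiles[j].intensity
                                       for t, j in zip(truth, members)))
    errs = {j: [] for j in members}
    for seed in range(20):
        data = simulate_profile(mix, 0.01, 300 + seed, qgrid)
        ens = minimal_ensemble(hu_pool_profiles, data, max_size=3)
        got = dict(zip(ens.member_ids, ens.weights))
        for t, j in zip(truth, members):
            errs[j].append(got.get(j, 0.0) - t)
    for j in members:
        assert abs(np.median(errs[j])) <= 0.1


def test_chi_by_size_is_monotone(hu_pool_profiles, qgrid):
    mix = ScatteringProfile(qgrid, 0.6 * hu_pool_profiles[1].intensity
                            + 0.4 * hu_pool_profiles[2].intensity)
    data = simulate_profile(mix, 0.01, 8, qgrid)
    ens = minimal_ensemble(hu_pool_profiles, data, max_size=3)
    chis = [ens.chi_by_size[s] for s in sorted(ens.chi_by_size)]
    assert all(b <= a * (1 + 1e-12) for a, b in zip(chis, chis[1:]))
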