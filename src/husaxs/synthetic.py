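"""Seeded synthetic SAXS profiles and the registered phase-diagram scenarios.

Profiles are generated on the instrument q-range 0.01–0.35 Å⁻¹ (400
log-spaced points) from either a lamellar Caillé model or a coarse bead
model via the Debye sum. Gaussian noise is intensity-proportional with
a signal-to-noise ratio that degrades towards high q:

    σ(q) = noise_frac · I(q) · (1 + 2 q/qmax)

Each registered scenario names one pH × NaCl condition of the HUαα (or
E34K mutant) + 80 bp DNA titration and carries its expected phase label,
lamellar spacing where applicable, and a fixed seed — so the whole
phase diagram is reproducible without any downloaded data. Lamellar
scenarios use shared nuisance parameters (N = 20 plates, η = 0.1,
δ = 20 Å, 5 % thickness polydispersity, 1 % noise); filament scenarios
use a saturated HU-coated 80 bp duplex; aggregate scenarios use a
featureless steep q⁻³·⁵ decay.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .debye import debye_intensity
from .lamellar import LamellarModel, lamellar_intensity
from .models import BuildSpec, build_bdna, place_hu
from .profiles import AtomisticModel, ScatteringProfile

__all__ = ["Scenario", "simulate_profile", "scenario_profile", "scenario_names",
           "default_qgrid", "SIGMA_FLOOR_FRAC"]

Q_MIN, Q_MAX, N_Q = 0.01, 0.35, 400
SIGMA_FLOOR_FRAC = 1e-9   # σ floor (× max I) for noise-free curves, keeps χ defined


def default_qgrid() -> np.ndarray:
    """Instrument q-grid: 400 log-spaced points over 0.01–0.35 Å⁻¹."""
    return np.geomspace(Q_MIN, Q_MAX, N_Q)


@dataclass
class Scenario:
    """Ground truth of one registered condition."""

    name: str
    expected_label: str             # lamellar | filament | aggregate
    kind: str                       # generator: lamellar | filament | aggregate
    d: float | None                 # repeat spacing, Å (lamellar only)
    noise_frac: float
    seed: int

    def __post_init__(self) -> None:
        if self.expected_label not in {"lamellar", "filament", "aggregate"}:
            raise ValueError(f"bad expected_label {self.expected_label}")
        if self.expected_label == "lamellar" and self.d is None:
            raise ValueError("lamellar scenarios must carry a spacing d")


@lru_cache(maxsize=1)
def _registry() -> dict:
    with resources.files("husaxs.data").joinpath("scenarios.toml").open("rb") as fh:
        return tomllib.load(fh)


def scenario_names() -> list[str]:
    return sorted(_registry()["scenarios"].keys())


def simulate_profile(source, noise_frac: float = 0.01, seed: int = 0,
                     qgrid: np.ndarray | None = None) -> ScatteringProfile:
    """Noisy synthetic profile from a lamellar model or a bead model.

    Fully reproducible per seed; ``noise_frac = 0`` returns the exact
    model curve with a tiny σ floor.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    q = default_qgrid() if qgrid is None else np.asarray(qgrid, dtype=float)
    if isinstance(source, LamellarModel):
        ideal = lamellar_intensity(q, source).intensity
    elif isinstance(source, AtomisticModel):
        ideal = debye_intensity(source, q).intensity
    elif isinstance(source, ScatteringProfile):
        if not np.array_equal(source.q, q):
            raise ValueError("ideal profile must live on the requested q grid")
        ideal = source.intensity
    else:
        raise TypeError(f"cannot simulate from {type(source).__name__}")
    floor = SIGMA_FLOOR_FRAC * float(np.max(np.abs(ideal)))
    sigma = np.maximum(noise_frac * np.abs(ideal) * (1.0 + 2.0 * q / q[-1]), floor)
    if noise_frac == 0:
        return ScatteringProfile(q, ideal.copy(), sigma)
    rng = np.random.default_rng(seed)
    noisy = ideal + rng.normal(0.0, 1.0, size=q.size) * sigma
    return ScatteringProfile(q, noisy, sigma)


@lru_cache(maxsize=4)
def _filament_ideal_cached(n_q: int) -> tuple:
    """Ideal Debye curve of the saturated HU-coated 80 bp duplex (cached)."""
    model = place_hu(build_bdna(BuildSpec(n_bp=80)), mode="saturated")
    q = default_qgrid()[:n_q] if n_q != N_Q else default_qgrid()
    prof = debye_intensity(model, q)
    return tuple(prof.q), tuple(prof.intensity)


def filament_model() -> AtomisticModel:
    """The saturated HU-coated 80 bp duplex behind the filament scenarios."""
    return place_hu(build_bdna(BuildSpec(n_bp=80)), mode="saturated")


def _scenario_from_entry(name: str, entry: dict, defaults: dict) -> Scenario:
    return Scenario(
        name=name,
        expected_label=entry["expected_label"],
        kind=entry["kind"],
        d=entry.get("d_A"),
        noise_frac=entry.get("noise_frac", defaults["noise_frac"]),
        seed=int(entry["seed"]),
    )


def get_scenario(name: str) -> Scenario:
    reg = _registry()
    if name not in reg["scenarios"]:
        raise KeyError(f"unknown scenario {name!r}; registered: {', '.join(scenario_names())}")
    return _scenario_from_entry(name, reg["scenarios"][name], reg["defaults"])


def scenario_profile(name: str, seed: int | None = None,
                     noise_frac: float | None = None) -> tuple[ScatteringProfile, Scenario]:
    """Generate a registered scenario at its registered seed.

    ``seed``/``noise_frac`` override the registry for reproducibility
    studies. Returns (profile, ground-truth scenario).
    """
    reg = _registry()
    sc = get_scenario(name)
    defaults = reg["defaults"]
    use_seed = sc.seed if seed is None else int(seed)
    use_noise = sc.noise_frac if noise_frac is None else float(noise_frac)
    q = default_qgrid()

    if sc.kind == "lamellar":
        model = LamellarModel(d=float(sc.d), delta=defaults["delta_A"],
                              n_plates=int(defaults["n_plates"]), eta=defaults["eta"],
                              poly_delta=defaults["poly_delta"])
        prof = simulate_profile(model, use_noise, use_seed, q)
    elif sc.kind == "filament":
        qi, ii = _filament_ideal_cached(N_Q)
        ideal = ScatteringProfile(np.array(qi), np.array(ii))
        prof = simulate_profile(ideal, use_noise, use_seed, q)
    elif sc.kind == "aggregate":
        expo = defaults["aggregate_exponent"]
        ideal = ScatteringProfile(q, (q / q[0]) ** expo)
        prof = simulate_profile(ideal, use_noise, use_seed, q)
    else:
        raise ValueError(f"unknown scenario kind {sc.kind!r}")
    prof.condition = name
    return prof, sc
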