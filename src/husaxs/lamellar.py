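"""Lamellar-stack intensity with Caillé structure factor, and its fitting.

DNA duplexes glued into parallel sheets by HU dimers scatter like a
random lamellar phase: the 1D intensity is

    I(q) = 2π · P(q) · S(q) / (q² δ)

with P(q) the sheet form factor (by default a uniform slab of total
thickness δ), and S(q) the Caillé structure factor of a finite stack of
N plates with repeat spacing d and dimensionless undulation/compression
disorder η (larger η damps and broadens the Bragg peaks):

    S(q) = 1 + 2 Σ_{n=1}^{N-1} (1 - n/N) cos(q d n)
               · exp(-q² d² η [ln(πn) + γ_E] / (4π²))

γ_E is the Euler–Mascheroni constant. At η = 0 and the Bragg condition
q* = 2π/d the sum telescopes to S(q*) = N exactly — this identity pins
the exponent convention and is unit-tested.

Polydispersity in the layer thickness δ (relative Gaussian width
``poly_delta``) is averaged over the form factor by Gaussian quadrature
truncated at ±2σ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .profiles import ScatteringProfile

__all__ = [
    "LamellarModel",
    "caille_structure_factor",
    "lamellar_form_factor",
    "lamellar_form_factor_headtail",
    "lamellar_intensity",
    "fit_lamellar",
    "LamellarFitError",
]

ETA_MAX = 0.8  # fits pinning eta here are flagged "at-bound"


class LamellarFitError(RuntimeError):
    """Raised when the lamellar fit cannot be initialized or fails to converge."""


@dataclass
class LamellarModel:
    """Parameters of the lamellar-stack Caillé intensity.

    d : repeat spacing (Å) — the real-space period of the Bragg peaks,
        i.e. the inter-duplex DNA spacing in an HU–DNA bundle.
    delta : total layer thickness δ (Å), 0 < δ < d.
    n_plates : number of lamellar plates N in the stack.
    eta : Caillé disorder parameter, 0 < η ≤ 0.8.
    poly_delta : relative Gaussian polydispersity of δ, in [0, 0.5].
    scale, background : overall intensity scale and flat background.
    """

    d: float
    delta: float = 20.0
    n_plates: int = 20
    eta: float = 0.1
    poly_delta: float = 0.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not (0 < self.delta < self.d):
            raise ValueError("layer thickness delta must satisfy 0 < delta < d")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if not (0 < self.eta <= ETA_MAX):
            raise ValueError(f"Caille parameter eta must be in (0, {ETA_MAX}]")
        if not (0 <= self.poly_delta <= 0.5):
            raise ValueError("poly_delta must be in [0, 0.5]")


def caille_structure_factor(q, d: float, n_plates: int, eta: float) -> np.ndarray:
    """Caillé structure factor S(q) of a finite stack of ``n_plates`` layers."""
    if d <= 0:
        raise ValueError("d must be positive")
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    q = np.asarray(q, dtype=float)
    s = np.ones_like(q)
    if n_plates == 1:
        return s
    n = np.arange(1, n_plates)                       # (N-1,)
    damp = eta * (np.log(np.pi * n) + np.euler_gamma) / (4 * np.pi ** 2)
    qd = np.outer(q, d * n)                          # (M, N-1)
    terms = (1.0 - n / n_plates) * np.cos(qd) * np.exp(-np.outer(q ** 2 * d ** 2, damp))
    return s + 2.0 * terms.sum(axis=1)


def lamellar_form_factor(q, delta: float) -> np.ndarray:
    """Uniform-slab form factor P(q) = [2 sin(qδ/2)/q]²; P(0⁺) → δ²."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    q = np.asarray(q, dtype=float)
    return (2.0 * np.sin(q * delta / 2.0) / q) ** 2


def lamellar_form_factor_headtail(q, delta_head: float, delta_tail: float,
                                  rho_head: float = 1.0, rho_tail: float = 1.0) -> np.ndarray:
    """Symmetric head/tail/tail/head sheet form factor.

    The sheet is an inner tail region of half-thickness ``delta_tail``
    flanked by head layers of thickness ``delta_head`` on each side
    (total thickness 2(δ_tail + δ_head)); ``rho_*`` are the two
    contrasts. With equal contrasts this reduces algebraically to the
    uniform slab of the total thickness.
    """
    if delta_head < 0 or delta_tail <= 0:
        raise ValueError("thicknesses must be positive")
    q = np.asarray(q, dtype=float)
    amp = (2.0 / q) * (rho_tail * np.sin(q * delta_tail)
                       + rho_head * (np.sin(q * (delta_tail + delta_head)) - np.sin(q * delta_tail)))
    return amp ** 2


def _poly_nodes(delta: float, poly_delta: float, n_nodes: int = 15):
    """Gaussian-quadrature nodes/weights for δ-polydispersity, truncated ±2σ."""
    if poly_delta <= 0:
        return np.array([delta]), np.array([1.0])
    sigma = poly_delta * delta
    x, w = np.polynomial.legendre.leggauss(n_nodes)   # on [-1, 1]
    t = 2.0 * sigma * x                               # on [-2σ, 2σ]
    pdf = np.exp(-0.5 * (t / sigma) ** 2)
    wts = w * pdf
    wts /= wts.sum()
    nodes = np.maximum(delta + t, 1e-6)
    return nodes, wts


def lamellar_intensity(q, model: LamellarModel) -> ScatteringProfile:
    """Evaluate I(q) = scale·2π·⟨P(q)⟩·S(q)/(q²δ) + background."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive (q=0 is singular)")
    nodes, wts = _poly_nodes(model.delta, model.poly_delta)
    pavg = np.zeros_like(q)
    for dl, w in zip(nodes, wts):
        pavg += w * lamellar_form_factor(q, dl)
    s = caille_structure_factor(q, model.d, model.n_plates, model.eta)
    i = model.scale * 2.0 * np.pi * pavg * s / (q ** 2 * model.delta) + model.background
    return ScatteringProfile(q, i, None, f"lamellar d={model.d:g}A")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_N_GRID_DEFAULT = (5, 10, 20, 40)


def _eval_intensity(q, d, delta, eta, poly, scale, bg, n_plates):
    m = LamellarModel(d=d, delta=delta, n_plates=n_plates,
                      eta=min(max(eta, 1e-6), ETA_MAX), poly_delta=min(max(poly, 0.0), 0.5),
                      scale=1.0, background=0.0)
    return scale * lamellar_intensity(q, m).intensity + bg


def fit_lamellar(profile: ScatteringProfile, init: LamellarModel | None = None,
                 n_grid=_N_GRID_DEFAULT):
    """Bounded weighted least-squares fit of the lamellar Caillé model.

    d, δ (as a fraction of d, keeping δ < d), η (bounded at 0.8),
    poly_delta, scale and background are optimized continuously; the
    plate count N is scanned on a small integer grid (its χ² dependence
    is shallow). When ``init`` is absent, d is initialized from the
    first detected Bragg peak.

    Returns ``(LamellarFit)`` carrying the best model, reduced χ², the
    per-N χ² map and an ``at_bound`` flag set when η pins at its upper
    bound.
    """
    from .phase import detect_peaks  # deferred: phase imports lamellar-free modules

    prof = profile.with_default_sigma()
    q, y, sig = prof.q, prof.intensity, prof.sigma

    if init is not None:
        d0, delta0 = init.d, init.delta
        eta0, poly0 = init.eta, init.poly_delta
        n_grid = tuple(sorted(set(list(n_grid) + [init.n_plates])))
    else:
        peaks = detect_peaks(profile)
        if not peaks:
            raise LamellarFitError("no Bragg peak detected and no initial model given")
        d0 = 2.0 * np.pi / peaks[0][0]
        delta0, eta0, poly0 = min(20.0, 0.45 * d0), 0.1, 0.05

    f0 = min(max(delta0 / d0, 0.06), 0.9)

    def residuals(x, n_plates):
        d, f, eta, poly, logscale, bg = x
        model_i = _eval_intensity(q, d, f * d, eta, poly, np.exp(logscale), bg, n_plates)
        return (model_i - y) / sig

    # initial scale: ratio of intensities at low q with unit-scale model
    base = _eval_intensity(q, d0, f0 * d0, eta0, poly0, 1.0, 0.0, n_grid[0])
    scale0 = max(float(np.median(y / np.maximum(base, 1e-300))), 1e-12)

    lo = [0.5 * d0, 0.05, 1e-4, 0.0, np.log(scale0) - 12.0, 0.0]
    hi = [1.5 * d0, 0.92, ETA_MAX, 0.5, np.log(scale0) + 12.0, max(1e-12, 10.0 * float(np.min(np.abs(y))))]
    x0 = [d0, f0, eta0, poly0, np.log(scale0), 0.0]
    x0 = [min(max(v, l), h) for v, l, h in zip(x0, lo, hi)]

    best = None
    chi2_by_n = {}
    for n_plates in n_grid:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), args=(n_plates,),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            raise LamellarFitError(f"optimizer failed for N={n_plates}: {exc}") from exc
        dof = max(len(q) - len(x0), 1)
        chi2 = float(np.sum(sol.fun ** 2) / dof)
        chi2_by_n[n_plates] = chi2
        if best is None or chi2 < best[0]:
            best = (chi2, n_plates, sol.x)

    chi2, n_plates, x = best
    d, f, eta, poly, logscale, bg = x
    model = LamellarModel(d=float(d), delta=float(f * d), n_plates=int(n_plates),
                          eta=float(min(max(eta, 1e-6), ETA_MAX)), poly_delta=float(poly),
                          scale=float(np.exp(logscale)), background=float(bg))
    return LamellarFit(model=model, reduced_chi2=chi2, chi2_by_n=chi2_by_n,
                       at_bound=bool(eta >= ETA_MAX - 1e-3))


@dataclass
class LamellarFit:
    model: LamellarModel
    reduced_chi2: float
    chi2_by_n: dict
    at_bound: bool

    def as_dict(self) -> dict:
        m = self.model
        return {
            "d_A": m.d, "delta_A": m.delta, "n_plates": m.n_plates,
            "eta": m.eta, "poly_delta": m.poly_delta,
            "scale": m.scale, "background": m.background,
            "reduced_chi2": self.reduced_chi2,
            "eta_at_bound": self.at_bound,
            "chi2_by_n": {str(k): v for k, v in self.chi2_by_n.items()},
        }
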