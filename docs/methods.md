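# Methods

`husaxs` re-implements, as a tested pipeline, the solution small-angle
X-ray scattering (SAXS) analysis used to characterize how the bacterial
nucleoid-associated protein HU organizes DNA: at acidic pH and
low-to-physiological ionic strength, HUαα dimers glue parallel 80 bp
DNA duplexes into lamellar bundles with a well-defined inter-duplex
repeat (42–70 Å, read off Bragg peaks); at higher pH or salt the bundles
dissolve into HU-coated single-duplex filaments (rod-like q⁻¹
scattering, no peaks); the charge-reversed mutant HUα(E34K) aggregates
at acidic pH. Everything below is computed by the package itself; no
deposited data are required.

## Scattering conventions

Momentum transfer q = 4π sin θ/λ is in Å⁻¹ everywhere (a `nm_inverse`
read flag divides foreign nm⁻¹ grids by 10). Profiles are the de facto
beamline format: whitespace 3-column ASCII (q, I, σ) with `#` comments.
Two-column files are assigned σ = 1 % of I (logged) so that χ-based
fitting stays defined. The synthetic instrument grid is 400 log-spaced
points over 0.01–0.35 Å⁻¹.

## Shape invariants

* **Guinier fit** (`guinier_fit`): ln I = ln I(0) − q²Rg²/3, automatic
  window starting at the 3rd point (beamstop guard). The window end is
  found by fixed-point iteration on the self-consistency condition
  qmax·Rg ≤ 1.3 (the customary validity limit): fit, recompute the
  largest admissible qmax, refit until stable. A greedy expansion gated
  on a running R² threshold was tried first and discarded: with noisy
  data a five-point window fits noise, R² collapses immediately and the
  window never grows. R² ≥ 0.99 instead flags linearity
  (`linear=False` is the aggregation screen). Because the straight
  Guinier line fitted out to qRg ≈ 1.3 overestimates a sphere's Rg by
  1.5–2 % (the q⁴ term of ln I), the reported Rg is refined by a
  quadratic fit in q² on the same window, whose linear coefficient is
  the unbiased −Rg²/3; residual bias on analytic spheres is ≈ 0.1 %.
* **Cross-section Rg** (`cross_section_rg`): rod-regime slope of
  ln(qI) vs q², Rc² = −2·slope; raises when the slope is non-negative
  (not rod-like). The window must sit past the overall-Guinier region
  *and* past the finite-length rollover — for a ~270 Å rod that means
  q ≳ 0.05 Å⁻¹; at q = 0.03 the modified Guinier plot still bends and
  Rc comes out ~17 % low.
* **Porod volume** Vp = 2π² I(0)/Q, Q = ∫q²I dq. Q combines (i) the
  analytic Guinier extension from 0 to qmin, (ii) the trapezoidal data
  integral after subtracting a flat background, and (iii) the analytic
  Porod tail K/qmax beyond the data. The tail matters: for a 20 Å-radius
  sphere truncated at 0.35 Å⁻¹ it carries ~14 % of Q, and omitting it
  pushes Vp outside any honest tolerance. B comes from a joint
  I ≈ K/q⁴ + B fit over the top quartile of q (a top-decile fit is
  ill-conditioned — 1/q⁴ barely varies there); K is then the top-decile
  mean of q⁴(I−B), robust to oscillations around the Porod plateau.
* **Volume of correlation** Vc = I(0)/∫qI dq with the same Guinier
  extension; no tail (the integrand decays fast enough that truncation
  at 0.35 Å⁻¹ moves Vc by < 5 %). P(r) normalization to Vc
  (`normalize_pr`) rescales to ∫P dr = Vc and is idempotent.

All invariants are invariant under intensity rescaling by construction.

## Phase classification

`fit_power_law` is a σ-weighted linear regression of log I on log q.
The classifier window is the lowest decade of q, capped at 0.6× the
first diffraction peak (or at 0.03 Å⁻¹ when there is none).

`detect_peaks` flattens the curve with a robust (positive-outlier
clipped) power-law baseline in log–log space, smooths with an 11-point
cubic Savitzky–Golay filter, and keeps local maxima that pass four
filters: prominence ≥ 3× the MAD-derived residual noise; an absolute
prominence floor of 0.3 log units ("distinct" peaks only); fractional
FWHM ≤ 0.9 in ln q — Bragg peaks of these stacks are ≲ 0.3 wide while
the rod form-factor hump of a filament curve is ≈ 2 and must not count
as diffraction; and relative prominence ≥ 0.5× the strongest peak,
which removes the Laue finite-stack fringes below the first Bragg peak
(prominence up to ~3.5 vs ~7.5 for the peak itself). Reflections past
the strongest peak (higher orders) are kept down to the absolute floor
and reported without indexing. Positions are refined by parabolic
interpolation; spacings are d = 2π/q*.

Labels: **lamellar** = ≥ 1 peak AND low-q exponent ≤ −1.6; **filament**
= no peak and exponent in [−1.4, −0.6]; **aggregate** = no peak and
exponent ≤ −3.0; otherwise **ambiguous**. The peak-primary design
follows the experimental discriminator (aggregation is a steep decay
*without* diffraction peaks). A two-sided lamellar band around −2 was
deliberately not used: a finite Caillé stack genuinely suppresses its
inter-peak intensity below the ideal q⁻² sheet law (correlation hole
plus Laue fringing), so the measured low-q exponent of the d = 42 Å
synthetic condition is ≈ −3.1 even though the phase is lamellar. The
ideal sheet law I ∝ q⁻² is the model's true q → 0 limit, reached for
q ≪ 1/(N·d); the acceptance check of the −2 exponent is made there.
All thresholds live in `ClassifyConfig`.

## Lamellar-stack Caillé model

I(q) = scale · 2π ⟨P(q)⟩ S(q)/(q²δ) + background, with the uniform-slab
form factor P(q) = [2 sin(qδ/2)/q]² by default (a symmetric
head/tail/tail/head variant with two contrasts is provided; with equal
contrasts it reduces algebraically to the slab, which is the fitting
default because no head/tail split is constrained by 1D data at this
resolution). The structure factor follows the standard finite-stack
Caillé form

S(q) = 1 + 2 Σ_{n=1}^{N−1} (1 − n/N) cos(qdn)
        exp(−q²d²η [ln(πn) + γ_E]/(4π²)),

pinned by the exact identity S(2π/d) = N at η = 0 and unit-tested
against a scalar double loop. η ≤ 0.8 (beyond that the Bragg peaks are
essentially washed out and the parameterization loses meaning); fits
that pin η at 0.8 are flagged `at_bound`. Thickness polydispersity is
Gaussian in δ only (not d), averaged over P(q) by 15-node Gauss–
Legendre quadrature truncated at ±2σ (matches a 10⁵-sample Monte Carlo
average to < 0.5 %).

`fit_lamellar` is bounded weighted least squares over (d, δ/d, η,
poly_δ, log scale, background) with the plate count N scanned on the
integer grid {5, 10, 20, 40} (its χ² dependence is shallow); δ is
parameterized as a fraction of d so δ < d is a box bound; d is
initialized from the first detected Bragg peak when no initial model is
given. Under 2 % noise the spacing is recovered within 2 % for 20/20
seeds at d ∈ {42, 60, 70} Å and the η median is within a few percent of
truth.

## Real-space analysis

`pr_from_model` histograms all w_i w_j-weighted pairwise bead distances
(200 bins centred on an equally spaced grid, unit integral); Dmax is
the exact maximum pairwise distance. The self-correlation (i = j) mass
that a distinct-pair histogram omits is carried as a separate
`self_fraction` and enters only the Rg second moment
Rg² = ∫r²P dr / (2(1 + s)∫P dr), making the relation exact down to a
two-bead system while changing nothing (< 0.1 %) for realistic models.

`ift` solves the linear model I(q) = 4π ∫ P(r) sinc(qr) dr on a
101-point r grid with P(0) = P(Dmax) = 0 and a second-difference
roughness penalty; α is picked at the maximum-curvature knee of the
(log χ², log roughness) L-curve over 20 log-spaced values.
Non-negativity is optional (`nonneg=True`, via NNLS) and off by
default — coarse protein–DNA contrast can legitimately produce small
negative lobes. When Dmax is not given, a scan over 2–6× the Guinier
Rg keeps the smallest Dmax whose χ² is within 2 % of anything larger,
then refines locally. The scan is reliable for globular scatterers
(sphere: Dmax within 4 %) but soft for rods, whose low-q data barely
constrain Dmax — for rod-like samples pass Dmax explicitly (the
numbered analyses do).

`shoulder_positions` reports secondary P(r) features: local maxima
besides the global one, and bumps of the smoothed first derivative past
the global maximum (held to a stiffer prominence floor — derivatives
are noisier). P(r) is pre-smoothed with a Gaussian of 2 % of Dmax:
coordinate histograms of helical bead models carry a comb at the 3.4 Å
rise that q ≤ 0.35 Å⁻¹ data cannot encode and that would otherwise
swamp the derivatives. The sparse-decoration signature (two HU dimers
22 bp ≈ 75 Å apart) shows up as a feature at ~71 Å.

## Coarse models and Debye scattering

B-DNA duplexes use two beads per nucleotide — backbone bead on the
9.4 Å phosphate track, base bead at 0.4 of that radius — two
antiparallel strands 154° apart in phase, 3.4 Å rise and 36° twist per
bp; weights are relative electron counts (backbone 95, base 65, H
ignored). The 80 bp duplex then spans 269 Å maximal dimension — the
~270 Å filament length scale. HU dimers are 20-bead blobs filling a
45×35×30 Å ellipsoid proxy (Rg ≈ 14 Å; no solution structure of the
dimer is assumed beyond its overall size), centred 12 Å off the helix
axis on a fixed lab azimuth (so explicit centre distances are exactly
Δbp × rise); placement modes are uniform, saturated (one per 9 bp,
giving 8 per 80 bp) and explicit. Bundles are rectangular n×m lattices
of duplex copies; a 3×3 lattice at 60 Å already shows its interference
peak within 2 % of the lattice spacing. Sequence-dependent geometry,
HU arm atoms and the true crystal packing are out of scope.

`debye_intensity` evaluates I(q) = ΣΣ w_i w_j sinc(q r_ij) in vacuum —
no excluded volume or hydration shell, which would be meaningless for
coarse beads; this is the main fidelity gap against atomistic SAXS
predictors and is acceptable here because only nm-scale observables
(spacings, lengths, decay exponents) are interpreted. Models over 500
beads use a 0.5 Å pair-distance histogram evaluated at per-bin weighted
mean distances (within 0.3 % of the exact double sum). Model-to-data
matching (`fit_scale`) is weighted linear least squares for (scale,
background) with χ = √[(1/M)Σ((I − cI_m − b)/σ)²] — the plain reduced-χ
convention, fixed here once since tool conventions differ.
`minimal_ensemble` scores all subsets up to `max_size` (exhaustive for
pools ≤ 15, greedy forward selection beyond) by non-negative least
squares with a free background, renormalizes weights to 1, and keeps
the smallest size whose χ is within 5 % of the next size — the
parsimony rule that implements "smallest ensemble that still fits".

## Synthetic data

σ(q) = noise_frac · I(q) · (1 + 2q/qmax), i.e. the signal-to-noise
degrades threefold across the detector, with Gaussian perturbations
from a per-call seed; noise_frac = 0 returns the exact curve with a
tiny σ floor. The 15 registered scenarios encode the phase diagram:
pH 4.5 × {50, 100, 150 mM} lamellar d = 42 Å and 300 mM filament;
pH 5.5 × {50 → 60 Å, 100 → 70 Å, 150 → 42 Å, 300 mM filament};
pH 6.5 × {50 mM → 60 Å, 150/300 mM filament}; pH 7.5 × 50 mM → 60 Å;
E34K at pH 4.5/5.5 aggregate and pH 6.5 filament. The higher-salt
pH 7.5 and E34K pH 7.5 filaments are not separately registered — their
scattering is identical to the pH 6.5 counterparts. Lamellar nuisance
parameters are shared (N = 20, η = 0.1, δ = 20 Å, 5 % δ-polydispersity,
1 % noise): the experiments constrain only the spacing and the label.
Filament scenarios use the Debye curve of the saturated HU-coated
80 bp duplex; aggregates are a phenomenological q⁻³·⁵ decay (the
aggregating samples show only featureless steep curves). What passing
tests show is that the *analysis* recovers what the generator put in;
the generator does not emulate buffer-subtraction residuals, smearing,
inter-frame drift or coexisting-phase mixtures, so real-data behaviour
on those axes is untested.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`). The test suite runs the full
parameter-recovery studies at the sizes quoted above (20 seeds × 3
spacings, 100 classification replicates × 15 scenarios, 10⁵-sample MC
oracle) in about 80 s on one CPU; `scripts/acceptance.py` regenerates
its four quantities from scratch in a few seconds. The numbered
analyses under `analysis/` write small CSV/JSON tables into
`results/`; `01_simulate_scenarios.py` regenerates the scenario curves
there.

## Known limitations

* Vacuum Debye scattering: absolute intensity scales are not
  comparable to experiment; only shapes and positions are.
* The Dmax scan of the IFT is soft for rods (see above).
* The Caillé low-q regime differs from measured lamellar data, which
  typically contain diffuse scattering from unstacked material filling
  the correlation hole; the classifier is calibrated for the pure
  model.
* Uniform HU placement and a rectangular bundle lattice are geometric
  idealizations; the inter-dimer register on real filaments is not
  recoverable from 1D scattering, so placement is an exposed parameter
  rather than an assertion.
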