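"""Coarse bead models of B-DNA duplexes, HU-decorated filaments and DNA bundles.

The model pool used for Debye fitting is built from three primitives:

* an ideal straight B-form duplex (two beads per nucleotide: a backbone
  bead on the phosphate track at ``helix_radius`` and a base bead at
  0.4·``helix_radius``; two antiparallel strands offset by the standard
  minor/major-groove phase),
* HU dimers as compact ~20-bead blobs (an ellipsoid proxy of about
  45×35×30 Å) centred 12 Å off the helix axis at prescribed base-pair
  positions, and
* rectangular lattices of parallel duplex copies with a prescribed
  axis-to-axis spacing — the coarse picture of an HU-glued DNA bundle.

All geometry is at the ~nm scale the solution-scattering observables
resolve (repeat spacings, filament length); no sequence-dependent fine
structure is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import AtomisticModel, KIND_DNA, KIND_PROTEIN, concatenate_models

__all__ = ["BuildSpec", "build_bdna", "place_hu", "build_bundle", "build_pool"]

#: default bead weights, relative electron counts per coarse bead
W_BACKBONE = 95.0      # phosphate + deoxyribose
W_BASE = 65.0          # mean nucleobase
W_HU_BEAD = 500.0      # ~19 kDa HU dimer (~10^4 electrons) over 20 beads

#: angular offset between the two strands' phosphate tracks (deg);
#: gives the B-form minor/major groove asymmetry
STRAND_PHASE = 154.0

HU_BEADS = 20
HU_OFFSET = 12.0       # blob centre distance from the helix axis, Å
HU_SEMI_AXES = (15.0, 17.5, 22.5)   # x, y, z semi-axes, long axis along the duplex


@dataclass
class BuildSpec:
    """Geometry of a duplex / decorated filament / bundle build.

    rise and twist default to canonical B-DNA (3.4 Å and 36° per bp);
    helix_radius is the phosphate-track radius. ``lattice`` is
    (n_x, n_y, spacing Å) for bundles.
    """

    n_bp: int = 80
    rise: float = 3.4
    twist: float = 36.0
    helix_radius: float = 9.4
    hu_per_duplex: int = 0
    hu_mode: str = "uniform"           # uniform | saturated | explicit
    hu_positions: list = field(default_factory=list)   # bp indices for explicit mode
    lattice: tuple | None = None       # (n_x, n_y, spacing)

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.rise <= 0 or self.helix_radius <= 0:
            raise ValueError("rise and helix_radius must be positive")
        if self.hu_per_duplex < 0:
            raise ValueError("hu_per_duplex must be >= 0")
        if self.lattice is not None:
            nx, ny, spacing = self.lattice
            if nx < 1 or ny < 1:
                raise ValueError("lattice counts must be >= 1")
            if (nx > 1 or ny > 1) and spacing <= 2 * self.helix_radius:
                raise ValueError("lattice spacing must exceed the duplex diameter (overlap)")


def build_bdna(spec: BuildSpec) -> AtomisticModel:
    """Ideal straight B-form duplex along z; axial extent (n_bp−1)·rise."""
    n = spec.n_bp
    i = np.arange(n)
    z = i * spec.rise
    theta1 = np.deg2rad(i * spec.twist)
    theta2 = theta1 + np.deg2rad(STRAND_PHASE)
    r_bb, r_base = spec.helix_radius, 0.4 * spec.helix_radius

    def strand(theta):
        bb = np.column_stack([r_bb * np.cos(theta), r_bb * np.sin(theta), z])
        base = np.column_stack([r_base * np.cos(theta), r_base * np.sin(theta), z])
        return bb, base

    bb1, base1 = strand(theta1)
    bb2, base2 = strand(theta2)
    beads = np.vstack([bb1, base1, bb2, base2])
    weights = np.concatenate([
        np.full(n, W_BACKBONE), np.full(n, W_BASE),
        np.full(n, W_BACKBONE), np.full(n, W_BASE),
    ])
    kinds = [KIND_DNA] * (4 * n)
    groups = ["A"] * (2 * n) + ["B"] * (2 * n)
    return AtomisticModel(beads, weights, kinds, groups)


def _hu_blob_template() -> np.ndarray:
    """Deterministic ~20-point filling of the HU-dimer ellipsoid proxy."""
    rng = np.random.default_rng(190306)   # fixed: the template is part of the model definition
    pts = []
    a = np.array(HU_SEMI_AXES)
    while len(pts) < HU_BEADS:
        p = rng.uniform(-1, 1, size=3)
        if np.sum(p ** 2) <= 1.0:
            pts.append(p * a)
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


_HU_TEMPLATE = _hu_blob_template()


def place_hu(model: AtomisticModel, n_dimers: int | None = None, mode: str = "uniform",
             positions=None, rise: float = 3.4) -> AtomisticModel:
    """Decorate a duplex model with HU-dimer blobs at base-pair positions.

    ``uniform`` spaces ``n_dimers`` centres evenly along the duplex;
    ``saturated`` tiles one dimer per 9 bp until the duplex is full
    (``n_dimers`` must then be omitted); ``explicit`` takes bp positions.
    Blobs sit on a fixed lab azimuth so explicit centre–centre distances
    are exactly Δbp·rise.
    """
    dna = [i for i, k in enumerate(model.kinds) if k == KIND_DNA]
    if not dna:
        raise ValueError("model contains no DNA beads to decorate")
    zmin = float(model.beads[dna, 2].min())
    zmax = float(model.beads[dna, 2].max())
    n_bp = int(round((zmax - zmin) / rise)) + 1

    if mode == "saturated":
        if n_dimers is not None:
            raise ValueError("saturated mode determines the count itself; do not pass n_dimers")
        n_dimers = n_bp // 9
        bp = (np.arange(n_dimers) + 0.5) * 9.0
    elif mode == "uniform":
        if n_dimers is None:
            raise ValueError("uniform mode requires n_dimers")
        if n_dimers == 0:
            return model
        bp = (np.arange(n_dimers) + 0.5) / n_dimers * (n_bp - 1)
    elif mode == "explicit":
        if positions is None:
            raise ValueError("explicit mode requires bp positions")
        bp = np.asarray(positions, dtype=float)
        if np.any(bp < 0) or np.any(bp > n_bp - 1):
            raise ValueError("explicit positions fall off the duplex")
    else:
        raise ValueError(f"unknown placement mode: {mode}")

    parts = [model]
    for j, b in enumerate(np.atleast_1d(bp)):
        centre = np.array([HU_OFFSET, 0.0, zmin + b * rise])
        beads = _HU_TEMPLATE + centre
        parts.append(AtomisticModel(
            beads, np.full(HU_BEADS, W_HU_BEAD),
            [KIND_PROTEIN] * HU_BEADS, [f"H{j}"] * HU_BEADS,
        ))
    return concatenate_models(parts)


def build_bundle(spec: BuildSpec) -> AtomisticModel:
    """n_x × n_y parallel duplex copies on a rectangular lattice.

    Per-duplex geometry (including any HU decoration) is preserved
    bead-for-bead; the minimum axis-to-axis distance equals the lattice
    spacing.
    """
    if spec.lattice is None:
        raise ValueError("bundle build requires a lattice in the spec")
    nx, ny, spacing = spec.lattice
    unit = build_bdna(spec)
    if spec.hu_per_duplex > 0:
        unit = place_hu(unit, spec.hu_per_duplex, spec.hu_mode, spec.hu_positions or None,
                        rise=spec.rise)
    parts = []
    for ix in range(int(nx)):
        for iy in range(int(ny)):
            copy = unit.translated([ix * spacing, iy * spacing, 0.0])
            copy.groups = [f"{g}.{ix}{iy}" for g in copy.groups]
            parts.append(copy)
    return concatenate_models(parts)


def build_pool(base: BuildSpec, stoichiometries) -> list[AtomisticModel]:
    """One uniformly decorated duplex per HU:DNA stoichiometry (deterministic)."""
    stoichiometries = list(stoichiometries)
    if not stoichiometries:
        raise ValueError("stoichiometry list must be non-empty")
    duplex = build_bdna(base)
    return [place_hu(duplex, s, "uniform", rise=base.rise) for s in stoichiometries]
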