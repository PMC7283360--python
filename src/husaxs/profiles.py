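"""Containers and file I/O for 1D SAXS profiles and coarse bead models.

A scattering profile is the standard 3-column beamline ASCII file:
momentum transfer q (Å⁻¹), relative intensity I(q), and optionally the
1-σ uncertainty of I. Lines starting with ``#`` are comments; a comment
of the form ``# condition: ...`` carries free-text sample metadata
(pH, NaCl molarity, sample name).

Coarse structural models (DNA duplexes, HU-decorated filaments, DNA
bundles) are held as flat bead lists and read/written either as PDB
coordinate files (one bead per ATOM record) or as a 5-column CSV bead
table (x, y, z, weight, kind).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger("husaxs")

__all__ = [
    "ScatteringProfile",
    "AtomisticModel",
    "ProfileFormatError",
    "ModelFormatError",
    "read_profile",
    "write_profile",
    "read_model",
    "write_model",
]


class ProfileFormatError(ValueError):
    """Raised when a profile file cannot be interpreted as (q, I[, σ])."""


class ModelFormatError(ValueError):
    """Raised when a model file yields no usable bead coordinates."""


# Relative electron counts for default PDB atom weights (H excluded:
# negligible X-ray contrast). Sufficient for coarse Debye profiles.
ELECTRONS = {"C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0, "MG": 10.0,
             "NA": 10.0, "CL": 18.0, "K": 18.0, "ZN": 28.0, "FE": 24.0}

#: kind labels used throughout
KIND_DNA = "DNA-nucleotide"
KIND_PROTEIN = "protein-residue"

_DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U", "DNA"}


@dataclass
class ScatteringProfile:
    """A 1D SAXS curve I(q) with optional per-point uncertainty.

    q is in Å⁻¹ and must be strictly increasing and positive; the
    intensity is in arbitrary (relative) units. ``condition`` is a
    free-text tag describing the sample/buffer.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must have equal length")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("q and intensity must be finite")
        if self.q[0] <= 0:
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing (profiles are never reordered silently)")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must have the same length as q")
            if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
                raise ValueError("sigma must be finite and > 0")

    def __len__(self) -> int:
        return self.q.size

    def slice(self, qmin: float, qmax: float) -> "ScatteringProfile":
        """Return the sub-profile with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not np.any(m):
            raise ValueError(f"no points in window [{qmin}, {qmax}]")
        return ScatteringProfile(
            self.q[m], self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            self.condition,
        )

    def with_default_sigma(self, frac: float = 0.01) -> "ScatteringProfile":
        """Return a copy with σ = frac·|I| where σ is absent (so χ is defined)."""
        if self.sigma is not None:
            return self
        floor = frac * float(np.max(np.abs(self.intensity)))
        sigma = np.maximum(frac * np.abs(self.intensity), 1e-12 * max(floor, 1.0))
        logger.info("profile '%s': no sigma column, assuming %.1f%% of I", self.condition, 100 * frac)
        return replace(self, sigma=sigma)


@dataclass
class AtomisticModel:
    """Coarse bead model: coordinates (Å), scattering weights, kind and group labels."""

    beads: np.ndarray                      # (n, 3) float
    weights: np.ndarray                    # (n,) float, > 0
    kinds: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float).reshape(-1, 3)
        n = self.beads.shape[0]
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if not self.kinds:
            self.kinds = [KIND_DNA] * n
        if not self.groups:
            self.groups = ["A"] * n
        self.validate()

    def validate(self) -> None:
        n = self.beads.shape[0]
        if n == 0:
            raise ValueError("model must contain at least one bead")
        if not np.all(np.isfinite(self.beads)):
            raise ValueError("bead coordinates must be finite")
        if self.weights.shape != (n,) or np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite, positive and one per bead")
        if len(self.kinds) != n or len(self.groups) != n:
            raise ValueError("kinds and groups must be one per bead")

    def __len__(self) -> int:
        return self.beads.shape[0]

    def translated(self, shift) -> "AtomisticModel":
        return AtomisticModel(self.beads + np.asarray(shift, float),
                              self.weights.copy(), list(self.kinds), list(self.groups))

    def rg(self) -> float:
        """Weight-averaged coordinate radius of gyration (Å)."""
        w = self.weights / self.weights.sum()
        c = w @ self.beads
        return float(np.sqrt(np.sum(w * np.sum((self.beads - c) ** 2, axis=1))))


def concatenate_models(parts: list[AtomisticModel]) -> AtomisticModel:
    return AtomisticModel(
        np.vstack([p.beads for p in parts]),
        np.concatenate([p.weights for p in parts]),
        sum((list(p.kinds) for p in parts), []),
        sum((list(p.groups) for p in parts), []),
    )


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def read_profile(path, nm_inverse: bool = False) -> ScatteringProfile:
    """Read a whitespace-delimited (q, I[, σ]) ASCII file.

    ``#``-prefixed lines are comments; ``# condition: ...`` is parsed
    into the profile metadata. Rows with non-positive q are dropped
    (with a logged count). Set ``nm_inverse=True`` for files with q in
    nm⁻¹ (divides q by 10).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read profile file {path}: {exc}") from exc

    condition = ""
    rows: list[list[float]] = []
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.lower().startswith("condition:"):
                condition = body.split(":", 1)[1].strip()
            continue
        try:
            vals = [float(x) for x in s.split()]
        except ValueError:
            continue  # tolerate stray text lines (common in beamline headers)
        if vals:
            rows.append(vals)

    if not rows:
        raise ProfileFormatError(f"{path}: no numeric rows")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ProfileFormatError(f"{path}: need at least 2 numeric columns")
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0] / (10.0 if nm_inverse else 1.0)
    keep = q > 0
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("%s: dropped %d rows with non-positive q", path.name, dropped)
    arr = arr[keep]
    q = q[keep]
    if q.size < 10:
        raise ProfileFormatError(f"{path}: fewer than 10 usable rows")
    order = np.argsort(q, kind="stable")
    if not np.array_equal(order, np.arange(q.size)):
        raise ProfileFormatError(f"{path}: q is not strictly increasing")
    sigma = arr[:, 2] if ncol >= 3 else None
    if sigma is not None and np.any(sigma <= 0):
        logger.info("%s: non-positive sigma values, discarding sigma column", path.name)
        sigma = None
    return ScatteringProfile(q, arr[:, 1], sigma, condition)


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column ASCII (q I σ) with a ``#`` header."""
    path = Path(path)
    lines = ["# husaxs SAXS profile (q [1/A]  I  sigma)"]
    if profile.condition:
        lines.append(f"# condition: {profile.condition}")
    sigma = profile.sigma
    for i in range(len(profile)):
        if sigma is None:
            lines.append(f"{profile.q[i]:.8e} {profile.intensity[i]:.8e}")
        else:
            lines.append(f"{profile.q[i]:.8e} {profile.intensity[i]:.8e} {sigma[i]:.8e}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write profile file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def _read_model_csv(path: Path) -> AtomisticModel:
    beads, weights, kinds, groups = [], [], [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or row[0].strip().lower() == "x":
                continue
            if len(row) < 5:
                raise ModelFormatError(f"{path}: bead table rows need >= 5 columns (x,y,z,weight,kind)")
            beads.append([float(row[0]), float(row[1]), float(row[2])])
            weights.append(float(row[3]))
            kinds.append(row[4].strip())
            groups.append(row[5].strip() if len(row) > 5 else "A")
    if not beads:
        raise ModelFormatError(f"{path}: no parseable bead rows")
    return AtomisticModel(np.array(beads), np.array(weights), kinds, groups)


def _read_model_pdb(path: Path) -> AtomisticModel:
    import gemmi

    st = gemmi.read_structure(str(path))
    beads, weights, kinds, groups = [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                resname = res.name.strip().upper()
                is_dna = resname in _DNA_RESNAMES
                for atom in res:
                    el = atom.element.name.upper()
                    if el == "H":
                        continue
                    # coarse bead files carry the weight in the B-factor
                    if resname in {"DNA", "HUP"} and atom.b_iso > 0:
                        w = float(atom.b_iso)
                    else:
                        w = ELECTRONS.get(el, 6.0)
                    beads.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(w)
                    kinds.append(KIND_DNA if is_dna else KIND_PROTEIN)
                    groups.append(chain.name)
        break  # first MODEL only
    if not beads:
        raise ModelFormatError(f"{path}: no coordinates found")
    return AtomisticModel(np.array(beads), np.array(weights), kinds, groups)


def read_model(path) -> AtomisticModel:
    """Read a coarse model from a PDB file or a CSV bead table.

    PDB atoms get default per-element weights (relative electron
    counts, H excluded) unless they come from a coarse bead record
    (residue name DNA/HUP), whose weight is stored in the B-factor.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    if path.suffix.lower() in {".csv", ".tsv", ".bead", ".txt"}:
        return _read_model_csv(path)
    return _read_model_pdb(path)


# PDB chain ids available for group mapping
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_model(model: AtomisticModel, path) -> None:
    """Write a model as PDB (``.pdb``) or CSV bead table (anything else).

    In PDB output each bead becomes one ATOM record; the kind is
    encoded in the residue name (DNA / HUP) and the weight in the
    B-factor column. Groups map to chain identifiers in order of first
    appearance (PDB chain ids are single characters).
    """
    path = Path(path)
    if path.suffix.lower() != ".pdb":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "z", "weight", "kind", "group"])
            for i in range(len(model)):
                w.writerow([f"{model.beads[i, 0]:.3f}", f"{model.beads[i, 1]:.3f}",
                            f"{model.beads[i, 2]:.3f}", f"{model.weights[i]:.6g}",
                            model.kinds[i], model.groups[i]])
        return

    chain_map: dict[str, str] = {}
    lines = []
    serial = 0
    for i in range(len(model)):
        g = model.groups[i]
        if g not in chain_map:
            chain_map[g] = _CHAIN_IDS[len(chain_map) % len(_CHAIN_IDS)]
        serial += 1
        resname = "DNA" if model.kinds[i] == KIND_DNA else "HUP"
        el = "P" if model.kinds[i] == KIND_DNA else "C"
        x, y, z = model.beads[i]
        b = min(model.weights[i], 999.99)
        lines.append(
            f"ATOM  {serial % 100000:5d} {el:>3s}  {resname:<3s} {chain_map[g]}{(i % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          {el:>2s}"
        )
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write model file {path}: {exc}") from exc
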