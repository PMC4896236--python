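"""Synthetic structures, ensembles and feature tables with known truth.

None of these generators is a physical simulator; each plants exactly the
signal one analysis stage is supposed to recover, so the whole pipeline is
testable without running molecular dynamics:

* :func:`make_toy_dimer` — a two-chain slab-like complex with a tunable
  interface separation (surface descriptors, hydrogen bonds, gap volume);
* :func:`make_harmonic_ensemble` — frames displaced along known orthogonal
  modes (essential-dynamics recovery);
* :func:`make_basin_ensemble` — a Gaussian-mixture landscape embedded
  along two modes (free-energy-minima counting);
* :func:`make_feature_study` — descriptor tables with a planted
  detached/compact split (the classification chain).

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .model_io import AtomRecord, PTMPattern, StructureModel, TrajectoryEnsemble
from .params import vdw_radius
from .statistics import FeatureMatrix, assemble_features

__all__ = [
    "ToySpec",
    "BasinSpec",
    "make_toy_dimer",
    "make_slab_pair",
    "make_harmonic_ensemble",
    "make_basin_ensemble",
    "make_feature_study",
]


@dataclass(frozen=True)
class ToySpec:
    """Geometry of the two-chain toy complex.

    ``separation`` is the minimum surface-to-surface distance between the
    chains, Å (0 = van der Waals contact).
    """

    n_res_per_chain: int = 9
    separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_res_per_chain < 2:
            raise ValueError("need at least 2 residues per chain")


# backbone-like offsets within one residue: (atom name, element, dx, dy, dz)
_RESIDUE_TEMPLATE: tuple[tuple[str, str, float, float, float], ...] = (
    ("N", "N", -1.3, 0.0, 1.0),
    ("H", "H", -1.3, 0.0, 2.0),
    ("CA", "C", 0.0, 0.0, 0.0),
    ("CB", "C", 0.0, 1.4, -0.9),
    ("C", "C", 1.3, 0.0, 0.4),
    ("O", "O", 1.3, 0.0, 1.4),
)

# tallest protrusion above the residue plane (H at dz 2.0 plus its radius)
_TOP = 2.0 + 1.20
_GRID_SPACING = 4.2


def make_toy_dimer(spec: ToySpec) -> StructureModel:
    """Two mirror-image poly-alanine-like chains facing across a plane.

    Residues sit on a square grid; chain B is chain A reflected through
    the interface plane, displaced so that the smallest inter-chain
    surface-to-surface distance equals ``spec.separation``. A 0.01 Å
    seeded jitter breaks exact symmetries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_res_per_chain
    nx = math.ceil(math.sqrt(n))
    z_half = (spec.separation + 2.0 * _TOP) / 2.0

    atoms: list[AtomRecord] = []
    serial = 0
    for chain, sign, z0 in (("A", 1.0, -z_half), ("B", -1.0, z_half)):
        for r in range(n):
            gx = (r % nx) * _GRID_SPACING
            gy = (r // nx) * _GRID_SPACING
            for name, element, dx, dy, dz in _RESIDUE_TEMPLATE:
                serial += 1
                jitter = rng.normal(0.0, 0.01, size=3)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        resname="ALA",
                        resid=r + 1,
                        chain=chain,
                        xyz=(
                            gx + dx + jitter[0],
                            gy + dy + jitter[1],
                            z0 + sign * dz + jitter[2],
                        ),
                        vdw_radius=vdw_radius(element),
                    )
                )
    return StructureModel(atoms)


def make_slab_pair(
    n_side: int = 12,
    gap: float = 3.0,
    spacing: float = 2.0,
    element: str = "C",
) -> tuple[StructureModel, float]:
    """Two flat square slabs of uniform atoms facing across ``gap`` Å.

    A deterministic fixture for gap-volume checks; returns the structure
    and the slab's lateral van der Waals footprint area
    ``((n_side - 1) * spacing + 2 r)**2`` (atom centers plus one radius of
    silhouette on each side), so the analytic slab volume ``gap * area``
    is available to callers.
    """
    r = vdw_radius(element)
    z = gap / 2.0 + r
    atoms: list[AtomRecord] = []
    serial = 0
    for chain, zc in (("A", -z), ("B", z)):
        for i in range(n_side):
            for j in range(n_side):
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name="C",
                        element=element,
                        resname="UNK",
                        resid=serial,
                        chain=chain,
                        xyz=(i * spacing, j * spacing, zc),
                        vdw_radius=r,
                    )
                )
    area = ((n_side - 1) * spacing + 2.0 * r) ** 2
    return StructureModel(atoms), area


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 columns) of rigid translations/rotations."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for k in range(3):
        basis[k::3, k] = 1.0
    for k, axis in enumerate(np.eye(3)):
        disp = np.cross(np.tile(axis, (n, 1)), centered)
        basis[:, 3 + k] = disp.ravel()
    q, _ = np.linalg.qr(basis)
    return q


def _planted_ca_modes(
    s: StructureModel, n_modes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random orthonormal Cα displacement modes, rigid body projected out.

    Returns ``(modes, ca_indices)`` with ``modes`` of shape
    ``(n_modes, n_ca, 3)``; the modes are unit vectors in the 3n_ca space,
    mutually orthogonal and orthogonal to net translation/rotation, so a
    superposition-based analysis sees exactly the planted variance.
    """
    ca = s.atom_indices("CA")
    if ca.size < 4:
        raise ValueError("need at least 4 Cα atoms to plant modes")
    dim = 3 * ca.size
    rigid = _rigid_body_basis(s.coords[ca])
    raw = rng.standard_normal((dim, n_modes))
    stacked = np.hstack([rigid, raw])
    q, _ = np.linalg.qr(stacked)
    modes = q[:, 6 : 6 + n_modes].T.reshape(n_modes, ca.size, 3)
    return modes, ca


def _embed_frames(
    s: StructureModel,
    modes: np.ndarray,
    ca: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Frames = reference + per-frame amplitude-weighted Cα displacements."""
    ref = s.coords
    n_frames = amplitudes.shape[0]
    frames = np.tile(ref, (n_frames, 1, 1))
    for k in range(modes.shape[0]):
        frames[:, ca, :] += amplitudes[:, k, None, None] * modes[k][None, :, :]
    return frames


def _full_atom_modes(
    s: StructureModel, modes: np.ndarray, ca: np.ndarray
) -> np.ndarray:
    full = np.zeros((modes.shape[0], len(s), 3))
    full[:, ca, :] = modes
    return full


def make_harmonic_ensemble(
    s: StructureModel,
    mode_variances: list[float],
    n_frames: int = 1000,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Gaussian displacements along planted orthonormal Cα modes.

    Frame ``t`` is the reference plus ``sum_k sqrt(var_k) z_tk mode_k``
    with standard-normal ``z``. The planted modes (full-atom layout) are
    stored on the ensemble for ground-truth comparisons.
    """
    rng = np.random.default_rng(seed)
    modes, ca = _planted_ca_modes(s, len(mode_variances), rng)
    z = rng.standard_normal((n_frames, len(mode_variances)))
    amp = z * np.sqrt(np.asarray(mode_variances, dtype=float))[None, :]
    frames = _embed_frames(s, modes, ca, amp)
    return TrajectoryEnsemble(
        topology=s,
        frames=frames,
        planted_modes=_full_atom_modes(s, modes, ca),
    )


@dataclass(frozen=True)
class BasinSpec:
    """A planted 2-D Gaussian-mixture free-energy landscape.

    Latent units are Å along the two embedding modes. Centers should be
    pairwise separated by at least 6 latent sigma for the well-separated
    recovery guarantee; basins whose weight falls below 0.7 of the largest
    are, by construction of the minima rule, not counted.
    """

    k: int = 1
    centers: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    weights: tuple[float, ...] = (1.0,)
    widths: tuple[float, ...] = (1.0,)
    n_frames: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (len(self.centers) == len(self.weights) == len(self.widths) == self.k):
            raise ValueError("centers/weights/widths must have length k")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @classmethod
    def well_separated(
        cls,
        k: int,
        weights: tuple[float, ...] | None = None,
        n_frames: int = 600,
        seed: int = 0,
        separation: float = 9.0,
    ) -> "BasinSpec":
        """Basins on a line, ``separation`` latent units apart, width 1."""
        centers = tuple((i * separation, 0.0) for i in range(k))
        if weights is None:
            weights = tuple(1.0 / k for _ in range(k))
        return cls(
            k=k,
            centers=centers,
            weights=weights,
            widths=tuple(1.0 for _ in range(k)),
            n_frames=n_frames,
            seed=seed,
        )


def make_basin_ensemble(s: StructureModel, spec: BasinSpec) -> TrajectoryEnsemble:
    """Embed Gaussian-mixture latent samples along two planted Cα modes."""
    rng = np.random.default_rng(spec.seed)
    modes, ca = _planted_ca_modes(s, 2, rng)
    comp = rng.choice(spec.k, size=spec.n_frames, p=np.asarray(spec.weights))
    centers = np.asarray(spec.centers, dtype=float)
    widths = np.asarray(spec.widths, dtype=float)
    latent = centers[comp] + rng.standard_normal((spec.n_frames, 2)) * widths[
        comp, None
    ]
    frames = _embed_frames(s, modes, ca, latent)
    return TrajectoryEnsemble(
        topology=s,
        frames=frames,
        planted_modes=_full_atom_modes(s, modes, ca),
    )


# per-descriptor (baseline, spread) on realistic scales; spreads are the
# sigma against which the effect size is expressed
_STUDY_SCALES: dict[str, tuple[float, float]] = {
    "Total SAS": (9000.0, 250.0),
    "Hydrophobic SAS": (3500.0, 120.0),
    "Buried SAS": (900.0, 60.0),
    "HB": (8.0, 1.0),
    "Gap_Index": (2.5, 0.4),
    "Volume": (1800.0, 150.0),
    "E_LJ": (400.0, 40.0),
    "AbsMin": (0.25, 0.04),
    "#Min": (3.0, 0.8),
}

# +1: shifted up in the detached regime; -1: shifted down
_DETACHED_DIRECTION: dict[str, int] = {
    "Total SAS": +1,
    "Hydrophobic SAS": +1,
    "Buried SAS": -1,
    "HB": -1,
    "Gap_Index": +1,
    "Volume": +1,
    "E_LJ": -1,
    "AbsMin": -1,
    "#Min": +1,
}


def make_feature_study(
    n_per_group: int = 8,
    effect_size: float = 5.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray, list[tuple[str, str]]]:
    """Planted two-regime descriptor study (compact vs detached interfaces).

    Each of ``n_per_group`` synthetic proteins contributes a compact
    (unmodified) and a detached (modified) system. In the detached regime
    the exposure/gap descriptors shift up and the packing descriptors
    shift down by ``effect_size`` per-variable sigma; noise is standard
    normal per scaled variable. Returns the feature matrix (with one
    modification indicator column), the ground-truth regime labels
    (0 compact, 1 detached) aligned with its rows, and the
    (compact, detached) row-name pairs for pairwise normalization.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    descriptors: list[DescriptorVector] = []
    patterns: list[PTMPattern] = []
    names: list[str] = []
    truth: list[int] = []
    pairs: list[tuple[str, str]] = []
    site = [("A", 1, "P")]
    for i in range(n_per_group):
        for regime, label in ((0, "cl"), (1, "op")):
            row = {}
            for name in DESCRIPTOR_NAMES:
                base, sigma = _STUDY_SCALES[name]
                direction = _DETACHED_DIRECTION[name] * (1 if regime else -1)
                z = direction * effect_size / 2.0 + rng.standard_normal()
                row[name] = base + sigma * z
            descriptors.append(DescriptorVector.from_row(row))
            patterns.append(PTMPattern(sites=list(site), state=(regime,)))
            names.append(f"sys{i + 1}-{label}")
            truth.append(regime)
        pairs.append((f"sys{i + 1}-cl", f"sys{i + 1}-op"))
    matrix = assemble_features(descriptors, patterns, names=names)
    return matrix, np.asarray(truth), pairs
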