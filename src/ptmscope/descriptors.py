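"""Trajectory-averaged structural and energetic interface descriptors.

The descriptor vector characterises one system (one PTM variant of a
multimeric complex) by nine quantities: total, hydrophobic and buried
solvent-accessible surface (Å²), mean inter-chain hydrogen-bond count,
interface gap index and gap volume, absolute inter-chain Lennard-Jones
energy (kJ/mol), and the two free-energy-landscape stability markers
(occupancy of the deepest minimum, number of minima).

This module computes the five ensemble-averaged quantities; the interface
geometry (volume, gap index) and landscape markers come from
:mod:`ptmscope.interface_geometry` and :mod:`ptmscope.fel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import StructureModel, TrajectoryEnsemble
from .params import HYDROPHOBIC_RESIDUES, lj_parameters

__all__ = [
    "DescriptorVector",
    "HBondCriteria",
    "DescriptorConfig",
    "sphere_points",
    "compute_sas",
    "buried_sas",
    "count_interchain_hbonds",
    "interchain_lj_energy",
    "trajectory_mean_descriptors",
]

DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Total SAS",
    "Hydrophobic SAS",
    "Buried SAS",
    "HB",
    "Gap_Index",
    "Volume",
    "E_LJ",
    "AbsMin",
    "#Min",
)


@dataclass
class DescriptorVector:
    """The nine general parameters for one system.

    Units: SAS in Å², volume in Å³, gap_index in Å (Å³/Å²), e_lj in kJ/mol
    (absolute value), hb a mean count per frame, abs_min a probability,
    n_min a count.
    """

    total_sas: float = np.nan
    hydrophobic_sas: float = np.nan
    buried_sas: float = np.nan
    hb: float = np.nan
    gap_index: float = np.nan
    volume: float = np.nan
    e_lj: float = np.nan
    abs_min: float = np.nan
    n_min: float = np.nan

    def as_row(self) -> dict[str, float]:
        """Mapping keyed by the canonical parameter names."""
        return {
            "Total SAS": self.total_sas,
            "Hydrophobic SAS": self.hydrophobic_sas,
            "Buried SAS": self.buried_sas,
            "HB": self.hb,
            "Gap_Index": self.gap_index,
            "Volume": self.volume,
            "E_LJ": self.e_lj,
            "AbsMin": self.abs_min,
            "#Min": self.n_min,
        }

    @classmethod
    def from_row(cls, row: dict[str, float]) -> "DescriptorVector":
        return cls(
            total_sas=row["Total SAS"],
            hydrophobic_sas=row["Hydrophobic SAS"],
            buried_sas=row["Buried SAS"],
            hb=row["HB"],
            gap_index=row["Gap_Index"],
            volume=row["Volume"],
            e_lj=row["E_LJ"],
            abs_min=row["AbsMin"],
            n_min=row["#Min"],
        )


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``da_cutoff``: maximum donor-acceptor distance, Å. ``angle_cutoff``:
    maximum hydrogen-donor-acceptor angle, degrees. When a structure has no
    hydrogens the heavy-atom fallback (distance only) applies.
    """

    da_cutoff: float = 3.5
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be > 0")
        if not 0 < self.angle_cutoff <= 90:
            raise ValueError("angle_cutoff must be in (0, 90]")


@dataclass
class DescriptorConfig:
    """Knobs for the ensemble-averaged descriptors."""

    probe: float = 1.4  # Å
    n_points: int = 960
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    lj_cutoff: float = 10.0  # Å
    hydrophobic_residues: frozenset[str] = HYDROPHOBIC_RESIDUES
    stride: int = 1


def sphere_points(n: int) -> np.ndarray:
    """``n`` nearly uniform points on the unit sphere (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _per_atom_sas(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    """Shrake-Rupley accessible area per atom, Å²."""
    expanded = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = float(expanded.max())
    out = np.empty(len(coords))
    for i in range(len(coords)):
        shell = coords[i] + expanded[i] * pts
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = ((shell[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def compute_sas(
    s: StructureModel,
    subset: str = "all",
    probe: float = 1.4,
    n_points: int = 960,
    hydrophobic_residues: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> float:
    """Solvent-accessible surface area by Shrake-Rupley sampling, Å².

    ``subset``: ``"all"`` for the whole structure; ``"hydrophobic"`` to sum
    only over carbon/sulfur atoms of apolar residues (occlusion still uses
    every atom); a chain id to compute the SAS of that chain *extracted*
    from the complex (isolated, complex conformation kept).
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a converged estimate")
    if subset not in ("all", "hydrophobic"):
        if subset not in s.chains:
            raise ValueError(f"unknown subset {subset!r}")
        s = s.subset(s.chain_mask(subset))
        subset = "all"
    areas = _per_atom_sas(s.coords, s.radii, probe, n_points)
    if subset == "hydrophobic":
        mask = np.array(
            [
                a.resname in hydrophobic_residues and a.element.upper() in ("C", "S")
                for a in s.atoms
            ]
        )
        if not mask.any():
            warnings.warn("no hydrophobic atoms in structure; hydrophobic SAS is 0")
            return 0.0
        return float(areas[mask].sum())
    return float(areas.sum())


def buried_sas(
    s: StructureModel, probe: float = 1.4, n_points: int = 960
) -> float:
    """Interface area buried on complexation, Å².

    Sum of the isolated single-chain SAS values minus the complex SAS, with
    every chain kept in its complex conformation. Requires exactly two
    chains (interface pairs of larger assemblies are handled by extracting
    the pair first).
    """
    if len(s.chains) != 2:
        raise ValueError("interface requires two chains")
    total = compute_sas(s, "all", probe, n_points)
    mono = sum(compute_sas(s, c, probe, n_points) for c in s.chains)
    return float(mono - total)


_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


def count_interchain_hbonds(
    s: StructureModel, criteria: HBondCriteria | None = None
) -> int:
    """Count hydrogen bonds whose donor and acceptor sit on different chains.

    Donors are N/O atoms bearing a covalent hydrogen (H within 1.25 Å);
    acceptors are N/O atoms. A bond requires donor-acceptor distance ≤
    ``da_cutoff`` and, when hydrogens are present, a hydrogen-donor-acceptor
    angle ≤ ``angle_cutoff`` for at least one attached hydrogen. Without any
    hydrogens the heavy-atom distance criterion alone applies.
    """
    if criteria is None:
        criteria = HBondCriteria()
    coords = s.coords
    elements = [e.upper() for e in s.elements]
    chains = np.array([a.chain for a in s.atoms])

    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    polar = [i for i, e in enumerate(elements) if e in _DONOR_ELEMENTS]
    if not polar:
        return 0
    have_h = bool(h_idx)

    # attach hydrogens to their nearest polar heavy atom within bond range
    attached: dict[int, list[int]] = {i: [] for i in polar}
    if have_h:
        polar_tree = cKDTree(coords[polar])
        for h in h_idx:
            dist, j = polar_tree.query(coords[h], k=1)
            if dist <= 1.25:
                attached[polar[j]].append(h)

    acceptors = [i for i, e in enumerate(elements) if e in _ACCEPTOR_ELEMENTS]
    count = 0
    if have_h:
        donors = [i for i in polar if attached[i]]
        for d in donors:
            for a in acceptors:
                if a == d or chains[a] == chains[d]:
                    continue
                r = np.linalg.norm(coords[a] - coords[d])
                if r > criteria.da_cutoff or r < 1e-6:
                    continue
                for h in attached[d]:
                    v_h = coords[h] - coords[d]
                    v_a = coords[a] - coords[d]
                    cosang = np.dot(v_h, v_a) / (
                        np.linalg.norm(v_h) * np.linalg.norm(v_a)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang <= criteria.angle_cutoff:
                        count += 1
                        break
    else:
        # heavy-atom fallback: each close inter-chain polar pair once
        for x, d in enumerate(polar):
            for a in polar[x + 1 :]:
                if chains[a] == chains[d]:
                    continue
                r = np.linalg.norm(coords[a] - coords[d])
                if 1e-6 < r <= criteria.da_cutoff:
                    count += 1
    return count


def interchain_lj_energy(
    s: StructureModel, r_cut: float = 10.0
) -> float:
    """Absolute summed 12-6 Lennard-Jones energy across the interface, kJ/mol.

    Pairs within ``r_cut`` whose atoms belong to different chains contribute
    ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` with Lorentz-Berthelot combined
    per-element parameters; the absolute value of the sum is returned.
    """
    coords = s.coords
    chains = np.array([a.chain for a in s.atoms])
    sigma = np.empty(len(s))
    eps = np.empty(len(s))
    for i, e in enumerate(s.elements):
        sigma[i], eps[i] = lj_parameters(e)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    if pairs.size == 0:
        return 0.0
    inter = chains[pairs[:, 0]] != chains[pairs[:, 1]]
    pairs = pairs[inter]
    if pairs.size == 0:
        return 0.0
    r = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    if np.any(r < 1e-6):
        raise ValueError("clashing atoms at zero separation")
    sij = 0.5 * (sigma[pairs[:, 0]] + sigma[pairs[:, 1]])
    eij = np.sqrt(eps[pairs[:, 0]] * eps[pairs[:, 1]])
    sr6 = (sij / r) ** 6
    energy = float(np.sum(4.0 * eij * (sr6 * sr6 - sr6)))
    return abs(energy)


def trajectory_mean_descriptors(
    t: TrajectoryEnsemble, cfg: DescriptorConfig | None = None
) -> DescriptorVector:
    """Average the five per-frame descriptors over the equilibrated window.

    Fills ``total_sas``, ``hydrophobic_sas``, ``buried_sas``, ``hb`` and
    ``e_lj``; the geometry and landscape entries are left NaN for the
    dedicated modules to fill.
    """
    if cfg is None:
        cfg = DescriptorConfig()
    indices = list(t.eq_indices())[:: cfg.stride]
    if not indices:
        raise ValueError("empty equilibrated window")
    totals = np.zeros(5)
    for i in indices:
        frame = t.frame_structure(i)
        totals += (
            compute_sas(frame, "all", cfg.probe, cfg.n_points),
            compute_sas(
                frame, "hydrophobic", cfg.probe, cfg.n_points,
                cfg.hydrophobic_residues,
            ),
            buried_sas(frame, cfg.probe, cfg.n_points),
            count_interchain_hbonds(frame, cfg.hbond),
            interchain_lj_energy(frame, cfg.lj_cutoff),
        )
    means = totals / len(indices)
    return DescriptorVector(
        total_sas=means[0],
        hydrophobic_sas=means[1],
        buried_sas=means[2],
        hb=means[3],
        e_lj=means[4],
    )
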