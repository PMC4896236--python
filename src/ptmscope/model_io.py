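"""Structure and ensemble I/O, PTM site bookkeeping, equilibration detection.

Coordinates are Å throughout; RMSD-based criteria (equilibration slope,
conformational clustering) are expressed in nm to match the conventions of
MD analysis tooling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._geometry import fitted_rmsd
from .params import PHOSPHOSERINE_CODES, vdw_radius

__all__ = [
    "AtomRecord",
    "StructureModel",
    "TrajectoryEnsemble",
    "PTMPattern",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "mark_phosphosites",
    "enumerate_patterns",
    "select_equilibrated",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position and van der Waals radius (Å)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")


class StructureModel:
    """An ordered collection of atoms grouped into chains.

    The atom order is the contract shared with every frame of an ensemble;
    all descriptor computations index into it.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise ValueError("StructureModel requires at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        self.chains: list[str] = list(seen)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def chain_mask(self, chain: str) -> np.ndarray:
        return np.array([a.chain == chain for a in self.atoms], dtype=bool)

    def atom_indices(self, name: str) -> np.ndarray:
        """Indices of atoms with a given atom name (e.g. ``"CA"``)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.name == name], dtype=int
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this model with replaced coordinates (same atoms)."""
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, xyz=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return StructureModel(atoms)

    def subset(self, mask: np.ndarray) -> "StructureModel":
        """Sub-structure containing atoms where ``mask`` is True."""
        picked = [a for a, keep in zip(self.atoms, mask) if keep]
        if not picked:
            raise ValueError("empty atom subset")
        return StructureModel(picked)


@dataclass
class TrajectoryEnsemble:
    """Ordered conformations over a shared topology.

    ``eq_window`` is the half-open [start, end) frame interval considered
    equilibrated; statistics are averaged over it.
    """

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray | None = None  # ps
    eq_window: tuple[int, int] = (0, 0)
    planted_modes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("frames must be (n_frames, n_atoms, 3) matching topology")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite frame coordinates")
        if self.eq_window == (0, 0):
            self.eq_window = (0, self.n_frames)
        lo, hi = self.eq_window
        if not (0 <= lo < hi <= self.n_frames):
            raise ValueError(f"eq_window {self.eq_window} outside [0, {self.n_frames})")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])

    def eq_frames(self) -> np.ndarray:
        lo, hi = self.eq_window
        return self.frames[lo:hi]

    def eq_indices(self) -> range:
        return range(*self.eq_window)


@dataclass
class PTMPattern:
    """Binary modification state over an ordered list of sites.

    ``sites`` entries are ``(chain, resid, label)``; ``state[i]`` is 1 when
    site *i* carries the modification (phospho-serine), else 0.
    """

    sites: list[tuple[str, int, str]]
    state: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.state):
            raise ValueError("sites and state length mismatch")
        if any(s not in (0, 1) for s in self.state):
            raise ValueError("state entries must be 0 or 1")

    @property
    def labels(self) -> list[str]:
        return [label for _, _, label in self.sites]

    @property
    def name(self) -> str:
        """Human-readable pattern name, e.g. ``A.45-B.59`` (``wt`` if none)."""
        on = [lab for lab, s in zip(self.labels, self.state) if s]
        return "-".join(on) if on else "wt"


def _site_label(chain: str, resid: int) -> str:
    return f"{chain}.{resid}"


# ---------------------------------------------------------------------------
# PDB I/O (Biopython-backed)


def _model_to_atoms(model) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            het, resid, _ = residue.id
            for atom in residue:
                serial += 1
                element = (atom.element or atom.get_name()[0]).strip()
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.get_name(),
                        element=element,
                        resname=residue.get_resname().strip(),
                        resid=int(resid),
                        chain=chain.id,
                        xyz=tuple(float(v) for v in atom.coord),
                        vdw_radius=vdw_radius(element),
                    )
                )
    return atoms


def read_structure(path: str | Path) -> StructureModel | TrajectoryEnsemble:
    """Read a PDB file.

    A single-MODEL file yields a :class:`StructureModel`; a multi-MODEL file
    yields a :class:`TrajectoryEnsemble` whose ``eq_window`` defaults to the
    full frame range.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no MODEL records parsed")
    atoms = _model_to_atoms(models[0])
    if not atoms:
        raise ValueError(f"{path}: no atoms with coordinates")
    topology = StructureModel(atoms)
    if len(models) == 1:
        return topology
    frames = []
    for m in models:
        coords = np.array([a.coord for a in m.get_atoms()], dtype=float)
        if coords.shape != (len(topology), 3):
            raise ValueError(f"{path}: MODEL {m.id} atom count differs from MODEL 1")
        frames.append(coords)
    return TrajectoryEnsemble(topology=topology, frames=np.stack(frames))


def read_trajectory(topology_pdb: str | Path, traj_path: str | Path) -> TrajectoryEnsemble:
    """Read a binary trajectory (XTC/DCD/...) against a PDB topology.

    Delegates to MDAnalysis; coordinates are converted to Å if needed.
    """
    import MDAnalysis as mda

    top = read_structure(topology_pdb)
    if isinstance(top, TrajectoryEnsemble):
        top = top.topology
    u = mda.Universe(str(topology_pdb), str(traj_path))
    if len(u.atoms) != len(top):
        raise ValueError("trajectory atom count differs from topology PDB")
    frames = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
    times = np.array([ts.time for ts in u.trajectory], dtype=float)
    return TrajectoryEnsemble(topology=top, frames=frames, times=times)


def write_structure(
    obj: StructureModel | TrajectoryEnsemble, path: str | Path
) -> None:
    """Write a structure (or ensemble, as multi-MODEL) to PDB."""
    from Bio.PDB import PDBIO, StructureBuilder

    if isinstance(obj, TrajectoryEnsemble):
        topology = obj.topology
        frame_coords: Iterable[np.ndarray] = obj.frames
    else:
        topology = obj
        frame_coords = [obj.coords]

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    for i, coords in enumerate(frame_coords):
        builder.init_model(i)
        current_chain = None
        current_res = None
        for atom, xyz in zip(topology.atoms, coords):
            if atom.chain != current_chain:
                builder.init_chain(atom.chain)
                builder.init_seg("    ")
                current_chain = atom.chain
                current_res = None
            key = (atom.resid, atom.resname)
            if key != current_res:
                builder.init_residue(atom.resname, " ", atom.resid, " ")
                current_res = key
            builder.init_atom(
                atom.name,
                np.asarray(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                atom.name.center(4)[:4],
                atom.serial,
                atom.element,
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# PTM patterns


def mark_phosphosites(
    s: StructureModel,
    sites: Sequence[tuple[str, int]],
    flagged: Sequence[tuple[str, int]] = (),
) -> PTMPattern:
    """Read the modification state of ``sites`` off a structure.

    A site is *on* when its residue name is a phospho-serine code (SEP) or
    when it appears in ``flagged``. Raises if a site does not exist.
    """
    flagged_set = set(flagged)
    residues = {(a.chain, a.resid): a.resname for a in s.atoms}
    state = []
    labelled = []
    for chain, resid in sites:
        if (chain, resid) not in residues:
            raise KeyError(f"site {chain}/{resid} not found in structure")
        resname = residues[(chain, resid)]
        on = resname in PHOSPHOSERINE_CODES or (chain, resid) in flagged_set
        state.append(1 if on else 0)
        labelled.append((chain, resid, _site_label(chain, resid)))
    return PTMPattern(sites=labelled, state=tuple(state))


def enumerate_patterns(sites: Sequence[tuple[str, int]]) -> list[PTMPattern]:
    """All 2^N binary on/off patterns over ``sites``, lexicographic order."""
    if not sites:
        raise ValueError("enumerate_patterns requires at least one site")
    labelled = [(c, r, _site_label(c, r)) for c, r in sites]
    return [
        PTMPattern(sites=list(labelled), state=state)
        for state in itertools.product((0, 1), repeat=len(sites))
    ]


# ---------------------------------------------------------------------------
# Equilibration detection


def rmsd_series(t: TrajectoryEnsemble, reference: StructureModel) -> np.ndarray:
    """Per-frame Cα RMSD (nm) to ``reference`` after optimal superposition."""
    ca = t.topology.atom_indices("CA")
    if ca.size == 0:
        raise ValueError("no Cα atoms in topology")
    ref = reference.coords[ca]
    out = np.empty(t.n_frames)
    for i in range(t.n_frames):
        out[i] = fitted_rmsd(t.frames[i][ca], ref) / 10.0  # Å -> nm
    return out


def select_equilibrated(
    t: TrajectoryEnsemble,
    reference: StructureModel | None = None,
    window: int | None = None,
    slope_tol: float = 1e-4,
) -> TrajectoryEnsemble:
    """Mark the equilibrated portion of a trajectory from its RMSD plateau.

    The Cα RMSD (nm) to ``reference`` (default: first frame) is scanned
    with a sliding linear fit of length ``window`` (default: 10% of frames,
    minimum 3). The window starts at the first frame from which every
    subsequent fitted slope stays within ``slope_tol`` (nm/frame) through
    the end. If the series never flattens, the last half is used with a
    warning; the window is never empty.
    """
    if reference is None:
        reference = t.frame_structure(0)
    if window is None:
        window = max(3, t.n_frames // 10)
    if t.n_frames <= window:
        raise ValueError("trajectory shorter than the slope window")

    series = rmsd_series(t, reference)
    x = np.arange(window, dtype=float)
    x -= x.mean()
    denom = float((x * x).sum())
    n_pos = t.n_frames - window + 1
    slopes = np.empty(n_pos)
    for i in range(n_pos):
        y = series[i : i + window]
        slopes[i] = float((x * (y - y.mean())).sum()) / denom

    flat = np.abs(slopes) <= slope_tol
    start = None
    # first i such that every window from i on is flat
    ok_from = np.flip(np.cumprod(np.flip(flat))).astype(bool)
    hits = np.nonzero(ok_from)[0]
    if hits.size:
        start = int(hits[0])
    if start is None:
        warnings.warn(
            "RMSD never plateaus under the slope tolerance; "
            "falling back to the last half of the trajectory"
        )
        start = t.n_frames // 2
    return TrajectoryEnsemble(
        topology=t.topology,
        frames=t.frames,
        times=t.times,
        eq_window=(start, t.n_frames),
        planted_modes=t.planted_modes,
    )
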