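"""Essential dynamics and the free-energy landscape stability markers.

The trajectory is projected on the first two principal components of Cα
motion; the 2-D occupancy histogram over that plane is the free-energy
landscape (high occupancy = low free energy). Two markers are read off it:

* ``abs_min`` — the probability mass of the most occupied 3x3 box, i.e.
  the population of the deepest free-energy minimum;
* ``n_min`` — the number of distinct landscape minima whose box occupancy
  reaches a fraction (default 0.7) of the deepest one.

A stable conformation shows one or few large minima; a metastable system
scatters mass over many.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import superpose
from .model_io import StructureModel, TrajectoryEnsemble

__all__ = [
    "EDBasis",
    "FELGrid",
    "essential_dynamics",
    "project",
    "build_fel",
    "count_minima",
    "fel_markers",
]


@dataclass
class EDBasis:
    """Principal components of positional motion (essential dynamics).

    ``eigenvectors`` columns are orthonormal 3n-vectors over the selected
    atoms; ``eigenvalues`` (Å²) are sorted descending. ``atom_indices``
    records which topology atoms the basis spans.
    """

    mean_coords: np.ndarray  # (n_sel, 3) Å
    eigenvectors: np.ndarray  # (3*n_sel, n_modes)
    eigenvalues: np.ndarray  # (n_modes,), Å², descending
    atom_indices: np.ndarray


def _superposed_selection(t: TrajectoryEnsemble, sel: np.ndarray) -> np.ndarray:
    """Eq-window frames of the selection, superposed on their mean (one pass)."""
    frames = t.eq_frames()[:, sel, :]
    ref = frames[0]
    fitted = np.stack([superpose(f, ref) for f in frames])
    mean = fitted.mean(axis=0)
    fitted = np.stack([superpose(f, mean) for f in fitted])
    return fitted


def essential_dynamics(
    t: TrajectoryEnsemble, selection: str = "CA"
) -> EDBasis:
    """Diagonalize the positional covariance of the selected atoms.

    Frames in the equilibrated window are superposed on their mean
    structure (one refinement pass), the 3n x 3n covariance of the
    selection's coordinates is built and eigendecomposed. Eigenvectors get
    a deterministic sign (largest-magnitude component positive).
    """
    sel = t.topology.atom_indices(selection)
    if sel.size == 0:
        raise ValueError(f"no {selection} atoms in topology")
    lo, hi = t.eq_window
    if hi - lo < 2:
        raise ValueError("essential dynamics needs at least 2 frames")
    fitted = _superposed_selection(t, sel)
    mean = fitted.mean(axis=0)
    x = (fitted - mean).reshape(len(fitted), -1)
    cov = x.T @ x / len(x)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return EDBasis(
        mean_coords=mean,
        eigenvectors=vecs,
        eigenvalues=vals,
        atom_indices=sel,
    )


def project(t: TrajectoryEnsemble, basis: EDBasis, n_modes: int = 2) -> np.ndarray:
    """Project eq-window frames on the first ``n_modes`` components, Å."""
    fitted = _superposed_selection(t, basis.atom_indices)
    x = (fitted - basis.mean_coords).reshape(len(fitted), -1)
    return x @ basis.eigenvectors[:, :n_modes]


@dataclass
class FELGrid:
    """Occupancy histogram over the first two essential-dynamics modes."""

    probs: np.ndarray  # (n_bins, n_bins), sums to 1
    edges: tuple[np.ndarray, np.ndarray]
    box: int = 3
    frac: float = 0.7

    @property
    def abs_min(self) -> float:
        """Probability of the most occupied box (the deepest minimum)."""
        return float(_window_sums(self.probs, self.box).max())

    @property
    def minima(self) -> list[tuple[int, int, float]]:
        """Surviving minima as (row, col, summed probability)."""
        return _find_minima(self.probs, self.box, self.frac)

    @property
    def n_min(self) -> int:
        return len(self.minima)

    def free_energy(self, kt: float = 1.0) -> np.ndarray:
        """-kT ln p for plotting; empty bins map to +inf."""
        with np.errstate(divide="ignore"):
            return -kt * np.log(self.probs)


def _window_sums(probs: np.ndarray, box: int) -> np.ndarray:
    """Summed probability of every box x box window fully inside the grid."""
    n = probs.shape[0]
    if n < box:
        return probs.sum(keepdims=True).reshape(1, 1)
    c = np.cumsum(np.cumsum(probs, axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    m = n - box + 1
    return (
        c[box : box + m, box : box + m]
        - c[0:m, box : box + m]
        - c[box : box + m, 0:m]
        + c[0:m, 0:m]
    )


def _find_minima(probs: np.ndarray, box: int, frac: float) -> list[tuple[int, int, float]]:
    sums = _window_sums(probs, box)
    max_sum = float(sums.max())
    if max_sum <= 0:
        return []
    m = sums.shape[0]
    out: list[tuple[int, int, float]] = []
    for i in range(m):
        for j in range(m):
            s = sums[i, j]
            if s < frac * max_sum or s <= 0:
                continue
            # non-maximum suppression among overlapping windows; ties go to
            # the lower (row, col) index
            keep = True
            for di in range(-(box - 1), box):
                for dj in range(-(box - 1), box):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if not (0 <= a < m and 0 <= b < m):
                        continue
                    other = sums[a, b]
                    if other > s or (other == s and (a, b) < (i, j)):
                        keep = False
                        break
                if not keep:
                    break
            if keep:
                out.append((i, j, float(s)))
    return out


def build_fel(
    t: TrajectoryEnsemble,
    basis: EDBasis,
    n_bins: int = 20,
    box: int = 3,
    frac: float = 0.7,
) -> FELGrid:
    """Histogram the PC1/PC2 projections on an ``n_bins`` x ``n_bins`` grid.

    Bins are equal-width over the data range per axis; probabilities are
    frame fractions. A degenerate axis (all projections equal) collapses to
    a single occupied bin.
    """
    proj = project(t, basis, n_modes=2)
    # both axes are Å along principal modes: use one common bin width
    # (the larger axis range), each axis centered on its own data midpoint
    spans = [
        (float(proj[:, k].min()), float(proj[:, k].max())) for k in range(2)
    ]
    width = max(hi - lo for lo, hi in spans)
    if width < 1e-12:
        width = 1.0
    edges = []
    for lo, hi in spans:
        mid = (lo + hi) / 2.0
        edges.append(np.linspace(mid - width / 2.0, mid + width / 2.0, n_bins + 1))
    counts, _, _ = np.histogram2d(proj[:, 0], proj[:, 1], bins=edges)
    probs = counts / counts.sum()
    return FELGrid(probs=probs, edges=(edges[0], edges[1]), box=box, frac=frac)


def count_minima(g: FELGrid, box: int | None = None, frac: float | None = None) -> int:
    """Number of distinct landscape minima reaching ``frac`` of the deepest.

    Sliding ``box`` x ``box`` windows are scored by summed probability; a
    window counts when it reaches ``frac`` of the best window's sum and is
    a local maximum among the windows overlapping it. Always >= 1 for a
    normalized grid.
    """
    return len(
        _find_minima(
            g.probs,
            g.box if box is None else box,
            g.frac if frac is None else frac,
        )
    )


def fel_markers(
    t: TrajectoryEnsemble,
    n_bins: int = 20,
    box: int = 3,
    frac: float = 0.7,
) -> tuple[float, int, FELGrid]:
    """Convenience: ED basis -> FEL -> (abs_min, n_min, grid)."""
    basis = essential_dynamics(t)
    grid = build_fel(t, basis, n_bins=n_bins, box=box, frac=frac)
    return grid.abs_min, grid.n_min, grid
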