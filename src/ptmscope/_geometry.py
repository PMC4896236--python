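"""Rigid-body superposition and RMSD utilities (Kabsch least squares)."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``mobile`` onto ``reference``.

    Both arrays are (n, 3). Returns ``(R, t)`` such that
    ``mobile @ R.T + t`` is the least-squares fit. Mass-unweighted.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    a = mobile - mob_c
    b = reference - ref_c
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mob_c
    return rot, trans


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``reference``."""
    rot, trans = kabsch(mobile, reference)
    return mobile @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two (n, 3) coordinate sets, Å."""
    diff = a - b
    return float(np.sqrt((diff * diff).sum() / len(a)))


def fitted_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal superposition, Å."""
    return rmsd(superpose(mobile, reference), reference)
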