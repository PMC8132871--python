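"""Trajectory analysis: dihedral PCA, radius of gyration, RMSD.

Dihedral PCA (dPCA) is ordinary principal component analysis applied to
the cos/sin feature matrix, which sidesteps the periodicity of raw angles.
The two physically meaningful collective variables used for free-energy
surfaces are the mass-weighted radius of gyration and the RMSD from a
reference structure after optimal rigid superposition (Kabsch).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ShapeError
from .featurize import FeatureMatrix

__all__ = [
    "DPCAResult",
    "CoordinateTrajectory",
    "dpca",
    "radius_of_gyration",
    "rmsd",
]


@dataclass
class DPCAResult:
    """Orthonormal components (rows), all eigenvalues (non-increasing), and
    per-frame projections on the leading components."""

    components: np.ndarray    # (n_components, 2D)
    eigenvalues: np.ndarray   # (2D,), full spectrum
    projections: np.ndarray   # (T, n_components)
    mean: np.ndarray          # feature mean used for centering


@dataclass
class CoordinateTrajectory:
    """frames x atoms x 3 coordinates (Angstrom) with per-atom masses."""

    xyz: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim == 2:
            self.xyz = self.xyz[None]
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.size != self.xyz.shape[1]:
            raise ShapeError("mass count must equal atom count")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]


def dpca(features: FeatureMatrix | np.ndarray, n_components: int) -> DPCAResult:
    """PCA of the mean-centered feature covariance.

    Deterministic up to component sign, which is fixed by making each
    component's largest-magnitude entry positive.
    """
    X = features.features if isinstance(features, FeatureMatrix) else np.atleast_2d(np.asarray(features, dtype=float))
    T, P = X.shape
    if T < 2:
        raise ValueError("need at least 2 frames for PCA")
    if not 1 <= n_components <= P:
        raise ValueError(f"n_components must lie in [1, {P}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (T - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    # sign convention: largest-|entry| of each component positive
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    comps = comps[:n_components]
    return DPCAResult(comps, evals, Xc @ comps.T, mean)


def radius_of_gyration(xyz, masses) -> float:
    """Mass-weighted RMS distance from the center of mass, same units as xyz."""
    xyz = np.asarray(xyz, dtype=float)
    m = np.asarray(masses, dtype=float)
    if xyz.shape[0] != m.size:
        raise ShapeError("mass count must equal atom count")
    M = m.sum()
    if M <= 0:
        raise ValueError("total mass must be > 0")
    com = (m[:, None] * xyz).sum(axis=0) / M
    d2 = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(m * d2) / M))


def rmsd(frame, reference, superpose: bool = True) -> float:
    """RMSD between two conformations, optionally after optimal rigid
    superposition (mass-unweighted Kabsch alignment).

    Callers wanting an atom subset (e.g. alpha carbons) select it upstream.
    """
    A = np.asarray(frame, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ShapeError(f"coordinate shapes must match and be (n, 3), got {A.shape} vs {B.shape}")
    if superpose:
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
        rot, _ = Rotation.align_vectors(B, A)
        A = rot.apply(A)
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def write_projection_tsv(path: str | Path, result: DPCAResult) -> None:
    """Projection TSV: frame, pc1..pcK."""
    K = result.components.shape[0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\t" + "\t".join(f"pc{j + 1}" for j in range(K)) + "\n")
        for i, row in enumerate(result.projections):
            fh.write(f"{i}\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def write_eigenvalue_tsv(path: str | Path, result: DPCAResult) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("component\teigenvalue\n")
        for i, v in enumerate(result.eigenvalues):
            fh.write(f"{i + 1}\t{v:.10g}\n")
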