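"""Synthetic metastable dihedral trajectories with ground-truth labels.

The generator emulates the statistical structure the sampling method
assumes: a molecule hopping between a few Ramachandran-like basins, with
angular noise around each basin center.  A hidden Markov chain over basins
produces the state path; given the state, each dihedral is drawn
independently from a von Mises distribution centered on that basin's
center.  The hidden path is returned as labels, so downstream models
(autoencoder latents, dihedral PCA) can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .featurize import AngleTrajectory, wrap_angle

__all__ = [
    "BasinModel",
    "generate_basin_trajectory",
    "default_two_basin_model",
    "write_labels_tsv",
    "read_labels_tsv",
]


@dataclass
class BasinModel:
    """B basins over D dihedrals: centers, von Mises concentration kappa,
    row-stochastic transition matrix, initial basin, and the seed."""

    centers: np.ndarray            # (B, D), angles in (-pi, pi]
    concentration: float           # von Mises kappa, shared by all angles
    transition: np.ndarray         # (B, B), rows sum to 1
    initial_basin: int = 0
    seed: int = 0

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        B = self.centers.shape[0]
        if self.transition.shape != (B, B):
            raise ValueError(f"transition must be ({B}, {B})")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be >= 0")
        if np.any(self.centers <= -np.pi) or np.any(self.centers > np.pi):
            raise ValueError("centers must lie in (-pi, pi]")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not 0 <= self.initial_basin < B:
            raise ValueError("initial_basin out of range")

    @property
    def n_basins(self) -> int:
        return self.centers.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.centers.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def generate_basin_trajectory(
    model: BasinModel, T: int, rng: np.random.Generator | None = None
) -> tuple[AngleTrajectory, np.ndarray]:
    """Sample T frames; returns (trajectory, basin labels).

    Fully reproducible: with rng omitted, the stream is seeded from
    model.seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    B = model.n_basins
    labels = np.empty(T, dtype=int)
    state = model.initial_basin
    cum = np.cumsum(model.transition, axis=1)
    u = rng.random(T)
    for t in range(T):
        labels[t] = state
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, B - 1)  # guard against roundoff at u ~ 1
    angles = rng.vonmises(model.centers[labels], model.concentration)
    return AngleTrajectory(np.asarray(wrap_angle(angles))), labels


def default_two_basin_model(D: int, seed: int = 0) -> BasinModel:
    """Two Ramachandran-like basins repeated across D dihedrals.

    Basin A alternates helix-like values (-60 deg, -45 deg); basin B
    alternates sheet-like values (-120 deg, +130 deg).  kappa = 20 (about
    13 deg circular spread) and stay-probability 0.995 give well-separated,
    long-lived metastable states.  This is the standard fixture for the
    autoencoder and dihedral-PCA tests.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    a = np.where(np.arange(D) % 2 == 0, -np.pi / 3.0, -np.pi / 4.0)
    b = np.where(np.arange(D) % 2 == 0, -2.0 * np.pi / 3.0, 13.0 * np.pi / 18.0)
    transition = np.array([[0.995, 0.005], [0.005, 0.995]])
    return BasinModel(
        centers=np.stack([a, b]),
        concentration=20.0,
        transition=transition,
        initial_basin=0,
        seed=seed,
    )


def write_labels_tsv(path: str | Path, labels: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\tbasin\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")


def read_labels_tsv(path: str | Path) -> np.ndarray:
    labels = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header != ["frame", "basin"]:
            raise ValueError(f"malformed labels TSV header: {header}")
        for line in fh:
            labels.append(int(line.split("\t")[1]))
    return np.asarray(labels, dtype=int)
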