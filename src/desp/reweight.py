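"""Reweighting biased trajectories to the canonical ensemble.

A bias V_bias added to the physical potential tilts the sampled density by
exp(-V_bias/kBT); each saved frame therefore receives an importance weight

    w_i  proportional to  exp(+V_bias,i / kBT),

normalized to sum to one (the printed form of the reweighting relation in
the source literature carries a negative beta and a stray exponent index;
we implement the standard canonical-ensemble result, which is the only
convention under which an exactly known biased toy run recovers its
Boltzmann distribution).  Weighted histograms over one or two collective
variables give the unbiased probability p per bin and the potential of
mean force F = -kBT ln p, shifted so its minimum is zero.  Bins never
visited are reported as unvisited, not as F = 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .biasing import BiasRecord
from .errors import ShapeError

__all__ = [
    "WeightedTrajectory",
    "PMFGrid",
    "CollectiveVariable",
    "frame_weights",
    "assign_block_bias",
    "pmf",
    "write_pmf_tsv",
]


@dataclass
class WeightedTrajectory:
    """Normalized per-frame importance weights and the temperature used."""

    weights: np.ndarray
    kbt: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        s = self.weights.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("weights must have a positive finite sum")
        self.weights = self.weights / s

    @property
    def n_frames(self) -> int:
        return self.weights.size


@dataclass
class CollectiveVariable:
    """Named deterministic map from a frame to a real number."""

    name: str
    func: Callable[[np.ndarray], float]

    def __call__(self, frame) -> float:
        v = float(self.func(frame))
        if not np.isfinite(v):
            raise ValueError(f"collective variable {self.name} is non-finite")
        return v

    def series(self, frames) -> np.ndarray:
        return np.array([self(f) for f in frames])


@dataclass
class PMFGrid:
    """Binned CV grid: probability, free energy (min-shifted to 0), counts.

    F is NaN on unvisited bins; `visited` marks bins with any weight.
    Supports 1-D (edges length 1) and 2-D grids.
    """

    edges: list[np.ndarray]
    p: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    visited: np.ndarray
    kbt: float

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def frame_weights(bias_values, kbt: float) -> WeightedTrajectory:
    """Importance weights w_i ~ exp(+V_i/kBT), guarded against overflow."""
    v = np.asarray(bias_values, dtype=float)
    if kbt <= 0:
        raise ValueError("kbt must be > 0")
    if not np.all(np.isfinite(v)):
        raise ValueError("bias values must be finite")
    x = v / kbt
    x = x - np.max(x)  # overflow guard; normalization removes the shift
    return WeightedTrajectory(np.exp(x), kbt)


def assign_block_bias(
    bias_records: Sequence[BiasRecord],
    frame_steps,
    block_length: int | None = None,
) -> np.ndarray:
    """Per-frame bias: the V_bias of the block active at each frame's step.

    Blocks are half-open [start, start + block_length): a frame exactly at
    a boundary takes the newly started block's value.  Frames before the
    first record (the unbiased bootstrap) get 0.  The final frame of a run
    lands on the closing edge of the last block and inherits its value;
    any frame beyond that is an error.  block_length defaults to the
    spacing of the records.
    """
    steps = np.asarray(frame_steps, dtype=int)
    if np.any(np.diff(steps) < 0):
        raise ValueError("frame steps must be sorted ascending")
    if len(bias_records) == 0:
        return np.zeros(steps.size)
    starts = np.array([r.step for r in bias_records], dtype=int)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("bias records must have strictly increasing steps")
    if block_length is None:
        block_length = int(starts[1] - starts[0]) if starts.size > 1 else None
    if block_length is not None and np.any(steps > starts[-1] + block_length):
        raise ValueError("frame step beyond the last bias record")
    values = np.array([r.v_bias for r in bias_records])
    idx = np.searchsorted(starts, steps, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, None)], 0.0)
    return out


def pmf(
    cv_values,
    weights: WeightedTrajectory,
    bins=50,
    ranges=None,
) -> PMFGrid:
    """Weighted histogram over one or two CV series -> probability and PMF.

    cv_values: a 1-D series, or a pair/2-column array for a 2-D grid.
    bins/ranges follow numpy.histogram(dd) semantics.
    """
    cv = np.asarray(cv_values, dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    elif cv.ndim == 2 and cv.shape[0] in (1, 2) and cv.shape[1] == weights.n_frames:
        cv = cv.T
    if cv.shape[0] != weights.n_frames:
        raise ShapeError("cv series length must equal the number of weights")
    if cv.shape[1] not in (1, 2):
        raise ShapeError("only 1-D and 2-D collective-variable grids are supported")

    if not np.isscalar(bins):
        b = np.asarray(bins, dtype=object)
        if b.ndim == 1 and np.isscalar(b[0]):  # one explicit edge array
            bins = [np.asarray(bins, dtype=float)] * cv.shape[1]
    hist, edges = np.histogramdd(cv, bins=bins, range=ranges, weights=weights.weights)
    counts, _ = np.histogramdd(cv, bins=edges)
    visited = counts > 0
    p = hist / hist.sum()
    F = np.full_like(p, np.nan)
    with np.errstate(divide="ignore"):
        F[visited] = -weights.kbt * np.log(p[visited])
    F[visited] -= np.nanmin(F[visited])
    return PMFGrid(list(edges), p, F, counts.astype(int), visited, weights.kbt)


def write_pmf_tsv(path: str | Path, grid: PMFGrid) -> None:
    """PMF TSV: bin center(s), p, F, count, visited flag."""
    centers = grid.centers
    with open(path, "w", encoding="utf-8") as fh:
        dims = len(centers)
        head = "\t".join(f"center_{i + 1}" for i in range(dims))
        fh.write(f"{head}\tp\tF\tcount\tvisited\n")
        it = np.ndindex(grid.p.shape)
        for idx in it:
            cs = "\t".join(format(centers[d][idx[d]], ".10g") for d in range(dims))
            F = grid.free_energy[idx]
            fh.write(
                f"{cs}\t{grid.p[idx]:.10g}\t"
                f"{'nan' if np.isnan(F) else format(F, '.10g')}\t"
                f"{grid.counts[idx]}\t{int(grid.visited[idx])}\n"
            )
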