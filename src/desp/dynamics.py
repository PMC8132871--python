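"""Toy dynamics on the torus, plus the adapter contract for real engines.

The built-in engine integrates overdamped (first-order) Langevin dynamics
on periodic model potentials over D angles,

    theta <- wrap(theta + (-grad U(theta) + F_extra) * dt / gamma
                  + sqrt(2 kBT dt / gamma) * xi),   xi ~ N(0, I),

whose stationary distribution is Boltzmann, exp(-U/kBT).  The toy
coordinates ARE the dihedral angles, so the latent-space bias force applies
directly.  A real molecular-dynamics engine is plugged in through the
EngineAdapter protocol instead; how it maps generalized dihedral forces to
its own coordinates is its own business.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .errors import AdapterError, ConfigurationError, DespError
from .featurize import AngleTrajectory, wrap_angle

__all__ = [
    "TorusPotential",
    "LangevinConfig",
    "SimState",
    "make_double_well",
    "make_cosine_wells",
    "product_potential",
    "langevin_step",
    "run_unbiased",
    "EngineAdapter",
    "LangevinEngine",
]


@dataclass
class TorusPotential:
    """Energy/gradient pair, periodic with period 2*pi per coordinate."""

    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    n_dim: int
    parameters: dict = field(default_factory=dict)


def make_double_well(center: float, barrier_height: float) -> TorusPotential:
    """1-D double well U = (h/2) (1 - cos 2(theta - c)).

    Minima (U = 0) at c and c + pi; the barrier between them is h.
    """
    if barrier_height <= 0:
        raise ValueError("barrier_height must be > 0")
    h = float(barrier_height)
    c = float(center)

    def energy(theta):
        return float(0.5 * h * (1.0 - np.cos(2.0 * (np.asarray(theta)[0] - c))))

    def gradient(theta):
        return np.array([h * np.sin(2.0 * (np.asarray(theta)[0] - c))])

    return TorusPotential(energy, gradient, 1, {"type": "double_well", "center": c, "barrier_height": h})


def make_cosine_wells(centers, heights, multiplicities) -> TorusPotential:
    """Separable potential: U = sum_d (h_d/2)(1 - cos m_d (theta_d - c_d))."""
    c = np.asarray(centers, dtype=float)
    h = np.asarray(heights, dtype=float)
    m = np.asarray(multiplicities, dtype=float)
    if not (c.shape == h.shape == m.shape):
        raise ValueError("centers, heights, multiplicities must have equal shapes")
    if np.any(h <= 0):
        raise ValueError("heights must be > 0")

    def energy(theta):
        return float(np.sum(0.5 * h * (1.0 - np.cos(m * (np.asarray(theta) - c)))))

    def gradient(theta):
        return 0.5 * h * m * np.sin(m * (np.asarray(theta) - c))

    return TorusPotential(energy, gradient, c.size,
                          {"type": "cosine_wells", "centers": c, "heights": h, "multiplicities": m})


def product_potential(pots: list[TorusPotential]) -> TorusPotential:
    """Direct sum of independent 1-D (or n-D) potentials over disjoint axes."""
    dims = [p.n_dim for p in pots]
    offsets = np.cumsum([0] + dims)

    def energy(theta):
        theta = np.asarray(theta)
        return float(sum(p.energy(theta[offsets[i]:offsets[i + 1]]) for i, p in enumerate(pots)))

    def gradient(theta):
        theta = np.asarray(theta)
        return np.concatenate(
            [np.atleast_1d(p.gradient(theta[offsets[i]:offsets[i + 1]])) for i, p in enumerate(pots)]
        )

    return TorusPotential(energy, gradient, int(sum(dims)), {"type": "product"})


@dataclass
class LangevinConfig:
    """Integrator settings in reduced units (kBT = 1 by default)."""

    dt: float = 0.01
    friction: float = 1.0
    kbt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.friction <= 0 or self.kbt <= 0:
            raise ConfigurationError("dt, friction, kbt must all be > 0")


@dataclass
class SimState:
    """Walker state: wrapped angles, step counter, and the noise stream."""

    angles: np.ndarray
    step: int = 0
    rng: np.random.Generator | None = None

    def __post_init__(self):
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        self.angles = np.asarray(wrap_angle(self.angles))


#: Stability guard threshold for dt * max|grad| / friction (must be well
#: below the torus half-width pi).
_STABILITY_LIMIT = 0.5


def check_stability(pot: TorusPotential, cfg: LangevinConfig, n_probe: int = 512) -> float:
    """Estimate dt * max|grad| / friction on a probe grid; raise if unstable."""
    rng = np.random.default_rng(0)
    thetas = rng.uniform(-np.pi, np.pi, size=(n_probe, pot.n_dim))
    gmax = max(float(np.max(np.abs(pot.gradient(t)))) for t in thetas)
    q = cfg.dt * gmax / cfg.friction
    if q > _STABILITY_LIMIT:
        raise ConfigurationError(
            f"unstable integrator settings: dt*max|grad|/friction = {q:.3g} > {_STABILITY_LIMIT}"
        )
    return q


def langevin_step(
    state: SimState,
    pot: TorusPotential,
    extra_force: np.ndarray | None,
    cfg: LangevinConfig,
) -> SimState:
    """One Euler-Maruyama update; mutates and returns the state."""
    rng = state.rng
    if rng is None:
        rng = state.rng = np.random.default_rng(cfg.seed)
    f = -pot.gradient(state.angles)
    if extra_force is not None:
        f = f + extra_force
    noise = np.sqrt(2.0 * cfg.kbt * cfg.dt / cfg.friction) * rng.standard_normal(pot.n_dim)
    theta = state.angles + f * cfg.dt / cfg.friction + noise
    if not np.all(np.isfinite(theta)):
        raise DespError(f"non-finite state at step {state.step}")
    state.angles = np.asarray(wrap_angle(theta))
    state.step += 1
    return state


def _advance(state, pot, n_steps, extra_force, cfg, save_every=None, chunk=4096):
    """Tight inner loop; draws noise in chunks (stream-identical to per-step
    draws for numpy Generators).  Returns saved frames (possibly empty)."""
    rng = state.rng
    if rng is None:
        rng = state.rng = np.random.default_rng(cfg.seed)
    D = pot.n_dim
    amp = np.sqrt(2.0 * cfg.kbt * cfg.dt / cfg.friction)
    scale = cfg.dt / cfg.friction
    grad = pot.gradient
    theta = state.angles
    frames = []
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal((m, D))
        for i in range(m):
            f = -grad(theta)
            if extra_force is not None:
                f = f + extra_force
            theta = theta + f * scale + amp * noise[i]
            theta = theta - 2.0 * np.pi * np.floor((theta + np.pi) / (2.0 * np.pi))
            np.copyto(theta, np.pi, where=theta <= -np.pi)
            state.step += 1
            if save_every is not None and state.step % save_every == 0:
                frames.append(theta.copy())
        done += m
        if not np.all(np.isfinite(theta)):
            raise DespError(f"non-finite state at step {state.step}")
    state.angles = theta
    return frames


def run_unbiased(
    state: SimState,
    pot: TorusPotential,
    n_steps: int,
    save_every: int,
    cfg: LangevinConfig,
) -> tuple[AngleTrajectory, SimState]:
    """n_steps of unbiased dynamics, saving a frame every save_every steps."""
    if n_steps % save_every != 0:
        raise ConfigurationError("n_steps must be a multiple of save_every")
    check_stability(pot, cfg)
    frames = _advance(state, pot, n_steps, None, cfg, save_every=save_every)
    return AngleTrajectory(np.array(frames)), state


@runtime_checkable
class EngineAdapter(Protocol):
    """Contract a dynamics engine must satisfy to be driven by the loop.

    advance() runs n_steps with a constant generalized force on the dihedral
    coordinates (None = unbiased) and returns the frames saved at the
    save_every cadence, as rows of angles; current_angles() reports the
    instantaneous dihedrals.  Contract violations must raise AdapterError
    rather than corrupting loop state.
    """

    def advance(self, n_steps: int, extra_force: np.ndarray | None,
                save_every: int | None) -> list[np.ndarray]: ...

    def current_angles(self) -> np.ndarray: ...

    @property
    def step(self) -> int: ...


class LangevinEngine:
    """Built-in adapter: the overdamped Langevin walker on a TorusPotential."""

    def __init__(self, pot: TorusPotential, cfg: LangevinConfig,
                 initial_angles, rng: np.random.Generator | None = None):
        self.pot = pot
        self.cfg = cfg
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.state = SimState(np.asarray(initial_angles, dtype=float), 0, rng)
        if self.state.angles.shape != (pot.n_dim,):
            raise AdapterError(
                f"initial angles shape {self.state.angles.shape} != potential dim ({pot.n_dim},)"
            )
        check_stability(pot, cfg)

    def advance(self, n_steps, extra_force=None, save_every=None):
        if extra_force is not None:
            extra_force = np.asarray(extra_force, dtype=float)
            if extra_force.shape != (self.pot.n_dim,):
                raise AdapterError("extra_force has wrong shape")
        return _advance(self.state, self.pot, n_steps, extra_force, self.cfg,
                        save_every=save_every)

    def current_angles(self) -> np.ndarray:
        return self.state.angles.copy()

    @property
    def step(self) -> int:
        return self.state.step

    # -- checkpoint support -------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "angles": self.state.angles.copy(),
            "step": self.state.step,
            "rng_state": self.state.rng.bit_generator.state,
        }

    def load_state_dict(self, d: dict) -> None:
        self.state.angles = np.asarray(d["angles"], dtype=float)
        self.state.step = int(d["step"])
        self.state.rng.bit_generator.state = d["rng_state"]
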