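"""Latent-space KL biasing.

The sampling loop discourages revisiting known conformations by measuring,
in the autoencoder's latent space, how close the current conformation is to
the pool of previously saved ones.  Closeness is the Gaussian KL divergence

    V_KL = KL(N(mu0, S0) || N(mu1, S1))
         = 1/2 [ tr(S1^-1 S0) + (mu1 - mu0)^T S1^-1 (mu1 - mu0)
                 - k + ln(det S1 / det S0) ]

specialized to the diagonal covariances the encoder emits, aggregated over
a set of representatives drawn from the pool (minimum by default: the bias
reacts to the nearest visited region).  The biasing potential is an inverse
square,

    V_bias = (V_KL_upper / V_KL)^2,

so it is negligible while the walker explores fresh territory (V_KL large)
and grows steeply as the walker approaches an already-sampled conformation
(V_KL -> 0).  A floor on V_KL and a cap on V_bias absorb the coincident
limit.  The force on the dihedral coordinates is the exact gradient of the
composition angles -> cos/sin features -> encoder -> V_KL -> V_bias,
computed by backpropagation through the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ShapeError, TrainingDivergedError
from .vae import LatentGaussian, TrainedVAE

__all__ = [
    "BiasConfig",
    "BiasRecord",
    "kl_divergence_gaussians",
    "aggregate_kl",
    "bias_potential",
    "bias_force",
    "write_bias_tsv",
    "read_bias_tsv",
]


@dataclass
class BiasConfig:
    """Bias-potential settings.

    v_kl_upper sets the scale at which the bias reaches 1 energy unit; it
    can be raised for more aggressive or lowered for more conservative
    enhancement.  Setting it to 0 disables biasing entirely (zero potential
    and force), which is useful as a control.  Energies are in units of kBT
    for the built-in toy backend; adapters for real engines must declare
    their unit.
    """

    v_kl_upper: float = 1e-5
    n_representatives: int = 32
    aggregation: str = "min"  # or "mean"
    v_kl_floor: float = 1e-12
    v_bias_cap: float = 1e6
    energy_unit: str = "kBT"

    def __post_init__(self):
        if self.v_kl_upper < 0:
            raise ValueError("v_kl_upper must be >= 0 (0 disables the bias)")
        if not 0 < self.v_kl_floor:
            raise ValueError("v_kl_floor must be > 0")
        if self.v_bias_cap <= 0:
            raise ValueError("v_bias_cap must be > 0")
        if self.n_representatives < 1:
            raise ValueError("n_representatives must be >= 1")
        if self.aggregation not in ("min", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class BiasRecord:
    """One bias update: simulation step, V_KL, and the applied V_bias."""

    step: int
    v_kl: float
    v_bias: float


def kl_divergence_gaussians(g0: LatentGaussian, g1: LatentGaussian) -> float:
    """Closed-form KL(N0 || N1) for diagonal Gaussians; exact, >= 0."""
    if g0.k != g1.k:
        raise ShapeError(f"dimension mismatch: {g0.k} vs {g1.k}")
    dlv = g0.ln_var - g1.ln_var
    ratio = np.exp(dlv)                       # sigma0^2 / sigma1^2
    maha = (g1.mean - g0.mean) ** 2 * np.exp(-g1.ln_var)
    val = 0.5 * np.sum(ratio + maha - 1.0 - dlv, axis=-1)
    return float(val) if np.ndim(val) == 0 else val


def _pairwise_kl(current: LatentGaussian, reps_mean, reps_ln_var):
    """KL of `current` from each representative; vectorized over reps."""
    dlv = current.ln_var[None, :] - reps_ln_var
    ratio = np.exp(dlv)
    maha = (reps_mean - current.mean[None, :]) ** 2 * np.exp(-reps_ln_var)
    return 0.5 * np.sum(ratio + maha - 1.0 - dlv, axis=1)


def aggregate_kl(
    current: LatentGaussian,
    reps: "list[LatentGaussian] | LatentGaussian",
    config: BiasConfig,
) -> float:
    """Reduce the per-representative divergences with config.aggregation."""
    reps_mean, reps_ln_var = _rep_arrays(reps)
    if reps_mean.shape[0] == 0:
        raise ValueError("representative set is empty")
    kls = _pairwise_kl(current, reps_mean, reps_ln_var)
    return float(np.min(kls) if config.aggregation == "min" else np.mean(kls))


def _rep_arrays(reps):
    if isinstance(reps, LatentGaussian):
        return np.atleast_2d(reps.mean), np.atleast_2d(reps.ln_var)
    means = np.atleast_2d(np.array([r.mean for r in reps]))
    lvs = np.atleast_2d(np.array([r.ln_var for r in reps]))
    return means, lvs


def bias_potential(v_kl: float, config: BiasConfig) -> float:
    """(v_kl_upper / v_kl)^2 with floor and cap; monotone non-increasing."""
    if config.v_kl_upper == 0.0:
        return 0.0
    v = (config.v_kl_upper / max(v_kl, config.v_kl_floor)) ** 2
    return float(min(v, config.v_bias_cap))


def bias_force(
    model: TrainedVAE,
    angles: np.ndarray,
    reps: "list[LatentGaussian] | LatentGaussian",
    config: BiasConfig,
    return_record: bool = False,
):
    """-dV_bias/dtheta via exact backpropagation through the encoder.

    Differentiates through the argmin representative (first index at ties,
    the standard subgradient choice for a min); in the capped or floored
    regime the potential is locally constant and the force is zero.
    """
    angles = np.asarray(angles, dtype=float)
    D = model.config.d_dihedrals
    if angles.shape != (D,):
        raise ShapeError(f"angles must have shape ({D},), got {angles.shape}")

    cos_t = np.cos(angles)
    sin_t = np.sin(angles)
    x = np.empty(2 * D)
    x[0::2] = cos_t
    x[1::2] = sin_t

    mu, lv, cache = model._encode_forward(x[None, :])
    current = LatentGaussian(mu[0], lv[0])

    reps_mean, reps_ln_var = _rep_arrays(reps)
    if reps_mean.shape[0] == 0:
        raise ValueError("representative set is empty")
    kls = _pairwise_kl(current, reps_mean, reps_ln_var)
    if config.aggregation == "min":
        j = int(np.argmin(kls))
        v_kl = float(kls[j])
    else:
        v_kl = float(np.mean(kls))
    v_bias = bias_potential(v_kl, config)

    zero = np.zeros(D)
    capped = (
        config.v_kl_upper == 0.0
        or v_kl <= config.v_kl_floor
        or (config.v_kl_upper / max(v_kl, config.v_kl_floor)) ** 2 >= config.v_bias_cap
    )
    if capped:
        force = zero
    else:
        dV_dkl = -2.0 * config.v_kl_upper**2 / v_kl**3
        if config.aggregation == "min":
            sel_mean = reps_mean[j:j + 1]
            sel_lv = reps_ln_var[j:j + 1]
            scale = 1.0
        else:
            sel_mean = reps_mean
            sel_lv = reps_ln_var
            scale = 1.0 / reps_mean.shape[0]
        # dKL/dmu0 and dKL/dlnvar0, summed over the selected representatives
        inv_var1 = np.exp(-sel_lv)
        dmu0 = scale * np.sum((current.mean[None, :] - sel_mean) * inv_var1, axis=0)
        dlv0 = scale * np.sum(0.5 * (np.exp(current.ln_var[None, :] - sel_lv) - 1.0), axis=0)
        dx = model._encode_backward_input(cache, (dV_dkl * dmu0)[None, :], (dV_dkl * dlv0)[None, :])[0]
        # chain through the cos/sin featurization
        dtheta = -sin_t * dx[0::2] + cos_t * dx[1::2]
        force = -dtheta
        if not np.all(np.isfinite(force)):
            raise TrainingDivergedError("non-finite bias force")

    if return_record:
        return force, v_kl, v_bias
    return force


def write_bias_tsv(path: str | Path, records: list[BiasRecord]) -> None:
    """Bias trajectory TSV: (step, v_kl, v_bias), one row per update."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step\tv_kl\tv_bias\n")
        for r in records:
            fh.write(f"{r.step}\t{r.v_kl:.10g}\t{r.v_bias:.10g}\n")


def read_bias_tsv(path: str | Path) -> list[BiasRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header != ["step", "v_kl", "v_bias"]:
            raise ValueError(f"malformed bias TSV header: {header}")
        for line in fh:
            step, v_kl, v_bias = line.split("\t")
            records.append(BiasRecord(int(step), float(v_kl), float(v_bias)))
    return records
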