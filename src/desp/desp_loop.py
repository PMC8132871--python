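"""The enhanced-sampling loop.

Orchestrates the full method: (1) an unbiased bootstrap run whose saved
frames seed the pool; (2) initial autoencoder training on the pool; (3) a
biased phase in which, every n_biasing steps, the latest conformation is
encoded, its KL divergence from randomly drawn pool representatives sets
the biasing potential, and the resulting force (held fixed over the block)
steers the dynamics; frames keep being saved every n_saving steps, and the
model is retrained every retrain_every steps on a random pool subset.
Counter discipline follows

    n_biasing << n_saving << n_short << n_needed

with "<<" meaning a factor of at least ten, and all divisibility relations
needed to keep block, saving, and retraining boundaries aligned.

Randomness derives from a single run seed fanned out into independent
streams (dynamics noise, model init, training shuffles, representative
draws, subset draws), so a run is reproducible and a bias-disabled run is
bit-identical to plain unbiased dynamics with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .biasing import BiasConfig, BiasRecord, bias_force, write_bias_tsv
from .dynamics import LangevinConfig, LangevinEngine, TorusPotential, make_cosine_wells, make_double_well
from .errors import CheckpointError, ConfigurationError
from .featurize import AngleTrajectory, encode_features, write_angles_tsv
from .vae import LatentGaussian, LossTrace, TrainedVAE, VAEConfig, build_vae, encode, train

logger = logging.getLogger(__name__)

__all__ = [
    "DespConfig",
    "FramePool",
    "DespResult",
    "validate_config",
    "run_desp",
    "resume",
    "derive_streams",
]


@dataclass
class DespConfig:
    """Loop counters plus the component configs.

    Production-scale literature defaults are n_needed = 1e9, n_short = 1e7,
    n_saving = 1e4, n_biasing = 50, retraining every n_saving * 100 steps;
    desk-scale runs shrink every counter by the same orders-of-magnitude
    ladder (e.g. 50_000 / 5_000 / 500 / 50).
    """

    n_needed: int
    n_short: int
    n_saving: int
    n_biasing: int
    retrain_every: int | None = None      # default n_saving * 100
    retrain_subset: int = 50_000          # frames drawn from the pool
    retrain_max_epochs: int = 200
    bias_config: BiasConfig = field(default_factory=BiasConfig)
    vae_config: VAEConfig | None = None
    langevin_config: LangevinConfig | None = None
    seed: int = 0

    def resolved_retrain_every(self) -> int:
        return self.n_saving * 100 if self.retrain_every is None else self.retrain_every


def validate_config(cfg: DespConfig) -> DespConfig:
    """Enforce the counter ordering and divisibility; report all failures."""
    problems = []
    for small, big, names in (
        (cfg.n_biasing, cfg.n_saving, ("n_biasing", "n_saving")),
        (cfg.n_saving, cfg.n_short, ("n_saving", "n_short")),
        (cfg.n_short, cfg.n_needed, ("n_short", "n_needed")),
    ):
        if small < 1:
            problems.append(f"{names[0]} must be >= 1")
        elif big < 10 * small:
            problems.append(f"{names[1]} must be >= 10 * {names[0]} ({big} < {10 * small})")
    if cfg.n_saving >= 1 and cfg.n_short % cfg.n_saving != 0:
        problems.append("n_short must be divisible by n_saving")
    if cfg.n_biasing >= 1 and cfg.n_saving % cfg.n_biasing != 0:
        problems.append("n_saving must be divisible by n_biasing")
    if cfg.n_biasing >= 1 and (cfg.n_needed - cfg.n_short) % cfg.n_biasing != 0:
        problems.append("(n_needed - n_short) must be divisible by n_biasing")
    re_ = cfg.resolved_retrain_every()
    if cfg.n_saving >= 1 and re_ % cfg.n_saving != 0:
        problems.append("retrain_every must be divisible by n_saving")
    if cfg.retrain_subset < 1:
        problems.append("retrain_subset must be >= 1")
    if problems:
        raise ConfigurationError("; ".join(problems))
    return cfg


class FramePool:
    """Append-only archive of saved frames with cached encoder latents."""

    def __init__(self, n_dihedrals: int, latent_dim: int):
        self._frames: list[np.ndarray] = []
        self.latent_mean = np.empty((0, latent_dim))
        self.latent_ln_var = np.empty((0, latent_dim))
        self.n_dihedrals = n_dihedrals
        self.latent_dim = latent_dim

    def __len__(self) -> int:
        return len(self._frames)

    @property
    def frames(self) -> np.ndarray:
        return np.array(self._frames) if self._frames else np.empty((0, self.n_dihedrals))

    def append(self, frame: np.ndarray, model: TrainedVAE | None = None) -> None:
        self._frames.append(np.asarray(frame, dtype=float).copy())
        if model is not None:
            g = encode(model, _features_of(frame[None, :]))
            self.latent_mean = np.vstack([self.latent_mean, g.mean])
            self.latent_ln_var = np.vstack([self.latent_ln_var, g.ln_var])

    def refresh(self, model: TrainedVAE) -> None:
        """Recompute every cached latent with the (re)trained model."""
        g = encode(model, _features_of(self.frames))
        self.latent_mean = np.atleast_2d(g.mean)
        self.latent_ln_var = np.atleast_2d(g.ln_var)

    def representatives(self, indices) -> LatentGaussian:
        return LatentGaussian(self.latent_mean[indices], self.latent_ln_var[indices])


def _features_of(angles: np.ndarray) -> np.ndarray:
    return encode_features(AngleTrajectory(angles)).features


@dataclass
class DespResult:
    """Everything a finished run produced."""

    trajectory: AngleTrajectory          # all saved frames, bootstrap + biased
    frame_steps: np.ndarray              # simulation step of each saved frame
    n_bootstrap_frames: int
    bias_records: list[BiasRecord]
    loss_trace: LossTrace
    model: TrainedVAE
    n_completed: int


def derive_streams(seed: int) -> dict[str, np.random.Generator]:
    """Fan one run seed out into fixed, independent component streams."""
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("dynamics", "vae_init", "vae_train", "representatives", "subset")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _vae_seed(seed: int) -> int:
    # deterministic, below 2**31, distinct from the run seed itself
    return int(np.random.SeedSequence(seed).generate_state(3)[2] % (2**31))


class _DespRun:
    """Mutable run state; drives the loop and can checkpoint/restore."""

    def __init__(self, cfg: DespConfig, engine=None, run_dir: str | Path | None = None,
                 potential: TorusPotential | None = None):
        validate_config(cfg)
        self.cfg = cfg
        self.run_dir = Path(run_dir) if run_dir is not None else None
        streams = derive_streams(cfg.seed)
        self.rng_reps = streams["representatives"]
        self.rng_subset = streams["subset"]
        self.rng_train = streams["vae_train"]

        if engine is None:
            if potential is None or cfg.langevin_config is None:
                raise ConfigurationError("either an engine or (potential + langevin_config) is required")
            engine = LangevinEngine(potential, cfg.langevin_config,
                                    initial_angles=np.zeros(potential.n_dim),
                                    rng=streams["dynamics"])
        self.engine = engine
        self.potential = potential

        vcfg = cfg.vae_config
        if vcfg is None:
            raise ConfigurationError("vae_config is required")
        vcfg = dataclasses.replace(vcfg, seed=_vae_seed(cfg.seed))
        self.model = build_vae(vcfg)
        self.pool = FramePool(vcfg.d_dihedrals, vcfg.latent_dim)
        self.records: list[BiasRecord] = []
        self.trace = LossTrace()
        self.n_completed = 0
        self.frame_steps: list[int] = []
        self.n_bootstrap_frames = 0

    # ---- phases ----------------------------------------------------------

    def bootstrap(self) -> None:
        cfg = self.cfg
        frames = self.engine.advance(cfg.n_short, None, save_every=cfg.n_saving)
        self.n_completed += cfg.n_short
        for f in frames:
            self.pool.append(f)
        self.frame_steps.extend(range(cfg.n_saving, cfg.n_short + 1, cfg.n_saving))
        self.n_bootstrap_frames = len(self.pool)
        logger.info("bootstrap done: %d steps, pool size %d", cfg.n_short, len(self.pool))

    def initial_training(self) -> None:
        _, tr = train(self.model, self._training_features(), rng=self.rng_train)
        self.trace.extend(tr)
        self.pool.refresh(self.model)
        logger.info("initial training: %d epochs, best loss %.6g",
                    len(tr), self.model.best_loss)

    def _training_features(self) -> np.ndarray:
        n = len(self.pool)
        k = min(n, self.cfg.retrain_subset)
        idx = self.rng_subset.choice(n, size=k, replace=False) if k < n else np.arange(n)
        return _features_of(self.pool.frames[idx])

    def biased_blocks(self) -> None:
        cfg = self.cfg
        retrain_every = cfg.resolved_retrain_every()
        bias_on = cfg.bias_config.v_kl_upper > 0.0
        while self.n_completed < cfg.n_needed:
            if bias_on:
                # a frame saved at this very step coincides with the current
                # configuration; KL from itself is 0 and carries no novelty
                # signal, so it is excluded from the representative draw
                n_pool = len(self.pool)
                if n_pool > 1 and self.frame_steps and self.frame_steps[-1] == self.n_completed:
                    n_pool -= 1
                k = min(cfg.bias_config.n_representatives, n_pool)
                idx = self.rng_reps.choice(n_pool, size=k, replace=False)
                reps = self.pool.representatives(idx)
                force, v_kl, v_bias = bias_force(
                    self.model, self.engine.current_angles(), reps,
                    cfg.bias_config, return_record=True,
                )
            else:
                force, v_kl, v_bias = None, np.inf, 0.0
            self.records.append(BiasRecord(self.n_completed, float(v_kl), float(v_bias)))
            frames = self.engine.advance(cfg.n_biasing, force, save_every=cfg.n_saving)
            self.n_completed += cfg.n_biasing
            for f in frames:
                self.pool.append(f, model=self.model)
                self.frame_steps.append(self.n_completed)
            if self.n_completed % retrain_every == 0 and self.n_completed < cfg.n_needed:
                _, tr = train(self.model, self._training_features(), rng=self.rng_train,
                              max_epochs=cfg.retrain_max_epochs)
                self.trace.extend(tr)
                self.pool.refresh(self.model)
                logger.info("retrained at step %d (pool %d, best loss %.6g)",
                            self.n_completed, len(self.pool), self.model.best_loss)
                self.checkpoint()

    def result(self) -> DespResult:
        self.flush()
        return DespResult(
            trajectory=AngleTrajectory(self.pool.frames),
            frame_steps=np.asarray(self.frame_steps, dtype=int),
            n_bootstrap_frames=self.n_bootstrap_frames,
            bias_records=list(self.records),
            loss_trace=self.trace,
            model=self.model,
            n_completed=self.n_completed,
        )

    # ---- persistence ------------------------------------------------------

    def flush(self) -> None:
        """Write the run directory artifacts (TSVs + latest model)."""
        if self.run_dir is None:
            return
        self.run_dir.mkdir(parents=True, exist_ok=True)
        if len(self.pool):
            write_angles_tsv(self.run_dir / "trajectory.tsv", AngleTrajectory(self.pool.frames))
        write_bias_tsv(self.run_dir / "bias.tsv", self.records)
        self.trace.to_tsv(self.run_dir / "loss.tsv")
        self.model.save(self.run_dir / "model.npz")

    def checkpoint(self) -> Path | None:
        if self.run_dir is None:
            return None
        self.run_dir.mkdir(parents=True, exist_ok=True)
        path = self.run_dir / f"checkpoint_{self.n_completed}.npz"
        meta = {
            "config": _config_to_dict(self.cfg),
            "potential": _potential_to_dict(self.potential),
            "n_completed": self.n_completed,
            "n_bootstrap_frames": self.n_bootstrap_frames,
            "frame_steps": self.frame_steps,
            "records": [[r.step, r.v_kl, r.v_bias] for r in self.records],
            "trace": {
                "epochs": self.trace.epochs,
                "loss_model": self.trace.loss_model,
                "loss_mse": self.trace.loss_mse,
                "loss_kl": self.trace.loss_kl,
                "learning_rate": self.trace.learning_rate,
            },
            "rng": {
                "reps": self.rng_reps.bit_generator.state,
                "subset": self.rng_subset.bit_generator.state,
                "train": self.rng_train.bit_generator.state,
            },
            "engine": {
                "step": int(self.engine.step),
                "rng_state": self.engine.state.rng.bit_generator.state,
            },
            "n_training_epochs": self.model.n_training_epochs,
        }
        arrays = {
            "pool_frames": self.pool.frames,
            "pool_mean": self.pool.latent_mean,
            "pool_ln_var": self.pool.latent_ln_var,
            "engine_angles": self.engine.state.angles,
        }
        arrays.update({f"param_{k}": v for k, v in self.model.params.items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        (self.run_dir / "checkpoint_latest.txt").write_text(path.name + "\n")
        return path

    @classmethod
    def from_checkpoint(cls, path: str | Path, potential: TorusPotential | None = None) -> "_DespRun":
        path = Path(path)
        if not path.exists():
            raise CheckpointError(f"no checkpoint at {path}")
        try:
            with np.load(path) as data:
                meta = json.loads(bytes(data["__meta__"]).decode())
                arrays = {k: data[k].copy() for k in data.files if k != "__meta__"}
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"corrupted checkpoint {path}: {exc}") from exc

        cfg = _config_from_dict(meta["config"])
        if potential is None:
            potential = _potential_from_dict(meta.get("potential"))
        run = cls(cfg, run_dir=path.parent, potential=potential)
        run.n_completed = int(meta["n_completed"])
        run.n_bootstrap_frames = int(meta["n_bootstrap_frames"])
        run.frame_steps = [int(s) for s in meta["frame_steps"]]
        run.records = [BiasRecord(int(s), float(a), float(b)) for s, a, b in meta["records"]]
        tr = meta["trace"]
        run.trace = LossTrace()
        for row in zip(tr["epochs"], tr["loss_model"], tr["loss_mse"],
                       tr["loss_kl"], tr["learning_rate"]):
            run.trace.append(*row)
        run.rng_reps.bit_generator.state = meta["rng"]["reps"]
        run.rng_subset.bit_generator.state = meta["rng"]["subset"]
        run.rng_train.bit_generator.state = meta["rng"]["train"]
        run.engine.state.angles = arrays["engine_angles"]
        run.engine.state.step = int(meta["engine"]["step"])
        run.engine.state.rng.bit_generator.state = meta["engine"]["rng_state"]
        run.model.params = {k[len("param_"):]: v for k, v in arrays.items() if k.startswith("param_")}
        run.model.n_training_epochs = int(meta["n_training_epochs"])
        run.pool = FramePool(run.model.config.d_dihedrals, run.model.config.latent_dim)
        for f in arrays["pool_frames"]:
            run.pool.append(f)
        run.pool.latent_mean = arrays["pool_mean"]
        run.pool.latent_ln_var = arrays["pool_ln_var"]
        return run


def _config_to_dict(cfg: DespConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("vae_config") is not None:
        d["vae_config"]["betas"] = list(d["vae_config"]["betas"])
    return d


def _config_from_dict(d: dict) -> DespConfig:
    d = dict(d)
    d.pop("potential", None)
    if d.get("bias_config") is not None:
        d["bias_config"] = BiasConfig(**d["bias_config"])
    if d.get("vae_config") is not None:
        v = dict(d["vae_config"])
        v["betas"] = tuple(v["betas"])
        d["vae_config"] = VAEConfig(**v)
    if d.get("langevin_config") is not None:
        d["langevin_config"] = LangevinConfig(**d["langevin_config"])
    return DespConfig(**d)


def _potential_to_dict(pot: TorusPotential | None) -> dict | None:
    if pot is None:
        return None
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in pot.parameters.items()}


def _potential_from_dict(d: dict | None) -> TorusPotential | None:
    if d is None:
        return None
    kind = d.get("type")
    if kind == "double_well":
        return make_double_well(d["center"], d["barrier_height"])
    if kind == "cosine_wells":
        return make_cosine_wells(d["centers"], d["heights"], d["multiplicities"])
    raise CheckpointError(f"cannot rebuild potential of type {kind!r}")


def run_desp(
    cfg: DespConfig,
    engine=None,
    potential: TorusPotential | None = None,
    run_dir: str | Path | None = None,
) -> DespResult:
    """Execute the full loop and return the assembled result.

    On a dynamics or training failure the run state is flushed to run_dir
    (when given) before the exception propagates.
    """
    run = _DespRun(cfg, engine=engine, run_dir=run_dir, potential=potential)
    try:
        run.bootstrap()
        run.initial_training()
        run.biased_blocks()
    except Exception:
        run.flush()
        raise
    return run.result()


def resume(checkpoint: str | Path, potential: TorusPotential | None = None) -> DespResult:
    """Continue an interrupted run from a checkpoint to completion.

    With the same seeds the continuation is bit-identical to the
    uninterrupted run.
    """
    run = _DespRun.from_checkpoint(checkpoint, potential=potential)
    try:
        run.biased_blocks()
    except Exception:
        run.flush()
        raise
    return run.result()
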