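"""Shared fixtures: synthetic two-basin data, a fully trained model on it,
and programmatic PDB text builders."""

from __future__ import annotations

import numpy as np
import pytest

from desp.featurize import encode_features
from desp.synthetic import default_two_basin_model, generate_basin_trajectory
from desp.vae import VAEConfig, build_vae, train

TWO_BASIN_SEED = 42
TWO_BASIN_D = 10
TWO_BASIN_T = 5000


@pytest.fixture(scope="session")
def two_basin_data():
    """Default two-basin trajectory (D=10, T=5000) with labels and features."""
    model = default_two_basin_model(TWO_BASIN_D, seed=TWO_BASIN_SEED)
    traj, labels = generate_basin_trajectory(model, TWO_BASIN_T)
    return traj, labels, encode_features(traj).features


@pytest.fixture(scope="session")
def trained_two_basin_vae(two_basin_data):
    """VAE trained once, with default protocol, on the two-basin fixture.

    Session-scoped because the full training protocol takes about a minute;
    several tests inspect different properties of the same trained model.
    """
    _, _, features = two_basin_data
    model = build_vae(VAEConfig(d_dihedrals=TWO_BASIN_D, seed=TWO_BASIN_SEED))
    model, trace = train(model, features)
    return model, trace


# ---------------------------------------------------------------------------
# PDB text builders (generated at test time; no stored fixtures)
# ---------------------------------------------------------------------------

_CHI1_EXTRA = {
    "VAL": ["CB", "CG1"],
    "ALA": ["CB"],
    "GLY": [],
    "SER": ["CB", "OG"],
}


def _backbone_coords(i: int) -> dict[str, np.ndarray]:
    """Non-degenerate, roughly extended backbone geometry for residue i."""
    base = np.array([3.5 * i, 0.0, 0.0])
    return {
        "N": base + np.array([0.0, 0.3, 0.0]),
        "CA": base + np.array([1.2, 1.0, 0.2]),
        "C": base + np.array([2.4, 0.4, -0.1]),
        "O": base + np.array([2.6, -0.8, -0.2]),
        "CB": base + np.array([1.3, 2.1, 1.3]),
        "CG1": base + np.array([2.2, 3.1, 1.6]),
        "OG": base + np.array([2.2, 3.1, 1.6]),
    }


def make_pdb_text(residues: list[str], n_models: int = 1, jitter: float = 0.0,
                  seed: int = 0) -> str:
    """Build a small multi-model PDB with full backbones and chi1 atoms."""
    rng = np.random.default_rng(seed)
    lines = []
    for m in range(n_models):
        if n_models > 1:
            lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for i, res in enumerate(residues):
            coords = _backbone_coords(i)
            names = ["N", "CA", "C", "O"] + _CHI1_EXTRA.get(res, ["CB"])
            for name in names:
                x, y, z = coords[name] + jitter * rng.standard_normal(3)
                pad = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad}{'':1s}{res:>3s} A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
        if n_models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_file_factory(tmp_path):
    def factory(residues, n_models=1, jitter=0.0, seed=0, name="test.pdb"):
        p = tmp_path / name
        p.write_text(make_pdb_text(residues, n_models, jitter, seed))
        return p

    return factory
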