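"""Dihedral-angle featurization.

A molecular conformation is represented by its backbone and side-chain
dihedral angles (omega, phi, psi, chi1).  Because dihedrals are periodic,
every angle theta is encoded as the pair (cos theta, sin theta); a T-frame
trajectory over D dihedrals therefore becomes a T x 2D feature matrix, the
input representation for the autoencoder.

Conventions
-----------
* Angles live in (-pi, pi]; the sign follows the IUPAC convention
  (clockwise positive when looking along the p2 -> p3 bond), which is also
  what mdtraj/MDAnalysis report.
* Feature columns are interleaved: [cos t1, sin t1, cos t2, sin t2, ...].
  This layout is fixed because a trained model's input layer depends on it.
* Residue and atom indices are 0-based internally; PDB serial numbers only
  survive in I/O metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, ShapeError, UndefinedAngleError

logger = logging.getLogger(__name__)

__all__ = [
    "DihedralKind",
    "DihedralSpec",
    "AngleTrajectory",
    "FeatureMatrix",
    "Structure",
    "CHI1_FOURTH_ATOM",
    "compute_dihedral",
    "identify_dihedrals",
    "compute_dihedral_trajectory",
    "encode_features",
    "decode_angles",
    "wrap_angle",
    "read_pdb",
    "read_angles_tsv",
    "write_angles_tsv",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles into (-pi, pi]."""
    wrapped = np.asarray(theta, dtype=float)
    wrapped = wrapped - TWO_PI * np.floor((wrapped + np.pi) / TWO_PI)
    # floor maps pi to the left edge -pi; fold it back to the closed right edge
    wrapped = np.where(wrapped <= -np.pi, np.pi, wrapped)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


class DihedralKind(str, Enum):
    OMEGA = "omega"
    PHI = "phi"
    PSI = "psi"
    CHI1 = "chi1"


#: Fourth atom of the chi1 quadruple N-CA-CB-X per residue type (standard
#: heavy-atom choice).  Residues absent from this table (GLY, ALA) have no chi1.
CHI1_FOURTH_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

_KIND_ORDER = (DihedralKind.OMEGA, DihedralKind.PHI, DihedralKind.PSI, DihedralKind.CHI1)


@dataclass(frozen=True)
class DihedralSpec:
    """One dihedral angle: its kind, owning residue, and atom quadruple."""

    kind: DihedralKind
    residue_index: int
    atom_indices: tuple[int, int, int, int]

    def __post_init__(self):
        if len(set(self.atom_indices)) != 4:
            raise ValueError(f"atom_indices must be 4 distinct atoms, got {self.atom_indices}")

    @property
    def label(self) -> str:
        return f"{self.kind.value}:{self.residue_index}"


@dataclass
class AngleTrajectory:
    """T x D matrix of dihedral angles in radians, each entry in (-pi, pi]."""

    angles: np.ndarray
    dihedral_specs: list[DihedralSpec] | None = None

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        t, d = self.angles.shape
        if t < 1 or d < 1:
            raise ShapeError(f"need T >= 1 and D >= 1, got shape {self.angles.shape}")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite entries")
        if np.any(self.angles <= -np.pi) or np.any(self.angles > np.pi):
            raise ValueError("angles must lie in (-pi, pi]")
        if self.dihedral_specs is not None and len(self.dihedral_specs) != d:
            raise ShapeError("dihedral_specs length must equal the number of angle columns")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]


@dataclass
class FeatureMatrix:
    """T x 2D cos/sin features, columns interleaved [cos t1, sin t1, ...]."""

    features: np.ndarray

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[1] % 2 != 0:
            raise ShapeError("feature matrix must have an even number of columns")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.features.shape[1] // 2


@dataclass
class Structure:
    """Minimal topology + coordinates: enough to locate dihedral quadruples.

    xyz has shape (n_frames, n_atoms, 3) in Angstrom; multi-model PDB files
    yield one frame per MODEL record.
    """

    atom_names: list[str]
    res_indices: np.ndarray  # 0-based residue index per atom
    res_names: list[str]     # residue name per atom
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim == 2:
            self.xyz = self.xyz[None]
        self.res_indices = np.asarray(self.res_indices, dtype=int)

    @property
    def n_residues(self) -> int:
        return int(self.res_indices.max()) + 1 if len(self.res_indices) else 0

    def residue_name(self, i: int) -> str:
        idx = np.nonzero(self.res_indices == i)[0]
        return self.res_names[idx[0]]

    def find_atom(self, res_index: int, atom_name: str) -> int | None:
        for a in np.nonzero(self.res_indices == res_index)[0]:
            if self.atom_names[a] == atom_name:
                return int(a)
        return None


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of the four points, radians in (-pi, pi].

    Clockwise rotations of the p3-p4 bond relative to the p1-p2 bond, viewed
    along p2 -> p3, are positive (IUPAC).  Raises GeometryError on zero-length
    bond vectors or collinear triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for name, b in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError(f"zero-length bond vector {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear atom triple: dihedral undefined")
    b2_hat = b2 / np.linalg.norm(b2)
    y = np.dot(np.cross(n1, n2), b2_hat)
    x = np.dot(n1, n2)
    return wrap_angle(float(np.arctan2(y, x)))


def _quadruple(structure: Structure, kind: DihedralKind, i: int):
    """Atom-index quadruple of dihedral `kind` for residue i, or None."""
    f = structure.find_atom
    if kind is DihedralKind.OMEGA:
        if i == 0:
            return None
        atoms = (f(i - 1, "CA"), f(i - 1, "C"), f(i, "N"), f(i, "CA"))
    elif kind is DihedralKind.PHI:
        if i == 0:
            return None
        atoms = (f(i - 1, "C"), f(i, "N"), f(i, "CA"), f(i, "C"))
    elif kind is DihedralKind.PSI:
        if i + 1 >= structure.n_residues:
            return None
        atoms = (f(i, "N"), f(i, "CA"), f(i, "C"), f(i + 1, "N"))
    else:  # chi1
        fourth = CHI1_FOURTH_ATOM.get(structure.residue_name(i))
        if fourth is None:
            return None
        atoms = (f(i, "N"), f(i, "CA"), f(i, "CB"), f(i, fourth))
    return atoms


def identify_dihedrals(structure: Structure) -> list[DihedralSpec]:
    """Enumerate all omega/phi/psi/chi1 dihedrals present in the structure.

    Order is deterministic: by residue index, then omega, phi, psi, chi1.
    Terminal residues contribute only the dihedrals whose atoms exist;
    residues lacking a required atom are skipped with a logged warning
    (dihedrals are never silently renumbered).
    """
    specs: list[DihedralSpec] = []
    for i in range(structure.n_residues):
        for kind in _KIND_ORDER:
            atoms = _quadruple(structure, kind, i)
            if atoms is None:
                continue  # dihedral does not exist at this position
            if any(a is None for a in atoms):
                logger.warning("residue %d: missing atom for %s, skipping", i, kind.value)
                continue
            specs.append(DihedralSpec(kind, i, tuple(int(a) for a in atoms)))
    return specs


def compute_dihedral_trajectory(
    structure: Structure, specs: Sequence[DihedralSpec] | None = None
) -> AngleTrajectory:
    """Evaluate every dihedral spec on every frame of the structure."""
    if specs is None:
        specs = identify_dihedrals(structure)
    if not specs:
        raise ValueError("no dihedrals to compute")
    T = structure.xyz.shape[0]
    out = np.empty((T, len(specs)))
    for t in range(T):
        frame = structure.xyz[t]
        for j, s in enumerate(specs):
            a, b, c, d = s.atom_indices
            out[t, j] = compute_dihedral(frame[a], frame[b], frame[c], frame[d])
    return AngleTrajectory(out, list(specs))


def encode_features(traj: AngleTrajectory) -> FeatureMatrix:
    """cos/sin encoding: T x D angles -> T x 2D features, interleaved."""
    ang = traj.angles
    T, D = ang.shape
    feats = np.empty((T, 2 * D))
    feats[:, 0::2] = np.cos(ang)
    feats[:, 1::2] = np.sin(ang)
    return FeatureMatrix(feats)


def decode_angles(features: FeatureMatrix | np.ndarray) -> AngleTrajectory:
    """Invert the cos/sin encoding via atan2; tolerates off-circle inputs.

    Reconstructions emitted by the decoder need not lie on the unit circle;
    atan2 projects them back.  A pair with both components below 1e-12 has no
    defined angle and raises UndefinedAngleError.
    """
    f = features.features if isinstance(features, FeatureMatrix) else np.atleast_2d(np.asarray(features, dtype=float))
    if f.shape[1] % 2 != 0:
        raise ShapeError("feature matrix must have an even number of columns")
    c = f[:, 0::2]
    s = f[:, 1::2]
    if np.any((np.abs(c) < 1e-12) & (np.abs(s) < 1e-12)):
        raise UndefinedAngleError("cos and sin components both ~0: angle undefined")
    return AngleTrajectory(wrap_angle(np.arctan2(s, c)))


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records (PDB v3.3); multi-model files give one frame
    per model."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack: models x atoms
    names = [str(n) for n in stack.atom_name]
    res_ids = np.asarray(stack.res_id, dtype=int)
    # compress PDB residue numbers to dense 0-based indices in file order
    order = {rid: k for k, rid in enumerate(dict.fromkeys(res_ids.tolist()))}
    dense = np.array([order[r] for r in res_ids.tolist()], dtype=int)
    return Structure(
        atom_names=names,
        res_indices=dense,
        res_names=[str(r) for r in stack.res_name],
        xyz=np.asarray(stack.coord, dtype=float),
    )


def write_angles_tsv(path: str | Path, traj: AngleTrajectory) -> None:
    """Angle TSV: optional `# kind:residue` comments, `theta_1..theta_D`
    header, one row per frame, radians."""
    with open(path, "w", encoding="utf-8") as fh:
        if traj.dihedral_specs is not None:
            for s in traj.dihedral_specs:
                fh.write(f"# {s.label}\n")
        D = traj.n_dihedrals
        fh.write("\t".join(f"theta_{j + 1}" for j in range(D)) + "\n")
        for row in traj.angles:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_angles_tsv(path: str | Path) -> AngleTrajectory:
    rows = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if not line.startswith("theta_"):
                    raise ValueError(f"malformed angle TSV header: {line!r}")
                header_seen = True
                continue
            rows.append([float(v) for v in line.split("\t")])
    if not rows:
        raise ValueError(f"no frames found in {path}")
    return AngleTrajectory(np.asarray(rows))
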