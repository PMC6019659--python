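"""Coordinate mathematics for disulfide engineering.

Dihedrals and inter-plane angles, internal-coordinate atom placement,
virtual cystine modelling at arbitrary residue pairs, the full geometric
descriptor of a candidate pair, and least-squares (Kabsch) superposition.

All angles are signed degrees in (-180, 180] under the IUPAC convention:
looking down the 2→3 bond, the far bond rotated clockwise from the near
bond gives a positive angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as K
from .errors import ContractError, DegenerateGeometryError, MissingAtomError
from .structure_io import Residue, ResiduePair, Structure

_EPS = 1e-10


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError("coincident points: zero-length vector")
    return v / n


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("three consecutive points are collinear")
    ang = np.degrees(np.arctan2(np.cross(n1, n2) @ _unit(b2), n1 @ n2))
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def plane_normal(a1, a2, a3) -> np.ndarray:
    """Unit normal of the plane through a1,a2,a3, oriented by atom order."""
    a1, a2, a3 = (np.asarray(a, dtype=float) for a in (a1, a2, a3))
    n = np.cross(a2 - a1, a3 - a1)
    if np.linalg.norm(n) < _EPS:
        raise DegenerateGeometryError("plane triple is collinear")
    return n / np.linalg.norm(n)


def plane_dihedral(a1, a2, a3, b1, b2, b3) -> float:
    """Angle in [0, 180] degrees between plane(a1,a2,a3) and plane(b1,b2,b3)."""
    na = plane_normal(a1, a2, a3)
    nb = plane_normal(b1, b2, b3)
    return float(np.degrees(np.arccos(np.clip(na @ nb, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms a-b-c by internal coordinates.

    D is at distance ``bond`` from c, with angle b-c-D = ``angle_deg`` and
    torsion a-b-c-D = ``torsion_deg`` (NeRF construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_cb(n, ca, c) -> np.ndarray:
    """Virtual Cβ from backbone N/Cα/C by ideal tetrahedral geometry."""
    return place_atom(c, n, ca, K.BOND_CA_CB, K.ANGLE_N_CA_CB, K.TORSION_C_N_CA_CB)


# ---------------------------------------------------------------------------
# chi angles and descriptors


@dataclass(frozen=True)
class ChiAngles:
    """The five torsions of a cystine bridge, degrees in (-180, 180].

    chi1 = N-Cα-Cβ-Sγ of residue A, chi2 = Cα-Cβ-Sγ-Sγ′, chi3 = Cβ-Sγ-Sγ′-Cβ′,
    chi2_prime and chi1_prime mirror chi2/chi1 on residue B.
    """

    chi1: float
    chi2: float
    chi3: float
    chi2_prime: float
    chi1_prime: float

    def swapped(self) -> "ChiAngles":
        return ChiAngles(self.chi1_prime, self.chi2_prime, self.chi3, self.chi2, self.chi1)


@dataclass
class DisulfideGeometry:
    """Full descriptor vector for one residue pair.

    cross_distances maps ``d_<atomA>_<atomB>`` (atoms of residue A × atoms of
    residue B over C,O,N,CA,CB,SG — 36 entries) to Å; plane_dihedrals maps the
    three corresponding-plane angles to degrees in [0, 180]; ``frame`` holds
    the 8 atoms N,CA,CB,SG of A then of B (8×3 Å) for template matching.
    """

    cross_distances: dict[str, float]
    plane_dihedrals: dict[str, float]
    chi: ChiAngles
    ca_ca: float
    cb_cb: float
    sg_sg: float
    frame: np.ndarray = field(repr=False, default=None)

    def features(self) -> dict[str, float]:
        """All 44 scalar descriptors in fixed order (36 + 3 + 5)."""
        out = dict(self.cross_distances)
        out.update(self.plane_dihedrals)
        out["chi1"] = self.chi.chi1
        out["chi2"] = self.chi.chi2
        out["chi3"] = self.chi.chi3
        out["chi2_prime"] = self.chi.chi2_prime
        out["chi1_prime"] = self.chi.chi1_prime
        return out


FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"d_{a}_{b}" for a in K.PAIR_ATOMS for b in K.PAIR_ATOMS]
    + [f"plane_{'_'.join(t)}" for t in K.PLANE_TRIPLES]
    + ["chi1", "chi2", "chi3", "chi2_prime", "chi1_prime"]
)

ANGLE_FEATURES = frozenset(
    [f"plane_{'_'.join(t)}" for t in K.PLANE_TRIPLES]
    + ["chi1", "chi2", "chi3", "chi2_prime", "chi1_prime"]
)


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed`` (Kabsch).

    Correspondence is by order; a proper rotation (det +1) is always returned.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ContractError(f"length mismatch: {moving.shape} vs {fixed.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ContractError("superposition needs >= 3 corresponding 3D points")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - fc, moving - mc)
    rmsd = rssd / np.sqrt(moving.shape[0])
    rmat = rot.as_matrix()
    return SuperpositionResult(float(rmsd), rmat, fc - rmat @ mc)


# ---------------------------------------------------------------------------
# virtual cystine modelling


@dataclass
class CystineModel:
    """One rotamer combination of a modelled cystine at a residue pair."""

    cb_a: np.ndarray
    sg_a: np.ndarray
    cb_b: np.ndarray
    sg_b: np.ndarray
    chi1_a: float
    chi1_b: float

    @property
    def sg_sg(self) -> float:
        return float(np.linalg.norm(self.sg_a - self.sg_b))


def _backbone(res: Residue) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for name in ("N", "CA", "C"):
        if name not in res.atoms:
            raise MissingAtomError(res.key, name)
    return res.atoms["N"], res.atoms["CA"], res.atoms["C"]


def _cb_of(res: Residue) -> np.ndarray:
    """Experimental Cβ when present, otherwise virtual placement (e.g. Gly)."""
    if "CB" in res.atoms:
        return res.atoms["CB"]
    return place_cb(*_backbone(res))


def model_cystine(
    structure: Structure,
    pair: ResiduePair,
    rotamer_set=K.DEFAULT_ROTAMERS,
) -> list[CystineModel]:
    """Model Cβ/Sγ on both residues for every chi1 rotamer combination.

    Sγ is placed at Cβ-Sγ 1.81 Å, Cα-Cβ-Sγ 114.0°, torsion N-Cα-Cβ-Sγ = chi1
    seed. The Cartesian product of seeds over the two residues is returned.
    """
    if not rotamer_set:
        raise ContractError("rotamer_set must be non-empty")
    res_a = structure.get_residue(pair.res_a)
    res_b = structure.get_residue(pair.res_b)
    out = []
    sides = []
    for res in (res_a, res_b):
        n, ca, c = _backbone(res)
        cb = _cb_of(res)
        sides.append(
            [
                (cb, place_atom(n, ca, cb, K.BOND_CB_SG, K.ANGLE_CA_CB_SG, chi1), chi1)
                for chi1 in rotamer_set
            ]
        )
    for (cb_a, sg_a, x1a), (cb_b, sg_b, x1b) in product(sides[0], sides[1]):
        out.append(CystineModel(cb_a, sg_a, cb_b, sg_b, x1a, x1b))
    return out


def _geometry_from_atoms(atoms_a: dict, atoms_b: dict) -> DisulfideGeometry:
    dists = {}
    for a in K.PAIR_ATOMS:
        for b in K.PAIR_ATOMS:
            dists[f"d_{a}_{b}"] = float(np.linalg.norm(atoms_a[a] - atoms_b[b]))
    planes = {}
    for triple in K.PLANE_TRIPLES:
        planes[f"plane_{'_'.join(triple)}"] = plane_dihedral(
            *(atoms_a[t] for t in triple), *(atoms_b[t] for t in triple)
        )
    chi = ChiAngles(
        chi1=dihedral(atoms_a["N"], atoms_a["CA"], atoms_a["CB"], atoms_a["SG"]),
        chi2=dihedral(atoms_a["CA"], atoms_a["CB"], atoms_a["SG"], atoms_b["SG"]),
        chi3=dihedral(atoms_a["CB"], atoms_a["SG"], atoms_b["SG"], atoms_b["CB"]),
        chi2_prime=dihedral(atoms_b["CA"], atoms_b["CB"], atoms_b["SG"], atoms_a["SG"]),
        chi1_prime=dihedral(atoms_b["N"], atoms_b["CA"], atoms_b["CB"], atoms_b["SG"]),
    )
    frame = np.array(
        [atoms_a[n] for n in ("N", "CA", "CB", "SG")]
        + [atoms_b[n] for n in ("N", "CA", "CB", "SG")]
    )
    return DisulfideGeometry(
        cross_distances=dists,
        plane_dihedrals=planes,
        chi=chi,
        ca_ca=dists["d_CA_CA"],
        cb_cb=dists["d_CB_CB"],
        sg_sg=dists["d_SG_SG"],
        frame=frame,
    )


def extract_geometry(
    structure: Structure,
    pair: ResiduePair,
    use_modeled: bool = False,
    rotamer_set=K.DEFAULT_ROTAMERS,
    sg_target: float = K.BOND_SG_SG,
) -> DisulfideGeometry:
    """Full 44-feature descriptor for a residue pair.

    With ``use_modeled`` the side chains are virtually mutated to cysteine and
    the rotamer combination minimizing \\|sg_sg - sg_target\\| is kept; otherwise
    experimental Cβ/Sγ must be present on both residues.
    """
    res_a = structure.get_residue(pair.res_a)
    res_b = structure.get_residue(pair.res_b)

    def assemble(res, cb, sg):
        n, ca, c = _backbone(res)
        if "O" not in res.atoms:
            raise MissingAtomError(res.key, "O")
        return {"N": n, "CA": ca, "C": c, "O": res.atoms["O"], "CB": cb, "SG": sg}

    if use_modeled:
        models = model_cystine(structure, pair, rotamer_set)
        best = min(models, key=lambda m: abs(m.sg_sg - sg_target))
        atoms_a = assemble(res_a, best.cb_a, best.sg_a)
        atoms_b = assemble(res_b, best.cb_b, best.sg_b)
    else:
        for res in (res_a, res_b):
            for name in ("CB", "SG"):
                if name not in res.atoms:
                    raise MissingAtomError(res.key, name)
        atoms_a = assemble(res_a, res_a.atoms["CB"], res_a.atoms["SG"])
        atoms_b = assemble(res_b, res_b.atoms["CB"], res_b.atoms["SG"])
    return _geometry_from_atoms(atoms_a, atoms_b)
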