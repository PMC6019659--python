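"""Synthetic structure, corpus, ensemble, and training-set generators.

These fixtures stand in for a mined structure corpus and for simulation
trajectories: ideal poly-alanine helices built from internal coordinates,
two-helix bundles carrying one cystine with fully specified bridge torsions,
corpora of such bundles with controlled noise, Gaussian coordinate ensembles
with a prescribed mass-weighted covariance spectrum, and a linearly separable
score-triple training set. Every generator is deterministic under a fixed
seed and records the ground truth needed for recovery tests.

Structures are emitted as PDB text through the package writer so parsers are
exercised end to end, never bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as K
from .classifier import NEGATIVE, POSITIVE, TrainingSet
from .entropy import Ensemble
from .errors import ContractError
from .geometry import place_atom, place_cb, superpose
from .structure_io import Chain, Residue, Structure, parse_structure, write_structure

PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def _first_residue_backbone():
    n = np.zeros(3)
    ca = np.array([K.BOND_N_CA, 0.0, 0.0])
    theta = np.radians(K.ANGLE_N_CA_C)
    # ideal N-CA-C angle, chain initially in the xy-plane
    c = ca + K.BOND_CA_C * (np.cos(theta) * (n - ca) / np.linalg.norm(n - ca)
                            + np.sin(theta) * np.array([0.0, 1.0, 0.0]))
    return n, ca, c


def _build_backbone(n_res: int, phi: float, psi: float):
    """Backbone N/CA/C positions for an ideal (phi, psi) chain."""
    ns, cas, cs = [], [], []
    n, ca, c = _first_residue_backbone()
    ns.append(n); cas.append(ca); cs.append(c)
    for _ in range(1, n_res):
        n_next = place_atom(ns[-1], cas[-1], cs[-1], K.BOND_C_N, K.ANGLE_CA_C_N, psi)
        ca_next = place_atom(cas[-1], cs[-1], n_next, K.BOND_N_CA, K.ANGLE_C_N_CA, OMEGA)
        c_next = place_atom(cs[-1], n_next, ca_next, K.BOND_CA_C, K.ANGLE_N_CA_C, phi)
        ns.append(n_next); cas.append(ca_next); cs.append(c_next)
    return ns, cas, cs


def _residue(chain_id, number, name, n, ca, c, psi_next=PSI_HELIX):
    atoms = {
        "N": n, "CA": ca, "C": c,
        "O": place_atom(n, ca, c, K.BOND_C_O, K.ANGLE_CA_C_O, psi_next + 180.0),
    }
    if name != "GLY":
        atoms["CB"] = place_cb(n, ca, c)
    return Residue(chain_id, number, "", name, atoms)


def make_helix(n_res: int, seed: int = 0, chain_id: str = "A",
               start_number: int = 1, res_name: str = "ALA") -> Structure:
    """Ideal poly-alanine α-helix (φ = −57°, ψ = −47°, ω = 180°).

    Deterministic; the seed only labels the structure id.
    """
    if n_res < 3:
        raise ContractError("a helix needs at least 3 residues")
    ns, cas, cs = _build_backbone(n_res, PHI_HELIX, PSI_HELIX)
    residues = [
        _residue(chain_id, start_number + i, res_name, ns[i], cas[i], cs[i])
        for i in range(n_res)
    ]
    return Structure(id=f"helix{n_res}_s{seed}", chains=[Chain(chain_id, residues)])


# ---------------------------------------------------------------------------
# cystine bundles


@dataclass
class CystineParams:
    """Ground-truth bridge parameters of a planted cystine."""

    chi1: float = -60.0
    chi2: float = -80.0
    chi3: float = 97.0
    chi2_prime: float = -80.0
    chi1_prime: float = -60.0
    sg_sg: float = K.BOND_SG_SG


def _canonical_cys(chi1: float):
    """A cysteine in a local frame with ideal geometry and the given chi1."""
    n, ca, c = _first_residue_backbone()
    cb = place_cb(n, ca, c)
    sg = place_atom(n, ca, cb, K.BOND_CB_SG, K.ANGLE_CA_CB_SG, chi1)
    return {"N": n, "CA": ca, "C": c, "CB": cb, "SG": sg}


def make_cystine_bundle(params: CystineParams | None = None, helix_len: int = 14,
                        pos_a: int = 7, pos_b: int = 7, seed: int = 0
                        ) -> tuple[Structure, tuple, tuple]:
    """Two-helix bundle, one chain, with one cystine of specified geometry.

    Helix 1 carries cysteine A at ordinal ``pos_a``; helix 2 is rigidly placed
    so that its cysteine at ordinal ``pos_b`` closes an S-S bridge with
    exactly the requested torsions and Sγ-Sγ distance. Returns the structure
    and the residue keys of the planted pair.
    """
    params = params or CystineParams()
    if not (2 <= pos_a < helix_len - 2 and 2 <= pos_b < helix_len - 2):
        raise ContractError("cysteine positions must be interior to the helices")
    h1 = make_helix(helix_len, seed=seed)
    res_a = h1.chains[0].residues[pos_a]
    res_a.res_name = "CYS"
    n_a, ca_a, cb_a = res_a.atoms["N"], res_a.atoms["CA"], res_a.atoms["CB"]
    sg_a = place_atom(n_a, ca_a, cb_a, K.BOND_CB_SG, K.ANGLE_CA_CB_SG, params.chi1)
    res_a.atoms["SG"] = sg_a

    # walk across the bridge by internal coordinates
    sg_b = place_atom(ca_a, cb_a, sg_a, params.sg_sg, K.ANGLE_CB_SG_SG, params.chi2)
    cb_b = place_atom(cb_a, sg_a, sg_b, K.BOND_CB_SG, K.ANGLE_CB_SG_SG, params.chi3)
    ca_b = place_atom(sg_a, sg_b, cb_b, K.BOND_CA_CB, K.ANGLE_CA_CB_SG, params.chi2_prime)

    # recover residue B's backbone frame from a canonical cysteine
    canon = _canonical_cys(params.chi1_prime)
    fit = superpose(
        np.array([canon["CA"], canon["CB"], canon["SG"]]),
        np.array([ca_b, cb_b, sg_b]),
    )
    n_b = fit.apply(canon["N"][None, :])[0]
    c_b = fit.apply(canon["C"][None, :])[0]

    h2 = make_helix(helix_len, seed=seed, start_number=helix_len + 1)
    res_b = h2.chains[0].residues[pos_b]
    fit2 = superpose(
        np.array([res_b.atoms["N"], res_b.atoms["CA"], res_b.atoms["C"]]),
        np.array([n_b, ca_b, c_b]),
    )
    for res in h2.chains[0].residues:
        for name in res.atoms:
            res.atoms[name] = fit2.apply(res.atoms[name][None, :])[0]
    res_b.res_name = "CYS"
    res_b.atoms["CB"] = cb_b
    res_b.atoms["SG"] = sg_b

    chain = Chain("A", h1.chains[0].residues + h2.chains[0].residues)
    st = Structure(id=f"bundle_s{seed}", chains=[chain])
    return st, res_a.key, res_b.key


def make_two_helix_bundle(seed: int = 0, helix_len: int = 15):
    """Bundle whose planted cross-helix pair has exactly the modal bridge
    geometry of :func:`make_cystine_corpus` — the ideal engineering target."""
    return make_cystine_bundle(CystineParams(), helix_len=helix_len,
                               pos_a=7, pos_b=7, seed=seed)


def make_cystine_corpus(n: int, chi3_modes=(97.0, -97.0), noise_sd: float = 0.02,
                        chi_noise_sd: float = 4.0, seed: int = 0,
                        helix_len: int = 10,
                        rotamer_probs=(0.7, 0.15, 0.15)) -> tuple[list[Structure], dict]:
    """Corpus of single-cystine bundles with controlled parameter noise.

    Sγ-Sγ ~ Normal(2.05 Å, noise_sd); χ3 drawn uniformly from the mode list
    with Normal(0, chi_noise_sd) jitter; χ2/χ2′ jittered around −80°; χ1/χ1′
    drawn from the rotamer seeds with gauche− dominant. Returns the structures
    (round-tripped through PDB text) and the ground-truth parameter record.
    """
    if n < 1:
        raise ContractError("corpus size must be >= 1")
    rng = np.random.default_rng(seed)
    structures, truth = [], {"chi3": [], "sg_sg": [], "chi1": []}
    rotamers = np.array(K.DEFAULT_ROTAMERS)
    for i in range(n):
        chi3 = rng.choice(chi3_modes) + rng.normal(0.0, chi_noise_sd)
        sg = rng.normal(K.BOND_SG_SG, noise_sd)
        chi1 = float(rng.choice(rotamers, p=rotamer_probs))
        chi1p = float(rng.choice(rotamers, p=rotamer_probs))
        params = CystineParams(
            chi1=chi1,
            chi2=-80.0 + rng.normal(0.0, chi_noise_sd),
            chi3=float(chi3),
            chi2_prime=-80.0 + rng.normal(0.0, chi_noise_sd),
            chi1_prime=chi1p,
            sg_sg=float(sg),
        )
        st, _, _ = make_cystine_bundle(params, helix_len=helix_len,
                                       pos_a=4, pos_b=4, seed=seed + i)
        st = parse_structure(write_structure(st), structure_id=f"corpus{i}_s{seed}")
        structures.append(st)
        truth["chi3"].append(float(chi3))
        truth["sg_sg"].append(float(sg))
        truth["chi1"].append(chi1)
    return structures, truth


# ---------------------------------------------------------------------------
# Gaussian ensembles


def rigid_body_basis(base: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of mass-weighted rigid translations/rotations."""
    n = len(base)
    sqrt_m = np.sqrt(masses)
    com = (base * masses[:, None]).sum(axis=0) / masses.sum()
    rel = base - com
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = 1.0
        vecs.append((v * sqrt_m[:, None]).ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        v = np.cross(axis, rel)
        vecs.append((v * sqrt_m[:, None]).ravel())
    q, _ = np.linalg.qr(np.array(vecs).T)
    return q


def make_gaussian_ensemble(n_atoms: int, n_frames: int, eigenvalues, seed: int = 0,
                           temperature: float = 300.0, masses=None
                           ) -> tuple[Ensemble, float]:
    """Ensemble with a prescribed mass-weighted covariance spectrum.

    Displacement modes are placed orthogonal to the rigid-body subspace of a
    fixed base structure, so superposition during analysis leaves the planted
    spectrum intact. Returns the ensemble and its closed-form quantum
    quasi-harmonic entropy (cal/mol/K), the recovery target.
    """
    from .entropy import entropy_from_eigenvalues

    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if n_frames < 2:
        raise ContractError("an ensemble needs >= 2 frames")
    if np.any(eigenvalues <= 0):
        raise ContractError("eigenvalues must be positive")
    if len(eigenvalues) > 3 * n_atoms - 6:
        raise ContractError("at most 3N - 6 internal modes exist")
    rng = np.random.default_rng(seed)
    masses = np.ones(n_atoms) if masses is None else np.asarray(masses, dtype=float)
    base = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    rigid = rigid_body_basis(base, masses)
    # orthonormal complement of the rigid subspace
    proj = np.eye(3 * n_atoms) - rigid @ rigid.T
    u, s, _ = np.linalg.svd(proj)
    internal = u[:, s > 0.5][:, : len(eigenvalues)]
    coeffs = rng.normal(size=(n_frames, len(eigenvalues))) * np.sqrt(eigenvalues)
    disp_q = coeffs @ internal.T
    disp_x = disp_q.reshape(n_frames, n_atoms, 3) / np.sqrt(masses)[None, :, None]
    frames = base[None] + disp_x
    names = [f"C{i}" for i in range(n_atoms)]
    ens = Ensemble(names, masses, frames, temperature)
    return ens, entropy_from_eigenvalues(eigenvalues, temperature)


# ---------------------------------------------------------------------------
# classifier fixtures


def make_separable_training_set(n: int = 100, seed: int = 42,
                                spread: float = 0.05) -> TrainingSet:
    """Linearly separable score triples: positives near (0.9, 0.9, 0.8),
    negatives near (0.1, 0.1, 0.1), clipped to [0, 1]."""
    if n < 2:
        raise ContractError("need at least one example per class")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    pos = rng.normal([0.9, 0.9, 0.8], spread, size=(n_pos, 3))
    neg = rng.normal([0.1, 0.1, 0.1], spread, size=(n - n_pos, 3))
    feats = np.clip(np.vstack([pos, neg]), 0.0, 1.0)
    labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * (n - n_pos), dtype=object)
    return TrainingSet(feats, labels)


def make_minimal_pdb_text(n_res: int = 3, seed: int = 0) -> str:
    """Small valid PDB text (an ideal helix) for parser round-trip tests."""
    return write_structure(make_helix(max(n_res, 3), seed=seed))
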