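"""Quasi-harmonic conformational entropy and fluctuation statistics.

An ensemble of conformers (e.g. MD snapshots or multi-model PDB) is reduced,
after rigid-body removal, to the eigenvalues of its mass-weighted coordinate
covariance matrix. Each eigenvalue λ defines an effective harmonic mode of
angular frequency ω = sqrt(k_B·T / λ), and the entropy is the sum of quantum
harmonic-oscillator mode entropies

    s(ω) = k_B [ x / (e^x − 1) − ln(1 − e^{−x}) ],   x = ħω / k_B·T,

reported per mole in cal·mol⁻¹·K⁻¹. Schlitter's upper-bound variant
(per-mode (k_B/2)·ln(1 + e²/x²)) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from .errors import ContractError, ZeroFluctuationError
from .geometry import superpose

# numerical floor below which a covariance eigenvalue is treated as null space
VARIANCE_FLOOR = 1e-8  # Å² · amu

_AMU_A2 = sc.atomic_mass * 1e-20  # one Å²·amu in kg·m²
_CAL = 4.184


@dataclass
class Ensemble:
    """Conformer stack: (n_frames, n_atoms, 3) coordinates in Å, masses in amu."""

    atom_names: list[str]
    masses: np.ndarray
    frames: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ContractError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.masses):
            raise ContractError("masses and frames disagree on atom count")
        if np.any(self.masses <= 0):
            raise ContractError("masses must be positive")
        if self.temperature <= 0:
            raise ContractError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class EnsembleEntropy:
    total_entropy: float            # cal/mol/K
    mode_frequencies: np.ndarray    # rad/s, in descending-variance order
    n_modes_used: int
    mode_entropies: np.ndarray = field(default=None, repr=False)
    eigenvalues: np.ndarray = field(default=None, repr=False)  # Å²·amu


def superpose_frames(ensemble: Ensemble, n_passes: int = 2) -> np.ndarray:
    """Frames least-squares fitted to their mean structure (mass-weighted
    centering, iterative mean refinement)."""
    if ensemble.n_frames < 2:
        raise ContractError("need >= 2 frames")
    frames = ensemble.frames.copy()
    w = ensemble.masses / ensemble.masses.sum()
    frames -= (frames * w[None, :, None]).sum(axis=1, keepdims=True)
    reference = frames[0]
    for _ in range(n_passes):
        fitted = np.empty_like(frames)
        for i, fr in enumerate(frames):
            if np.allclose(fr, reference, atol=1e-12):
                fitted[i] = fr
                continue
            fitted[i] = superpose(fr, reference).apply(fr)
        reference = fitted.mean(axis=0)
        frames = fitted
    return frames


def _covariance_eigenvalues(ensemble: Ensemble) -> np.ndarray:
    frames = superpose_frames(ensemble)
    sqrt_m = np.sqrt(ensemble.masses)
    q = (frames * sqrt_m[None, :, None]).reshape(ensemble.n_frames, -1)
    cov = np.cov(q, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]  # descending, Å²·amu
    return np.clip(eig, 0.0, None)


def mode_entropy_quantum(omega: np.ndarray, temperature: float) -> np.ndarray:
    """Quantum harmonic-oscillator entropy per mode, in k_B units."""
    x = sc.hbar * omega / (sc.k * temperature)
    return x / np.expm1(x) - np.log1p(-np.exp(-x))

def mode_entropy_schlitter(omega: np.ndarray, temperature: float) -> np.ndarray:
    """Schlitter's upper-bound per-mode entropy, in k_B units."""
    x = sc.hbar * omega / (sc.k * temperature)
    return 0.5 * np.log1p(np.e**2 / x**2)


def quasiharmonic_entropy(ensemble: Ensemble, flavor: str = "quantum",
                          variance_floor: float = VARIANCE_FLOOR) -> EnsembleEntropy:
    """Quasi-harmonic entropy of a conformational ensemble.

    Modes with eigenvalue below ``variance_floor`` (numerical null space,
    including the six rigid-body directions removed by superposition) are
    discarded; at most 3N − 6 modes contribute.
    """
    if ensemble.n_frames < 2:
        raise ContractError("entropy needs >= 2 frames")
    eig = _covariance_eigenvalues(ensemble)
    eig = eig[eig > variance_floor]
    max_modes = max(3 * ensemble.n_atoms - 6, 1)
    eig = eig[:max_modes]
    if eig.size == 0:
        raise ZeroFluctuationError("all frames identical: no variance above the floor")
    omega = np.sqrt(sc.k * ensemble.temperature / (eig * _AMU_A2))
    if flavor == "quantum":
        s_kb = mode_entropy_quantum(omega, ensemble.temperature)
    elif flavor == "schlitter":
        s_kb = mode_entropy_schlitter(omega, ensemble.temperature)
    else:
        raise ContractError(f"unknown entropy flavor {flavor!r}")
    per_mole = s_kb * sc.k * sc.Avogadro / _CAL  # cal/mol/K
    return EnsembleEntropy(
        total_entropy=float(per_mole.sum()),
        mode_frequencies=omega,
        n_modes_used=int(eig.size),
        mode_entropies=per_mole,
        eigenvalues=eig,
    )


def entropy_from_eigenvalues(eigenvalues, temperature: float = 300.0,
                             flavor: str = "quantum") -> float:
    """Closed-form entropy (cal/mol/K) for known mass-weighted eigenvalues."""
    eig = np.asarray(eigenvalues, dtype=float)
    if np.any(eig <= 0):
        raise ContractError("eigenvalues must be positive")
    omega = np.sqrt(sc.k * temperature / (eig * _AMU_A2))
    fn = mode_entropy_quantum if flavor == "quantum" else mode_entropy_schlitter
    return float((fn(omega, temperature) * sc.k * sc.Avogadro / _CAL).sum())


def fluctuation_bfactors(ensemble: Ensemble) -> np.ndarray:
    """Per-atom B-factors B = (8π²/3)·⟨Δr²⟩ in Å² from the fitted frames."""
    frames = superpose_frames(ensemble)
    mean = frames.mean(axis=0)
    msf = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)
    return (8 * np.pi**2 / 3) * msf


def terminal_distance_series(ensemble: Ensemble, atom_i: int, atom_j: int) -> np.ndarray:
    """Per-frame Euclidean distance between two atoms (no superposition needed)."""
    n = ensemble.n_atoms
    for idx in (atom_i, atom_j):
        if not (-n <= idx < n):
            raise ContractError(f"atom index {idx} out of range for {n} atoms")
    return np.linalg.norm(ensemble.frames[:, atom_i] - ensemble.frames[:, atom_j], axis=1)


# ---------------------------------------------------------------------------
# input


def ensemble_from_pdb(source: str, temperature: float = 300.0) -> Ensemble:
    """Build an Ensemble from multi-model PDB text (all models, all atoms)."""
    from . import constants as K
    from .structure_io import parse_models

    models = parse_models(source)
    if len(models) < 2:
        raise ContractError("multi-model PDB with >= 2 models required")
    names, frames = [], []
    first = models[0]
    order = [(r.key, a) for r in first.residues() for a in r.atoms]
    for key, aname in order:
        names.append(aname)
    for st in models:
        coords = []
        for key, aname in order:
            coords.append(st.get_residue(key).atoms[aname])
        frames.append(coords)
    masses = np.array(
        [K.ATOMIC_MASSES.get(n[0], 12.0) for n in names]
    )
    return Ensemble(names, masses, np.asarray(frames), temperature)
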