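"""Native-disulfide statistics mined from a structure corpus.

The library holds (a) per-feature empirical densities over the 44-dimensional
geometric descriptor, used by the geometric probability score; (b) 8-atom
coordinate templates (N/Cα/Cβ/Sγ of both cysteines) for nearest-native RMSD
matching; and (c) a local-environment profile (secondary-structure class by
φ/ψ region × burial class by Cα neighbor count).

Densities are Laplace-smoothed (add-one per bin) inside each feature's
occupied range so the geometric score never vanishes from sampling holes
alone; a hard zero is reserved for values outside the range any native
disulfide occupies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .errors import ContractError, EmptyLibraryError, ParseError, SchemaVersionError
from .geometry import ANGLE_FEATURES, FEATURE_NAMES, dihedral, extract_geometry, superpose
from .structure_io import Structure, detect_native_disulfides

SCHEMA_VERSION = 1


@dataclass
class FeatureHistogram:
    """Smoothed empirical density of one scalar feature.

    ``support_lo``/``support_hi`` bound the contiguous range of bins occupied
    by at least one raw observation; densities are defined (and integrate to
    one) over that range only.
    """

    edges: np.ndarray
    densities: np.ndarray  # zero outside [support_lo, support_hi)
    support_lo: float
    support_hi: float

    def density_at(self, value: float) -> float:
        """Piecewise-linear density between bin centers; 0 outside the support.

        Linear interpolation keeps the score continuous in every descriptor,
        so values on a bin boundary are numerically stable under rigid-body
        round-off.
        """
        if not (self.support_lo <= value <= self.support_hi):
            return 0.0
        centers = (self.edges[:-1] + self.edges[1:]) / 2
        inside = (self.edges[:-1] >= self.support_lo - 1e-12) & (
            self.edges[1:] <= self.support_hi + 1e-12
        )
        return float(np.interp(value, centers[inside], self.densities[inside]))

    @property
    def max_density(self) -> float:
        return float(self.densities.max())

    def modal_value(self) -> float:
        """Center of the highest-density bin."""
        i = int(np.argmax(self.densities))
        return float((self.edges[i] + self.edges[i + 1]) / 2)


@dataclass
class LibraryConfig:
    sg_cutoff: float = K.NATIVE_SG_CUTOFF
    distance_bin_width: float = K.DISTANCE_BIN_WIDTH
    angle_bin_width: float = K.ANGLE_BIN_WIDTH
    burial_neighbor_cutoff: float = 10.0  # Å around Cα
    burial_threshold: int = 10            # neighbors above which a site is buried


@dataclass
class DisulfideLibrary:
    feature_histograms: dict[str, FeatureHistogram]
    templates: list[tuple[str, np.ndarray, str]]  # (template id, 8x3 frame, source id)
    env_profile: dict[str, float]
    n_observations: int
    config: LibraryConfig = field(default_factory=LibraryConfig)


def _feature_edges(name: str, config: LibraryConfig) -> np.ndarray:
    if name in ANGLE_FEATURES:
        lo, hi = K.ANGLE_RANGE
        width = config.angle_bin_width
    else:
        lo, hi = K.DISTANCE_RANGE
        width = config.distance_bin_width
    return np.arange(lo, hi + width / 2, width)


def _build_histogram(values: np.ndarray, edges: np.ndarray) -> FeatureHistogram:
    counts, _ = np.histogram(values, bins=edges)
    occupied = np.nonzero(counts)[0]
    lo_i, hi_i = occupied[0], occupied[-1]
    width = edges[1] - edges[0]
    k = hi_i - lo_i + 1
    dens = np.zeros(len(counts))
    dens[lo_i : hi_i + 1] = (counts[lo_i : hi_i + 1] + 1) / (counts.sum() + k) / width
    return FeatureHistogram(
        edges=edges,
        densities=dens,
        support_lo=float(edges[lo_i]),
        support_hi=float(edges[hi_i + 1]),
    )


# ---------------------------------------------------------------------------
# environment classes


def _phi_psi(chain_residues, i):
    try:
        prev_c = chain_residues[i - 1].atoms["C"] if i > 0 else None
        res = chain_residues[i]
        next_n = chain_residues[i + 1].atoms["N"] if i + 1 < len(chain_residues) else None
        if prev_c is None or next_n is None:
            return None, None
        phi = dihedral(prev_c, res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], next_n)
        return phi, psi
    except KeyError:
        return None, None


def _ss_class(phi, psi) -> str:
    if phi is None or psi is None:
        return "other"
    if -120 <= phi <= -30 and -80 <= psi <= -5:
        return "helix"
    if -180 <= phi <= -45 and (psi >= 90 or psi <= -150):
        return "strand"
    return "other"


def environment_class(structure: Structure, res_key, config: LibraryConfig) -> str:
    """Joint class: φ/ψ secondary-structure region × Cα-neighbor burial."""
    chain_id, pos = structure.ordinal(res_key)
    chain = next(c for c in structure.chains if c.chain_id == chain_id)
    phi, psi = _phi_psi(chain.residues, pos)
    ca = structure.get_residue(res_key).atoms.get("CA")
    n_neigh = 0
    if ca is not None:
        for other in structure.residues():
            if other.key == tuple(res_key) or "CA" not in other.atoms:
                continue
            if np.linalg.norm(other.atoms["CA"] - ca) <= config.burial_neighbor_cutoff:
                n_neigh += 1
    burial = "buried" if n_neigh > config.burial_threshold else "exposed"
    return f"{_ss_class(phi, psi)}_{burial}"


# ---------------------------------------------------------------------------
# build / query


def build_library(corpus: list[Structure], config: LibraryConfig | None = None) -> DisulfideLibrary:
    """Mine every native disulfide of the corpus into histograms and templates.

    One observation per detected disulfide; deterministic for a fixed corpus
    order. Raises :class:`EmptyLibraryError` when the corpus contains none.
    """
    if not corpus:
        raise ContractError("corpus must be non-empty")
    config = config or LibraryConfig()
    observations: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    templates = []
    env_counts: dict[str, int] = {}
    n_obs = 0
    for st in corpus:
        for pair in detect_native_disulfides(st, sg_cutoff=config.sg_cutoff):
            geom = extract_geometry(st, pair, use_modeled=False)
            for name, value in geom.features().items():
                observations[name].append(value)
            templates.append((f"{st.id}:{pair.res_a[1]}-{pair.res_b[1]}", geom.frame, st.id))
            for key in (pair.res_a, pair.res_b):
                cls = environment_class(st, key, config)
                env_counts[cls] = env_counts.get(cls, 0) + 1
            n_obs += 1
    if n_obs == 0:
        raise EmptyLibraryError("corpus contains no native disulfides")
    histograms = {
        name: _build_histogram(np.asarray(vals), _feature_edges(name, config))
        for name, vals in observations.items()
    }
    total_env = sum(env_counts.values())
    env_profile = {cls: cnt / total_env for cls, cnt in sorted(env_counts.items())}
    return DisulfideLibrary(histograms, templates, env_profile, n_obs, config)


_SWAP = [4, 5, 6, 7, 0, 1, 2, 3]  # residue-order swap of the 8-atom frame


def nearest_template(frame: np.ndarray, library: DisulfideLibrary) -> tuple[str, float]:
    """Template minimizing superposition RMSD over the 8 corresponding atoms.

    Both residue orderings of the query are tried (a disulfide is symmetric);
    ties break toward the earlier template id.
    """
    if not library.templates:
        raise EmptyLibraryError("library has no templates")
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (8, 3):
        raise ContractError("query frame must be 8 atoms (N,CA,CB,SG x 2)")
    best_id, best_rmsd = None, np.inf
    for tid, tframe, _ in library.templates:
        for query in (frame, frame[_SWAP]):
            r = superpose(query, tframe).rmsd
            if r < best_rmsd - 1e-12:
                best_id, best_rmsd = tid, r
    return best_id, float(best_rmsd)


# ---------------------------------------------------------------------------
# persistence


def save_library(library: DisulfideLibrary, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_observations": library.n_observations,
        "config": vars(library.config),
        "env_profile": library.env_profile,
        "feature_histograms": {
            name: {
                "edges": h.edges.tolist(),
                "densities": h.densities.tolist(),
                "support_lo": h.support_lo,
                "support_hi": h.support_hi,
            }
            for name, h in library.feature_histograms.items()
        },
        "templates": [
            {"id": tid, "frame": frame.tolist(), "source": src}
            for tid, frame, src in library.templates
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_library(path) -> DisulfideLibrary:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"corrupt library file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"library schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    histograms = {
        name: FeatureHistogram(
            edges=np.asarray(h["edges"]),
            densities=np.asarray(h["densities"]),
            support_lo=h["support_lo"],
            support_hi=h["support_hi"],
        )
        for name, h in payload["feature_histograms"].items()
    }
    templates = [
        (t["id"], np.asarray(t["frame"]), t["source"]) for t in payload["templates"]
    ]
    return DisulfideLibrary(
        feature_histograms=histograms,
        templates=templates,
        env_profile=payload["env_profile"],
        n_observations=payload["n_observations"],
        config=LibraryConfig(**payload["config"]),
    )
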