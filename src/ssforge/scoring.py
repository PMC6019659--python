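"""The three candidate scores and the filter/rank procedure.

For any residue pair the pipeline computes:

* ``p_geom`` — geometric probability: the geometric mean, over all 44
  descriptors, of the library density at the observed value normalized by
  that feature's maximum density. Exactly zero iff any descriptor falls
  outside the range occupied by native disulfides.
* ``p_rmsd`` — closeness to the nearest native template:
  exp(-rmsd² / (2σ²)) with rmsd from 8-atom Kabsch superposition.
* ``p_delta_s`` — admissibility and magnitude of the loop-closure
  conformational entropy change ΔS = -2.1 - (3/2)·R·ln n (cal·mol⁻¹·K⁻¹)
  for a loop of n residues closed by the new bond.

Candidates with ``p_geom = 0`` or ``p_delta_s = 0`` are removed and the rest
sorted by ``p_geom`` descending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .errors import ContractError, EmptyLibraryError, MissingAtomError
from .geometry import DisulfideGeometry, extract_geometry
from .library import DisulfideLibrary, nearest_template
from .structure_io import ResiduePair, Structure, make_pair

logger = logging.getLogger(__name__)


@dataclass
class ScoreTriple:
    p_geom: float
    p_rmsd: float
    delta_s: float      # cal/mol/K, <= 0 for admissible candidates
    p_delta_s: float

    def as_features(self) -> tuple[float, float, float]:
        """The classifier's feature vector (p_geom, p_rmsd, p_delta_s)."""
        return (self.p_geom, self.p_rmsd, self.p_delta_s)


@dataclass
class CandidateRecord:
    pair: ResiduePair
    geometry: DisulfideGeometry
    scores: ScoreTriple
    rmsd: float
    svm_label: str = "unscored"
    svm_margin: float = float("nan")


@dataclass
class ScoringConfig:
    min_separation: int = 4
    rotamer_set: tuple = K.DEFAULT_ROTAMERS
    sigma: float = K.DEFAULT_RMSD_SIGMA
    sg_target: float = K.BOND_SG_SG
    include_inter_chain: bool = False
    entropy_cap: float = K.ENTROPY_CAP


def p_geom(geometry: DisulfideGeometry, library: DisulfideLibrary) -> float:
    """Geometric mean of normalized per-feature densities, in [0, 1]."""
    if not library.feature_histograms:
        raise EmptyLibraryError("library has no feature histograms")
    log_sum = 0.0
    feats = geometry.features()
    for name, value in feats.items():
        hist = library.feature_histograms[name]
        d = hist.density_at(value)
        if d == 0.0:
            return 0.0
        log_sum += math.log(d / hist.max_density)
    return float(math.exp(log_sum / len(feats)))


def p_rmsd(frame: np.ndarray, library: DisulfideLibrary,
           sigma: float = K.DEFAULT_RMSD_SIGMA) -> tuple[float, float]:
    """(probability, rmsd) against the geometrically closest native template."""
    if sigma <= 0:
        raise ContractError("sigma must be positive")
    _, rmsd = nearest_template(frame, library)
    return float(math.exp(-(rmsd**2) / (2 * sigma**2))), rmsd


def loop_entropy(n_residues: int) -> float:
    """Loop-closure ΔS (cal·mol⁻¹·K⁻¹) for a loop of n residues."""
    if n_residues < 2:
        raise ContractError("loop must span at least 2 residues")
    return K.LOOP_ENTROPY_CONST - 1.5 * K.GAS_CONSTANT_CAL * math.log(n_residues)


def p_delta_s(pair: ResiduePair, structure: Structure, min_separation: int = 4,
              entropy_cap: float = K.ENTROPY_CAP) -> tuple[float, float]:
    """(delta_s, p_delta_s) for the loop the candidate bond would close.

    Pairs closer in sequence than ``min_separation`` (ordinal positions) and
    inter-chain pairs (no covalent path to close a loop) are inadmissible:
    p_delta_s = 0. Otherwise p_delta_s = min(1, |ΔS| / cap).
    """
    if min_separation < 2:
        raise ContractError("min_separation must be >= 2")
    if pair.inter_chain or pair.sequence_separation < min_separation:
        n = pair.sequence_separation + 1 if not pair.inter_chain else 0
        ds = loop_entropy(n) if n >= 2 else 0.0
        return ds, 0.0
    n = pair.sequence_separation + 1
    ds = loop_entropy(n)
    return ds, min(1.0, abs(ds) / entropy_cap)


def score_pair(structure: Structure, pair: ResiduePair, library: DisulfideLibrary,
               config: ScoringConfig | None = None) -> CandidateRecord:
    """Score one candidate pair with virtually modelled cysteine side chains."""
    config = config or ScoringConfig()
    geom = extract_geometry(
        structure, pair, use_modeled=True,
        rotamer_set=config.rotamer_set, sg_target=config.sg_target,
    )
    pg = p_geom(geom, library)
    pr, rmsd = p_rmsd(geom.frame, library, sigma=config.sigma)
    ds, pds = p_delta_s(pair, structure, config.min_separation, config.entropy_cap)
    return CandidateRecord(pair, geom, ScoreTriple(pg, pr, ds, pds), rmsd)


def enumerate_pairs(structure: Structure, config: ScoringConfig) -> list[ResiduePair]:
    """All admissible residue pairs (intra-chain by default)."""
    keys = [r.key for r in structure.residues()]
    pairs = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            pair = make_pair(structure, keys[i], keys[j])
            if pair.inter_chain and not config.include_inter_chain:
                continue
            pairs.append(pair)
    return pairs


def rank_candidates(structure: Structure, library: DisulfideLibrary,
                    classifier=None, config: ScoringConfig | None = None
                    ) -> list[CandidateRecord]:
    """Score every pair, filter zero-probability candidates, sort by p_geom.

    Pairs with ``p_delta_s = 0`` or ``p_geom = 0`` are removed. Remaining
    records are sorted by p_geom descending (ties: ascending template RMSD,
    then residue order). When a classifier is given, its label and margin are
    attached to each surviving record.
    """
    config = config or ScoringConfig()
    pairs = enumerate_pairs(structure, config)
    n_enumerated = len(pairs)
    records = []
    n_missing = n_filtered = 0
    for pair in pairs:
        # quick gate: sequence-local and inter-chain pairs can never pass the
        # entropy rule, so skip the expensive geometry for them
        _, pds = p_delta_s(pair, structure, config.min_separation, config.entropy_cap)
        if pds == 0.0:
            n_filtered += 1
            continue
        try:
            rec = score_pair(structure, pair, library, config)
        except MissingAtomError:
            n_missing += 1
            continue
        if rec.scores.p_geom == 0.0 or rec.scores.p_delta_s == 0.0:
            n_filtered += 1
            continue
        records.append(rec)
    if classifier is not None:
        for rec in records:
            label, margin = classifier.predict_one(rec.scores.as_features())
            rec.svm_label = label
            rec.svm_margin = margin
    records.sort(key=lambda r: (-r.scores.p_geom, r.rmsd, r.pair.res_a, r.pair.res_b))
    logger.info(
        "ranked %d/%d candidate pairs (%d filtered by zero score, %d unscoreable)",
        len(records), n_enumerated, n_filtered, n_missing,
    )
    return records
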