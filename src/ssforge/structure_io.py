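"""Structure input/output and native disulfide identification.

Parsing is delegated to gemmi; the result is flattened into a small
``Structure`` container that preserves author numbering and insertion codes
and resolves alternate locations to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as K
from .errors import ContractError, EmptyStructureError, ParseError

logger = logging.getLogger(__name__)

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC",
}


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_number, insertion_code) — unique within a Structure."""
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    # SSBOND declarations from the header, as pairs of residue keys
    declared_ssbonds: list[tuple[tuple, tuple]] = field(default_factory=list)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def get_residue(self, key) -> Residue:
        key = (key[0], int(key[1]), key[2] if len(key) > 2 else "")
        try:
            return self._index()[key]
        except KeyError:
            raise KeyError(f"no residue {key} in structure {self.id!r}") from None

    def _index(self):
        if not hasattr(self, "_res_index") or len(self._res_index) != sum(
            len(c.residues) for c in self.chains
        ):
            self._res_index = {r.key: r for r in self.residues()}
        return self._res_index

    def ordinal(self, key) -> tuple[str, int]:
        """(chain_id, position within chain) — survives author-numbering gaps."""
        key = (key[0], int(key[1]), key[2] if len(key) > 2 else "")
        for chain in self.chains:
            for i, res in enumerate(chain.residues):
                if res.key == key:
                    return chain.chain_id, i
        raise KeyError(key)


@dataclass(frozen=True)
class ResiduePair:
    """A candidate pair in canonical order (lower chain, then lower number)."""

    res_a: tuple
    res_b: tuple
    sequence_separation: int  # ordinal separation; -1 flags inter-chain

    @property
    def inter_chain(self) -> bool:
        return self.sequence_separation < 0


def make_pair(structure: Structure, key_a, key_b) -> ResiduePair:
    ra = structure.get_residue(key_a)
    rb = structure.get_residue(key_b)
    if ra.key == rb.key:
        raise ContractError("a residue cannot pair with itself")
    ka, kb = sorted([ra.key, rb.key])
    ca, ia = structure.ordinal(ka)
    cb, ib = structure.ordinal(kb)
    sep = abs(ia - ib) if ca == cb else -1
    return ResiduePair(ka, kb, sep)


# ---------------------------------------------------------------------------
# parsing


def parse_structure(source: str, structure_id: str = "struct", model_index: int = 0) -> Structure:
    """Parse PDB-format text into a Structure.

    Altloc conformers are resolved by highest occupancy (ties by altloc letter);
    only the requested model is read (first by default). Raises
    :class:`ParseError` on unreadable text and :class:`EmptyStructureError`
    when no protein residues are present.
    """
    import gemmi

    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"unreadable PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("no models in input")
    if model_index >= len(st):
        raise ContractError(f"model {model_index} not present ({len(st)} models)")
    model = st[model_index]

    out = Structure(id=structure_id or st.name)
    for ch in model:
        chain = Chain(chain_id=ch.name or "A")
        for res in ch:
            if res.name not in _STANDARD_AA:
                continue
            # pick the winning conformer per atom name: max occupancy,
            # ties broken by altloc letter order
            best: dict[str, tuple] = {}
            for atom in res:
                alt = atom.altloc or ""
                cur = best.get(atom.name)
                cand = (-atom.occ, alt)
                if cur is None or cand < cur[0]:
                    best[atom.name] = (cand, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
            residue = Residue(
                chain_id=chain.chain_id,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or " ").strip(),
                res_name=res.name,
                atoms={name: pos for name, (_, pos) in best.items()},
            )
            chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    if not any(out.residues()):
        raise EmptyStructureError("no protein residues in input")

    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            k1 = (con.partner1.chain_name, con.partner1.res_id.seqid.num,
                  (con.partner1.res_id.seqid.icode or " ").strip())
            k2 = (con.partner2.chain_name, con.partner2.res_id.seqid.num,
                  (con.partner2.res_id.seqid.icode or " ").strip())
            out.declared_ssbonds.append(tuple(sorted([k1, k2])))
    return out


def parse_models(source: str, structure_id: str = "struct") -> list[Structure]:
    """All models of a multi-model PDB, each as a Structure."""
    import gemmi

    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"unreadable PDB text: {exc}") from exc
    return [parse_structure(source, f"{structure_id}.m{i}", model_index=i) for i in range(len(st))]


# ---------------------------------------------------------------------------
# native disulfide detection


def detect_native_disulfides(
    structure: Structure, sg_cutoff: float = K.NATIVE_SG_CUTOFF
) -> list[ResiduePair]:
    """CYS-CYS pairs with Sγ-Sγ distance <= sg_cutoff.

    Each cysteine joins at most one pair; when a cysteine has several partners
    within the cutoff the closest wins (greedy on ascending distance). The
    result is independent of input residue order. Disagreement with declared
    SSBOND records is logged, not raised.
    """
    if sg_cutoff <= 0:
        raise ContractError("sg_cutoff must be positive")
    cys = [r for r in structure.residues() if r.res_name == "CYS" and "SG" in r.atoms]
    cys.sort(key=lambda r: r.key)
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].atoms["SG"] - cys[j].atoms["SG"]))
            if d <= sg_cutoff:
                candidates.append((d, cys[i].key, cys[j].key))
    candidates.sort()
    used: set = set()
    pairs = []
    for _, ka, kb in candidates:
        if ka in used or kb in used:
            continue
        used.update((ka, kb))
        pairs.append(make_pair(structure, ka, kb))
    if structure.declared_ssbonds:
        found = {tuple(sorted([p.res_a, p.res_b])) for p in pairs}
        declared = set(structure.declared_ssbonds)
        if found != declared:
            logger.warning(
                "structure %s: SSBOND records disagree with geometric detection "
                "(declared-only: %s, detected-only: %s)",
                structure.id, sorted(declared - found), sorted(found - declared),
            )
    return sorted(pairs, key=lambda p: (p.res_a, p.res_b))


# ---------------------------------------------------------------------------
# writing


_ELEMENT_FROM_NAME = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}


def _element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return _ELEMENT_FROM_NAME.get(ch, ch)
    return "X"


def write_structure(structure: Structure) -> str:
    """Serialize a Structure to standard PDB ATOM records (one model)."""
    return _format_model(structure, serial_start=1) + "END\n"


def write_ensemble_pdb(structures: list[Structure]) -> str:
    """Serialize several conformers of one molecule as a multi-model PDB."""
    lines = []
    for i, st in enumerate(structures, start=1):
        lines.append(f"MODEL     {i:4d}\n")
        lines.append(_format_model(st, serial_start=1))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    return "".join(lines)


def _format_model(structure: Structure, serial_start: int = 1) -> str:
    lines = []
    serial = serial_start
    for chain in structure.chains:
        for res in chain.residues:
            for name, pos in res.atoms.items():
                el = _element(name)
                # PDB atom-name column rules: 1-char elements start in col 14
                aname = f" {name:<3s}" if len(name) < 4 and len(el) == 1 else f"{name:<4s}"
                lines.append(
                    f"ATOM  {serial:5d} {aname} {res.res_name:<3s} {chain.chain_id:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {el:>2s}\n"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].res_name:<3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].seq_number:4d}\n")
        serial += 1
    return "".join(lines)


CANDIDATE_COLUMNS = [
    "chain_a", "res_a", "chain_b", "res_b",
    "p_geom", "p_rmsd", "delta_s", "svm_label", "svm_score",
]


def write_candidates(records, destination) -> None:
    """Write prediction records as a TSV table (header + one row each)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "chain_a": rec.pair.res_a[0],
                "res_a": rec.pair.res_a[1],
                "chain_b": rec.pair.res_b[0],
                "res_b": rec.pair.res_b[1],
                "p_geom": rec.scores.p_geom,
                "p_rmsd": rec.scores.p_rmsd,
                "delta_s": rec.scores.delta_s,
                "svm_label": rec.svm_label,
                "svm_score": rec.svm_margin,
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(destination, sep="\t", index=False, float_format="%.6f")


def read_candidates(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t")
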