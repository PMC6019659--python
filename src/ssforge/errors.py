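"""Exception hierarchy for ssforge.

All package errors derive from :class:`SSForgeError` so callers can catch one
base class; contract violations (bad arguments, unusable state) additionally
derive from :class:`ContractError`, itself a ``ValueError``.
"""


class SSForgeError(Exception):
    """Base class for all ssforge errors."""


class ContractError(SSForgeError, ValueError):
    """A precondition of an operation was violated."""


class ParseError(SSForgeError):
    """Input text could not be parsed; message names the offending line."""


class EmptyStructureError(ParseError):
    """A structure source contained no protein residues."""


class MissingAtomError(SSForgeError, KeyError):
    """A required atom is absent; message identifies residue and atom."""

    def __init__(self, residue_id, atom_name):
        self.residue_id = residue_id
        self.atom_name = atom_name
        super().__init__(f"residue {residue_id} is missing atom {atom_name!r}")

    def __str__(self):  # KeyError quotes its arg; keep a readable message
        return self.args[0]


class DegenerateGeometryError(SSForgeError):
    """Collinear or coincident points make an angle undefined."""


class EmptyLibraryError(SSForgeError):
    """A disulfide library has no observations/templates."""


class SchemaVersionError(SSForgeError):
    """A serialized file declares an unsupported schema version."""


class ZeroFluctuationError(SSForgeError):
    """An ensemble has no variance above the numerical floor."""
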