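"""Exception hierarchy for fragsite."""


class FragsiteError(Exception):
    """Base class for all fragsite errors."""


class PdbParseError(FragsiteError):
    """Raised when a PDB text cannot be parsed into a structure model."""


class DsspFormatError(FragsiteError):
    """Raised when a DSSP flat file is malformed."""


class SecondaryStructureMismatchError(FragsiteError):
    """Raised when DSSP residues cannot be matched to the structure model."""

    def __init__(self, positions):
        self.positions = list(positions)
        super().__init__(
            f"DSSP residues not present in model: {self.positions}"
        )


class EmptyChainError(FragsiteError):
    """Raised when an operation requires at least one usable residue."""


class DegenerateTripletError(FragsiteError):
    """Raised when a backbone triplet is collinear and cannot be superposed."""


class MoietyPartitionError(FragsiteError):
    """Raised when a ligand cannot be decomposed into moieties."""


class TemplateDbFormatError(FragsiteError):
    """Raised when a serialized template database is malformed."""


class TemplateDbVersionError(TemplateDbFormatError):
    """Raised when a template database has an incompatible version tag."""


class UnknownSymbolError(FragsiteError):
    """Raised when a residue or secondary-structure symbol is not scoreable."""


class DegenerateScoresError(FragsiteError):
    """Raised when all binding scores of a protein are identical (SD = 0)."""


class EvaluationError(FragsiteError):
    """Raised on invalid evaluation inputs (single class, too few proteins)."""
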