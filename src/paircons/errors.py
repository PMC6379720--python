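"""Exception hierarchy for paircons.

All package-specific errors derive from :class:`PairconsError` so callers can
catch one type at pipeline boundaries.
"""


class PairconsError(Exception):
    """Base class for all paircons errors."""


class FastaParseError(PairconsError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class OrthologTableError(PairconsError):
    """Structural problem in an ortholog table; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class TranslationError(PairconsError):
    """Sequence cannot be translated (internal stop, bad length, bad codon)."""

    def __init__(self, message: str, codon_index: int | None = None):
        #: 1-based index of the offending codon, when known.
        self.codon_index = codon_index
        super().__init__(message)


class AlignmentError(PairconsError):
    """Invalid input to the protein aligner."""


class BacktranslationError(PairconsError):
    """Nucleotide sequence disagrees with the aligned amino acids."""

    def __init__(self, message: str, species: str | None = None,
                 column: int | None = None):
        self.species = species
        self.column = column
        super().__init__(message)


class CodonAlignmentError(PairconsError):
    """Aligned FASTA is not a valid codon-aware alignment."""


class DegenerateFitError(PairconsError):
    """Origin-constrained fit has no usable design (all x = 0)."""


class SimulationError(PairconsError):
    """Synthetic-data request cannot be satisfied (e.g. genome capacity)."""


class ConfigError(PairconsError):
    """Invalid run configuration."""
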