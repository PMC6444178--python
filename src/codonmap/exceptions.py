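"""Exception hierarchy for codonmap."""


class CodonMapError(Exception):
    """Base class for all codonmap errors."""


class GeneticCodeError(CodonMapError):
    """Problem loading or validating a genetic-code table."""


class UnknownGeneticCodeError(GeneticCodeError):
    """Requested translation-table id is not available."""

    def __init__(self, code_id, valid_ids):
        self.code_id = code_id
        self.valid_ids = tuple(sorted(valid_ids))
        super().__init__(
            f"unknown genetic code {code_id!r}; valid ids: "
            + ", ".join(str(i) for i in self.valid_ids)
        )


class UntranslatableCodonError(CodonMapError):
    """Codon contains ambiguity codes or other non-ACGTU characters."""


class SequenceError(CodonMapError):
    """Invalid input sequence (bad character, bad length)."""


class SignalError(CodonMapError):
    """Invalid signal pair (length mismatch, empty, constant, ...)."""


class TreeError(CodonMapError):
    """Invalid tree input (leaf-set mismatch, missing root, ...)."""
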