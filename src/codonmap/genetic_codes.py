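"""NCBI translation tables and symbolic codon translation.

The 24 currently valid NCBI genetic codes (ids 1-6, 9-14, 16, 21-31; the
retired ids 7, 8, 15, 17, 18, 19 and 20 are absent) are shipped as a TSV
data file with one row per code::

    id<TAB>name<TAB>aa_string

where ``aa_string`` is the 64-character amino-acid assignment in NCBI's
fixed storage order: codons enumerated with base order T, C, A, G at each
position (TTT, TTC, TTA, TTG, TCT, ..., GGG).  ``*`` marks termination
codons.  Codes whose NCBI entry marks codons as *conditional* stop/sense
(27, 28, 31) carry the primary amino-acid assignment, so they may contain
no ``*`` at all.  Only the basic tables are represented; alternative
initiation codons and other special cases are out of scope.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import GeneticCodeError, UnknownGeneticCodeError, UntranslatableCodonError

__all__ = [
    "CODON_ORDER",
    "STANDARD_AMINO_ACIDS",
    "GeneticCode",
    "normalize_codon",
    "load_genetic_codes",
    "list_genetic_codes",
    "load_genetic_code",
    "translate_codon",
]

#: The 64 codons in NCBI storage order (base order T, C, A, G per position).
CODON_ORDER: tuple[str, ...] = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)

#: One-letter codes of the 20 standard proteinogenic amino acids.
STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The 24 table numbers that are valid at NCBI (7, 8, 15, 17-20 retired).
VALID_CODE_IDS = (1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 16,
                  21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31)

_DATA_RESOURCE = "genetic_codes.tsv"

_U_TO_T = str.maketrans("uU", "tT")


def normalize_codon(codon: str) -> str:
    """Upper-case a codon and map U to T; reject anything else.

    Raises :class:`UntranslatableCodonError` for ambiguity codes (N, R, ...)
    or a codon whose length is not 3.
    """
    codon = str(codon).translate(_U_TO_T).upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise UntranslatableCodonError(
            f"untranslatable codon {codon!r}: expected 3 letters over A/C/G/T/U"
        )
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table.

    Parameters
    ----------
    id : int
        NCBI table number.
    name : str
        Text label, e.g. ``"Vertebrate Mitochondrial"``.
    aa_string : str
        64-character amino-acid assignment in NCBI storage order, ``*``
        for termination codons.
    """

    id: int
    name: str
    aa_string: str
    _forward: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.aa_string) != 64:
            raise GeneticCodeError(
                f"genetic code {self.id}: aa_string must have 64 characters, "
                f"got {len(self.aa_string)}"
            )
        bad = set(self.aa_string) - STANDARD_AMINO_ACIDS - {"*"}
        if bad:
            raise GeneticCodeError(
                f"genetic code {self.id}: invalid amino-acid symbols {sorted(bad)}"
            )
        object.__setattr__(
            self, "_forward", dict(zip(CODON_ORDER, self.aa_string))
        )

    def translate(self, codon: str) -> str:
        """Amino acid (one-letter code) or ``'*'`` for the given codon."""
        return self._forward[normalize_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODON_ORDER if self._forward[c] == "*")

    @property
    def n_amino_acids(self) -> int:
        """Number of distinct amino acids used by this code."""
        return len(set(self.aa_string) - {"*"})


def _default_tables_path() -> Path:
    return Path(importlib.resources.files("codonmap") / "data" / _DATA_RESOURCE)


def load_genetic_codes(path: str | Path | None = None) -> dict[int, GeneticCode]:
    """Load all translation tables from the packaged (or a user) TSV file.

    The file format is ``id<TAB>name<TAB>aa_string`` per row, UTF-8, with
    ``#`` comment lines allowed.
    """
    path = Path(path) if path is not None else _default_tables_path()
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise GeneticCodeError(f"cannot read genetic-code table file {path}: {exc}") from exc
    codes: dict[int, GeneticCode] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GeneticCodeError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        try:
            code_id = int(parts[0])
        except ValueError as exc:
            raise GeneticCodeError(f"{path}:{lineno}: bad code id {parts[0]!r}") from exc
        if code_id in codes:
            raise GeneticCodeError(f"{path}:{lineno}: duplicate code id {code_id}")
        codes[code_id] = GeneticCode(code_id, parts[1], parts[2])
    if not codes:
        raise GeneticCodeError(f"no genetic codes found in {path}")
    return codes


def list_genetic_codes(path: str | Path | None = None) -> tuple[int, ...]:
    """Sorted tuple of the available translation-table ids."""
    return tuple(sorted(load_genetic_codes(path)))


def load_genetic_code(code_id: int, path: str | Path | None = None) -> GeneticCode:
    """Load a single translation table by NCBI number."""
    codes = load_genetic_codes(path)
    try:
        return codes[code_id]
    except KeyError:
        raise UnknownGeneticCodeError(code_id, codes) from None


def translate_codon(code: GeneticCode, codon: str) -> str:
    """Translate one codon under ``code``; returns ``'*'`` for stops."""
    return code.translate(codon)
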