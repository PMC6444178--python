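"""Nucleotide-integer maps and numerical conversion of coding sequences.

A *numerical map* assigns the four nucleotides A, C, G, T bijectively to
the integers 0-3; there are 4! = 24 such maps.  Reading the three mapped
digits of a codon as a quaternary number yields its *codon index* in
0-63, e.g. ATG under T=0, C=1, A=2, G=3 is 203 in base 4, i.e. 35.

Amino acids receive integer values 1-20 by *first-encounter assignment*:
walk the codon indices 0..63 in ascending order, give each previously
unseen amino acid the next counter value, and reserve 0 for termination
codons regardless of their position.  The resulting length-64 vector from
codon index to amino-acid value is the *transformation function*; it is
what the map optimization (see :mod:`codonmap.optimize`) judges.

Signals live at three levels: nucleotide (0-3), codon (0-63) and
amino acid (0-20).  Codon and amino-acid signals derived from one CDS
have the same length M = len(cds)/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .exceptions import SequenceError
from .genetic_codes import CODON_ORDER, GeneticCode, normalize_codon

__all__ = [
    "NucleotideMap",
    "AminoAcidMap",
    "TransformationFunction",
    "Signal",
    "ORIGINAL_MAP",
    "GLOBAL_OPTIMAL_MAP",
    "enumerate_maps",
    "codon_index",
    "index_to_codon",
    "build_amino_acid_map",
    "transformation_function",
    "encode_nucleotides",
    "encode_codons",
    "encode_amino_acids",
    "encode_signal_pair",
]

_BASES = "ACGT"


@dataclass(frozen=True, order=True)
class NucleotideMap:
    """A bijection from {A, C, G, T} to {0, 1, 2, 3}.

    ``acgt`` holds the integers assigned to A, C, G, T *in that order*;
    the canonical notation ``[1 0 3 2]`` therefore means A=1, C=0, G=3,
    T=2.
    """

    acgt: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.acgt) != [0, 1, 2, 3]:
            raise ValueError(
                f"nucleotide map {self.acgt} is not a permutation of 0..3"
            )
        object.__setattr__(self, "acgt", tuple(int(v) for v in self.acgt))

    @classmethod
    def from_assignment(cls, **bases: int) -> "NucleotideMap":
        """Build from keyword values, e.g. ``NucleotideMap.from_assignment(T=0, C=1, A=2, G=3)``."""
        return cls(tuple(bases[b] for b in _BASES))

    @classmethod
    def from_string(cls, text: str) -> "NucleotideMap":
        """Parse ``"1,0,3,2"`` or ``"[1 0 3 2]"`` (A, C, G, T order)."""
        parts = text.strip().strip("[]").replace(",", " ").split()
        if len(parts) != 4:
            raise ValueError(f"cannot parse nucleotide map from {text!r}")
        return cls(tuple(int(p) for p in parts))

    def __getitem__(self, base: str) -> int:
        return self.acgt[_BASES.index(base)]

    @property
    def label(self) -> str:
        """Canonical bracket notation, e.g. ``[1 0 3 2]``."""
        return "[" + " ".join(str(v) for v in self.acgt) + "]"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The previously published optimal map T=0, C=1, A=2, G=3.
ORIGINAL_MAP = NucleotideMap((2, 1, 3, 0))

#: The globally optimal map A=1, C=0, G=3, T=2 (rank-sum optimum over all
#: 24 NCBI codes; recomputed, not assumed, by codonmap.optimize).
GLOBAL_OPTIMAL_MAP = NucleotideMap((1, 0, 3, 2))


def enumerate_maps() -> list[NucleotideMap]:
    """All 24 nucleotide maps, ascending by the (A, C, G, T) value tuple."""
    return [NucleotideMap(p) for p in sorted(permutations(range(4)))]


def codon_index(nmap: NucleotideMap, codon: str) -> int:
    """Decimal codon index 0..63: the mapped digits read as quaternary."""
    b1, b2, b3 = normalize_codon(codon)
    return 16 * nmap[b1] + 4 * nmap[b2] + nmap[b3]


def index_to_codon(nmap: NucleotideMap, index: int) -> str:
    """Inverse of :func:`codon_index`."""
    if not 0 <= index <= 63:
        raise ValueError(f"codon index {index} outside 0..63")
    inv = {nmap[b]: b for b in _BASES}
    return inv[index // 16] + inv[(index // 4) % 4] + inv[index % 4]


@dataclass(frozen=True)
class AminoAcidMap:
    """Integer values 1..k for the amino acids of one code, 0 for stops."""

    values: dict[str, int]
    nmap: NucleotideMap
    code: GeneticCode

    def __getitem__(self, amino_acid: str) -> int:
        if amino_acid == "*":
            return 0
        return self.values[amino_acid]


@dataclass(frozen=True)
class TransformationFunction:
    """Length-64 vector: codon index -> amino-acid value (0 for stops)."""

    values: np.ndarray
    amino_acids: tuple[str, ...]  # per codon index, '*' for stops
    nmap: NucleotideMap
    code: GeneticCode

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if v.shape != (64,):
            raise ValueError("transformation function must have 64 entries")
        object.__setattr__(self, "values", v)

    def __getitem__(self, index: int) -> int:
        return int(self.values[index])


def build_amino_acid_map(nmap: NucleotideMap, code: GeneticCode) -> AminoAcidMap:
    """First-encounter amino-acid value assignment.

    Codon indices are walked in ascending order under ``nmap``; stops get
    0, each previously unseen amino acid gets the next counter value
    starting at 1, repeats are skipped.
    """
    by_index = sorted(CODON_ORDER, key=lambda c: codon_index(nmap, c))
    values: dict[str, int] = {}
    counter = 0
    for codon in by_index:
        aa = code.translate(codon)
        if aa == "*" or aa in values:
            continue
        counter += 1
        values[aa] = counter
    return AminoAcidMap(values, nmap, code)


def transformation_function(nmap: NucleotideMap, code: GeneticCode) -> TransformationFunction:
    """Compose codon indexing with the amino-acid value assignment."""
    aa_map = build_amino_acid_map(nmap, code)
    values = np.zeros(64, dtype=np.int64)
    aas = [""] * 64
    for codon in CODON_ORDER:
        i = codon_index(nmap, codon)
        aa = code.translate(codon)
        aas[i] = aa
        values[i] = aa_map[aa]
    return TransformationFunction(values, tuple(aas), nmap, code)


@dataclass(frozen=True)
class Signal:
    """Integer signal at nucleotide (0-3), codon (0-63) or amino-acid (0-20) level."""

    values: np.ndarray
    level: str

    _RANGES = {"nucleotide": 3, "codon": 63, "amino_acid": 20}

    def __post_init__(self) -> None:
        if self.level not in self._RANGES:
            raise ValueError(f"unknown signal level {self.level!r}")
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 1:
            raise ValueError("signal values must be one-dimensional")
        if v.size and (v.min() < 0 or v.max() > self._RANGES[self.level]):
            raise ValueError(
                f"{self.level} signal values outside 0..{self._RANGES[self.level]}"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)


def _normalize_sequence(sequence: str) -> str:
    return str(sequence).translate(str.maketrans("uU", "tT")).upper()


def encode_nucleotides(
    nmap: NucleotideMap, sequence: str, permissive: bool = False
) -> Signal:
    """Replace each base by its integer; output length equals input length.

    With ``permissive`` set, non-ACGTU characters are skipped; otherwise
    the first offending position raises :class:`SequenceError`.
    """
    seq = _normalize_sequence(sequence)
    out = []
    for pos, base in enumerate(seq):
        if base not in _BASES:
            if permissive:
                continue
            raise SequenceError(
                f"invalid character {base!r} at position {pos + 1}"
            )
        out.append(nmap[base])
    return Signal(np.array(out, dtype=np.int64), "nucleotide")


def _codons_of(cds: str, truncate: bool, permissive: bool) -> list[str | None]:
    """Split a CDS into triplets; ``None`` marks an unusable codon."""
    seq = _normalize_sequence(cds)
    if len(seq) % 3 != 0:
        if not truncate:
            raise SequenceError(
                f"CDS length {len(seq)} is not divisible by 3 "
                "(use truncate to drop trailing bases)"
            )
        warnings.warn(
            f"truncating {len(seq) % 3} trailing base(s) of a length-{len(seq)} CDS",
            stacklevel=3,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    codons: list[str | None] = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if all(b in _BASES for b in codon):
            codons.append(codon)
        elif permissive:
            codons.append(None)
        else:
            raise SequenceError(
                f"untranslatable codon {codon!r} at codon position {i // 3 + 1}"
            )
    return codons


def encode_codons(
    nmap: NucleotideMap,
    cds: str,
    truncate: bool = False,
    permissive: bool = False,
) -> Signal:
    """Codon signal: one index 0..63 per consecutive non-overlapping triplet."""
    values = [
        codon_index(nmap, c)
        for c in _codons_of(cds, truncate, permissive)
        if c is not None
    ]
    return Signal(np.array(values, dtype=np.int64), "codon")


def encode_amino_acids(
    nmap: NucleotideMap,
    code: GeneticCode,
    cds: str,
    truncate: bool = False,
    permissive: bool = False,
    strip_stops: bool = False,
) -> Signal:
    """Amino-acid signal: the transformation function applied per codon."""
    _, aa = encode_signal_pair(
        nmap, code, cds, truncate=truncate, permissive=permissive,
        strip_stops=strip_stops,
    )
    return aa


def encode_signal_pair(
    nmap: NucleotideMap,
    code: GeneticCode,
    cds: str,
    truncate: bool = False,
    permissive: bool = False,
    strip_stops: bool = False,
) -> tuple[Signal, Signal]:
    """Index-aligned (codon signal, amino-acid signal) pair for one CDS.

    Codons dropped in permissive mode are removed from *both* signals so
    they stay aligned for the distortion metrics.  With ``strip_stops``,
    a single trailing termination codon is removed from both.
    """
    codons = [c for c in _codons_of(cds, truncate, permissive) if c is not None]
    tf = transformation_function(nmap, code)
    c_values = [codon_index(nmap, c) for c in codons]
    a_values = [tf[i] for i in c_values]
    if strip_stops and codons and code.is_stop(codons[-1]):
        codons, c_values, a_values = codons[:-1], c_values[:-1], a_values[:-1]
    internal_stops = sum(1 for c in codons[:-1] if code.is_stop(c))
    if internal_stops:
        warnings.warn(
            f"{internal_stops} internal stop codon(s) found; possible frame error",
            stacklevel=2,
        )
    return (
        Signal(np.array(c_values, dtype=np.int64), "codon"),
        Signal(np.array(a_values, dtype=np.int64), "amino_acid"),
    )
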