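"""Degeneration-weight optimization of nucleotide maps.

The genetic code is degenerated: several codons share one amino acid, so
the transformation function from codon index to amino-acid value cannot
be monotone for every map.  A *degenerated segment* is a maximal run of
consecutive codon indices (after removing termination codons) whose
shared amino-acid value lies strictly below the running maximum of the
values seen earlier in the scan.  Each segment has a length ``L`` (codons
in the run), a height ``H`` (running maximum minus the run's value) and
a weight ``w = L * H``.

Two criteria summarize a map's quality for one genetic code: ``N``, the
number of degenerated segments (the earlier, coarser criterion), and
``W``, the sum of segment weights, which also penalizes how far and how
broadly the function drops.  The per-code optimal map minimizes ``W``
over the 24 candidates.  Across codes, each map is ranked by ``W``
within every code and the *suitability score* is its rank sum; the map
with the minimal score is the global optimum, which this module derives
rather than hard-codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import CodonMapError
from .genetic_codes import GeneticCode
from .maps import NucleotideMap, TransformationFunction, enumerate_maps, transformation_function

__all__ = [
    "DegeneratedSegment",
    "MapScore",
    "SuitabilityTable",
    "find_degenerated_segments",
    "weight_criterion_W",
    "count_criterion_N",
    "score_all_maps",
    "optimal_map_for_code",
    "suitability_scores",
    "global_optimal_map",
]


@dataclass(frozen=True)
class DegeneratedSegment:
    """One below-running-maximum run of the transformation function."""

    amino_acid: str
    codon_indices: tuple[int, ...]
    L: int
    H: int

    @property
    def w(self) -> int:
        """Weight of the segment, ``L * H``."""
        return self.L * self.H


def find_degenerated_segments(tf: TransformationFunction) -> list[DegeneratedSegment]:
    """Detect the degenerated segments of a transformation function.

    Stop entries (value 0) are removed before scanning, so they neither
    contribute to nor break a run; the remaining entries are scanned in
    ascending codon-index order against the prefix running maximum.  A
    segment is a maximal run of equal values strictly below the running
    maximum at the run's start.
    """
    entries = [
        (i, int(v), tf.amino_acids[i])
        for i, v in enumerate(tf.values)
        if v != 0
    ]
    segments: list[DegeneratedSegment] = []
    running_max = 0
    pos = 0
    while pos < len(entries):
        value = entries[pos][1]
        end = pos
        while end < len(entries) and entries[end][1] == value:
            end += 1
        if value < running_max:
            segments.append(
                DegeneratedSegment(
                    amino_acid=entries[pos][2],
                    codon_indices=tuple(e[0] for e in entries[pos:end]),
                    L=end - pos,
                    H=running_max - value,
                )
            )
        running_max = max(running_max, value)
        pos = end
    return segments


def weight_criterion_W(tf: TransformationFunction) -> int:
    """Sum of degenerated-segment weights (termination codons excluded)."""
    return sum(seg.w for seg in find_degenerated_segments(tf))


def count_criterion_N(tf: TransformationFunction) -> int:
    """Number of degenerated segments (termination codons excluded)."""
    return len(find_degenerated_segments(tf))


@dataclass(frozen=True)
class MapScore:
    """W, N and the segment breakdown of one map on one genetic code."""

    nmap: NucleotideMap
    code_id: int
    segments: tuple[DegeneratedSegment, ...]

    @property
    def W(self) -> int:
        return sum(seg.w for seg in self.segments)

    @property
    def N(self) -> int:
        return len(self.segments)


def score_all_maps(code: GeneticCode) -> list[MapScore]:
    """One :class:`MapScore` per nucleotide map, in canonical map order."""
    return [
        MapScore(
            nmap,
            code.id,
            tuple(find_degenerated_segments(transformation_function(nmap, code))),
        )
        for nmap in enumerate_maps()
    ]


def optimal_map_for_code(code: GeneticCode) -> tuple[MapScore, list[MapScore]]:
    """The W-minimal map for a code.

    Returns ``(primary, ties)`` where ``ties`` lists *all* scores
    attaining the minimal W (canonical order) and ``primary`` is the
    first of them.
    """
    scores = score_all_maps(code)
    w_min = min(s.W for s in scores)
    ties = [s for s in scores if s.W == w_min]
    return ties[0], ties


@dataclass(frozen=True)
class SuitabilityTable:
    """W values, per-code suitability ranks and rank-sum scores.

    ``W`` and ``ranks`` are DataFrames indexed by canonical map label
    with one column per genetic-code id; ``scores`` is the rank sum per
    map.  ``unique_optimum_count`` counts the codes for which the
    rank-sum winner is the *unique* W minimizer; ``optimum_count`` also
    admits ties.
    """

    maps: tuple[NucleotideMap, ...]
    W: pd.DataFrame
    ranks: pd.DataFrame
    scores: pd.Series
    tie_method: str

    @property
    def global_map(self) -> NucleotideMap:
        winners = self.global_ties
        return winners[0]

    @property
    def global_ties(self) -> list[NucleotideMap]:
        best = self.scores.min()
        labels = [m.label for m in self.maps]
        return [
            m for m in self.maps
            if self.scores[m.label] == best
        ] or [self.maps[int(np.argmin([self.scores[l] for l in labels]))]]

    def optimum_counts(self, nmap: NucleotideMap | None = None) -> tuple[int, int]:
        """(unique-minimizer count, ties-included count) for ``nmap``.

        Counts over the table's genetic codes how often ``nmap`` (default:
        the global rank-sum winner) attains the minimal W — uniquely, and
        including ties.
        """
        nmap = nmap or self.global_map
        unique = included = 0
        for code_id in self.W.columns:
            col = self.W[code_id]
            winners = col[col == col.min()]
            if nmap.label in winners.index:
                included += 1
                if len(winners) == 1:
                    unique += 1
        return unique, included


def suitability_scores(
    codes: Iterable[GeneticCode], tie_method: str = "average"
) -> SuitabilityTable:
    """Rank every map within every code by W and sum the ranks.

    ``tie_method`` is passed to :func:`scipy.stats.rankdata`; the neutral
    default gives tied W values their average rank, ``"min"`` gives
    competition ranks.
    """
    codes = list(codes)
    if not codes:
        raise CodonMapError("suitability_scores requires a non-empty code set")
    maps = enumerate_maps()
    labels = [m.label for m in maps]
    w = pd.DataFrame(
        {
            code.id: [
                weight_criterion_W(transformation_function(m, code)) for m in maps
            ]
            for code in codes
        },
        index=labels,
    )
    ranks = w.apply(lambda col: rankdata(col, method=tie_method), axis=0)
    ranks = pd.DataFrame(ranks, index=labels, columns=w.columns)
    scores = ranks.sum(axis=1)
    scores.name = "suitability_score"
    return SuitabilityTable(tuple(maps), w, ranks, scores, tie_method)


def global_optimal_map(
    codes: Iterable[GeneticCode], tie_method: str = "average"
) -> NucleotideMap:
    """Map with the minimal suitability score (ties: canonical-order first)."""
    return suitability_scores(codes, tie_method=tie_method).global_map
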