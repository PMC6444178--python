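"""Distortion metrics between codon and amino-acid signals.

Translation in numerical form loses information (64 codons, at most 20
amino acids), so a codon signal c[n] and the amino-acid signal a[n] of
the same CDS diverge.  Two measures quantify that divergence per
sequence:

* the Pearson correlation coefficient between c and a, and
* the percentage deviation
  ``D = 100/M * sum_n |c[n]/63 - a[n]/20|``,
  i.e. the mean absolute difference after normalizing each signal by its
  maximal possible value (63 and 20 — fixed constants, not per-code
  maxima).

Dataset-level evaluation reports mean +/- standard deviation of both
over a set of coding sequences, and codon-usage counting exposes the
bias that makes theoretically optimal maps imperfect on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SignalError
from .genetic_codes import GeneticCode
from .maps import NucleotideMap, Signal, encode_codons, encode_signal_pair

__all__ = [
    "DistortionReport",
    "CodonUsage",
    "pearson_corr",
    "percentage_deviation",
    "evaluate_map_on_dataset",
    "codon_usage",
]


def _paired(c, a) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    if c.shape != a.shape:
        raise SignalError(
            f"signal length mismatch: {c.shape[0]} vs {a.shape[0]}"
        )
    return c, a


def pearson_corr(c: Signal | np.ndarray, a: Signal | np.ndarray) -> float:
    """Pearson product-moment correlation between two equal-length signals."""
    c, a = _paired(c, a)
    if c.size < 2:
        raise SignalError("correlation requires signals of length >= 2")
    if np.ptp(c) == 0 or np.ptp(a) == 0:
        raise SignalError("undefined correlation: at least one signal is constant")
    return float(np.corrcoef(c, a)[0, 1])


def percentage_deviation(c: Signal | np.ndarray, a: Signal | np.ndarray) -> float:
    """Percentage deviation D between a codon and an amino-acid signal."""
    c, a = _paired(c, a)
    if c.size == 0:
        raise SignalError("percentage deviation requires non-empty signals")
    return float(np.mean(np.abs(c / 63.0 - a / 20.0)) * 100.0)


@dataclass(frozen=True)
class DistortionReport:
    """Per-sequence and dataset-level distortion metrics.

    ``per_sequence`` has one row per CDS with columns ``id``, ``M``
    (number of codons), ``corrcoef`` and ``D``.
    """

    per_sequence: pd.DataFrame
    nmap: NucleotideMap
    code_id: int

    @property
    def mean_corrcoef(self) -> float:
        return float(self.per_sequence["corrcoef"].mean())

    @property
    def std_corrcoef(self) -> float:
        return float(self.per_sequence["corrcoef"].std(ddof=0))

    @property
    def mean_D(self) -> float:
        return float(self.per_sequence["D"].mean())

    @property
    def std_D(self) -> float:
        return float(self.per_sequence["D"].std(ddof=0))

    def summary(self) -> str:
        """Two-line "mean +/- STD" summary (4 decimals for corrcoef, 2 for D)."""
        return (
            f"map {self.nmap.label}, genetic code {self.code_id}, "
            f"n={len(self.per_sequence)}\n"
            f"corrcoef: {self.mean_corrcoef:.4f} ± {self.std_corrcoef:.4f}\n"
            f"D: {self.mean_D:.2f} ± {self.std_D:.2f}"
        )


def evaluate_map_on_dataset(
    cds_set: dict[str, str],
    code: GeneticCode,
    nmap: NucleotideMap,
    strip_stops: bool = True,
) -> DistortionReport:
    """Per-sequence corrcoef and D plus dataset mean/STD for a CDS set.

    ``cds_set`` maps sequence identifiers to CDS strings.  A single
    trailing stop codon per CDS is stripped by default before the
    metrics are computed.
    """
    if not cds_set:
        raise SignalError("cannot evaluate distortion on an empty dataset")
    rows = []
    for seq_id, cds in cds_set.items():
        c, a = encode_signal_pair(nmap, code, cds, strip_stops=strip_stops)
        rows.append(
            {
                "id": seq_id,
                "M": len(c),
                "corrcoef": pearson_corr(c, a),
                "D": percentage_deviation(c, a),
            }
        )
    return DistortionReport(pd.DataFrame(rows), nmap, code.id)


@dataclass(frozen=True)
class CodonUsage:
    """Codon counts over a CDS set, indexed by codon index under a map."""

    counts: np.ndarray  # length 64
    nmap: NucleotideMap

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total
        return self.counts / total if total else np.zeros(64)

    def to_frame(self) -> pd.DataFrame:
        from .maps import index_to_codon

        return pd.DataFrame(
            {
                "codon": [index_to_codon(self.nmap, i) for i in range(64)],
                "index": np.arange(64),
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def codon_usage(cds_set: dict[str, str] | list[str], nmap: NucleotideMap) -> CodonUsage:
    """Count every codon index over all sequences of a CDS set."""
    sequences = list(cds_set.values()) if isinstance(cds_set, dict) else list(cds_set)
    counts = np.zeros(64, dtype=np.int64)
    for cds in sequences:
        signal = encode_codons(nmap, cds)
        counts += np.bincount(signal.values, minlength=64)
    return CodonUsage(counts, nmap)
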