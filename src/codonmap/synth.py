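"""Synthetic coding sequences with controlled codon-usage bias.

Real CDS datasets show codon-usage bias — unequal frequencies of the
synonymous codons of one amino acid — which is exactly what degrades a
theoretically optimal nucleotide map.  This module emulates that
phenomenon so the optimizer, distortion metrics and signal phylogenetics
can be exercised without any downloads:

* per-codon sampling weights drawn from a symmetric Dirichlet over the
  non-stop codons (small concentration = few dominant codons, large =
  near-uniform usage);
* i.i.d. CDS generation from those weights, stop-free internally, with
  an optional terminal stop;
* tree-structured families: a root CDS evolved down a rooted topology by
  Poisson-distributed codon replacements per branch (substitutions only,
  no indels, so all leaves keep the root's length).

Substitution operates at the codon level rather than per nucleotide so
sequences stay stop-free by construction; this is a deliberate departure
from biological realism in exchange for validity without rejection
sampling.  All randomness flows from an explicit seed; there is no
global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .exceptions import CodonMapError, SequenceError, TreeError
from .genetic_codes import CODON_ORDER, GeneticCode

__all__ = [
    "UsageWeights",
    "biased_usage_weights",
    "uniform_usage_weights",
    "generate_cds",
    "generate_family",
]


@dataclass(frozen=True)
class UsageWeights:
    """Per-codon sampling weights aligned to codon text in NCBI storage order.

    Stop codons of the generating code carry weight zero (they are never
    sampled at internal positions); the non-stop weights sum to one.
    """

    weights: np.ndarray  # length 64, aligned to CODON_ORDER
    code_id: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (64,):
            raise ValueError("usage weights must have 64 entries")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("usage weights must be finite and non-negative")
        if w.sum() <= 0:
            raise ValueError("at least one codon must have positive weight")
        object.__setattr__(self, "weights", w / w.sum())

    def weight_of(self, codon: str) -> float:
        return float(self.weights[CODON_ORDER.index(codon)])


def _nonstop_indices(code: GeneticCode) -> np.ndarray:
    return np.array(
        [i for i, c in enumerate(CODON_ORDER) if not code.is_stop(c)], dtype=int
    )


def uniform_usage_weights(code: GeneticCode) -> UsageWeights:
    """Equal weight on every non-stop codon of ``code``."""
    w = np.zeros(64)
    w[_nonstop_indices(code)] = 1.0
    return UsageWeights(w, code.id)


def biased_usage_weights(
    code: GeneticCode,
    concentration: float,
    seed: int | np.random.Generator = 0,
) -> UsageWeights:
    """Dirichlet-distributed codon usage over the non-stop codons.

    ``concentration`` is the symmetric Dirichlet parameter: values well
    below 1 give strongly biased usage with a few dominant codons (as in
    real mitochondrial data); large values approach uniform usage.
    """
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    nonstop = _nonstop_indices(code)
    w = np.zeros(64)
    w[nonstop] = rng.dirichlet(np.full(nonstop.size, concentration))
    return UsageWeights(w, code.id)


def generate_cds(
    code: GeneticCode,
    n_codons: int,
    weights: UsageWeights | None = None,
    seed: int | np.random.Generator = 0,
    with_terminal_stop: bool = False,
) -> str:
    """Sample a CDS of ``n_codons`` codons i.i.d. from usage weights.

    Stop codons never occur internally; with ``with_terminal_stop`` one
    stop codon of ``code`` (uniformly chosen) is appended.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    weights = weights or uniform_usage_weights(code)
    rng = np.random.default_rng(seed)
    sampled = rng.choice(64, size=n_codons, p=weights.weights)
    cds = "".join(CODON_ORDER[i] for i in sampled)
    if with_terminal_stop:
        stops = code.stop_codons
        if not stops:
            raise CodonMapError(
                f"genetic code {code.id} has no termination codons to append"
            )
        cds += stops[rng.integers(len(stops))]
    return cds


def generate_family(
    topology: TreeNode,
    root_cds: str,
    sub_rate_per_branch: float,
    seed: int | np.random.Generator = 0,
    code: GeneticCode | None = None,
    weights: UsageWeights | None = None,
) -> dict[str, str]:
    """Evolve a root CDS down a rooted topology; returns leaf-labelled CDS.

    Per branch the number of codon replacements is Poisson with mean
    ``sub_rate_per_branch * branch_length`` (a missing branch length
    counts as 1); replacement positions are uniform and replacement
    codons are drawn from ``weights`` (default: uniform non-stop usage
    of ``code``).  Lengths are preserved, so every leaf satisfies the
    strict encoder preconditions by construction.
    """
    if code is None and weights is None:
        raise CodonMapError("generate_family needs a genetic code or usage weights")
    if sub_rate_per_branch < 0:
        raise ValueError("substitution rate must be non-negative")
    root_cds = str(root_cds).upper().replace("U", "T")
    if len(root_cds) % 3 != 0 or not root_cds:
        raise SequenceError("root CDS length must be a positive multiple of 3")
    if any(b not in "ACGT" for b in root_cds):
        raise SequenceError("root CDS contains non-ACGT characters")
    if code is not None:
        internal = [root_cds[i : i + 3] for i in range(0, len(root_cds) - 3, 3)]
        if any(code.is_stop(c) for c in internal):
            raise SequenceError("root CDS contains internal stop codons")
    if weights is None:
        weights = uniform_usage_weights(code)
    rng = np.random.default_rng(seed)
    n_codons = len(root_cds) // 3

    leaves: dict[str, str] = {}

    def descend(node: TreeNode, cds: str) -> None:
        for child in node.children:
            length = child.length if child.length is not None else 1.0
            n_subs = rng.poisson(sub_rate_per_branch * length)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            for _ in range(n_subs):
                pos = rng.integers(n_codons)
                codons[pos] = CODON_ORDER[rng.choice(64, p=weights.weights)]
            child_cds = "".join(codons)
            if child.is_tip():
                if child.name is None:
                    raise TreeError("topology has an unlabeled leaf")
                if child.name in leaves:
                    raise TreeError(f"duplicate leaf label {child.name!r}")
                leaves[child.name] = child_cds
            else:
                descend(child, child_cds)

    descend(topology.root(), root_cds)
    if not leaves:
        raise TreeError("topology has no leaves")
    return leaves
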