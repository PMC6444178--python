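# Methods

## Numerical conversion

A nucleotide map is a bijection {A,C,G,T} → {0,1,2,3}, written
throughout as the value tuple in A,C,G,T order (`[1 0 3 2]` means A=1,
C=0, G=3, T=2). The codon index of a triplet b₁b₂b₃ is
16·m(b₁) + 4·m(b₂) + m(b₃), i.e. the mapped digits read as a quaternary
number, so the codon signal of a CDS has one value in 0–63 per triplet
and one third of the nucleotide length.

Amino-acid values are assigned by *first encounter*: walk codon indices
0…63 in ascending order; termination codons always take 0; each amino
acid not seen before takes the next counter value starting at 1;
repeats are skipped. A genetic code using k distinct amino acids thus
occupies exactly the values 1…k, with k ≤ 20 for every one of the 24
NCBI tables. The resulting length-64 vector from codon index
to amino-acid value is the transformation function; the amino-acid
signal is that function applied pointwise to the codon signal, so both
signals always have equal length M.

Input handling at every codon-accepting boundary: U→T and
case-folding; ambiguity codes raise an error by default, or in
permissive mode drop the affected codon from *both* signals so the pair
stays index-aligned; CDS length not divisible by 3 is a hard error
unless truncation is requested (dropping 1–2 trailing bases with a
warning). A single trailing stop codon can be stripped (`strip_stops`),
which is the default for dataset-level distortion evaluation since the
terminator carries no signal of interest; internal stops trigger a
frame-error warning but are kept as 0/0-paired values when stripping is
off.

## Genetic-code tables

The 24 currently valid NCBI translation tables (1–6, 9–14, 16, 21–31)
ship as a TSV resource (`id`, `name`, 64-character amino-acid string in
the T,C,A,G enumeration order). Only the basic tables are represented:
no alternative initiation codons or per-taxon special cases. Codes
whose NCBI entry marks codons as *conditional* stop/sense (27, 28, 31)
carry the primary amino-acid assignment, so they contain no `*` at all;
the first-encounter assignment and the segment scan tolerate this (the
scan simply never deletes anything). The file is user-overridable
(`--tables`), so new codes can be added without touching the package.
The packaged content matches Biopython's rendering of NCBI's data and
is cross-checked against it in the test suite.

## Degenerated segments and the W criterion

Stops are deleted from the transformation function before scanning —
they are pinned to 0 by convention regardless of position, and the
criterion explicitly excludes terminators — so a stop neither
contributes to nor splits a run. The remaining entries are scanned in
ascending codon-index order while tracking the prefix running maximum.
A *degenerated segment* is a maximal run of equal values strictly below
the running maximum at the run's start; its height H is measured
against that running maximum, not the immediately preceding value.
Only this reference reproduces the standard-code worked example for the
map `[2 1 3 0]`: arginine at AGA/AGG (value 10) directly follows serine
(value 3) but has H = 15 − 10 = 5, referenced to the lysine maximum.
W is the sum of L·H over segments; N is the segment count. The scan is
O(64) and verified against a brute-force prefix-maximum oracle on
random vectors.

Per-code optimization evaluates all 24 maps exhaustively. Ties for the
minimal W are all reported; the canonical enumeration order (ascending
A,C,G,T value tuple) selects the primary. Two codes (13 and 26) have
two tied W-minimal maps each; the printed primary is the
canonical-order first.

The global map minimizes the *suitability score*: within each code the
24 maps are ranked ascending by W (rank ties get their average rank by
default; competition ranks are available via `tie_method="min"` — the
winner is the same either way), and the score is the rank sum over
codes. Rank-sum aggregation deliberately discards the W scale, so a
code with huge W values cannot dominate the choice. The package also
reports, for the global winner, in how many codes it is the unique
per-code W minimizer and in how many it at least ties; with the
primary-assignment encoding of the conditional-stop codes both counts
are 14. These counts are computed, never hard-coded, because they are
sensitive to how conditional-stop tables are encoded.

## Distortion metrics

Percentage deviation D = 100/M · Σ |c[n]/63 − a[n]/20| uses the fixed
normalization constants 63 and 20 — the maximal *possible* value of
each representation — rather than per-code maxima, so D values are
comparable across codes. Pearson correlation is computed on the raw
signals (it is scale-free). Constant signals make the correlation
undefined and raise an error rather than returning NaN. Dataset
evaluation reports mean ± population standard deviation of both metrics
(4 decimals for corrcoef, 2 for D).

## Signal phylogenetics

The distance between two equal-length amino-acid signals is the
proportional deviation d = 1/M · Σ |a₁[n]/20 − a₂[n]/20| (a true metric;
no alignment is attempted — unequal lengths are an error instructing
the user to pre-align). Trees are built with Saitou–Nei
neighbor-joining via scikit-bio, negative branch lengths clamped to
zero. Rooting is by explicit outgroup only; there is no silent midpoint
default, and rooted tree comparison without a bifurcating root is an
error.

Robinson–Foulds distances are normalized to [0,1]: rooted mode compares
the sets of non-trivial clades and divides the symmetric difference by
2(n−2), unrooted mode compares bipartitions and divides by 2(n−3) —
the maxima for fully resolved binary trees with n leaves. For
multifurcating inputs the value can therefore stay below 1 even for
disjoint split sets; this convention was chosen over per-tree-resolution
denominators for comparability.

The bootstrap resamples amino-acid signal *columns* (codon-level
positions) with replacement, applying the same column choice to every
taxon per replicate, then rebuilds the distance matrix and NJ tree.
Support of an internal edge of the full-data tree is the percentage of
replicates whose tree contains the same clade (rooted) or bipartition
(unrooted), written as integer-percent internal node labels in Newick
output. A single seeded `numpy` generator drives each run, so results
are reproducible from the CLI seed. Signal bootstraps are noisier than
symbolic ones, so on the order of 1000 replicates is the sensible
default.

## Synthetic data

The generator emulates two features of real CDS collections:

- **codon-usage bias**: per-codon sampling weights drawn from a
  symmetric Dirichlet over the non-stop codons. The concentration
  parameter is the knob: 0.1 gives a few dominant codons (like the CTA
  excess in vertebrate mitochondrial data), 1 is moderate bias, values
  ≫ 1 approach uniform usage. Sequences are i.i.d. codon draws, stop
  codons excluded internally, optional terminal stop appended.
- **tree-structured families**: a root CDS evolves down a rooted
  topology; per branch the number of codon replacements is Poisson with
  mean rate × branch length, positions uniform, replacement codons
  drawn from the usage weights. Substitution acts at the codon level —
  not per nucleotide — so sequences remain stop-free and equal-length
  by construction (no indels, no rejection sampling). This is a
  deliberate simplification: there is no transition/transversion
  structure, no selection, no rate heterogeneity.

Consequently, passing tests demonstrate correctness of the machinery
and the W↔distortion relationship under uniform or Dirichlet usage;
they do not certify performance on real data, where codon bias is
structured by amino acid and by gene. Default sizes used in tests and
examples — 50 sequences of 148 codons (444 nt) — mirror the scale of a
typical single-gene comparative dataset (e.g. mammalian beta-globin
CDS). Family-recovery tests use a balanced 8-leaf topology with
moderate rates chosen so that the task is non-trivial but solvable
(~8 expected substitutions per unit branch on 148 codons).

## Numerical and design notes

- All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; there is no global random state.
- The map keyword `original` is pinned to `[2 1 3 0]` (T=0, C=1, A=2,
  G=3), the classical assignment the optimization improves on;
  `global` is resolved by recomputing the rank-sum optimum over the
  loaded tables, which keeps user-supplied table files honest.
- Degenerate inputs: the all-zero distance matrix yields a star tree
  with a warning; a genetic code without stop codons is handled
  throughout (nothing is deleted before the segment scan, and
  requesting a terminal stop from such a code is an error).
- User-facing positions are 1-based; internal indices 0-based; codon n
  covers nucleotides 3n+1…3n+3 (1-based).

## Known limitations

- The W criterion assumes uniform codon usage; on strongly biased real
  data the W-optimal map need not minimize observed distortion. The
  package exposes codon-usage counts so users can see when this bites,
  but deliberately does not define a usage-weighted criterion.
- Translation-table special cases (alternative starts, conditional
  stop semantics) are out of scope; for the conditional-stop nuclear
  codes the primary amino-acid reading is a modelling choice that
  affects their W tables.
- No sequence alignment: signal distances require equal-length,
  colinear CDS.
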