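# codonmap

Degeneration-aware integer maps for genomic signal processing, covering
all 24 NCBI genetic codes.

## The problem

Genomic signal processing starts by replacing the four nucleotides with
the integers 0–3. Reading the three mapped digits of a codon as a
quaternary number gives a codon signal c[n] ∈ 0–63, and numerical
translation gives an amino-acid signal a[n] ∈ 0–20 (1–20 for amino
acids by first-encounter assignment along ascending codon index, 0 for
termination codons). Because the genetic code is degenerate — up to six
codons per amino acid — the length-64 *transformation function* from
codon index to amino-acid value cannot be monotone, and every
non-monotony distorts the amino-acid signal relative to the codon
signal. Which of the 4! = 24 possible nucleotide→integer assignments
minimizes that distortion depends on the genetic code.

`codonmap` quantifies the damage done by each map and picks the best
one. A *degenerated segment* is a maximal run of consecutive codon
indices (stops removed) whose shared amino-acid value lies strictly
below the running maximum of the transformation function; it has length
*L*, height *H* (drop below the running maximum) and weight *w = L·H*.
Two criteria follow:

- **N** — the number of degenerated segments (the older, coarser criterion);
- **W = Σ w** — the total degeneration weight, which also penalizes how
  far and how broadly the function drops.

The per-code optimal map minimizes W over the 24 candidates. Across
codes, each map is ranked by W within every code; the map with the
minimal rank sum (*suitability score*) is the **global optimal map**,
A = 1, C = 0, G = 3, T = 2 — written `[1 0 3 2]` in A,C,G,T order. The
package derives this from the tables at run time rather than assuming it.

On top of the optimizer the package provides:

- **distortion metrics** between the codon and amino-acid signal of a
  CDS: Pearson correlation and the percentage deviation
  D = 100/M · Σₙ |c[n]/63 − a[n]/20|, plus codon-usage counting;
- **signal phylogenetics**: proportional deviation
  d = 1/M · Σₙ |a₁[n]/20 − a₂[n]/20| between equal-length amino-acid
  signals, neighbor-joining trees, normalized Robinson–Foulds
  comparison (rooted and unrooted) and column-bootstrap supports;
- **synthetic data**: CDS sets with Dirichlet-controlled codon-usage
  bias and tree-structured sequence families, so everything is testable
  without downloads.

It is aimed at people building signal-based sequence analyses
(comparative genomics, motif and period detection, alignment-free
phylogenetics) who need a defensible integer encoding for coding
sequences under any NCBI translation table.

## Worked example

The standard genetic code (table 1), scanned exhaustively over all 24
maps:

```text
$ codonmap optimal --code 1
code    map        W   N  segments(aa:L:H:w)
1       [1 0 3 2]  33  7  H:1:1:1;N:1:1:1;R:1:6:6;R:1:6:6;L:1:9:9;L:1:9:9;D:1:1:1
```

The W-minimal map for the standard code is `[1 0 3 2]` with W = 33: its
worst defects are two single-codon leucine dips of height 9 and two
single-codon arginine dips of height 6. For comparison, the classical
map T=0, C=1, A=2, G=3 (`--map original`, i.e. `[2 1 3 0]`) has only
three degenerated segments — leucine (L=4, H=4, w=16), serine (L=2,
H=12, w=24) and arginine (L=2, H=5, w=10) — but their total weight
W = 50 is much worse.

```text
$ codonmap optimal --global
global optimal map                      [1 0 3 2]
suitability score                       58.5
unique per-code optimum for             14 codes
per-code optimum (ties included) for    14 codes
```

Summing W-ranks over all 24 genetic codes selects `[1 0 3 2]` globally;
it is also the unique per-code W minimizer for 14 of the 24 codes. For
codes with a different optimum the specialized map is reported instead,
e.g. the vertebrate mitochondrial code:

```text
$ codonmap optimal --code 2
code    map        W   N  segments(aa:L:H:w)
2       [3 1 0 2]  20  8  E:1:1:1;Q:1:1:1;W:1:1:1;L:1:5:5;L:1:6:6;S:2:2:4;M:1:1:1;K:1:1:1
```

Library use mirrors the CLI:

```python
from codonmap import (load_genetic_code, ORIGINAL_MAP, transformation_function,
                      weight_criterion_W, optimal_map_for_code)

code1 = load_genetic_code(1)
weight_criterion_W(transformation_function(ORIGINAL_MAP, code1))  # 50
best, ties = optimal_map_for_code(code1)
best.nmap.label, best.W                                           # ('[1 0 3 2]', 33)
```

Other subcommands: `codes` (list tables), `encode` (signal TSV),
`distort` (corrcoef and D per dataset), `usage` (codon counts),
`phylo` (NJ tree, optional bootstrap and reference-tree RF),
`simulate cds` / `simulate family` (synthetic data). See
`codonmap --help`.

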