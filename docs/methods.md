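# Methods

## Clone identity and deterministic ordering

A clone is identified by its CDR3β sequence at one of four levels: the
nucleotide sequence (`nt`, the default for clonality/D50/homeostasis), the
amino-acid sequence (`aa`, the default for overlap and cross-site
tracking), or either sequence together with the TRBV and TRBJ gene labels
(`nt_vj`, `aa_vj`). Nucleotide identity is the stricter notion (synonymous
rearrangements stay separate), which is the right granularity for counting
distinct rearrangement events; amino-acid identity is the right granularity
for asking whether two tissues contain the *same receptor*, since exact
peptide identity is what antigen recognition sees. Both are exposed as
parameters because clone-table vendors differ in which keys they collapse
on.

Gene-allele suffixes (`*01`) and aligner score annotations are stripped on
ingest, so usage is always aggregated at gene level.

Every repertoire is stored in a fixed deterministic order — reads
descending, ties broken by the lexicographically smallest CDR3β nucleotide
sequence — fixed once at ingest. All ranked statistics (D50, homeostasis
bins, top-N proportions, clone ranks) inherit this order, so results are
bit-reproducible and rank ties cannot silently reorder across runs.
Read counts are raw sequencing reads; zero or missing counts are rejected
by default (a lenient mode imputes 1 for presence-only tables).

## D50 diversity index

Clones are ranked by reads descending. With *U* unique sequences:

- *U* ≥ 10,000 — restrict to the top 10,000 clones, let *T* be their
  summed reads, find the smallest rank *r* with cumulative reads ≥ *T*/2,
  and report `r · 100 / 10,000`.
- *U* < 10,000 — *T* is the total read count and the result is
  `r · 100 / U`.

Interpretation choices, both configurable and logged per sample:

- "where 50% falls" is read as the smallest rank whose cumulative count
  *reaches at least* half the reference total; no interpolation, since the
  rank in the formula is integral.
- In the large-sample branch the 50% reference total is computed within
  the top-10,000 truncation (`reference_total="top10k"`). Computing it
  against all reads instead is available (`"all"`); the two differ only
  when appreciable read mass lies beyond rank 10,000.
- *U* = 10,000 exactly uses the large-sample branch.

Useful consequences, all tested: a perfectly even repertoire with
*U* < 10,000 gives `ceil(U/2)·100/U` ≈ 50; D50 is invariant to scaling all
read counts by a positive integer; adding reads to the most abundant clone
never increases it. The branch applied is recorded in every result because
values from different branches are not on the same footing (one divides by
10,000, the other by *U*).

## Clonal-space homeostasis

Read mass is partitioned over fixed clone-rank bins — ranks 1–10, 11–35,
36–535, 536–3,535, 3,536–13,535, 13,536–113,535 (the top 10 clones, next
25, 500, 3,000, 10,000, 100,000). Proportions are fractions of the
repertoire's total reads; for repertoires with at most 113,535 unique
clones they sum to 1, and any mass beyond the last bin is reported
separately as a remainder.

## Normalized overlap index

For two repertoires with total reads R₁ and R₂, the index is the number of
exactly shared CDR3β amino-acid sequences divided by R₁ × R₂. The
denominator is the product of *read* counts, exactly as the formula is
stated, even though this yields very small values (~10⁻⁷ at typical
depths); a reporting multiplier (default 1) affects display only. A
variant dividing by the product of unique clone counts — the convention of
some repertoire packages — is available by name, never silently. Overlap
is symmetric, and self-overlap is permitted (it equals the unique-clone
count over the squared depth, not 1).

## Gene usage and PCA

Usage frequencies are per-gene fractions of read mass (default) or of
unique clones; the weighting is a parameter because published figures
rarely state which was used. Matrices are dense over the union of observed
genes with numeric-aware label ordering (TRBV2 before TRBV12-1).

PCA runs on column-centered but *not* variance-scaled frequencies:
frequencies already share a scale, and unit-scaling would inflate rare
genes' noise. A deterministic sign convention (the largest-magnitude
loading of each component is positive) removes the sign ambiguity of SVD.

Per-gene group comparisons use two-sample t-tests with Šidák family-wise
adjustment `1 − (1 − p)^m` over the m genes tested, mirroring the
multiple-comparison convention of repertoire figure panels without
committing to a figure-specific ANOVA layout; a full two-factor ANOVA
(Type II sums of squares) is available in the stats module.

## Cross-site clone tracking

The top-N (default 10) clones of the joint repertoire are mapped to their
dense ranks in the paired lymph-node repertoire and summarized with
Spearman's rank correlation. Orientation is fixed (joint → pLN). A joint
clone absent from the lymph node is, by default, censored to rank
U_pLN + 1 — just beyond the repertoire — so every top clone enters the
correlation; dropping absent clones is available for sensitivity. The
D'Agostino–Pearson normality statistic is reported alongside as an
informational gate (it needs ≥ 8 pairs) and never switches the estimator:
one reproducible code path.

## Synthetic cohort generator

Each repertoire is a fixed probability vector over a clone universe:
`n_expanded` dominant clones carrying a total probability `expanded_mass`,
and `n_background` clones with Zipf weights k^(−tail_exponent) carrying
the rest. Reads are drawn multinomially at the configured depth; clones
sampling zero reads drop out, as in real sequencing. CDR3β nucleotide
sequences are random in-frame codon strings (27–45 nt), unique at both
nucleotide and amino-acid level within a generating context; V/J labels
are drawn per clone from categorical profiles. Expanded-clone
probabilities decay geometrically (ratio `expanded_decay`, default 0.85;
1.0 gives a uniform split). The geometric grading is what makes the
within-top ranking of expanded clones stable, so that paired samples can
exhibit the rank concordance the cross-site analysis measures; a uniform
split would make within-top ranks exchangeable and the designed late-phase
concordance unrealizable.

Paired samples realize a designed number of shared amino-acid sequences
exactly at the universe level before sampling. The `late` rule takes the
joint's expanded clones from the lymph node's most abundant clones in
matching order; the `early`/`control` rules make a fraction (default 0.5)
of them de novo and draw the rest at random from the lymph node's top 500
clones, which decorrelates the cross-site ranks. Remaining shared slots
are filled from the lymph node's next most abundant clones so that
designed sharing survives sampling dropout in practice.

### Default study design

Three arms, 5 subjects each, paired pLN/joint at depth 50,000 reads.
`expanded_mass` / `n_background` / `tail_exponent` per sample:

| arm            | pLN                 | joint               | sharing | rule    |
|----------------|---------------------|---------------------|---------|---------|
| early inflamed | 0.18 / 4,200 / 0.6  | 0.44 / 4,500 / 0.6  | 400     | early   |
| late inflamed  | 0.02 / 12,000 / 0.4 | 0.44 / 4,500 / 0.6  | 100     | late    |
| control (IFA)  | 0.02 / 12,000 / 0.4 | 0.29 / 4,500 / 0.6  | 60      | control |

Rationale: early lymph nodes have ~4,200 clones with the top 10 carrying
~18% of reads; late lymph nodes have a much larger, flatter clone pool
(top 10 ≈ 2%, crossing into the D50 large-sample branch) and a broadened,
shifted TRBV profile; joints are dominated by ~10 clones with a *fixed*
high expanded mass (0.44) at both phases, so phase differences in joint
diversity reflect noise only; adjuvant-only control lymph nodes share the
late-inflamed design exactly (inflammation without antigen), while control
joints carry only 29% in their top clones. Cross-site amino-acid sharing
is higher early (400) than late (100). Per-subject biological variation is
a ±5% uniform jitter on expanded mass and background pool size. A master
seed expands to per-subject seeds as `(master · 100003 + k) mod 2³¹`,
recorded in the manifest so any sample is regenerable alone.

### What the generator does and does not emulate

It reproduces heavy-tailed clone-size distributions, sampling depth and
dropout, paired-tissue sharing, and group-level usage shifts. It does not
model V(D)J recombination statistics, sequencing error, PCR amplification
bias, UMI deduplication, or convergent recombination beyond chance
synonymy. Passing end-to-end tests therefore demonstrates that the
*analysis* recovers designed population structure from multinomial
samples — not that it is robust to upstream artefacts, which enter this
package already baked into clone tables.

## Numerical and degenerate-input choices

- Clone-rank ties: lexicographic CDR3β nucleotide tie-break everywhere.
- Median clone frequency uses the lower median, so data-driven read
  thresholds are achievable integer counts.
- t-tests with zero variance in both groups return t = 0, p = 1 for equal
  means and an explicitly flagged infinite statistic with p = 0 otherwise,
  instead of NaN.
- Two-way ANOVA uses Type II sums of squares (unbalanced animal groups);
  with a constant response all effects are exactly null; without cell
  replication the interaction is dropped and noted.
- Empty repertoires: clonality is 0; D50, homeostasis and overlap are
  errors (undefined), never silent zeros.
- Spearman correlations with fewer than 3 usable pairs or constant paired
  ranks are reported as undefined with a reason, never as 0.

## Problem sizes in the test suite

Unit and property tests run on repertoires of up to 15,000 clones (D50
oracle equivalence over 1,000 random repertoires against an independent
brute-force cumulative-sum implementation) and 500–1,000 randomized trials
per invariant. Simulator-recovery checks use 50 seeds at depth 100,000;
the end-to-end cohort check uses the full default design (30 samples at
depth 50,000); pipeline unit tests use a scaled-down cohort (depth 4,000,
~400-clone pools) that preserves every qualitative contrast.

## Known limitations

- Exact-match identity only: no fuzzy/hamming clone matching, no clonal
  lineage inference.
- No abundance-weighted overlap statistics (Morisita–Horn, Jaccard) and no
  Shannon/Simpson/Chao1 or rarefaction-based diversity — the D50 and the
  normalized overlap index are the implemented measures.
- Single β-chain analysis; no paired αβ chains or single-cell barcodes.
- The D50 large-sample branch divides by a fixed 10,000, so values are not
  comparable across the branch boundary; the branch label should always be
  reported alongside the value.
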