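# clonotrace

Analysis of TCRβ (CDR3β) clonotype repertoires for studies that follow
clonal T-cell responses across paired tissues and disease phases — for
example antigen-experienced CD4 T cells sampled from inflamed joints and
their draining popliteal lymph nodes (pLNs) in models of inflammatory
arthritis.

The package consumes clone tables (AIRR Rearrangement TSV or MiXCR-style
tables), not raw reads, and computes:

- **Clonality** — the number of unique CDR3β sequences in a repertoire
  (a richness count), at a configurable identity level (nucleotide,
  amino acid, optionally with TRBV/TRBJ genes).
- **D50 diversity index** — the percentage of ranked clones needed to
  accumulate 50% of reads. With *U* unique sequences and clones ranked by
  reads descending:

  - *U* ≥ 10,000: `D50 = r · 100 / 10,000`, where *r* is the smallest rank
    whose cumulative reads reach half the summed reads of the top 10,000
    clones;
  - *U* < 10,000: `D50 = r · 100 / U` against half of all reads.

  Low D50 ⇒ domination by few expanded clones; an even repertoire ⇒ ≈ 50.
- **Clonal-space homeostasis** — read-mass fractions of the fixed rank
  bins: top 10 clones, next 25, 500, 3,000, 10,000, 100,000.
- **Normalized overlap index** — for repertoires with total reads R₁, R₂:
  `|exactly shared CDR3β amino-acid sequences| / (R₁ × R₂)`, with an
  optional display scale.
- **TRBV/TRBJ usage** — per-sample gene frequency matrices (read- or
  clone-weighted), PCA on centered V-usage frequencies, and per-gene group
  comparisons with Šidák family-wise correction.
- **Cross-site clone tracking** — dense ranks of the joint's top-N clones
  inside the paired pLN repertoire, Spearman rank correlation (with a
  D'Agostino–Pearson normality note), and presence/absence tables.
- **Group statistics** — unpaired Student's t, Welch's t, and two-way
  ANOVA (Type II sums of squares).
- **Synthetic cohorts** — a generator for paired pLN/joint repertoires
  (expanded clones + Zipf background, multinomial read sampling, exact
  designed amino-acid sharing between paired samples) so every stage of
  the pipeline can be validated end to end without sequencing data.

## Worked example

```python
import clonotrace as ct

# simulate one paired sample: a late-phase animal whose joint's expanded
# clones are drawn from its lymph node's most abundant clones
pln_spec   = ct.RepertoireSpec(n_expanded=10, expanded_mass=0.02,
                               n_background=12_000, tail_exponent=0.4,
                               depth=50_000)
joint_spec = ct.RepertoireSpec(n_expanded=10, expanded_mass=0.44,
                               n_background=4_500, tail_exponent=0.6,
                               depth=50_000)
pln, joint = ct.generate_paired_sample("late", pln_spec, joint_spec,
                                       sharing=100, seed=7,
                                       subject_id="m1", phase="late",
                                       condition="inflamed")

print(ct.d50(pln))
print(ct.d50(joint))
print(ct.top_n_proportion(joint, 10))
print(ct.normalized_overlap(pln, joint))
print(ct.cross_site_ranks(joint, pln).rho)
```

prints

```
DiversityResult(sample_id='m1_pLN', clonality=11555, d50=27.38, branch='ge10k')
DiversityResult(sample_id='m1_joint', clonality=4379, d50=0.890614295501256, branch='lt10k')
0.43866
4e-08
0.9757575757575757
```

The lymph node is large and even (11,555 unique CDR3β sequences, D50 ≈ 27,
computed on the ≥10k branch), the joint is dominated by 10 clones carrying
44% of reads (D50 ≈ 0.9), 100 amino-acid sequences are shared
(100 / 50,000² = 4×10⁻⁸), and the joint's top-10 clones sit in the lymph
node's ranking in nearly the same order (Spearman ρ ≈ 0.98).

The same analyses run from the shell:

```bash
clonotrace simulate --seed 1 --out data/
clonotrace run --manifest data/manifest.tsv --out results/
```

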