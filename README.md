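# ighrep — mouse immunoglobulin heavy-chain repertoire analysis

`ighrep` analyses the IGHV-D-J rearrangements of B-cell clones sequenced
colony-by-colony from mice, the way chronic lymphocytic leukemia /
small lymphocytic lymphoma (CLL/SLL) mouse-model cohorts are characterised.
It is aimed at immunogenetics groups who sequence a handful of colonies per
tissue sample and need the full downstream accounting: germline gene
assignment, mutation-status calling that is robust to strain background,
HCDR3 physicochemistry, clonality, stereotypy, and usage-bias statistics.

## What it computes

* **V(D)J assignment** — overlap (free end-gap) alignment of each clone
  against a germline reference; the V and J boundaries are delimited at the
  maximum-cumulative-score column so junction nucleotides never contaminate
  the V identity. The D call is the reference gene with the longest exact
  run (≥ 5 nt) inside the junction. Isotype is called from the
  constant-region reverse-primer footprint; the HCDR3 is anchored on the
  conserved V 2nd-CYS and the J-TRP of the W-G-x-G motif and reported
  anchor-stripped.
* **SSP vs SHM discrimination** — in an F1 hybrid whose strain germlines are
  missing from the reference database, inherited strain-specific
  polymorphisms (SSP) masquerade as somatic hypermutation (SHM). Because
  SHM deposits any of the four nucleotides essentially at random, a mismatch
  of the *same* nucleotide at the *same* V position recurring in a strict
  majority of the clones of a gene (n ≥ 3) and in ≥ 2 distinct mice is
  called a polymorphism; the rest is SHM. A clone is unmutated (UM) when
  the corrected divergence is ≤ 2 % (≥ 98 % germline identity), mutated (M)
  otherwise.
* **HCDR3 features** — length, composition, and isoelectric point under the
  Bjellqvist charge model (residue-specific N-terminal pKa, C-terminal
  Asp/Glu adjustments), solved by bisection of the net-charge function.
* **Clonotype accounting and stereotypy** — identical clones found in
  several tissues of one mouse, or in a parental mouse and its
  allotransplanted F1 recipient, are counted once; stereotyped HCDR3 are
  identical sequences shared by ≥ 2 mice.
* **Usage statistics** — frequency tables of gene/subgroup usage; Pearson
  chi-square and likelihood-ratio tests with seeded Monte Carlo correction;
  one-sample proportion tests against background rearrangement frequencies;
  two-sample t-tests for HCDR3 length and pI.
* **Synthetic repertoires** — a ground-truthed generator (strain germline
  derivation, junction trimming and N-addition, UM/M founder mixture,
  genotype-dependent Dirichlet clonal expansion, planted stereotypes and F1
  transplants) so every stage is testable without external data.

## Worked example

The packaged expanded-clone table (per-tissue clone observations from ten
leukemic double-transgenic mice plus three allotransplanted recipients) runs
through dedup, features, stereotypy and usage in one command:

```bash
python analysis/01_expanded_clone_accounting.py
```

```
27 per-tissue observations -> 20 canonical expanded clones
mutation status: 85% UM / 15% M
stereotype ASGYDYAMDY: 2 mice
stereotype GRDDGYYYAMDY: 3 mice
stereotyped clones: 25% of the canonical set
HCDR3 length 11.6 +/- 2.9 AA; pI 4.54 +/- 1.31 (n = 20)
VH7183.a47.76: 5/20 (25%) vs 1.86% background, z = 7.66, p = 1.9e-14
VHJ558.b9: 3/20 (15%) vs 1.18% background, z = 5.72, p = 1e-08
VHSM7.a2psi.88: 3/20 (15%) vs 0.1% background, z = 21.08, p = 1.2e-98
```

Reading: collapsing cross-tissue and transplant duplicates leaves 20
canonical expanded leukemic clones, 85 % of them germline-unmutated. Two
HCDR3 amino-acid sequences recur in unrelated mice (2 and 3 mice), so a
quarter of the clones are stereotyped. The HCDR3 are short and strongly
acidic (mean pI 4.54), and three V genes that rearrange at ≤ 2 % frequency
in normal mice carry 25 %, 15 % and 15 % of the leukemic clones — a heavily
biased gene usage.

`analysis/02_synthetic_recovery.py` simulates a four-genotype cohort with
planted ground truth and inverts it (on the default conditions: 77/77
correct V/D/J calls, SSP precision 1.00 / recall 0.98, UM/M accuracy 0.97),
and `analysis/03_usage_statistics.py` exercises the cross-genotype
chi-square/likelihood-ratio machinery on synthetic data. The same stages
are available as CLI subcommands (`ighrep simulate | annotate | shm |
features | stereotypy | stats | run`).

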