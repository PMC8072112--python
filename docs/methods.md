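# Methods

## The problem

Colony-level Sanger sequencing of IGHV-D-J rearrangements from mouse
CLL/SLL cohorts yields 5–15 colonies per tissue sample. Three things make
the downstream analysis non-trivial: (i) the mice are F1 hybrids
(FVB/N × BALB/c-style backgrounds) whose germline IGHV alleles are poorly
represented in reference databases, so naive germline comparison
over-counts mutations; (ii) the same clone is observed repeatedly — across
colonies, across tissues of one mouse, and across allotransplanted
recipients — so frequency statistics need a canonical clonotype unit; and
(iii) the claims of interest (biased gene usage, stereotypy, acidic HCDR3)
are statements about small-n frequency tables. `ighrep` implements each
stage with explicit, testable rules.

## V(D)J assignment

Each clone is aligned to every reference V with an overlap (free end-gap)
pairwise alignment (match +1, mismatch −1, gap open −4, extend −1; Biopython
`PairwiseAligner`). Free end gaps are required because RT-PCR amplicons
primed with a degenerate FR1 primer start inside the V segment. Since the
V 3′ end is trimmed during recombination, an end-gap-free alignment drags
the reference's trailing residues over N-region nucleotides, where they pair
at chance identity; we therefore delimit the aligned V region at the column
maximising the cumulative per-column score from the 5′ side (ties resolved
rightward). The J segment, anchored on its 3′ side, is truncated
symmetrically from the right. This mirrors how interactive annotation
tools delimit segment boundaries, and without it both the mutation count
and the junction are systematically contaminated.

The winning V is the highest alignment score, ties broken by higher
identity then lexicographic name; calls with identity < 60 % or fewer than
60 aligned columns are flagged failed and excluded downstream (both
thresholds are config knobs). The D call is the reference D with the
longest exact contiguous run inside the junction between the V end and the
J start; 5 nt is the conventional minimum to avoid chance calls and is
configurable. The HCDR3 frame is frame 1 of the reference V mapped through
the alignment: the 2nd-CYS is the codon aligned to the reference's final
Cys, the junction ends at the first in-frame W-G-x-G tryptophan, and the
reported HCDR3 strips both anchors (the printed convention of the packaged
clone table). A junction with a stop codon is nonproductive; a frameshift
(no in-frame W-G-x-G) is nonproductive with no HCDR3. Isotype is assigned
from exact IUPAC matches of the three constant-region reverse-primer
footprints (CHµ/CHγ/CHα); ties and misses give "unknown".

## SSP vs SHM

Clones are pooled by V call across all genotypes and mice. In groups of
≥ 3 clones, a (position, substituted-nucleotide) mismatch observed in a
strict majority of clones (> 0.5, exclusive) **and** in ≥ 2 distinct mice is
called a strain-specific polymorphism; requiring the same substituted base
— not merely the same position — is the point of the criterion, since
hypermutation chooses among the three alternative bases at random. Both
cutoffs are configurable; the strict-majority/two-mouse default is our
operationalisation of "conserved in most individuals". Clones in groups of
< 3 are classified from uncorrected counts and flagged `ssp_uncorrected`.

`shm_percent` = 100 × (raw mismatches − SSP-matched mismatches) / aligned V
columns, reported to two decimals; the aligned-columns denominator (rather
than the full reference length) is what makes one residual mismatch on a
286-nt alignment equal 0.35 %. Status is UM iff shm_percent ≤ 2.0
(boundary inclusive, i.e. ≥ 98 % identity).

## Isoelectric point

The Bjellqvist model as used by the ExPASy Compute pI/Mw tool: net charge
at a given pH is the sum of Henderson–Hasselbalch occupancies over the
N-terminus (pKa 7.50, residue-specific for A 7.59, M 7.00, S 6.93, P 8.36,
T 6.82, V 7.44, E 7.70), side chains R 12.00, K 10.00, H 5.98 (positive)
and D 4.05, E 4.45, C 9.00, Y 10.00 (negative; C-terminal D 4.55, E 4.75),
plus the C-terminus at 3.55. The pI is found by bisection on [0, 14],
iterated to ~4 × 10⁻¹⁸ pH resolution so exact-midpoint roots round
deterministically, then rounded half-up to two decimals. Biopython's
isoelectric-point routine uses a different pKa set and does not reproduce
the published per-peptide values, so the implementation here is first-class
and is tested against an independent fine-grid scan of the same charge
function and against seventeen published HCDR3 pI values.

## Clonotype accounting, expansion, stereotypy

The canonical clone is one entry per (parental mouse, HCDR3) pair:
cross-tissue duplicates collapse, and allotransplanted F1 observations are
attributed to the donor mouse (an F1 record without a parental ID is an
error). A clone is *expanded* if in some sample it reached ≥ 2 colonies
and ≥ 20 % of the sample — our operationalisation of the reported expanded
clones, whose smallest printed fraction is 22.2 %; both thresholds are
knobs. Stereotypes are groups of identical anchor-stripped HCDR3 spanning
≥ 2 distinct parental mice; an optional Hamming-distance ≤ 1 mode (off by
default) merges near-identical sequences of equal length. The similarity
search against an annotated HCDR3 set uses a global alignment (identity +1,
BLOSUM62-positive +0.5, gap −1) and reports 100 × identities / columns,
with a 75 % default reporting cutoff; global alignment is appropriate
because queries are 6–17 residues, where BLAST-style heuristics are
meaningless.

## Statistics

Pearson X² and the likelihood-ratio G (0·ln 0 ≡ 0) are computed with
asymptotic chi-square p-values on (r−1)(c−1) df. The Monte Carlo
correction resamples cell counts multinomially under the independence model
with the grand total fixed, scores each simulated table against expected
counts rebuilt from its own margins (the plug-in statistic — scoring
against fixed expectations would inflate the null to rc−1 df), and reports
(1 + #{statistic ≥ observed}) / (reps + 1) with a recorded seed. The
proportion test is the SPSS-style normal-approximation z-test with an exact
binomial option; the t-test is pooled by default with a Welch flag, with
the p = 1 convention for two zero-variance samples with equal means.
Summary features report sample SD (n−1), one decimal for length, two
for pI.

## Synthetic cohorts

The generator's defaults are the study conditions. A base reference pool
(6 V of 294 nt, 4 D of 12–16 nt, 4 J of 42–60 nt) is built with realistic
anchors: a FR1 leader matching the degenerate V primer, a Y-Y-C 2nd-CYS
9 nt before the V end with two CDR3-opening codons after it, and a
W-G-x-G motif in each J. One *strain* germline is derived from it by
substituting Binomial(294, 0.0254) positions per V gene — 2.54 % being the
average reported strain divergence of mouse IGHV — and is shared by every
simulated mouse, which is exactly what makes SSPs conserved across
individuals. Clones are V[: −t₁] + N₁ + D[t₂ : −t₃] + N₂ + J[t₄ :] with
trims ≤ 4 nt and inserts ≤ 6 nt, the N₂ length adjusted so the J
tryptophan sits in the V frame, and junction nucleotides resampled until
the junction is stop-free with its first W-G-x-G at the planted position.
Founders are mutated with probability 0.15 (matching the observed 15 % M
fraction); SHM rates are drawn uniformly from 0–2 % (UM) or 2–5 % (M) and
substitutions land uniformly on the trimmed V, never on an SSP site (the
truth channel keeps the two position sets disjoint). Per sample, 5–15
colonies are split across 3–7 founders by a Dirichlet whose concentration
is 0.1 for double-transgenic (+/+) mice — mono/oligoclonal dominance — and
20 otherwise (polyclonal); identical colonies collapse into one record with
a colony count. Optional planted stereotypes share one unmutated founder
across several +/+ mice, and optional F1 recipients re-expand the parental
dominant clone. Everything derives from one `numpy` generator seed;
identical configurations are byte-identical.

What the generator does **not** emulate: AID hotspot motifs (substitutions
are uniform — the SSP criterion only relies on SHM randomness across
clones, which uniformity satisfies), indel SHM, class switching (all clones
carry an IgM constant-region stub), lineage structure within a clone, and
sequencing error. Passing recovery tests therefore show the pipeline
inverts its stated generative model at the stated rates, not that it is
robust to hotspot-clustered mutations or indels on real chromatograms.

## Problem sizes and numerical choices

Test and analysis cohorts use 4–5 mice per genotype (≈ 55–80 clone records),
chosen to exercise every code path at comfortable margins; recovery metrics
at these sizes are V/D/J call accuracy ≥ 99 %, SSP precision/recall ≥ 0.9
over eligible gene groups (≥ 3 clones from ≥ 2 mice), and UM/M accuracy
≥ 95 % on SSP-corrected clones, as measured by the test suite. Monte Carlo
tests use 10,000 replicates. Bisection and grid oracles agree to two
decimals with a 0.011–0.015 guard for grid granularity. Percent outputs
follow the source table conventions: integers for headline percentages, one
decimal in usage tables.

## Known limitations

* SSP calling cannot distinguish a polymorphism from a hypermutation that
  is shared because the clones are clonally related across samples; the
  two-mouse requirement is the guard, and truly private polymorphisms
  (one mouse only) are unrecoverable by design.
* No indel handling in mutation calling; gapped columns count against
  identity but are not reported as mutation events.
* Allele-level disambiguation is limited to best alignment score; the
  reference carries one name per record and cross-nomenclature (IMGT vs
  VBASE2) mapping is user-provided metadata, as in the packaged table.
* The antigen-similarity search ranks a user-supplied annotated HCDR3 set;
  it does not reproduce homology percentages against live external
  databases.
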