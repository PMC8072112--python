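"""Discriminating strain polymorphism from somatic hypermutation.

The cohort is an F1 hybrid of two strains whose germline IGHV repertoire is
poorly represented in the reference database, so a naive comparison against
reference germlines over-counts mutations.  Because hypermutation introduces
any of the four nucleotides essentially at random across clones, a mismatch
of the *same* nucleotide at the *same* position recurring in most clones of
a gene — and in at least two different mice — is far more likely an
inherited strain-specific polymorphism (SSP) than independent mutation.
Mismatches surviving that filter are counted as somatic hypermutation (SHM),
and a clone is unmutated (UM) when its corrected divergence from germline is
at most 2% (>= 98% identity), mutated (M) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import VDJAnnotation
from .io import CloneRecord

UM_THRESHOLD_PERCENT = 2.0
MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class SSPEntry:
    """One polymorphism call on a germline V gene."""

    v_position: int  # 1-based position on the germline segment
    germline_nt: str
    observed_nt: str
    support: int     # clones sharing the mismatch
    n_mice: int      # distinct mice carrying it
    n_group: int     # clones examined


@dataclass
class GeneGroup:
    """Clones assigned to one germline V gene, pooled across genotypes."""

    gene: str
    items: list[tuple[CloneRecord, VDJAnnotation]] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.items)

    @property
    def n_mice(self) -> int:
        return len({rec.parental_mouse for rec, _ in self.items})

    @property
    def eligible(self) -> bool:
        return self.n_clones >= MIN_GROUP_SIZE


@dataclass(frozen=True)
class MutationCall:
    raw_mismatches: int
    ssp_count: int
    shm_count: int
    shm_percent: float
    status: str  # "UM" | "M"
    ssp_uncorrected: bool = False


def classify_status(shm_percent: float) -> str:
    """UM iff corrected divergence <= 2% (boundary inclusive)."""
    if shm_percent < 0:
        raise ValueError(f"shm_percent must be >= 0, got {shm_percent}")
    return "UM" if shm_percent <= UM_THRESHOLD_PERCENT else "M"


def group_clones_by_gene(annotated: list[tuple[CloneRecord, VDJAnnotation]]
                         ) -> dict[str, GeneGroup]:
    """Group annotated clones by V call, across all genotypes and mice.

    Failed annotations are skipped.  Groups with fewer than three clones are
    ineligible for polymorphism calling (``GeneGroup.eligible``).
    """
    groups: dict[str, GeneGroup] = {}
    for rec, ann in annotated:
        if ann.failed or not ann.v_call:
            continue
        groups.setdefault(ann.v_call, GeneGroup(gene=ann.v_call)).items.append((rec, ann))
    return groups


def call_ssps(group: GeneGroup, min_fraction: float = 0.5,
              min_mice: int = 2) -> list[SSPEntry]:
    """Call polymorphisms in one eligible gene group.

    A (position, observed nucleotide) mismatch is an SSP iff it recurs in a
    strict majority (> ``min_fraction``) of the group's clones and in at
    least ``min_mice`` distinct mice.  Everything else stays SHM candidate.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if not group.eligible:
        raise ValueError(f"group {group.gene}: fewer than {MIN_GROUP_SIZE} clones")
    tally: dict[tuple[int, str, str], list] = {}
    for rec, ann in group.items:
        for pos, germ_nt, obs_nt in ann.v_mismatches:
            entry = tally.setdefault((pos, germ_nt, obs_nt), [0, set()])
            entry[0] += 1
            entry[1].add(rec.parental_mouse)
    n = group.n_clones
    out = []
    for (pos, germ_nt, obs_nt), (support, mice) in tally.items():
        if support > min_fraction * n and len(mice) >= min_mice:
            out.append(SSPEntry(v_position=pos, germline_nt=germ_nt,
                                observed_nt=obs_nt, support=support,
                                n_mice=len(mice), n_group=n))
    out.sort(key=lambda e: (e.v_position, e.observed_nt))
    return out


def compute_corrected_shm(annotation: VDJAnnotation, ssps: list[SSPEntry],
                          ssp_uncorrected: bool = False) -> MutationCall:
    """Split a clone's raw germline mismatches into SSP and SHM counts.

    A mismatch is absorbed by the SSP table only when both the position and
    the substituted nucleotide agree.  The percent denominator is the
    clone's aligned V length.
    """
    ssp_keys = {(e.v_position, e.observed_nt) for e in ssps}
    raw = len(annotation.v_mismatches)
    ssp_count = sum(1 for pos, _, obs in annotation.v_mismatches
                    if (pos, obs) in ssp_keys)
    shm_count = raw - ssp_count
    length = annotation.v_aligned_columns
    if length <= 0:
        raise ValueError("annotation has no aligned V columns")
    shm_percent = round(100.0 * shm_count / length, 2)
    return MutationCall(raw_mismatches=raw, ssp_count=ssp_count,
                        shm_count=shm_count, shm_percent=shm_percent,
                        status=classify_status(shm_percent),
                        ssp_uncorrected=ssp_uncorrected)


def correct_cohort(annotated: list[tuple[CloneRecord, VDJAnnotation]],
                   min_fraction: float = 0.5, min_mice: int = 2
                   ) -> tuple[dict[str, list[SSPEntry]], dict[str, MutationCall]]:
    """SSP tables per gene plus a corrected mutation call per record.

    Clones in ineligible (< 3 clone) groups are classified from uncorrected
    mismatch counts and flagged ``ssp_uncorrected``.
    """
    groups = group_clones_by_gene(annotated)
    ssp_table = {
        gene: call_ssps(grp, min_fraction, min_mice) if grp.eligible else []
        for gene, grp in groups.items()
    }
    calls: dict[str, MutationCall] = {}
    for gene, grp in groups.items():
        for rec, ann in grp.items:
            calls[rec.record_id] = compute_corrected_shm(
                ann, ssp_table[gene], ssp_uncorrected=not grp.eligible)
    return ssp_table, calls
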