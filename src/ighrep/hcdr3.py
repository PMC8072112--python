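"""HCDR3 feature computation, clonotype accounting and stereotypy.

The isoelectric point follows the Bjellqvist charge model used by the
ExPASy Compute pI/Mw tool: the peptide's net charge at a given pH sums the
Henderson-Hasselbalch occupancies of the N-terminus (residue-specific pKa),
the C-terminus, and the ionisable side chains, with distinct pKa values for
C-terminal Asp/Glu.  The pI is the root of that monotone-decreasing
function, found by bisection on [0, 14].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Bjellqvist pKa set (ExPASy flavour).  N-terminal pKa depends on the first
# residue; C-terminal Asp/Glu side chains are slightly weaker acids.
_NTERM_PKA = {"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82,
              "V": 7.44, "E": 7.70}
_NTERM_DEFAULT = 7.50
_CTERM_PKA = 3.55
_POSITIVE_SIDE = {"R": 12.00, "K": 10.00, "H": 5.98}
_NEGATIVE_SIDE = {"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}
_NEGATIVE_SIDE_CTERM = {"D": 4.55, "E": 4.75}


def _validate_peptide(seq: str) -> str:
    if not seq:
        raise ValueError("empty peptide")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard amino acids {sorted(bad)} in {seq!r}")
    return seq


def peptide_charge(seq: str, ph: float) -> float:
    """Net charge of a peptide at ``ph`` under the Bjellqvist model."""
    seq = _validate_peptide(seq)
    positive = [_NTERM_PKA.get(seq[0], _NTERM_DEFAULT)]
    negative = [_CTERM_PKA]
    last = len(seq) - 1
    for i, aa in enumerate(seq):
        if aa in _POSITIVE_SIDE:
            positive.append(_POSITIVE_SIDE[aa])
        elif aa in _NEGATIVE_SIDE:
            if i == last and aa in _NEGATIVE_SIDE_CTERM:
                negative.append(_NEGATIVE_SIDE_CTERM[aa])
            else:
                negative.append(_NEGATIVE_SIDE[aa])
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - pka)) for pka in positive)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pka - ph)) for pka in negative)
    return charge


def _round_half_up(x: float, digits: int = 2) -> float:
    scale = 10 ** digits
    return math.floor(x * scale + 0.5) / scale


def compute_pi(seq: str, tol: float = 1e-4) -> float:
    """Isoelectric point (pH of zero net charge), 2 decimals, half-up.

    Bisection runs past the charge tolerance so midpoint roots (e.g. a
    peptide whose pI is exactly half-way between two pKa values) round
    deterministically.
    """
    seq = _validate_peptide(seq)
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if peptide_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    assert abs(peptide_charge(seq, mid)) < tol
    return _round_half_up(mid)


@dataclass(frozen=True)
class HCDR3Features:
    sequence: str
    length: int
    pI: float
    frac_tyrosine: float
    frac_acidic: float
    frac_basic: float


def hcdr3_features(seq: str) -> HCDR3Features:
    """Length, pI and composition fractions of an HCDR3 peptide."""
    seq = _validate_peptide(seq)
    n = len(seq)
    return HCDR3Features(
        sequence=seq,
        length=n,
        pI=compute_pi(seq),
        frac_tyrosine=seq.count("Y") / n,
        frac_acidic=sum(seq.count(a) for a in "DE") / n,
        frac_basic=sum(seq.count(a) for a in "KRH") / n,
    )


@dataclass
class CanonicalClone:
    """A deduplicated clonotype: one per (parental mouse, HCDR3) pair.

    Identical clones seen in several tissues of one mouse, or in a parental
    mouse and its allotransplanted F1 recipient, collapse into a single
    entry — the unit all frequency statistics count.
    """

    mouse_id: str
    cdr3_aa: str
    v_call: str
    d_call: str
    j_call: str
    mutation_status: str
    v_subgroup: str = ""
    d_subgroup: str = ""
    j_subgroup: str = ""
    tissues: frozenset = frozenset()
    max_fraction: float = 0.0
    max_count: int = 0
    is_expanded: bool = False

    @property
    def key(self):
        return (self.mouse_id, self.cdr3_aa)


def canonicalize_clones(frame: pd.DataFrame,
                        expansion_min_fraction: float = 0.20,
                        expansion_min_count: int = 2) -> list[CanonicalClone]:
    """Collapse per-tissue clone observations into canonical clonotypes.

    ``frame`` needs columns ``mouse_id``, ``cdr3_aa``, ``v_call``, ``d_call``,
    ``j_call``, ``mutation_status``, ``tissue``, ``colony_count`` and
    optionally ``is_allotransplant``/``parental_mouse_id`` (F1 recipients are
    attributed to their parental mouse) and ``total_colonies`` (otherwise the
    per-(mouse, tissue) colony sum is used as the sample size).
    """
    df = frame.copy()
    df = df[df["cdr3_aa"].astype(str) != ""]
    if "is_allotransplant" not in df.columns:
        df["is_allotransplant"] = False
    if "parental_mouse_id" not in df.columns:
        df["parental_mouse_id"] = ""
    allo = df["is_allotransplant"].astype(bool)
    if (allo & (df["parental_mouse_id"].astype(str) == "")).any():
        bad = df.loc[allo & (df["parental_mouse_id"].astype(str) == ""), "mouse_id"].tolist()
        raise ValueError(f"allotransplant records without parental_mouse_id: {bad}")
    df["parental"] = df["mouse_id"].where(~allo, df["parental_mouse_id"])
    if "total_colonies" not in df.columns or df["total_colonies"].isna().any():
        totals = df.groupby(["mouse_id", "tissue"])["colony_count"].transform("sum")
        df["total_colonies"] = totals
    df["fraction"] = df["colony_count"] / df["total_colonies"]

    out = []
    for (mouse, cdr3), grp in df.groupby(["parental", "cdr3_aa"], sort=False):
        top = grp.loc[grp["fraction"].idxmax()]
        out.append(CanonicalClone(
            mouse_id=str(mouse),
            cdr3_aa=str(cdr3),
            v_call=str(top["v_call"]),
            d_call=str(top.get("d_call", "")),
            j_call=str(top.get("j_call", "")),
            mutation_status=str(top.get("mutation_status", "")),
            v_subgroup=str(top.get("v_subgroup", "")),
            d_subgroup=str(top.get("d_subgroup", "")),
            j_subgroup=str(top.get("j_subgroup", "")),
            tissues=frozenset(grp["tissue"].astype(str)),
            max_fraction=float(grp["fraction"].max()),
            max_count=int(grp["colony_count"].max()),
            is_expanded=bool(((grp["colony_count"] >= expansion_min_count)
                              & (grp["fraction"] >= expansion_min_fraction)).any()),
        ))
    return out


def mutation_status_summary(clones: list[CanonicalClone],
                            expanded_only: bool = False) -> tuple[int, int]:
    """(percent UM, percent M) over canonical clones, nearest integer."""
    pool = [c for c in clones if c.is_expanded] if expanded_only else list(clones)
    if not pool:
        raise ValueError("no canonical clones to summarise")
    n_um = sum(1 for c in pool if c.mutation_status == "UM")
    pct_um = round(100 * n_um / len(pool))
    return pct_um, 100 - pct_um


@dataclass
class StereotypeSet:
    cdr3_aa: str
    members: list[CanonicalClone] = field(default_factory=list)

    @property
    def n_mice(self) -> int:
        return len({c.mouse_id for c in self.members})


def detect_stereotypes(clones: list[CanonicalClone],
                       max_hamming: int = 0) -> tuple[list[StereotypeSet], float]:
    """Identical HCDR3 shared by >= 2 distinct mice, plus percent stereotyped.

    ``max_hamming=1`` additionally merges equal-length HCDR3 differing at a
    single residue (near-identity mode, off by default).
    """
    groups: dict[str, list[CanonicalClone]] = {}
    for clone in clones:
        groups.setdefault(clone.cdr3_aa, []).append(clone)

    if max_hamming > 0:
        keys = sorted(groups)
        parent = {k: k for k in keys}

        def find(k):
            while parent[k] != k:
                parent[k] = parent[parent[k]]
                k = parent[k]
            return k

        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= max_hamming:
                    parent[find(a)] = find(b)
        merged: dict[str, list[CanonicalClone]] = {}
        for k in keys:
            merged.setdefault(find(k), []).extend(groups[k])
        groups = merged

    sets = []
    for cdr3 in sorted(groups):
        members = groups[cdr3]
        if len({c.mouse_id for c in members}) >= 2:
            sets.append(StereotypeSet(cdr3_aa=cdr3, members=sorted(
                members, key=lambda c: c.mouse_id)))
    n_stereo = sum(len(s.members) for s in sets)
    pct = 100.0 * n_stereo / len(clones) if clones else 0.0
    return sets, pct


def _similarity_aligner() -> Align.PairwiseAligner:
    """Global aligner scoring +1 identity, +0.5 BLOSUM62-positive, -1 gap."""
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = blosum.alphabet
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b:
                matrix[a, b] = 1.0
            elif blosum[a, b] > 0:
                matrix[a, b] = 0.5
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def similarity_search(query: str, reference: list[tuple[str, str]],
                      min_similarity: float = 75.0) -> list[dict]:
    """Rank an annotated HCDR3 reference set by percent similarity to ``query``.

    ``reference`` holds (sequence, antigen_label) pairs.  Percent similarity
    is 100 x identities / alignment columns of a global alignment; hits below
    ``min_similarity`` are dropped.
    """
    query = _validate_peptide(query)
    if not reference:
        raise ValueError("empty reference set")
    aligner = _similarity_aligner()
    hits = []
    for seq, label in reference:
        seq = _validate_peptide(seq)
        aln = aligner.align(query, seq)[0]
        identities = sum(
            1
            for (qs, qe), (ts, te) in zip(*aln.aligned)
            for q, t in zip(query[qs:qe], seq[ts:te])
            if q == t
        )
        pct = 100.0 * identities / aln.length
        if pct >= min_similarity:
            hits.append({"sequence": seq, "antigen": label,
                         "similarity": round(pct, 1)})
    hits.sort(key=lambda h: (-h["similarity"], h["sequence"]))
    return hits
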