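"""Readers and writers for the formats the repertoire pipeline touches.

Germline segments and clone sequences travel as FASTA; cohort metadata as a
tab-separated sample sheet; annotated output as an AIRR-flavoured
rearrangement TSV that round-trips losslessly through :func:`read_rearrangement_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GENOTYPES = ("-/-", "+/-", "-/+", "+/+")

#: Column order of the rearrangement table.  ``is_allotransplant``,
#: ``parental_mouse_id`` and ``total_colonies`` extend the core schema so the
#: dedup rules downstream need no side channel.
REARRANGEMENT_COLUMNS = [
    "sequence_id", "mouse_id", "genotype", "tissue", "sequence",
    "v_call", "d_call", "j_call", "v_identity", "junction_aa", "cdr3_aa",
    "productive", "isotype", "ssp_count", "shm_count", "shm_percent",
    "mutation_status", "colony_count",
    "is_allotransplant", "parental_mouse_id", "total_colonies",
]


class RepertoireIOError(ValueError):
    """Malformed input file or inconsistent metadata."""


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V, D or J reference gene."""

    name: str
    segment_type: str  # "V" | "D" | "J"
    sequence: str
    subgroup: str = ""
    functionality: str = "unknown"  # F | P | ORF | unknown

    def __post_init__(self):
        if self.segment_type not in ("V", "D", "J"):
            raise RepertoireIOError(f"bad segment_type {self.segment_type!r}")
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise RepertoireIOError(
                f"{self.name}: sequence must be non-empty uppercase ACGT(N)")

    def __len__(self):
        return len(self.sequence)


@dataclass
class GermlineSet:
    """Reference segments keyed by type; the pool V(D)J assignment searches."""

    v: dict[str, GermlineSegment] = field(default_factory=dict)
    d: dict[str, GermlineSegment] = field(default_factory=dict)
    j: dict[str, GermlineSegment] = field(default_factory=dict)

    def of_type(self, segment_type: str) -> dict[str, GermlineSegment]:
        return {"V": self.v, "D": self.d, "J": self.j}[segment_type]

    def add(self, seg: GermlineSegment) -> None:
        pool = self.of_type(seg.segment_type)
        if seg.name in pool:
            raise RepertoireIOError(f"duplicate germline identifier {seg.name!r}")
        pool[seg.name] = seg


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced colony group (identical colonies collapse via colony_count)."""

    record_id: str
    mouse_id: str
    genotype: str
    tissue: str
    sequence: str
    is_allotransplant: bool = False
    parental_mouse_id: str = ""
    colony_count: int = 1

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise RepertoireIOError(f"{self.record_id}: genotype {self.genotype!r} "
                                    f"not in {GENOTYPES}")
        if not self.mouse_id:
            raise RepertoireIOError(f"{self.record_id}: empty mouse_id")
        if self.colony_count < 1:
            raise RepertoireIOError(f"{self.record_id}: colony_count must be >= 1")
        if self.is_allotransplant != bool(self.parental_mouse_id):
            raise RepertoireIOError(
                f"{self.record_id}: parental_mouse_id must be set iff allotransplant")

    @property
    def parental_mouse(self) -> str:
        """Mouse the clone is attributed to (F1 recipients map to the donor)."""
        return self.parental_mouse_id if self.is_allotransplant else self.mouse_id


def infer_subgroup(name: str) -> str:
    """Derive a subgroup label from a gene name prefix.

    ``IGHV5-17*02`` -> ``IGHV5``; ``VH7183.a47.76`` -> ``VH7183``;
    ``IGHJ4`` -> ``IGHJ4``.
    """
    stem = name.split("*")[0]
    for sep in ("-", "."):
        if sep in stem:
            return stem.split(sep)[0]
    return stem


def _normalise_nt(raw: str, name: str, allow_n: bool) -> str:
    seq = raw.upper().replace("U", "T")
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise RepertoireIOError(
            f"record {name!r}: non-ACGT characters {sorted(bad)}")
    return seq


def read_germline_fasta(path, segment_type: str, allow_n: bool = False) -> GermlineSet:
    """Read germline segments of one type from FASTA.

    Headers use the pipe-delimited dialect ``>name|subgroup|functionality``;
    missing fields fall back to a prefix-derived subgroup and ``unknown``
    functionality.  Extra pipe fields are ignored.
    """
    if segment_type not in ("V", "D", "J"):
        raise RepertoireIOError(f"segment_type must be V, D or J, got {segment_type!r}")
    gs = GermlineSet()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        name = fields[0].strip() or rec.id
        subgroup = fields[1].strip() if len(fields) > 1 and fields[1].strip() else infer_subgroup(name)
        functionality = fields[2].strip() if len(fields) > 2 and fields[2].strip() else "unknown"
        seq = _normalise_nt(str(rec.seq), name, allow_n)
        gs.add(GermlineSegment(name=name, segment_type=segment_type,
                               sequence=seq, subgroup=subgroup,
                               functionality=functionality))
        n += 1
    if n == 0:
        logger.warning("no records in germline FASTA %s", path)
    return gs


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the TSV mapping FASTA record IDs to cohort metadata."""
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"record_id", "mouse_id", "genotype", "tissue"}
    missing = required - set(sheet.columns)
    if missing:
        raise RepertoireIOError(f"sample sheet missing columns {sorted(missing)}")
    if "is_allotransplant" not in sheet.columns:
        sheet["is_allotransplant"] = "false"
    if "parental_mouse_id" not in sheet.columns:
        sheet["parental_mouse_id"] = ""
    if sheet["record_id"].duplicated().any():
        dups = sheet.loc[sheet["record_id"].duplicated(), "record_id"].tolist()
        raise RepertoireIOError(f"duplicate record_id in sample sheet: {dups}")
    return sheet


def read_clone_fasta(path, sheet: pd.DataFrame, allow_n: bool = False) -> list[CloneRecord]:
    """Read clone sequences and bind each record to its sample-sheet row."""
    meta = sheet.set_index("record_id")
    records, unmapped = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid not in meta.index:
            unmapped.append(rid)
            continue
        row = meta.loc[rid]
        records.append(CloneRecord(
            record_id=rid,
            mouse_id=row["mouse_id"],
            genotype=row["genotype"],
            tissue=row["tissue"],
            sequence=_normalise_nt(str(rec.seq), rid, allow_n),
            is_allotransplant=str(row["is_allotransplant"]).lower() in ("true", "1", "yes"),
            parental_mouse_id=row["parental_mouse_id"],
            colony_count=int(row["colony_count"]) if "colony_count" in row.index and str(row["colony_count"]) else 1,
        ))
    if unmapped:
        raise RepertoireIOError(f"FASTA records missing from sample sheet: {unmapped}")
    return records


_REARR_DTYPES = {
    "v_identity": float, "shm_percent": float,
    "ssp_count": "Int64", "shm_count": "Int64",
    "colony_count": int, "total_colonies": "Int64",
}


def write_rearrangement_table(frame: pd.DataFrame, path) -> None:
    """Write the rearrangement TSV with the canonical column order."""
    out = frame.copy()
    for col in REARRANGEMENT_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[REARRANGEMENT_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_rearrangement_table(path) -> pd.DataFrame:
    """Read a rearrangement TSV written by :func:`write_rearrangement_table`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col, dtype in _REARR_DTYPES.items():
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col].replace("", pd.NA)).astype(dtype)
    if "productive" in frame.columns:
        frame["productive"] = frame["productive"].str.lower().isin(("true", "1", "t"))
    if "is_allotransplant" in frame.columns:
        frame["is_allotransplant"] = frame["is_allotransplant"].str.lower().isin(("true", "1", "t"))
    return frame


def write_germline_fasta(segments: Iterable[GermlineSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.name}|{seg.subgroup}|{seg.functionality}\n{seg.sequence}\n")


def write_clone_fasta(records: Iterable[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")


def write_sample_sheet(records: Iterable[CloneRecord], path) -> None:
    rows = [{
        "record_id": r.record_id, "mouse_id": r.mouse_id, "genotype": r.genotype,
        "tissue": r.tissue, "is_allotransplant": str(r.is_allotransplant).lower(),
        "parental_mouse_id": r.parental_mouse_id, "colony_count": r.colony_count,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
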