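"""End-to-end orchestration: simulate/load -> annotate -> SSP/SHM ->
features -> stereotypy -> usage statistics, with a run manifest.

Every stage logs records in/out so filtering is auditable, and the manifest
records the seed and a hash of the full configuration: rerunning with the
same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as rio
from .annotate import AlignConfig, PrimerSet, annotate_cohort
from .hcdr3 import canonicalize_clones, compute_pi, detect_stereotypes, \
    hcdr3_features, mutation_status_summary
from .shm import correct_cohort
from .simulate import SimConfig, simulate_cohort, write_truth_json
from .stats import frequency_table, proportion_test, summarize_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "ighrep_run"
    seed: int = 0
    # input paths; all empty -> simulate a cohort from sim
    germline_v: str = ""
    germline_d: str = ""
    germline_j: str = ""
    clones_fasta: str = ""
    sample_sheet: str = ""
    rearrangement_tsv: str = ""        # pre-annotated mode: skip alignment
    background_tsv: str = ""           # gene\tbackground_percent
    sim: SimConfig = field(default_factory=SimConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    ssp_min_fraction: float = 0.5
    ssp_min_mice: int = 2
    expansion_min_fraction: float = 0.20
    expansion_min_count: int = 2
    expanded_only: bool = True

    def validate(self) -> None:
        if not 0 <= self.align.v_identity_floor <= 100:
            raise ValueError("v_identity_floor must be in [0, 100], got "
                             f"{self.align.v_identity_floor}")
        if not 0 < self.ssp_min_fraction <= 1:
            raise ValueError("ssp_min_fraction must be in (0, 1]")
        if not 0 <= self.expansion_min_fraction <= 1:
            raise ValueError("expansion_min_fraction must be in [0, 1]")
        self.sim.validate()

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where outputs land does not change what they are
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_rearrangement_frame(records, annotations, calls) -> pd.DataFrame:
    """Assemble the rearrangement table from per-record annotation output."""
    totals: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.mouse_id, rec.tissue)
        totals[key] = totals.get(key, 0) + rec.colony_count
    rows = []
    for rec, ann in zip(records, annotations):
        call = calls.get(rec.record_id)
        rows.append({
            "sequence_id": rec.record_id, "mouse_id": rec.mouse_id,
            "genotype": rec.genotype, "tissue": rec.tissue,
            "sequence": rec.sequence, "v_call": ann.v_call,
            "d_call": ann.d_call, "j_call": ann.j_call,
            "v_identity": ann.v_identity, "junction_aa": ann.junction_aa,
            "cdr3_aa": ann.cdr3_aa, "productive": ann.productive,
            "isotype": ann.isotype,
            "ssp_count": call.ssp_count if call else pd.NA,
            "shm_count": call.shm_count if call else pd.NA,
            "shm_percent": call.shm_percent if call else float("nan"),
            "mutation_status": call.status if call else "",
            "colony_count": rec.colony_count,
            "is_allotransplant": rec.is_allotransplant,
            "parental_mouse_id": rec.parental_mouse_id,
            "total_colonies": totals[(rec.mouse_id, rec.tissue)],
        })
    return pd.DataFrame(rows)


def annotate_and_correct(records, germline, align_cfg=None,
                         ssp_min_fraction=0.5, ssp_min_mice=2):
    """Annotate a cohort and apply SSP-corrected mutation calls.

    Returns (rearrangement frame, ssp table dict, annotated pairs).
    """
    annotated = annotate_cohort(records, germline, align_cfg)
    n_failed = sum(1 for _, ann in annotated if ann.failed)
    if n_failed:
        logger.info("annotation: %d/%d records failed and are excluded "
                    "downstream", n_failed, len(annotated))
    ssp_table, calls = correct_cohort(annotated, ssp_min_fraction, ssp_min_mice)
    frame = build_rearrangement_frame(records, [a for _, a in annotated], calls)
    return frame, ssp_table, annotated


def ssp_table_frame(ssp_table) -> pd.DataFrame:
    rows = [{"gene": gene, "position": e.v_position, "germline_nt": e.germline_nt,
             "observed_nt": e.observed_nt, "support": e.support,
             "n_mice": e.n_mice, "n_group": e.n_group}
            for gene in sorted(ssp_table) for e in ssp_table[gene]]
    return pd.DataFrame(rows, columns=["gene", "position", "germline_nt",
                                       "observed_nt", "support", "n_mice",
                                       "n_group"])


def features_frame(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, row in frame.iterrows():
        cdr3 = str(row.get("cdr3_aa", ""))
        if not cdr3 or cdr3 == "nan":
            continue
        feats = hcdr3_features(cdr3)
        rows.append({"sequence_id": row["sequence_id"], "cdr3_aa": cdr3,
                     "length": feats.length, "pI": feats.pI,
                     "frac_Y": round(feats.frac_tyrosine, 3),
                     "frac_acidic": round(feats.frac_acidic, 3),
                     "frac_basic": round(feats.frac_basic, 3)})
    return pd.DataFrame(rows)


def stereotype_frame(sets) -> pd.DataFrame:
    rows = [{"cdr3_aa": s.cdr3_aa, "n_mice": s.n_mice,
             "mice": ";".join(sorted({c.mouse_id for c in s.members})),
             "n_members": len(s.members)} for s in sets]
    return pd.DataFrame(rows, columns=["cdr3_aa", "n_mice", "mice", "n_members"])


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(frame: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        outputs.append(name)
        return path

    ssp_table = {}
    if config.rearrangement_tsv:
        logger.info("pre-annotated mode: reading %s", config.rearrangement_tsv)
        frame = rio.read_rearrangement_table(config.rearrangement_tsv)
    else:
        if config.clones_fasta:
            germline = rio.GermlineSet()
            for seg_type, path in (("V", config.germline_v),
                                   ("D", config.germline_d),
                                   ("J", config.germline_j)):
                loaded = rio.read_germline_fasta(path, seg_type)
                for pool in (loaded.v, loaded.d, loaded.j):
                    for seg in pool.values():
                        germline.add(seg)
            sheet = rio.read_sample_sheet(config.sample_sheet)
            records = rio.read_clone_fasta(config.clones_fasta, sheet)
        else:
            logger.info("no inputs given: simulating cohort (seed=%d)",
                        config.sim.seed)
            cohort = simulate_cohort(config.sim)
            records, germline = cohort.records, cohort.base_germline
            write_truth_json(cohort.truth, outdir / "truth.json")
            outputs.append("truth.json")
        logger.info("cohort: %d records", len(records))
        frame, ssp_table, _ = annotate_and_correct(
            records, germline, config.align,
            config.ssp_min_fraction, config.ssp_min_mice)
        rio.write_rearrangement_table(frame, outdir / "rearrangements.tsv")
        outputs.append("rearrangements.tsv")
        emit(ssp_table_frame(ssp_table), "ssp_table.tsv")

    emit(features_frame(frame), "features.tsv")

    canonical = canonicalize_clones(frame, config.expansion_min_fraction,
                                    config.expansion_min_count)
    pool = [c for c in canonical if c.is_expanded] if config.expanded_only else canonical
    logger.info("canonical clones: %d (%d expanded)", len(canonical),
                sum(c.is_expanded for c in canonical))
    sets, pct_stereo = detect_stereotypes(pool)
    emit(stereotype_frame(sets), "stereotypes.tsv")

    pct_um, pct_m = mutation_status_summary(canonical,
                                            expanded_only=config.expanded_only)
    lengths = {c.cdr3_aa: float(len(c.cdr3_aa)) for c in pool}
    pis = {c.cdr3_aa: compute_pi(c.cdr3_aa) for c in pool}
    mean_len, sd_len, n = summarize_features(pool, lengths, "length")
    mean_pi, sd_pi, _ = summarize_features(pool, pis, "pI")

    usage = frequency_table(pool, level="gene", segment="V")
    emit(usage.reset_index(), "gene_usage.tsv")

    proportion_rows = []
    if config.background_tsv:
        background = pd.read_csv(config.background_tsv, sep="\t")
        for _, row in background.iterrows():
            gene = str(row["gene"])
            k = int(usage["all"].get(gene, 0)) if "all" in usage else 0
            res = proportion_test(k, n, float(row["background_percent"]) / 100.0)
            proportion_rows.append({"gene": gene, "k": k, "n": n,
                                    "background_percent": row["background_percent"],
                                    "z": round(res.statistic, 3),
                                    "p": res.p_value})
        emit(pd.DataFrame(proportion_rows), "proportion_tests.tsv")

    report = {
        "n_canonical": len(canonical),
        "n_reported": n,
        "percent_um": pct_um, "percent_m": pct_m,
        "stereotype_sets": [{"cdr3_aa": s.cdr3_aa, "n_mice": s.n_mice}
                            for s in sets],
        "stereotyped_percent": round(pct_stereo, 1),
        "mean_length": mean_len, "sd_length": sd_len,
        "mean_pi": mean_pi, "sd_pi": sd_pi,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    outputs.append("report.json")

    outputs.append("manifest.json")
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "outputs": sorted(outputs)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    report["manifest"] = manifest
    return report
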