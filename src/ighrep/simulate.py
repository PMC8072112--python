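"""Synthetic V(D)J repertoires with ground truth.

The generator emulates the statistical structure the analysis assumes:

* one shared *strain* germline derived from the reference pool by planting
  per-site polymorphisms in every V gene (mean rate 2.54% of V positions,
  the average strain divergence reported for inbred mouse IGHV) — shared by
  every simulated mouse, which is exactly what makes SSPs conserved across
  individuals while hypermutation is not;
* clonal V-D-J rearrangements with junction trimming and N-additions,
  frame-corrected so clones are productive unless requested otherwise;
* per-clone hypermutation restricted to the V region, drawn from an
  unmutated/mutated founder mixture;
* genotype-dependent clonal expansion: colony fractions per sample follow a
  Dirichlet whose concentration is low for double-transgenic (+/+) mice
  (mono/oligoclonal dominance) and high otherwise (polyclonal).

Identical colonies within a sample collapse into one record carrying
``colony_count``, mirroring how sequenced colonies are tabulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .annotate import PrimerSet, reverse_complement_iupac
from .io import GENOTYPES, CloneRecord, GermlineSegment, GermlineSet

NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# FR1 leader compatible with the degenerate V forward primer.
_V_LEADER = "GAGGTGCAGCTGGAGGAGTCTGGA"
_CDR3_SECOND_CODONS = ("AGA", "AGT", "ACT", "GTT", "CTT", "GGT")  # R S T V L G


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    n_mice_per_genotype: int = 5
    colonies_per_sample: tuple[int, int] = (5, 15)
    germline_counts: tuple[int, int, int] = (6, 4, 4)   # (n_V, n_D, n_J)
    v_length: int = 294
    ssp_rate: float = 0.0254
    shm_rate_um: tuple[float, float] = (0.0, 0.02)
    shm_rate_m: tuple[float, float] = (0.02, 0.05)
    prob_mutated_clone: float = 0.15
    expansion_dirichlet_alpha: dict = field(
        default_factory=lambda: {"+/+": 0.1, "-/-": 20.0, "+/-": 20.0, "-/+": 20.0})
    n_founders_range: tuple[int, int] = (3, 7)
    trim_max: int = 4
    n_insert_max: int = 6
    n_stereotype_mice: int = 0
    n_f1_recipients: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("ssp_rate", "prob_mutated_clone"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in ("shm_rate_um", "shm_rate_m"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"{name} must be an ascending range in [0, 1]")
        lo, hi = self.colonies_per_sample
        if not 1 <= lo <= hi <= 50:
            raise ValueError("colonies_per_sample must lie within [1, 50]")
        for alpha in self.expansion_dirichlet_alpha.values():
            if alpha <= 0:
                raise ValueError("expansion_dirichlet_alpha values must be > 0")
        if self.v_length % 3 or self.v_length < 45:
            raise ValueError("v_length must be a multiple of 3 and >= 45")
        if not 0 <= self.trim_max <= 6:
            raise ValueError("trim_max must be in [0, 6] (the V 3' tail past the "
                             "conserved Cys is 6 nt)")
        if self.n_insert_max < 0:
            raise ValueError("n_insert_max must be >= 0")


@dataclass
class CloneTruth:
    v_call: str
    d_call: str
    j_call: str
    shm_positions: list[int]          # 1-based on the strain germline V
    shm_count: int
    shm_percent: float                # over the trimmed V length
    status: str                       # UM | M from realized SHM
    cdr3_aa: str                      # planted, pre-SHM, anchor-stripped
    fraction: float                   # clonal fraction within the sample
    productive: bool


@dataclass
class SimTruth:
    ssp: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    clones: dict[str, CloneTruth] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    records: list[CloneRecord]
    truth: SimTruth
    base_germline: GermlineSet
    strain_germline: GermlineSet
    j_w_offsets: dict[str, int]


def _random_nonstop_codon(rng) -> str:
    while True:
        codon = "".join(rng.choice(NT, 3))
        if codon not in _STOPS:
            return codon


def random_germline_set(counts: tuple[int, int, int], v_length: int,
                        rng) -> tuple[GermlineSet, dict[str, int]]:
    """Reference pool with realistic anchors; returns it plus per-J W offsets."""
    n_v, n_d, n_j = counts
    gs = GermlineSet()
    n_codons = v_length // 3
    for i in range(n_v):
        subgroup_no = 1 + i % 5
        mid = "".join(_random_nonstop_codon(rng) for _ in range(n_codons - 8 - 5))
        tail = ("TATTACTGT"                       # Y-Y-C: the 2nd-CYS anchor
                + "GC" + rng.choice(NT)           # Ala opening the CDR3
                + str(rng.choice(_CDR3_SECOND_CODONS)))
        seq = _V_LEADER + mid + tail
        gs.add(GermlineSegment(name=f"IGHV{subgroup_no}-{i + 1}*01",
                               segment_type="V", sequence=seq,
                               subgroup=f"IGHV{subgroup_no}", functionality="F"))
    for i in range(n_d):
        length = int(rng.integers(12, 17))
        gs.add(GermlineSegment(name=f"DSP{1 + i % 4}.{i + 1}", segment_type="D",
                               sequence="".join(rng.choice(NT, length)),
                               subgroup=f"D{1 + i % 4}", functionality="F"))
    w_offsets = {}
    for i in range(n_j):
        k = int(rng.integers(2, 5))               # CDR3-side codons before W
        prefix = "".join(_random_nonstop_codon(rng) for _ in range(k))
        motif = ("TGG" + "GG" + rng.choice(NT)    # W-G
                 + _random_nonstop_codon(rng)     # x
                 + "GG" + rng.choice(NT))         # G
        fr4 = "".join(_random_nonstop_codon(rng) for _ in range(8))
        name = f"IGHJ{i + 1}"
        gs.add(GermlineSegment(name=name, segment_type="J",
                               sequence=prefix + motif + fr4,
                               subgroup=f"JH{i + 1}", functionality="F"))
        w_offsets[name] = 3 * k
    return gs, w_offsets


def derive_strain_germline(base: GermlineSet, ssp_rate: float,
                           seed) -> tuple[GermlineSet, dict[str, list[tuple[int, str, str]]]]:
    """Plant strain polymorphisms in every V gene of the reference pool.

    Each V receives Binomial(length, ssp_rate) substitutions at uniform
    positions with uniform alternative nucleotides.  D and J segments are
    carried over unchanged.  Truth positions are 1-based.
    """
    if not 0 <= ssp_rate <= 1:
        raise ValueError(f"ssp_rate must be in [0, 1], got {ssp_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strain = GermlineSet(d=dict(base.d), j=dict(base.j))
    truth: dict[str, list[tuple[int, str, str]]] = {}
    for name, seg in base.v.items():
        seq = list(seg.sequence)
        n_sub = rng.binomial(len(seq), ssp_rate)
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        entries = []
        for pos in sorted(int(p) for p in positions):
            old = seq[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq[pos] = new
            entries.append((pos + 1, old, new))
        truth[name] = entries
        strain.add(GermlineSegment(name=name, segment_type="V",
                                   sequence="".join(seq), subgroup=seg.subgroup,
                                   functionality=seg.functionality))
    return strain, truth


_CONSTANT_STUB = reverse_complement_iupac(PrimerSet().ch_mu)


def _translate(nt: str) -> str:
    return str(Seq(nt[:len(nt) - len(nt) % 3]).translate())


def simulate_clone(v: GermlineSegment, d: GermlineSegment, j: GermlineSegment,
                   cfg: SimConfig, rng, j_w_offset: int,
                   shm_rate: float = 0.0,
                   ssp_positions: frozenset[int] = frozenset(),
                   nonproductive: bool = False,
                   max_retries: int = 50) -> tuple[str, CloneTruth]:
    """Build one rearranged clone sequence plus its truth entry.

    The junction is V[:len-t1] + N1 + D[t2:len-t3] + N2 + J[t4:], with the
    N2 length adjusted so the J tryptophan sits in the V reading frame;
    junction nucleotides are resampled until the translated junction is
    stop-free and its first W-G-x-G is the planted one.  Hypermutation then
    substitutes Binomial(len(V'), shm_rate) V positions, never on a strain
    polymorphism site.  A constant-region stub (the IgM reverse-primer
    footprint) is appended.
    """
    cys_nt = len(v) - 9
    for attempt in range(max_retries):
        t1 = int(rng.integers(0, cfg.trim_max + 1))
        d_budget = max(len(d) - 6, 0)  # keep >= 5 nt of D plus margin
        t2 = int(rng.integers(0, min(cfg.trim_max, d_budget // 2) + 1))
        t3 = int(rng.integers(0, min(cfg.trim_max, d_budget - t2) + 1))
        t4 = int(rng.integers(0, min(cfg.trim_max, j_w_offset) + 1))
        v_part = v.sequence[:len(v) - t1]
        d_part = d.sequence[t2:len(d) - t3]
        n1 = "".join(rng.choice(NT, int(rng.integers(0, cfg.n_insert_max + 1))))
        n2 = "".join(rng.choice(NT, int(rng.integers(0, cfg.n_insert_max + 1))))
        w_clone = len(v_part) + len(n1) + len(d_part) + len(n2) + (j_w_offset - t4)
        shift = (cys_nt - w_clone) % 3
        if nonproductive:
            shift = (shift + 1) % 3  # force a frameshift
        n2 += "".join(rng.choice(NT, shift))
        seq = v_part + n1 + d_part + n2 + j.sequence[t4:]
        junction_nt = seq[cys_nt:]
        aa = _translate(junction_nt)
        w_idx = (len(v_part) + len(n1) + len(d_part) + len(n2)
                 + (j_w_offset - t4) - cys_nt) // 3
        if nonproductive:
            break
        if "*" in aa[:w_idx + 1]:
            continue
        first_w = next((i for i in range(1, len(aa) - 3)
                        if aa[i] == "W" and aa[i + 1] == "G" and aa[i + 3] == "G"), -1)
        if first_w != w_idx:
            continue
        break
    else:
        raise SimulationError("could not build a productive junction "
                              f"for {v.name}/{d.name}/{j.name}")

    junction_aa = aa[:w_idx + 1] if not nonproductive else ""
    cdr3_aa = junction_aa[1:-1] if junction_aa else ""

    n_mut = int(rng.binomial(len(v_part), shm_rate)) if shm_rate > 0 else 0
    shm_positions: list[int] = []
    if n_mut:
        candidates = np.array([p for p in range(len(v_part))
                               if (p + 1) not in ssp_positions])
        n_mut = min(n_mut, len(candidates))
        chosen = rng.choice(candidates, size=n_mut, replace=False)
        seq_list = list(seq)
        for pos in sorted(int(p) for p in chosen):
            seq_list[pos] = str(rng.choice([b for b in "ACGT" if b != seq_list[pos]]))
            shm_positions.append(pos + 1)
        seq = "".join(seq_list)

    shm_percent = round(100.0 * len(shm_positions) / len(v_part), 2)
    truth = CloneTruth(
        v_call=v.name, d_call=d.name, j_call=j.name,
        shm_positions=shm_positions, shm_count=len(shm_positions),
        shm_percent=shm_percent,
        status="UM" if shm_percent <= 2.0 else "M",
        cdr3_aa=cdr3_aa, fraction=0.0, productive=not nonproductive)
    return seq + _CONSTANT_STUB, truth


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full multi-genotype cohort with ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base, j_w_offsets = random_germline_set(cfg.germline_counts, cfg.v_length, rng)
    strain, ssp_truth = derive_strain_germline(base, cfg.ssp_rate, rng)
    truth = SimTruth(ssp=ssp_truth)
    records: list[CloneRecord] = []

    v_names = sorted(strain.v)
    d_names = sorted(strain.d)
    j_names = sorted(strain.j)
    mouse_tag = {"-/-": "wt", "+/-": "traf2", "-/+": "bcl2", "+/+": "dtg"}

    def make_founder(nonproductive=False, force_unmutated=False):
        v = strain.v[str(rng.choice(v_names))]
        d = strain.d[str(rng.choice(d_names))]
        j = strain.j[str(rng.choice(j_names))]
        if force_unmutated:
            rate = 0.0
        else:
            mutated = rng.random() < cfg.prob_mutated_clone
            lo, hi = cfg.shm_rate_m if mutated else cfg.shm_rate_um
            rate = float(rng.uniform(lo, hi))
        ssp_pos = frozenset(p for p, _, _ in ssp_truth[v.name])
        return simulate_clone(v, d, j, cfg, rng, j_w_offsets[j.name],
                              shm_rate=rate, ssp_positions=ssp_pos,
                              nonproductive=nonproductive)

    shared = None
    if cfg.n_stereotype_mice > 0:
        shared = make_founder(force_unmutated=True)

    dominant: dict[str, tuple[str, CloneTruth]] = {}
    for genotype in GENOTYPES:
        alpha = cfg.expansion_dirichlet_alpha[genotype]
        for m in range(cfg.n_mice_per_genotype):
            mouse = f"{mouse_tag[genotype]}{m + 1}"
            n_col = int(rng.integers(cfg.colonies_per_sample[0],
                                     cfg.colonies_per_sample[1] + 1))
            n_founders = int(rng.integers(cfg.n_founders_range[0],
                                          cfg.n_founders_range[1] + 1))
            founders = [make_founder() for _ in range(n_founders)]
            if (shared is not None and genotype == "+/+"
                    and m < cfg.n_stereotype_mice):
                founders[0] = shared
            fractions = rng.dirichlet(np.full(n_founders, alpha))
            counts = rng.multinomial(n_col, fractions)
            order = np.argsort(-counts)
            idx = 0
            for rank in order:
                count = int(counts[rank])
                if count == 0:
                    continue
                seq, clone_truth = founders[rank]
                rid = f"{mouse}_spleen_c{idx + 1}"
                idx += 1
                records.append(CloneRecord(
                    record_id=rid, mouse_id=mouse, genotype=genotype,
                    tissue="spleen", sequence=seq, colony_count=count))
                entry = CloneTruth(**{**asdict(clone_truth),
                                      "fraction": count / n_col})
                truth.clones[rid] = entry
                if genotype == "+/+" and (mouse not in dominant
                                          or count / n_col > dominant[mouse][1].fraction):
                    dominant[mouse] = (seq, entry)

    # Allotransplanted F1 recipients re-expand one parental clone.
    f1_parents = sorted(dominant)[:cfg.n_f1_recipients]
    for parent in f1_parents:
        seq, parent_truth = dominant[parent]
        mouse = f"{parent} F1"
        n_col = int(rng.integers(cfg.colonies_per_sample[0],
                                 cfg.colonies_per_sample[1] + 1))
        rid = f"{mouse_tag['+/+']}f1_{parent}_spleen_c1"
        records.append(CloneRecord(
            record_id=rid, mouse_id=mouse, genotype="+/+", tissue="spleen",
            sequence=seq, is_allotransplant=True, parental_mouse_id=parent,
            colony_count=n_col))
        truth.clones[rid] = CloneTruth(**{**asdict(parent_truth), "fraction": 1.0})

    return SimulatedCohort(records=records, truth=truth, base_germline=base,
                           strain_germline=strain, j_w_offsets=j_w_offsets)


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "ssp": {gene: [[p, a, b] for p, a, b in entries]
                for gene, entries in truth.ssp.items()},
        "clones": {rid: asdict(ct) for rid, ct in truth.clones.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
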