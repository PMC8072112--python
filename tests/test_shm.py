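"""SSP calling, SHM correction and UM/M classification."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ighrep.annotate import VDJAnnotation
from ighrep.io import CloneRecord
from ighrep.shm import (GeneGroup, MutationCall, SSPEntry, call_ssps,
                        classify_status, compute_corrected_shm,
                        group_clones_by_gene)

V294 = "ACGT" * 74  # placeholder clone sequence for metadata-only records


def make_item(record_id, mouse, mismatches, gene="IGHV1-1*01"):
    rec = CloneRecord(record_id=record_id, mouse_id=mouse, genotype="+/+",
                      tissue="spleen", sequence=V294)
    ann = VDJAnnotation(v_call=gene, v_mismatches=list(mismatches),
                        v_aligned_columns=294)
    return rec, ann


def make_group(spec, gene="IGHV1-1*01"):
    """spec: list of (mouse_id, [(pos, germ, obs), ...])"""
    items = [make_item(f"c{i}", mouse, mm, gene)
             for i, (mouse, mm) in enumerate(spec)]
    return GeneGroup(gene=gene, items=items)


class TestGrouping:
    def test_groups_cross_mice_and_eligibility(self):
        items = [make_item(f"c{i}", f"m{i % 4}", []) for i in range(5)]
        items += [make_item("x0", "m0", [], gene="IGHV2-1*01"),
                  make_item("x1", "m1", [], gene="IGHV2-1*01")]
        groups = group_clones_by_gene(items)
        assert groups["IGHV1-1*01"].eligible
        assert groups["IGHV1-1*01"].n_mice == 4
        assert not groups["IGHV2-1*01"].eligible

    def test_failed_annotations_are_skipped(self):
        rec, ann = make_item("c0", "m0", [])
        ann.failed = True
        assert group_clones_by_gene([(rec, ann)]) == {}

    def test_empty_cohort(self):
        assert group_clones_by_gene([]) == {}


class TestCallSSPs:
    def test_unanimous_shared_mismatch_is_ssp(self):
        mm = [(57, "G", "A")]
        group = make_group([("m1", mm), ("m1", mm), ("m2", mm),
                            ("m3", mm), ("m3", mm)])
        entries = call_ssps(group)
        assert entries == [SSPEntry(57, "G", "A", support=5, n_mice=3, n_group=5)]

    def test_private_mismatch_stays_shm_candidate(self):
        group = make_group([("m1", [(120, "C", "T")]), ("m2", []), ("m3", []),
                            ("m4", []), ("m5", [])])
        assert call_ssps(group) == []

    def test_single_mouse_majority_is_not_ssp(self):
        # 3/5 clones share the mismatch but all come from one mouse:
        # likely clonal hypermutation, not an inherited polymorphism
        mm = [(33, "A", "G")]
        group = make_group([("m1", mm), ("m1", mm), ("m1", mm),
                            ("m2", []), ("m3", [])])
        assert call_ssps(group) == []

    def test_same_position_different_base_not_pooled(self):
        group = make_group([("m1", [(10, "A", "G")]), ("m2", [(10, "A", "G")]),
                            ("m3", [(10, "A", "C")]), ("m4", [(10, "A", "C")])])
        # neither variant reaches a strict majority of the 4 clones
        assert call_ssps(group) == []

    def test_ineligible_group_rejected(self):
        group = make_group([("m1", []), ("m2", [])])
        with pytest.raises(ValueError, match="fewer than"):
            call_ssps(group)

    def test_invalid_fraction_rejected(self):
        group = make_group([("m1", []), ("m2", []), ("m3", [])])
        with pytest.raises(ValueError, match="min_fraction"):
            call_ssps(group, min_fraction=0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_brute_force_enumeration(self, data):
        n_clones = data.draw(st.integers(3, 6))
        spec = []
        for i in range(n_clones):
            mouse = data.draw(st.integers(0, 3))
            mm = data.draw(st.lists(
                st.tuples(st.integers(1, 30), st.just("A"),
                          st.sampled_from("CGT")),
                max_size=5, unique_by=lambda t: t[0]))
            spec.append((f"m{mouse}", mm))
        group = make_group(spec)
        called = {(e.v_position, e.observed_nt) for e in call_ssps(group)}
        brute = set()
        for pos, obs in product(range(1, 31), "CGT"):
            carriers = [m for m, mm in spec if (pos, "A", obs) in mm]
            if len(carriers) > 0.5 * n_clones and len(set(carriers)) >= 2:
                brute.add((pos, obs))
        assert called == brute

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_raising_min_fraction_never_adds_ssps(self, data):
        spec = []
        for i in range(data.draw(st.integers(3, 6))):
            mouse = data.draw(st.integers(0, 2))
            mm = data.draw(st.lists(
                st.tuples(st.integers(1, 10), st.just("A"), st.just("G")),
                max_size=3, unique_by=lambda t: t[0]))
            spec.append((f"m{mouse}", mm))
        group = make_group(spec)
        f1, f2 = sorted(data.draw(st.tuples(
            st.floats(0.1, 0.9), st.floats(0.1, 0.9))))
        low = {(e.v_position, e.observed_nt) for e in call_ssps(group, f1)}
        high = {(e.v_position, e.observed_nt) for e in call_ssps(group, f2)}
        assert high <= low


class TestCorrectedSHM:
    def test_one_residual_mismatch_on_286nt_alignment(self):
        ssps = [SSPEntry(p, "A", "G", 5, 3, 5) for p in (10, 20, 30)]
        ann = VDJAnnotation(v_call="g", v_aligned_columns=286,
                           v_mismatches=[(10, "A", "G"), (20, "A", "G"),
                                         (30, "A", "G"), (99, "C", "T")])
        call = compute_corrected_shm(ann, ssps)
        assert call == MutationCall(raw_mismatches=4, ssp_count=3, shm_count=1,
                                    shm_percent=0.35, status="UM")

    def test_all_mismatches_polymorphic_on_256nt_alignment(self):
        positions = list(range(1, 25))
        ssps = [SSPEntry(p, "A", "G", 4, 2, 4) for p in positions]
        ann = VDJAnnotation(v_call="g", v_aligned_columns=256,
                           v_mismatches=[(p, "A", "G") for p in positions])
        call = compute_corrected_shm(ann, ssps)
        assert call.ssp_count == 24
        assert call.shm_percent == 0.0
        assert round(100 * call.ssp_count / 256, 3) == 9.375

    def test_position_match_alone_is_not_enough(self):
        # same position but a different substituted base stays SHM
        ssps = [SSPEntry(10, "A", "G", 5, 3, 5)]
        ann = VDJAnnotation(v_call="g", v_aligned_columns=294,
                           v_mismatches=[(10, "A", "C")])
        assert compute_corrected_shm(ann, ssps).shm_count == 1

    def test_clean_clone(self):
        ann = VDJAnnotation(v_call="g", v_aligned_columns=294)
        call = compute_corrected_shm(ann, [])
        assert (call.shm_percent, call.status) == (0.0, "UM")

    def test_conservation_on_simulated_cohort(self, annotated_cohort):
        _, _, annotated = annotated_cohort
        frame = annotated_cohort[0]
        raw = {rec.record_id: len(ann.v_mismatches) for rec, ann in annotated}
        for _, row in frame.iterrows():
            assert row["ssp_count"] + row["shm_count"] == raw[row["sequence_id"]]


class TestClassification:
    @pytest.mark.parametrize("percent,status", [
        (1.1, "UM"), (2.1, "M"), (2.0, "UM"), (0.0, "UM"), (4.9, "M")])
    def test_two_percent_boundary(self, percent, status):
        assert classify_status(percent) == status

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_status(-0.1)


class TestRecovery:
    def test_planted_ssps_and_status_recovered(self, cohort, annotated_cohort):
        frame, ssp_table, annotated = annotated_cohort
        groups = group_clones_by_gene(annotated)
        tp = fp = fn = 0
        evaluated_genes = set()
        for gene, grp in groups.items():
            if not (grp.eligible and grp.n_mice >= 2):
                continue
            evaluated_genes.add(gene)
            called = {(e.v_position, e.observed_nt) for e in ssp_table[gene]}
            planted = {(p, nt) for p, _, nt in cohort.truth.ssp[gene]}
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        assert evaluated_genes
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9

        corrected = frame[~frame["sequence_id"].isin(
            [rec.record_id for gene, grp in groups.items()
             if gene not in evaluated_genes for rec, _ in grp.items])]
        match = sum(row["mutation_status"] == cohort.truth.clones[row["sequence_id"]].status
                    for _, row in corrected.iterrows())
        assert match / len(corrected) >= 0.95
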