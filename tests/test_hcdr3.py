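"""Isoelectric point, HCDR3 features, clonotype dedup and stereotypy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ighrep.hcdr3 import (AMINO_ACIDS, canonicalize_clones, compute_pi,
                          detect_stereotypes, hcdr3_features,
                          mutation_status_summary, peptide_charge,
                          similarity_search)

# HCDR3 sequences with their published isoelectric points.
PUBLISHED_PI = [
    ("GRDDGYYYAMDY", 3.93), ("AREGPRRDYYAMDY", 6.16), ("ASYAFAY", 5.57),
    ("ASRSTMIIMDY", 5.88), ("ASPSYDYPYYYAMDY", 3.56),
    ("ATYYGYDRVYYYAMDY", 4.21), ("ARGDYDGEFAY", 4.03), ("ASGYDYAMDY", 3.56),
    ("ARGNWDFYYAMDY", 4.21), ("AVYVIYDGYYGAMDY", 3.56), ("ARGGDY", 5.88),
    ("ALGAGYFDY", 3.80), ("ARGNDGSYWYFDV", 4.21), ("ARIRGGAMDY", 8.79),
    ("ARVRNWDFEDY", 4.56), ("ASGPDFDY", 3.56), ("ARGGYYGYDGDYYAMDY", 3.93),
]


def grid_pi(seq, step=5e-4):
    """Independent oracle: fine-grid scan for the zero-charge pH."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([peptide_charge(seq, ph) for ph in grid])
    return float(grid[np.argmin(np.abs(charges))])


class TestComputePI:
    @pytest.mark.parametrize("seq,expected", PUBLISHED_PI)
    def test_published_values(self, seq, expected):
        assert compute_pi(seq) == pytest.approx(expected, abs=0.005)

    def test_no_sidechain_peptide_matches_oracle(self):
        # only N-terminus (7.50) and C-terminus (3.55) ionise
        assert compute_pi("GGGG") == pytest.approx(round(grid_pi("GGGG"), 2), abs=0.01)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=20))
    def test_matches_grid_oracle(self, seq):
        assert abs(compute_pi(seq) - grid_pi(seq)) < 0.011

    def test_interior_permutation_invariance(self):
        # interior free of D/E and of position-specific pKa effects
        base = "ARGYKSWG"
        rng = np.random.default_rng(3)
        for _ in range(10):
            interior = list(base[1:-1])
            rng.shuffle(interior)
            assert compute_pi(base[0] + "".join(interior) + base[-1]) == compute_pi(base)

    def test_monotone_in_charged_appends(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            seq = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(2, 12)))
            assert compute_pi(seq + "R") >= compute_pi(seq) - 0.011
            assert compute_pi(seq + "D") <= compute_pi(seq) + 0.011

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_pi("")
        with pytest.raises(ValueError):
            compute_pi("ARGX")


class TestFeatures:
    @pytest.mark.parametrize("seq,length", [
        ("ARGGYYGYDGDYYAMDY", 17), ("ASYAFAY", 7), ("Y", 1)])
    def test_lengths(self, seq, length):
        assert hcdr3_features(seq).length == length

    def test_composition_fractions(self):
        feats = hcdr3_features("ASYAFAY")
        assert feats.frac_tyrosine == pytest.approx(2 / 7)
        assert feats.frac_acidic == 0.0
        assert hcdr3_features("Y").frac_tyrosine == 1.0
        acidic = hcdr3_features("GRDDGYYYAMDY")
        assert acidic.frac_acidic == pytest.approx(3 / 12)
        assert acidic.frac_basic == pytest.approx(1 / 12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hcdr3_features("")


class TestCanonicalization:
    def test_twenty_canonical_expanded_clones(self, canonical, expanded):
        assert len(canonical) == 20
        assert len(expanded) == 20

    def test_cross_tissue_clone_counted_once(self, canonical):
        hits = [c for c in canonical if c.cdr3_aa == "ASRSTMIIMDY"]
        assert len(hits) == 1
        assert hits[0].tissues == frozenset({"spleen", "blood"})

    def test_f1_clone_attributed_to_parent(self, canonical):
        hits = [c for c in canonical if c.cdr3_aa == "ARGGDY"]
        assert len(hits) == 1
        assert hits[0].mouse_id == "55"

    def test_idempotent_and_bounded(self, table1, canonical):
        assert len(canonical) <= len(table1)
        keys = [c.key for c in canonical]
        assert len(keys) == len(set(keys))

    def test_removing_f1_rows_preserves_count(self, table1, canonical):
        trimmed = table1[~table1["is_allotransplant"]]
        assert len(canonicalize_clones(trimmed)) == len(canonical)

    def test_expansion_threshold(self, table1):
        low = table1.copy()
        low["colony_count"] = 1
        low["total_colonies"] = 10
        clones = canonicalize_clones(low)
        assert not any(c.is_expanded for c in clones)

    def test_orphan_f1_record_rejected(self, table1):
        bad = table1.copy()
        bad.loc[bad["is_allotransplant"], "parental_mouse_id"] = ""
        with pytest.raises(ValueError, match="parental"):
            canonicalize_clones(bad)


class TestMutationSummary:
    def test_published_um_m_split(self, canonical):
        assert mutation_status_summary(canonical, expanded_only=True) == (85, 15)

    def test_all_unmutated(self, canonical):
        um_only = [c for c in canonical if c.mutation_status == "UM"]
        assert mutation_status_summary(um_only) == (100, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mutation_status_summary([])


class TestStereotypy:
    def test_published_sets_and_percent(self, expanded):
        sets, pct = detect_stereotypes(expanded)
        by_cdr3 = {s.cdr3_aa: s.n_mice for s in sets}
        assert by_cdr3 == {"ASGYDYAMDY": 2, "GRDDGYYYAMDY": 3}
        assert pct == pytest.approx(25.0)

    def test_invariant_to_mouse_relabeling(self, expanded):
        relabeled = []
        for c in expanded:
            clone = type(c)(**{**c.__dict__, "mouse_id": "m" + c.mouse_id})
            relabeled.append(clone)
        sets, pct = detect_stereotypes(relabeled)
        assert {s.cdr3_aa for s in sets} == {"ASGYDYAMDY", "GRDDGYYYAMDY"}
        assert pct == pytest.approx(25.0)

    def test_single_mouse_duplicates_do_not_form_set(self, expanded):
        same_mouse = [c for c in expanded if c.mouse_id == "13"]
        doubled = same_mouse + same_mouse
        sets, pct = detect_stereotypes(doubled)
        assert sets == []
        assert pct == 0.0

    def test_distinct_cohort_yields_nothing(self, expanded):
        unique = [c for c in expanded
                  if c.cdr3_aa not in ("ASGYDYAMDY", "GRDDGYYYAMDY")]
        sets, pct = detect_stereotypes(unique)
        assert sets == [] and pct == 0.0

    def test_hamming_mode_merges_near_identical(self, expanded):
        sets0, _ = detect_stereotypes(expanded, max_hamming=0)
        sets1, _ = detect_stereotypes(expanded, max_hamming=1)
        assert len(sets1) >= len(sets0) - 1  # merging can only coarsen


class TestSimilaritySearch:
    REF = [("ASGYDYAMDY", "phosphatidylcholine"), ("AAAT", "cardiolipin"),
           ("WWWWWWWW", "decoy")]

    def test_identical_query_scores_100(self):
        hits = similarity_search("ASGYDYAMDY", self.REF)
        assert hits[0]["similarity"] == 100.0
        assert hits[0]["antigen"] == "phosphatidylcholine"

    def test_three_quarters_identity(self):
        hits = similarity_search("AAAA", self.REF, min_similarity=70.0)
        assert any(h["similarity"] == 75.0 and h["antigen"] == "cardiolipin"
                   for h in hits)

    def test_low_similarity_excluded(self):
        hits = similarity_search("AAAA", self.REF, min_similarity=75.0)
        assert all(h["antigen"] != "decoy" for h in hits)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            similarity_search("AAAA", [])
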