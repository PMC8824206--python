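"""Domain-hit parsing, filtering, overlap resolution, and family assignment."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from pupminer.annotate import (
    DomainHit,
    DomtblParseError,
    SimilarityEvidence,
    assign_families,
    filter_hits,
    parse_domain_hits,
    resolve_overlaps,
)

from conftest import make_catalog


def hit(
    domain="Dom",
    evalue=1e-10,
    hmm_from=1,
    hmm_to=90,
    hmm_length=100,
    ali_from=1,
    ali_to=90,
    protein="p1",
):
    return DomainHit(
        protein_id=protein,
        domain_name=domain,
        evalue=evalue,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        hmm_length=hmm_length,
        ali_from=ali_from,
        ali_to=ali_to,
    )


def domtbl_row(domain="Dom", protein="p1", tlen=100, qlen=300, ievalue=1e-10,
               hmm=(5, 90), ali=(1, 86)):
    return (
        f"{domain} - {tlen} {protein} - {qlen} {ievalue} 50.0 0.1 1 1 "
        f"{ievalue} {ievalue} 49.0 0.1 {hmm[0]} {hmm[1]} {ali[0]} {ali[1]} "
        f"{ali[0]} {ali[1]} 0.9 some description here\n"
    )


class TestParseDomainHits:
    def test_parses_rows_and_skips_comments(self):
        text = "# comment\n" + domtbl_row() + domtbl_row(domain="Other") + domtbl_row()
        hits = parse_domain_hits(io.StringIO(text))
        assert len(hits) == 3
        assert hits[1].domain_name == "Other"

    def test_comment_only_table_is_empty(self):
        assert parse_domain_hits(io.StringIO("# a\n# b\n")) == []

    def test_coverage_from_hmm_span(self):
        (h,) = parse_domain_hits(io.StringIO(domtbl_row(hmm=(5, 90), tlen=100)))
        assert h.coverage == pytest.approx(0.86)

    def test_wrong_column_count_names_line(self):
        with pytest.raises(DomtblParseError, match="line 2"):
            parse_domain_hits(io.StringIO(domtbl_row() + "too few columns\n"))

    def test_independent_evalue_column_used(self):
        row = domtbl_row().split()
        row[6] = "1e-99"  # full-sequence E-value must be ignored
        row[12] = "2e-07"
        (h,) = parse_domain_hits(io.StringIO(" ".join(row) + "\n"))
        assert h.evalue == pytest.approx(2e-07)


class TestFilterHits:
    def test_homolog_mode_keeps_passing_hit(self):
        h = hit(evalue=1e-6, hmm_to=70)  # coverage 0.7
        assert filter_hits([h], "homolog") == [h]

    def test_boundary_evalue_rejected_in_both_modes(self):
        h = hit(evalue=1e-5, hmm_to=90)
        assert filter_hits([h], "seed") == []
        assert filter_hits([h], "homolog") == []

    def test_coverage_threshold_differs_by_mode(self):
        h = hit(evalue=1e-10, hmm_to=50)  # coverage 0.5
        assert filter_hits([h], "homolog") == []
        assert filter_hits([h], "seed") == [h]

    def test_boundary_coverage_rejected(self):
        h = hit(evalue=1e-10, hmm_from=1, hmm_to=60, hmm_length=100)  # exactly 0.6
        assert filter_hits([h], "homolog") == []

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-30, max_value=1.0),
                st.integers(min_value=1, max_value=100),
            ),
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_idempotence(self, raw):
        hits = [hit(evalue=e, hmm_to=span) for e, span in raw]
        once = filter_hits(hits, "homolog")
        assert filter_hits(once, "homolog") == once


class TestResolveOverlaps:
    def test_nested_hit_with_worse_evalue_dropped(self):
        a = hit(domain="A", evalue=1e-20, ali_from=1, ali_to=100)
        b = hit(domain="B", evalue=1e-6, ali_from=10, ali_to=90)
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_hits_kept(self):
        a = hit(domain="A", ali_from=1, ali_to=50)
        b = hit(domain="B", ali_from=60, ali_to=120)
        assert resolve_overlaps([a, b]) == [a, b]

    def test_half_overlap_boundary_keeps_both(self):
        # overlap of exactly 50% of the shorter alignment is tolerated
        a = hit(domain="A", ali_from=1, ali_to=100)
        b = hit(domain="B", ali_from=51, ali_to=150)
        assert len(resolve_overlaps([a, b])) == 2

    def test_equal_tie_broken_by_domain_name(self):
        a = hit(domain="Zeta", evalue=1e-10, ali_from=1, ali_to=100)
        b = hit(domain="Alpha", evalue=1e-10, ali_from=1, ali_to=100)
        assert resolve_overlaps([a, b]) == [b]

    def test_multiple_proteins_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            resolve_overlaps([hit(protein="p1"), hit(protein="p2")])


@pytest.fixture
def two_family_catalog():
    return make_catalog(
        {
            "OR6": ({"HpaB", "HpaB_N"}, {"s6"}),
            "FR1": ({"Alpha-amylase"}, {"s1"}),
            "HR1": ({"Glyco_hydro_1"}, {"s2"}),
            "UC1": (set(), {"s3"}),
        }
    )


class TestAssignFamilies:
    def test_full_combination_required_and_sufficient(self, two_family_catalog):
        hits = {
            "p1": [hit(domain="HpaB", ali_to=50), hit(domain="HpaB_N", ali_from=60, ali_to=120)],
            "p2": [hit(domain="HpaB")],
        }
        anns = assign_families(hits, two_family_catalog)
        assert [(a.protein_id, a.family_id) for a in anns] == [("p1", "OR6")]
        assert {h.domain_name for h in anns[0].supporting_hits} == {"HpaB", "HpaB_N"}

    def test_multi_family_protein_reported_twice_with_flag(self, two_family_catalog):
        hits = {
            "p1": [
                hit(domain="Alpha-amylase", ali_to=50),
                hit(domain="Glyco_hydro_1", ali_from=60, ali_to=120),
            ]
        }
        anns = assign_families(hits, two_family_catalog)
        assert {a.family_id for a in anns} == {"FR1", "HR1"}
        assert all(a.multi_family for a in anns)

    def test_hit_order_invariance(self, two_family_catalog):
        h1 = hit(domain="HpaB", ali_to=50)
        h2 = hit(domain="HpaB_N", ali_from=60, ali_to=120)
        a = assign_families({"p1": [h1, h2]}, two_family_catalog)
        b = assign_families({"p1": [h2, h1]}, two_family_catalog)
        assert [(x.protein_id, x.family_id) for x in a] == [
            (x.protein_id, x.family_id) for x in b
        ]

    def test_uc_assignment_from_similarity_evidence(self, two_family_catalog):
        sim = {
            "p9": [
                SimilarityEvidence("p9", "UC1", "seedX", 1e-6),
                SimilarityEvidence("p9", "UC1", "seedY", 0.5),  # fails contract
            ]
        }
        anns = assign_families({}, two_family_catalog, similarity_hits=sim)
        assert [(a.family_id, a.evidence) for a in anns] == [("UC1", "similarity_search")]
        assert len(anns[0].supporting_hits) == 1

    def test_similarity_hits_above_cutoff_ignored(self, two_family_catalog):
        sim = {"p9": [SimilarityEvidence("p9", "UC1", "seedX", 0.01)]}
        assert assign_families({}, two_family_catalog, similarity_hits=sim) == []

    def test_unknown_family_in_similarity_hits_rejected(self, two_family_catalog):
        sim = {"p9": [SimilarityEvidence("p9", "ZZ9", "seedX", 1e-6)]}
        with pytest.raises(KeyError, match="ZZ9"):
            assign_families({}, two_family_catalog, similarity_hits=sim)

    def test_exact_signature_proteins_recovered_perfectly(self, two_family_catalog):
        # one protein per signature family carrying exactly its signature
        hits = {}
        expected = set()
        for fid, fam in two_family_catalog.families.items():
            if not fam.signature_domains:
                continue
            hits[f"prot_{fid}"] = [
                hit(domain=d, ali_from=1 + 200 * i, ali_to=150 + 200 * i)
                for i, d in enumerate(sorted(fam.signature_domains))
            ]
            expected.add((f"prot_{fid}", fid))
        anns = assign_families(hits, two_family_catalog)
        assert {(a.protein_id, a.family_id) for a in anns} == expected
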