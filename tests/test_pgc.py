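"""PGC detection rules, oracle equivalence, and substrate inference."""

import numpy as np
import pytest

from pupminer.pgc import (
    PGC,
    detect_pgcs,
    infer_substrates,
    intergenic_gap,
    load_gene_features,
    pgc_summary,
    read_pgc_table,
    write_pgc_table,
)
from pupminer.annotate import PupAnnotation, SimilarityEvidence

from conftest import brute_force_pgc_windows, make_catalog, make_gene, random_contig


class TestIntergenicGap:
    def test_gap_counts_bases_strictly_between(self):
        assert intergenic_gap(make_gene("a", 1, 1000), make_gene("b", 1200, 1500)) == 199

    def test_adjacent_genes_have_zero_gap(self):
        assert intergenic_gap(make_gene("a", 1, 1000), make_gene("b", 1001, 1500)) == 0

    def test_overlap_floors_at_zero(self):
        assert intergenic_gap(make_gene("a", 1, 500), make_gene("b", 400, 900)) == 0

    def test_different_contigs_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            intergenic_gap(
                make_gene("a", 1, 10, contig="c1"), make_gene("b", 20, 30, contig="c2")
            )


class TestDetectPgcs:
    def test_two_pups_with_one_intervening_gene(self):
        genes = [
            make_gene("p1", 100, 1000, {"FR1"}),
            make_gene("o1", 1200, 1500),
            make_gene("p2", 1600, 2400, {"HR1"}),
        ]
        (pgc,) = detect_pgcs(genes)
        assert (pgc.n_pup, pgc.n_other) == (2, 1)
        assert pgc.span == (100, 2400)

    def test_four_intervening_genes_break_the_cluster(self):
        genes = [make_gene("p1", 100, 400, {"FR1"})]
        pos = 500
        for i in range(4):
            genes.append(make_gene(f"o{i}", pos, pos + 200))
            pos += 300
        genes.append(make_gene("p2", pos, pos + 300, {"FR1"}))
        assert detect_pgcs(genes) == []

    def test_gap_of_1099_breaks_the_cluster(self):
        genes = [
            make_gene("p1", 100, 1000, {"FR1"}),
            make_gene("p2", 2100, 2900, {"FR1"}),
        ]
        assert detect_pgcs(genes) == []

    def test_gap_of_999_links(self):
        genes = [
            make_gene("p1", 100, 1000, {"FR1"}),
            make_gene("p2", 2000, 2900, {"FR1"}),  # gap 999 < 1000
        ]
        assert len(detect_pgcs(genes)) == 1

    def test_clusters_trimmed_to_pup_boundaries(self):
        genes = [
            make_gene("o0", 10, 50),
            make_gene("p1", 100, 400, {"FR1"}),
            make_gene("p2", 500, 900, {"FR1"}),
            make_gene("o1", 1000, 1200),
        ]
        (pgc,) = detect_pgcs(genes)
        assert [g.gene_id for g in pgc.genes] == ["p1", "p2"]

    def test_unsorted_input_rejected(self):
        genes = [make_gene("b", 500, 900, {"FR1"}), make_gene("a", 1, 100, {"FR1"})]
        with pytest.raises(ValueError, match="sorted"):
            detect_pgcs(genes)

    def test_emitted_pgcs_revalidate_all_rules(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            for pgc in detect_pgcs(random_contig(rng)):
                assert pgc.validates_rules()

    def test_agrees_with_window_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            genes = random_contig(rng)
            detected = {
                (
                    genes.index(p.genes[0]),
                    genes.index(p.genes[-1]),
                )
                for p in detect_pgcs(genes)
            }
            assert detected == brute_force_pgc_windows(genes)

    def test_monotone_in_gap_and_between_parameters(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            genes = random_contig(rng)

            def pup_count(**kw):
                return sum(p.n_pup for p in detect_pgcs(genes, **kw))

            assert pup_count(max_gap_bp=1500) >= pup_count(max_gap_bp=1000)
            assert pup_count(max_between=4) >= pup_count(max_between=3)

    def test_invariant_under_coordinate_translation(self):
        rng = np.random.default_rng(9)
        genes = random_contig(rng)
        shifted = [
            make_gene(g.gene_id, g.start + 10_000, g.end + 10_000, set(g.family_ids))
            for g in genes
        ]
        ids = lambda pgcs: [[g.gene_id for g in p.genes] for p in pgcs]
        assert ids(detect_pgcs(genes)) == ids(detect_pgcs(shifted))


class TestLoadGeneFeatures:
    GFF = (
        "##gff-version 3\n"
        "c1\tsrc\tCDS\t300\t600\t.\t+\t0\tID=g2\n"
        "c1\tsrc\tCDS\t1\t200\t.\t+\t0\tID=g1\n"
        "c2\tsrc\tCDS\t50\t400\t.\t-\t0\tID=g3\n"
    )

    def _annotations(self):
        ev = SimilarityEvidence("g1", "FR1", "", 1e-9)
        return [PupAnnotation("g1", "FR1", "similarity_search", (ev,))]

    def test_sorted_per_contig_with_pup_flags(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(self.GFF)
        by_contig = load_gene_features(gff, self._annotations())
        assert sorted(by_contig) == ["c1", "c2"]
        assert [g.gene_id for g in by_contig["c1"]] == ["g1", "g2"]
        assert by_contig["c1"][0].is_pup and not by_contig["c1"][1].is_pup

    def test_missing_id_attribute_reported(self, tmp_path):
        gff = tmp_path / "b.gff3"
        gff.write_text("##gff-version 3\nc1\tsrc\tCDS\t1\t200\t.\t+\t0\tName=x\n")
        with pytest.raises(ValueError, match="ID attribute"):
            load_gene_features(gff, [])


@pytest.fixture
def substrate_catalog():
    return make_catalog(
        {
            "FR1": ({"A"}, {"daidzin"}),
            "HR1": ({"B"}, {"luteolin"}),
            "OR1": ({"C"}, {"genistein"}),
        }
    )


def cluster_of(families_per_gene):
    genes = []
    pos = 100
    for i, fams in enumerate(families_per_gene):
        genes.append(make_gene(f"g{i}", pos, pos + 300, fams))
        pos += 400
    return PGC(pgc_id="x", contig="c", genes=tuple(genes))


class TestInferSubstrates:
    def test_majority_wins(self, substrate_catalog):
        pgc = cluster_of([{"FR1"}, {"FR1"}, {"HR1"}])
        assert infer_substrates(pgc, substrate_catalog) == {"daidzin"}

    def test_tie_returns_both(self, substrate_catalog):
        pgc = cluster_of([{"FR1"}, {"HR1"}])
        assert infer_substrates(pgc, substrate_catalog) == {"daidzin", "luteolin"}

    def test_unanimous_group(self, substrate_catalog):
        pgc = cluster_of([{"OR1"}, {"OR1"}])
        assert infer_substrates(pgc, substrate_catalog) == {"genistein"}

    def test_gene_with_two_families_votes_once_per_substrate(self, substrate_catalog):
        # one gene in both FR1 and HR1, plus one OR1 gene: three-way tie
        pgc = cluster_of([{"FR1", "HR1"}, {"OR1"}])
        assert infer_substrates(pgc, substrate_catalog) == {
            "daidzin",
            "luteolin",
            "genistein",
        }

    def test_family_without_substrates_excluded_with_warning(self):
        cat = make_catalog({"FR1": ({"A"}, {"daidzin"}), "HR1": ({"B"}, set())})
        pgc = cluster_of([{"FR1"}, {"HR1"}])
        with pytest.warns(UserWarning, match="excluded"):
            assert infer_substrates(pgc, cat) == {"daidzin"}


class TestSummaryAndIo:
    def test_size_histogram(self, substrate_catalog):
        pgcs = [cluster_of([{"FR1"}, {"FR1"}]), cluster_of([{"FR1"}, set(), {"HR1"}])]
        summary = pgc_summary(pgcs)
        assert summary.size_hist == {2: 1, 3: 1}

    def test_pup_fraction(self):
        pgc = cluster_of([{"FR1"}, set(), {"FR1"}, set(), {"FR1"}, set(), {"FR1"}, set()])
        # trailing non-PUP genes do not occur in detected clusters, but the
        # summary is agnostic: 4 PUP of 8 genes
        summary = pgc_summary([pgc])
        assert summary.size_hist == {8: 1}
        assert summary.pup_fraction == pytest.approx(0.5)

    def test_empty_input(self):
        summary = pgc_summary([])
        assert summary.size_hist == {} and summary.substrate_hist == {}

    def test_table_round_trip(self, tmp_path, substrate_catalog):
        pgc = cluster_of([{"FR1"}, set(), {"HR1"}])
        pgc.substrates = infer_substrates(pgc, substrate_catalog)
        path = tmp_path / "pgcs.tsv"
        write_pgc_table([pgc], path)
        (again,) = read_pgc_table(path)
        assert [g.gene_id for g in again.genes] == [g.gene_id for g in pgc.genes]
        assert again.substrates == pgc.substrates
        assert again.span == pgc.span
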