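import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbplandscape.data_io import (
    BinaryInteractionNetwork,
    FunctionalUnit,
    FunctionalUnitCompendium,
    GenomicInterval,
    ScoredInteractionMatrix,
    TranscriptModel,
    binarize,
    define_background,
    filter_compendium,
    filter_proteins_by_length,
    map_peaks_to_genes,
    read_edge_list,
    read_gene_sets,
    read_score_matrix,
    select_representative_transcripts,
    write_edge_list,
    write_gene_sets,
    write_score_matrix,
)


def unit(uid, members, source="complex"):
    return FunctionalUnit(uid, source, frozenset(members))


class TestGeneSets:
    def test_duplicate_members_collapse(self, tmp_path):
        p = tmp_path / "fu.gmt"
        p.write_text("U1\tcomplex\tg1\tg2\tg2\n")
        comp = read_gene_sets(p)
        assert comp.unit("U1").members == {"g1", "g2"}

    def test_empty_file_gives_empty_compendium(self, tmp_path):
        p = tmp_path / "fu.gmt"
        p.write_text("")
        assert len(read_gene_sets(p)) == 0

    @pytest.mark.parametrize(
        "content, fragment",
        [
            ("U1\tcomplex\n", "1"),  # no members: error names the line
            ("U1\tcomplex\tg1\nU1\tmodule\tg2\n", "duplicate"),
            ("justone\n", "field"),
        ],
    )
    def test_malformed_lines_rejected(self, tmp_path, content, fragment):
        p = tmp_path / "fu.gmt"
        p.write_text(content)
        with pytest.raises(ValueError, match=fragment):
            read_gene_sets(p)

    def test_round_trip(self, tmp_path):
        comp = FunctionalUnitCompendium(
            [unit("U1", ["g1", "g2"]), unit("U2", ["g3"], "pathway-A")]
        )
        p = tmp_path / "fu.gmt"
        write_gene_sets(comp, p)
        back = read_gene_sets(p)
        assert [(u.unit_id, u.source, u.members) for u in back] == [
            (u.unit_id, u.source, u.members) for u in comp
        ]


class TestFilterCompendium:
    universe = frozenset(f"g{i}" for i in range(600))

    def test_size_window_inclusive(self):
        comp = FunctionalUnitCompendium(
            [
                unit("small", [f"g{i}" for i in range(4)]),
                unit("edge_lo", [f"g{i}" for i in range(5)]),
                unit("edge_hi", [f"g{i}" for i in range(500)]),
            ]
        )
        kept = filter_compendium(comp, self.universe)
        assert [u.unit_id for u in kept] == ["edge_lo", "edge_hi"]

    def test_intersection_rule_drops_unit(self):
        # 10 members but only 3 in the universe -> below min size
        comp = FunctionalUnitCompendium(
            [unit("U", ["g1", "g2", "g3"] + [f"x{i}" for i in range(7)])]
        )
        assert len(filter_compendium(comp, self.universe)) == 0

    def test_members_restricted_to_universe(self):
        comp = FunctionalUnitCompendium([unit("U", ["g1", "g2", "g3", "g4", "g5", "zz"])])
        kept = filter_compendium(comp, self.universe)
        assert kept.unit("U").members == {"g1", "g2", "g3", "g4", "g5"}

    def test_idempotent(self):
        comp = FunctionalUnitCompendium(
            [unit(f"U{k}", [f"g{i}" for i in range(k)]) for k in (3, 7, 40)]
        )
        once = filter_compendium(comp, self.universe)
        twice = filter_compendium(once, self.universe)
        assert [(u.unit_id, u.members) for u in once] == [
            (u.unit_id, u.members) for u in twice
        ]

    def test_empty_universe_rejected(self):
        comp = FunctionalUnitCompendium([unit("U", ["g1"] * 1)])
        with pytest.raises(ValueError):
            filter_compendium(comp, frozenset())


class TestPeakMapping:
    transcripts = [
        TranscriptModel("t1", "G", GenomicInterval("chr1", 200, 400, "+"), 200),
        TranscriptModel("t2", "G", GenomicInterval("chr1", 600, 900, "+"), 300),
        TranscriptModel("t3", "H", GenomicInterval("chr1", 150, 300, "-"), 150),
        TranscriptModel("t4", "J", GenomicInterval("chr2", 0, 100, "+"), 100),
    ]

    def test_single_base_overlap_suffices(self):
        net = map_peaks_to_genes([("R", GenomicInterval("chr1", 150, 250))], self.transcripts)
        assert ("R", "G") in net.edges

    def test_isoforms_collapse_to_one_edge(self):
        peaks = [
            ("R", GenomicInterval("chr1", 210, 260)),
            ("R", GenomicInterval("chr1", 650, 700)),
        ]
        net = map_peaks_to_genes(peaks, self.transcripts)
        assert sum(1 for r, g in net.edges if g == "G") == 1

    def test_half_open_coordinates_no_touching_overlap(self):
        net = map_peaks_to_genes([("R", GenomicInterval("chr1", 100, 150))], self.transcripts)
        # peak ends exactly where t3 starts: zero shared bases
        assert ("R", "H") not in net.edges

    def test_universe_is_whole_transcript_table(self):
        net = map_peaks_to_genes([("R", GenomicInterval("chr1", 210, 220))], self.transcripts)
        assert net.genes == {"G", "H", "J"}

    def test_unmapped_chromosome_is_not_fatal(self, caplog):
        net = map_peaks_to_genes([("R", GenomicInterval("chrM", 0, 50))], self.transcripts)
        assert net.edges == frozenset()

    def test_invariant_under_duplication_and_order(self, rng):
        peaks = [
            ("R", GenomicInterval("chr1", 210, 260)),
            ("S", GenomicInterval("chr2", 50, 80)),
            ("R", GenomicInterval("chr1", 180, 230)),
        ]
        base = map_peaks_to_genes(peaks, self.transcripts)
        shuffled = list(peaks)[::-1] + peaks  # reordered and duplicated
        again = map_peaks_to_genes(shuffled, self.transcripts)
        assert base.edges == again.edges

    def test_stranded_mode_requires_matching_strand(self):
        peak = [("R", GenomicInterval("chr1", 200, 250, "-"))]
        relaxed = map_peaks_to_genes(peak, self.transcripts, stranded=False)
        strict = map_peaks_to_genes(peak, self.transcripts, stranded=True)
        assert ("R", "G") in relaxed.edges
        assert ("R", "G") not in strict.edges and ("R", "H") in strict.edges


class TestRepresentativeTranscripts:
    def make(self, tid, gene, length):
        return TranscriptModel(tid, gene, GenomicInterval("chr1", 0, 10), length)

    def test_longest_in_window_wins(self):
        mapping = select_representative_transcripts(
            [self.make("a", "G", 300), self.make("b", "G", 900)]
        )
        assert mapping == {"G": "b"}

    def test_gene_with_only_out_of_window_transcripts_absent(self):
        assert select_representative_transcripts([self.make("a", "G", 1500)]) == {}
        assert select_representative_transcripts([self.make("a", "G", 49)]) == {}

    def test_window_bounds_inclusive(self):
        mapping = select_representative_transcripts(
            [self.make("a", "G", 50), self.make("b", "H", 1200)]
        )
        assert mapping == {"G": "a", "H": "b"}

    def test_tie_breaks_to_lexicographically_smallest_id(self):
        mapping = select_representative_transcripts(
            [self.make("tB", "G", 700), self.make("tA", "G", 700), self.make("tC", "G", 700)]
        )
        assert mapping == {"G": "tA"}


class TestProteinLengthFilter:
    def test_inclusive_bounds(self):
        kept = filter_proteins_by_length({"a": 50, "b": 750, "c": 751, "d": 49, "e": 300})
        assert kept == {"a", "b", "e"}

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            filter_proteins_by_length({"a": 0})


class TestBinarize:
    def make_matrix(self, values):
        df = pd.DataFrame(values, index=["R1", "R2"], columns=["g1", "g2"])
        return ScoredInteractionMatrix(df.astype(float))

    def test_threshold_is_inclusive(self):
        m = self.make_matrix([[50.0, 49.99], [75.0, -10.0]])
        net = binarize(m)
        assert net.edges == {("R1", "g1"), ("R2", "g1")}
        assert net.genes == {"g1", "g2"}

    def test_empty_matrix(self):
        m = ScoredInteractionMatrix(pd.DataFrame(dtype=float))
        assert binarize(m).edges == frozenset()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scores=st.lists(
            st.floats(min_value=-100, max_value=200, allow_nan=False), min_size=4, max_size=4
        ),
        t1=st.floats(min_value=-50, max_value=150),
        t2=st.floats(min_value=-50, max_value=150),
    )
    def test_monotone_in_threshold(self, scores, t1, t2):
        lo, hi = sorted((t1, t2))
        m = self.make_matrix([scores[:2], scores[2:]])
        assert binarize(m, hi).edges <= binarize(m, lo).edges

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            self.make_matrix([[np.nan, 1.0], [0.0, 2.0]])


class TestBackground:
    def test_annotated_intersection(self):
        net = BinaryInteractionNetwork(
            frozenset({"R"}),
            frozenset({"g1", "g2", "g3", "g4", "g5"}),
            frozenset({("R", "g1")}),
        )
        comp = FunctionalUnitCompendium([unit("U1", ["g1", "g2"]), unit("U2", ["g9"])])
        assert define_background(net, comp) == {"g1", "g2"}

    def test_all_annotated_gives_universe(self):
        net = BinaryInteractionNetwork(frozenset({"R"}), frozenset({"g1", "g2"}), frozenset())
        comp = FunctionalUnitCompendium([unit("U", ["g1", "g2", "g3"])])
        assert define_background(net, comp) == net.genes

    def test_disjoint_is_an_error(self):
        net = BinaryInteractionNetwork(frozenset(), frozenset({"g1"}), frozenset())
        comp = FunctionalUnitCompendium([unit("U", ["zz"])])
        with pytest.raises(ValueError):
            define_background(net, comp)

    def test_full_universe_switch(self):
        net = BinaryInteractionNetwork(frozenset(), frozenset({"g1", "g2"}), frozenset())
        comp = FunctionalUnitCompendium([unit("U", ["g1"])])
        assert define_background(net, comp, use_full_universe=True) == {"g1", "g2"}


class TestRoundTrips:
    def test_edge_list_round_trip_preserves_universe(self, tmp_path):
        net = BinaryInteractionNetwork(
            frozenset({"R1", "R2"}),
            frozenset({"g1", "g2", "g3"}),
            frozenset({("R1", "g1"), ("R2", "g2")}),
        )
        p = tmp_path / "net.tsv"
        write_edge_list(net, p)
        back = read_edge_list(p)
        assert back.edges == net.edges and back.genes == net.genes

    def test_score_matrix_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(
            rng.normal(30, 10, size=(3, 4)),
            index=["R1", "R2", "R3"],
            columns=["g1", "g2", "g3", "g4"],
        )
        m = ScoredInteractionMatrix(df)
        p = tmp_path / "scores.tsv"
        write_score_matrix(m, p)
        back = read_score_matrix(p)
        assert np.allclose(back.scores.to_numpy(), df.to_numpy())
        assert list(back.scores.index) == list(df.index)


class TestIntervalValidation:
    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_empty_chrom_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
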