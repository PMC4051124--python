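import pytest
from hypothesis import given
from hypothesis import strategies as st

from geneconnectome import (
    AmbiguousAliasError,
    DataError,
    InteractionRecord,
    VariantRecord,
    read_aliases,
    read_gene_list,
    read_interactions,
    read_variants,
    write_interactions,
    write_table,
    write_variants,
)
from geneconnectome.netio import read_table


def tsv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadInteractions:
    def test_normalizes_scores_by_scale(self, tmp_path):
        p = tsv(tmp_path, "e.tsv", "TLR3\tTICAM1\t900\n")
        (rec,) = read_interactions(p, score_scale=1000)
        assert rec.pair == ("TICAM1", "TLR3")
        assert rec.score == pytest.approx(0.9)

    def test_duplicate_pairs_collapse_to_max_score(self, tmp_path):
        p = tsv(tmp_path, "e.tsv", "A\tB\t500\nB\tA\t700\n")
        (rec,) = read_interactions(p)
        assert (rec.gene_a, rec.gene_b, rec.score) == ("A", "B", pytest.approx(0.7))

    def test_self_loops_dropped_with_warning(self, tmp_path, caplog):
        p = tsv(tmp_path, "e.tsv", "A\tA\t800\nA\tB\t500\n")
        with caplog.at_level("WARNING"):
            records = read_interactions(p)
        assert [r.pair for r in records] == [("A", "B")]
        assert "self-loop" in caplog.text

    def test_header_row_skipped(self, tmp_path):
        p = tsv(tmp_path, "e.tsv", "gene_a\tgene_b\tscore\nA\tB\t500\n")
        assert len(read_interactions(p)) == 1

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tsv(tmp_path, "e.tsv", "A\tB\t500\nC\tD\n")
        with pytest.raises(DataError, match="line 2"):
            read_interactions(p)

    @pytest.mark.parametrize("raw", ["0", "-5", "1001"])
    def test_score_out_of_scale_rejected(self, tmp_path, raw):
        p = tsv(tmp_path, "e.tsv", f"A\tB\t{raw}\n")
        with pytest.raises(DataError):
            read_interactions(p)

    def test_symbols_upper_cased(self, tmp_path):
        p = tsv(tmp_path, "e.tsv", "tlr3\tTicam1\t900\n")
        (rec,) = read_interactions(p)
        assert rec.pair == ("TICAM1", "TLR3")

    @given(
        rows=st.lists(
            st.tuples(
                st.sampled_from(["A", "B", "C", "D"]),
                st.sampled_from(["A", "B", "C", "D"]),
                st.integers(min_value=1, max_value=1000),
            ),
            max_size=20,
        ),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_duplicate_collapse_is_order_independent(self, tmp_path_factory, rows, seed):
        import random

        shuffled = rows[:]
        random.Random(seed).shuffle(shuffled)
        base = tmp_path_factory.mktemp("perm")
        out = []
        for tag, rws in (("a", rows), ("b", shuffled)):
            p = base / f"{tag}.tsv"
            p.write_text("".join(f"{a}\t{b}\t{s}\n" for a, b, s in rws))
            out.append(set(read_interactions(p)))
        assert out[0] == out[1]

    def test_round_trip(self, tmp_path):
        records = [InteractionRecord("A", "B", 0.9), InteractionRecord("B", "C", 0.123)]
        p = tmp_path / "rt.tsv"
        write_interactions(records, p)
        assert read_interactions(p) == sorted(records)


class TestInteractionRecord:
    def test_pair_is_unordered(self):
        assert InteractionRecord("B", "A", 0.5) == InteractionRecord("A", "B", 0.5)

    def test_self_pair_rejected(self):
        with pytest.raises(DataError):
            InteractionRecord("A", "a", 0.5)

    @pytest.mark.parametrize("score", [0.0, -0.1, 1.5])
    def test_score_bounds(self, score):
        with pytest.raises(DataError):
            InteractionRecord("A", "B", score)


class TestAliases:
    ALIASES = (
        "alias\tcanonical\tfull_name\n"
        "TRIF\tTICAM1\tTIR domain containing adaptor molecule 1\n"
        "TICAM1\tTICAM1\tTIR domain containing adaptor molecule 1\n"
        "TLR3\tTLR3\tToll-like receptor 3\n"
    )

    def test_alias_resolves_to_canonical(self, tmp_path):
        amap = read_aliases(tsv(tmp_path, "a.tsv", self.ALIASES))
        assert amap.resolve("TRIF") == "TICAM1"

    def test_canonical_resolves_to_itself_with_full_name(self, tmp_path):
        amap = read_aliases(tsv(tmp_path, "a.tsv", self.ALIASES))
        assert amap.resolve("TLR3") == "TLR3"
        assert amap.full_name("TLR3") == "Toll-like receptor 3"

    def test_unknown_symbol_returns_none(self, tmp_path):
        amap = read_aliases(tsv(tmp_path, "a.tsv", self.ALIASES))
        assert amap.resolve("NOSUCHGENE") is None
        assert amap.full_name("NOSUCHGENE") == ""

    def test_conflicting_alias_raises(self, tmp_path):
        text = self.ALIASES + "TRIF\tTLR3\tbogus\n"
        with pytest.raises(AmbiguousAliasError, match="TRIF"):
            read_aliases(tsv(tmp_path, "a.tsv", text))

    def test_lookup_is_case_insensitive(self, tmp_path):
        amap = read_aliases(tsv(tmp_path, "a.tsv", self.ALIASES))
        assert amap.resolve("trif") == "TICAM1"


class TestVariants:
    def test_round_trip_identity(self, tmp_path):
        records = [
            VariantRecord("TICAM1", "missense", 0.001, 0.002, 0.0),
            VariantRecord("TBK1", "synonymous", 0.5, 0.0, 0.006),
            VariantRecord("TLR3", "frameshift", 0.0, 0.0, 0.0),
        ]
        p = tmp_path / "v.tsv"
        write_variants(records, p)
        assert read_variants(p) == records

    def test_unknown_effect_names_token(self, tmp_path):
        p = tsv(tmp_path, "v.tsv", "TLR3\tintergenic\t0\t0\t0\n")
        with pytest.raises(DataError, match="intergenic"):
            read_variants(p)

    def test_missing_frequencies_parse_as_zero(self, tmp_path):
        p = tsv(tmp_path, "v.tsv", "TLR3\tmissense\n")
        (rec,) = read_variants(p)
        assert (rec.freq_db1, rec.freq_db2, rec.cohort_freq) == (0.0, 0.0, 0.0)

    def test_frequency_out_of_range_rejected(self, tmp_path):
        p = tsv(tmp_path, "v.tsv", "TLR3\tmissense\t1.5\t0\t0\n")
        with pytest.raises(DataError, match="line 1"):
            read_variants(p)


class TestGeneListAndTables:
    def test_empty_candidate_list_is_empty_not_error(self, tmp_path):
        assert read_gene_list(tsv(tmp_path, "g.txt", "")) == []

    def test_symbols_upper_cased_and_comments_skipped(self, tmp_path):
        p = tsv(tmp_path, "g.txt", "# WES hits\ntlr3\n\nTicam1\n")
        assert read_gene_list(p) == ["TLR3", "TICAM1"]

    def test_table_round_trip_preserves_annotation_columns(self, tmp_path, g1_net):
        from geneconnectome import build_connectome

        frame = build_connectome(g1_net, "A").to_frame()
        p = tmp_path / "conn.tsv"
        write_table(frame, p)
        back = read_table(p)
        assert list(back.columns) == [
            "target", "distance", "rank", "p_value", "brp", "ratio_median",
            "ratio_mean", "sphere", "route", "degrees", "full_name",
        ]
        assert list(back["target"]) == list(frame["target"])
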