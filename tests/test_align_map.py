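import pytest
from Bio.Align import substitution_matrices

from fmo_roadmap.align_map import (
    PairwiseAlignment,
    align_global,
    anchor_projection_msa,
    extract_diagnostics,
    map_anchor_sites,
)
from fmo_roadmap.core_io import MultipleAlignment, ProteinSequence
from fmo_roadmap.synthetic_data import GeneratorSpec, make_queries

from oracles import exhaustive_global_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _seq(residues, sid="s"):
    return ProteinSequence(id=sid, residues=residues)


class TestAlignGlobal:
    def test_identity_alignment_sums_diagonal_scores(self):
        aln = align_global(_seq("MFK", "a"), _seq("MFK", "b"))
        assert aln.row_a == "MFK" and aln.row_b == "MFK"
        expected = sum(BLOSUM62[c, c] for c in "MFK")
        assert aln.score == pytest.approx(expected)

    def test_single_terminal_gap_costs_gap_open(self):
        aln = align_global(_seq("A", "a"), _seq("AA", "b"))
        assert sorted([aln.row_a, aln.row_b]) == ["-A", "AA"] or sorted(
            [aln.row_a, aln.row_b]
        ) == ["A-", "AA"]
        assert aln.score == pytest.approx(BLOSUM62["A", "A"] - 11.0)

    def test_score_matches_exhaustive_enumeration(self, rng, make_random_residues):
        for _ in range(40):
            a = make_random_residues(int(rng.integers(1, 7)))
            b = make_random_residues(int(rng.integers(1, 7)))
            aln = align_global(_seq(a, "a"), _seq(b, "b"))
            assert aln.score == pytest.approx(exhaustive_global_score(a, b))

    def test_score_is_symmetric(self, make_random_residues):
        for _ in range(10):
            a, b = make_random_residues(40), make_random_residues(35)
            assert align_global(_seq(a, "a"), _seq(b, "b")).score == pytest.approx(
                align_global(_seq(b, "b"), _seq(a, "a")).score
            )

    def test_ungapping_rows_recovers_inputs(self, make_random_residues):
        a, b = make_random_residues(50), make_random_residues(44)
        aln = align_global(_seq(a, "a"), _seq(b, "b"))
        assert aln.row_a.replace("-", "") == a
        assert aln.row_b.replace("-", "") == b

    def test_all_gap_column_rejected(self):
        with pytest.raises(ValueError, match="all-gap"):
            PairwiseAlignment(row_a="A-", row_b="--", score=0, gap_open=11, gap_extend=1)


class TestMapAnchorSites:
    def test_identity_alignment_maps_sites_to_themselves(self):
        aln = PairwiseAlignment(
            row_a="ACDEF", row_b="ACDEF", score=0, gap_open=11, gap_extend=1
        )
        mapped = map_anchor_sites(aln, {"s1": 1, "s3": 3, "s5": 5})
        assert mapped == {"s1": (1, "A"), "s3": (3, "D"), "s5": (5, "F")}

    def test_hand_traced_column_walk(self):
        aln = PairwiseAlignment(
            row_a="ACD-EF", row_b="A-DGEF", score=0, gap_open=11, gap_extend=1
        )
        mapped = map_anchor_sites(aln, {"site2": 2, "site4": 4})
        assert mapped["site2"] == (None, "-")
        assert mapped["site4"] == (4, "E")

    def test_site_beyond_anchor_length_raises(self):
        aln = PairwiseAlignment(
            row_a="ACD-EF", row_b="A-DGEF", score=0, gap_open=11, gap_extend=1
        )
        with pytest.raises(ValueError, match="outside anchor length"):
            map_anchor_sites(aln, {"bad": 7})
        with pytest.raises(ValueError, match="outside anchor length"):
            map_anchor_sites(aln, {"bad": 0})


class TestExtractDiagnostics:
    def test_panel_references_agree_fully_with_their_own_clade(self, panel):
        for entry in panel.references:
            if entry.clade not in ("I", "II", "III", "IV"):
                continue
            report = extract_diagnostics([entry.sequence], panel)[0]
            n_match, n_scored = report.per_clade_agreement[entry.clade]
            assert n_scored > 0 and n_match == n_scored

    def test_clade_iv_dyad2_is_glutamine_and_beats_clade_i(self, panel):
        seq = panel.entries_for("IV")[0].sequence
        report = extract_diagnostics([seq], panel)[0]
        assert report.site_residues["dyad2"][1] == "Q"
        frac = lambda c: report.per_clade_agreement[c][0] / report.per_clade_agreement[c][1]
        assert frac("IV") > frac("I")

    def test_deletion_spanning_dyad_reduces_scored_sites(self, panel):
        anchor = panel.anchor
        # remove anchor positions 58-87: spans the dyad (61/62) but not Tyr56
        residues = anchor.residues[:57] + anchor.residues[87:]
        query = ProteinSequence(id="del_dyad", residues=residues)
        intact = extract_diagnostics([anchor], panel)[0]
        report = extract_diagnostics([query], panel)[0]
        assert report.site_residues["dyad1"] == (None, "-")
        assert report.site_residues["dyad2"] == (None, "-")
        assert report.warnings
        n_i = report.per_clade_agreement["I"][1]
        assert n_i == intact.per_clade_agreement["I"][1] - 2

    def test_msa_route_matches_pairwise_route(self, panel):
        queries = [
            seq for seq, _ in make_queries(
                GeneratorSpec(seed=5, clade="II", mutation_rate=0.05), 3
            )
        ]
        pairwise = extract_diagnostics(queries, panel)
        msa = anchor_projection_msa(queries, panel.anchor)
        via_msa = {r.query_id: r for r in extract_diagnostics(msa, panel)}
        for report in pairwise:
            other = via_msa[report.query_id]
            assert {k: v[1] for k, v in report.site_residues.items()} == {
                k: v[1] for k, v in other.site_residues.items()
            }
            assert report.per_clade_agreement == other.per_clade_agreement

    def test_missing_anchor_row_in_msa_raises(self, panel):
        msa = MultipleAlignment(rows=(("x", "ACD"), ("y", "ACD")))
        with pytest.raises(ValueError, match="anchor"):
            extract_diagnostics(msa, panel)


class TestAnchorProjection:
    def test_projection_has_anchor_width(self, panel):
        queries = [
            seq for seq, _ in make_queries(
                GeneratorSpec(seed=2, clade="I", mutation_rate=0.02), 2
            )
        ]
        msa = anchor_projection_msa(queries, panel.anchor)
        assert msa.n_columns == len(panel.anchor)
        assert msa.ids[0] == panel.anchor.id
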