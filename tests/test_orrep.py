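"""OR candidate extension, deduplication, classification, and diversity."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from raptorsig import orrep, simulate
from raptorsig.alignment import AlignmentMatrix
from raptorsig.errors import InvalidSequenceError, UndefinedStatisticError


def _gene(cds, **kw):
    return orrep.ORGene(id=kw.pop("id", "g1"), cds=cds, **kw)


def _orf(n_codons, stop="TAA"):
    # Leu codons: no internal starts or stops
    return "ATG" + "CTT" * (n_codons - 1) + stop


class TestExtendOrf:
    def test_complete_candidate_unchanged(self):
        genome = "CCCCCC" + _orf(10) + "CCCCCC"
        g = orrep.ORGene(id="x", scaffold="s", start=6, end=6 + len(_orf(10)), strand="+", cds="")
        out = orrep.extend_orf(g, genome)
        assert (out.start, out.end) == (g.start, g.end)
        assert not out.missing_start and not out.missing_stop

    def test_start_recovered_30bp_upstream(self):
        # in-frame ATG exactly 30 bp before the annotated start
        filler = "CTT" * 9  # 27 bp between ATG and candidate
        genome = "GGGGGG" + "ATG" + filler + "CTTCTTTAA" + "GGGGGG"
        start = 6 + 30
        g = orrep.ORGene(id="x", scaffold="s", start=start, end=start + 9, strand="+", cds="")
        out = orrep.extend_orf(g, genome)
        assert out.start == start - 30
        assert not out.missing_start

    def test_no_start_within_flank_sets_flag(self):
        genome = "CTT" * 40 + "CTTCTTTAA" + "CTT" * 10
        g = orrep.ORGene(id="x", scaffold="s", start=120, end=129, strand="+", cds="")
        out = orrep.extend_orf(g, genome)
        assert out.missing_start

    def test_minus_strand_stop_recovery(self):
        cds_fwd = "ATG" + "CTT" * 5  # missing stop on the coding strand
        rc = orrep._revcomp(cds_fwd)
        # on '-' strand the stop lies genomically *before* the interval
        genome = "GG" + orrep._revcomp("TGA") + rc + "GGGG"
        start, end = 5, 5 + len(rc)
        g = orrep.ORGene(id="x", scaffold="s", start=start, end=end, strand="-", cds="")
        out = orrep.extend_orf(g, genome)
        assert not out.missing_stop
        assert out.cds.endswith("TGA")

    def test_scan_truncated_at_scaffold_edge(self):
        genome = "CTTCTTTAA"  # candidate starts at 0: nowhere to scan upstream
        g = orrep.ORGene(id="x", scaffold="s", start=0, end=9, strand="+", cds="")
        out = orrep.extend_orf(g, genome)
        assert out.missing_start


class TestDedupe:
    def test_all_unique_preserved(self):
        genes = [_gene("ATGTAA", id="a"), _gene("ATGTGA", id="b")]
        assert orrep.dedupe_identical(genes) == genes

    def test_exact_duplicates_collapse_to_first(self):
        genes = [_gene("ATGTAA", id="a"), _gene("ATGTAA", id="b"), _gene("ATGTGA", id="c")]
        out = orrep.dedupe_identical(genes)
        assert [g.id for g in out] == ["a", "c"]

    def test_one_base_difference_keeps_both(self):
        genes = [_gene("ATGAAATAA", id="a"), _gene("ATGAACTAA", id="b")]
        assert len(orrep.dedupe_identical(genes)) == 2

    def test_idempotent(self):
        genes = [_gene("ATGTAA", id="a"), _gene("ATGTAA", id="b")]
        once = orrep.dedupe_identical(genes)
        assert orrep.dedupe_identical(once) == once


class TestClassify:
    def test_internal_stop_is_pseudogene(self):
        orf = _orf(300)
        mutated = orf[:300] + "TAA" + orf[303:]
        g = _gene(mutated)
        assert orrep.classify_or(g) == "pseudogene"
        assert "premature_stop" in g.lesions

    def test_one_bp_deletion_is_pseudogene(self):
        orf = _orf(300)
        g = _gene(orf[:10] + orf[11:])
        assert orrep.classify_or(g) == "pseudogene"
        assert "frameshift" in g.lesions

    def test_long_complete_orf_is_intact(self):
        assert orrep.classify_or(_gene(_orf(320))) == "intact"  # 320 aa protein

    def test_short_complete_orf_is_partial(self):
        assert orrep.classify_or(_gene(_orf(100))) == "partial"  # 100 aa

    def test_boundary_exactly_215_aa_is_partial(self):
        # _orf(n) translates to an n-residue protein; intact needs > 215
        assert orrep.classify_or(_gene(_orf(215))) == "partial"
        assert orrep.classify_or(_gene(_orf(216))) == "intact"

    def test_missing_start_is_partial(self):
        assert orrep.classify_or(_gene("CTT" * 250 + "TAA")) == "partial"

    def test_missing_stop_is_partial(self):
        assert orrep.classify_or(_gene("ATG" + "CTT" * 250)) == "partial"

    def test_non_acgt_rejected_with_positions(self):
        with pytest.raises(InvalidSequenceError, match=r"\[3\]"):
            orrep.classify_or(_gene("ATGNAATAA"))

    def test_full_agreement_with_planted_truth(self, or_simulation):
        genes, scaffolds, truth = or_simulation
        statuses = {}
        for g in genes:
            ext = orrep.extend_orf(g, scaffolds[g.scaffold])
            statuses[g.id] = orrep.classify_or(ext)
        for row in truth.itertuples(index=False):
            assert statuses[row.gene_id] == row.truth, (row.gene_id, row.lesion)

    def test_partition_after_classification(self, or_simulation):
        genes, scaffolds, truth = or_simulation
        deduped = orrep.dedupe_identical(genes)
        counts = {"intact": 0, "partial": 0, "pseudogene": 0}
        for g in deduped:
            counts[orrep.classify_or(orrep.extend_orf(g, scaffolds[g.scaffold]))] += 1
        assert sum(counts.values()) == len(deduped)


class TestEntropy:
    def test_closed_forms(self):
        assert orrep.column_entropy("A" * 10) == pytest.approx(0.0, abs=1e-12)
        assert orrep.column_entropy("L" * 5 + "V" * 5) == pytest.approx(math.log(2), abs=1e-12)
        assert orrep.column_entropy("ACDEFGHIKLMNPQRSTVWY") == pytest.approx(math.log(20), abs=1e-12)

    def test_gaps_ignored(self):
        assert orrep.column_entropy("AA--") == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            orrep.column_entropy("----")

    @given(st.permutations(list("LLVVAAKK")))
    def test_invariant_to_row_permutation(self, perm):
        assert orrep.column_entropy(perm) == pytest.approx(
            orrep.column_entropy("LLVVAAKK"), abs=1e-12
        )

    def test_invariant_to_residue_relabeling(self):
        assert orrep.column_entropy("LLVV") == pytest.approx(orrep.column_entropy("WWYY"), abs=1e-12)


class TestRepertoireDiversity:
    def test_identical_sequences_have_zero_diversity(self):
        aln = AlignmentMatrix(ids=["a", "b"], rows=["MKTL", "MKTL"])
        d = orrep.repertoire_diversity(aln)
        assert d.mean_entropy == pytest.approx(0.0, abs=1e-12)
        assert d.n_columns_used == 4

    def test_high_gap_columns_excluded_and_mean_matches_hand_computation(self):
        # column 0: 25% gaps -> excluded; column 1: uniform 2 classes; column 2: constant
        rows = ["-LA", "ALA", "AVA", "AVA"]
        aln = AlignmentMatrix(ids=list("abcd"), rows=rows)
        d = orrep.repertoire_diversity(aln, gap_threshold=0.20)
        assert d.n_columns_used == 2
        assert d.mean_entropy == pytest.approx(math.log(2) / 2, abs=1e-12)

    def test_exactly_20_percent_gaps_retained(self):
        rows = ["-A", "AA", "AA", "AA", "AA"]  # col 0 gap fraction exactly 0.20
        d = orrep.repertoire_diversity(AlignmentMatrix(ids=list("abcde"), rows=rows))
        assert d.n_columns_used == 2

    def test_single_sequence_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            orrep.repertoire_diversity(AlignmentMatrix(ids=["a"], rows=["MKT"]))

    def test_all_columns_gapped_undefined(self):
        aln = AlignmentMatrix(ids=list("ab"), rows=["-", "-"])
        with pytest.raises(UndefinedStatisticError):
            orrep.repertoire_diversity(aln)
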