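"""NG86 counting, dN/dS calibration, Mann-Whitney comparisons, GC3, and
group-specific residues."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oracles import mannwhitney_exact_two_sided, ng86_diffs, ng86_sites
from raptorsig import codon, simulate
from raptorsig.errors import InvalidSequenceError, SaturationError, UndefinedStatisticError


class TestSiteCounts:
    def test_met_is_fully_nonsynonymous(self):
        assert codon.count_sites_ng86("ATG") == (0.0, 3.0)

    def test_fourfold_third_position(self):
        s, n = codon.count_sites_ng86("GGG")
        assert s >= 1.0  # position 3 alone contributes 1.0

    def test_all_sense_codons_match_enumeration_oracle(self):
        for c in codon.SENSE_CODONS:
            s, n = codon.count_sites_ng86(c)
            so, no = ng86_sites(c)
            assert s == pytest.approx(so, abs=1e-12), c
            assert s + n == pytest.approx(3.0, abs=1e-15)

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidSequenceError):
            codon.count_sites_ng86("TAA")


class TestDiffCounts:
    def test_synonymous_single_change(self):
        assert codon.count_diffs_ng86("TTT", "TTC") == (1.0, 0.0)

    def test_nonsynonymous_single_change(self):
        assert codon.count_diffs_ng86("TTT", "TTA") == (0.0, 1.0)

    def test_all_pairs_up_to_two_diffs_match_pathway_oracle(self):
        for a, b in itertools.product(codon.SENSE_CODONS, repeat=2):
            k = sum(x != y for x, y in zip(a, b))
            if not 1 <= k <= 2:
                continue
            expected = ng86_diffs(a, b)
            if expected is None:
                continue  # no stop-free path: fallback behavior tested separately
            s, n = codon.count_diffs_ng86(a, b)
            assert (s, n) == pytest.approx(expected, abs=1e-12), (a, b)
            assert s + n == pytest.approx(k, abs=1e-12)

    def test_every_sense_pair_has_a_stop_free_pathway(self):
        # in the standard code no sense-codon pair is fully stop-blocked, so
        # the all-pathways fallback never triggers on valid input
        for a, b in itertools.product(codon.SENSE_CODONS, repeat=2):
            if a != b:
                assert ng86_diffs(a, b) is not None, (a, b)

    def test_stop_traversing_fallback_counts_steps_as_nonsynonymous(self):
        # exercised directly: walking TAT -> TAA (stop) -> TGA (stop) -> TGG
        s, n = codon._walk_through_stops("TAT", "TGG", (2, 1))
        assert (s, n) == (0.0, 2.0)


class TestDnDsPair:
    def test_identical_sequences(self):
        seq = "ATGGCTTGG" * 10
        est = codon.dnds_pair(seq, seq)
        assert (est.pN, est.pS, est.dN, est.dS) == (0.0, 0.0, 0.0, 0.0)
        assert est.omega is None

    def test_symmetry(self):
        anc, desc = simulate.gen_codon_alignment(300, 0.5, 0.3, seed=9)
        e1, e2 = codon.dnds_pair(anc, desc), codon.dnds_pair(desc, anc)
        assert e1.omega == pytest.approx(e2.omega, rel=1e-12)
        assert e1.s_sites == pytest.approx(e2.s_sites, rel=1e-12)

    def test_site_count_conservation(self):
        anc, desc = simulate.gen_codon_alignment(500, 1.0, 0.3, seed=2)
        est = codon.dnds_pair(anc, desc)
        assert est.s_sites + est.n_sites == pytest.approx(3 * est.n_codons, abs=1e-9)
        assert est.s_diffs + est.n_diffs == pytest.approx(
            sum(x != y for x, y in zip(anc, desc)), abs=1e-9
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_neutral_simulation_recovers_omega_one(self, seed):
        anc, desc = simulate.gen_codon_alignment(5000, 1.0, 0.3, seed=seed)
        est = codon.dnds_pair(anc, desc)
        assert 0.9 <= est.omega <= 1.1

    def test_strict_purifying_gives_exact_zero(self):
        anc, desc = simulate.gen_codon_alignment(5000, 0.0, 0.3, seed=1)
        est = codon.dnds_pair(anc, desc)
        assert est.n_diffs == 0.0 and est.dN == 0.0 and est.omega == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_moderate_purifying_recovered(self, seed):
        anc, desc = simulate.gen_codon_alignment(5000, 0.2, 0.3, seed=seed)
        est = codon.dnds_pair(anc, desc)
        assert est.omega == pytest.approx(0.2, abs=0.05)

    def test_gapped_codons_skipped_pairwise(self):
        est = codon.dnds_pair("ATG---GGGAAATTT", "ATGAAAGGCAAATTT")
        assert est.n_codons == 4
        assert est.s_diffs == 1.0 and est.n_diffs == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidSequenceError):
            codon.dnds_pair("ATGATG", "ATG")

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            codon._jukes_cantor(0.8)


class TestGenesetAcceleration:
    def test_separated_groups_exact_p(self):
        u, p = codon.geneset_acceleration([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        u, p = codon.geneset_acceleration([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        assert p == 1.0

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="tied"):
            u, p = codon.geneset_acceleration([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_exact_matches_full_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        a = list(np.round(rng.random(n), 2))  # rounding plants ties
        b = list(np.round(rng.random(n), 2))
        _, p = codon.geneset_acceleration(a, b)
        assert p == pytest.approx(mannwhitney_exact_two_sided(a, b), abs=1e-12)

    def test_shift_increases_u_monotonically(self):
        rng = np.random.default_rng(5)
        a = list(rng.random(6))
        b = list(rng.random(6))
        u0, _ = codon.geneset_acceleration(a, b)
        u1, _ = codon.geneset_acceleration([x + 0.5 for x in a], b)
        assert u1 >= u0

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = list(rng.normal(0.3, 0.05, 40))
        b = list(rng.normal(0.2, 0.05, 40))
        _, p = codon.geneset_acceleration(a, b)
        assert p < 0.05  # clearly accelerated set detected


class TestGC3:
    def test_all_gc_thirds(self):
        assert codon.gc3("ATGGCCTTG").gc3 == 1.0

    def test_no_gc_thirds(self):
        assert codon.gc3("ATTGCATTA").gc3 == 0.0

    def test_binomial_recovery_at_half(self):
        rng = np.random.default_rng(12)
        thirds = rng.choice(list("GCAT"), size=1000)
        seq = "".join("AT" + t for t in thirds)
        rec = codon.gc3(seq)
        sd = math.sqrt(0.25 / 1000)
        assert abs(rec.gc3 - 0.5) < 3 * sd
        assert rec.n_codons_used == 1000

    def test_incomplete_terminal_codon_trimmed_with_warning(self):
        with pytest.warns(UserWarning, match="trimming"):
            rec = codon.gc3("ATGGCCTT")
        assert rec.n_codons_used == 2

    def test_ambiguous_thirds_excluded(self):
        rec = codon.gc3("ATGATNATC")
        assert rec.n_codons_used == 2

    def test_empty_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            codon.gc3("ATN")


class TestGC3Profile:
    def _records(self):
        rows = []
        rng = np.random.default_rng(0)
        for sp in ["owl", "buzzard", "kestrel"]:
            for g in range(10):
                shift = 0.1 if (sp == "owl" and g < 5) else 0.0
                rows.append(
                    {"gene_id": f"g{g}", "species": sp, "gc3": 0.5 + 0.02 * g + shift}
                )
        return pd.DataFrame(rows)

    def test_rows_are_standardized(self):
        z, _, _ = codon.gc3_profile(self._records(), {"setA": [f"g{i}" for i in range(5)], "setB": [f"g{i}" for i in range(5, 10)]})
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_planted_shift_maximizes_species_zscore(self):
        z, _, _ = codon.gc3_profile(self._records(), {"setA": [f"g{i}" for i in range(5)]})
        assert z.loc["setA"].idxmax() == "owl"

    def test_identical_species_vectors_give_zero(self):
        rows = [
            {"gene_id": f"g{g}", "species": sp, "gc3": 0.4 + 0.05 * g}
            for sp in ["a", "b"]
            for g in range(4)
        ]
        z, _, _ = codon.gc3_profile(pd.DataFrame(rows), {"s": ["g0", "g1", "g2", "g3"]})
        assert np.allclose(z.loc["s"], 0.0)

    def test_small_sets_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            z, _, _ = codon.gc3_profile(self._records(), {"tiny": ["g1"], "setA": ["g0", "g1"]})
        assert list(z.index) == ["setA"]


class TestSpecificResidues:
    def test_generator_round_trip(self):
        for seed in range(5):
            aln, truth = simulate.gen_protein_alignment(3, 6, 300, [7, 150, 299], seed=seed)
            sites = codon.specific_residues(aln, aln.row_indices(["target0", "target1", "target2"]))
            assert [s.column for s in sites] == [7, 150, 299]
            for s, t in zip(sites, truth.itertuples(index=False)):
                assert s.target_residue == t.target_residue
                assert s.target_residue not in s.outgroup_residues

    def test_outgroup_sharing_residue_disqualifies(self):
        from raptorsig.alignment import AlignmentMatrix

        aln = AlignmentMatrix(ids=["t1", "t2", "o1", "o2"], rows=["A", "A", "A", "C"])
        assert codon.specific_residues(aln, {0, 1}) == []

    def test_strict_mode_excludes_outgroup_gaps(self):
        from raptorsig.alignment import AlignmentMatrix

        aln = AlignmentMatrix(ids=["t1", "t2", "o1", "o2"], rows=["A", "A", "-", "C"])
        assert len(codon.specific_residues(aln, {0, 1})) == 1
        assert codon.specific_residues(aln, {0, 1}, strict_gaps=True) == []

    def test_all_rows_as_targets_rejected(self):
        from raptorsig.alignment import AlignmentMatrix

        aln = AlignmentMatrix(ids=["a", "b"], rows=["A", "C"])
        with pytest.raises(ValueError):
            codon.specific_residues(aln, {0, 1})
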