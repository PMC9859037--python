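"""Scanner internals: matrices, exact null distributions, scanning, BH, ranking."""

import numpy as np
import pytest
from conftest import enumerate_pvalues

from pprscan.io_formats import AnnotatedGenome, GeneFeature, SequenceRecord
from pprscan.motif_scan import (Background, FrequencyMatrix, Hit,
                                bh_qvalues, estimate_background,
                                exact_score_distribution,
                                iupac_to_frequency_matrix, log_odds,
                                rank_targets, reverse_complement, scan)
from pprscan.recognition_code import ConsensusMotif
from pprscan.synthetic_data import generate_mito_genome

UNIFORM = Background((0.25, 0.25, 0.25, 0.25))


def _consensus(word):
    return ConsensusMotif(word, tuple(range(1, len(word) + 1)))


class TestBackground:
    def test_from_data_pseudocount(self):
        bg = estimate_background([SequenceRecord("s", "", "AAAA")])
        assert bg.frequencies == pytest.approx((5 / 8, 1 / 8, 1 / 8, 1 / 8))

    def test_uniform(self):
        assert estimate_background([], "uniform").frequencies == (0.25,) * 4

    def test_symmetric_sequence(self):
        bg = estimate_background([SequenceRecord("s", "", "ACGT")])
        assert bg.frequencies == pytest.approx((0.25,) * 4)

    def test_empty_from_data_is_error(self):
        with pytest.raises(ValueError):
            estimate_background([], "from_data")


class TestFrequencyMatrix:
    def test_iupac_columns(self):
        m = iupac_to_frequency_matrix(_consensus("RN"))
        assert m.probs[0].tolist() == [0.5, 0.0, 0.5, 0.0]
        assert m.probs[1].tolist() == [0.25] * 4

    def test_literal_word_is_one_hot(self):
        m = iupac_to_frequency_matrix(_consensus("GAT"))
        assert m.probs.max(axis=1).tolist() == [1.0, 1.0, 1.0]
        assert m.probs.sum() == pytest.approx(3.0)

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            iupac_to_frequency_matrix("GAX")


class TestLogOdds:
    def test_one_hot_zero_pseudocount_is_two_bits(self):
        m = iupac_to_frequency_matrix(_consensus("A"))
        lom = log_odds(m, UNIFORM, pseudo=0.0)
        assert lom.scores[0, 0] == pytest.approx(2.0)

    def test_uniform_column_scores_zero(self):
        m = FrequencyMatrix(np.full((3, 4), 0.25))
        lom = log_odds(m, UNIFORM, pseudo=0.37)
        assert np.allclose(lom.scores, 0.0)

    def test_default_pseudocount_closed_form(self):
        m = iupac_to_frequency_matrix(_consensus("A"))
        lom = log_odds(m, UNIFORM, pseudo=0.1)
        assert lom.scores[0, 0] == pytest.approx(np.log2((1 + 0.025) / 0.275))
        assert lom.scores[0, 1] == pytest.approx(np.log2(0.025 / 0.275))

    def test_negative_pseudocount_is_error(self):
        with pytest.raises(ValueError):
            log_odds(iupac_to_frequency_matrix(_consensus("A")), UNIFORM, -0.1)

    def test_zero_pseudocount_clamps_disallowed_bases(self):
        lom = log_odds(iupac_to_frequency_matrix(_consensus("A")), UNIFORM, 0.0)
        assert np.all(np.isfinite(lom.scores))
        assert np.all(lom.scores[0, 1:] < -20)


class TestExactScoreDistribution:
    def test_width_one_top_score_survival(self):
        lom = log_odds(iupac_to_frequency_matrix(_consensus("A")), UNIFORM)
        dist = exact_score_distribution(lom, UNIFORM)
        assert dist.survival[dist.int_scores[0].max()] == pytest.approx(0.25)

    def test_width_two_max_score_pvalue(self):
        lom = log_odds(iupac_to_frequency_matrix(_consensus("AC")), UNIFORM)
        dist = exact_score_distribution(lom, UNIFORM)
        top = int(dist.int_scores.max(axis=1).sum())
        assert dist.survival[top] == pytest.approx(1 / 16)

    def test_pmf_sums_to_one_survival_monotone(self):
        lom = log_odds(iupac_to_frequency_matrix(_consensus("RANDGY")), UNIFORM)
        dist = exact_score_distribution(lom, UNIFORM)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.survival) <= 1e-15)
        assert dist.survival[0] == pytest.approx(1.0)

    def test_matches_enumeration_randgy(self):
        bg = Background((0.31, 0.31, 0.13, 0.25))
        lom = log_odds(iupac_to_frequency_matrix(_consensus("RANDGY")), bg)
        dist = exact_score_distribution(lom, bg)
        surv = enumerate_pvalues(dist.int_scores, bg.array)
        for t, p in surv.items():
            assert dist.survival[t] == pytest.approx(p, rel=1e-9)

    def test_granularity_refinement_stable(self):
        bg = Background((0.4, 0.2, 0.2, 0.2))
        lom = log_odds(iupac_to_frequency_matrix(_consensus("GRNTAY")), bg)
        coarse = exact_score_distribution(lom, bg, granularity=1000)
        fine = exact_score_distribution(lom, bg, granularity=10000)
        # p-value of each word's coarse score vs its fine score
        for word_cols in np.ndindex(4, 4, 4, 4, 4, 4):
            tc = sum(coarse.int_scores[i, b] for i, b in enumerate(word_cols))
            tf = sum(fine.int_scores[i, b] for i, b in enumerate(word_cols))
            pc, pf = coarse.survival[tc], fine.survival[tf]
            assert abs(pc - pf) <= coarse.pmf[tc] + 1e-12

    def test_granularity_floor_and_zero_width(self):
        lom = log_odds(iupac_to_frequency_matrix(_consensus("ACG")), UNIFORM)
        with pytest.raises(ValueError):
            exact_score_distribution(lom, UNIFORM, granularity=10)


class TestScan:
    def _setup(self, word, genome):
        bg = estimate_background([genome.sequence])
        lom = log_odds(iupac_to_frequency_matrix(_consensus(word)), bg)
        dist = exact_score_distribution(lom, bg)
        return lom, dist, bg

    def test_planted_site_found_with_max_score(self):
        word = "GATTACAGATTACA"
        genome, _ = generate_mito_genome(2000, genes=[],
                                         planted=[(word, 101, "+")], seed=8)
        lom, dist, bg = self._setup(word, genome)
        hits = scan(lom, dist, genome, bg)
        best = hits[0]
        assert (best.start, best.stop, best.strand) == (101, 114, "+")
        assert best.matched_sequence == word
        top = int(dist.int_scores.max(axis=1).sum())
        assert dist.survival[top] == pytest.approx(best.p_value)

    def test_threshold_one_keeps_every_window(self):
        genome, _ = generate_mito_genome(300, genes=[], seed=9)
        lom, dist, bg = self._setup("GATTAC", genome)
        hits = scan(lom, dist, genome, bg, strands="forward", p_threshold=1.0)
        assert len(hits) == 300 - 6 + 1

    def test_palindromic_motif_mirrors_strands(self):
        # symmetry requires a strand-symmetric (here uniform) background
        genome, _ = generate_mito_genome(500, genes=[], seed=10)
        bg = UNIFORM
        lom = log_odds(iupac_to_frequency_matrix(_consensus("GAATTC")), bg)
        dist = exact_score_distribution(lom, bg)
        hits = scan(lom, dist, genome, bg, strands="both", p_threshold=1.0)
        fwd = {(h.start, h.stop, round(h.score, 6)) for h in hits if h.strand == "+"}
        rev = {(h.start, h.stop, round(h.score, 6)) for h in hits if h.strand == "-"}
        assert fwd == rev

    def test_strand_consistency_under_reverse_complement(self):
        word = "GRTTACA"
        genome, _ = generate_mito_genome(800, genes=[], seed=12)
        lom, dist, bg = self._setup(word, genome)
        hits = scan(lom, dist, genome, bg, p_threshold=0.05)
        flipped = AnnotatedGenome(
            SequenceRecord(genome.sequence.id, "",
                           reverse_complement(genome.sequence.residues)), [])
        hits_rc = scan(lom, dist, flipped, bg, p_threshold=0.05)
        length = len(genome.sequence)
        remapped = {
            (length - h.stop + 1, length - h.start + 1,
             "+" if h.strand == "-" else "-", round(h.p_value, 12))
            for h in hits_rc
        }
        original = {(h.start, h.stop, h.strand, round(h.p_value, 12)) for h in hits}
        assert original == remapped

    def test_ambiguous_bases_score_as_background_expectation(self):
        seq = SequenceRecord("s", "", "ACGTNACGTA")
        lom, dist, bg = self._setup("ACGT", AnnotatedGenome(seq))
        hits = scan(lom, dist, [seq], bg, strands="forward", p_threshold=1.0)
        assert len(hits) == 7          # every window scored, N included
        hits_skip = scan(lom, dist, [seq], bg, strands="forward",
                         p_threshold=1.0, skip_ambiguous=True)
        assert len(hits_skip) == 3     # windows touching the N dropped

    def test_all_sequences_too_short_warns_empty(self):
        seq = SequenceRecord("s", "", "ACG")
        lom, dist, bg = self._setup("ACGTACGT", AnnotatedGenome(seq))
        with pytest.warns(UserWarning):
            assert scan(lom, dist, [seq], bg) == []


class TestBHQvalues:
    def test_equal_spacing_toy(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_qvalues([0.37]) == pytest.approx([0.37])

    def test_two_values(self):
        assert bh_qvalues([0.5, 0.001]) == pytest.approx([0.5, 0.002])

    def test_out_of_range_is_error(self):
        for bad in ([0.0, 0.5], [1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_qvalues(bad)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1.0, size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_qvalues(p) == pytest.approx(expected.tolist())

    def test_permutation_invariance_and_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-9, 1.0, size=50)
        q = np.array(bh_qvalues(p))
        perm = rng.permutation(50)
        q_perm = np.array(bh_qvalues(p[perm]))
        assert np.allclose(q[perm], q_perm)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


class TestRankTargets:
    def _genome(self):
        seq = SequenceRecord("g", "", "A" * 100)
        return AnnotatedGenome(seq, [GeneFeature("geneA", 10, 40, "+"),
                                     GeneFeature("geneB", 60, 90, "-")])

    def _hit(self, start, p):
        return Hit("m", "g", start, start + 4, "+", 1.0, p, None, "AAAAA")

    def test_gene_and_intergenic_rows(self):
        ranking = rank_targets([self._hit(12, 1e-6), self._hit(45, 1e-3)],
                               self._genome())
        assert [r.gene for r in ranking.rows] == ["geneA", "intergenic"]

    def test_best_p_and_count_per_gene(self):
        ranking = rank_targets([self._hit(12, 1e-6), self._hit(20, 1e-3)],
                               self._genome())
        (row,) = ranking.rows
        assert (row.gene, row.best_p, row.n_hits) == ("geneA", 1e-6, 2)

    def test_ties_break_by_gene_name(self):
        hits = [self._hit(12, 1e-4), self._hit(62, 1e-4)]
        ranking = rank_targets(hits, self._genome())
        assert [r.gene for r in ranking.rows] == ["geneA", "geneB"]

    def test_top_n_truncates(self):
        hits = [self._hit(12, 1e-6), self._hit(62, 1e-5), self._hit(95, 1e-4)]
        ranking = rank_targets(hits, self._genome(), top_n=2)
        assert len(ranking) == 2
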