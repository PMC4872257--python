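"""Word enumeration, background significance, BH control and the
per-subset discovery engines."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from promotif.discovery import (CandidateWord, EngineConfig,
                                benjamini_hochberg, discover_motifs,
                                enumerate_words, word_significance)
from promotif.motifs import reverse_complement_word
from promotif.synthetic import (PlantedMotifSpec, motif_from_consensus,
                                plant_motifs, sample_background_sequences,
                                uniform_background)


def naive_counts(sequences, word, max_mismatches=0, both_strands=True):
    """All-offsets counting oracle for one word."""
    rc = reverse_complement_word(word)
    seq_hits = total = 0
    for seq in sequences:
        found = 0
        for i in range(len(seq) - len(word) + 1):
            window = seq[i:i + len(word)]
            if "N" in window:
                continue
            d = sum(a != b for a, b in zip(window, word))
            if both_strands:
                d = min(d, sum(a != b for a, b in zip(window, rc)))
            if d <= max_mismatches:
                found += 1
        total += found
        seq_hits += found > 0
    return seq_hits, total


class TestEnumerateWords:
    def test_single_sequence_canonical_entry(self, region_factory):
        (cand,) = enumerate_words([region_factory("ACGTAC")], width=6)
        # canonical form of {ACGTAC, GTACGT}
        assert cand.word == "ACGTAC"
        assert cand.seq_hits == 1 and cand.total_hits == 1

    def test_absent_word_not_listed(self, region_factory):
        cands = enumerate_words([region_factory("AAAAAAAA")], width=6)
        assert {c.word for c in cands} == {"AAAAAA"}

    def test_mismatch_neighborhood_listed(self, region_factory):
        cands = enumerate_words([region_factory("AAAAAA")], width=6,
                                max_mismatches=1)
        words = {c.word for c in cands}
        assert "AAAAAA" in words and "AAACAA" in words
        assert all(naive_counts(["AAAAAA"], c.word, 1)[0] == c.seq_hits
                   for c in cands)

    @pytest.mark.parametrize("mm", [0, 1])
    def test_counts_match_naive_oracle(self, flat_background, mm):
        regions = sample_background_sequences(flat_background, 4, 60,
                                              seed=21)
        sequences = [r.sequence for r in regions]
        cands = enumerate_words(regions, width=6, max_mismatches=mm)
        sample = cands[:: max(1, len(cands) // 25)]
        for c in sample:
            sh, th = naive_counts(sequences, c.word, mm)
            rc = reverse_complement_word(c.word)
            if rc != c.word:
                # canonical counting merges the pair
                sh2, th2 = naive_counts(sequences, rc, mm)
                assert sh == sh2 and th == th2
            assert (c.seq_hits, c.total_hits) == (sh, th)

    def test_width_exceeding_region_rejected(self, region_factory):
        with pytest.raises(ValueError):
            enumerate_words([region_factory("ACGT")], width=6)

    def test_mismatch_monotonicity(self, flat_background):
        regions = sample_background_sequences(flat_background, 3, 80,
                                              seed=22)
        by_word = {}
        for mm in (0, 1):
            for c in enumerate_words(regions, 6, max_mismatches=mm):
                by_word.setdefault(c.word, {})[mm] = c.seq_hits
        for word, hits in by_word.items():
            if 0 in hits and 1 in hits:
                assert hits[1] >= hits[0]


class TestWordSignificance:
    def test_zero_hits_gives_one(self, flat_background):
        c = CandidateWord("ACGTAC", 6, 0, 0)
        assert word_significance(c, flat_background, 10, 1000) == 1.0

    def test_closed_form_all_hits(self, region_factory):
        from promotif.genome_io import build_background
        # background where the word is certain per window: p1 = 1 for any
        # length; use instead a constructed half-probability single window
        c = CandidateWord("AAAAAA", 6, 10, 10)
        bg = uniform_background()
        # region of exactly one window: p1 = p_word (palindrome-free)
        p_word = 0.25 ** 6 * 2  # both strands
        p = word_significance(c, bg, subset_size=10, region_length=6)
        assert p == pytest.approx(p_word ** 10, rel=1e-9)

    def test_binomial_against_monte_carlo(self, flat_background):
        """p-value agrees with a simulated null within 3 standard errors."""
        width, n_seq, length, n_sim = 6, 5, 30, 50_000
        word = "ACGTCA"
        rng = np.random.default_rng(23)
        bases = rng.integers(0, 4, size=(n_sim * n_seq, length))
        # count sequences containing word or its reverse complement
        target = np.array([["ACGT".index(b) for b in w]
                           for w in (word, reverse_complement_word(word))])
        windows = np.lib.stride_tricks.sliding_window_view(bases, width,
                                                           axis=1)
        hit = ((windows == target[0]).all(axis=2) |
               (windows == target[1]).all(axis=2)).any(axis=1)
        seq_hits = hit.reshape(n_sim, n_seq).sum(axis=1)
        for k in (1, 2):
            mc = float((seq_hits >= k).mean())
            se = np.sqrt(mc * (1 - mc) / n_sim)
            c = CandidateWord(word, width, k, k)
            p = word_significance(c, flat_background, n_seq, length)
            assert abs(p - mc) <= 3 * se + 1e-12

    def test_monotone_in_seq_hits(self, flat_background):
        ps = [word_significance(CandidateWord("ACGTCA", 6, k, k),
                                flat_background, 10, 1000)
              for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def bh_oracle(pvals):
    """Independent step-up implementation by explicit sorting."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert benjamini_hochberg([0.01]) == pytest.approx([0.01])

    def test_closed_form_triple(self):
        assert benjamini_hochberg([0.001, 0.02, 0.9]) == pytest.approx(
            [0.003, 0.03, 0.9])

    def test_random_vectors_match_oracle(self, rng):
        for _ in range(5):
            p = rng.uniform(size=100)
            assert benjamini_hochberg(p) == pytest.approx(bh_oracle(
                p.tolist()))

    def test_monotone_along_sorted_p(self, rng):
        p = np.sort(rng.uniform(size=50))
        q = benjamini_hochberg(p)
        assert all(a <= b + 1e-12 for a, b in zip(q, q[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestEngines:
    @pytest.fixture
    def planted_subset(self, flat_background):
        regions = sample_background_sequences(flat_background, 10, 1000,
                                              seed=31)
        spec = PlantedMotifSpec(motif_from_consensus("ACGTCAGT"),
                                prevalence=1.0, seed=32)
        planted, _ = plant_motifs(regions, spec)
        return planted

    def test_planted_word_top_ranked_and_significant(self, planted_subset,
                                                     flat_background):
        config = EngineConfig(engine="seed_qvalue")
        motifs = discover_motifs(planted_subset, flat_background, config)
        assert motifs, "planted word must clear the q-gate"
        assert motifs[0].consensus == "ACGTCAGT"
        assert all(m.score <= 0.05 for m in motifs)

    def test_topk_cap(self, planted_subset, flat_background):
        config = EngineConfig(engine="ranked_topk")
        motifs = discover_motifs(planted_subset, flat_background, config)
        assert len(motifs) <= 5
        assert motifs[0].consensus == "ACGTCAGT"
        assert [m.score for m in motifs] == [1, 2, 3, 4, 5][:len(motifs)]

    def test_em_refine_gate_and_recovery(self, planted_subset,
                                         flat_background):
        config = EngineConfig(engine="em_refine", width_range=(8, 8))
        motifs = discover_motifs(planted_subset, flat_background, config)
        assert motifs
        assert all(m.score <= 0.001 for m in motifs)
        assert any(m.consensus == "ACGTCAGT" for m in motifs)

    def test_null_subsets_mostly_empty(self, flat_background):
        config = EngineConfig(engine="seed_qvalue", width_range=(6, 8))
        empty = 0
        n_runs = 40
        for i in range(n_runs):
            subset = sample_background_sequences(flat_background, 10, 1000,
                                                 seed=1000 + i)
            if not discover_motifs(subset, flat_background, config):
                empty += 1
        assert empty >= 0.9 * n_runs

    def test_revcomp_input_invariance(self, planted_subset,
                                      flat_background, region_factory):
        config = EngineConfig(engine="seed_qvalue")
        flipped = [region_factory(reverse_complement_word(r.sequence),
                                  gene_id=r.gene_id)
                   for r in planted_subset]
        a = discover_motifs(planted_subset, flat_background, config)
        b = discover_motifs(flipped, flat_background, config)
        assert [m.consensus for m in a] == [m.consensus for m in b]

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="unknown engine"):
            EngineConfig(engine="gibbs")

    def test_minimum_width_enforced(self):
        with pytest.raises(ValueError, match="minimum motif width"):
            EngineConfig(width_range=(4, 8))
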