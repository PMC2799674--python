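"""Motif scoring, seed-and-refine discovery, and IUPAC scanning."""

import math
from itertools import product

import numpy as np
import pytest

from elpcip import MotifModel, find_motifs, motif_score, scan_iupac
from elpcip._seq import IUPAC, revcomp


def independent_score(site_words, background=(0.25,) * 4):
    """Score recomputed from scratch with plain Python arithmetic."""
    n = len(site_words)
    w = len(site_words[0])
    total = 0.0
    for col in range(w):
        for bi, base in enumerate("ACGT"):
            count = sum(1 for s in site_words if s[col] == base)
            f = (count + 0.5) / (n + 2)
            total += f * math.log2(f / background[bi])
    return math.log2(n) * total / w


def model_from_words(words):
    counts = np.zeros((4, len(words[0])))
    for word in words:
        for j, b in enumerate(word):
            counts["ACGT".index(b), j] += 1
    sites = [(f"s{i}", 0, "+") for i in range(len(words))]
    return MotifModel(width=len(words[0]), counts=counts, sites=sites)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestMotifScore:
    def test_four_identical_sites_hand_example(self):
        m = model_from_words(["ACGT"] * 4)
        assert motif_score(m) == pytest.approx(1.585, abs=2e-3)
        assert motif_score(m) == pytest.approx(independent_score(["ACGT"] * 4), rel=1e-12)

    def test_background_matching_counts_scores_near_zero(self):
        # 40 sites whose columns mirror the uniform background exactly
        words = ["".join(p) for p in product("ACGT", repeat=1)] * 10
        words = [w * 4 for w in words]  # width 4, each base 25% per column
        m = model_from_words(words)
        assert motif_score(m) == pytest.approx(0.0, abs=5e-3)

    def test_doubling_identical_sites_increases_score(self):
        s4 = motif_score(model_from_words(["ACGT"] * 4))
        s8 = motif_score(model_from_words(["ACGT"] * 8))
        assert s8 > s4

    def test_site_order_invariance(self, rng):
        words = [random_dna(rng, 6) for _ in range(8)]
        a = motif_score(model_from_words(words))
        b = motif_score(model_from_words(words[::-1]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_independent_formula(self, rng):
        for _ in range(20):
            words = [random_dna(rng, 8) for _ in range(int(rng.integers(2, 12)))]
            m = model_from_words(words)
            assert motif_score(m) == pytest.approx(independent_score(words), rel=1e-10)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            model_from_words(["ACGT"])


def brute_force_best_score(sequences, w, m):
    """Exhaustive seed enumeration + plain greedy refinement, coded independently.

    Sites are w-mer *instances*: each position/strand can join a motif once.
    """
    words = []  # every w-mer instance on both strands
    for name, seq in sequences.items():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - w + 1):
                words.append(s[i : i + w])
    best = -math.inf
    for seed in set(words):
        sites = [
            i for i, x in enumerate(words)
            if sum(a == b for a, b in zip(x, seed)) >= m
        ]
        if len(sites) < 2:
            continue
        for _ in range(100):
            current = independent_score([words[i] for i in sites])
            moves = []
            in_set = set(sites)
            for i in range(len(words)):
                if i not in in_set:
                    moves.append((independent_score([words[j] for j in sites] + [words[i]]),
                                  sites + [i]))
            if len(sites) > 2:
                for j in range(len(sites)):
                    cand = sites[:j] + sites[j + 1 :]
                    moves.append((independent_score([words[i] for i in cand]), cand))
            top_score, top_sites = max(moves, key=lambda t: t[0])
            if top_score <= current + 1e-12:
                break
            sites = top_sites
        best = max(best, independent_score([words[i] for i in sites]))
    return best


class TestFindMotifs:
    def test_planted_word_recovered(self, rng):
        motif = "AGTCAAAC"
        seqs = {}
        for i in range(20):
            s = random_dna(rng, 200)
            off = int(rng.integers(0, 200 - 8))
            seqs[f"prom{i}"] = s[:off] + motif + s[off + 8 :]
        found = find_motifs(seqs, w=8, top_t=5)
        # both strands are searched, so the consensus may surface in either
        # orientation of the same double-stranded element
        assert found[0].consensus in (motif, revcomp(motif))
        assert found[0].n_sites >= 15

    def test_deterministic_across_runs(self, rng):
        seqs = {f"s{i}": random_dna(rng, 80) for i in range(6)}
        a = find_motifs(seqs, w=6, top_t=3)
        b = find_motifs(seqs, w=6, top_t=3)
        assert [(m.consensus, m.score, m.sites) for m in a] == [
            (m.consensus, m.score, m.sites) for m in b
        ]

    def test_null_scores_below_planted(self, rng):
        """A planted motif scores clearly above the best spurious null motif."""
        motif = "AGTCAAAC"
        planted, null = {}, {}
        for i in range(20):
            s = random_dna(rng, 200)
            off = int(rng.integers(0, 200 - 8))
            planted[f"p{i}"] = s[:off] + motif + s[off + 8 :]
            null[f"n{i}"] = random_dna(rng, 200)
        top_planted = find_motifs(planted, w=8)[0].score
        top_null = find_motifs(null, w=8)[0].score
        assert top_planted > top_null

    def test_refinement_never_decreases_score(self, rng):
        from elpcip.motifs import _all_wmers, _refine, _score_from_counts

        seqs = {f"s{i}": random_dna(rng, 60) for i in range(4)}
        W, onehot, sites = _all_wmers(seqs, 6)
        bg = np.full(4, 0.25)
        start = list(range(0, 8))
        before = float(_score_from_counts(onehot[start].sum(axis=0), len(start), bg))
        refined = _refine(start, onehot, bg)
        after = float(_score_from_counts(onehot[refined].sum(axis=0), len(refined), bg))
        assert after >= before - 1e-12

    def test_tiny_input_matches_brute_force(self):
        rng = np.random.default_rng(42)
        seqs = {f"s{i}": random_dna(rng, 12) for i in range(3)}
        found = find_motifs(seqs, w=4, top_t=3, match_threshold=3, max_candidates=10_000)
        brute = brute_force_best_score(seqs, w=4, m=3)
        assert found[0].score == pytest.approx(brute, rel=1e-9)

    def test_width_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_motifs({"s": "ACGT"}, w=10)


class TestScanIupac:
    def test_direct_containment(self):
        assert scan_iupac({"s": "AAGTCAAACTT"}, "AGTCAAAC") == {"s": 1}

    def test_n8_on_length_10(self):
        assert scan_iupac({"s": "ACGTACGTAC"}, "NNNNNNNN") == {"s": 3}

    def test_overlapping_occurrences(self):
        assert scan_iupac({"s": "AAAAA"}, "AAA")["s"] == 3

    def test_matches_brute_force(self, rng):
        def brute(seq, pattern):
            allowed = [set(IUPAC[c]) for c in pattern]
            rc = revcomp(pattern)
            allowed_rc = [set(IUPAC[c]) for c in rc]
            hits = set()
            for i in range(len(seq) - len(pattern) + 1):
                win = seq[i : i + len(pattern)]
                if all(c in a for c, a in zip(win, allowed)):
                    hits.add(i)
                if all(c in a for c, a in zip(win, allowed_rc)):
                    hits.add(i)
            return len(hits)

        for pattern in ("AGTCAAAC", "GCCGCGGC", "TCTCTCTC", "WRKYNNNN", "RYSWKM"):
            seqs = {f"s{i}": random_dna(rng, 120) for i in range(5)}
            expected = {name: brute(seq, pattern) for name, seq in seqs.items()}
            assert scan_iupac(seqs, pattern) == expected

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            scan_iupac({"s": "ACGT"}, "AXGT")
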