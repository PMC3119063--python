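"""Run/connector decomposition: word matching, scaffolding, refinement,
tiling and alignment-oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import kmer_counts, mutate_pair, nw_align
from strainpair.seq_io import Genome
from strainpair.run_connector import (
    Connector,
    Run,
    build_scaffold,
    compare_chromosomes,
    refine,
    shared_identity,
    unique_word_matches,
)
from strainpair.synthetic_data import random_sequence


def _rand(seed, n, gc=0.478):
    return random_sequence(np.random.default_rng(seed), n, gc)


class TestUniqueWordMatches:
    def test_exhaustive_oracle(self):
        segA = segB = "ACGTACGT"
        got = unique_word_matches(segA, segB, 4)
        ca, cb = kmer_counts(segA, 4), kmer_counts(segB, 4)
        expected = {
            (pa[0], cb[w][0])
            for w, pa in ca.items()
            if len(pa) == 1 and len(cb.get(w, [])) == 1
        }
        assert got == expected
        assert len(got) == 3  # CGTA, GTAC, TACG; ACGT occurs twice

    def test_random_pair_matches_oracle(self):
        a, b = _rand(1, 300), _rand(2, 300)
        for k in (3, 5, 9):
            got = unique_word_matches(a, b, k)
            ca, cb = kmer_counts(a, k), kmer_counts(b, k)
            expected = {
                (pa[0], cb[w][0])
                for w, pa in ca.items()
                if len(pa) == 1 and len(cb.get(w, [])) == 1
            }
            assert got == expected

    def test_disjoint_alphabet_empty(self):
        assert unique_word_matches("AAAACCCC", "GGGGTTTT", 3) == set()

    def test_n_excluded(self):
        assert unique_word_matches("ANGNTNAN", "ANGNTNAN", 3) == set()

    def test_word_length_floor(self):
        with pytest.raises(ValueError):
            unique_word_matches("ACGT", "ACGT", 2)


class TestScaffold:
    def test_identical_genomes_single_full_run(self):
        seq = _rand(3, 2000)
        g1, g2 = Genome("a", seq), Genome("b", seq)
        runs = build_scaffold(g1, g2)
        assert len(runs) == 1
        assert runs[0].length == 2000 and runs[0].startA == runs[0].startB == 0

    def test_planted_block_in_unrelated_genomes(self):
        block = _rand(10, 1000)
        a = _rand(11, 20_000) + block + _rand(12, 29_000)
        b = _rand(13, 35_000) + block + _rand(14, 14_000)
        runs = build_scaffold(Genome("a", a), Genome("b", b))
        main = max(runs, key=lambda r: r.length)
        assert main.startA <= 20_000 and main.startA + main.length >= 21_000
        assert main.startB <= 35_000 and main.startB + main.length >= 36_000
        # everything else can only be short chance matches
        assert all(r.length < 50 for r in runs if r is not main)

    def test_no_shared_words_empty_scaffold(self):
        a = "A" * 5000  # no unique 15-mer exists in a homopolymer
        b = _rand(15, 5000)
        assert build_scaffold(Genome("a", a), Genome("b", b)) == []


class TestRefine:
    def test_point_mutation_single_base_connector(self):
        a = _rand(20, 400)
        b = a[:200] + ("A" if a[200] != "A" else "C") + a[201:]
        ga, gb = Genome("a", a), Genome("b", b)
        parts = refine(ga, gb, (150, 250), (150, 250))
        conns = [e for e in parts if isinstance(e, Connector)]
        assert len(conns) == 1 and conns[0].lenA == 1 and conns[0].lenB == 1

    def test_pure_indel_connector(self):
        a = _rand(21, 300)
        ins = _rand(22, 20)
        b = a[:150] + ins + a[150:]
        parts = refine(Genome("a", a), Genome("b", b), (100, 200), (100, 220))
        conns = [e for e in parts if isinstance(e, Connector)]
        assert len(conns) == 1
        assert conns[0].lenA == 0 and conns[0].lenB == 20

    def test_ndiffs_close_to_optimal_alignment(self):
        # 200 bp pair at ~90% identity: summed connector difference counts
        # stay within 10% of the optimal global alignment distance
        rng = np.random.default_rng(5)
        for seed in range(5):
            base = _rand(100 + seed, 200)
            a, b = mutate_pair(np.random.default_rng(seed), base, sub_rate=0.10)
            cmap = compare_chromosomes(Genome("a", a), Genome("b", b))
            assert cmap.tiles_exactly()
            total = sum(c.n_diffs(a, b) for c in cmap.connectors())
            opt, _ = nw_align(a, b)
            assert opt <= total <= opt * 1.1 + 1


class TestCompare:
    def test_identical_one_run(self):
        seq = _rand(30, 5000)
        cmap = compare_chromosomes(Genome("a", seq), Genome("b", seq))
        assert len(cmap.runs()) == 1 and len(cmap.connectors()) == 0
        assert cmap.tiles_exactly()

    def test_planted_insertion_single_connector(self):
        a = _rand(31, 4000)
        ins = "".join(c for c in _rand(32, 25))
        # keep the junction unambiguous
        ins = ("C" if a[2000] == "A" else "A") + ins[1:-1] + ("C" if a[1999] == "A" else "A")
        b = a[:2000] + ins + a[2000:]
        cmap = compare_chromosomes(Genome("a", a), Genome("b", b))
        conns = cmap.connectors()
        assert cmap.tiles_exactly()
        assert len(conns) == 1
        assert conns[0].lenA == 0 and conns[0].lenB == 25

    def test_empty_genome_degenerates_to_connector(self):
        cmap = compare_chromosomes(Genome("a", ""), Genome("b", "ACGTACGTAA"))
        assert len(cmap.elements) == 1
        c = cmap.elements[0]
        assert isinstance(c, Connector) and c.lenA == 0 and c.lenB == 10

    def test_symmetry_on_tie_free_pair(self):
        base = _rand(40, 3000)
        a, b = mutate_pair(np.random.default_rng(41), base, sub_rate=0.01, n_indels=2)
        m1 = compare_chromosomes(Genome("a", a), Genome("b", b))
        m2 = compare_chromosomes(Genome("b", b), Genome("a", a))
        swapped = [
            (e.startB, e.startA, e.length) if isinstance(e, Run) else (e.startB, e.lenB, e.startA, e.lenA)
            for e in m2.elements
        ]
        direct = [
            (e.startA, e.startB, e.length) if isinstance(e, Run) else (e.startA, e.lenA, e.startB, e.lenB)
            for e in m1.elements
        ]
        assert direct == swapped

    def test_determinism(self):
        base = _rand(50, 2000)
        a, b = mutate_pair(np.random.default_rng(51), base, sub_rate=0.02, n_indels=1)
        m1 = compare_chromosomes(Genome("a", a), Genome("b", b))
        m2 = compare_chromosomes(Genome("a", a), Genome("b", b))
        assert [(type(e).__name__, e.startA, e.startB) for e in m1.elements] == [
            (type(e).__name__, e.startA, e.startB) for e in m2.elements
        ]

    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(0, 120),
        m=st.integers(0, 120),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_tiling_on_arbitrary_pairs(self, seed, n, m):
        """The tiling property must hold for any input pair, related or not."""
        rng = np.random.default_rng(seed)
        a = random_sequence(rng, n) if n else ""
        b = random_sequence(rng, m) if m else ""
        cmap = compare_chromosomes(Genome("a", a), Genome("b", b))
        assert cmap.tiles_exactly()
        # run order strictly increases in both genomes
        runs = cmap.runs()
        for r1, r2 in zip(runs, runs[1:]):
            assert r1.endA <= r2.startA and r1.endB <= r2.startB

    def test_runs_are_identical_segments(self):
        base = _rand(60, 2000)
        a, b = mutate_pair(np.random.default_rng(61), base, sub_rate=0.03, n_indels=3)
        cmap = compare_chromosomes(Genome("a", a), Genome("b", b))
        for r in cmap.runs():
            assert a[r.startA : r.endA] == b[r.startB : r.endB]
            assert r.length >= 3


class TestSharedIdentity:
    def test_zero_mutation_pair(self):
        seq = _rand(70, 3000)
        cmap = compare_chromosomes(Genome("a", seq), Genome("b", seq))
        assert shared_identity(cmap) == 1.0

    def test_empty_shared_signalled(self):
        cmap = compare_chromosomes(Genome("a", ""), Genome("b", ""))
        with pytest.raises(ValueError):
            shared_identity(cmap)

    def test_substitution_only_identity_matches_direct_count(self):
        base = _rand(80, 20_000)
        a, b = mutate_pair(np.random.default_rng(81), base, sub_rate=0.014)
        n_diff = sum(1 for x, y in zip(a, b) if x != y)
        cmap = compare_chromosomes(Genome("a", a), Genome("b", b))
        ident = shared_identity(cmap)
        assert ident == pytest.approx(1 - n_diff / len(base), abs=1e-4)
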