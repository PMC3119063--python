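"""Catalog-driven element location, SSEI calling, target duplications,
core deletions and the targeting matrix."""

import numpy as np
import pytest

from strainpair.seq_io import Genome
from strainpair.run_connector import compare_chromosomes
from strainpair.mge_analysis import (
    CATEGORIES,
    ElementFamily,
    ElementHit,
    TargetingMatrix,
    call_ssei,
    detect_core_deletion,
    detect_target_duplication,
    load_catalog,
    locate_elements,
    targeting_matrix,
    write_catalog,
)
from strainpair.synthetic_data import default_catalog, pate_remnant, random_sequence


def _rand(seed, n):
    return random_sequence(np.random.default_rng(seed), n)


CATALOG = default_catalog()
PATE = next(f for f in CATALOG if f.code == "PATE1")
TPB = next(f for f in CATALOG if f.code == "TPB1")
SMRA = next(f for f in CATALOG if f.code == "SMRA1")


class TestFamilyInvariants:
    def test_td_only_for_canonical_and_mite(self):
        for f in CATALOG:
            if f.category in ("TP_B", "MITE"):
                assert f.td_range is not None
            else:
                assert f.td_range is None and f.max_td == 0

    def test_td_forbidden_for_other_categories(self):
        with pytest.raises(ValueError):
            ElementFamily("X", "PATE", "ACGT" * 30, td_range=(4, 6))

    def test_catalog_round_trip(self, tmp_path):
        write_catalog(CATALOG, tmp_path / "cat.fasta", tmp_path / "cat.tsv")
        back = load_catalog(tmp_path / "cat.fasta", tmp_path / "cat.tsv")
        assert [(f.code, f.category, f.consensus, f.td_range) for f in back] == [
            (f.code, f.category, f.consensus, f.td_range) for f in CATALOG
        ]


class TestLocateElements:
    def test_planted_exact_copy(self):
        g = Genome("g", _rand(1, 20_000) + PATE.consensus + _rand(2, 20_000))
        hits = locate_elements(g, [PATE])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (20_000, 20_390)
        assert h.completeness == "complete" and h.identity >= 0.99

    def test_terminal_only_remnant(self):
        remnant, _, _ = pate_remnant(PATE)
        g = Genome("g", _rand(3, 15_000) + remnant + _rand(4, 15_000))
        hits = locate_elements(g, [PATE])
        assert any(h.completeness == "terminal_only" for h in hits)
        h = next(h for h in hits if h.completeness == "terminal_only")
        assert abs(h.start - 15_000) <= 2 and abs(h.end - 15_052) <= 2

    def test_empty_catalog(self):
        g = Genome("g", _rand(5, 12_000))
        assert locate_elements(g, []) == []

    def test_nested_insert_still_complete(self):
        comp = PATE.consensus[:200] + SMRA.consensus + PATE.consensus[200:]
        g = Genome("g", _rand(6, 10_000) + comp + _rand(7, 10_000))
        hits = locate_elements(g, [PATE, SMRA])
        by_fam = {h.family.code: h for h in hits}
        assert by_fam["PATE1"].completeness == "complete"
        assert by_fam["SMRA1"].completeness == "complete"
        # strict nesting
        assert by_fam["PATE1"].start < by_fam["SMRA1"].start
        assert by_fam["SMRA1"].end < by_fam["PATE1"].end

    def test_shared_itr_does_not_cross_match(self):
        # the MITE shares its ITR with the parent transposon; neither scan
        # may claim the other family's site
        mite = next(f for f in CATALOG if f.code == "MITE1")
        g = Genome("g", _rand(8, 10_000) + mite.consensus + _rand(9, 10_000))
        assert locate_elements(g, [TPB]) == []
        hits = locate_elements(g, [mite])
        assert len(hits) == 1 and hits[0].completeness == "complete"


class TestSSEI:
    def _pair_with_ssei(self, fam, td):
        left, right = _rand(20, 5_000), _rand(21, 5_000)
        # unambiguous junction: the element must not extend the duplicated
        # target by chance on either side
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        if left[-td - 1] == fam.consensus[-1]:
            left = left[: -td - 1] + alt[left[-td - 1]] + left[-td:]
        if right[0] == fam.consensus[0]:
            right = alt[right[0]] + right[1:]
        if left[-1] == fam.consensus[-1]:
            left = left[:-1] + alt[left[-1]]
        ins = fam.consensus + (left[-td:] if td else "")
        a = left + ins + right
        b = left + right
        A, B = Genome("A", a), Genome("B", b)
        cmap = compare_chromosomes(A, B)
        region = [c for c in cmap.connectors() if max(c.lenA, c.lenB) >= 20][0]
        hitsA = locate_elements(A, [fam], genome_label="A")
        hitsB = locate_elements(B, [fam], genome_label="B")
        call_ssei(cmap, hitsA, hitsB, [region])
        return cmap, region, hitsA, hitsB

    def test_planted_mite_with_td_is_ssei(self):
        mite = next(f for f in CATALOG if f.code == "MITE1")
        cmap, region, hitsA, _ = self._pair_with_ssei(mite, td=5)
        assert len(hitsA) == 1 and hitsA[0].status == "SSEI"
        assert detect_target_duplication(cmap, hitsA[0], region) == 5

    def test_pate_ssei_no_td(self):
        cmap, region, hitsA, _ = self._pair_with_ssei(PATE, td=0)
        assert hitsA[0].status == "SSEI"
        assert detect_target_duplication(cmap, hitsA[0], region) == 0

    def test_common_element_at_aligned_positions(self):
        seq = _rand(30, 4_000) + SMRA.consensus + _rand(31, 4_000)
        a = seq
        b = seq[:1000] + seq[1000:]  # identical
        A, B = Genome("A", a), Genome("B", b)
        cmap = compare_chromosomes(A, B)
        hitsA = locate_elements(A, [SMRA], genome_label="A")
        hitsB = locate_elements(B, [SMRA], genome_label="B")
        call_ssei(cmap, hitsA, hitsB, [])
        assert hitsA[0].status == "common" and hitsB[0].status == "common"

    def test_element_inside_larger_indel(self):
        left, right = _rand(40, 4_000), _rand(41, 4_000)
        foreign = _rand(42, 800) + SMRA.consensus + _rand(43, 900)
        a = left + foreign + right
        b = left + right
        A, B = Genome("A", a), Genome("B", b)
        cmap = compare_chromosomes(A, B)
        region = [c for c in cmap.connectors() if max(c.lenA, c.lenB) >= 20][0]
        hitsA = locate_elements(A, [SMRA], genome_label="A")
        call_ssei(cmap, hitsA, [], [region])
        assert hitsA[0].status == "within_indel"


class TestTargetingMatrix:
    def test_no_nesting_zero_matrix(self):
        h1 = ElementHit(PATE, "A", 100, 490)
        h2 = ElementHit(SMRA, "A", 600, 710)
        m = targeting_matrix([h1, h2], [])
        assert m.grand_total == 0

    def test_strict_nesting_counted_per_genome(self):
        host = ElementHit(PATE, "A", 100, 600)
        inner = ElementHit(SMRA, "A", 200, 310)
        abutting = ElementHit(SMRA, "A", 100, 210)  # shares the host start
        m = targeting_matrix([host, inner, abutting], [host, inner])
        assert m.counts.loc["SMR_A", "PATE"] == 2
        assert m.grand_total == 2

    def test_margins_recompute_from_cells(self):
        rng = np.random.default_rng(0)
        counts = TargetingMatrix.from_counts(
            __import__("pandas").DataFrame(
                rng.integers(0, 9, size=(6, 6)), index=CATEGORIES, columns=CATEGORIES
            )
        )
        wm = counts.with_margins()
        assert wm.loc["Total", "Total"] == counts.grand_total
        assert (wm.loc["Total"][CATEGORIES] == counts.column_totals).all()
        assert (wm["Total"][CATEGORIES] == counts.row_totals).all()


class TestCoreDeletion:
    def test_complete_vs_remnant_pair(self):
        remnant, rep_len, lead = pate_remnant(PATE)
        left, right = _rand(50, 4_000), _rand(51, 4_000)
        a = left + PATE.consensus + right
        b = left + remnant + right
        A, B = Genome("A", a), Genome("B", b)
        cmap = compare_chromosomes(A, B)
        region = [c for c in cmap.connectors() if max(c.lenA, c.lenB) >= 20][0]
        hitA = locate_elements(A, [PATE], genome_label="A")[0]
        hitB = locate_elements(B, [PATE], genome_label="B")[0]
        assert hitA.completeness == "complete" and hitB.completeness == "terminal_only"
        ok, fl = detect_core_deletion((hitA, hitB), cmap, region)
        assert ok and fl is not None and fl.repeat_len == rep_len

    def test_both_complete_false(self):
        h1 = ElementHit(PATE, "A", 0, 390, completeness="complete")
        h2 = ElementHit(PATE, "B", 0, 390, completeness="complete")
        assert detect_core_deletion((h1, h2)) == (False, None)
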