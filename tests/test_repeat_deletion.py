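"""Junction direct repeats, the deletion length law, and the chance
expectation statistic."""

import numpy as np
import pytest

from strainpair.run_connector import Connector
from strainpair.repeat_deletion import (
    CENSUS_BINS,
    RepeatFlank,
    apply_repeat_mediated_deletion,
    expected_chance_repeats,
    flanking_direct_repeat,
    repeat_length_census,
)
from strainpair.synthetic_data import default_catalog, pate_remnant, random_sequence


def _rand(seed, n):
    return random_sequence(np.random.default_rng(seed), n)


def _planted_region(seed, repeat, core, flank=300):
    """Retained strain: L R core R Rt; deleted strain: L R Rt.  Returns
    (seqA, seqB, region) with the region as the map would place it
    (junction after the left run L+R)."""
    rng = np.random.default_rng(seed)
    left, right = _rand(seed + 1, flank), _rand(seed + 2, flank)
    core = list(core)
    if core[0] == right[0]:
        core[0] = "ACGT"["ACGT".index(right[0]) - 1]
    if core[-1] == left[-1]:
        core[-1] = "ACGT"["ACGT".index(left[-1]) - 1]
    core = "".join(core)
    seqA = left + repeat + core + repeat + right
    seqB = left + repeat + right
    region = Connector(flank + len(repeat), len(core) + len(repeat), flank + len(repeat), 0)
    return seqA, seqB, region


class TestFlankingDirectRepeat:
    def test_known_ten_mer_junction(self):
        # the classic genomic-island boundary case: ACATCATTCT repeated at
        # both ends of the retained segment, single copy in the other strain
        rep = "ACATCATTCT"
        seqA, seqB, region = _planted_region(1, rep, _rand(3, 200))
        fl = flanking_direct_repeat((seqA, seqB), region)
        assert fl is not None and fl.exact
        assert fl.repeat_len == 10 and fl.repeat_seq == rep
        assert fl.deleted_total == fl.core_len + 10

    def test_unrelated_junction_none(self):
        seqA, seqB, region = _planted_region(5, "", _rand(6, 60))
        # force mismatching junction bases on both phases
        fl = flanking_direct_repeat((seqA, seqB), region)
        assert fl is None or fl.repeat_len < 4

    @pytest.mark.parametrize("rep_len", [4, 8, 15, 22])
    def test_planted_repeat_recovered_exactly(self, rep_len):
        rep = _rand(50 + rep_len, rep_len)
        seqA, seqB, region = _planted_region(60 + rep_len, rep, _rand(70 + rep_len, 120))
        fl = flanking_direct_repeat((seqA, seqB), region)
        assert fl is not None and fl.exact and fl.repeat_len == rep_len

    def test_brute_force_scan_oracle(self):
        # oracle: exhaustive max prefix/suffix junction match
        rep = _rand(90, 8)
        seqA, seqB, region = _planted_region(91, rep, _rand(92, 50))
        ins = seqA[region.startA : region.endA]
        left = seqA[: region.startA]
        right = seqA[region.endA :]
        best = 0
        for r in range(1, len(ins) + 1):
            if ins[:r] == right[:r] or ins[-r:] == left[-r:]:
                best = r
        fl = flanking_direct_repeat((seqA, seqB), region)
        assert fl.repeat_len == best == 8


class TestApplyDeletion:
    def test_pate_element_shortens_to_fused_termini(self):
        # 390 bp element with a perfect 22 bp direct repeat: core deletion
        # leaves the concatenated 52 bp terminal sequences
        fam = next(f for f in default_catalog() if f.code == "PATE1")
        remnant, rep_len, lead = pate_remnant(fam)
        out = apply_repeat_mediated_deletion(fam.consensus, lead, lead + rep_len + 316, rep_len)
        assert len(fam.consensus) == 390 and len(out) == 52
        assert out == remnant

    def test_zero_core_removes_one_copy(self):
        seq = "AAGG" + "TTCA" + "TTCA" + "GGAA"
        out = apply_repeat_mediated_deletion(seq, 4, 8, 4)
        assert out == "AAGG" + "TTCA" + "GGAA"

    def test_round_trip_on_random_construction(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            left = _rand(int(rng.integers(1e6)), 30)
            rep = _rand(int(rng.integers(1e6)), int(rng.integers(4, 23)))
            core = _rand(int(rng.integers(1e6)), int(rng.integers(0, 200)))
            right = _rand(int(rng.integers(1e6)), 30)
            seq = left + rep + core + rep + right
            out = apply_repeat_mediated_deletion(seq, 30, 30 + len(rep) + len(core), len(rep))
            assert out == left + rep + right
            assert len(seq) - len(out) == len(core) + len(rep)

    def test_mismatched_repeats_error(self):
        with pytest.raises(ValueError):
            apply_repeat_mediated_deletion("AAAACCCC", 0, 4, 4)


class TestChanceExpectation:
    def test_printed_value_for_99_indels(self):
        e = expected_chance_repeats(99, 4)
        assert e == pytest.approx(99 * 0.25**4)
        assert round(e, 1) == 0.4

    def test_zero_indels(self):
        assert expected_chance_repeats(0, 4) == 0.0

    def test_monotonicity(self):
        ks = [expected_chance_repeats(99, k) for k in range(1, 10)]
        assert ks == sorted(ks, reverse=True)
        ns = [expected_chance_repeats(n, 4) for n in (0, 10, 50, 99)]
        assert ns == sorted(ns)

    def test_composition_adjusted(self):
        freqs = {"A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26}
        p = sum(f * f for f in freqs.values())
        assert expected_chance_repeats(99, 4, freqs) == pytest.approx(99 * p**4)

    def test_invalid_freqs_rejected(self):
        with pytest.raises(ValueError):
            expected_chance_repeats(10, 4, [0.5, 0.5, 0.5, 0.5])

    def test_monte_carlo_match_probability(self):
        # simulation oracle: fraction of random junction pairs whose first
        # 4 bases match is (1/4)^4 within 3 standard errors
        rng = np.random.default_rng(0)
        n = 100_000
        a = rng.integers(0, 4, size=(n, 4))
        b = rng.integers(0, 4, size=(n, 4))
        frac = float(np.mean((a == b).all(axis=1)))
        p = 0.25**4
        se = (p * (1 - p) / n) ** 0.5
        assert abs(frac - p) < 3 * se


class TestCensus:
    def test_empty_all_zero(self):
        df = repeat_length_census([])
        assert list(df["repeat_length"]) == CENSUS_BINS
        assert df["observed"].sum() == 0

    def test_planted_bins(self):
        flanks = [
            RepeatFlank("AAAA", 4, True, 0, 10, 14),
            RepeatFlank("AAAA", 4, True, 0, 10, 14),
            RepeatFlank("AAAA", 4, True, 0, 10, 14),
            RepeatFlank("A" * 12, 12, True, 0, 5, 17),
            RepeatFlank("A" * 15, 15, True, 0, 5, 20),
            RepeatFlank("A" * 8, 8, False, 1, 5, 13),  # variant: excluded
            None,
        ]
        df = repeat_length_census(flanks).set_index("repeat_length")
        assert df.loc["4", "observed"] == 3
        assert df.loc["10-19", "observed"] == 2
        assert df.loc["7-9", "observed"] == 0
        assert df.loc["4", "expected_by_chance"] == pytest.approx(
            expected_chance_repeats(7, 4)
        )
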