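"""The simulator: determinism, calibration, reconstructability, and
recovery scoring."""

import numpy as np
import pytest

from strainpair.seq_io import RegionRecord
from strainpair.synthetic_data import (
    DEFAULT_EVENT_COUNTS,
    SimConfig,
    derive_strain_pair,
    generate_ancestor,
    score_recovery,
)


def _cfg(**kw):
    base = dict(ancestor_length=60_000, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestAncestor:
    def test_gc_calibration(self):
        cfg = _cfg(ancestor_length=100_000, gc=0.5, seed=1)
        g = generate_ancestor(cfg)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert gc == pytest.approx(0.5, abs=0.005)

    def test_seed_determinism(self):
        cfg = _cfg(seed=7)
        assert generate_ancestor(cfg).sequence == generate_ancestor(cfg).sequence

    def test_gc_zero_all_at(self):
        g = generate_ancestor(_cfg(ancestor_length=20_000, gc=0.0))
        assert set(g.sequence) <= {"A", "T"}

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            generate_ancestor(_cfg(ancestor_length=500))


class TestDeriveStrainPair:
    def test_no_events_no_subs_identical(self):
        cfg = _cfg(substitution_rate=0.0, event_counts={})
        anc = generate_ancestor(cfg)
        A, B, truth = derive_strain_pair(anc, cfg)
        assert A.sequence == B.sequence == anc.sequence
        assert truth == []

    def test_determinism(self):
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        A1, B1, _ = derive_strain_pair(anc, cfg)
        A2, B2, _ = derive_strain_pair(anc, cfg)
        assert A1.sequence == A2.sequence and B1.sequence == B2.sequence

    def test_reconstruction_from_truth(self):
        # replaying the truth log on the ancestor reproduces both strains
        # byte-exactly: the simulator is its own oracle
        cfg = _cfg(common_elements=2, nested_elements=2)
        anc = generate_ancestor(cfg)
        A, B, truth = derive_strain_pair(anc, cfg)
        partsA, partsB = [], []
        prev = 0
        for t in sorted(truth, key=lambda t: t.ancestor_pos):
            seg = anc.sequence[prev : t.ancestor_pos]
            partsA.append(seg)
            partsB.append(seg)
            partsA.append(t.payload_a)
            partsB.append(t.payload_b)
            prev = t.ancestor_pos + t.consumed
        partsA.append(anc.sequence[prev:])
        partsB.append(anc.sequence[prev:])
        assert "".join(partsA) == A.sequence
        assert "".join(partsB) == B.sequence

    def test_region_payloads_extractable(self):
        # region coordinates point at the planted sequence difference
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        A, B, truth = derive_strain_pair(anc, cfg)
        for t in truth:
            if not t.expects_region or t.kind != "dci":
                continue
            assert A.sequence[t.posA : t.posA + t.lenA] == t.payload_a
            assert B.sequence[t.posB : t.posB + t.lenB] == t.payload_b

    def test_planted_repeat_deletions_satisfy_length_law(self):
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        A, B, truth = derive_strain_pair(anc, cfg)
        for t in truth:
            if t.kind != "repeat_deletion":
                continue
            # deleted total = region length = core + one repeat copy
            region_len = max(t.lenA, t.lenB)
            assert region_len == abs(len(t.payload_a) - len(t.payload_b))
            assert region_len > t.repeat_len

    def test_infeasible_packing_raises(self):
        cfg = _cfg(ancestor_length=10_000, event_counts={"indel_long": 50})
        anc = generate_ancestor(cfg)
        with pytest.raises(ValueError, match="indel"):
            derive_strain_pair(anc, cfg)

    def test_default_event_mix_sums_to_fifty(self):
        assert sum(DEFAULT_EVENT_COUNTS.values()) == 50


class TestScoreRecovery:
    def _records_from_truth(self, truth):
        recs = []
        i = 1
        for t in truth:
            if not t.expects_region:
                continue
            recs.append(
                RegionRecord(
                    region_number=i,
                    category=t.category,
                    posA=t.posA + 1,
                    lenA=t.lenA,
                    posB=t.posB + 1,
                    lenB=t.lenB,
                )
            )
            i += 1
        return sorted(recs, key=lambda r: r.posA)

    def test_perfect_output(self):
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        _, _, truth = derive_strain_pair(anc, cfg)
        m = score_recovery(self._records_from_truth(truth), truth)
        assert m.sensitivity == 1.0 and m.precision == 1.0
        assert m.boundary_exact_fraction == 1.0
        assert m.category_match_fraction == 1.0

    def test_shifted_by_repeat_period_still_exact(self):
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        _, _, truth = derive_strain_pair(anc, cfg)
        recs = self._records_from_truth(truth)
        by_pos = {r.posA - 1: r for r in recs}
        for t in truth:
            if t.kind == "repeat_deletion" and t.shift_slack > 0:
                r = by_pos[t.posA]
                r.posA -= t.shift_slack
                r.posB -= t.shift_slack
        m = score_recovery(recs, truth)
        assert m.boundary_exact_fraction == 1.0

    def test_random_output_near_zero_precision(self):
        rng = np.random.default_rng(3)
        cfg = _cfg()
        anc = generate_ancestor(cfg)
        _, _, truth = derive_strain_pair(anc, cfg)
        junk = [
            RegionRecord(i + 1, "misc", int(p) + 1, 17, int(p) + 1, 0)
            for i, p in enumerate(np.sort(rng.integers(0, 50_000, size=40)))
        ]
        m = score_recovery(junk, truth)
        assert m.precision <= 0.1
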