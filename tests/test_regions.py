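"""CNAR/MCR region algebra: overlap, grouping, intersection, recurrence."""

import numpy as np
import pytest

from cnamcr.regions import (
    amplification_deletion_regions,
    annotate_genes,
    build_cnar,
    build_mcr,
    reciprocal_overlap,
    recurrence_table,
)
from cnamcr.types import CNACall, GeneModel, RecurrentRegion


def call(sample, start, end, direction="gain", chrom="chr1", platform="p1", mean=None):
    if mean is None:
        mean = 0.5 if direction == "gain" else -0.5
    klass = direction
    if abs(mean) >= 0.8:
        klass = "amplification" if direction == "gain" else "deletion"
    return CNACall(
        sample_id=sample, chrom=chrom, start=start, end=end, i0=0, i1=3,
        mean_log2=mean, score=10.0, platform_id=platform,
        direction=direction, amplitude_class=klass,
    )


class TestReciprocalOverlap:
    def test_identity(self):
        assert reciprocal_overlap(("c", 0, 100), ("c", 0, 100)) == 1.0

    def test_half_overlap(self):
        assert reciprocal_overlap(("c", 0, 100), ("c", 50, 150)) == 0.5

    def test_asymmetric_lengths(self):
        assert reciprocal_overlap(("c", 0, 100), ("c", 90, 200)) == pytest.approx(10 / 110)

    def test_disjoint_and_cross_chromosome(self):
        assert reciprocal_overlap(("c", 0, 10), ("c", 10, 20)) == 0.0
        assert reciprocal_overlap(("c1", 0, 10), ("c2", 0, 10)) == 0.0


class TestBuildCnar:
    def test_two_identical_segments(self):
        cnars = build_cnar([call("a", 100, 200), call("b", 100, 200)], "gain", n_cohort=10)
        assert len(cnars) == 1
        assert cnars[0].frequency == pytest.approx(0.2)
        assert (cnars[0].start, cnars[0].end) == (100, 200)

    def test_exactly_ninety_percent_is_not_enough(self):
        # overlap = 90/100 = 0.9, rule is strictly greater
        cnars = build_cnar([call("a", 100, 200), call("b", 105, 195)], "gain", n_cohort=10)
        assert cnars == []

    def test_transitive_chain_forms_one_cnar(self):
        a = call("a", 0, 100)
        b = call("b", 5, 105)     # RO(a,b) = 95/100 > 0.9
        c = call("c", 10, 110)    # RO(b,c) > 0.9 but RO(a,c) = 90/100 = 0.9
        assert reciprocal_overlap(a, c) == pytest.approx(0.9)
        cnars = build_cnar([a, b, c], "gain", n_cohort=3)
        assert len(cnars) == 1
        assert cnars[0].samples == {"a", "b", "c"}
        assert (cnars[0].start, cnars[0].end) == (0, 110)

    def test_single_sample_component_dropped(self):
        cnars = build_cnar([call("a", 0, 100), call("a", 2, 98)], "gain", n_cohort=5)
        assert cnars == []

    def test_order_independence(self, rng):
        calls = [call(f"s{i}", int(s), int(s) + 100) for i, s in
                 enumerate(rng.integers(0, 50, 12))]
        a = build_cnar(calls, "gain", n_cohort=12)
        b = build_cnar(calls[::-1], "gain", n_cohort=12)
        assert [(r.start, r.end, tuple(sorted(r.samples))) for r in a] == [
            (r.start, r.end, tuple(sorted(r.samples))) for r in b
        ]


def cnar_from(members, platform):
    return RecurrentRegion(
        kind="CNAR",
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        direction=members[0].direction,
        member_segments=members,
        samples={m.sample_id for m in members},
        platforms={platform},
        frequency=0.0,
    )


class TestBuildMcr:
    def test_three_platform_intersection(self):
        cnars = {
            "p1": [cnar_from([call("a", 100, 200, platform="p1")], "p1")],
            "p2": [cnar_from([call("b", 150, 250, platform="p2")], "p2")],
            "p3": [cnar_from([call("c", 120, 220, platform="p3")], "p3")],
        }
        mcrs = build_mcr(cnars, n_cohort=3)
        assert len(mcrs) == 1
        assert (mcrs[0].start, mcrs[0].end) == (150, 200)

    def test_empty_intersection_dropped(self):
        cnars = {
            "p1": [cnar_from([call("a", 0, 100, platform="p1"),
                              call("b", 200, 300, platform="p1")], "p1")],
            "p2": [cnar_from([call("c", 90, 210, platform="p2")], "p2")],
        }
        # members [0,100), [200,300), [90,210) have empty common intersection
        assert build_mcr(cnars, n_cohort=3) == []

    def test_missing_platform_excluded(self):
        cnars = {
            "p1": [cnar_from([call("a", 100, 200, platform="p1")], "p1")],
            "p2": [],
        }
        assert build_mcr(cnars, n_cohort=2) == []

    def test_mcr_frequency_counts_fully_covering_samples(self):
        cnars = {
            "p1": [cnar_from([call("a", 100, 200, platform="p1"),
                              call("b", 160, 240, platform="p1")], "p1")],
            "p2": [cnar_from([call("c", 150, 250, platform="p2")], "p2")],
        }
        mcrs = build_mcr(cnars, n_cohort=4, n_by_platform={"p1": 2, "p2": 2})
        assert len(mcrs) == 1
        m = mcrs[0]
        assert (m.start, m.end) == (160, 200)
        assert m.samples == {"a", "b", "c"}  # all members cover [160,200)
        assert m.frequency == pytest.approx(3 / 4)
        assert m.frequency_by_platform == {"p1": 1.0, "p2": 0.5}

    def test_invariant_mcr_inside_every_member_inside_cnar(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            loc = int(r.integers(0, 1000))
            members = {}
            for plat in ("p1", "p2", "p3"):
                ms = [
                    call(f"{plat}_s{i}", loc + int(r.integers(0, 40)),
                         loc + 100 + int(r.integers(0, 40)), platform=plat)
                    for i in range(int(r.integers(1, 4)))
                ]
                members[plat] = [cnar_from(ms, plat)]
            for m in build_mcr(members, n_cohort=9):
                for seg in m.member_segments:
                    assert seg.start <= m.start and m.end <= seg.end

    def test_matches_brute_force_oracle_on_random_instances(self):
        from oracles import brute_force_mcr, random_mcr_instance

        for seed in range(60):
            cnars, n_cohort = random_mcr_instance(seed)
            got = {(m.chrom, m.start, m.end, m.direction) for m in build_mcr(cnars, n_cohort)}
            want = brute_force_mcr(cnars)
            assert got == want


class TestRecurrenceTable:
    def _region(self, freq, direction="gain"):
        return RecurrentRegion("MCR", "chr1", 0, 100, direction, [], set(), {"p"}, freq)

    @pytest.mark.parametrize(
        "num,den,min_freq,inclusive,kept",
        [
            (18, 88, 0.20, False, True),   # 20.45% > 20%
            (17, 88, 0.20, False, False),  # 19.3%
            (9, 88, 0.10, True, True),     # 10.2% >= 10%
            (20, 100, 0.20, False, False),  # exactly 20%, exclusive
            (20, 100, 0.20, True, True),
        ],
    )
    def test_frequency_filter_boundaries(self, num, den, min_freq, inclusive, kept):
        tab = recurrence_table([self._region(num / den)], den, min_freq, inclusive)
        assert (len(tab) == 1) is kept

    def test_percent_column_rounding(self):
        tab = recurrence_table([self._region(0.4318)], 100, 0.2, False)
        assert tab.iloc[0]["percent"] == pytest.approx(43.2)


class TestAnnotateGenes:
    def test_containment_overlap_and_miss(self):
        region = RecurrentRegion("MCR", "c", 5, 30, "gain", [], set(), set(), 0.5)
        genes = [GeneModel("inside", "c", 10, 20), GeneModel("edge", "c", 25, 40),
                 GeneModel("away", "c", 40, 50), GeneModel("other", "x", 10, 20)]
        contained, overlapping = annotate_genes(region, genes)
        assert contained == ["inside"]
        assert overlapping == ["edge"]


class TestAmplificationDeletionRegions:
    def test_planted_high_amplitude_event_appears(self):
        calls = {"p1": [call(f"s{i}", 100, 200, mean=1.0) for i in range(3)]}
        tab = amplification_deletion_regions(calls, n_cohort=25, min_freq=0.10)
        amp = tab[tab["class"] == "amplification"]
        assert len(amp) == 1
        assert amp.iloc[0]["frequency"] == pytest.approx(3 / 25)

    def test_low_amplitude_gains_excluded(self):
        calls = {"p1": [call(f"s{i}", 100, 200, mean=0.5) for i in range(5)]}
        tab = amplification_deletion_regions(calls, n_cohort=10)
        assert len(tab) == 0

    def test_negation_maps_amplifications_to_deletions(self):
        gains = {"p1": [call(f"s{i}", 100, 200, mean=1.0) for i in range(3)]}
        losses = {"p1": [call(f"s{i}", 100, 200, direction="loss", mean=-1.0)
                         for i in range(3)]}
        ta = amplification_deletion_regions(gains, n_cohort=10)
        td = amplification_deletion_regions(losses, n_cohort=10)
        assert list(ta["class"]) == ["amplification"]
        assert list(td["class"]) == ["deletion"]
        assert ta.iloc[0]["frequency"] == td.iloc[0]["frequency"]
        assert (ta.iloc[0]["start"], ta.iloc[0]["end"]) == (td.iloc[0]["start"], td.iloc[0]["end"])
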