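"""Compartment/TAD/FIRE/chromatin-state overlap logic."""

import numpy as np
import pandas as pd
import pytest

from crhnet.annotations import (
    STATE_GROUPING,
    compartment_category,
    region_set_enrichment,
    state_combination,
    state_combination_census,
    state_profile,
    tad_overlap_count,
    tads_with_k_crhs,
)
from crhnet.hubs import build_crhs, crh_metrics
from crhnet.intervals import GenomicInterval


def make_crh(node_positions, edges):
    """node_positions: id -> (start, end); edges: (gene, element) pairs."""
    pairs = pd.DataFrame(
        [{"gene_id": g, "element_id": e, "functional": True} for g, e in edges]
    )
    (crh,) = build_crhs(pairs)
    el = {
        e: GenomicInterval("chr1", *node_positions[e], id=e) for e in crh.distal_ids
    }
    pr = {
        g: GenomicInterval("chr1", *node_positions[g], id=g) for g in crh.promoter_ids
    }
    crh_metrics(crh, el, pr)
    return crh, el, pr


COMPARTMENTS = [
    GenomicInterval("chr1", 0, 10_000, id="A"),
    GenomicInterval("chr1", 10_000, 20_000, id="B"),
    GenomicInterval("chr1", 20_000, 30_000, id="A"),
]


class TestCompartmentCategory:
    def test_both_extremes_in_A(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (2000, 2500), "E2": (8000, 8500)},
            [("P1", "E1"), ("P1", "E2")],
        )
        assert compartment_category(crh, COMPARTMENTS, el, pr) == "AA"

    def test_extremes_in_A_and_B(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (15_000, 15_500)}, [("P1", "E1")]
        )
        assert compartment_category(crh, COMPARTMENTS, el, pr) == "AB"

    def test_extreme_outside_calls_unassigned(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (40_000, 40_500)}, [("P1", "E1")]
        )
        assert compartment_category(crh, COMPARTMENTS, el, pr) == "unassigned"

    def test_invalid_labels_rejected(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (2000, 2500)}, [("P1", "E1")]
        )
        with pytest.raises(ValueError, match="A/B"):
            compartment_category(
                crh, [GenomicInterval("chr1", 0, 10_000, id="open")], el, pr
            )


TADS = [
    GenomicInterval("chr1", 0, 10_000, id="t1"),
    GenomicInterval("chr1", 10_000, 20_000, id="t2"),
]


class TestTadOverlap:
    def test_span_inside_one_tad(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (4000, 4500)}, [("P1", "E1")]
        )
        assert tad_overlap_count(crh, TADS) == 1

    def test_span_crossing_boundary(self):
        crh, el, pr = make_crh(
            {"P1": (8000, 8500), "E1": (12_000, 12_500)}, [("P1", "E1")]
        )
        assert tad_overlap_count(crh, TADS) == 2

    def test_overlapping_tads_rejected(self):
        crh, el, pr = make_crh(
            {"P1": (1000, 1500), "E1": (4000, 4500)}, [("P1", "E1")]
        )
        bad = TADS + [GenomicInterval("chr1", 5000, 15_000, id="t3")]
        with pytest.raises(ValueError, match="overlap"):
            tad_overlap_count(crh, bad)

    def test_histogram_identity(self):
        crhs = []
        for positions, edges in [
            ({"P1": (1000, 1500), "E1": (4000, 4500)}, [("P1", "E1")]),
            ({"P2": (8000, 8500), "E2": (12_000, 12_500)}, [("P2", "E2")]),
            ({"P3": (15_000, 15_200), "E3": (18_000, 18_400)}, [("P3", "E3")]),
        ]:
            crh, _, _ = make_crh(positions, edges)
            crhs.append(crh)
        hist = tads_with_k_crhs(crhs, TADS)
        total_pairs = sum(k * v for k, v in hist.items())
        oracle = sum(
            1 for c in crhs for t in TADS if c.span.overlap_bp(t) >= 1
        )
        assert total_pairs == oracle
        assert sum(tad_overlap_count(c, TADS) for c in crhs) >= len(crhs)


class TestRegionSetEnrichment:
    def test_degenerate_table_haldane(self):
        inside = [GenomicInterval("chr1", 0, 100, id="i0"),
                  GenomicInterval("chr1", 200, 300, id="i1")]
        outside = [GenomicInterval("chr1", 5000, 5100, id="c0"),
                   GenomicInterval("chr1", 6000, 6100, id="c1")]
        regions = [GenomicInterval("chr1", 0, 400)]
        res = region_set_enrichment(inside, outside, regions)
        assert res.table == (2, 0, 0, 2)
        assert res.corrected and np.isfinite(res.odds_ratio)

    def test_identical_rates_or_near_one(self):
        inside = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, id=f"i{i}")
                  for i in range(10)]
        outside = [GenomicInterval("chr1", 50_000 + i * 1000, 50_000 + i * 1000 + 100,
                                   id=f"c{i}") for i in range(10)]
        regions = [GenomicInterval("chr1", 0, 5100),
                   GenomicInterval("chr1", 50_000, 55_100)]
        res = region_set_enrichment(inside, outside, regions)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_planted_overlap_detected_across_seeds(self):
        # in-hub elements overlap the region set ~2x more often than candidates
        detected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            inside = [GenomicInterval("chr1", int(p), int(p) + 100, id=f"i{k}")
                      for k, p in enumerate(rng.integers(0, 100_000, 150))]
            outside = [GenomicInterval("chr1", int(p), int(p) + 100, id=f"c{k}")
                       for k, p in enumerate(rng.integers(0, 100_000, 150))]
            regions = [GenomicInterval("chr1", s, s + 1000)
                       for s in range(0, 100_000, 10_000)]  # 10% of the genome
            # double the in-set's hit rate by moving half its misses into regions
            inside = [
                GenomicInterval("chr1", 500, 600, id=iv.id)
                if (k % 2 == 0 and not any(iv.overlap_bp(r) for r in regions))
                else iv
                for k, iv in enumerate(inside)
            ]
            res = region_set_enrichment(inside, outside, regions)
            if res.odds_ratio > 1 and res.p_two_sided < 0.05:
                detected += 1
        assert detected >= 45  # >= 90% of 50 seeds


STATES = [
    GenomicInterval("chr1", 0, 10_000, id="1_TssA"),
    GenomicInterval("chr1", 10_000, 20_000, id="18_Quies"),
    GenomicInterval("chr1", 20_000, 30_000, id="9_EnhA1"),
]


class TestStateProfile:
    def test_fully_inside_quiescent(self):
        ivs = [GenomicInterval("chr1", 12_000, 12_500, id="e1")]
        _, state_props, group_props = state_profile(ivs, STATES)
        assert state_props == {"18_Quies": 1.0}
        assert group_props == {"InactiveRepressor": 1.0}

    def test_straddling_counts_in_both_groups(self):
        ivs = [GenomicInterval("chr1", 9500, 10_500, id="e1")]
        _, state_props, group_props = state_profile(ivs, STATES)
        assert state_props == {"1_TssA": 1.0, "18_Quies": 1.0}
        assert group_props == {"Active": 1.0, "InactiveRepressor": 1.0}

    def test_unknown_label_rejected(self):
        ivs = [GenomicInterval("chr1", 0, 100, id="e1")]
        with pytest.raises(ValueError, match="unknown state"):
            state_profile(ivs, [GenomicInterval("chr1", 0, 1000, id="19_Custom")])

    def test_proportions_match_bitmask_oracle(self, rng):
        ivs = [
            GenomicInterval("chr1", int(p), int(p) + int(rng.integers(100, 2000)),
                            id=f"e{k}")
            for k, p in enumerate(rng.integers(0, 28_000, 40))
        ]
        _, state_props, _ = state_profile(ivs, STATES)
        for st in STATES:
            mask = np.zeros(40_000, dtype=bool)
            mask[st.start : st.end] = True
            expect = np.mean([mask[iv.start : iv.end].any() for iv in ivs])
            assert state_props.get(st.id, 0.0) == pytest.approx(expect)

    def test_grouping_covers_all_18_states(self):
        assert len(STATE_GROUPING) == 18
        assert set(STATE_GROUPING.values()) == {
            "Active", "WeaklyActive", "InactiveRepressor"
        }


class TestStateCombination:
    def combo_for(self, coverages, fraction=0.8):
        """Build a 1-element hub whose state coverages are as prescribed."""
        # lay out states consecutively, element spans them all
        states = []
        pos = 0
        for name, bp in coverages.items():
            states.append(GenomicInterval("chr1", pos, pos + bp, id=name))
            pos += bp
        crh, el, pr = make_crh(
            {"P1": (100_000, 100_500), "E1": (0, pos)}, [("P1", "E1")]
        )
        return state_combination(crh, states, el, pr, fraction), crh, states, el, pr

    def test_eighty_percent_prefix(self):
        combo, *_ = self.combo_for({"5_Tx": 50, "6_TxWk": 30, "13_Het": 20})
        assert combo == ("5_Tx", "6_TxWk")

    def test_single_state(self):
        combo, *_ = self.combo_for({"5_Tx": 100}, fraction=0.5)
        assert combo == ("5_Tx",)

    def test_zero_coverage_empty(self):
        crh, el, pr = make_crh(
            {"P1": (100, 600), "E1": (1000, 1400)}, [("P1", "E1")]
        )
        far = [GenomicInterval("chr1", 50_000, 60_000, id="5_Tx")]
        assert state_combination(crh, far, el, pr) == ()

    @pytest.mark.parametrize("seed", range(8))
    def test_minimal_prefix_matches_subset_enumeration(self, seed):
        from itertools import combinations

        rng = np.random.default_rng(seed)
        names = ["1_TssA", "5_Tx", "6_TxWk", "13_Het", "18_Quies"][
            : int(rng.integers(2, 6))
        ]
        coverages = {n: int(rng.integers(10, 200)) for n in names}
        combo, *_ = self.combo_for(coverages)
        total = sum(coverages.values())
        # oracle: smallest subset reaching 80% of the total coverage
        best = None
        for k in range(1, len(names) + 1):
            for sub in combinations(names, k):
                if sum(coverages[n] for n in sub) >= 0.8 * total:
                    best = k
                    break
            if best:
                break
        assert len(combo) == best
        assert sum(coverages[n] for n in combo) >= 0.8 * total

    def test_census_accounting(self):
        crhs, els, prs = [], {}, {}
        layouts = [
            {"P1": (0, 500), "E1": (1000, 1400)},
            {"P2": (50_000, 50_500), "E2": (51_000, 51_400)},
            {"P3": (100_000, 100_500), "E3": (101_000, 101_400)},
        ]
        edges = [("P1", "E1"), ("P2", "E2"), ("P3", "E3")]
        for layout, edge in zip(layouts, edges):
            crh, el, pr = make_crh(layout, [edge])
            crhs.append(crh)
            els.update(el)
            prs.update(pr)
        states = [GenomicInterval("chr1", 0, 60_000, id="5_Tx"),
                  GenomicInterval("chr1", 60_000, 200_000, id="18_Quies")]
        census = state_combination_census(crhs, states, els, prs)
        assert census["n_crhs_with_coverage"] == sum(
            v for v in census["combinations"].values()
        )
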