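"""Overlap of hubs with 3D-genome and chromatin-state annotations.

Consumes interval calls (A/B compartments, TADs, FIREs, 18-state
ChromHMM-style segmentations, ENCODE candidate elements) as labelled BED;
calling those annotations is out of scope — any disjoint TAD set or A/B
labelling is accepted.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .hubs import CRH
from .intervals import GenomicInterval, overlap_hits
from .stats import EnrichmentResult, fisher_exact_2x2

__all__ = [
    "STATE_GROUPING",
    "compartment_category",
    "tad_overlap_count",
    "tads_with_k_crhs",
    "region_set_enrichment",
    "state_profile",
    "state_combination",
    "state_combination_census",
]

# 18-state chromatin model collapsed into three broad activity categories.
STATE_GROUPING: dict[str, str] = {
    "1_TssA": "Active",
    "2_TssFlnk": "Active",
    "3_TssFlnkU": "Active",
    "4_TssFlnkD": "Active",
    "5_Tx": "Active",
    "7_EnhG1": "Active",
    "8_EnhG2": "Active",
    "9_EnhA1": "Active",
    "10_EnhA2": "Active",
    "12_ZNF/Rpts": "Active",
    "6_TxWk": "WeaklyActive",
    "11_EnhWk": "WeaklyActive",
    "14_TssBiv": "WeaklyActive",
    "15_EnhBiv": "WeaklyActive",
    "13_Het": "InactiveRepressor",
    "16_ReprPC": "InactiveRepressor",
    "17_ReprPCWk": "InactiveRepressor",
    "18_Quies": "InactiveRepressor",
}


def _crh_node_intervals(
    crh: CRH,
    elements: Mapping[str, GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
) -> list[GenomicInterval]:
    ivs = [promoters[g] for g in sorted(crh.promoter_ids)]
    ivs += [elements[e] for e in sorted(crh.distal_ids)]
    return ivs


def compartment_category(
    crh: CRH,
    compartments: Sequence[GenomicInterval],
    elements: Mapping[str, GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
) -> str:
    """AA / AB / BB / unassigned from the hub's two outermost elements.

    Each extreme element is assigned to the A or B block it overlaps most
    (ties toward A; no overlap at all -> unassigned).
    """
    labels = {iv.id for iv in compartments}
    if not labels <= {"A", "B"}:
        raise ValueError(f"compartment labels must be A/B, got {sorted(labels)}")
    ivs = _crh_node_intervals(crh, elements, promoters)
    leftmost = min(ivs, key=lambda iv: (iv.start, iv.end))
    rightmost = max(ivs, key=lambda iv: (iv.end, iv.start))

    def assign(iv: GenomicInterval) -> str | None:
        best_label, best_bp = None, 0
        for comp in compartments:
            bp = iv.overlap_bp(comp)
            if bp > best_bp or (bp == best_bp and bp > 0 and comp.id == "A"):
                best_label, best_bp = comp.id, bp
        return best_label

    la, lb = assign(leftmost), assign(rightmost)
    if la is None or lb is None:
        return "unassigned"
    return {frozenset(["A"]): "AA", frozenset(["B"]): "BB", frozenset(["A", "B"]): "AB"}[
        frozenset([la, lb])
    ]


def _check_disjoint(tads: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(f"TADs overlap: {a} and {b}")


def tad_overlap_count(crh: CRH, tads: Sequence[GenomicInterval]) -> int:
    """Number of distinct (disjoint) TADs overlapped by the hub's span."""
    if crh.span is None:
        raise ValueError("call crh_metrics first (span missing)")
    _check_disjoint(tads)
    return sum(1 for t in tads if crh.span.overlap_bp(t) >= 1)


def tads_with_k_crhs(
    crhs: Sequence[CRH], tads: Sequence[GenomicInterval]
) -> dict[int, int]:
    """Histogram over TADs of the number of hub spans each one overlaps."""
    _check_disjoint(tads)
    spans = []
    for c in crhs:
        if c.span is None:
            raise ValueError("call crh_metrics first (span missing)")
        spans.append(c.span)
    per_tad = [sum(1 for s in spans if s.overlap_bp(t) >= 1) for t in tads]
    return dict(Counter(per_tad))


def region_set_enrichment(
    in_elements: Sequence[GenomicInterval],
    candidate_elements: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> EnrichmentResult:
    """Fisher 2x2 of {in hub vs candidate} x {overlaps region set vs not}."""
    def n_overlapping(ivs: Sequence[GenomicInterval]) -> int:
        return len({q for q, _, _ in overlap_hits(list(ivs), list(regions))})

    a = n_overlapping(in_elements)
    b = len(in_elements) - a
    c = n_overlapping(candidate_elements)
    d = len(candidate_elements) - c
    return fisher_exact_2x2(a, b, c, d)


def state_profile(
    element_ivs: Sequence[GenomicInterval],
    states: Sequence[GenomicInterval],
    grouping: Mapping[str, str] = STATE_GROUPING,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Which states (>=1 bp) each element overlaps, plus state/group proportions.

    Proportions are over all elements; one element may count toward several
    states and groups, so proportions need not sum to 1.
    """
    unknown = {s.id for s in states} - set(grouping)
    if unknown:
        raise ValueError(f"unknown state label(s): {sorted(unknown)}")
    hits = overlap_hits(list(element_ivs), list(states))
    state_by_idx = {i: s.id for i, s in enumerate(states)}
    per_element: dict[str, set[str]] = {}
    n = len(element_ivs)
    id_of = lambda i, iv: iv.id if iv.id is not None else str(i)
    for i, iv in enumerate(element_ivs):
        per_element[id_of(i, iv)] = set()
    # overlap_hits reports subject ids; map back via index fallback
    sid_to_state = {
        (s.id if s.id is not None else str(j)): s.id for j, s in enumerate(states)
    }
    for q, sid, _ in hits:
        per_element[q].add(sid_to_state[sid])
    state_counts: Counter = Counter()
    group_counts: Counter = Counter()
    for st_set in per_element.values():
        for st in st_set:
            state_counts[st] += 1
        for grp in {grouping[st] for st in st_set}:
            group_counts[grp] += 1
    rows = [
        {"element_id": eid, "states": ",".join(sorted(sts))}
        for eid, sts in sorted(per_element.items())
    ]
    state_props = {st: c / n for st, c in sorted(state_counts.items())}
    group_props = {g: c / n for g, c in sorted(group_counts.items())}
    return pd.DataFrame(rows), state_props, group_props


def state_combination(
    crh: CRH,
    states: Sequence[GenomicInterval],
    elements: Mapping[str, GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
    coverage_fraction: float = 0.8,
) -> tuple[str, ...]:
    """Minimal descending-coverage prefix of states reaching the coverage
    fraction of the hub's total chromatin-state signal (bp of overlap).

    Ties in coverage break by state name. A hub with zero coverage returns
    the empty combination.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    ivs = _crh_node_intervals(crh, elements, promoters)
    cov: Counter = Counter()
    for iv in ivs:
        for st in states:
            bp = iv.overlap_bp(st)
            if bp > 0:
                cov[st.id] += bp
    total = sum(cov.values())
    if total == 0:
        return ()
    ranked = sorted(cov.items(), key=lambda kv: (-kv[1], kv[0]))
    acc = 0
    combo = []
    for st, bp in ranked:
        combo.append(st)
        acc += bp
        if acc >= coverage_fraction * total:
            break
    return tuple(combo)


def state_combination_census(
    crhs: Sequence[CRH],
    states: Sequence[GenomicInterval],
    elements: Mapping[str, GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
    coverage_fraction: float = 0.8,
) -> dict:
    """Combination counts across hubs and how many occur exactly once."""
    combos = [
        state_combination(c, states, elements, promoters, coverage_fraction)
        for c in crhs
    ]
    nonzero = [c for c in combos if c]
    counts = Counter(nonzero)
    unique = sum(1 for c, k in counts.items() if k == 1)
    return {
        "combinations": counts,
        "n_crhs_with_coverage": len(nonzero),
        "n_unique_combinations": unique,
        "frac_unique": unique / len(nonzero) if nonzero else float("nan"),
    }
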