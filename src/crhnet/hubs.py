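"""Cis-regulatory hubs: connected components of the bipartite
promoter / distal-element graph defined by functional ABC pairs.

A hub (CRH) contains at least one promoter and one distal element.
Node roles:

* ``monogamous`` — the node sits in a two-node hub (one promoter, one
  distal element, exclusively paired);
* ``one_one_N`` — degree-1 node inside a hub of three or more nodes
  (its unique partner is shared with others);
* ``polygamous`` — degree >= 2.

These three classes partition the nodes of any hub set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import ElementRecord, GenomicInterval, PromoterRecord, overlap_hits

__all__ = [
    "CRH",
    "build_crhs",
    "classify_roles",
    "crh_metrics",
    "degree_profile",
    "build_candidate_sets",
    "classify_pair_replication",
    "crhs_to_frames",
]


@dataclass
class CRH:
    """One bipartite connected component with derived topology metrics."""

    id: str
    promoter_ids: frozenset
    distal_ids: frozenset
    edges: frozenset  # of (gene_id, element_id)
    # derived (filled by crh_metrics)
    mean_pair_distance: float | None = None
    span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.promoter_ids or not self.distal_ids:
            raise ValueError("a CRH needs at least one promoter and one distal element")
        for g, e in self.edges:
            if g not in self.promoter_ids or e not in self.distal_ids:
                raise ValueError(f"edge ({g}, {e}) references unknown node")

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)

    @property
    def n_distal(self) -> int:
        return len(self.distal_ids)

    @property
    def n_elements(self) -> int:
        return self.n_promoters + self.n_distal

    @property
    def n_edges(self) -> int:
        """Edge count = the hub's *complexity*."""
        return len(self.edges)

    @property
    def prop_distal(self) -> float:
        return self.n_distal / self.n_elements

    def degree(self, node: str) -> int:
        return sum(1 for g, e in self.edges if g == node or e == node)


def build_crhs(
    pairs: pd.DataFrame,
    promoters: Sequence[PromoterRecord] | None = None,
    elements: Sequence[ElementRecord] | None = None,
) -> list[CRH]:
    """Connected components of the functional-pair bipartite graph.

    Only rows with ``functional == True`` are used (all rows if the column
    is absent). When ``promoters``/``elements`` registries are given,
    pairs referencing unknown endpoints raise. Output order (and ids) are
    deterministic: components sorted by their smallest gene id.
    """
    if "functional" in pairs.columns:
        pairs = pairs[pairs["functional"]]
    if promoters is not None:
        known = {p.gene_id for p in promoters}
        bad = set(pairs["gene_id"]) - known
        if bad:
            raise ValueError(f"pairs reference unknown promoters: {sorted(bad)[:5]}")
    if elements is not None:
        known_e = {e.interval.id for e in elements}
        bad = set(pairs["element_id"]) - known_e
        if bad:
            raise ValueError(f"pairs reference unknown elements: {sorted(bad)[:5]}")

    G = nx.Graph()
    for g, e in zip(pairs["gene_id"], pairs["element_id"]):
        G.add_edge(("P", g), ("E", e))
    comps = []
    for comp in nx.connected_components(G):
        proms = frozenset(n[1] for n in comp if n[0] == "P")
        dists = frozenset(n[1] for n in comp if n[0] == "E")
        edges = frozenset(
            (u[1], v[1]) if u[0] == "P" else (v[1], u[1])
            for u, v in G.edges(comp)
        )
        comps.append((min(proms), proms, dists, edges))
    comps.sort(key=lambda t: t[0])
    return [
        CRH(f"crh_{k:04d}", proms, dists, edges)
        for k, (_, proms, dists, edges) in enumerate(comps)
    ]


def classify_roles(crhs: Sequence[CRH]) -> pd.DataFrame:
    """Per-node role table (node_id, node_class, role, degree, crh_id)."""
    rows = []
    for crh in crhs:
        two_node = crh.n_elements == 2
        for node_class, ids in (("promoter", crh.promoter_ids), ("distal", crh.distal_ids)):
            for node in sorted(ids):
                deg = crh.degree(node)
                if two_node:
                    role = "monogamous"
                elif deg == 1:
                    role = "one_one_N"
                else:
                    role = "polygamous"
                rows.append(
                    {
                        "node_id": node,
                        "node_class": node_class,
                        "role": role,
                        "degree": deg,
                        "crh_id": crh.id,
                    }
                )
    return pd.DataFrame(rows, columns=["node_id", "node_class", "role", "degree", "crh_id"])


def crh_metrics(
    crh: CRH,
    elements: Mapping[str, GenomicInterval],
    promoters: Mapping[str, GenomicInterval],
) -> CRH:
    """Fill mean pairwise midpoint distance and genomic span of the hub."""
    mids = []
    spans = []
    for g in crh.promoter_ids:
        if g not in promoters:
            raise KeyError(f"no coordinates for promoter {g}")
        mids.append(promoters[g].midpoint)
        spans.append(promoters[g])
    for e in crh.distal_ids:
        if e not in elements:
            raise KeyError(f"no coordinates for element {e}")
        mids.append(elements[e].midpoint)
        spans.append(elements[e])
    mids_arr = np.asarray(mids)
    diffs = np.abs(mids_arr[:, None] - mids_arr[None, :])
    n = len(mids_arr)
    mean_dist = float(diffs[np.triu_indices(n, k=1)].mean()) if n > 1 else 0.0
    chrom = spans[0].chrom
    span = GenomicInterval(
        chrom, min(iv.start for iv in spans), max(iv.end for iv in spans), id=crh.id
    )
    crh.mean_pair_distance = mean_dist
    crh.span = span
    return crh


def degree_profile(crhs: Sequence[CRH]) -> dict:
    """Degree distributions per node class with nearest-rank percentiles.

    Returns ``{"promoter": {"degrees", "counts", "cdf"}, "distal": {...},
    "percentile": fn(node_class, q)}``.
    """
    degs: dict[str, list[int]] = {"promoter": [], "distal": []}
    for crh in crhs:
        degs["promoter"] += [crh.degree(g) for g in crh.promoter_ids]
        degs["distal"] += [crh.degree(e) for e in crh.distal_ids]

    out: dict = {}
    for cls, values in degs.items():
        arr = np.sort(np.asarray(values))
        uniq, counts = np.unique(arr, return_counts=True)
        cdf = np.cumsum(counts) / arr.size if arr.size else np.array([])
        out[cls] = {"degrees": uniq, "counts": counts, "cdf": cdf, "sorted": arr}

    def percentile(node_class: str, q: float) -> int:
        arr = out[node_class]["sorted"]
        if arr.size == 0:
            raise ValueError(f"no {node_class} nodes")
        rank = int(np.ceil(q / 100 * arr.size))  # nearest-rank
        return int(arr[max(rank, 1) - 1])

    out["percentile"] = percentile
    return out


@dataclass
class CandidateSets:
    """Comparator sets: accessible elements / promoters outside any hub."""

    candidate_distal: list[ElementRecord]
    candidate_promoters: list[PromoterRecord]


def build_candidate_sets(
    dnase_peaks: Sequence[ElementRecord],
    functional_elements: Sequence[ElementRecord],
    all_promoters: Sequence[PromoterRecord],
    crhs: Sequence[CRH],
) -> CandidateSets:
    """Candidate distal = DNAse peaks overlapping no functional element;
    candidate promoters = promoters of genes absent from every hub."""
    func_ivs = [e.interval for e in functional_elements]
    peak_ivs = [p.interval for p in dnase_peaks]
    overlapping = {q for q, _, _ in overlap_hits(peak_ivs, func_ivs)}
    cand_distal = [
        p
        for i, p in enumerate(dnase_peaks)
        if (p.interval.id if p.interval.id is not None else str(i)) not in overlapping
    ]
    hub_genes = set().union(*(crh.promoter_ids for crh in crhs)) if crhs else set()
    cand_prom = [p for p in all_promoters if p.gene_id not in hub_genes]
    return CandidateSets(cand_distal, cand_prom)


def classify_pair_replication(
    pairs_ref: pd.DataFrame,
    pairs_other: pd.DataFrame,
    crhs_other: Sequence[CRH],
    elements_ref: Mapping[str, GenomicInterval] | None = None,
    elements_other: Mapping[str, GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Cross-sample replication class for each reference functional pair.

    ``Direct``        — the matched pair is functional in the other sample;
    ``SameCRH_NoDirect`` — both endpoints map into one hub of the other
                        sample but without a direct edge;
    ``NoConnection``  — both endpoints exist in the other sample, in
                        different hubs (or outside any single hub);
    ``NotFound``      — an endpoint has no match in the other sample.

    Promoters match by gene id; elements match by any coordinate overlap
    when coordinate maps are supplied, else by element id.
    """
    if "functional" in pairs_ref.columns:
        pairs_ref = pairs_ref[pairs_ref["functional"]]
    if "functional" in pairs_other.columns:
        pairs_other = pairs_other[pairs_other["functional"]]

    # element matching: ref element id -> set of other element ids
    if elements_ref is not None and elements_other is not None:
        ref_ids = list(elements_ref)
        other_ids = list(elements_other)
        hits = overlap_hits(
            [_with_id(elements_ref[i], i) for i in ref_ids],
            [_with_id(elements_other[j], j) for j in other_ids],
        )
        ematch: dict[str, set[str]] = {}
        for q, s, _ in hits:
            ematch.setdefault(q, set()).add(s)
    else:
        shared = set(pairs_other["element_id"])
        ematch = {e: {e} for e in set(pairs_ref["element_id"]) if e in shared}

    other_edges = set(zip(pairs_other["gene_id"], pairs_other["element_id"]))
    other_genes = set(pairs_other["gene_id"])
    node_to_crh: dict[tuple[str, str], str] = {}
    for crh in crhs_other:
        for g in crh.promoter_ids:
            node_to_crh[("P", g)] = crh.id
        for e in crh.distal_ids:
            node_to_crh[("E", e)] = crh.id

    rows = []
    for g, e in zip(pairs_ref["gene_id"], pairs_ref["element_id"]):
        matched_e = ematch.get(e, set())
        if g not in other_genes or not matched_e:
            cls = "NotFound"
        elif any((g, em) in other_edges for em in matched_e):
            cls = "Direct"
        else:
            gc = node_to_crh.get(("P", g))
            same = any(node_to_crh.get(("E", em)) == gc for em in matched_e if gc)
            cls = "SameCRH_NoDirect" if same else "NoConnection"
        rows.append({"gene_id": g, "element_id": e, "replication_class": cls})
    return pd.DataFrame(rows, columns=["gene_id", "element_id", "replication_class"])


def _with_id(iv: GenomicInterval, id_: str) -> GenomicInterval:
    return GenomicInterval(iv.chrom, iv.start, iv.end, id=id_, strand=iv.strand)


def crhs_to_frames(crhs: Sequence[CRH]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(summary, membership, edge list) DataFrames for TSV export."""
    roles = classify_roles(crhs)
    summary = pd.DataFrame(
        [
            {
                "crh_id": c.id,
                "n_promoters": c.n_promoters,
                "n_distal": c.n_distal,
                "n_elements": c.n_elements,
                "n_edges": c.n_edges,
                "prop_distal": c.prop_distal,
                "mean_pair_distance": c.mean_pair_distance,
                "span_chrom": c.span.chrom if c.span else None,
                "span_start": c.span.start if c.span else None,
                "span_end": c.span.end if c.span else None,
            }
            for c in crhs
        ]
    )
    edges = pd.DataFrame(
        [
            {"crh_id": c.id, "gene_id": g, "element_id": e}
            for c in crhs
            for g, e in sorted(c.edges)
        ]
    )
    return summary, roles, edges
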