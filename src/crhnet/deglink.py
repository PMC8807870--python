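"""Linking noncoding associated SNPs to differentially expressed genes
through three structure classes: hubs (CRHs), single promoter-distal
pairs, and TADs.

A clumped SNP is assigned to a structure only when it falls inside one of
the structure's *distal* elements (never a promoter); TAD structures own
the functional distal elements fully contained in them and the genes whose
TSS they contain. Per-structure DEG proportions are then compared across
structure kinds among structures carrying at least one assigned SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hubs import CRH
from .intervals import GenomicInterval
from .stats import EnrichmentResult, fisher_exact_2x2, rank_tests, snps_in_intervals

__all__ = [
    "StructureView",
    "build_structure_views",
    "assign_snps",
    "deg_proportions",
    "deg_crh_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class StructureView:
    """One structure (hub / pair / TAD) with its genes and distal elements."""

    kind: str  # crh | ep_pair | tad
    structure_id: str
    gene_ids: frozenset
    distal_intervals: tuple[GenomicInterval, ...]
    assigned_snps: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("crh", "ep_pair", "tad"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.kind == "ep_pair" and (
            len(self.gene_ids) != 1 or len(self.distal_intervals) != 1
        ):
            raise ValueError("an ep_pair has exactly one gene and one distal element")


def build_structure_views(
    crhs: Sequence[CRH],
    pairs: pd.DataFrame,
    tads: Sequence[GenomicInterval],
    elements: Mapping[str, GenomicInterval],
    gene_tss: Mapping[str, tuple[str, int]],
) -> list[StructureView]:
    """Materialise the three structure kinds from one hub build.

    ``gene_tss`` maps gene_id -> (chrom, tss). TAD gene membership is by
    TSS containment; TAD distal elements are functional distal elements
    fully inside the TAD.
    """
    views: list[StructureView] = []
    for crh in crhs:
        views.append(
            StructureView(
                "crh",
                crh.id,
                crh.promoter_ids,
                tuple(elements[e] for e in sorted(crh.distal_ids)),
            )
        )
    func = pairs[pairs["functional"]] if "functional" in pairs.columns else pairs
    for k, row in enumerate(func.itertuples(index=False)):
        views.append(
            StructureView(
                "ep_pair",
                f"pair_{k:05d}",
                frozenset([row.gene_id]),
                (elements[row.element_id],),
            )
        )
    functional_eids = sorted({e for c in crhs for e in c.distal_ids})
    for t, tad in enumerate(tads):
        genes = frozenset(
            g
            for g, (chrom, tss) in gene_tss.items()
            if chrom == tad.chrom and tad.start <= tss < tad.end
        )
        if not genes:
            continue
        dist = tuple(
            elements[e]
            for e in functional_eids
            if elements[e].chrom == tad.chrom
            and elements[e].start >= tad.start
            and elements[e].end <= tad.end
        )
        views.append(StructureView("tad", tad.id or f"tad_{t:04d}", genes, dist))
    return views


def assign_snps(
    structures: Sequence[StructureView],
    snps: pd.DataFrame,
    promoter_intervals: Sequence[GenomicInterval] | None = None,
) -> list[StructureView]:
    """Assign each clumped SNP to every structure with a distal element
    containing it. SNPs inside a promoter window are never assigned."""
    snps = snps.reset_index(drop=True)
    in_promoter = (
        snps_in_intervals(snps, promoter_intervals)
        if promoter_intervals
        else np.zeros(len(snps), dtype=bool)
    )
    eligible = snps[~in_promoter]
    out = []
    for s in structures:
        if s.distal_intervals:
            mask = snps_in_intervals(eligible, s.distal_intervals)
            assigned = frozenset(eligible.loc[mask, "snp_id"])
        else:
            assigned = frozenset()
        out.append(
            StructureView(s.kind, s.structure_id, s.gene_ids, s.distal_intervals, assigned)
        )
    return out


def deg_proportions(
    structures: Sequence[StructureView], deg_labels: Mapping[str, bool]
) -> tuple[pd.DataFrame, dict]:
    """Per-structure DEG proportion plus a per-kind summary.

    The summary covers, per kind, the fraction of structures with >= 1
    assigned SNP and the median DEG proportion among those; kinds are
    compared pairwise with the two-sided Wilcoxon rank-sum test.
    """
    rows = []
    for s in structures:
        genes = [g for g in s.gene_ids if g in deg_labels]
        if not genes:
            logger.warning("structure %s has no labelled genes; excluded", s.structure_id)
            continue
        n_deg = sum(bool(deg_labels[g]) for g in genes)
        rows.append(
            {
                "kind": s.kind,
                "structure_id": s.structure_id,
                "n_genes": len(genes),
                "n_deg": n_deg,
                "n_assigned_snps": len(s.assigned_snps),
                "deg_proportion": n_deg / len(genes),
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {"per_kind": {}, "tests": {}}
    for kind, sub in table.groupby("kind"):
        with_snp = sub[sub["n_assigned_snps"] > 0]
        summary["per_kind"][kind] = {
            "n_structures": int(len(sub)),
            "frac_with_snp": float(len(with_snp) / len(sub)) if len(sub) else float("nan"),
            "median_deg_proportion": float(with_snp["deg_proportion"].median())
            if len(with_snp)
            else float("nan"),
        }
    kinds = sorted(table["kind"].unique())
    for i, ka in enumerate(kinds):
        for kb in kinds[i + 1 :]:
            xa = table.query("kind == @ka and n_assigned_snps > 0")["deg_proportion"]
            xb = table.query("kind == @kb and n_assigned_snps > 0")["deg_proportion"]
            if len(xa) and len(xb):
                stat, p = rank_tests(xa, xb, mode="rank_sum")
                summary["tests"][f"{ka}_vs_{kb}"] = {"statistic": stat, "pvalue": p}
    return table, summary


def deg_crh_enrichment(genes: pd.DataFrame) -> EnrichmentResult:
    """Fisher 2x2 of {gene in hub vs candidate} x {DEG vs not}."""
    for col in ("in_crh", "deg"):
        if col not in genes.columns:
            raise ValueError(f"genes table missing column {col!r}")
    g = genes.dropna(subset=["in_crh", "deg"])
    in_crh = g["in_crh"].astype(bool).to_numpy()
    deg = g["deg"].astype(bool).to_numpy()
    a = int(np.sum(in_crh & deg))
    b = int(np.sum(in_crh & ~deg))
    c = int(np.sum(~in_crh & deg))
    d = int(np.sum(~in_crh & ~deg))
    return fisher_exact_2x2(a, b, c, d)
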