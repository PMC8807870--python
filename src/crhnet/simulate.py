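"""Seeded synthetic fixture generator.

Emits a complete toy dataset with the statistical structure the pipeline
assumes: distance-decay Hi-C contacts with planted hub contacts, DNAse /
H3K27ac peaks with lognormal signals, compartment / TAD / FIRE / chromatin
state tracks, clumped-style SNPs with planted enrichment inside risk
elements, and gene-level phenotypes (association p-values, expression with
a between-hub variance component, DEG labels).

Geometry. Each chromosome is divided into fixed-stride territories
("blocks") separated by gaps wider than the background contact range, so
active elements can only ever contact promoters of their own block.
Planted promoter-element edges receive a large additive contact boost; a
dry-run ABC computation verifies that exactly the planted edges clear the
score threshold and raises otherwise. Background counts follow
Poisson(baseline_rate * (d+1)^-alpha) up to ``contact_range_bins`` bins,
the short-range regime of real contact maps; long-range background and
inter-chromosomal contacts are not emulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from . import abc as abc_mod
from .contacts import ContactMatrix
from .intervals import ElementRecord, GenomicInterval, PromoterRecord, make_promoters

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "write_fixture"]

# 40 hubs; mean planted distal-per-gene 248/64 = 3.875, inside the
# 2-5 calibration band used for real data.
DEFAULT_HUB_SHAPES: tuple[tuple[int, int], ...] = (
    ((1, 1),) * 12 + ((1, 3),) * 6 + ((1, 5),) * 6 + ((2, 6),) * 6
    + ((2, 10),) * 4 + ((3, 12),) * 4 + ((4, 20),) * 2
)


@dataclass
class FixtureConfig:
    seed: int = 1
    n_chrom: int = 2
    chrom_length: int = 20_000_000
    bin_size: int = 10_000
    n_genes: int = 300
    n_elements: int = 1500
    planted_hubs: tuple[tuple[int, int], ...] = DEFAULT_HUB_SHAPES
    contact_decay_alpha: float = 1.0
    baseline_rate: float = 0.5
    hub_boost: float = 2000.0
    contact_range_bins: int = 25
    frac_active_elements: float = 1.0
    abc_threshold: float = abc_mod.DEFAULT_ABC_THRESHOLD
    # phenotype layer
    snp_density_per_mb: float = 50.0
    snps_per_element: int = 3
    planted_risk_elements: float = 0.5
    risk_effect: float = 3.0
    sig_threshold: float = 0.05
    deg_rate_in_crh: float = 0.30
    deg_rate_out: float = 0.074
    icc_true: float = 0.25
    logistic_betas: tuple[float, float, float, float] = (0.5, -0.3, 0.8, 0.4)
    assoc_in_crh_effect: float = 1.6
    # geometry
    block_span: int = 400_000
    block_gap: int = 300_000

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_length", "bin_size", "n_genes", "n_elements"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_active_elements", "planted_risk_elements",
                     "deg_rate_in_crh", "deg_rate_out"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.icc_true < 1):
            raise ValueError("icc_true must be in [0, 1)")
        if self.block_gap <= self.contact_range_bins * self.bin_size:
            raise ValueError("block_gap must exceed the background contact range")


@dataclass
class Fixture:
    config: FixtureConfig
    genes: pd.DataFrame                      # gene_id chrom strand tss hub_id
    promoters: list[PromoterRecord]
    elements: list[ElementRecord]            # all DNAse peaks (active + candidate)
    matrices: dict[str, ContactMatrix]
    annotations: dict[str, list[GenomicInterval]]
    truth: dict
    snps: pd.DataFrame | None = None         # snp_id chrom pos pvalue is_clumped_index
    gene_stats: pd.DataFrame | None = None


def _blocks(cfg: FixtureConfig) -> list[tuple[str, int, int]]:
    """(chrom, start, end) content regions, gap-separated."""
    stride = cfg.block_span + cfg.block_gap
    out = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        pos = cfg.block_gap // 2
        while pos + cfg.block_span + cfg.block_gap // 2 <= cfg.chrom_length:
            out.append((chrom, pos, pos + cfg.block_span))
            pos += stride
    return out


def generate_regulatory_landscape(cfg: FixtureConfig, rng: np.random.Generator) -> Fixture:
    """Genes, promoters, peaks with lognormal signals, annotation tracks."""
    shapes = list(cfg.planted_hubs)
    n_hub_genes = sum(m for m, _ in shapes)
    n_planted = sum(n for _, n in shapes)
    if n_hub_genes > cfg.n_genes:
        raise ValueError("more hub promoters than genes")
    if n_planted > cfg.n_elements:
        raise ValueError("more planted elements than peaks")
    blocks = _blocks(cfg)
    if len(shapes) > len(blocks):
        raise ValueError(
            f"{len(shapes)} hubs do not fit into {len(blocks)} genome blocks; "
            "increase chrom_length or n_chrom"
        )
    block_order = rng.permutation(len(blocks))
    hub_blocks = [blocks[i] for i in block_order[: len(shapes)]]
    null_blocks = [blocks[i] for i in block_order[len(shapes):]]
    if not null_blocks:
        null_blocks = hub_blocks  # degenerate tiny genomes

    bs = cfg.bin_size
    genes_rows = []
    elements: list[ElementRecord] = []
    truth_hubs = []
    gene_ctr = el_ctr = 0
    n_active_target = math.ceil(cfg.frac_active_elements * n_planted)
    used_bins: dict[str, set[int]] = {}

    for hub_idx, ((m, n), (chrom, bstart, bend)) in enumerate(zip(shapes, hub_blocks)):
        bins = np.arange(bstart // bs, bend // bs)
        chosen = rng.choice(bins, size=m + n, replace=False)
        used_bins.setdefault(chrom, set()).update(chosen.tolist())
        prom_bins, el_bins = chosen[:m], chosen[m:]
        gids, eids = [], []
        for b in prom_bins:
            gid = f"g{gene_ctr:04d}"
            gene_ctr += 1
            gids.append(gid)
            tss = int(b) * bs + bs // 2 + int(rng.integers(-2000, 2000))
            genes_rows.append(
                {"gene_id": gid, "chrom": chrom,
                 "strand": "+" if rng.random() < 0.5 else "-",
                 "tss": tss, "hub_id": f"hub_{hub_idx:03d}"}
            )
        for b in el_bins:
            eid = f"e{el_ctr:05d}"
            eids.append(eid)
            width = int(rng.integers(300, 800))
            center = int(b) * bs + bs // 2 + int(rng.integers(-2000, 2000))
            iv = GenomicInterval(chrom, center - width // 2, center + width // 2, id=eid)
            dnase = float(rng.lognormal(mean=1.0, sigma=0.4))
            active = el_ctr < n_active_target
            h3k = float(rng.lognormal(mean=1.0, sigma=0.4)) if active else 0.0
            elements.append(
                ElementRecord(iv, dnase, h3k, abc_mod.compute_activity(dnase, h3k),
                              "active" if active else "candidate")
            )
            el_ctr += 1
        # planted bipartite edges: round-robin primaries + a connectivity chain
        edges = []
        for i, eid in enumerate(eids):
            edges.append((gids[i % m], eid))
        for j in range(1, m):
            edges.append((gids[j], eids[j - 1]))
        truth_hubs.append(
            {"hub_id": f"hub_{hub_idx:03d}", "genes": gids, "elements": eids,
             "edges": sorted(set(edges))}
        )

    # null genes spread over the remaining blocks
    for k in range(cfg.n_genes - n_hub_genes):
        chrom, bstart, bend = null_blocks[k % len(null_blocks)]
        tss = int(rng.integers(bstart + 1000, bend - 1000))
        genes_rows.append(
            {"gene_id": f"g{gene_ctr:04d}", "chrom": chrom,
             "strand": "+" if rng.random() < 0.5 else "-", "tss": tss, "hub_id": None}
        )
        gene_ctr += 1

    # candidate peaks anywhere outside active-element bins
    active_bins = {
        (e.interval.chrom, int(e.interval.midpoint) // bs)
        for e in elements
    }
    while el_ctr < cfg.n_elements:
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        center = int(rng.integers(1000, cfg.chrom_length - 1000))
        if (chrom, center // bs) in active_bins:
            continue
        width = int(rng.integers(300, 800))
        iv = GenomicInterval(chrom, center - width // 2, center + width // 2,
                             id=f"e{el_ctr:05d}")
        dnase = float(rng.lognormal(mean=1.0, sigma=0.4))
        elements.append(ElementRecord(iv, dnase, 0.0, 0.0, "candidate"))
        el_ctr += 1

    genes = pd.DataFrame(genes_rows).sort_values("gene_id").reset_index(drop=True)
    promoters = make_promoters(genes)
    annotations = _make_annotations(cfg, rng, hub_blocks, elements, genes)
    truth = {
        "hubs": truth_hubs,
        "n_planted_edges": sum(len(h["edges"]) for h in truth_hubs),
        "hub_blocks": [list(b) for b in hub_blocks],
    }
    return Fixture(cfg, genes, promoters, elements, {}, annotations, truth)


def _make_annotations(
    cfg: FixtureConfig,
    rng: np.random.Generator,
    hub_blocks: list[tuple[str, int, int]],
    elements: list[ElementRecord],
    genes: pd.DataFrame,
) -> dict[str, list[GenomicInterval]]:
    ann: dict[str, list[GenomicInterval]] = {}
    # compartments: alternating A/B 2.5-Mb blocks
    comp = []
    comp_size = 2_500_000
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        for k, start in enumerate(range(0, cfg.chrom_length, comp_size)):
            comp.append(
                GenomicInterval(chrom, start, min(start + comp_size, cfg.chrom_length),
                                id="A" if (k + c) % 2 == 0 else "B")
            )
    ann["compartment"] = comp
    # TADs: gapless tiling with cycling widths
    widths = [800_000, 1_100_000, 900_000, 1_200_000]
    tads = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        pos = k = 0
        while pos < cfg.chrom_length:
            end = min(pos + widths[k % len(widths)], cfg.chrom_length)
            tads.append(GenomicInterval(chrom, pos, end, id=f"tad_{chrom}_{k:03d}"))
            pos, k = end, k + 1
    ann["TAD"] = tads
    # FIREs: inside 60% of hub blocks plus sparse background
    fires = []
    for chrom, bstart, bend in hub_blocks:
        if rng.random() < 0.6:
            s = int(rng.integers(bstart, bend - 100_000))
            fires.append(GenomicInterval(chrom, s, s + 100_000, id="FIRE"))
    for _ in range(10 * cfg.n_chrom):
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        s = int(rng.integers(0, cfg.chrom_length - 50_000))
        fires.append(GenomicInterval(chrom, s, s + 50_000, id="FIRE"))
    ann["FIRE"] = fires
    # chromatin states: active states over hub blocks, quiescent elsewhere
    states = []
    hub_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, bstart, bend in hub_blocks:
        hub_by_chrom.setdefault(chrom, []).append((bstart, bend))
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        spans = sorted(hub_by_chrom.get(chrom, []))
        pos = 0
        for bstart, bend in spans:
            if pos < bstart:
                states.append(GenomicInterval(chrom, pos, bstart, id="18_Quies"))
            third = (bend - bstart) // 3
            states.append(GenomicInterval(chrom, bstart, bstart + third, id="1_TssA"))
            states.append(GenomicInterval(chrom, bstart + third, bstart + 2 * third,
                                          id="9_EnhA1"))
            states.append(GenomicInterval(chrom, bstart + 2 * third, bend, id="6_TxWk"))
            pos = bend
        if pos < cfg.chrom_length:
            states.append(GenomicInterval(chrom, pos, cfg.chrom_length, id="18_Quies"))
    ann["chromatin_state"] = states
    # ENCODE-style candidate elements: marks over hub promoters + background
    encode = []
    for row in genes.itertuples(index=False):
        if row.hub_id is not None:
            encode.append(
                GenomicInterval(row.chrom, max(0, row.tss - 400), row.tss + 400,
                                id="H3K4me3")
            )
    for _ in range(30 * cfg.n_chrom):
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        s = int(rng.integers(0, cfg.chrom_length - 500))
        encode.append(GenomicInterval(chrom, s, s + 500,
                                      id=str(rng.choice(["DNAse", "H3K27ac", "CTCF"]))))
    ann["encode_ccre"] = encode
    return ann


def generate_contacts(cfg: FixtureConfig, fixture: Fixture,
                      rng: np.random.Generator) -> dict[str, ContactMatrix]:
    """Distance-decay background plus boosted planted-edge contacts.

    After construction, ABC scores are recomputed as a dry run and the
    functional pair set must equal the planted (active-element) edge set;
    otherwise the boost/baseline combination does not separate and a
    ValueError suggests larger ``hub_boost``.
    """
    bs = cfg.bin_size
    n_bins = int(np.ceil(cfg.chrom_length / bs))
    tss_bin = {
        row.gene_id: (row.chrom, int(row.tss) // bs)
        for row in fixture.genes.itertuples(index=False)
    }
    el_bin = {
        e.interval.id: (e.interval.chrom, int(e.interval.midpoint) // bs)
        for e in fixture.elements
    }
    matrices: dict[str, ContactMatrix] = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        rows, cols, vals = [], [], []
        if cfg.baseline_rate > 0:
            for d in range(cfg.contact_range_bins + 1):
                lam = cfg.baseline_rate * (d + 1) ** (-cfg.contact_decay_alpha)
                counts = rng.poisson(lam, size=n_bins - d)
                nz = np.nonzero(counts)[0]
                rows.append(nz)
                cols.append(nz + d)
                vals.append(counts[nz])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            vals = np.concatenate(vals).astype(float)
        else:
            rows = np.array([], dtype=int)
            cols = np.array([], dtype=int)
            vals = np.array([], dtype=float)
        boost_r, boost_c, boost_v = [], [], []
        for hub in fixture.truth["hubs"]:
            for g, e in hub["edges"]:
                gc, gb = tss_bin[g]
                ec, eb = el_bin[e]
                if gc != chrom:
                    continue
                assert ec == gc
                i, j = min(gb, eb), max(gb, eb)
                boost_r.append(i)
                boost_c.append(j)
                boost_v.append(cfg.hub_boost)
        rows = np.concatenate([rows, np.array(boost_r, dtype=int)])
        cols = np.concatenate([cols, np.array(boost_c, dtype=int)])
        vals = np.concatenate([vals, np.array(boost_v, dtype=float)])
        off = rows != cols
        mat = sparse.coo_matrix(
            (
                np.concatenate([vals, vals[off]]),
                (np.concatenate([rows, cols[off]]), np.concatenate([cols, rows[off]])),
            ),
            shape=(n_bins, n_bins),
        ).tocsr()
        mat.sum_duplicates()
        matrices[chrom] = ContactMatrix(chrom, bs, mat, "raw", cfg.chrom_length)

    _verify_separation(cfg, fixture, matrices)
    fixture.matrices = matrices
    return matrices


def _verify_separation(cfg: FixtureConfig, fixture: Fixture,
                       matrices: dict[str, ContactMatrix]) -> None:
    pairs = abc_mod.compute_abc_scores(fixture.elements, fixture.promoters, matrices)
    pairs = abc_mod.threshold_pairs(pairs, cfg.abc_threshold)
    got = set(
        zip(pairs.loc[pairs["functional"], "gene_id"],
            pairs.loc[pairs["functional"], "element_id"])
    )
    active = {e.interval.id for e in fixture.elements if e.element_class == "active"}
    want = {
        (g, e)
        for hub in fixture.truth["hubs"]
        for g, e in hub["edges"]
        if e in active
    }
    if got != want:
        raise ValueError(
            f"planted separation failed at threshold {cfg.abc_threshold}: "
            f"{len(got - want)} spurious and {len(want - got)} missing pairs; "
            "increase hub_boost or lower baseline_rate"
        )


def generate_phenotypes(cfg: FixtureConfig, fixture: Fixture,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP table and per-gene stats wired to the planted truth."""
    # --- SNPs: genome background + per-element SNPs, Beta(a, 1) p-values
    # inside risk elements so that P(p <= t) = risk_effect * t at t = sig_threshold
    genome_mb = cfg.n_chrom * cfg.chrom_length / 1e6
    n_bg = int(cfg.snp_density_per_mb * genome_mb)
    chroms = [f"chr{int(i) + 1}" for i in rng.integers(cfg.n_chrom, size=n_bg)]
    pos = rng.integers(0, cfg.chrom_length, size=n_bg).tolist()
    for e in fixture.elements:
        iv = e.interval
        for _ in range(cfg.snps_per_element):
            chroms.append(iv.chrom)
            pos.append(int(rng.integers(iv.start, iv.end)))
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{k:06d}" for k in range(len(pos))],
            "chrom": chroms,
            "pos": pos,
            "pvalue": rng.uniform(size=len(pos)),
            "is_clumped_index": True,
        }
    )
    active_ids = [e.interval.id for e in fixture.elements if e.element_class == "active"]
    n_risk = int(round(cfg.planted_risk_elements * len(active_ids)))
    risk_ids = set(rng.choice(active_ids, size=n_risk, replace=False)) if n_risk else set()
    risk_ivs = [e.interval for e in fixture.elements if e.interval.id in risk_ids]
    if risk_ivs and cfg.risk_effect != 1.0:
        from .stats import snps_in_intervals

        a = 1.0 + math.log(cfg.risk_effect) / math.log(cfg.sig_threshold)
        if a <= 0:
            raise ValueError("risk_effect too large for the reference threshold")
        mask = snps_in_intervals(snps, risk_ivs)
        snps.loc[mask, "pvalue"] = rng.beta(a, 1.0, size=int(mask.sum()))

    # --- gene-level stats
    sigma_w = 1.0
    sigma_b = math.sqrt(cfg.icc_true / (1 - cfg.icc_true)) * sigma_w if cfg.icc_true else 0.0
    hub_effect = {
        h["hub_id"]: rng.normal(0.0, sigma_b) for h in fixture.truth["hubs"]
    }
    gene_hub = dict(zip(fixture.genes["gene_id"], fixture.genes["hub_id"]))
    degree: dict[str, int] = {}
    partners: dict[str, list[str]] = {}
    for h in fixture.truth["hubs"]:
        for g, e in h["edges"]:
            degree[g] = degree.get(g, 0) + 1
            partners.setdefault(g, []).append(e)
    hub_sizes = {h["hub_id"]: (len(h["genes"]), len(h["elements"]))
                 for h in fixture.truth["hubs"]}
    chrom_active = {
        e.interval.id: bool(rng.random() < 0.6)
        for e in fixture.elements
        if e.element_class == "active"
    }
    rows = []
    for gid in fixture.genes["gene_id"]:
        hub = gene_hub.get(gid)
        in_crh = hub is not None
        b = hub_effect.get(hub, rng.normal(0.0, sigma_b)) if sigma_b else 0.0
        rna = 6.0 + b + rng.normal(0.0, sigma_w)
        n_conn = degree.get(gid, 0)
        prop_active = (
            float(np.mean([chrom_active.get(e, False) for e in partners[gid]]))
            if gid in partners
            else 0.0
        )
        monog = bool(in_crh and hub_sizes[hub] == (1, 1))
        rows.append(
            {
                "gene_id": gid,
                "rna_level": rna,
                "n_connections": n_conn,
                "prop_active_distal": prop_active,
                "monogamous": monog,
                "in_crh": in_crh,
                "crh_id": hub,
            }
        )
    gs = pd.DataFrame(rows)
    # planted disease status via the configured logistic model
    p90 = gs["prop_active_distal"].quantile(0.9)
    z_rna = (gs["rna_level"] - gs["rna_level"].mean()) / gs["rna_level"].std()
    b1, b2, b3, b4 = cfg.logistic_betas
    # intercept set for a ~23% baseline association rate outside hubs; the
    # hub main effect raises in-hub genes toward the ~35% rate the pipeline
    # emulates, while the negative connection coefficient concentrates
    # association in small hubs
    lin = (
        -1.2
        + b1 * z_rna
        + b2 * gs["n_connections"]
        + b3 * (gs["prop_active_distal"] > p90).astype(float)
        + b4 * gs["monogamous"].astype(float)
        + cfg.assoc_in_crh_effect * gs["in_crh"].astype(float)
    )
    prob = 1.0 / (1.0 + np.exp(-lin))
    status = rng.uniform(size=len(gs)) < prob
    gs["scz_associated"] = status
    gs["assoc_pvalue"] = np.where(
        status,
        10.0 ** (-rng.uniform(4, 10, size=len(gs))),
        rng.uniform(0.05, 1.0, size=len(gs)),
    )
    gs["deg"] = rng.uniform(size=len(gs)) < np.where(
        gs["in_crh"], cfg.deg_rate_in_crh, cfg.deg_rate_out
    )
    fixture.truth["risk_elements"] = sorted(risk_ids)
    fixture.truth["parameters"] = {
        "icc_true": cfg.icc_true,
        "risk_effect": cfg.risk_effect,
        "logistic_betas": list(cfg.logistic_betas),
        "deg_rates": [cfg.deg_rate_in_crh, cfg.deg_rate_out],
    }
    fixture.snps = snps
    fixture.gene_stats = gs
    return snps, gs


def generate_fixture(cfg: FixtureConfig | None = None, seed: int | None = None) -> Fixture:
    """Full deterministic fixture: landscape + contacts + phenotypes."""
    if cfg is None:
        cfg = FixtureConfig()
    if seed is not None:
        cfg = FixtureConfig(**{**asdict(cfg), "seed": seed,
                               "planted_hubs": cfg.planted_hubs})
    rng = np.random.default_rng(cfg.seed)
    fixture = generate_regulatory_landscape(cfg, rng)
    generate_contacts(cfg, fixture, rng)
    generate_phenotypes(cfg, fixture, rng)
    return fixture


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the pipeline's consumed formats; returns paths."""
    from .contacts import save_contacts
    from .intervals import write_intervals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = fixture.genes[["gene_id", "chrom", "strand", "tss"]]
    paths["genes"] = outdir / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False)

    dnase = [
        GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                        id=e.interval.id, strand=".", signal=e.dnase_signal)
        for e in fixture.elements
    ]
    paths["dnase"] = outdir / "dnase.narrowPeak"
    write_intervals(sorted(dnase, key=lambda iv: (iv.chrom, iv.start)),
                    paths["dnase"], format="narrowPeak")
    h3k = [
        GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                        signal=e.h3k27ac_signal)
        for e in fixture.elements
        if e.h3k27ac_signal > 0
    ]
    paths["h3k27ac"] = outdir / "h3k27ac.bedGraph"
    write_intervals(sorted(h3k, key=lambda iv: (iv.chrom, iv.start)),
                    paths["h3k27ac"], format="bedGraph")

    for chrom, cm in fixture.matrices.items():
        p = outdir / f"contacts_{chrom}.tsv"
        save_contacts(cm, p)
        paths[f"contacts_{chrom}"] = p

    for kind, ivs in fixture.annotations.items():
        p = outdir / f"{kind}.bed"
        write_intervals(sorted(ivs, key=lambda iv: (iv.chrom, iv.start)), p, format="BED")
        paths[kind] = p

    if fixture.snps is not None:
        paths["snps"] = outdir / "snps.tsv"
        fixture.snps.to_csv(paths["snps"], sep="\t", index=False)
    if fixture.gene_stats is not None:
        paths["gene_stats"] = outdir / "gene_stats.tsv"
        fixture.gene_stats.to_csv(paths["gene_stats"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(fixture.truth, indent=1, sort_keys=True))
    return paths
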