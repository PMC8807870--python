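"""Config-driven orchestration of the full hub analysis.

Stages: simulate -> abc -> crh -> overlap -> enrich -> deglink -> report.
Each stage writes TSV/JSON artifacts plus a manifest (parameters, input
hashes, wall time) into its own subdirectory; reruns with the same inputs,
config and seed reproduce identical result files (manifests carry the only
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import annotations as ann_mod
from . import deglink as deg_mod
from . import hubs as hub_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .contacts import load_contacts
from .intervals import (
    GenomicInterval,
    make_promoters,
    read_gene_table,
    read_intervals,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "abc", "crh", "overlap", "enrich", "deglink", "report")


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "crhnet_out"
    promoter_width: int = 500
    abc_threshold: float | None = abc_mod.DEFAULT_ABC_THRESHOLD
    calibrate: bool = False
    calibration_target: float = 4.51
    calibration_bounds: tuple[float, float] = (2.0, 5.0)
    window: int = abc_mod.DEFAULT_WINDOW
    bin_size: int = 10_000
    snp_p_thresholds: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    sig_threshold: float = 0.05
    ldsc_extend: int = 500
    strata_bounds: tuple[int, int] = (3, 25)
    inputs: dict = field(default_factory=dict)  # per-kind paths; set by simulate
    simulate_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.abc_threshold is not None and not (0 <= self.abc_threshold <= 1):
            raise ValueError("abc_threshold must be in [0, 1]")
        if self.ldsc_extend < 0:
            raise ValueError("ldsc_extend must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"invalid config key(s): {sorted(bad)}")
        for key in ("calibration_bounds", "snp_p_thresholds", "strata_bounds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _manifest(stage_dir: Path, params: dict, inputs: dict[str, Path], t0: float) -> None:
    manifest = {
        "parameters": params,
        "inputs": {k: _hash_file(Path(p)) for k, p in inputs.items() if Path(p).exists()},
        "wall_time_s": round(time.time() - t0, 3),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


class Pipeline:
    """Stateful runner; stages communicate through files under outdir."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # ---------- helpers ----------
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _require(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires {path}; run its upstream stage first"
            )
        return path

    def _load_common(self):
        cfg = self.config
        sim = self.outdir / "simulate"
        genes = read_gene_table(self._require("abc", sim / "genes.tsv"))
        promoters = make_promoters(genes, width=cfg.promoter_width)
        dnase = read_intervals(sim / "dnase.narrowPeak", format="narrowPeak")
        h3k = read_intervals(sim / "h3k27ac.bedGraph", format="bedGraph")
        h3k_by_id: dict[tuple, float] = {
            (iv.chrom, iv.start, iv.end): iv.signal or 0.0 for iv in h3k
        }
        elements = []
        for iv in dnase:
            h = h3k_by_id.get((iv.chrom, iv.start, iv.end), 0.0)
            elements.append(
                sim_mod.ElementRecord(
                    iv, iv.signal or 0.0, h,
                    abc_mod.compute_activity(iv.signal or 0.0, h),
                    "candidate",
                )
            )
        matrices = {}
        for p in sorted(sim.glob("contacts_*.tsv")):
            cm = load_contacts(p, bin_size=cfg.bin_size)
            matrices[cm.chrom] = cm
        return genes, promoters, elements, matrices

    # ---------- stages ----------
    def stage_simulate(self) -> None:
        cfg = self.config
        t0 = time.time()
        overrides = dict(cfg.simulate_overrides)
        overrides["seed"] = cfg.seed
        fixture = sim_mod.generate_fixture(sim_mod.FixtureConfig(**overrides))
        d = self._stage_dir("simulate")
        sim_mod.write_fixture(fixture, d)
        _manifest(d, {"seed": cfg.seed, **cfg.simulate_overrides}, {}, t0)

    def stage_abc(self) -> None:
        cfg = self.config
        t0 = time.time()
        genes, promoters, elements, matrices = self._load_common()
        pairs = abc_mod.compute_abc_scores(
            elements, promoters, matrices, window=cfg.window
        )
        if cfg.calibrate or cfg.abc_threshold is None:
            threshold = abc_mod.calibrate_threshold(
                pairs, cfg.calibration_target, cfg.calibration_bounds
            )
        else:
            threshold = cfg.abc_threshold
        pairs = abc_mod.threshold_pairs(pairs, threshold)
        d = self._stage_dir("abc")
        pairs.to_csv(d / "pairs.tsv", sep="\t", index=False)
        (d / "threshold.json").write_text(
            json.dumps(
                {
                    "threshold": threshold,
                    "calibrated": bool(cfg.calibrate or cfg.abc_threshold is None),
                    "mean_distal_per_gene": abc_mod.mean_distal_per_gene(pairs, threshold),
                    "n_functional_pairs": int(pairs["functional"].sum()),
                }
            )
        )
        _manifest(d, {"threshold": threshold, "window": cfg.window},
                  {"genes": self.outdir / "simulate" / "genes.tsv"}, t0)

    def _load_pairs(self) -> pd.DataFrame:
        p = self._require("crh", self.outdir / "abc" / "pairs.tsv")
        return pd.read_csv(p, sep="\t")

    def _element_maps(self, elements):
        by_id = {}
        rec_by_id = {}
        for i, e in enumerate(elements):
            eid = e.interval.id if e.interval.id is not None else str(i)
            by_id[eid] = e.interval
            rec_by_id[eid] = e
        return by_id, rec_by_id

    def stage_crh(self) -> None:
        t0 = time.time()
        genes, promoters, elements, _ = self._load_common()
        pairs = self._load_pairs()
        crhs = hub_mod.build_crhs(pairs)
        el_iv, _ = self._element_maps(elements)
        pr_iv = {p.gene_id: p.interval for p in promoters}
        for c in crhs:
            hub_mod.crh_metrics(c, el_iv, pr_iv)
        summary, roles, edges = hub_mod.crhs_to_frames(crhs)
        d = self._stage_dir("crh")
        summary.to_csv(d / "crh_summary.tsv", sep="\t", index=False)
        roles.to_csv(d / "crh_membership.tsv", sep="\t", index=False)
        edges.to_csv(d / "crh_edges.tsv", sep="\t", index=False)
        _manifest(d, {"n_crhs": len(crhs)}, {"pairs": self.outdir / "abc" / "pairs.tsv"}, t0)

    def _rebuild_crhs(self):
        genes, promoters, elements, _ = self._load_common()
        pairs = self._load_pairs()
        crhs = hub_mod.build_crhs(pairs)
        el_iv, el_rec = self._element_maps(elements)
        pr_iv = {p.gene_id: p.interval for p in promoters}
        for c in crhs:
            hub_mod.crh_metrics(c, el_iv, pr_iv)
        return genes, promoters, elements, pairs, crhs, el_iv, el_rec, pr_iv

    def stage_overlap(self) -> None:
        t0 = time.time()
        self._require("overlap", self.outdir / "crh" / "crh_summary.tsv")
        genes, promoters, elements, pairs, crhs, el_iv, el_rec, pr_iv = self._rebuild_crhs()
        sim = self.outdir / "simulate"
        comp = read_intervals(sim / "compartment.bed")
        tads = read_intervals(sim / "TAD.bed")
        fires = read_intervals(sim / "FIRE.bed")
        states = read_intervals(sim / "chromatin_state.bed")

        rows = []
        for c in crhs:
            rows.append(
                {
                    "crh_id": c.id,
                    "compartment_category": ann_mod.compartment_category(
                        c, comp, el_iv, pr_iv
                    ),
                    "n_tads_overlapped": ann_mod.tad_overlap_count(c, tads),
                    "state_combination": ",".join(
                        ann_mod.state_combination(c, states, el_iv, pr_iv)
                    ),
                }
            )
        overlap_df = pd.DataFrame(rows)

        func_ids = sorted({e for c in crhs for e in c.distal_ids})
        func_elements = [el_rec[e] for e in func_ids]
        cand = hub_mod.build_candidate_sets(elements, func_elements, promoters, crhs)
        fire_enr = ann_mod.region_set_enrichment(
            [el_iv[e] for e in func_ids],
            [e.interval for e in cand.candidate_distal],
            fires,
        )
        crh_ivs = [el_iv[e] for e in func_ids] + [
            pr_iv[g] for c in crhs for g in sorted(c.promoter_ids)
        ]
        _, state_props, group_props = ann_mod.state_profile(crh_ivs, states)
        census = ann_mod.state_combination_census(crhs, states, el_iv, pr_iv)
        hist = ann_mod.tads_with_k_crhs(crhs, tads)

        d = self._stage_dir("overlap")
        overlap_df.to_csv(d / "crh_overlap.tsv", sep="\t", index=False)
        (d / "overlap_summary.json").write_text(
            json.dumps(
                {
                    "compartment_counts": overlap_df["compartment_category"]
                    .value_counts()
                    .to_dict(),
                    "tads_with_k_crhs": {str(k): v for k, v in sorted(hist.items())},
                    "fire_enrichment": {
                        "table": fire_enr.table,
                        "odds_ratio": fire_enr.odds_ratio,
                        "p": fire_enr.p_two_sided,
                        "ci95": fire_enr.ci95,
                    },
                    "state_group_proportions": group_props,
                    "state_proportions": state_props,
                    "n_unique_state_combinations": census["n_unique_combinations"],
                    "frac_unique_state_combinations": census["frac_unique"],
                },
                indent=1,
                sort_keys=True,
            )
        )
        _manifest(d, {}, {"crh": self.outdir / "crh" / "crh_summary.tsv"}, t0)

    def stage_enrich(self) -> None:
        cfg = self.config
        t0 = time.time()
        self._require("enrich", self.outdir / "crh" / "crh_summary.tsv")
        genes, promoters, elements, pairs, crhs, el_iv, el_rec, pr_iv = self._rebuild_crhs()
        sim = self.outdir / "simulate"
        snps = pd.read_csv(self._require("enrich", sim / "snps.tsv"), sep="\t")
        gs = pd.read_csv(self._require("enrich", sim / "gene_stats.tsv"), sep="\t")

        func_ids = sorted({e for c in crhs for e in c.distal_ids})
        func_elements = [el_rec[e] for e in func_ids]
        cand = hub_mod.build_candidate_sets(elements, func_elements, promoters, crhs)
        crh_el_ivs = [el_iv[e] for e in func_ids]
        cand_el_ivs = [e.interval for e in cand.candidate_distal]
        hub_genes = set().union(*(c.promoter_ids for c in crhs)) if crhs else set()

        # schizophrenia-associated gene selection and hub enrichment
        gs = gs.copy()
        gs["scz_selected"] = stats_mod.bh_select(gs["assoc_pvalue"], cfg.sig_threshold)
        gs["in_crh_obs"] = gs["gene_id"].isin(hub_genes)
        a = int((gs["scz_selected"] & gs["in_crh_obs"]).sum())
        b = int((gs["scz_selected"] & ~gs["in_crh_obs"]).sum())
        c_ = int((~gs["scz_selected"] & gs["in_crh_obs"]).sum())
        d_ = int((~gs["scz_selected"] & ~gs["in_crh_obs"]).sum())
        scz_enr = stats_mod.fisher_exact_2x2(a, c_, b, d_)

        # per-CRH associated-gene census
        sel = set(gs.loc[gs["scz_selected"], "gene_id"])
        per_crh = [len(set(c.promoter_ids) & sel) for c in crhs]
        census = {
            "n_crhs": len(crhs),
            "n_with_assoc_gene": int(sum(k >= 1 for k in per_crh)),
            "n_with_several_assoc_genes": int(sum(k >= 2 for k in per_crh)),
            "pct_with_assoc_gene": round(
                100 * sum(k >= 1 for k in per_crh) / len(crhs)
            ) if crhs else None,
            "pct_with_several_assoc_genes": round(
                100 * sum(k >= 2 for k in per_crh) / len(crhs)
            ) if crhs else None,
        }

        # SNP enrichment at thresholds + fold enrichment
        snp_results = {}
        for pt in cfg.snp_p_thresholds:
            try:
                enr = stats_mod.snp_threshold_enrichment(
                    snps, crh_el_ivs, cand_el_ivs, pt
                )
                snp_results[str(pt)] = {
                    "table": enr.table,
                    "odds_ratio": enr.odds_ratio,
                    "p": enr.p_two_sided,
                    "ci95": enr.ci95,
                }
            except ValueError as exc:
                snp_results[str(pt)] = {"error": str(exc)}
        rel_fold = stats_mod.relative_fold(
            snps, crh_el_ivs, cand_el_ivs, cfg.sig_threshold
        )

        # logistic regression of gene status on hub covariates; small
        # fixtures can quasi-separate, which the stats layer reports as an
        # error — recorded rather than fatal
        try:
            logi = stats_mod.logistic_fit(gs, outcome="scz_associated")
        except ValueError as exc:
            logger.warning("logistic fit not estimable on this fixture: %s", exc)
            logi = pd.DataFrame(
                [{"term": "not_estimable", "coef": float("nan"),
                  "odds_ratio": float("nan"), "ci_low": float("nan"),
                  "ci_high": float("nan"), "pvalue": float("nan"),
                  "note": str(exc)}]
            )

        # ICC of expression grouped by hub + strata
        hub_gs = gs[gs["in_crh_obs"]].copy()
        gene_to_crh = {g: c.id for c in crhs for g in c.promoter_ids}
        hub_gs["crh_obs"] = hub_gs["gene_id"].map(gene_to_crh)
        icc = stats_mod.icc_fit(hub_gs["rna_level"], hub_gs["crh_obs"])
        strata = stats_mod.stratify_crhs(crhs)

        # LDSC-style annotation preparation
        annot, merged = stats_mod.prepare_ldsc_annotation(
            crh_el_ivs + [pr_iv[g] for g in sorted(hub_genes)], snps, cfg.ldsc_extend
        )

        d = self._stage_dir("enrich")
        gs.to_csv(d / "gene_stats_annotated.tsv", sep="\t", index=False)
        logi.to_csv(d / "logistic_fit.tsv", sep="\t", index=False)
        annot.to_csv(d / "ldsc_annot.tsv", sep="\t", index=False)
        (d / "enrichment_summary.json").write_text(
            json.dumps(
                {
                    "scz_gene_enrichment": {
                        "table": scz_enr.table,
                        "odds_ratio": scz_enr.odds_ratio,
                        "p": scz_enr.p_two_sided,
                        "ci95": scz_enr.ci95,
                    },
                    "crh_assoc_census": census,
                    "snp_enrichment": snp_results,
                    "relative_fold_enrichment": rel_fold,
                    "icc": {
                        "sigma2_between": icc.sigma2_between,
                        "sigma2_within": icc.sigma2_within,
                        "icc": icc.icc,
                    },
                    "strata_counts": {k: len(v) for k, v in strata.items()},
                },
                indent=1,
                sort_keys=True,
            )
        )
        _manifest(d, {"snp_p_thresholds": list(cfg.snp_p_thresholds)},
                  {"snps": sim / "snps.tsv"}, t0)

    def stage_deglink(self) -> None:
        t0 = time.time()
        self._require("deglink", self.outdir / "crh" / "crh_summary.tsv")
        genes, promoters, elements, pairs, crhs, el_iv, el_rec, pr_iv = self._rebuild_crhs()
        sim = self.outdir / "simulate"
        snps = pd.read_csv(self._require("deglink", sim / "snps.tsv"), sep="\t")
        gs = pd.read_csv(self._require("deglink", sim / "gene_stats.tsv"), sep="\t")
        tads = read_intervals(sim / "TAD.bed")
        gene_tss = {
            row.gene_id: (row.chrom, int(row.tss))
            for row in genes.itertuples(index=False)
        }
        views = deg_mod.build_structure_views(crhs, pairs, tads, el_iv, gene_tss)
        views = deg_mod.assign_snps(views, snps, [p.interval for p in promoters])
        deg_labels = dict(zip(gs["gene_id"], gs["deg"].astype(bool)))
        table, summary = deg_mod.deg_proportions(views, deg_labels)
        hub_genes = set().union(*(c.promoter_ids for c in crhs)) if crhs else set()
        gdf = gs.copy()
        gdf["in_crh"] = gdf["gene_id"].isin(hub_genes)
        enr = deg_mod.deg_crh_enrichment(gdf)
        d = self._stage_dir("deglink")
        table.to_csv(d / "structure_deg.tsv", sep="\t", index=False)
        (d / "deglink_summary.json").write_text(
            json.dumps(
                {
                    "summary": summary,
                    "deg_enrichment": {
                        "table": enr.table,
                        "odds_ratio": enr.odds_ratio,
                        "p": enr.p_two_sided,
                        "ci95": enr.ci95,
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
        _manifest(d, {}, {"snps": sim / "snps.tsv"}, t0)

    def stage_report(self) -> None:
        t0 = time.time()
        report: dict = {}
        for stage, fname in [
            ("abc", "threshold.json"),
            ("overlap", "overlap_summary.json"),
            ("enrich", "enrichment_summary.json"),
            ("deglink", "deglink_summary.json"),
        ]:
            p = self.outdir / stage / fname
            if p.exists():
                report[stage] = json.loads(p.read_text())
        crh_summary = self.outdir / "crh" / "crh_summary.tsv"
        if crh_summary.exists():
            df = pd.read_csv(crh_summary, sep="\t")
            roles = pd.read_csv(self.outdir / "crh" / "crh_membership.tsv", sep="\t")
            report["crh"] = {
                "n_crhs": int(len(df)),
                "n_nodes": int(df["n_elements"].sum()),
                "median_elements": float(df["n_elements"].median()),
                "max_elements": int(df["n_elements"].max()),
                "pct_monogamous_crhs": round(
                    100 * float((df["n_elements"] == 2).mean())
                ),
                "role_counts": roles.groupby(["node_class", "role"])
                .size()
                .unstack(fill_value=0)
                .to_dict(),
            }
        d = self._stage_dir("report")
        (d / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                  default=str))
        _manifest(d, {}, {}, t0)

    def run(self, stages: Sequence[str] | None = None) -> Path:
        stages = list(stages or STAGES)
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        for stage in STAGES:
            if stage in stages:
                logger.info("running stage %s", stage)
                getattr(self, f"stage_{stage}")()
        return self.outdir


def run(config: PipelineConfig, stages: Sequence[str] | None = None) -> Path:
    """Run the requested stages (all by default); returns the artifact dir."""
    return Pipeline(config).run(stages)
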