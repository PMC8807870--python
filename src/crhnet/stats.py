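"""Statistical layer: exact tests, multiple-testing control, SNP
enrichment, rank statistics, logistic regression, variance-component ICC,
and preparation of heritability (LDSC-style) SNP annotations.

Conventions used throughout the pipeline:

* Fisher's exact test is two-sided with the "probability at most that of
  the observed table" rule (the scipy/R convention).
* Odds ratios are sample cross-product ratios; the Haldane-Anscombe +0.5
  correction is applied to every cell only when some cell is zero, and
  95% CIs use the Woolf log-OR normal approximation on the (possibly
  corrected) table.
* SNP positions are 0-based; a SNP on the first base of a half-open
  element is inside it, a SNP on the end coordinate is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit, add_constant
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "EnrichmentResult",
    "ICCResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "bh_select",
    "snps_in_intervals",
    "snp_threshold_enrichment",
    "snp_fold_enrichment",
    "relative_fold",
    "rank_tests",
    "spearman",
    "logistic_fit",
    "icc_fit",
    "stratify_crhs",
    "prepare_ldsc_annotation",
]


@dataclass
class EnrichmentResult:
    """2x2 enrichment: table, odds ratio, two-sided p, Woolf 95% CI."""

    table: tuple[int, int, int, int]
    odds_ratio: float
    p_two_sided: float
    ci95: tuple[float, float]
    corrected: bool = False  # Haldane-Anscombe applied


@dataclass
class ICCResult:
    """One-way random-intercept variance components."""

    sigma2_between: float
    sigma2_within: float

    @property
    def icc(self) -> float:
        return self.sigma2_between / (self.sigma2_between + self.sigma2_within)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    Requires every row and column margin positive (otherwise the odds
    ratio is undefined). The reported OR is (a*d)/(b*c) with +0.5 on all
    cells iff any cell is zero.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("table cells must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError(f"zero margin in table {cells}: odds ratio undefined")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in cells
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = cells
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(odds) - 1.959963984540054 * se)
    hi = math.exp(math.log(odds) + 1.959963984540054 * se)
    return EnrichmentResult(cells, float(odds), float(p), (lo, hi), corrected)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_select(pvalues: Sequence[float], threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of hypotheses with BH-adjusted p <= threshold."""
    return bh_adjust(pvalues) <= threshold


def snps_in_intervals(
    snps: pd.DataFrame, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: SNP (chrom, pos) inside some half-open interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    mask = np.zeros(len(snps), dtype=bool)
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        sel = (snps["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = snps.loc[sel, "pos"].to_numpy()
        # rightmost interval starting at or before pos; assume intervals may
        # overlap, so check against running max of ends
        run_end = np.maximum.accumulate(ends)
        k = np.searchsorted(starts, pos, side="right") - 1
        inside = (k >= 0) & (pos < run_end[np.clip(k, 0, None)])
        mask[np.where(sel)[0]] = inside
    return mask


def snp_threshold_enrichment(
    snps: pd.DataFrame,
    annot_A: Sequence[GenomicInterval],
    annot_B: Sequence[GenomicInterval] | None,
    p_thresh: float,
    comparator: str = "candidates",
) -> EnrichmentResult:
    """Fisher 2x2 of {SNP in A vs comparator} x {p <= threshold vs not}.

    ``comparator="candidates"`` restricts to SNPs inside A or B and
    contrasts the two annotations; ``"genome"`` contrasts SNPs in A with
    every SNP outside A.
    """
    in_a = snps_in_intervals(snps, annot_A)
    if comparator == "candidates":
        if annot_B is None:
            raise ValueError("annot_B required for comparator='candidates'")
        in_b = snps_in_intervals(snps, annot_B) & ~in_a
        keep = in_a | in_b
        if not keep.any():
            raise ValueError("no SNP falls in either annotation")
        grp_a = in_a[keep]
        sig = (snps["pvalue"].to_numpy() <= p_thresh)[keep]
    elif comparator == "genome":
        grp_a = in_a
        sig = snps["pvalue"].to_numpy() <= p_thresh
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    a = int(np.sum(grp_a & sig))
    b = int(np.sum(grp_a & ~sig))
    c = int(np.sum(~grp_a & sig))
    d = int(np.sum(~grp_a & ~sig))
    return fisher_exact_2x2(a, b, c, d)


def snp_fold_enrichment(
    snps: pd.DataFrame, annotation: Sequence[GenomicInterval], p_thresh: float
) -> float:
    """(significant SNPs in annotation / all significant) over
    (SNPs in annotation / all SNPs)."""
    sig = snps["pvalue"].to_numpy() <= p_thresh
    if len(snps) == 0:
        raise ValueError("no SNPs supplied")
    if not sig.any():
        raise ValueError("no significant SNP at this threshold")
    inside = snps_in_intervals(snps, annotation)
    denom = inside.sum() / len(snps)
    if denom == 0:
        raise ValueError("no SNP overlaps the annotation")
    num = (sig & inside).sum() / sig.sum()
    return float(num / denom)


def relative_fold(
    snps: pd.DataFrame,
    annotation: Sequence[GenomicInterval],
    candidate_annotation: Sequence[GenomicInterval],
    p_thresh: float,
) -> float:
    """Fold enrichment of the annotation relative to its candidate set."""
    return snp_fold_enrichment(snps, annotation, p_thresh) / snp_fold_enrichment(
        snps, candidate_annotation, p_thresh
    )


def rank_tests(
    x: Sequence[float], y: Sequence[float], mode: str = "rank_sum"
) -> tuple[float, float]:
    """Two-sided Wilcoxon tests: ``rank_sum`` (two samples) or
    ``signed_rank`` (paired). Exact null for small samples without ties,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "rank_sum":
        exact = min(len(x), len(y)) <= 8 and len(np.unique(np.concatenate([x, y]))) == (
            len(x) + len(y)
        )
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if mode == "signed_rank":
        if len(x) != len(y):
            raise ValueError("signed_rank requires paired equal-length inputs")
        diff = x - y
        if np.all(diff == 0):
            raise ValueError("all paired differences are zero")
        exact = len(diff) <= 10 and len(np.unique(np.abs(diff[diff != 0]))) == np.sum(
            diff != 0
        )
        res = sps.wilcoxon(
            x, y, alternative="two-sided", method="exact" if exact else "approx"
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


DEFAULT_COVARIATES = [
    "rna_level",
    "n_connections",
    "prop_active_distal_p90_indicator",
    "monogamous",
]


def logistic_fit(
    genes: pd.DataFrame,
    outcome: str = "scz_associated",
    covariates: Sequence[str] | None = None,
    use_raw_proportion: bool = False,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of gene disease status.

    Default covariates: expression level, number of distal connections,
    an indicator of the proportion of active distal elements exceeding the
    across-gene 90th percentile (``use_raw_proportion`` substitutes the
    raw proportion), and monogamy status. Returns per-term OR with Wald
    95% CI. Raises on constant covariates or (near-)perfect separation.
    """
    df = genes.copy()
    if covariates is None:
        covariates = list(DEFAULT_COVARIATES)
        if use_raw_proportion:
            covariates[2] = "prop_active_distal"
    if "prop_active_distal_p90_indicator" in covariates and (
        "prop_active_distal_p90_indicator" not in df.columns
    ):
        p90 = df["prop_active_distal"].quantile(0.9)
        df["prop_active_distal_p90_indicator"] = (
            df["prop_active_distal"] > p90
        ).astype(float)
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = df[list(covariates)].astype(float)
    const_cov = [c for c in covariates if X[c].nunique() <= 1]
    if const_cov:
        raise ValueError(f"constant covariate(s): {const_cov}")
    Xc = add_constant(X, has_constant="add")
    model = Logit(y, Xc)
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except Exception as exc:  # statsmodels raises on hard separation
        raise ValueError(
            f"logistic fit failed ({exc}); consider penalized regression"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(
            "logistic fit did not converge; consider penalized regression"
        )
    if np.any(np.abs(fit.params) > 15):
        raise ValueError(
            "perfect separation suspected (|coef| > 15 on logit scale); "
            "consider penalized regression"
        )
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "term": Xc.columns,
            "coef": fit.params,
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "pvalue": fit.pvalues,
        }
    ).reset_index(drop=True)
    return out


def icc_fit(values: Sequence[float], groups: Sequence) -> ICCResult:
    """One-way random-intercept ICC by ANOVA method of moments.

    Uses the unbalanced-design group-size correction
    n0 = (N - sum n_i^2 / N) / (k - 1); negative between-group variance is
    truncated at zero.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    sizes = df.groupby("g")["y"].count()
    k = len(sizes)
    if k < 2:
        raise ValueError("need at least two groups")
    N = len(df)
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    sigma2_b = max(0.0, (msb - msw) / n0)
    return ICCResult(sigma2_b, msw)


def stratify_crhs(crhs: Sequence) -> dict[str, list]:
    """Small (<=3 promoters), medium (>3 and <=25), large (>25) hub strata."""
    strata: dict[str, list] = {"small": [], "medium": [], "large": []}
    for crh in crhs:
        n = crh.n_promoters
        if n <= 3:
            strata["small"].append(crh)
        elif n <= 25:
            strata["medium"].append(crh)
        else:
            strata["large"].append(crh)
    return strata


def prepare_ldsc_annotation(
    intervals: Sequence[GenomicInterval],
    snps: pd.DataFrame,
    extend: int = 500,
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Heritability-partitioning annotation: extend intervals +-``extend`` bp,
    merge, and flag each SNP inside the merged set.

    Returns a thin-annot style frame (CHR, BP, SNP, ANNOT) and the merged
    intervals. The LD-score regression itself is not performed here.
    """
    extended = [
        GenomicInterval(iv.chrom, max(0, iv.start - extend), iv.end + extend)
        for iv in intervals
    ]
    merged = merge_intervals(extended)
    inside = snps_in_intervals(snps, merged)
    annot = pd.DataFrame(
        {
            "CHR": snps["chrom"].to_numpy(),
            "BP": snps["pos"].to_numpy(),
            "SNP": snps["snp_id"].to_numpy(),
            "ANNOT": inside.astype(int),
        }
    )
    return annot, merged
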