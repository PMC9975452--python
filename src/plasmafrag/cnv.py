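"""Bin-level copy-number scoring against a healthy reference panel.

A sample's GC-corrected per-bin fragment fractions are compared with a
panel of healthy profiles: the CNV score of a bin is the log2 ratio of the
sample fraction to the panel median, with a companion z-score against the
panel per-bin mean and standard deviation. In healthy plasma the scores
concentrate around zero; tumor-derived copy-number alterations shift
whole bins and inflate the per-sample score variance. Gene-level
amplification calls aggregate bin scores over each gene's span and test
cancer vs healthy with a two-sided Wilcoxon rank-sum test under
Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import GenomeBins


@dataclass
class CNVProfile:
    sample_id: str
    log2_ratio: np.ndarray  # NaN on masked bins
    z_score: np.ndarray
    mask: np.ndarray  # True = bin scored

    @property
    def variance(self) -> float:
        """Variance of log2 scores over scored bins (heterogeneity summary)."""
        v = self.log2_ratio[self.mask]
        return float(np.var(v)) if v.size else float("nan")


@dataclass
class GeneCNVCall:
    gene: str
    chrom: str
    cancer_mean: float
    healthy_mean: float
    statistic: float
    p_value: float
    q_value: float
    call: str  # "amplified" | "not_called"
    reason: str = ""


def panel_summary(panel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin median, mean and sd of a (samples x bins) fraction matrix."""
    med = np.nanmedian(panel, axis=0)
    mean = np.nanmean(panel, axis=0)
    sd = np.nanstd(panel, axis=0, ddof=1)
    return med, mean, sd


def cnv_scores(sample_fractions: np.ndarray, panel: np.ndarray,
               sample_id: str = "sample") -> CNVProfile:
    """Score one sample's per-bin fractions against a healthy panel.

    ``panel`` is (n_samples x n_bins) of GC-corrected fractions (each row
    summing to 1, which makes the scores invariant to library size). Bins
    with zero panel median or zero panel sd are masked.
    """
    sample_fractions = np.asarray(sample_fractions, float)
    panel = np.asarray(panel, float)
    if panel.ndim != 2 or panel.shape[0] < 3:
        raise ValueError("panel needs >= 3 samples")
    if panel.shape[1] != sample_fractions.shape[0]:
        raise ValueError(
            f"bin count mismatch: sample {sample_fractions.shape[0]} "
            f"vs panel {panel.shape[1]}"
        )
    med, mean, sd = panel_summary(panel)
    mask = (
        np.isfinite(sample_fractions)
        & np.isfinite(med)
        & (med > 0)
        & np.isfinite(sd)
        & (sd > 0)
        & (sample_fractions > 0)
    )
    log2 = np.full_like(sample_fractions, np.nan)
    z = np.full_like(sample_fractions, np.nan)
    log2[mask] = np.log2(sample_fractions[mask] / med[mask])
    z[mask] = (sample_fractions[mask] - mean[mask]) / sd[mask]
    return CNVProfile(sample_id, log2, z, mask)


def cohort_variance_test(
    cancer: list[CNVProfile], healthy: list[CNVProfile]
) -> dict:
    """Per-sample score variances and a two-sided rank-sum group comparison."""
    if not cancer or not healthy:
        raise ValueError("both groups must be non-empty")
    var_c = np.array([p.variance for p in cancer])
    var_h = np.array([p.variance for p in healthy])
    result = {
        "cancer_variances": var_c,
        "healthy_variances": var_h,
        "cancer_median_variance": float(np.nanmedian(var_c)),
        "healthy_median_variance": float(np.nanmedian(var_h)),
        "p_value": None,
    }
    if len(cancer) >= 2 and len(healthy) >= 2:
        result["p_value"] = float(stats.ranksums(var_c, var_h).pvalue)
    else:
        warnings.warn("group of size < 2: variance test skipped")
    return result


def map_genes_to_bins(genes: pd.DataFrame, bins: GenomeBins) -> dict[str, list[int]]:
    """Gene span (BED4: chrom,start,end,gene) -> indices of overlapping bins."""
    mapping: dict[str, list[int]] = {}
    bt = bins.bins
    for row in genes.itertuples(index=False):
        hits = bt.index[
            (bt["chrom"] == row.chrom)
            & (bt["start"] < row.end)
            & (bt["end"] > row.start)
        ]
        mapping[row.gene] = list(hits)
    return mapping


def _gene_scores(profiles: list[CNVProfile], bin_idx: list[int]) -> np.ndarray:
    """Per-sample mean log2 score over a gene's (unmasked) bins."""
    out = np.full(len(profiles), np.nan)
    for i, p in enumerate(profiles):
        usable = [b for b in bin_idx if p.mask[b]]
        if usable:
            out[i] = float(np.mean(p.log2_ratio[usable]))
    return out


def call_amplified_genes(
    cancer: list[CNVProfile],
    healthy: list[CNVProfile],
    gene_map: dict[str, list[int]],
    gene_chroms: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[GeneCNVCall]:
    """Per-gene amplification calls: rank-sum cancer vs healthy + BH.

    A gene is called amplified iff its BH-adjusted q-value is below
    ``alpha`` and the cancer group's mean score exceeds the healthy
    group's. Genes whose bins are all masked are reported ``not_called``.
    """
    gene_chroms = gene_chroms or {}
    rows = []
    for gene, bin_idx in gene_map.items():
        sc = _gene_scores(cancer, bin_idx)
        sh = _gene_scores(healthy, bin_idx)
        ok_c, ok_h = sc[np.isfinite(sc)], sh[np.isfinite(sh)]
        if len(ok_c) < 2 or len(ok_h) < 2 or not bin_idx:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan,
                         "all bins masked or insufficient samples"))
            continue
        if np.ptp(np.concatenate([ok_c, ok_h])) == 0:
            stat, p = 0.0, 1.0  # identical constant groups
        else:
            res = stats.ranksums(ok_c, ok_h)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((gene, float(ok_c.mean()), float(ok_h.mean()), stat, p, ""))

    pvals = np.array([r[4] for r in rows], float)
    testable = np.isfinite(pvals)
    qvals = np.full_like(pvals, np.nan)
    if testable.any():
        qvals[testable] = multipletests(pvals[testable], method="fdr_bh")[1]

    calls = []
    for (gene, mc, mh, stat, p, reason), q in zip(rows, qvals):
        if reason:
            call = "not_called"
        else:
            amplified = np.isfinite(q) and q < alpha and mc > mh
            call = "amplified" if amplified else "not_called"
        calls.append(
            GeneCNVCall(gene, gene_chroms.get(gene, ""), mc, mh, stat, p, q,
                        call, reason)
        )
    return calls


def calls_frame(calls: list[GeneCNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "chrom": c.chrom,
                "cancer_mean_log2": c.cancer_mean,
                "healthy_mean_log2": c.healthy_mean,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "q_value": c.q_value,
                "call": c.call,
                "reason": c.reason,
            }
            for c in calls
        ]
    )
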