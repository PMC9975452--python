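"""Per-bin fragment-size-ratio and fragment-fraction profiles.

Tumor-derived cfDNA is enriched in short (~100-150 bp) fragments, so the
per-bin ratio of short to long fragment counts is elevated and more
heterogeneous across the genome in cancer plasma. Counts are corrected
for GC sampling bias by locally weighted regression against per-bin GC
content before ratios and fractions are formed. Cohort structure is
summarized by pairwise Pearson correlation of the profiles and by each
sample's correlation with the per-bin median profile of the healthy
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import BinAssignment, GenomeBins, SampleFragments, assign_to_bins

SHORT_RANGE = (100, 150)  # inclusive; 150 belongs to short
LONG_RANGE = (151, 220)  # inclusive
DEFAULT_LOWESS_SPAN = 0.75


@dataclass
class SampleProfile:
    """Per-bin fragmentation profile of one sample.

    ``table`` columns: short_count, long_count, total_count, the three
    GC-corrected versions, ratio, normalized_ratio, fraction and a boolean
    mask (True = bin usable). Masked bins (zero or non-positive corrected
    long counts) carry NaN in the derived columns.
    """

    sample_id: str
    table: pd.DataFrame

    @property
    def mask(self) -> np.ndarray:
        return self.table["mask"].to_numpy(bool)

    def vector(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy(float)


@dataclass
class CohortSimilarity:
    matrix: pd.DataFrame  # pairwise Pearson, samples x samples
    reference: np.ndarray  # healthy-median profile on shared bins
    r_to_reference: pd.Series  # per-sample Pearson vs reference
    shared_bins: np.ndarray  # indices of bins used
    wilcoxon_p: float | None = None  # healthy vs non-healthy r comparison


def bin_size_counts(
    sample: SampleFragments,
    bins: GenomeBins,
    assignment: BinAssignment | None = None,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> pd.DataFrame:
    """Raw per-bin short/long/total fragment counts (inclusive ranges)."""
    if short_range[1] >= long_range[0]:
        raise ValueError(
            f"short {short_range} and long {long_range} ranges overlap"
        )
    if assignment is None:
        assignment = assign_to_bins(sample, bins)
    idx = assignment.bin_index
    lengths = sample.data["length"].to_numpy()
    ok = idx >= 0
    n = len(bins)

    def count(sel) -> np.ndarray:
        return np.bincount(idx[ok & sel], minlength=n).astype(np.int64)

    short = count((lengths >= short_range[0]) & (lengths <= short_range[1]))
    long_ = count((lengths >= long_range[0]) & (lengths <= long_range[1]))
    total = np.bincount(idx[ok], minlength=n).astype(np.int64)
    return pd.DataFrame(
        {"short_count": short, "long_count": long_, "total_count": total}
    )


def gc_correct(
    values: np.ndarray,
    gc: np.ndarray,
    span: float = DEFAULT_LOWESS_SPAN,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Remove the smooth GC trend from per-bin values.

    A lowess fit of value on GC is subtracted and the global mean added
    back; a final additive re-centering preserves the total exactly. With
    a (near-)constant GC covariate the correction is the identity. Bins
    outside ``mask`` are passed through untouched.
    """
    values = np.asarray(values, float)
    gc = np.asarray(gc, float)
    if values.shape != gc.shape:
        raise ValueError("values and gc must be aligned")
    if mask is None:
        mask = np.isfinite(gc) & np.isfinite(values)
    v, g = values[mask], gc[mask]
    if v.size < 2 or np.ptp(g) < 1e-12:
        return values.copy()
    fit = lowess(v, g, frac=span, return_sorted=False)
    corrected = values.copy()
    corr = v - fit + v.mean()
    corr += (v.sum() - corr.sum()) / v.size  # exact total preservation
    corrected[mask] = corr
    return corrected


def build_profile(
    sample: SampleFragments,
    bins: GenomeBins,
    span: float = DEFAULT_LOWESS_SPAN,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    z_scale: bool = False,
) -> SampleProfile:
    """Counts -> GC correction -> ratio/normalized-ratio/fraction profile.

    Without per-bin GC content the correction step is skipped (corrected
    columns equal the raw counts). ``z_scale=True`` additionally divides
    the centered ratio by its standard deviation.
    """
    counts = bin_size_counts(sample, bins, None, short_range, long_range)
    gc = bins.gc
    have_gc = np.isfinite(gc).sum() >= 10
    usable = counts["total_count"].to_numpy() > 0
    out = counts.copy()
    for col in ("short_count", "long_count", "total_count"):
        raw = counts[col].to_numpy(float)
        if have_gc:
            out[f"gc_corrected_{col.removesuffix('_count')}"] = gc_correct(
                raw, gc, span, usable & np.isfinite(gc)
            )
        else:
            out[f"gc_corrected_{col.removesuffix('_count')}"] = raw
    cs = out["gc_corrected_short"].to_numpy(float)
    cl = out["gc_corrected_long"].to_numpy(float)
    ct = out["gc_corrected_total"].to_numpy(float)

    mask = usable & (cl > 0)
    n_newly_masked = int(usable.sum() - mask.sum())
    if n_newly_masked:
        warnings.warn(
            f"{sample.sample_id}: masked {n_newly_masked} bin(s) with "
            "non-positive corrected long counts"
        )
    ratio = np.where(mask, cs / np.where(mask, cl, 1.0), np.nan)
    normalized = ratio - np.nanmean(ratio[mask]) if mask.any() else ratio
    if z_scale and mask.any():
        sd = np.nanstd(normalized[mask])
        if sd > 0:
            normalized = normalized / sd
    ct_masked = np.where(mask, ct, 0.0)
    tot = ct_masked.sum()
    if tot <= 0:
        raise ValueError(f"{sample.sample_id}: zero corrected total")
    fraction = np.where(mask, ct_masked / tot, np.nan)

    out["ratio"] = ratio
    out["normalized_ratio"] = np.where(mask, normalized, np.nan)
    out["fraction"] = fraction
    out["mask"] = mask
    return SampleProfile(sample.sample_id, pd.concat(
        [bins.bins[["chrom", "start", "end"]].reset_index(drop=True), out], axis=1
    ))


def ratio_profile(profile: SampleProfile) -> pd.DataFrame:
    """Per-bin ratio and mean-centered ratio of a built profile."""
    return profile.table[["chrom", "start", "end", "ratio", "normalized_ratio"]]


def fraction_profile(profile: SampleProfile) -> pd.DataFrame:
    """Per-bin fraction of (corrected) fragments; sums to 1 over unmasked bins."""
    return profile.table[["chrom", "start", "end", "fraction"]]


def cohort_similarity(
    profiles: list[SampleProfile],
    healthy_ids: list[str],
    on: str = "ratio",
) -> CohortSimilarity:
    """Pairwise Pearson matrix and per-sample similarity to the healthy median.

    Bins masked in any sample are dropped cohort-wide so every correlation
    uses the same support. The healthy reference is the per-bin median over
    ``healthy_ids``; when non-healthy samples exist, a two-sided Wilcoxon
    rank-sum test compares the two groups' similarities to the reference.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples")
    if on not in {"ratio", "fraction", "normalized_ratio"}:
        raise ValueError(f"unknown profile column {on!r}")
    if not healthy_ids:
        raise ValueError("healthy_ids must be non-empty")
    ids = [p.sample_id for p in profiles]
    shared = np.logical_and.reduce([p.mask for p in profiles])
    if shared.sum() < 3:
        raise ValueError("fewer than 3 shared unmasked bins")
    X = np.stack([p.vector(on)[shared] for p in profiles])

    sd = X.std(axis=1)
    with np.errstate(invalid="ignore"):
        mat = np.corrcoef(X)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    np.fill_diagonal(mat, 1.0)
    matrix = pd.DataFrame(mat, index=ids, columns=ids)

    healthy_rows = [i for i, s in enumerate(ids) if s in set(healthy_ids)]
    reference = np.median(X[healthy_rows], axis=0)
    r_ref = np.array(
        [
            stats.pearsonr(x, reference)[0] if x.std() > 0 and reference.std() > 0
            else np.nan
            for x in X
        ]
    )
    r_to_reference = pd.Series(r_ref, index=ids)

    other = [i for i in range(len(ids)) if i not in set(healthy_rows)]
    p = None
    if other and len(healthy_rows) >= 2 and len(other) >= 2:
        p = float(
            stats.ranksums(r_ref[healthy_rows], r_ref[other]).pvalue
        )
    return CohortSimilarity(matrix, reference, r_to_reference,
                            np.flatnonzero(shared), p)
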