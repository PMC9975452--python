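"""TSS relative coverage and promoter chromatin-state calls.

Active promoters carry a nucleosome-depleted region (NDR) just around the
transcription start site; cfDNA, being nucleosome-protected, covers such
promoters less than their flanks. Three per-gene quantities capture this:

* ``ndr_rc``   - mean depth over the NDR window (default -150..+50 around
  the strand-oriented TSS) divided by mean depth over the reference
  flanks (+-1000..3000);
* ``k2_rc``    - the same for the 2-kb promoter window (+-1000);
* ``conventional_rc`` - 2-kb window depth divided by the genome-wide mean
  depth.

Cohort-level calls: a gene is *permissive* (open chromatin) when both
``ndr_rc`` and ``k2_rc`` fall below 1 in a strict majority of samples,
*nonpermissive* (closed) when both exceed 1.5 in a strict majority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import SampleFragments

NDR_WINDOW = (-150, 50)
K2_WINDOW = (-1000, 1000)
REF_FLANK = (1000, 3000)  # mirrored on both sides of the TSS
OPEN_THRESHOLD = 1.0
CLOSED_THRESHOLD = 1.5
FREQ_MIN = 0.5


@dataclass
class TSSAnnotation:
    """Per-gene primary TSS table: columns gene, chrom, strand, tss."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, collapse: bool = True) -> "TSSAnnotation":
        df = df[["gene", "chrom", "strand", "tss"]].copy()
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if collapse and df["gene"].duplicated().any():
            # most upstream TSS by strand: min for +, max for -
            order = {g: i for i, g in enumerate(dict.fromkeys(df["gene"]))}
            plus = (
                df[df["strand"] == "+"]
                .sort_values("tss", kind="stable")
                .drop_duplicates("gene", keep="first")
            )
            minus = (
                df[df["strand"] == "-"]
                .sort_values("tss", kind="stable")
                .drop_duplicates("gene", keep="last")
            )
            df = pd.concat([plus, minus]).sort_values(
                "gene", key=lambda s: s.map(order), kind="stable"
            )
        return cls(df.reset_index(drop=True))

    @classmethod
    def read(cls, path) -> "TSSAnnotation":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


class _ChromIndex:
    """Sorted per-chromosome fragment arrays for fast interval depth."""

    def __init__(self, sample: SampleFragments):
        self.chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.max_len = 0
        for chrom, g in sample.data.groupby("chrom", sort=False):
            starts = g["start"].to_numpy(np.int64)
            ends = g["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            self.chroms[chrom] = (starts[order], ends[order])
            if len(ends):
                self.max_len = max(self.max_len, int((ends - starts).max()))
        self.total_bases = int(sample.data["length"].sum())

    def overlap_sum(self, chrom: str, a: int, b: int) -> int:
        """Sum over fragments of their overlap with [a, b)."""
        if chrom not in self.chroms:
            return 0
        starts, ends = self.chroms[chrom]
        lo = np.searchsorted(starts, a - self.max_len, side="left")
        hi = np.searchsorted(starts, b, side="left")
        s, e = starts[lo:hi], ends[lo:hi]
        ov = np.minimum(e, b) - np.maximum(s, a)
        return int(ov[ov > 0].sum())


def region_depth(sample: SampleFragments | _ChromIndex, chrom: str,
                 start: int, end: int) -> float:
    """Mean per-base fragment coverage over the half-open interval."""
    if end <= start:
        raise ValueError("interval must have positive length")
    index = sample if isinstance(sample, _ChromIndex) else _ChromIndex(sample)
    return index.overlap_sum(chrom, start, end) / (end - start)


def _oriented(tss: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    """Strand-oriented window (negative = upstream) -> genomic interval."""
    lo, hi = window
    if strand == "+":
        return tss + lo, tss + hi
    return tss - hi, tss - lo


def tss_relative_coverages(
    sample: SampleFragments,
    annotations: TSSAnnotation,
    chrom_sizes: dict[str, int] | None = None,
    ndr_window: tuple[int, int] = NDR_WINDOW,
    k2_window: tuple[int, int] = K2_WINDOW,
    ref_flank: tuple[int, int] = REF_FLANK,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Per-gene conventional / NDR / 2K relative coverages for one sample.

    Genes whose full +-``ref_flank[1]`` context falls off the chromosome
    are skipped; genes with zero reference-flank depth are returned with
    NaN coverages. ``genome_size`` (or the chrom-sizes total) anchors the
    genome-wide mean depth behind ``conventional_rc``.
    """
    index = _ChromIndex(sample)
    if genome_size is None:
        if chrom_sizes:
            genome_size = int(sum(chrom_sizes.values()))
        else:
            genome_size = int(
                sample.data.groupby("chrom")["end"].max().sum()
            )
    genome_depth = index.total_bases / genome_size if genome_size else np.nan

    rows = []
    margin = ref_flank[1]
    for g in annotations.table.itertuples(index=False):
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        if g.tss < margin or (size is not None and g.tss + margin > size):
            rows.append((g.gene, np.nan, np.nan, np.nan, "near chromosome edge"))
            continue
        ndr = _oriented(g.tss, g.strand, ndr_window)
        k2 = _oriented(g.tss, g.strand, k2_window)
        ref_l = (g.tss - ref_flank[1], g.tss - ref_flank[0])
        ref_r = (g.tss + ref_flank[0], g.tss + ref_flank[1])
        ref_bases = index.overlap_sum(g.chrom, *ref_l) + index.overlap_sum(
            g.chrom, *ref_r
        )
        ref_depth = ref_bases / (2 * (ref_flank[1] - ref_flank[0]))
        k2_depth = index.overlap_sum(g.chrom, *k2) / (k2[1] - k2[0])
        ndr_depth = index.overlap_sum(g.chrom, *ndr) / (ndr[1] - ndr[0])
        if ref_depth == 0:
            rows.append((g.gene, np.nan, np.nan, np.nan, "zero reference depth"))
            continue
        conventional = k2_depth / genome_depth if genome_depth else np.nan
        rows.append(
            (g.gene, conventional, ndr_depth / ref_depth, k2_depth / ref_depth, "")
        )
    return pd.DataFrame(
        rows, columns=["gene", "conventional_rc", "ndr_rc", "k2_rc", "note"]
    )


@dataclass
class ChromatinStateCall:
    gene: str
    median_ndr_rc: float
    median_k2_rc: float
    freq_open: float
    freq_closed: float
    state: str  # permissive | nonpermissive | indeterminate


def classify_chromatin_state(
    ndr_table: pd.DataFrame,
    k2_table: pd.DataFrame,
    open_threshold: float = OPEN_THRESHOLD,
    closed_threshold: float = CLOSED_THRESHOLD,
    freq_min: float = FREQ_MIN,
) -> list[ChromatinStateCall]:
    """Cohort chromatin-state call per gene.

    ``ndr_table`` / ``k2_table`` are genes x samples matrices of relative
    coverages (aligned indexes). ``freq_open`` is the fraction of samples
    with both coverages strictly below ``open_threshold``; ``freq_closed``
    the fraction with both strictly above ``closed_threshold``; the call
    needs a strict majority (> ``freq_min``).
    """
    if not ndr_table.index.equals(k2_table.index):
        raise ValueError("tables must share the same gene index")
    calls = []
    ndr = ndr_table.to_numpy(float)
    k2 = k2_table.to_numpy(float)
    valid = np.isfinite(ndr) & np.isfinite(k2)
    for i, gene in enumerate(ndr_table.index):
        n = int(valid[i].sum())
        if n == 0:
            calls.append(ChromatinStateCall(gene, np.nan, np.nan, 0.0, 0.0,
                                            "indeterminate"))
            continue
        both_open = (ndr[i] < open_threshold) & (k2[i] < open_threshold) & valid[i]
        both_closed = (
            (ndr[i] > closed_threshold) & (k2[i] > closed_threshold) & valid[i]
        )
        fo, fc = both_open.sum() / n, both_closed.sum() / n
        if fo > freq_min and fo >= fc:
            state = "permissive"
        elif fc > freq_min:
            state = "nonpermissive"
        else:
            state = "indeterminate"
        calls.append(
            ChromatinStateCall(
                gene,
                float(np.nanmedian(ndr[i][valid[i]])),
                float(np.nanmedian(k2[i][valid[i]])),
                float(fo),
                float(fc),
                state,
            )
        )
    return calls


def calls_frame(calls: list[ChromatinStateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "median_ndr_rc": c.median_ndr_rc,
                "median_k2_rc": c.median_k2_rc,
                "freq_open": c.freq_open,
                "freq_closed": c.freq_closed,
                "state": c.state,
            }
            for c in calls
        ]
    )


def expression_concordance(
    values: pd.Series,
    groups: pd.Series,
    group_a: str = "up",
    group_b: str = "down",
) -> dict:
    """Two-sided rank-sum comparison of per-gene values between two gene sets.

    Used both ways: expression between permissive/nonpermissive calls, and
    relative coverage (or PFE) between up/down expression labels. Returns
    medians, direction, and the p-value (None when a group has < 2 genes).
    """
    joined = pd.concat({"value": values, "group": groups}, axis=1).dropna()
    a = joined.loc[joined["group"] == group_a, "value"].to_numpy(float)
    b = joined.loc[joined["group"] == group_b, "value"].to_numpy(float)
    out = {
        "n_a": len(a),
        "n_b": len(b),
        "median_a": float(np.median(a)) if len(a) else np.nan,
        "median_b": float(np.median(b)) if len(b) else np.nan,
        "p_value": None,
        "direction": None,
    }
    if len(a) < 2 or len(b) < 2:
        warnings.warn("group with < 2 genes: test skipped")
        return out
    out["p_value"] = float(stats.ranksums(a, b).pvalue)
    out["direction"] = (
        f"{group_a}>{group_b}" if out["median_a"] > out["median_b"]
        else f"{group_a}<{group_b}" if out["median_a"] < out["median_b"]
        else "equal"
    )
    return out
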