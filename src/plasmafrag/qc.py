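"""Fragment-size quality control and hemolysis risk flagging.

Plasma cfDNA has a characteristic mononucleosomal size mode near 167 bp.
Hemolysis (red-blood-cell rupture during handling) contaminates plasma
with high-molecular-weight genomic DNA, inflating the >=150 bp tail and
the 30-60 bp range while depressing the short-fragment ratio. A sample is
flagged as high hemolysis risk when the genome-wide short(100-150 bp) to
long(151-220 bp) count ratio drops strictly below a threshold
(default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import SampleFragments

HEMOLYSIS_THRESHOLD = 0.05
SHORT_RANGE = (100, 150)  # inclusive
LONG_RANGE = (151, 220)  # inclusive

#: printed size ranges; half-open [lo, hi) so they partition [30, inf)
SIZE_RANGE_EDGES = (30, 80, 150, 220, 1000)
SIZE_RANGE_NAMES = ("f_30_80", "f_80_150", "f_150_220", "f_220_1000", "f_ge_1000")


@dataclass
class SizeHistogram:
    """1-bp resolution fragment-length histogram with a >=1000 bp overflow.

    ``counts`` maps length (bp) to count; lengths >= ``overflow_at`` are
    pooled under the key ``overflow_at``.
    """

    counts: dict[int, int]
    overflow_at: int = 1000

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def mass(self, lo: int, hi: float) -> int:
        """Total count with lo <= length < hi (overflow class counts as
        exactly ``overflow_at``)."""
        return int(sum(c for l, c in self.counts.items() if lo <= l < hi))

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame(items, columns=["length", "count"])


@dataclass
class SizeFractions:
    f_30_80: float
    f_80_150: float
    f_150_220: float
    f_220_1000: float
    f_ge_1000: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_30_80, self.f_80_150, self.f_150_220, self.f_220_1000,
             self.f_ge_1000]
        )


@dataclass
class QCReport:
    sample_id: str
    fractions: SizeFractions
    short_long_ratio: float
    hemolysis_flag: bool
    hemolysis_reason: str
    chromosome_table: pd.DataFrame


def size_histogram(sample: SampleFragments, overflow_at: int = 1000) -> SizeHistogram:
    """Integer counts per fragment length; >= ``overflow_at`` pooled."""
    lengths = sample.data["length"].to_numpy()
    if lengths.size == 0:
        warnings.warn(f"{sample.sample_id}: empty sample, empty histogram")
        return SizeHistogram({}, overflow_at)
    clipped = np.minimum(lengths, overflow_at)
    vals, cnt = np.unique(clipped, return_counts=True)
    return SizeHistogram(dict(zip(vals.tolist(), cnt.tolist())), overflow_at)


def size_fractions(hist: SizeHistogram) -> SizeFractions:
    """Fractions in [30,80), [80,150), [150,220), [220,1000), [1000, inf).

    Ranges are half-open so the partition is disjoint and exhaustive;
    fragments below 30 bp are excluded upstream by the loader.
    """
    total = hist.total
    if total == 0:
        raise ValueError("empty histogram")
    edges = SIZE_RANGE_EDGES
    masses = [hist.mass(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    masses.append(hist.mass(edges[-1], np.inf))
    return SizeFractions(*(m / total for m in masses))


def hemolysis_flag(
    source: SizeHistogram | SampleFragments,
    threshold: float = HEMOLYSIS_THRESHOLD,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> tuple[float, bool, str]:
    """Genome-wide short/long count ratio and the strict-< hemolysis flag.

    Returns ``(ratio, flag, reason)``; a zero long count makes the ratio
    undefined and the sample is flagged with a degenerate-profile reason.
    """
    if isinstance(source, SampleFragments):
        lengths = source.data["length"].to_numpy()
        short = int(((lengths >= short_range[0]) & (lengths <= short_range[1])).sum())
        long_ = int(((lengths >= long_range[0]) & (lengths <= long_range[1])).sum())
    else:
        short = source.mass(short_range[0], short_range[1] + 1)
        long_ = source.mass(long_range[0], long_range[1] + 1)
    if long_ == 0:
        return float("nan"), True, "degenerate size profile (no long fragments)"
    ratio = short / long_
    flagged = ratio < threshold
    reason = f"short/long ratio {ratio:.4f} < {threshold}" if flagged else ""
    return ratio, flagged, reason


def chromosome_stats(
    sample: SampleFragments, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-chromosome read count, mean length and mean mapping quality.

    One row per chromosome in ``chrom_sizes`` (zero-filled when absent from
    the data); without a sizes table, rows cover the chromosomes observed.
    """
    df = sample.data
    chroms = list(chrom_sizes) if chrom_sizes else sorted(df["chrom"].unique())
    grouped = df.groupby("chrom")
    rows = []
    for chrom in chroms:
        if chrom in grouped.groups:
            g = grouped.get_group(chrom)
            rows.append(
                (chrom, len(g), float(g["length"].mean()),
                 float(g["mapq"].mean()))
            )
        else:
            rows.append((chrom, 0, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["chrom", "n_fragments", "mean_length",
                                       "mean_mapq"])


def qc_report(
    sample: SampleFragments,
    chrom_sizes: dict[str, int] | None = None,
    hemolysis_threshold: float = HEMOLYSIS_THRESHOLD,
) -> QCReport:
    """Full per-sample QC: size fractions, hemolysis flag, chromosome table."""
    hist = size_histogram(sample)
    fractions = size_fractions(hist)
    ratio, flag, reason = hemolysis_flag(hist, hemolysis_threshold)
    table = chromosome_stats(sample, chrom_sizes)
    return QCReport(sample.sample_id, fractions, ratio, flag, reason, table)


def qc_report_frame(report: QCReport) -> pd.DataFrame:
    """One-row summary table for TSV export."""
    row = {
        "sample_id": report.sample_id,
        **dict(zip(SIZE_RANGE_NAMES, report.fractions.as_array())),
        "short_long_ratio": report.short_long_ratio,
        "hemolysis_flag": report.hemolysis_flag,
        "hemolysis_reason": report.hemolysis_reason,
    }
    return pd.DataFrame([row])
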