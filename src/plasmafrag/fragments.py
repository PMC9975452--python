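"""Loading, filtering and binning of cfDNA fragments.

A fragment is one sequenced cell-free DNA molecule, represented as a
0-based half-open genomic interval (BED convention). Fragments come either
from a coordinate-sorted paired-end BAM/SAM (one fragment per properly
paired template, using the outer template span) or from a 3-4 column
fragment BED (chrom, start, end[, mapq]).

All downstream feature extraction (size QC, per-bin ratio/fraction
profiles, CNV, TSS coverage, PFE, TF occupancy) consumes the containers
defined here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default filters for binned profiles; QC histograms lift the upper length
#: bound so the ">=1000 bp" fraction stays computable
DEFAULT_MIN_MAPQ = 30
DEFAULT_LENGTH_RANGE = (30, 1000)
QC_LENGTH_RANGE = (30, None)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length", "mapq"]


@dataclass
class SampleFragments:
    """All retained fragments of one sample, sorted by (chrom, start).

    Attributes
    ----------
    sample_id:
        Sample identifier.
    data:
        DataFrame with columns chrom, start, end, length, mapq. Coordinates
        are 0-based half-open; ``length == end - start``.
    n_total:
        Number of records seen before filtering.
    n_after_filters:
        Number of fragments retained (== ``len(data)``).
    """

    sample_id: str
    data: pd.DataFrame
    n_total: int
    n_after_filters: int
    n_rejected_lines: int = 0

    def __post_init__(self) -> None:
        if self.n_after_filters != len(self.data):
            raise ValueError("n_after_filters must equal the number of rows")
        if len(self.data) and not (self.data["start"] < self.data["end"]).all():
            raise ValueError("fragments must satisfy start < end")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def subset_lengths(self, lo: int, hi: int | None) -> "SampleFragments":
        """Fragments with lo <= length (< hi if hi is given)."""
        m = self.data["length"] >= lo
        if hi is not None:
            m &= self.data["length"] < hi
        d = self.data[m].reset_index(drop=True)
        return SampleFragments(self.sample_id, d, self.n_total, len(d))


@dataclass
class GenomeBins:
    """Non-overlapping half-open tiling of the genome into fixed-size bins.

    ``bins`` has columns chrom, start, end, gc (NaN when no GC source was
    given) and partial (True for a kept terminal bin shorter than
    ``bin_size``). A terminal partial bin is kept iff it spans at least half
    of ``bin_size``, avoiding high-variance tiny bins.
    """

    bins: pd.DataFrame
    bin_size: int

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(float)


def _from_records(sample_id, recs, n_total, n_rejected=0) -> SampleFragments:
    if recs:
        df = pd.DataFrame(recs, columns=FRAGMENT_COLUMNS)
    else:
        df = pd.DataFrame(
            {
                "chrom": pd.Series([], dtype=str),
                "start": pd.Series([], dtype=np.int64),
                "end": pd.Series([], dtype=np.int64),
                "length": pd.Series([], dtype=np.int64),
                "mapq": pd.Series([], dtype=float),
            }
        )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return SampleFragments(sample_id, df, n_total, len(df), n_rejected)


def _length_ok(length: int, length_range) -> bool:
    lo, hi = length_range
    if length < (lo if lo is not None else 1):
        return False
    if hi is not None and length > hi:
        return False
    return 1 <= length <= 10_000_000


def _load_bed(
    path: Path, sample_id: str, min_mapq: int, length_range
) -> SampleFragments:
    recs: list[tuple] = []
    n_total = 0
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                n_rejected += 1
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_rejected += 1
                continue
            n_total += 1
            mapq = float(parts[3]) if len(parts) > 3 and parts[3] != "." else np.nan
            if min_mapq and not np.isnan(mapq) and mapq < min_mapq:
                continue
            length = end - start
            if not _length_ok(length, length_range):
                continue
            recs.append((chrom, start, end, length, mapq))
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} malformed BED line(s)", stacklevel=3
        )
    return _from_records(sample_id, recs, n_total, n_rejected)


def _load_bam(
    path: Path, sample_id: str, min_mapq: int, dedup: bool, length_range
) -> SampleFragments:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    recs: list[tuple] = []
    n_total = 0
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            # one fragment per template: count it on the forward-strand mate
            if (
                read.is_unmapped
                or not read.is_paired
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.template_length <= 0
            ):
                continue
            n_total += 1
            if dedup and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            start = read.reference_start  # pysam already 0-based
            length = read.template_length
            if not _length_ok(length, length_range):
                continue
            recs.append(
                (read.reference_name, start, start + length, length,
                 float(read.mapping_quality))
            )
    return _from_records(sample_id, recs, n_total)


def load_fragments(
    path: str | Path,
    sample_id: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dedup: bool = True,
    length_range: tuple[int, int | None] = DEFAULT_LENGTH_RANGE,
) -> SampleFragments:
    """Load fragments from a BAM/SAM or fragment BED file.

    For BAM input one fragment per properly paired template is emitted,
    spanning the outer template length; duplicates (when ``dedup``),
    sub-``min_mapq`` records and lengths outside ``length_range`` are
    dropped. ``length_range`` is inclusive on both ends; ``None`` as upper
    bound disables the cap (QC mode).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"fragment file not found: {path}")
    if sample_id is None:
        sample_id = path.stem.removesuffix(".frag")
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        sf = _load_bam(path, sample_id, min_mapq, dedup, length_range)
    else:
        sf = _load_bed(path, sample_id, min_mapq, length_range)
    if sf.n_after_filters == 0:
        warnings.warn(f"{path}: no fragments survived filtering", stacklevel=2)
    return sf


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chromosome-sizes file -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def _gc_from_fasta(bins: pd.DataFrame, fasta_path: str | Path) -> np.ndarray:
    from pyfaidx import Fasta

    gc = np.full(len(bins), np.nan)
    with Fasta(str(fasta_path)) as fa:
        for i, row in enumerate(bins.itertuples(index=False)):
            seq = str(fa[row.chrom][row.start : row.end]).upper()
            acgt = sum(seq.count(b) for b in "ACGT")
            if acgt:
                gc[i] = (seq.count("G") + seq.count("C")) / acgt
    return gc


def make_bins(
    chrom_sizes: Mapping[str, int],
    bin_size: int = 5_000_000,
    gc_source: str | Path | pd.DataFrame | None = None,
) -> GenomeBins:
    """Tile each chromosome into half-open ``bin_size`` bins from 0.

    The terminal partial bin is kept (and flagged) iff it covers at least
    half of ``bin_size``. ``gc_source`` may be a per-bin GC table
    (DataFrame or TSV with columns chrom, start, end, gc) or a genome FASTA
    path; omitted, ``gc`` is NaN.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"non-positive size for chromosome {chrom}")
        pos = 0
        while pos < size:
            end = min(pos + bin_size, size)
            width = end - pos
            if width == bin_size:
                rows.append((chrom, pos, end, False))
            elif width >= bin_size / 2:
                rows.append((chrom, pos, end, True))
            pos += bin_size
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
    bins["gc"] = np.nan

    if gc_source is not None:
        if isinstance(gc_source, (str, Path)) and str(gc_source).lower().endswith(
            (".fa", ".fasta", ".fa.gz", ".fna")
        ):
            bins["gc"] = _gc_from_fasta(bins, gc_source)
        else:
            table = (
                gc_source
                if isinstance(gc_source, pd.DataFrame)
                else pd.read_csv(gc_source, sep="\t", comment="#")
            )
            missing = set(table["chrom"]) - set(chrom_sizes)
            if missing:
                raise ValueError(
                    "GC table names chromosome(s) absent from chrom_sizes: "
                    + ", ".join(sorted(missing))
                )
            merged = bins.drop(columns="gc").merge(
                table[["chrom", "start", "gc"]], on=["chrom", "start"], how="left"
            )
            bins["gc"] = merged["gc"].to_numpy()
    bad = bins["gc"].dropna()
    if len(bad) and not ((bad >= 0) & (bad <= 1)).all():
        raise ValueError("gc fractions must lie in [0, 1]")
    return GenomeBins(bins[["chrom", "start", "end", "gc", "partial"]], bin_size)


@dataclass
class BinAssignment:
    """Fragment-to-bin index: per-fragment bin id (-1 = unassigned)."""

    bin_index: np.ndarray
    n_excluded: int  # fragments on chromosomes absent from the bin frame
    n_outside: int = 0  # midpoints past the last kept bin (dropped partials)

    @property
    def n_assigned(self) -> int:
        return int((self.bin_index >= 0).sum())


def assign_to_bins(sample: SampleFragments, bins: GenomeBins) -> BinAssignment:
    """Assign each fragment to the bin containing its midpoint.

    Midpoint = floor((start + end) / 2); bins are half-open so every
    midpoint maps to exactly one bin or to none (dropped terminal partial,
    or a chromosome absent from the bin frame).
    """
    df = sample.data
    idx = np.full(len(df), -1, dtype=np.int64)
    n_excluded = 0
    n_outside = 0
    if len(df) == 0:
        return BinAssignment(idx, 0, 0)
    mid = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    chroms = df["chrom"].to_numpy()
    for chrom, sub in bins.bins.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        local = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (local >= 0) & (mid[sel] < ends[np.clip(local, 0, len(ends) - 1)])
        idx[sel[ok]] = sub.index.to_numpy()[local[ok]]
        n_outside += int((~ok).sum())
    known = np.isin(chroms, bins.bins["chrom"].unique())
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info(
            "%s: %d fragment(s) on chromosomes absent from bin frame",
            sample.sample_id,
            n_excluded,
        )
    return BinAssignment(idx, n_excluded, n_outside)


def bin_counts(sample: SampleFragments, bins: GenomeBins,
               assignment: BinAssignment | None = None) -> np.ndarray:
    """Per-bin fragment counts (midpoint assignment)."""
    if assignment is None:
        assignment = assign_to_bins(sample, bins)
    counts = np.bincount(
        assignment.bin_index[assignment.bin_index >= 0], minlength=len(bins)
    )
    return counts.astype(np.int64)
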