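"""Composite nucleosome-occupancy profiles around TF binding sites.

Averaging cfDNA coverage over the many binding sites of one transcription
factor produces a composite occupancy map: factors active in the cells
shedding the DNA show a central coverage dip (accessible, nucleosome-free
sites) flanked by phased nucleosome signal. Profiles are normalized to
the mean coverage of the outer 25% of positions on each side so they are
invariant to sequencing depth; the central score is the mean normalized
coverage within +-50 bp of the site center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import SampleFragments
from .tss import _ChromIndex

WINDOW = 1000
STEP = 10
CENTRAL_HALF_WIDTH = 50
MIN_SITES = 10


@dataclass
class CompositeProfile:
    tf_name: str
    positions: np.ndarray  # site-relative, -window..window at `step`
    mean_coverage: np.ndarray  # flank-normalized
    n_sites: int
    central_score: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "coverage": self.mean_coverage}
        )


def read_sites(path) -> pd.DataFrame:
    """BED3/BED6 site list -> DataFrame(chrom, start, end, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.split()
            strand = p[5] if len(p) > 5 and p[5] in "+-" else "+"
            rows.append((p[0], int(p[1]), int(p[2]), strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def composite_profile(
    sample: SampleFragments,
    sites: pd.DataFrame,
    tf_name: str = "TF",
    window: int = WINDOW,
    step: int = STEP,
    central_half_width: int = CENTRAL_HALF_WIDTH,
    min_sites: int = MIN_SITES,
    chrom_sizes: dict[str, int] | None = None,
) -> CompositeProfile:
    """Site-averaged, flank-normalized coverage around site centers.

    Coverage is evaluated at positions -window..window in ``step``-bp
    increments relative to each site center (strand-oriented when strand
    is given); sites whose window leaves the chromosome are skipped.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    positions = np.arange(-window, window + 1, step)
    acc = np.zeros(len(positions), float)
    n_used = 0
    index = _ChromIndex(sample)
    for s in sites.itertuples(index=False):
        center = (s.start + s.end) // 2
        if center - window < 0:
            continue
        if chrom_sizes and center + window >= chrom_sizes.get(s.chrom, np.inf):
            continue
        if s.chrom not in index.chroms:
            continue
        starts, ends = index.chroms[s.chrom]
        lo = np.searchsorted(starts, center - window - index.max_len, "left")
        hi = np.searchsorted(starts, center + window + 1, "left")
        st, en = starts[lo:hi], ends[lo:hi]
        # per-position depth = number of fragments overlapping that base
        pos = center + positions
        depth = (
            (st[None, :] <= pos[:, None]) & (en[None, :] > pos[:, None])
        ).sum(axis=1).astype(float)
        if s.strand == "-":
            depth = depth[::-1]
        acc += depth
        n_used += 1
    if n_used < min_sites:
        raise ValueError(f"too few usable sites ({n_used} < {min_sites})")
    mean_cov = acc / n_used
    n_flank = max(1, len(positions) // 4)  # outer 25% of positions, each side
    flank_mean = np.concatenate([mean_cov[:n_flank], mean_cov[-n_flank:]]).mean()
    if flank_mean <= 0:
        raise ValueError("zero flank coverage; cannot normalize")
    norm = mean_cov / flank_mean
    central = np.abs(positions) <= central_half_width
    return CompositeProfile(
        tf_name, positions, norm, n_used, float(norm[central].mean())
    )


def tf_feature_vector(
    profiles: dict[str, CompositeProfile | None], tf_order: list[str]
) -> pd.Series:
    """Ordered per-sample vector of central scores (NaN for failed TFs)."""
    return pd.Series(
        {
            tf: (profiles[tf].central_score if profiles.get(tf) else np.nan)
            for tf in tf_order
        }
    )
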