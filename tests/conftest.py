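import numpy as np
import pandas as pd
import pytest

from plasmafrag.fragments import SampleFragments
from plasmafrag.synthetic import SimConfig, default_config, simulate_cohort


def make_sample(rows, sample_id="s"):
    """Build a SampleFragments from (chrom, start, end[, mapq]) tuples."""
    recs = []
    for r in rows:
        chrom, start, end = r[:3]
        mapq = float(r[3]) if len(r) > 3 else 60.0
        recs.append((chrom, start, end, end - start, mapq))
    df = (
        pd.DataFrame(recs, columns=["chrom", "start", "end", "length", "mapq"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    return SampleFragments(sample_id, df, len(df), len(df))


def uniform_tiling_sample(chrom="chr1", size=100_000, frag_len=100, phase=0,
                          sample_id="uniform"):
    """Fragments tiling a chromosome end to end: exact depth 1 everywhere."""
    starts = np.arange(phase, size - frag_len + 1, frag_len)
    return make_sample([(chrom, int(s), int(s + frag_len)) for s in starts],
                       sample_id)


@pytest.fixture(scope="session")
def small_cohort():
    """8 cancer + 8 healthy + 2 hemolysis on the default mini genome."""
    cfg = default_config(7, n_fragments=30_000)
    cfg.genes.n_genes = 60
    return simulate_cohort(cfg, 8, 8, 2)


@pytest.fixture(scope="session")
def tss_dense_cohort():
    """High-depth cohort on a small gene-dense genome for TSS/PFE recovery.

    1 Mb genome, 100 genes, 30 samples at 400k fragments/sample (~70x),
    the depth regime where per-gene promoter coverage is informative."""
    cfg = SimConfig(
        seed=11,
        genome=(("chr1", 1_000_000),),
        bin_size=250_000,
        n_fragments=400_000,
    )
    cfg.genes.n_genes = 100
    cfg.tf.n_sites = 150
    return simulate_cohort(cfg, 0, 30, 0)
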