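"""Seeded simulator of cfDNA fragment cohorts.

Generates plasma-like fragment sets with the statistical structure the
feature modules assume, so every pipeline stage is testable without
sequencing data:

* fragment lengths from a Gaussian mixture: a ~167 bp mononucleosome peak
  with ~10.4 bp helical phasing ripple, a dinucleosomal shoulder near
  334 bp, and a tumor-associated short component near 145 bp whose weight
  rises in cancer samples;
* hemolysis contamination as an added heavy >=150 bp genomic-DNA tail plus
  an excess 30-60 bp component;
* fragment placement proportional to per-bin copy-number multipliers and
  a smooth GC-preference curve (controllable confounder for the GC
  correction);
* promoter effects coupled to expression labels: nucleosome-depleted
  regions (thinned coverage) and broadened fragment-length mixtures at
  expressed genes, extra occupancy at closed genes;
* central coverage depletion at TF binding sites.

Ground truth (labels, multipliers, gene states, TF depletions) is a
first-class output so recovery tests read truth, never expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import GenomeBins, SampleFragments, make_bins

DEFAULT_GENOME = (("chr1", 30_000_000), ("chr2", 30_000_000), ("chr3", 30_000_000))


@dataclass
class SizeMixture:
    """Gaussian mixture over fragment length plus optional special tails.

    ``components`` is a list of (mu, sd, weight); ``w_gdna`` adds a
    hemolysis-style genomic-DNA tail (150 bp + exponential of mean
    ``gdna_scale``) and ``w_tiny`` a uniform 30-60 bp component. All
    weights must sum to 1.
    """

    components: tuple[tuple[float, float, float], ...]
    w_gdna: float = 0.0
    gdna_scale: float = 300.0
    w_tiny: float = 0.0
    phasing_amp: float = 0.1
    phasing_period: float = 10.4

    def validate(self) -> None:
        total = sum(w for _, _, w in self.components) + self.w_gdna + self.w_tiny
        if any(w < 0 for _, _, w in self.components) or self.w_gdna < 0 or self.w_tiny < 0:
            raise ValueError("mixture weights must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    def broadened(self, spread: float) -> "SizeMixture":
        """Same mixture with all Gaussian sds multiplied by ``spread``."""
        return replace(
            self,
            components=tuple((mu, sd * spread, w) for mu, sd, w in self.components),
        )

    def mass(self, lo: float, hi: float) -> float:
        """Analytic probability of length in [lo, hi) (phasing ripple and
        integer rounding ignored; adequate for +-0.02 checks)."""
        from scipy.stats import expon, norm, uniform

        p = 0.0
        for mu, sd, w in self.components:
            p += w * (norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd))
        if self.w_gdna:
            p += self.w_gdna * (
                expon.cdf(hi - 150, scale=self.gdna_scale)
                - expon.cdf(lo - 150, scale=self.gdna_scale)
            )
        if self.w_tiny:
            p += self.w_tiny * (uniform.cdf(hi, 30, 30) - uniform.cdf(lo, 30, 30))
        return p


HEALTHY_MIXTURE = SizeMixture(((167, 10, 0.86), (334, 20, 0.08), (145, 10, 0.06)))
CANCER_MIXTURE = SizeMixture(((167, 10, 0.72), (334, 20, 0.08), (145, 10, 0.20)))
HEMOLYSIS_MIXTURE = SizeMixture(
    ((167, 10, 0.40), (334, 20, 0.05)), w_gdna=0.50, w_tiny=0.05
)


@dataclass
class GeneModel:
    """Promoter model: gene positions, expression labels and effect sizes."""

    n_genes: int = 200
    ndr_depletion: float = 0.4  # NDR coverage factor for expressed (up) genes
    k2_depletion: float = 0.7  # promoter-wide factor for expressed genes
    occupancy: float = 1.6  # 2-kb factor for closed (down) genes
    length_spread: float = 1.8  # sd multiplier for lengths at up promoters
    frac_up: float = 0.3
    frac_down: float = 0.3
    ndr_window: tuple[int, int] = (-150, 50)
    k2_half_width: int = 1000


@dataclass
class TFModel:
    """TF site lists with central coverage depletion per label."""

    n_sites: int = 200
    central_half_width: int = 50
    depletion_healthy: float = 0.9
    depletion_cancer: float = 0.6
    tf_names: tuple[str, ...] = ("TF_open", "TF_ctrl")
    # second and later TFs get no depletion (control factors)


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    bin_size: int = 5_000_000
    n_fragments: int = 100_000
    healthy_mixture: SizeMixture = field(default_factory=lambda: HEALTHY_MIXTURE)
    cancer_mixture: SizeMixture = field(default_factory=lambda: CANCER_MIXTURE)
    hemolysis_mixture: SizeMixture = field(
        default_factory=lambda: HEMOLYSIS_MIXTURE
    )
    gc_range: tuple[float, float] = (0.35, 0.55)
    gc_bias_strength: float = 1.0
    # bin-level ratio structure: a fixed zero-mean modulation of the short
    # component shared by every sample (regional chromatin signal), plus
    # per-sample zero-sum distortions in cancer (ratio heterogeneity)
    ratio_modulation_amp: float = 0.5
    cancer_ratio_noise_sd: float = 0.5
    # cancer copy-number events: {bin_index: multiplier}; built from
    # (copies, tumor_fraction) via cn_multiplier()
    amplified_bins: dict[int, float] = field(default_factory=dict)
    genes: GeneModel = field(default_factory=GeneModel)
    tf: TFModel = field(default_factory=TFModel)

    def validate(self) -> None:
        for mix in (self.healthy_mixture, self.cancer_mixture,
                    self.hemolysis_mixture):
            mix.validate()
        if self.n_fragments <= 0 or self.bin_size <= 0:
            raise ValueError("n_fragments and bin_size must be positive")
        if any(m <= 0 for m in self.amplified_bins.values()):
            raise ValueError("copy multipliers must be positive")
        g = self.genes
        if min(g.ndr_depletion, g.k2_depletion, g.occupancy, g.length_spread) <= 0:
            raise ValueError("gene-model factors must be positive")

    def mixture_for(self, label: str) -> SizeMixture:
        return {
            "healthy": self.healthy_mixture,
            "cancer": self.cancer_mixture,
            "hemolysis": self.hemolysis_mixture,
        }[label]


def cn_multiplier(copies: float, tumor_fraction: float) -> float:
    """Bulk bin multiplier of a clonal CNA: 1 + tf * (copies/2 - 1)."""
    return 1.0 + tumor_fraction * (copies / 2.0 - 1.0)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Default study conditions: mini genome, two amplified bins in cancer
    (3 copies at 25% tumor fraction)."""
    cfg = SimConfig(
        seed=seed, amplified_bins={3: cn_multiplier(3, 0.25),
                                   4: cn_multiplier(3, 0.25)}
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# genome scaffolding derived deterministically from the config


def chrom_sizes(config: SimConfig) -> dict[str, int]:
    return dict(config.genome)


def genome_bins(config: SimConfig) -> GenomeBins:
    bins = make_bins(chrom_sizes(config), config.bin_size)
    n = len(bins)
    lo, hi = config.gc_range
    gc = lo + (hi - lo) * (np.arange(n) / max(n - 1, 1))
    table = bins.bins.copy()
    table["gc"] = gc
    return GenomeBins(table, config.bin_size)


def gene_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene placement + expression labels.

    Genes are spaced evenly with an 8-kb margin from chromosome edges;
    labels cycle deterministically under the master seed so truth is
    reproducible. Columns: gene, chrom, strand, tss, expression
    (up/down/neutral), chromatin_state (truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sizes = chrom_sizes(config)
    total = sum(sizes.values())
    per_chrom = {
        c: max(1, round(config.genes.n_genes * s / total)) for c, s in sizes.items()
    }
    rows = []
    margin = 8000
    i = 0
    for chrom, size in sizes.items():
        k = per_chrom[chrom]
        span = size - 2 * margin
        positions = margin + (np.arange(k) + 0.5) / k * span
        for tss in positions.astype(np.int64):
            rows.append((f"gene_{i:04d}", chrom, "+" if i % 2 == 0 else "-",
                         int(tss)))
            i += 1
    df = pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"])
    n = len(df)
    n_up = round(config.genes.frac_up * n)
    n_down = round(config.genes.frac_down * n)
    labels = np.array(["neutral"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_up]] = "up"
    labels[order[n_up : n_up + n_down]] = "down"
    df["expression"] = labels
    df["chromatin_state"] = np.select(
        [labels == "up", labels == "down"], ["permissive", "nonpermissive"],
        "indeterminate",
    )
    return df


def tf_sites(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Deterministic per-TF site lists (BED-like frames), away from edges."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sizes = chrom_sizes(config)
    chroms = list(sizes)
    out = {}
    for tf in config.tf.tf_names:
        chosen = rng.integers(0, len(chroms), config.tf.n_sites)
        rows = []
        for ci in chosen:
            chrom = chroms[ci]
            center = int(rng.integers(5000, sizes[chrom] - 5000))
            rows.append((chrom, center - 10, center + 10, "+"))
        out[tf] = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return out


# ---------------------------------------------------------------------------
# fragment generation


def _sample_lengths(rng: np.random.Generator, mixture: SizeMixture,
                    n: int) -> np.ndarray:
    """Draw integer fragment lengths from the mixture.

    The mononucleosome-phasing ripple multiplies the first component's
    density by 1 + amp*cos(2*pi*(l-mu)/period), applied by rejection.
    """
    weights = [w for _, _, w in mixture.components] + [mixture.w_gdna,
                                                       mixture.w_tiny]
    comp = rng.choice(len(weights), size=n, p=np.array(weights) / sum(weights))
    lengths = np.empty(n, float)
    for i, (mu, sd, _) in enumerate(mixture.components):
        sel = comp == i
        k = int(sel.sum())
        if not k:
            continue
        draws = rng.normal(mu, sd, k)
        if i == 0 and mixture.phasing_amp > 0:
            # helical-phasing ripple on the mononucleosome peak
            amp, period = mixture.phasing_amp, mixture.phasing_period
            for _ in range(8):
                u = rng.random(draws.shape[0])
                keep = u < (1 + amp * np.cos(2 * np.pi * (draws - mu) / period)) / (
                    1 + amp
                )
                bad = ~keep
                if not bad.any():
                    break
                draws[bad] = rng.normal(mu, sd, int(bad.sum()))
        lengths[sel] = draws
    sel = comp == len(mixture.components)
    if sel.any():
        lengths[sel] = 150 + rng.exponential(mixture.gdna_scale, int(sel.sum()))
    sel = comp == len(mixture.components) + 1
    if sel.any():
        lengths[sel] = rng.uniform(30, 60, int(sel.sum()))
    return np.clip(np.rint(lengths), 30, 50_000).astype(np.int64)


def _reweight_short(mixture: SizeMixture, factor: float) -> SizeMixture:
    """Scale the short (<160 bp) Gaussian component's weight by ``factor``
    and renormalize; identity when no such component exists."""
    short_idx = None
    for i, (mu, _, _) in enumerate(mixture.components):
        if mu < 160 and (short_idx is None
                         or mu < mixture.components[short_idx][0]):
            short_idx = i
    if short_idx is None or factor == 1.0:
        return mixture
    comps = [list(c) for c in mixture.components]
    comps[short_idx][2] *= max(factor, 0.0)
    total = sum(c[2] for c in comps) + mixture.w_gdna + mixture.w_tiny
    comps = tuple((mu, sd, w / total) for mu, sd, w in comps)
    return replace(
        mixture,
        components=comps,
        w_gdna=mixture.w_gdna / total,
        w_tiny=mixture.w_tiny / total,
    )


def ratio_modulation(config: SimConfig, n_bins: int) -> np.ndarray:
    """Fixed zero-mean per-bin modulation of the short-component weight."""
    i = np.arange(n_bins)
    m = config.ratio_modulation_amp * np.sin(4 * np.pi * i / max(n_bins, 1))
    return m - m.mean()


def _interval_factor(
    mids: np.ndarray, intervals: list[tuple[int, int, float]]
) -> np.ndarray:
    """Multiplicative acceptance factor per midpoint from (start, end, f)."""
    factor = np.ones(len(mids), float)
    for a, b, f in intervals:
        sel = (mids >= a) & (mids < b)
        if sel.any():
            factor[sel] *= f
    return factor


def _promoter_intervals(
    genes: pd.DataFrame, config: SimConfig, chrom: str
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int]]]:
    """(coverage-factor intervals, broadened-length intervals) for one chrom."""
    gm = config.genes
    cov: list[tuple[int, int, float]] = []
    broad: list[tuple[int, int]] = []
    for g in genes[genes["chrom"] == chrom].itertuples(index=False):
        sgn = 1 if g.strand == "+" else -1
        ndr = sorted((g.tss + sgn * gm.ndr_window[0], g.tss + sgn * gm.ndr_window[1]))
        k2 = (g.tss - gm.k2_half_width, g.tss + gm.k2_half_width)
        if g.expression == "up":
            cov.append((k2[0], k2[1], gm.k2_depletion))
            cov.append((ndr[0], ndr[1], gm.ndr_depletion / gm.k2_depletion))
            broad.append(k2)
        elif g.expression == "down":
            cov.append((k2[0], k2[1], gm.occupancy))
    return cov, broad


def simulate_sample(
    config: SimConfig, label: str, seed: int | None = None,
    sample_id: str = "sample",
) -> SampleFragments:
    """Simulate one sample's fragments (BED-dialect frame inside
    ``SampleFragments``); deterministic for a fixed seed.

    ``label`` selects the size mixture, the per-bin copy multipliers
    (cancer only) and the TF-site depletion depth. The hemolysis label
    uses healthy copy numbers with the contaminated mixture.
    """
    if label not in {"healthy", "cancer", "hemolysis"}:
        raise ValueError(f"unknown label {label!r}")
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 7])
    )
    bins = genome_bins(config)
    genes = gene_table(config)
    sites = tf_sites(config)
    mixture = config.mixture_for(label)
    gm = config.genes

    bt = bins.bins
    widths = (bt["end"] - bt["start"]).to_numpy(float)
    mult = np.ones(len(bt))
    if label == "cancer":
        for b, f in config.amplified_bins.items():
            mult[b] = f
    gc_pref = np.exp(config.gc_bias_strength * (bins.gc - np.nanmean(bins.gc)))
    weights = widths * mult * gc_pref
    probs = weights / weights.sum()

    fmax = max(1.0, gm.occupancy)
    n_draw = int(math.ceil(config.n_fragments * fmax * 1.05))
    bin_of = rng.choice(len(bt), size=n_draw, p=probs)
    offset = rng.random(n_draw)
    starts_of_bin = bt["start"].to_numpy()
    mids = (starts_of_bin[bin_of] + offset * widths[bin_of]).astype(np.int64)
    chrom_of = bt["chrom"].to_numpy()[bin_of]

    tf_depl = (
        config.tf.depletion_cancer if label == "cancer"
        else config.tf.depletion_healthy
    )

    keep = np.zeros(n_draw, bool)
    broadened_mask = np.zeros(n_draw, bool)
    for chrom in bt["chrom"].unique():
        sel = np.flatnonzero(chrom_of == chrom)
        if sel.size == 0:
            continue
        cov, broad = _promoter_intervals(genes, config, chrom)
        # first TF in the list carries the configured central depletion
        open_tf = config.tf.tf_names[0]
        hw = config.tf.central_half_width
        for s in sites[open_tf].itertuples(index=False):
            if s.chrom == chrom:
                c = (s.start + s.end) // 2
                cov.append((c - hw, c + hw, tf_depl))
        factor = _interval_factor(mids[sel], cov)
        keep[sel] = rng.random(sel.size) < factor / fmax
        bmask = np.zeros(sel.size, bool)
        for a, b in broad:
            bmask |= (mids[sel] >= a) & (mids[sel] < b)
        broadened_mask[sel] = bmask

    idx = np.flatnonzero(keep)
    if idx.size > config.n_fragments:
        idx = idx[
            np.sort(rng.choice(idx.size, config.n_fragments, replace=False))
        ]
    mids, chrom_of, broadened_mask = mids[idx], chrom_of[idx], broadened_mask[idx]
    bin_idx = bin_of[idx]

    mod = ratio_modulation(config, len(bt))
    if label == "cancer" and config.cancer_ratio_noise_sd > 0:
        noise = rng.normal(0, config.cancer_ratio_noise_sd, len(bt))
        noise -= noise.mean()  # zero-sum: genome-wide mixture preserved
    else:
        noise = np.zeros(len(bt))
    short_factor = np.clip((1 + mod) * (1 + noise), 0.05, None)
    # normalize by the placement-weighted mean so the genome-wide size
    # mixture stays at its configured masses
    short_factor = short_factor / float(short_factor @ probs)

    lengths = np.empty(len(mids), np.int64)
    for b in np.unique(bin_idx):
        sel_b = (bin_idx == b) & ~broadened_mask
        if sel_b.any():
            lengths[sel_b] = _sample_lengths(
                rng, _reweight_short(mixture, short_factor[b]),
                int(sel_b.sum()),
            )
    if broadened_mask.any():
        lengths[broadened_mask] = _sample_lengths(
            rng, mixture.broadened(gm.length_spread), int(broadened_mask.sum())
        )

    sizes = chrom_sizes(config)
    chrom_len = np.array([sizes[c] for c in chrom_of])
    half = lengths // 2
    mids = np.clip(mids, half, chrom_len - (lengths - half))
    starts = mids - half
    ends = starts + lengths

    df = pd.DataFrame(
        {
            "chrom": chrom_of,
            "start": starts,
            "end": ends,
            "length": lengths,
            "mapq": 60.0,
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return SampleFragments(sample_id, df, len(df), len(df))


@dataclass
class SimulatedCohort:
    config: SimConfig
    samples: dict[str, SampleFragments]
    truth: pd.DataFrame  # per-sample: sample_id, label, hemolysis, seed
    genes: pd.DataFrame  # per-gene truth (expression, chromatin_state)
    bins: GenomeBins
    amplified_bins: dict[int, float]
    tf_sites: dict[str, pd.DataFrame]

    @property
    def labels(self) -> pd.Series:
        return self.truth.set_index("sample_id")["label"]

    def amplified_genes(self) -> list[str]:
        """Genes whose span (+-10 kb promoter context) overlaps an
        amplified bin (truth for CNV recovery tests)."""
        bt = self.bins.bins
        out = []
        for g in self.genes.itertuples(index=False):
            for b in self.amplified_bins:
                row = bt.iloc[b]
                if row["chrom"] == g.chrom and row["start"] <= g.tss < row["end"]:
                    out.append(g.gene)
                    break
        return out


def simulate_cohort(
    config: SimConfig,
    n_cancer: int,
    n_healthy: int,
    n_hemolysis: int = 0,
) -> SimulatedCohort:
    """Simulate a labelled cohort; per-sample seeds derive from the master
    seed, so a fixed config reproduces the cohort exactly."""
    if min(n_cancer, n_healthy, n_hemolysis) < 0:
        raise ValueError("sample counts must be >= 0")
    if n_cancer + n_healthy + n_hemolysis == 0:
        raise ValueError("cohort must contain at least one sample")
    config.validate()
    plan = (
        [("cancer", i) for i in range(n_cancer)]
        + [("healthy", i) for i in range(n_healthy)]
        + [("hemolysis", i) for i in range(n_hemolysis)]
    )
    ss = np.random.SeedSequence([config.seed, 3_000_017])
    child_seeds = ss.generate_state(len(plan)) % (2**31)
    samples = {}
    rows = []
    for (label, i), seed in zip(plan, child_seeds):
        sid = f"{label}_{i:03d}"
        samples[sid] = simulate_sample(config, label, int(seed), sid)
        rows.append((sid, label, label == "hemolysis", int(seed)))
    truth = pd.DataFrame(rows, columns=["sample_id", "label", "hemolysis", "seed"])
    return SimulatedCohort(
        config, samples, truth, gene_table(config), genome_bins(config),
        dict(config.amplified_bins), tf_sites(config),
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text files: per-sample fragment BEDs,
    chrom.sizes, per-bin GC table, TSS table, TF site BEDs, truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, sf in cohort.samples.items():
        p = out / f"{sid}.frag.bed"
        sf.data[["chrom", "start", "end", "mapq"]].astype(
            {"start": int, "end": int}
        ).to_csv(p, sep="\t", header=False, index=False)
        paths[sid] = p
    cs = out / "chrom.sizes"
    with open(cs, "w") as fh:
        for chrom, size in cohort.config.genome:
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = cs
    gc = out / "bins.gc.tsv"
    cohort.bins.bins[["chrom", "start", "end", "gc"]].to_csv(
        gc, sep="\t", index=False
    )
    paths["gc_table"] = gc
    tss_p = out / "tss.tsv"
    cohort.genes[["gene", "chrom", "strand", "tss"]].to_csv(
        tss_p, sep="\t", index=False
    )
    paths["tss"] = tss_p
    for tf, sites in cohort.tf_sites.items():
        p = out / f"sites.{tf}.bed"
        sites.to_csv(p, sep="\t", header=False, index=False)
        paths[f"sites_{tf}"] = p
    truth_p = out / "truth.samples.tsv"
    cohort.truth.to_csv(truth_p, sep="\t", index=False)
    paths["truth_samples"] = truth_p
    gene_truth = out / "truth.genes.tsv"
    cohort.genes.to_csv(gene_truth, sep="\t", index=False)
    paths["truth_genes"] = gene_truth
    amp = out / "truth.amplified_bins.tsv"
    pd.DataFrame(
        [(b, f) for b, f in cohort.amplified_bins.items()],
        columns=["bin_index", "multiplier"],
    ).to_csv(amp, sep="\t", index=False)
    paths["truth_amplified_bins"] = amp
    return paths
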