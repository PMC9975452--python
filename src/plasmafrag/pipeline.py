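"""Pipeline orchestration: config validation, stage wiring, run manifest.

The pipeline runs the feature modules in dependency order

    io -> qc -> fragmentation -> cnv / tss / pfe / tfbs -> ml

over either a simulated cohort (``simulate`` section) or a directory of
fragment BED files with a labels table. Every run writes a JSON manifest
with the tool version, a config snapshot, input checksums, seeds and
per-stage output checksums; rerunning an unchanged config over unchanged
inputs skips stages whose stage key (config subset + input checksums)
matches the manifest, and deterministic stages reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cnv as cnv_mod
from . import fragmentation, ml, pfe, qc, tfbs, tss
from .fragments import GenomeBins, SampleFragments, load_fragments, make_bins, read_chrom_sizes
from .synthetic import SimulatedCohort, default_config, simulate_cohort, write_cohort

ALL_STAGES = ("simulate", "qc", "fragmentation", "cnv", "tss", "pfe", "tfbs", "ml")

# key -> (section schema: key -> python type)
CONFIG_SCHEMA: dict[str, dict[str, type]] = {
    "seed": {"": int},
    "stages": {"": list},
    "simulate": {
        "n_cancer": int,
        "n_healthy": int,
        "n_hemolysis": int,
        "n_fragments": int,
        "n_genes": int,
        "bin_size": int,
    },
    "inputs": {
        "fragments_dir": str,
        "labels": str,
        "chrom_sizes": str,
        "gc_table": str,
        "tss": str,
        "tf_sites_dir": str,
    },
    "qc": {"hemolysis_threshold": float},
    "fragmentation": {
        "bin_size": int,
        "span": float,
        "short_range": list,
        "long_range": list,
    },
    "cnv": {"alpha": float},
    "tss": {"open_threshold": float, "closed_threshold": float, "freq_min": float},
    "pfe": {"window": int, "min_fragments": int, "pseudocount": float},
    "tfbs": {"window": int, "step": int},
    "ml": {"folds": int, "test_fraction": float},
}


def validate_config(config: dict) -> dict:
    """Validate a config mapping against the schema; every offending key is
    listed in one error. Returns the config with defaults applied."""
    errors = []
    for key, value in config.items():
        if key not in CONFIG_SCHEMA:
            errors.append(f"unknown section {key!r}")
            continue
        schema = CONFIG_SCHEMA[key]
        if "" in schema:  # scalar section
            want = schema[""]
            if not isinstance(value, want) or isinstance(value, bool):
                errors.append(f"{key}: expected {want.__name__}, got "
                              f"{type(value).__name__}")
            continue
        if not isinstance(value, dict):
            errors.append(f"{key}: expected a mapping")
            continue
        for sub, sv in value.items():
            if sub not in schema:
                errors.append(f"{key}.{sub}: unknown key")
            else:
                want = schema[sub]
                ok = isinstance(sv, want) or (want is float and isinstance(sv, int))
                if not ok or isinstance(sv, bool):
                    errors.append(
                        f"{key}.{sub}: expected {want.__name__}, got "
                        f"{type(sv).__name__}"
                    )
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = dict(config)
    out.setdefault("seed", 0)
    out.setdefault("stages", list(ALL_STAGES))
    bad_stages = [s for s in out["stages"] if s not in ALL_STAGES]
    if bad_stages:
        raise ValueError(f"invalid config: unknown stage(s) {bad_stages}")
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(config_subset: dict, input_checksums: dict[str, str]) -> str:
    payload = json.dumps(
        {"config": config_subset, "inputs": input_checksums},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class Manifest:
    """Run manifest: versioned record of config, inputs and stage outputs."""

    def __init__(self, out_dir: Path, config: dict):
        self.path = out_dir / "manifest.json"
        self.data = {
            "tool": "plasmafrag",
            "version": __version__,
            "config": config,
            "seed": config.get("seed", 0),
            "stages": {},
            "warnings": [],
        }
        self.previous = None
        if self.path.exists():
            with open(self.path) as fh:
                self.previous = json.load(fh)

    def stage_unchanged(self, name: str, key: str, out_dir: Path) -> bool:
        if not self.previous:
            return False
        prev = self.previous.get("stages", {}).get(name)
        if not prev or prev.get("key") != key:
            return False
        for rel, digest in prev.get("outputs", {}).items():
            p = out_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        # carry the verified record forward
        self.data["stages"][name] = {**prev, "skipped": True}
        return True

    def record(self, name: str, key: str, out_dir: Path, files: list[Path],
               runtime: float, skipped: bool = False) -> None:
        self.data["stages"][name] = {
            "key": key,
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)
            },
            "runtime_s": round(runtime, 3),
            "skipped": skipped,
        }

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True, default=str)

    def output_checksums(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for stage in self.data["stages"].values():
            out.update(stage.get("outputs", {}))
        return out


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# feature extraction over an in-memory cohort


def compute_feature_blocks(
    samples: dict[str, SampleFragments],
    bins: GenomeBins,
    labels: pd.Series,
    genes: pd.DataFrame | None = None,
    tf_sites: dict[str, pd.DataFrame] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    span: float = fragmentation.DEFAULT_LOWESS_SPAN,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Default per-modality summary blocks for the classifier.

    size_fractions: the five size-range fractions. fragment_ratio: per-bin
    normalized ratios + Pearson r to the healthy median. fragment_fraction:
    r to the healthy median fraction profile. cnv: per-sample score
    variance + mean |z| vs the healthy panel. tss: mean NDR relative
    coverage over the gene panel. pfe: mean promoter entropy over the
    panel. tf: central occupancy score per TF.

    Returns the blocks plus a dict of intermediate per-module results.
    """
    sids = list(samples)
    healthy_ids = [s for s in sids if labels.get(s) == "healthy"]
    if not healthy_ids:
        raise ValueError("cohort must contain healthy samples (reference panel)")

    fractions = {}
    for sid, sf in samples.items():
        fr = qc.size_fractions(qc.size_histogram(sf))
        fractions[sid] = dict(zip(qc.SIZE_RANGE_NAMES, fr.as_array()))
    block_sizes = pd.DataFrame(fractions).T

    profiles = {
        sid: fragmentation.build_profile(sf, bins, span=span)
        for sid, sf in samples.items()
    }
    sim_ratio = fragmentation.cohort_similarity(
        list(profiles.values()), healthy_ids, on="ratio"
    )
    sim_frac = fragmentation.cohort_similarity(
        list(profiles.values()), healthy_ids, on="fraction"
    )
    ratio_cols = pd.DataFrame(
        {sid: profiles[sid].vector("normalized_ratio") for sid in sids}
    ).T
    ratio_cols.columns = [f"bin_{i}" for i in range(ratio_cols.shape[1])]
    block_ratio = ratio_cols.copy()
    block_ratio["r_to_healthy_median"] = sim_ratio.r_to_reference
    block_fraction = pd.DataFrame(
        {"r_to_healthy_median": sim_frac.r_to_reference}
    )

    panel = np.stack([profiles[s].vector("fraction") for s in healthy_ids])
    cnv_profiles = {
        sid: cnv_mod.cnv_scores(profiles[sid].vector("fraction"), panel, sid)
        for sid in sids
    }
    block_cnv = pd.DataFrame(
        {
            sid: {
                "log2_variance": cnv_profiles[sid].variance,
                "mean_abs_z": float(
                    np.nanmean(np.abs(cnv_profiles[sid].z_score))
                ),
            }
            for sid in sids
        }
    ).T

    blocks = {
        "size_fractions": block_sizes,
        "fragment_ratio": block_ratio,
        "fragment_fraction": block_fraction,
        "cnv": block_cnv,
    }
    intermediates = {
        "profiles": profiles,
        "similarity_ratio": sim_ratio,
        "similarity_fraction": sim_frac,
        "cnv_profiles": cnv_profiles,
    }

    if genes is not None and len(genes):
        ann = tss.TSSAnnotation.from_frame(genes)
        ndr_cols, k2_cols, pfe_means = {}, {}, {}
        for sid, sf in samples.items():
            cov = tss.tss_relative_coverages(sf, ann, chrom_sizes)
            ndr_cols[sid] = cov.set_index("gene")["ndr_rc"]
            k2_cols[sid] = cov.set_index("gene")["k2_rc"]
            res = pfe.promoter_entropy(sf, ann)
            ent = pfe.pfe_frame(res)["entropy"]
            pfe_means[sid] = float(ent.mean()) if ent.notna().any() else np.nan
        ndr_table = pd.DataFrame(ndr_cols)
        k2_table = pd.DataFrame(k2_cols)
        blocks["tss"] = pd.DataFrame(
            {"mean_ndr_rc": ndr_table.mean(), "mean_k2_rc": k2_table.mean()}
        )
        blocks["pfe"] = pd.DataFrame({"mean_pfe": pd.Series(pfe_means)})
        intermediates["ndr_table"] = ndr_table
        intermediates["k2_table"] = k2_table

    if tf_sites:
        tf_order = list(tf_sites)
        rows = {}
        for sid, sf in samples.items():
            prof = {}
            for tf_name, sites in tf_sites.items():
                try:
                    prof[tf_name] = tfbs.composite_profile(
                        sf, sites, tf_name, chrom_sizes=chrom_sizes
                    )
                except ValueError:
                    prof[tf_name] = None
            rows[sid] = tfbs.tf_feature_vector(prof, tf_order)
        blocks["tf"] = pd.DataFrame(rows).T.add_prefix("central_")
    return blocks, intermediates


# ---------------------------------------------------------------------------
# staged run


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Manifest:
    """Execute the configured stages into ``out_dir`` and write a manifest.

    Stages whose config subset and inputs match the existing manifest (and
    whose outputs verify by checksum) are skipped.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, config)
    stages = config["stages"]
    seed = config["seed"]

    cohort: SimulatedCohort | None = None
    samples: dict[str, SampleFragments] = {}
    labels = pd.Series(dtype=object)
    bins: GenomeBins | None = None
    sizes: dict[str, int] | None = None
    genes: pd.DataFrame | None = None
    site_map: dict[str, pd.DataFrame] = {}
    input_checksums: dict[str, str] = {}

    def run_stage(name: str, cfg_subset: dict, fn) -> None:
        key = _stage_key(cfg_subset, input_checksums)
        stage_dir = out / name
        t0 = time.perf_counter()
        if manifest.stage_unchanged(name, key, out):
            return
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            files = fn(stage_dir)
        for w in caught:
            manifest.data["warnings"].append(f"{name}: {w.message}")
        manifest.record(name, key, out, files, time.perf_counter() - t0)

    # --- input acquisition -------------------------------------------------
    sim_cfg = config.get("simulate", {})
    if "inputs" not in config:
        overrides = {}
        if "n_fragments" in sim_cfg:
            overrides["n_fragments"] = sim_cfg["n_fragments"]
        if "bin_size" in sim_cfg:
            overrides["bin_size"] = sim_cfg["bin_size"]
        scfg = default_config(seed, **overrides)
        if "n_genes" in sim_cfg:
            scfg.genes.n_genes = sim_cfg["n_genes"]
        cohort = simulate_cohort(
            scfg,
            sim_cfg.get("n_cancer", 10),
            sim_cfg.get("n_healthy", 10),
            sim_cfg.get("n_hemolysis", 0),
        )
        samples, labels = cohort.samples, cohort.labels
        bins, sizes, genes = cohort.bins, dict(scfg.genome), cohort.genes
        site_map = cohort.tf_sites

        def _sim(stage_dir: Path) -> list[Path]:
            paths = write_cohort(cohort, stage_dir)
            return list(paths.values())

        if "simulate" in stages:
            run_stage("simulate", {"seed": seed, **sim_cfg}, _sim)
    else:
        inp = config["inputs"]
        for req in ("fragments_dir", "labels", "chrom_sizes"):
            if req not in inp:
                raise ValueError(f"stage io: missing required input {req!r}")
        frag_dir = Path(inp["fragments_dir"])
        if not frag_dir.is_dir():
            raise FileNotFoundError(f"stage io: {frag_dir} not found")
        sizes = read_chrom_sizes(inp["chrom_sizes"])
        gc = pd.read_csv(inp["gc_table"], sep="\t") if "gc_table" in inp else None
        bin_size = config.get("fragmentation", {}).get("bin_size", 5_000_000)
        bins = make_bins(sizes, bin_size, gc)
        lab = pd.read_csv(inp["labels"], sep="\t")
        labels = lab.set_index("sample_id")["label"]
        for sid in labels.index:
            path = frag_dir / f"{sid}.frag.bed"
            if not path.exists():
                raise FileNotFoundError(f"stage io: missing fragment file {path}")
            samples[sid] = load_fragments(path, sid)
            input_checksums[str(path)] = _sha256(path)
        if "tss" in inp:
            genes = pd.read_csv(inp["tss"], sep="\t")
        if "tf_sites_dir" in inp:
            for p in sorted(Path(inp["tf_sites_dir"]).glob("sites.*.bed")):
                site_map[p.stem.removeprefix("sites.")] = tfbs.read_sites(p)

    # --- qc ---------------------------------------------------------------
    if "qc" in stages:
        thr = config.get("qc", {}).get("hemolysis_threshold",
                                       qc.HEMOLYSIS_THRESHOLD)

        def _qc(stage_dir: Path) -> list[Path]:
            rows = []
            files = []
            for sid, sf in samples.items():
                rep = qc.qc_report(sf, sizes, thr)
                rows.append(qc.qc_report_frame(rep))
                files.append(
                    _write_tsv(rep.chromosome_table,
                               stage_dir / f"{sid}.chromosomes.tsv")
                )
                files.append(
                    _write_tsv(qc.size_histogram(sf).to_frame(),
                               stage_dir / f"{sid}.histogram.tsv")
                )
            files.append(
                _write_tsv(pd.concat(rows, ignore_index=True),
                           stage_dir / "qc_report.tsv")
            )
            return files

        run_stage("qc", {"threshold": thr, "seed": seed}, _qc)

    # --- features (fragmentation/cnv/tss/pfe/tfbs) ------------------------
    need_features = {"fragmentation", "cnv", "tss", "pfe", "tfbs", "ml"} & set(
        stages
    )
    blocks: dict[str, pd.DataFrame] = {}
    inter: dict = {}
    if need_features:
        span = config.get("fragmentation", {}).get(
            "span", fragmentation.DEFAULT_LOWESS_SPAN
        )
        blocks, inter = compute_feature_blocks(
            samples, bins, labels,
            genes if ("tss" in stages or "pfe" in stages or "ml" in stages) else None,
            site_map if ("tfbs" in stages or "ml" in stages) else None,
            sizes, span,
        )

    if "fragmentation" in stages:

        def _frag(stage_dir: Path) -> list[Path]:
            files = []
            for sid, prof in inter["profiles"].items():
                files.append(_write_tsv(prof.table, stage_dir / f"{sid}.profile.tsv"))
            files.append(
                _write_tsv(inter["similarity_ratio"].matrix,
                           stage_dir / "similarity_ratio.tsv", index=True)
            )
            files.append(
                _write_tsv(
                    inter["similarity_ratio"].r_to_reference.rename("r").to_frame(),
                    stage_dir / "r_to_healthy_median.tsv", index=True,
                )
            )
            return files

        run_stage("fragmentation", {"seed": seed,
                                    **config.get("fragmentation", {})}, _frag)

    if "cnv" in stages:
        alpha = config.get("cnv", {}).get("alpha", 0.05)

        def _cnv(stage_dir: Path) -> list[Path]:
            files = []
            prof_rows = []
            for sid, p in inter["cnv_profiles"].items():
                prof_rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sid,
                            "bin": np.arange(len(p.log2_ratio)),
                            "log2_ratio": p.log2_ratio,
                            "z_score": p.z_score,
                        }
                    )
                )
            files.append(
                _write_tsv(pd.concat(prof_rows, ignore_index=True),
                           stage_dir / "cnv_scores.tsv")
            )
            cancer = [p for s, p in inter["cnv_profiles"].items()
                      if labels[s] == "cancer"]
            healthy = [p for s, p in inter["cnv_profiles"].items()
                       if labels[s] == "healthy"]
            if cancer and healthy and genes is not None:
                gene_spans = pd.DataFrame(
                    {
                        "chrom": genes["chrom"],
                        "start": genes["tss"],
                        "end": genes["tss"] + 1,
                        "gene": genes["gene"],
                    }
                )
                gmap = cnv_mod.map_genes_to_bins(gene_spans, bins)
                calls = cnv_mod.call_amplified_genes(
                    cancer, healthy, gmap,
                    dict(zip(genes["gene"], genes["chrom"])), alpha,
                )
                files.append(
                    _write_tsv(cnv_mod.calls_frame(calls),
                               stage_dir / "gene_calls.tsv")
                )
                var = cnv_mod.cohort_variance_test(cancer, healthy)
                files.append(
                    _write_tsv(
                        pd.DataFrame(
                            [
                                {
                                    "cancer_median_variance":
                                        var["cancer_median_variance"],
                                    "healthy_median_variance":
                                        var["healthy_median_variance"],
                                    "p_value": var["p_value"],
                                }
                            ]
                        ),
                        stage_dir / "variance_test.tsv",
                    )
                )
            return files

        run_stage("cnv", {"alpha": alpha, "seed": seed}, _cnv)

    if "tss" in stages and "ndr_table" in inter:
        tcfg = config.get("tss", {})

        def _tss(stage_dir: Path) -> list[Path]:
            files = [
                _write_tsv(inter["ndr_table"], stage_dir / "ndr_rc.tsv", index=True),
                _write_tsv(inter["k2_table"], stage_dir / "k2_rc.tsv", index=True),
            ]
            calls = tss.classify_chromatin_state(
                inter["ndr_table"], inter["k2_table"],
                tcfg.get("open_threshold", tss.OPEN_THRESHOLD),
                tcfg.get("closed_threshold", tss.CLOSED_THRESHOLD),
                tcfg.get("freq_min", tss.FREQ_MIN),
            )
            files.append(
                _write_tsv(tss.calls_frame(calls), stage_dir / "state_calls.tsv")
            )
            return files

        run_stage("tss", {"seed": seed, **tcfg}, _tss)

    if "pfe" in stages and "pfe" in blocks:

        def _pfe(stage_dir: Path) -> list[Path]:
            return [_write_tsv(blocks["pfe"], stage_dir / "pfe_summary.tsv",
                               index=True)]

        run_stage("pfe", {"seed": seed, **config.get("pfe", {})}, _pfe)

    if "tfbs" in stages and "tf" in blocks:

        def _tfbs(stage_dir: Path) -> list[Path]:
            return [_write_tsv(blocks["tf"], stage_dir / "tf_scores.tsv",
                               index=True)]

        run_stage("tfbs", {"seed": seed, **config.get("tfbs", {})}, _tfbs)

    if "ml" in stages:
        mcfg = config.get("ml", {})
        # hemolysis samples are QC subjects, not classifier subjects
        clf_labels = labels[labels.isin(["cancer", "healthy"])]

        def _ml(stage_dir: Path) -> list[Path]:
            matrix = ml.assemble_features(
                {k: v.loc[[s for s in clf_labels.index if s in v.index]]
                 for k, v in blocks.items()},
                clf_labels,
            )
            report = ml.train_eval_sgd(
                matrix, mcfg.get("folds", 10), seed, mcfg.get("test_fraction", 0.3)
            )
            files = [
                _write_tsv(report.cv_roc, stage_dir / "roc_cv.tsv"),
                _write_tsv(report.test_roc, stage_dir / "roc_test.tsv"),
                _write_tsv(report.confusion, stage_dir / "confusion.tsv",
                           index=True),
                _write_tsv(
                    report.probabilities.rename("probability").to_frame(),
                    stage_dir / "probabilities.tsv", index=True,
                ),
                _write_tsv(
                    pd.DataFrame(
                        [
                            {
                                "cv_auc": report.cv_auc,
                                "train_auc": report.train_auc,
                                "test_auc": report.test_auc,
                                "n_folds": report.n_folds,
                            }
                        ]
                    ),
                    stage_dir / "auc.tsv",
                ),
            ]
            consistency = ml.per_modality_consistency(
                matrix, mcfg.get("folds", 10), seed
            )
            files.append(_write_tsv(consistency, stage_dir / "consistency.tsv",
                                    index=True))
            return files

        run_stage("ml", {"seed": seed, **mcfg}, _ml)

    manifest.save()
    return manifest
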