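"""End-to-end orchestration: simulate/load -> QC -> GRM/PCA -> Fst scan ->
stepwise QTL -> overlap, with a YAML config, stage logging and a manifest.

One run is fully determined by its config plus seed: the manifest records
parameter values, the seed, package versions and SHA-256 checksums of every
output file, so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .io import (
    TRAITS,
    GenotypeMatrix,
    qc_filter,
    read_sample_table,
    read_vcf,
    write_sample_table,
    write_vcf,
)
from .overlap import label_hits_with_features, overlap_qtl_windows
from .popgen import FstThresholds, top_quantile_loci, wc_fst_site, window_stats
from .qtl import VarianceComponents, stepwise_select
from .relationship import pca, vanraden_grm

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "simulate_to_dir"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage."""


class _StageStop(Exception):
    """Internal: truncate the run after the requested stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``vcf``/``samples`` paths or a ``simulate`` spec must be given.
    Thresholds default to the study's conventions: 1 Mb windows for
    signature calling (mean Fst > 0.05, q95 Fst > 0.25), 2 Mb windows for
    diversity reporting, 100 kb windows for the Manhattan export, top 1%
    per-SNP Fst outliers, and 5 kb allele-frequency flanks.
    """

    vcf: str | None = None
    samples: str | None = None
    simulate: dict | None = None
    traits: tuple[str, ...] = TRAITS
    min_call_rate: float = 0.8
    min_maf: float = 0.01
    window_bp: int = 1_000_000
    pi_window_bp: int = 2_000_000
    manhattan_window_bp: int = 100_000
    elevated_mean: float = 0.05
    elevated_q95: float = 0.25
    top_quantile: float = 0.01
    scan_alpha: float = 0.05
    min_distance_bp: int = 1_000_000
    max_qtl: int = 20
    flank_bp: int = 5000
    overlap_criterion: str = "elevated_q95"
    features: str | None = None
    n_pcs: int = 10
    seed: int = 0
    out_dir: str = "divergescan_run"

    def __post_init__(self):
        if self.vcf is None and self.simulate is None:
            raise ValueError("config needs either input paths or a simulate spec")
        if self.vcf is not None and self.samples is None:
            raise ValueError("a samples table must accompany the VCF")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        raw = dict(self.simulate or {})
        if "qtl_list" in raw:
            raw["qtl_list"] = tuple(tuple(q) for q in raw["qtl_list"])
        if "divergent_centers" in raw:
            raw["divergent_centers"] = tuple(raw["divergent_centers"])
        if "varcomp_true" in raw:
            raw["varcomp_true"] = VarianceComponents(**raw["varcomp_true"])
        raw.setdefault("seed", self.seed)
        return CohortSpec(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_to_dir(spec: CohortSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as VCF + samples TSV + phenotypes TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes, samples = simulate_cohort(spec)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_vcf(genotypes, paths["vcf"])
    write_sample_table(samples[list(samples.columns[:5])], paths["samples"])
    write_sample_table(samples[["sample_id", *TRAITS]], paths["phenotypes"])
    return paths


def _load_inputs(config: RunConfig, out: Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    if config.simulate is not None or config.vcf is None:
        spec = config.cohort_spec()
        genotypes, samples = simulate_cohort(spec)
        sim_dir = out / "simulated_input"
        sim_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(genotypes, sim_dir / "genotypes.vcf")
        write_sample_table(samples, sim_dir / "cohort.tsv")
        return genotypes, samples
    genotypes = read_vcf(config.vcf)
    samples = read_sample_table(config.samples)
    return genotypes, samples


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Execute every stage for each trait; returns the run manifest.

    Identical config + seed give identical output checksums. Any stage
    failure raises :class:`PipelineError` naming the stage, after writing a
    partial manifest. ``stop_after`` ("popgen_scan" or "qtl_scan") truncates
    the run after that stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "stages": {},
        "outputs": {},
    }
    stage = "load"
    try:
        genotypes, samples = _load_inputs(config, out)
        manifest["stages"]["load"] = {
            "n_samples": genotypes.n_samples, "n_markers": genotypes.n_markers
        }

        stage = "qc"
        genotypes, report = qc_filter(
            genotypes, min_call_rate=config.min_call_rate, min_maf=config.min_maf
        )
        manifest["stages"]["qc"] = report._asdict()

        stage = "relationship"
        grm = vanraden_grm(genotypes)
        grm.to_frame().to_csv(out / "grm.tsv", sep="\t")
        pca_res = pca(genotypes, n_components=config.n_pcs)
        scores = pca_res.to_frame()
        scores["line"] = samples.set_index("sample_id").loc[
            genotypes.samples, "line"
        ].to_numpy()
        scores.rename_axis("sample_id").to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["stages"]["relationship"] = {
            "grm_markers": grm.n_markers,
            "pc1_variance": float(pca_res.proportion_variance[0])
            if len(pca_res.proportion_variance)
            else 0.0,
        }

        stage = "popgen_scan"
        sites = wc_fst_site(genotypes, samples)
        sites.rename_axis("marker_id").to_csv(out / "fst_sites.tsv", sep="\t")
        thr = FstThresholds(mean=config.elevated_mean, q95=config.elevated_q95)
        windows = window_stats(sites, config.window_bp, thr)
        windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        pi_windows = window_stats(sites, config.pi_window_bp, thr)
        pi_windows[["chrom", "start", "end", "n_snps", "pi_sel", "pi_con"]].to_csv(
            out / "pi_windows.tsv", sep="\t", index=False
        )
        window_stats(sites, config.manhattan_window_bp, thr).to_csv(
            out / "fst_manhattan.tsv", sep="\t", index=False
        )
        top = top_quantile_loci(sites, quantile=config.top_quantile)
        top.rename_axis("marker_id").to_csv(out / "selection_loci.tsv", sep="\t")
        elevated = windows[windows["elevated_mean"] | windows["elevated_q95"]]
        with open(out / "elevated_windows.bed", "w") as fh:
            for _, w in elevated.iterrows():
                fh.write(f"{w['chrom']}\t{w['start'] - 1}\t{w['end'] - 1}\n")
        manifest["stages"]["popgen_scan"] = {
            "n_windows": len(windows),
            "n_elevated_q95": int(windows["elevated_q95"].sum()),
            "n_elevated_mean": int(windows["elevated_mean"].sum()),
            "n_top_loci": len(top),
            "fst_threshold": float(top["threshold"].iloc[0]),
        }
        if stop_after == "popgen_scan":
            raise _StageStop

        stage = "qtl_scan"
        all_hits = []
        varcomp_rows = []
        gebv_frames = []
        avail = [t for t in config.traits if t in samples.columns]
        for trait in avail:
            hits, fit = stepwise_select(
                genotypes, samples, trait, grm,
                alpha=config.scan_alpha,
                min_distance_bp=config.min_distance_bp,
                max_qtl=config.max_qtl,
            )
            all_hits.extend(hits)
            v = fit.varcomp
            varcomp_rows.append(
                {
                    "trait": trait, "cage_variance": v.cage,
                    "polygenic_variance": v.polygenic,
                    "qtl_variance": v.qtl, "error_variance": v.residual,
                    "total_genetic_variance": v.qtl + v.polygenic,
                    "h2": fit.h2,
                    "vq_vg": v.qtl / (v.qtl + v.polygenic)
                    if (v.qtl + v.polygenic) > 0
                    else np.nan,
                }
            )
            gebv_frames.append(
                pd.DataFrame(
                    {"sample_id": fit.sample_ids, "trait": trait, "gebv": fit.gebv}
                )
            )
        pd.DataFrame(
            [
                {
                    "trait": h.trait, "marker_id": h.marker_id, "chrom": h.chrom,
                    "pos": h.pos, "effect": h.effect, "stat": h.stat,
                    "pvalue": h.pvalue, "cp": h.cp,
                }
                for h in all_hits
            ],
            columns=["trait", "marker_id", "chrom", "pos", "effect", "stat",
                     "pvalue", "cp"],
        ).to_csv(out / "qtl_hits.tsv", sep="\t", index=False)
        pd.DataFrame(varcomp_rows).to_csv(
            out / "variance_components.tsv", sep="\t", index=False
        )
        pd.concat(gebv_frames, ignore_index=True).to_csv(
            out / "gebv.tsv", sep="\t", index=False
        ) if gebv_frames else None
        manifest["stages"]["qtl_scan"] = {"n_qtl": len(all_hits), "traits": avail}
        if stop_after == "qtl_scan":
            raise _StageStop

        stage = "overlap"
        hits = overlap_qtl_windows(
            all_hits, windows, criterion=config.overlap_criterion,
            top_loci=top if config.overlap_criterion == "top_quantile" else None,
        )
        if config.features:
            from .overlap import read_feature_intervals

            features = read_feature_intervals(config.features)
        else:
            features = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        ov_table = label_hits_with_features(hits, features)
        ov_table.to_csv(out / "overlap_hits.tsv", sep="\t", index=False)
        for h in hits:
            from .overlap import flank_allele_frequencies

            rep = flank_allele_frequencies(
                genotypes, samples, (h.chrom, h.pos, h.pos), flank_bp=config.flank_bp
            )
            rep.to_csv(
                out / f"flank_{h.trait}_{h.chrom}_{h.pos}.tsv", sep="\t", index=False
            )
        manifest["stages"]["overlap"] = {"n_overlap_hits": len(hits)}
    except _StageStop:
        pass
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    return manifest
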