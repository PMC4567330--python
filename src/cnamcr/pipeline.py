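"""Pipeline configuration and the end-to-end driver.

`run_pipeline` executes simulate/ingest -> normalize -> segment -> common
aberrations -> CNAR/MCR region extraction, writing every stage's tables and
a machine-readable run manifest into the output directory.  MLPA,
expression, and clinical stages run when configured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from . import synthetic
from .clinical import lauren_association
from .common_regions import detect_common
from .expression import fold_change_table, stratified_expression_table
from .mlpa import call_mlpa_profile
from .normalization import centralize, estimate_probe_noise, lowess_correct, quantile_normalize
from .regions import amplification_deletion_regions, build_cnar, build_mcr, recurrence_table
from .segmentation import aberration_summary, detect_aberrations, filter_and_classify, fuzzy_zero_filter
from .synthetic import DEFAULT_PLATFORM_SIZES

log = logging.getLogger("cnamcr")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and switches of the pipeline, with the study defaults."""

    seed: int = 0
    # synthetic cohort
    n_samples_per_platform: dict = field(
        default_factory=lambda: {"acgh-400k": 30, "acgh-244k": 10, "acgh-60k": 48}
    )
    platform_sizes: dict = field(default_factory=lambda: dict(DEFAULT_PLATFORM_SIZES))
    noise_sd: float = 0.15
    curvature: float = 0.2
    offset_sd: float = 0.1
    # normalization
    skip_lowess: bool = False
    lowess_span: float = 0.3
    kde_bandwidth: float | None = None
    # segmentation
    threshold: float = 6.0
    min_probes: int = 3
    min_abs_mean: float = 0.25
    amp_cut: float = 0.8
    fuzzy_nu: float | None = None  # None: robust SD of centralization offsets
    method: str = "exact"
    # common aberrations / regions
    alpha: float = 0.05
    overlap: float = 0.9
    recurrence_exclusive: float = 0.20
    recurrence_inclusive: float = 0.10
    # optional stages
    run_mlpa: bool = False
    run_expression: bool = False
    run_clinical: bool = False
    make_plots: bool = False

    def validate(self) -> None:
        checks = [
            (self.threshold > 0, "threshold must be > 0"),
            (self.min_probes >= 1, "min_probes must be >= 1"),
            (self.min_abs_mean > 0, "min_abs_mean must be > 0"),
            (self.amp_cut > 0, "amp_cut must be > 0"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (0 < self.overlap <= 1, "overlap must lie in (0, 1]"),
            (0 <= self.recurrence_exclusive <= 1, "recurrence threshold must lie in [0, 1]"),
            (0 <= self.recurrence_inclusive <= 1, "recurrence threshold must lie in [0, 1]"),
            (0 < self.lowess_span <= 1, "lowess span must lie in (0, 1]"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.method in ("exact", "fast"), "method must be exact|fast"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _normalize_all(profiles, cfg):
    by_platform: dict[str, list] = {}
    for p in profiles:
        by_platform.setdefault(p.platform_id, []).append(p)
    out = []
    for plat, group in by_platform.items():
        if not cfg.skip_lowess:
            group = [lowess_correct(p, span=cfg.lowess_span) for p in group]
        if len(group) >= 2:
            group = quantile_normalize(group)
        group = [centralize(p, bandwidth=cfg.kde_bandwidth) for p in group]
        out.extend(group)
    return out


def segment_cohort(profiles, cfg: "PipelineConfig"):
    """Segment every profile: detect, fuzzy-zero filter, classify.

    The fuzzy-zero nu defaults to the robust (MAD-based) SD of the
    per-array centralization offsets across the cohort."""
    sigmas = {p.sample_id: estimate_probe_noise(p) for p in profiles}
    if cfg.fuzzy_nu is None:
        offs = np.array([p.state.get("offset", 0.0) for p in profiles])
        nu = float(1.4826 * np.median(np.abs(offs - np.median(offs)))) if len(offs) > 1 else 0.0
    else:
        nu = cfg.fuzzy_nu
    calls_by_sample = {}
    for p in profiles:
        segs = detect_aberrations(p, threshold=cfg.threshold, sigma=sigmas[p.sample_id],
                                  method=cfg.method)
        segs = fuzzy_zero_filter(segs, nu=nu, sigma=sigmas[p.sample_id], threshold=cfg.threshold)
        calls_by_sample[p.sample_id] = filter_and_classify(
            segs, min_probes=cfg.min_probes, min_abs_mean=cfg.min_abs_mean, amp_cut=cfg.amp_cut
        )
    return calls_by_sample, nu


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run the synthetic end-to-end analysis; returns the output directory."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        genome = synthetic.default_genome()
        designs = [
            synthetic.make_platform_design(pid, genome, n, seed=cfg.seed + 1 + i)
            for i, (pid, n) in enumerate(sorted(cfg.platform_sizes.items()))
        ]
        catalog = synthetic.default_catalog()
        profiles, truth = synthetic.simulate_cohort(
            designs, catalog, cfg.n_samples_per_platform,
            noise_sd=cfg.noise_sd, curvature=cfg.curvature, offset_sd=cfg.offset_sd,
            seed=cfg.seed,
        )
        truth.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        cio.write_truth(truth, outdir / "truth.json", outdir / "truth_carriers.tsv")

        stage("normalize")
        profiles = _normalize_all(profiles, cfg)

        stage("segment")
        calls_by_sample, nu = segment_cohort(profiles, cfg)
        manifest["fuzzy_nu"] = nu
        all_calls = [c for cs in calls_by_sample.values() for c in cs]
        cio.write_seg(all_calls, outdir / "calls.seg")
        summary = aberration_summary(calls_by_sample)
        summary["per_sample"].to_csv(outdir / "aberration_summary.tsv", sep="\t", index=False)

        if cfg.make_plots:
            stage("plots")
            from .plots import plot_frequency, plot_length_density

            main_design = max(designs, key=lambda d: d.n_probes)
            sub = {s: cs for s, cs in calls_by_sample.items()
                   if truth.platform_of[s] == main_design.platform_id}
            plot_frequency(sub, main_design, outdir / "frequency.png")
            plot_length_density(all_calls, outdir / "length_density.png")

        stage("common")
        design_of = {d.platform_id: d for d in designs}
        commons = []
        for plat, design in design_of.items():
            sub = {s: calls_by_sample[s] for s in calls_by_sample if truth.platform_of[s] == plat}
            if not sub:
                continue
            for direction in ("gain", "loss"):
                commons.extend(
                    detect_common(sub, design, direction, alpha=cfg.alpha, overlap=cfg.overlap)
                )
        with open(outdir / "common_aberrations.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tdirection\tn_support\tp_min\n")
            for c in commons:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.direction}\t{c.n_support}\t{c.p_min:.3g}\n")

        stage("regions")
        n_cohort = len(calls_by_sample)
        n_by_platform = {
            plat: sum(1 for s in calls_by_sample if truth.platform_of[s] == plat)
            for plat in design_of
        }
        calls_by_platform = {
            plat: [c for s, cs in calls_by_sample.items() if truth.platform_of[s] == plat for c in cs]
            for plat in design_of
        }
        cnars_by_platform = {}
        for plat, cs in calls_by_platform.items():
            cnars_by_platform[plat] = [
                r
                for direction in ("gain", "loss")
                for r in build_cnar(cs, direction, n_cohort, overlap_threshold=cfg.overlap)
            ]
        mcrs = build_mcr(cnars_by_platform, n_cohort, n_by_platform=n_by_platform)
        recurrent = recurrence_table(mcrs, n_cohort, min_freq=cfg.recurrence_exclusive,
                                     inclusive=False)
        recurrent.to_csv(outdir / "recurrent_mcrs.tsv", sep="\t", index=False)
        cio.write_regions_bed(mcrs, outdir / "mcrs.bed")
        ampdel = amplification_deletion_regions(
            calls_by_platform, n_cohort, cutoff=cfg.amp_cut,
            min_freq=cfg.recurrence_inclusive, overlap_threshold=cfg.overlap,
            n_by_platform=n_by_platform,
        )
        ampdel.to_csv(outdir / "amplification_deletion.tsv", sep="\t", index=False)

        if cfg.run_mlpa:
            stage("mlpa")
            from .types import GeneModel

            genes = [GeneModel(ev.name, ev.chrom, ev.start, ev.end) for ev in catalog]
            mlpa_profiles = synthetic.simulate_mlpa(truth, genes, seed=cfg.seed + 101)
            cio.write_mlpa_table(mlpa_profiles, outdir / "mlpa_peaks.tsv")
            refs = [p for p in mlpa_profiles if p.tissue == "normal"]
            calls = [
                call_mlpa_profile(p, refs) for p in mlpa_profiles if p.tissue == "tumor"
            ]
            import pandas as pd

            pd.concat(calls, ignore_index=True).to_csv(outdir / "mlpa_calls.tsv", sep="\t", index=False)
        else:
            manifest["stages"].append("mlpa:skipped")

        if cfg.run_expression:
            stage("expression")
            genes = [(ev.name, ev.chrom, ev.start, ev.end, 1.0) for ev in catalog]
            ct = synthetic.simulate_expression(truth, genes, noise_sd=0.3, seed=cfg.seed + 202)
            ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
            fc = fold_change_table(ct)
            fc.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
        else:
            manifest["stages"].append("expression:skipped")

        if cfg.run_clinical:
            stage("clinical")
            status = {
                ev.name: {s: (ev in truth.carriers[s]) for s in calls_by_sample}
                for ev in catalog
            }
            types = dict(zip(truth.clinical["sample_id"], truth.clinical["lauren_type"]))
            lauren_association(status, types).to_csv(
                outdir / "lauren_association.tsv", sep="\t", index=False
            )
        else:
            manifest["stages"].append("clinical:skipped")

        manifest["n_cohort"] = n_cohort
        manifest["summary"] = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in summary.items()
            if k != "per_sample"
        }
    except Exception as exc:  # partial outputs stay on disk for inspection
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
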