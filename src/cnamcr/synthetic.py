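"""Synthetic multi-platform aCGH cohort generator with known ground truth.

Emulates the structure of a two-channel aCGH study of gastric tumors: three
array platforms of different probe density over a shared genome, planted
gain/loss segments whose prevalence differs between Lauren histological
types, probe noise with intensity-dependent curvature (the target of lowess
correction), an array-level baseline offset (the target of centralization),
matched qPCR expression with configurable gene-dosage coupling, MLPA peak
tables, and clinical covariates.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ArrayProfile, CohortTruth, GeneModel, MLPAProfile, PlantedAberration, ProbeDesign

__all__ = [
    "default_genome",
    "default_catalog",
    "make_platform_design",
    "simulate_cohort",
    "simulate_expression",
    "simulate_mlpa",
]

#: Desk-scale mini-genome: three autosomes of 10 Mb each.  Sex chromosomes
#: are excluded by default — the frequency analyses this package supports are
#: autosome-focused and diploid throughout.
DEFAULT_GENOME: dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}

#: Default platform probe counts, mirroring the three-density structure of a
#: 400K / 244K / custom 60K platform trio at desk scale.
DEFAULT_PLATFORM_SIZES: dict[str, int] = {
    "acgh-400k": 10_000,
    "acgh-244k": 5_000,
    "acgh-60k": 1_500,
}

#: Lauren-type mix matching a cohort of 43 diffuse / 41 intestinal / 4 mixed.
LAUREN_PROBS: dict[str, float] = {"diffuse": 43 / 88, "intestinal": 41 / 88, "mixed": 4 / 88}


def default_genome() -> dict[str, int]:
    return dict(DEFAULT_GENOME)


def default_catalog() -> list[PlantedAberration]:
    """A catalog of planted events echoing the study's qualitative findings:
    gains are more prevalent in intestinal-type tumors, losses are shorter
    than gains, and one high-amplitude event exceeds the ±0.8 class cut."""
    return [
        PlantedAberration("gain_8q24_like", "chr1", 2_000_000, 2_600_000, "gain", 0.8,
                          {"intestinal": 0.45, "diffuse": 0.20, "mixed": 0.30}),
        PlantedAberration("gain_20q_like", "chr2", 5_000_000, 5_500_000, "gain", 0.6,
                          {"intestinal": 0.40, "diffuse": 0.18, "mixed": 0.30}),
        PlantedAberration("amp_focal", "chr3", 1_000_000, 1_200_000, "gain", 1.2,
                          {"intestinal": 0.15, "diffuse": 0.08, "mixed": 0.10}),
        PlantedAberration("loss_3p14_like", "chr1", 7_000_000, 7_250_000, "loss", -0.7,
                          {"intestinal": 0.35, "diffuse": 0.40, "mixed": 0.35}),
        PlantedAberration("loss_17p_like", "chr3", 8_000_000, 8_150_000, "loss", -0.6,
                          {"intestinal": 0.20, "diffuse": 0.25, "mixed": 0.20}),
    ]


def make_platform_design(
    platform_id: str,
    genome: dict[str, int] | list[tuple[str, int]],
    n_probes: int,
    seed: int,
    grid: bool = False,
    probe_length: int = 60,
) -> ProbeDesign:
    """Lay out ``n_probes`` probes over ``genome``.

    Probes are apportioned to chromosomes proportionally to length (largest
    remainder) and placed either uniformly at random without replacement
    (default) or on a regular grid (``grid=True``).  Deterministic under a
    fixed seed.
    """
    if isinstance(genome, list):
        genome = dict(genome)
    if not genome:
        raise ValueError("genome must be non-empty")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)

    total = sum(genome.values())
    chroms = sorted(genome)
    quotas = {c: n_probes * genome[c] / total for c in chroms}
    counts = {c: int(np.floor(quotas[c])) for c in chroms}
    short = n_probes - sum(counts.values())
    for c in sorted(chroms, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    chrom_col, start_col, end_col = [], [], []
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        length = genome[c]
        span = max(probe_length, 1)
        n_positions = max(length - span + 1, 0)
        if k > n_positions:
            raise ValueError(
                f"cannot place {k} distinct probes on chromosome {c!r} "
                f"(only {n_positions} positions)"
            )
        if grid:
            starts = (np.arange(k) * (length // k)).astype(np.int64)
        else:
            starts = np.sort(rng.choice(n_positions, size=k, replace=False)).astype(np.int64)
        ends = np.minimum(starts + span, length)
        chrom_col.extend([c] * k)
        start_col.append(starts)
        end_col.append(ends)

    return ProbeDesign(
        platform_id=platform_id,
        chrom=np.array(chrom_col, dtype=object),
        start=np.concatenate(start_col),
        end=np.concatenate(end_col),
        genome=dict(genome),
    )


def _true_signal(design: ProbeDesign, events: list[PlantedAberration]) -> np.ndarray:
    """Per-probe planted log2 signal: overlapping events add."""
    sig = np.zeros(design.n_probes)
    for ev in events:
        mask = (design.chrom == ev.chrom) & (design.start >= ev.start) & (design.start < ev.end)
        sig[mask] += ev.true_log2
    return sig


def _draw_clinical(sample_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    types = rng.choice(list(LAUREN_PROBS), size=len(sample_ids), p=list(LAUREN_PROBS.values()))
    ages = np.clip(rng.normal(60.0, 11.0, size=len(sample_ids)), 28, 90).round(1)
    # overall survival in months, administratively censored at 80 months
    raw = rng.exponential(scale=55.0, size=len(sample_ids))
    time = np.minimum(raw, 80.0)
    event = (raw <= 80.0).astype(int)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lauren_type": types,
            "age": ages,
            "survival_time": np.maximum(time, 0.1).round(2),
            "event": event,
        }
    )


def simulate_cohort(
    designs: list[ProbeDesign],
    catalog: list[PlantedAberration],
    n_samples_per_platform: dict[str, int] | int,
    noise_sd: float = 0.15,
    curvature: float = 0.0,
    offset_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ArrayProfile], CohortTruth]:
    """Simulate tumor/normal log2-ratio profiles on each platform.

    Per-probe model::

        log2 = sum of carried true_log2 over covering events
             + array offset ~ Normal(0, offset_sd)
             + curvature * f(intensity covariate)        (zero-mean quadratic)
             + Normal(0, noise_sd)

    The intensity covariate is log10 of a lognormal channel intensity; ``f``
    is the centered quadratic in that covariate, which gives the within-array
    lowess correction something real to remove.  Carrier status is drawn per
    sample according to the catalog prevalence for the sample's Lauren type.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(n_samples_per_platform, int):
        n_samples_per_platform = {d.platform_id: n_samples_per_platform for d in designs}
    n_total = sum(n_samples_per_platform.get(d.platform_id, 0) for d in designs)
    if n_total == 0 and not catalog:
        raise ValueError("nothing to simulate: empty catalog and zero samples")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    platform_of: dict[str, str] = {}
    for d in designs:
        for i in range(n_samples_per_platform.get(d.platform_id, 0)):
            sid = f"{d.platform_id}_s{i:03d}"
            sample_ids.append(sid)
            platform_of[sid] = d.platform_id

    clinical = _draw_clinical(sample_ids, rng)
    type_of = dict(zip(clinical["sample_id"], clinical["lauren_type"]))

    profiles: list[ArrayProfile] = []
    carriers: dict[str, list[PlantedAberration]] = {}
    offsets: dict[str, float] = {}
    design_of = {d.platform_id: d for d in designs}

    for sid in sample_ids:
        design = design_of[platform_of[sid]]
        ltype = type_of[sid]
        carried = [
            ev
            for ev in catalog
            if rng.random() < ev.prevalence_by_type.get(
                ltype, float(np.mean(list(ev.prevalence_by_type.values())))
            )
        ]
        carriers[sid] = carried
        offset = float(rng.normal(0.0, offset_sd)) if offset_sd > 0 else 0.0
        offsets[sid] = offset

        signal = _true_signal(design, carried)
        # channel intensity: lognormal around ~1000 counts; covariate is log10
        intensity = rng.lognormal(mean=np.log(1000.0), sigma=0.5, size=design.n_probes)
        x = np.log10(intensity)
        xc = x - x.mean()
        f = xc**2 - np.mean(xc**2)
        noise = rng.normal(0.0, noise_sd, size=design.n_probes) if noise_sd > 0 else 0.0
        log2 = signal + offset + curvature * f + noise
        profiles.append(
            ArrayProfile(sample_id=sid, design=design, log2=log2, tissue="tumor", intensity=x)
        )

    truth = CohortTruth(
        carriers=carriers,
        offsets=offsets,
        clinical=clinical,
        catalog=list(catalog),
        platform_of=platform_of,
    )
    return profiles, truth


def _gene_dosage(truth: CohortTruth, sid: str, gene: GeneModel) -> float:
    """True log2 dosage of a gene in a sample (sum of covering events)."""
    total = 0.0
    for ev in truth.carriers.get(sid, []):
        if ev.chrom == gene.chrom and ev.start < gene.end and gene.start < ev.end:
            total += ev.true_log2
    return total


def simulate_expression(
    truth: CohortTruth,
    genes: list[tuple[str, str, int, int, float]] | list[tuple[GeneModel, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_shift: float = 0.0,
    genome: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Generate a qPCR Ct table whose expected log2 fold change per
    (sample, gene) is ``beta * true_dosage + baseline_shift``.

    ``genes`` is a list of ``(name, chrom, start, end, beta)`` tuples where
    ``beta`` is the gene-dosage coupling exponent; ``beta = 0`` genes are
    dosage-decoupled.  Columns follow the Ct input contract:
    sample_id, gene, ct_t, ct_n, ref_ct_t, ref_ct_n.
    """
    rng = np.random.default_rng(seed)
    parsed: list[tuple[GeneModel, float]] = []
    for g in genes:
        if isinstance(g[0], GeneModel):
            parsed.append((g[0], float(g[1])))
        else:
            name, chrom, start, end, beta = g
            parsed.append((GeneModel(name, chrom, int(start), int(end)), float(beta)))
    if genome:
        for gm, _ in parsed:
            if gm.chrom not in genome or gm.end > genome[gm.chrom]:
                raise ValueError(f"gene {gm.name} lies outside the genome")
    for _, beta in parsed:
        if not np.isfinite(beta):
            raise ValueError("coupling exponent beta must be finite")

    rows = []
    for sid in truth.carriers:
        ref_t = 20.0 + float(rng.normal(0, noise_sd)) if noise_sd > 0 else 20.0
        ref_n = 20.0 + float(rng.normal(0, noise_sd)) if noise_sd > 0 else 20.0
        for gm, beta in parsed:
            dosage = _gene_dosage(truth, sid, gm)
            log2_fc = beta * dosage + baseline_shift
            ct_n = 25.0 + (float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0)
            eps = float(rng.normal(0, noise_sd)) if noise_sd > 0 else 0.0
            # ΔΔCt = (ct_t - ref_t) - (ct_n - ref_n) = -log2 FC
            ct_t = ct_n + (ref_t - ref_n) - log2_fc + eps
            rows.append((sid, gm.name, ct_t, ct_n, ref_t, ref_n))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct_t", "ct_n", "ref_ct_t", "ref_ct_n"])


def simulate_mlpa(
    truth: CohortTruth,
    genes: list[GeneModel],
    n_controls: int = 14,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> list[MLPAProfile]:
    """Generate tumor and matched-normal MLPA peak-height profiles.

    Tumor peak heights at a gene probe scale as ``2**true_log2`` of the
    gene's planted dosage; normals are copy-neutral.  Control probes are
    dosage-independent.  A global per-sample scale factor emulates input-DNA
    variation (removed by population normalization)."""
    rng = np.random.default_rng(seed)
    probes = [f"ctrl_{i:02d}" for i in range(n_controls)] + [g.name for g in genes]
    gene_names = [""] * n_controls + [g.name for g in genes]
    is_control = np.array([True] * n_controls + [False] * len(genes))
    base = np.concatenate([rng.uniform(800, 1200, n_controls), rng.uniform(800, 1200, len(genes))])

    out: list[MLPAProfile] = []
    for sid in truth.carriers:
        for tissue in ("normal", "tumor"):
            scale = float(rng.uniform(0.7, 1.3))
            h = base.copy()
            if tissue == "tumor":
                for k, g in enumerate(genes):
                    h[n_controls + k] *= 2.0 ** _gene_dosage(truth, sid, g)
            h = h * scale * (1.0 + rng.normal(0, noise_cv, size=len(h)))
            out.append(
                MLPAProfile(
                    sample_id=sid,
                    tissue=tissue,
                    probe=np.array(probes, dtype=object),
                    gene=np.array(gene_names, dtype=object),
                    height=np.maximum(h, 0.0),
                    is_control=is_control,
                )
            )
    return out
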