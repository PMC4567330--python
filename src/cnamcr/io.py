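"""Readers and writers for the pipeline's plain-text formats.

Probe tables are TSV with header ``probe_id, chrom, start, end, log2_ratio
[, intensity]``; segment calls are written as SEG (sample, chrom, start,
end, n_probes, seg.mean) and regions as BED6 with the frequency percentage
in the score column.  All coordinates are 0-based half-open.

Real two-channel array exports are not parsed natively; convert them to the
probe-table contract above (one file per sample, log2 tumor/normal ratio
per probe, optional raw-channel intensity as log10) with any column-mapping
tool before ingestion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ArrayProfile, CNACall, GeneModel, MLPAProfile, ProbeDesign, RecurrentRegion

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_seg",
    "read_seg",
    "write_regions_bed",
    "read_gene_models",
    "read_mlpa_table",
    "write_mlpa_table",
    "read_clinical",
    "write_truth",
]

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "log2_ratio"]


def read_probe_table(
    path, platform_id: str | None = None, sample_id: str | None = None, sort: bool = False
) -> tuple[ProbeDesign, ArrayProfile]:
    """Read one sample's probe-level TSV into a design + profile pair.

    Malformed numeric fields are reported with their 1-based file line
    number; duplicate probe ids and unsorted rows (without ``sort=True``)
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("start", "end", "log2_ratio", "intensity"):
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ValueError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
        df[col] = converted
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    keys = list(zip(df["chrom"], df["start"]))
    if keys != sorted(keys):
        if not sort:
            raise ValueError(f"{path}: rows not sorted by (chrom, start); pass sort=True/--sort")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    genome = {c: int(g["end"].max()) for c, g in df.groupby("chrom")}
    design = ProbeDesign(
        platform_id=platform_id or path.stem,
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        genome=genome,
        probe_id=df["probe_id"].to_numpy(dtype=object),
    )
    intensity = df["intensity"].to_numpy(dtype=float) if "intensity" in df.columns else None
    profile = ArrayProfile(
        sample_id=sample_id or path.stem,
        design=design,
        log2=df["log2_ratio"].to_numpy(dtype=float),
        intensity=intensity,
    )
    return design, profile


def write_probe_table(profile: ArrayProfile, path) -> None:
    d = profile.design
    df = pd.DataFrame(
        {
            "probe_id": d.probe_id,
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "log2_ratio": profile.log2,
        }
    )
    if profile.intensity is not None:
        df["intensity"] = profile.intensity
    df.to_csv(path, sep="\t", index=False)


def write_seg(calls: list[CNACall], path) -> None:
    """SEG format: sample, chrom, loc.start, loc.end, num.mark, seg.mean."""
    rows = [
        (c.sample_id, c.chrom, c.start, c.end, c.n_probes, f"{c.mean_log2:.6g}")
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: SEG header must be {expected}")
    return df


def write_regions_bed(regions: list[RecurrentRegion], path) -> None:
    """BED6; the score column carries the frequency as a percentage with
    two decimals (e.g. 0.4318 -> "43.18")."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in regions:
            name = f"{r.kind}_{r.direction}_{r.chrom}_{r.start}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{100 * r.frequency:.2f}\t.\n"
            )


def write_segments_bed(segments, path) -> None:
    """BED6 for per-sample segments with the interval score in the score
    column."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample_id}\t{s.score:.2f}\t.\n")


def read_gene_models(path) -> list[GeneModel]:
    """Genes from a BED-like TSV: chrom, start, end, name (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name"], dtype=str)
    if df.iloc[0]["start"] == "start":  # header row present
        df = df.iloc[1:]
    return [
        GeneModel(str(r["name"]), str(r["chrom"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_mlpa_table(profiles: list[MLPAProfile], path) -> None:
    rows = []
    for p in profiles:
        for probe, gene, h, ctrl in zip(p.probe, p.gene, p.height, p.is_control):
            rows.append((p.sample_id, p.tissue, probe, gene, f"{h:.6g}", int(ctrl)))
    pd.DataFrame(
        rows, columns=["sample_id", "tissue", "probe", "gene", "height", "is_control"]
    ).to_csv(path, sep="\t", index=False)


def read_mlpa_table(path) -> list[MLPAProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=False)
    out = []
    for (sid, tissue), g in df.groupby(["sample_id", "tissue"], sort=True):
        out.append(
            MLPAProfile(
                sample_id=sid,
                tissue=tissue,
                probe=g["probe"].to_numpy(dtype=object),
                gene=g["gene"].to_numpy(dtype=object),
                height=g["height"].to_numpy(dtype=float),
                is_control=g["is_control"].to_numpy(dtype=bool),
            )
        )
    return out


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "lauren_type", "age", "survival_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return df


def write_truth(truth, path_json, path_tsv) -> None:
    """Ground truth as a JSON catalog plus a per-sample carrier TSV."""
    catalog = [
        {
            "name": ev.name, "chrom": ev.chrom, "start": ev.start, "end": ev.end,
            "direction": ev.direction, "true_log2": ev.true_log2,
            "prevalence_by_type": ev.prevalence_by_type,
        }
        for ev in truth.catalog
    ]
    with open(path_json, "w") as fh:
        json.dump({"catalog": catalog, "offsets": truth.offsets}, fh, indent=2)
    rows = [
        (sid, ev.name)
        for sid, evs in truth.carriers.items()
        for ev in evs
    ]
    pd.DataFrame(rows, columns=["sample_id", "event"]).to_csv(path_tsv, sep="\t", index=False)
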