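"""CNAR/MCR region algebra: recurrent-region construction across samples
and platforms, recurrence filtering, and gene annotation.

A CNAR (copy-number alteration region) is the union hull of a group of
same-direction calls whose pairwise reciprocal overlap exceeds 90% (strict,
per the "more than 90 percent" rule), closed transitively; groups need
calls from at least two distinct samples.  An MCR (minimal common region)
is the 100%-overlap core: the intersection of every member segment of a
cross-platform group of CNARs, required to be supported on all platforms.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .types import CNACall, GeneModel, RecurrentRegion, Segment

__all__ = [
    "reciprocal_overlap",
    "build_cnar",
    "build_mcr",
    "recurrence_table",
    "annotate_genes",
    "amplification_deletion_regions",
]


def reciprocal_overlap(a, b) -> float:
    """min(|A∩B|/|A|, |A∩B|/|B|); 0 when disjoint or on different
    chromosomes.  Accepts Segment-like objects or (chrom, start, end)."""
    ac, a0, a1 = (a.chrom, a.start, a.end) if hasattr(a, "chrom") else a
    bc, b0, b1 = (b.chrom, b.start, b.end) if hasattr(b, "chrom") else b
    if ac != bc:
        return 0.0
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _group_by_overlap(items: list, threshold: float, strict: bool) -> list[list[int]]:
    """Connected components of the pairwise reciprocal-overlap graph.

    Edge when overlap > threshold (strict) or >= threshold.  Items are
    coordinate-sorted and only coordinate-overlapping pairs are compared, so
    the sweep is near-linear for sparse inputs."""
    order = sorted(range(len(items)), key=lambda k: (items[k].chrom, items[k].start, items[k].end))
    uf = _UnionFind(len(items))
    active: list[int] = []
    for k in order:
        it = items[k]
        active = [
            a for a in active
            if items[a].chrom == it.chrom and items[a].end > it.start
        ]
        for a in active:
            ro = reciprocal_overlap(items[a], it)
            if (ro > threshold) if strict else (ro >= threshold):
                uf.union(a, k)
        active.append(k)
    comps: dict[int, list[int]] = defaultdict(list)
    for k in range(len(items)):
        comps[uf.find(k)].append(k)
    return [sorted(v) for _, v in sorted(comps.items())]


def build_cnar(
    calls: list[CNACall],
    direction: str,
    n_cohort: int,
    overlap_threshold: float = 0.9,
) -> list[RecurrentRegion]:
    """Group direction-matched calls into CNARs.

    Edges require reciprocal overlap strictly greater than
    ``overlap_threshold``; components are closed transitively and kept when
    they contain calls from >= 2 distinct samples.  The CNAR interval is the
    union hull of its members; frequency = distinct samples / n_cohort.
    """
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    dcalls = [c for c in calls if c.direction == direction]
    out: list[RecurrentRegion] = []
    for comp in _group_by_overlap(dcalls, overlap_threshold, strict=True):
        members = [dcalls[k] for k in comp]
        samples = {c.sample_id for c in members}
        if len(samples) < 2:
            continue
        out.append(
            RecurrentRegion(
                kind="CNAR",
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                direction=direction,
                member_segments=members,
                samples=samples,
                platforms={c.platform_id for c in members},
                frequency=len(samples) / n_cohort,
            )
        )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def build_mcr(
    cnars_by_platform: dict[str, list[RecurrentRegion]],
    n_cohort: int,
    require_platforms: set[str] | None = None,
    n_by_platform: dict[str, int] | None = None,
) -> list[RecurrentRegion]:
    """Extract minimal common regions shared across platforms.

    Same-direction CNARs from different platforms are grouped by any
    positive reciprocal overlap (transitively).  For each group observed on
    every required platform (default: all platforms supplied), the MCR is
    the intersection of *all* member segments of the group's CNARs; groups
    with an empty intersection are dropped.  MCR frequency counts the
    distinct samples whose call fully covers the MCR against the full
    cohort; a per-platform breakdown is attached when ``n_by_platform`` is
    given.
    """
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    if require_platforms is None:
        require_platforms = set(cnars_by_platform)
    tagged: list[tuple[str, RecurrentRegion]] = [
        (plat, r) for plat, rs in cnars_by_platform.items() for r in rs
    ]
    out: list[RecurrentRegion] = []
    for direction in ("gain", "loss"):
        idx = [k for k, (_, r) in enumerate(tagged) if r.direction == direction]
        items = [tagged[k][1] for k in idx]
        for comp in _group_by_overlap(items, 0.0, strict=True):
            group = [(tagged[idx[k]][0], items[k]) for k in comp]
            platforms = {plat for plat, _ in group}
            if not require_platforms <= platforms:
                continue
            members: list[Segment] = [m for _, r in group for m in r.member_segments]
            start = max(m.start for m in members)
            end = min(m.end for m in members)
            if end <= start:
                continue
            chrom = members[0].chrom
            support = {m.sample_id for m in members if m.start <= start and m.end >= end}
            freq_by_plat = {}
            if n_by_platform:
                for plat in platforms:
                    ns = {
                        m.sample_id
                        for m in members
                        if m.platform_id == plat and m.start <= start and m.end >= end
                    }
                    freq_by_plat[plat] = len(ns) / n_by_platform[plat]
            out.append(
                RecurrentRegion(
                    kind="MCR",
                    chrom=chrom,
                    start=start,
                    end=end,
                    direction=direction,
                    member_segments=members,
                    samples=support,
                    platforms=platforms,
                    frequency=len(support) / n_cohort,
                    frequency_by_platform=freq_by_plat,
                )
            )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def recurrence_table(
    regions: list[RecurrentRegion],
    n_cohort: int,
    min_freq: float = 0.20,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Filter regions by recurrence and tabulate.

    ``inclusive=False`` keeps frequency strictly above ``min_freq`` (the
    ">20%" recurrence rule); ``inclusive=True`` keeps >= (the ">=10%"
    amplification/deletion rule).  The table reports the exact fraction and
    a rounded percentage.
    """
    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    rows = []
    for r in regions:
        keep = r.frequency >= min_freq if inclusive else r.frequency > min_freq
        if not keep:
            continue
        rows.append(
            {
                "kind": r.kind,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "n_support": r.n_support,
                "frequency": r.frequency,
                "percent": round(100.0 * r.frequency, 1),
                "platforms": ",".join(sorted(r.platforms)),
                "contained_genes": ",".join(r.contained_genes),
                "overlapping_genes": ",".join(r.overlapping_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "chrom", "start", "end", "direction", "n_support",
            "frequency", "percent", "platforms", "contained_genes", "overlapping_genes",
        ],
    )


def annotate_genes(
    region: RecurrentRegion, genes: list[GeneModel]
) -> tuple[list[str], list[str]]:
    """Split genes into fully-contained and merely-overlapping sets.

    A gene is *contained* when its whole interval lies within the region
    (the set rendered bold in recurrence tables); *overlapping* when it
    intersects the region without being contained.  Results are stored on
    the region and returned.
    """
    contained, overlapping = [], []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        if g.chrom != region.chrom:
            continue
        if g.start >= region.start and g.end <= region.end:
            contained.append(g.name)
        elif g.start < region.end and region.start < g.end:
            overlapping.append(g.name)
    region.contained_genes = contained
    region.overlapping_genes = overlapping
    return contained, overlapping


def amplification_deletion_regions(
    calls_by_platform: dict[str, list[CNACall]],
    n_cohort: int,
    cutoff: float = 0.8,
    min_freq: float = 0.10,
    overlap_threshold: float = 0.9,
    n_by_platform: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Recurrent (>=10%, inclusive) regions restricted to high-amplitude
    calls (|mean log2| >= cutoff: amplification / deletion classes).

    With multiple platforms the cross-platform MCRs are reported; with one
    platform its CNARs are.
    """
    frames = []
    for direction, klass in (("gain", "amplification"), ("loss", "deletion")):
        filtered = {
            plat: [c for c in calls if c.amplitude_class == klass and abs(c.mean_log2) >= cutoff]
            for plat, calls in calls_by_platform.items()
        }
        cnars = {
            plat: build_cnar(cs, direction, n_cohort, overlap_threshold)
            for plat, cs in filtered.items()
        }
        if len(calls_by_platform) > 1:
            regions = build_mcr(cnars, n_cohort, n_by_platform=n_by_platform)
            regions = [r for r in regions if r.direction == direction]
        else:
            regions = next(iter(cnars.values())) if cnars else []
        tab = recurrence_table(regions, n_cohort, min_freq=min_freq, inclusive=True)
        tab.insert(0, "class", klass)
        frames.append(tab)
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return frames[0].iloc[0:0]
    return pd.concat(nonempty, ignore_index=True)
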