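"""Core domain types for the copy-number pipeline.

Coordinates are 0-based, half-open throughout (BED convention).  A probe is
an interval on a chromosome; an array platform is an ordered probe set; a
sample's measurement is a vector of log2 tumor/normal ratios aligned to that
probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ProbeDesign",
    "ArrayProfile",
    "Segment",
    "CNACall",
    "CommonAberration",
    "RecurrentRegion",
    "GeneModel",
    "PlantedAberration",
    "CohortTruth",
    "MLPAProfile",
]


@dataclass
class ProbeDesign:
    """An array platform: ordered genomic probe coordinates.

    Parameters
    ----------
    platform_id : str
        Platform label (e.g. ``"acgh-400k"``).
    chrom, start, end : ndarray
        Per-probe chromosome label and half-open interval.  Must be sorted
        by (chromosome, start).
    genome : dict
        Chromosome name -> length in base pairs.
    probe_id : ndarray of str, optional
        Unique probe identifiers; generated if omitted.
    """

    platform_id: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    genome: dict[str, int]
    probe_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == n):
            raise ValueError("chrom/start/end lengths differ")
        if np.any(self.end <= self.start):
            raise ValueError("probe intervals must satisfy end > start")
        if np.any(self.start < 0):
            raise ValueError("negative probe coordinates")
        for c in np.unique(self.chrom):
            if c not in self.genome:
                raise ValueError(f"probe chromosome {c!r} absent from genome")
            mask = self.chrom == c
            if np.any(self.end[mask] > self.genome[c]):
                raise ValueError(f"probe beyond end of chromosome {c!r}")
            if np.any(np.diff(self.start[mask]) < 0):
                raise ValueError(f"probes unsorted on chromosome {c!r}")
        if self.probe_id is None:
            self.probe_id = np.array(
                [f"{self.platform_id}_p{i:06d}" for i in range(n)], dtype=object
            )
        else:
            self.probe_id = np.asarray(self.probe_id, dtype=object)
            if len(np.unique(self.probe_id)) != n:
                raise ValueError("duplicate probe ids")

    @property
    def n_probes(self) -> int:
        return len(self.chrom)

    def chrom_slices(self) -> dict[str, slice]:
        """Index slice for each chromosome's probe run (probes are
        chromosome-contiguous by the sortedness invariant)."""
        out: dict[str, slice] = {}
        i = 0
        n = self.n_probes
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            out[c] = slice(i, j)
            i = j
        return out


@dataclass
class ArrayProfile:
    """One sample's per-probe log2 ratios aligned to a :class:`ProbeDesign`."""

    sample_id: str
    design: ProbeDesign
    log2: np.ndarray
    tissue: str = "tumor"
    intensity: Optional[np.ndarray] = None
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        if len(self.log2) != self.design.n_probes:
            raise ValueError(
                f"profile length {len(self.log2)} != design probe count "
                f"{self.design.n_probes}"
            )
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if len(self.intensity) != self.design.n_probes:
                raise ValueError("intensity length != design probe count")
        self.state.setdefault("lowess_done", False)
        self.state.setdefault("quantile_done", False)
        self.state.setdefault("centralized", False)
        self.state.setdefault("offset", 0.0)

    @property
    def platform_id(self) -> str:
        return self.design.platform_id

    def with_log2(self, log2: np.ndarray, **state_updates) -> "ArrayProfile":
        """Copy of this profile with new ratios and updated state flags."""
        new = replace(self, log2=np.asarray(log2, dtype=float))
        new.state = dict(self.state)
        new.state.update(state_updates)
        return new


@dataclass
class Segment:
    """A contiguous probe run with its interval score.

    ``i0:i1`` is the half-open probe index range in the design; genomic
    coordinates span from the first probe's start to the last probe's end.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    i0: int
    i1: int
    mean_log2: float
    score: float
    platform_id: str = ""

    @property
    def n_probes(self) -> int:
        return self.i1 - self.i0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNACall(Segment):
    """A filtered aberration call with direction and amplitude class."""

    direction: str = ""  # gain | loss
    amplitude_class: str = ""  # gain | loss | amplification | deletion


@dataclass
class CommonAberration:
    """A cross-sample common aberration from the context-corrected test."""

    chrom: str
    start: int
    end: int
    direction: str
    members: list[str]
    p_min: float
    i0: int = 0
    i1: int = 0

    @property
    def n_support(self) -> int:
        return len(set(self.members))


@dataclass
class RecurrentRegion:
    """A CNAR (union of >90%-overlapping calls) or MCR (their intersection)."""

    kind: str  # CNAR | MCR
    chrom: str
    start: int
    end: int
    direction: str
    member_segments: list[Segment]
    samples: set[str]
    platforms: set[str]
    frequency: float
    frequency_by_platform: dict[str, float] = field(default_factory=dict)
    contained_genes: list[str] = field(default_factory=list)
    overlapping_genes: list[str] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.samples)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end must exceed start")


@dataclass(frozen=True)
class PlantedAberration:
    """A ground-truth copy-number event planted by the simulator."""

    name: str
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    true_log2: float
    prevalence_by_type: dict  # Lauren type -> carrier probability

    def __post_init__(self) -> None:
        if self.true_log2 == 0:
            raise ValueError("true_log2 must be nonzero")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be gain or loss")
        if (self.true_log2 > 0) != (self.direction == "gain"):
            raise ValueError("direction inconsistent with sign of true_log2")
        for t, p in self.prevalence_by_type.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {t!r} outside [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth emitted by the simulator for recovery testing."""

    carriers: dict[str, list[PlantedAberration]]  # sample -> events
    offsets: dict[str, float]  # sample -> array-level offset
    clinical: "object"  # pandas DataFrame: sample_id, lauren_type, age, ...
    catalog: list[PlantedAberration]
    platform_of: dict[str, str] = field(default_factory=dict)


@dataclass
class MLPAProfile:
    """One sample's MLPA peak heights with control-probe flags."""

    sample_id: str
    tissue: str
    probe: np.ndarray  # probe names
    gene: np.ndarray  # gene per probe ("" for controls)
    height: np.ndarray
    is_control: np.ndarray

    def __post_init__(self) -> None:
        self.probe = np.asarray(self.probe, dtype=object)
        self.gene = np.asarray(self.gene, dtype=object)
        self.height = np.asarray(self.height, dtype=float)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        if not self.is_control.any():
            raise ValueError("MLPA profile needs at least one control probe")
        if np.any(self.height < 0):
            raise ValueError("negative peak heights")
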