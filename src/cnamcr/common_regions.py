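"""Context-corrected common-aberration detection across samples.

For a fixed direction, each sample s contributes a "context" g_s: the
fraction of the platform's probes covered by its direction-matched calls
(its genome-wide aberration burden).  Under the null that each sample
aberrates probe j independently with probability g_s, the carrier count K_j
follows a Poisson-binomial distribution with success probabilities
(g_1..g_S).  A probe is significant when the exact upper tail
P(K >= K_j) falls below alpha; runs of significant probes form candidate
common aberrations, and a sample is a member only if one of its calls has
reciprocal overlap >= the overlap threshold with the candidate (0.9 in the
study).
"""

from __future__ import annotations

import numpy as np

from .types import CNACall, CommonAberration, ProbeDesign

__all__ = [
    "genome_context",
    "coverage_matrix",
    "poisson_binomial_pmf",
    "context_pvalues",
    "context_pvalues_from_matrix",
    "detect_common",
]


def _covered_mask(calls: list[CNACall], design: ProbeDesign, direction: str) -> np.ndarray:
    """Boolean mask over design probes covered by direction-matched calls.

    A probe counts as covered when its start lies in the call interval, so
    calls from any platform can be projected onto this design."""
    mask = np.zeros(design.n_probes, dtype=bool)
    slices = design.chrom_slices()
    for c in calls:
        if c.direction != direction or c.chrom not in slices:
            continue
        sl = slices[c.chrom]
        starts = design.start[sl]
        lo = int(np.searchsorted(starts, c.start, side="left"))
        hi = int(np.searchsorted(starts, c.end, side="left"))
        mask[sl.start + lo : sl.start + hi] = True
    return mask


def coverage_matrix(
    calls_by_sample: dict[str, list[CNACall]], design: ProbeDesign, direction: str
) -> tuple[list[str], np.ndarray]:
    """(sample order, S x P boolean coverage matrix) for one direction."""
    samples = sorted(calls_by_sample)
    mat = np.stack(
        [_covered_mask(calls_by_sample[s], design, direction) for s in samples]
    ) if samples else np.zeros((0, design.n_probes), dtype=bool)
    return samples, mat


def genome_context(
    calls_by_sample: dict[str, list[CNACall]], design: ProbeDesign, direction: str
) -> dict[str, float]:
    """Per-sample aberrant fraction g_s of the design's probes."""
    samples, mat = coverage_matrix(calls_by_sample, design, direction)
    fracs = mat.mean(axis=1) if len(samples) else np.array([])
    return dict(zip(samples, fracs.astype(float)))


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_s) via dynamic
    programming (sequential convolution); length S + 1."""
    pmf = np.array([1.0])
    for p in np.asarray(probs, dtype=float):
        new = np.zeros(len(pmf) + 1)
        new[:-1] += pmf * (1.0 - p)
        new[1:] += pmf * p
        pmf = new
    return pmf


def context_pvalues_from_matrix(mat: np.ndarray) -> np.ndarray:
    """Per-probe upper-tail p-values from an S x P boolean coverage matrix.

    Contexts g_s are the row means; p_j = P(K >= K_j) under the exact
    Poisson-binomial with success probabilities (g_1..g_S)."""
    mat = np.asarray(mat, dtype=bool)
    g = mat.mean(axis=1)
    pmf = poisson_binomial_pmf(g)
    # survival function: sf[k] = P(K >= k)
    sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
    sf = np.minimum(sf, 1.0)
    counts = mat.sum(axis=0)
    return sf[counts]


def context_pvalues(
    calls_by_sample: dict[str, list[CNACall]], design: ProbeDesign, direction: str
) -> np.ndarray:
    """Per-probe upper-tail p-values P(K >= K_j) under the Poisson-binomial
    null with per-sample success probabilities g_s."""
    if not calls_by_sample:
        raise ValueError("need at least one sample")
    _, mat = coverage_matrix(calls_by_sample, design, direction)
    return context_pvalues_from_matrix(mat)


def _reciprocal_overlap_interval(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def detect_common(
    calls_by_sample: dict[str, list[CNACall]],
    design: ProbeDesign,
    direction: str,
    alpha: float = 0.05,
    overlap: float = 0.9,
) -> list[CommonAberration]:
    """Merge runs of significant probes and assemble member samples.

    Candidates are maximal runs of consecutive same-chromosome probes with
    p < alpha and at least one carrier.  A sample joins a candidate only if
    one of its direction-matched calls has reciprocal overlap >= ``overlap``
    with the candidate interval; candidates with fewer than two members are
    dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < overlap <= 1:
        raise ValueError("overlap must lie in (0, 1]")
    samples, mat = coverage_matrix(calls_by_sample, design, direction)
    if not samples:
        return []
    p = context_pvalues(calls_by_sample, design, direction)
    counts = mat.sum(axis=0)
    sig = (p < alpha) & (counts > 0)

    out: list[CommonAberration] = []
    for chrom, sl in design.chrom_slices().items():
        flags = sig[sl]
        i = 0
        m = sl.stop - sl.start
        while i < m:
            if not flags[i]:
                i += 1
                continue
            j = i
            while j < m and flags[j]:
                j += 1
            gi, gj = sl.start + i, sl.start + j  # half-open probe range
            start = int(design.start[gi])
            end = int(design.end[gj - 1])
            members = []
            for s in samples:
                for c in calls_by_sample[s]:
                    if c.direction != direction or c.chrom != chrom:
                        continue
                    if _reciprocal_overlap_interval(c.start, c.end, start, end) >= overlap:
                        members.append(s)
                        break
            if len(members) >= 2:
                out.append(
                    CommonAberration(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction=direction,
                        members=members,
                        p_min=float(p[gi:gj].min()),
                        i0=gi,
                        i1=gj,
                    )
                )
            i = j
    return out
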