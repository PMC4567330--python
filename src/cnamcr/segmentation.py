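"""Interval-score aberration detection (ADM-2 style).

A candidate interval [i, j] of a noise-standardized log2 profile scores

    score(i, j) = |sum(r[i..j]) / sigma| / sqrt(j - i + 1)

i.e. the absolute standardized mean times sqrt(probe count).  Detection
greedily extracts the maximum-score interval per chromosome; if its score
reaches the threshold (6.0 by default, the study setting) the interval is
recorded and the search recurses on the flanking probe runs.  Signed sums
make gains and losses symmetric.

Exact mode evaluates every O(n^2) interval with vectorized prefix sums.
Fast mode scans a multi-resolution candidate family (geometric lengths,
half-overlapping starts) and then polishes the best candidate by an exact
search in a window around it; it is intended for long chromosomes and must
agree with exact mode on clear signals.

The per-array noise sigma comes from the DLRS estimator
(:func:`cnamcr.normalization.estimate_probe_noise`) rather than a per-probe
error model; the fuzzy-zero correction is applied afterwards as a segment
filter with an explicit baseline term.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .normalization import estimate_probe_noise
from .types import ArrayProfile, CNACall, Segment

__all__ = [
    "interval_score",
    "max_scoring_interval",
    "detect_aberrations",
    "fuzzy_zero_filter",
    "filter_and_classify",
    "aberration_summary",
]


def interval_score(ratios: np.ndarray, sigma: float, i: int, j: int) -> float:
    """Score of the inclusive probe interval [i, j]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    if not (0 <= i <= j < n):
        raise IndexError(f"invalid interval [{i}, {j}] for n={n}")
    s = float(ratios[i : j + 1].sum())
    return abs(s / sigma) / np.sqrt(j - i + 1)


def _best_from_matrix(score: np.ndarray, starts: np.ndarray, lengths: np.ndarray):
    """Pick (score, start, length) maximizing score, ties broken by smaller
    start then smaller length.  Inputs are flat aligned arrays."""
    top = score.max()
    cand = np.flatnonzero(score == top)
    order = np.lexsort((lengths[cand], starts[cand]))
    k = cand[order[0]]
    return float(top), int(starts[k]), int(lengths[k])


def max_scoring_interval(
    ratios: np.ndarray, sigma: float, lo: int = 0, hi: Optional[int] = None
) -> tuple[int, int, float]:
    """Exact maximum-score interval within [lo, hi) by O(m^2) scan.

    Returns inclusive indices (i, j) and the score.  Ties on score are
    broken by leftmost start, then shortest length.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(ratios, dtype=float)
    if hi is None:
        hi = len(x)
    m = hi - lo
    if m <= 0:
        raise ValueError("empty interval")
    seg = x[lo:hi]
    prefix = np.concatenate([[0.0], np.cumsum(seg)])
    best = (-1.0, 0, 1)  # score, start(rel), length
    for L in range(1, m + 1):
        sums = prefix[L:] - prefix[:-L]
        sc = np.abs(sums) / (sigma * np.sqrt(L))
        top = sc.max()
        if top > best[0]:
            best = (float(top), int(np.argmax(sc)), L)
        elif top == best[0]:
            i = int(np.argmax(sc))
            if i < best[1]:  # same score, more-left start; L grows so never shorter
                best = (float(top), i, L)
    score, i_rel, L = best
    return lo + i_rel, lo + i_rel + L - 1, score


def _fast_candidate(seg: np.ndarray, sigma: float) -> tuple[int, int, float]:
    """Multi-resolution scan: geometric lengths with half-overlapping
    starts give one candidate per scale; the strongest candidates are then
    polished by an exact search in a window spanning several scale steps."""
    m = len(seg)
    prefix = np.concatenate([[0.0], np.cumsum(seg)])
    per_scale = []
    L = 1
    while L <= m:
        step = max(L // 2, 1)
        starts = np.arange(0, m - L + 1, step)
        sums = prefix[starts + L] - prefix[starts]
        sc = np.abs(sums) / (sigma * np.sqrt(L))
        k = int(np.argmax(sc))
        per_scale.append((float(sc[k]), int(starts[k]), L))
        L *= 2
    per_scale.sort(reverse=True)
    best: tuple[int, int, float] | None = None
    for _, i, L in per_scale[:3]:
        w_lo = max(i - 2 * L, 0)
        w_hi = min(i + 3 * L, m)
        cand = max_scoring_interval(seg, sigma, w_lo, w_hi)
        if (
            best is None
            or cand[2] > best[2]
            or (cand[2] == best[2] and (cand[0], cand[1] - cand[0]) < (best[0], best[1] - best[0]))
        ):
            best = cand
    return best


def detect_aberrations(
    profile: ArrayProfile,
    threshold: float = 6.0,
    sigma: Optional[float] = None,
    method: str = "exact",
) -> list[Segment]:
    """Detect aberrant intervals in one profile by greedy interval scoring.

    Per chromosome: find the maximum-score interval; if score >= threshold,
    record it and recurse on the probe runs flanking it.  ``sigma`` defaults
    to the profile's DLRS estimate.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if method not in ("exact", "fast"):
        raise ValueError("method must be 'exact' or 'fast'")
    if not profile.state.get("centralized", False):
        warnings.warn(
            f"profile {profile.sample_id} not centralized; detecting anyway"
        )
    if sigma is None:
        sigma = estimate_probe_noise(profile)

    design = profile.design
    segments: list[Segment] = []
    for chrom, sl in design.chrom_slices().items():
        stack = [(sl.start, sl.stop)]
        while stack:
            lo, hi = stack.pop()
            if hi - lo < 1:
                continue
            if method == "exact" or hi - lo <= 64:
                i, j, score = max_scoring_interval(profile.log2, sigma, lo, hi)
            else:
                ii, jj, score = _fast_candidate(profile.log2[lo:hi], sigma)
                i, j = lo + ii, lo + jj
            if score < threshold:
                continue
            mean = float(profile.log2[i : j + 1].mean())
            segments.append(
                Segment(
                    sample_id=profile.sample_id,
                    chrom=chrom,
                    start=int(design.start[i]),
                    end=int(design.end[j]),
                    i0=i,
                    i1=j + 1,
                    mean_log2=mean,
                    score=float(score),
                    platform_id=design.platform_id,
                )
            )
            stack.append((lo, i))
            stack.append((j + 1, hi))
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    return segments


def fuzzy_zero_filter(
    segments: list[Segment], nu: float, sigma: float, threshold: float = 6.0
) -> list[Segment]:
    """Drop segments whose fuzzy-zero quality falls below the threshold.

    quality = |mean_log2| / sqrt(sigma^2 / n_probes + nu^2)

    ``nu`` is a global baseline-uncertainty term (typically the robust SD of
    per-array centralization offsets across the cohort); it penalizes long,
    low-amplitude segments whose nominal score is inflated by probe count.
    ``nu = 0`` disables the correction (quality reduces to the interval
    score), so the input is returned unchanged.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if nu == 0:
        return list(segments)
    kept = []
    for s in segments:
        quality = abs(s.mean_log2) / np.sqrt(sigma**2 / s.n_probes + nu**2)
        if quality >= threshold:
            kept.append(s)
    return kept


def filter_and_classify(
    segments: list[Segment],
    min_probes: int = 3,
    min_abs_mean: float = 0.25,
    amp_cut: float = 0.8,
) -> list[CNACall]:
    """Apply the probe-count and amplitude filters and classify calls.

    Keeps segments with n_probes >= min_probes and |mean_log2| >=
    min_abs_mean (both inclusive).  Direction is the sign of the mean;
    amplitude class is amplification/deletion when |mean_log2| >= amp_cut,
    else gain/loss.
    """
    if min_probes <= 0 or min_abs_mean <= 0 or amp_cut <= 0:
        raise ValueError("thresholds must be positive")
    calls: list[CNACall] = []
    for s in segments:
        if s.n_probes < min_probes or abs(s.mean_log2) < min_abs_mean:
            continue
        direction = "gain" if s.mean_log2 > 0 else "loss"
        if abs(s.mean_log2) >= amp_cut:
            amp_class = "amplification" if direction == "gain" else "deletion"
        else:
            amp_class = direction
        calls.append(
            CNACall(
                sample_id=s.sample_id,
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                i0=s.i0,
                i1=s.i1,
                mean_log2=s.mean_log2,
                score=s.score,
                platform_id=s.platform_id,
                direction=direction,
                amplitude_class=amp_class,
            )
        )
    return calls


def aberration_summary(calls_by_sample: dict[str, list[CNACall]]) -> dict:
    """Per-sample gain/loss counts plus cohort mean counts and median lengths.

    Returns a dict with a ``per_sample`` DataFrame and the cohort-level
    ``mean_gain_count``, ``mean_loss_count``, ``median_gain_length_bp``,
    ``median_loss_length_bp`` (NaN when no calls of that direction exist).
    """
    rows = []
    gain_lengths: list[int] = []
    loss_lengths: list[int] = []
    for sid, calls in calls_by_sample.items():
        gains = [c for c in calls if c.direction == "gain"]
        losses = [c for c in calls if c.direction == "loss"]
        gain_lengths.extend(c.length for c in gains)
        loss_lengths.extend(c.length for c in losses)
        rows.append(
            {
                "sample_id": sid,
                "n_gain": len(gains),
                "n_loss": len(losses),
                "median_gain_length_bp": float(np.median([c.length for c in gains])) if gains else np.nan,
                "median_loss_length_bp": float(np.median([c.length for c in losses])) if losses else np.nan,
            }
        )
    per_sample = pd.DataFrame(rows)
    return {
        "per_sample": per_sample,
        "mean_gain_count": float(per_sample["n_gain"].mean()) if rows else np.nan,
        "mean_loss_count": float(per_sample["n_loss"].mean()) if rows else np.nan,
        "median_gain_length_bp": float(np.median(gain_lengths)) if gain_lengths else np.nan,
        "median_loss_length_bp": float(np.median(loss_lengths)) if loss_lengths else np.nan,
    }
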