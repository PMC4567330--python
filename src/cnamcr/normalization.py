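"""Per-array and between-array normalization of log2 ratio profiles.

Order of application mirrors standard two-channel practice: within-array
lowess correction against the intensity covariate, quantile normalization
across arrays of the same platform, then centralization (shifting the modal,
copy-neutral state to log2 = 0).  The fuzzy-zero correction lives in
:mod:`cnamcr.segmentation` because it acts on segments, not probes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .types import ArrayProfile

__all__ = [
    "lowess_correct",
    "quantile_normalize",
    "centralize",
    "estimate_probe_noise",
]


def lowess_correct(
    profile: ArrayProfile, span: float = 0.3, on_degenerate: str = "error"
) -> ArrayProfile:
    """Subtract the locally weighted regression of log2 ratio on intensity.

    The fitted curve's mean is removed before subtraction so the array's
    global level is preserved (centralization handles the level).

    Parameters
    ----------
    profile : ArrayProfile
        Must carry the ``intensity`` covariate.
    span : float
        Lowess span (fraction of points per local fit), in (0, 1].
    on_degenerate : {"error", "identity"}
        Behavior when the covariate is constant.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if profile.intensity is None:
        raise ValueError(
            "profile has no intensity covariate; skip the lowess stage "
            "(e.g. pass --skip-lowess) for intensity-free inputs"
        )
    x = profile.intensity
    if np.ptp(x) == 0:
        if on_degenerate == "identity":
            return profile.with_log2(profile.log2, lowess_done=True)
        raise ValueError("constant intensity covariate: lowess fit is degenerate")
    fitted = _sm_lowess(profile.log2, x, frac=span, return_sorted=False)
    fitted = fitted - fitted.mean()
    return profile.with_log2(profile.log2 - fitted, lowess_done=True)


def quantile_normalize(profiles: list[ArrayProfile]) -> list[ArrayProfile]:
    """Between-array quantile normalization (per platform).

    Each array's sorted values are replaced by the across-array arithmetic
    mean of order statistics; within-array ranks are preserved, ties share
    the average of the tied target values.
    """
    if len(profiles) < 2:
        raise ValueError("quantile normalization needs >= 2 profiles")
    platforms = {p.platform_id for p in profiles}
    if len(platforms) > 1:
        raise ValueError(f"mixed platforms in one call: {sorted(platforms)}")
    n = profiles[0].design.n_probes
    mat = np.stack([p.log2 for p in profiles])
    target = np.sort(mat, axis=1).mean(axis=0)
    out = []
    grid = np.arange(1, n + 1, dtype=float)
    for p, row in zip(profiles, mat):
        ranks = stats.rankdata(row, method="average")
        new = np.interp(ranks, grid, target)
        out.append(p.with_log2(new, quantile_done=True))
    return out


def centralize(profile: ArrayProfile, bandwidth: float | None = None) -> ArrayProfile:
    """Shift the profile so its modal (copy-neutral) log2 ratio is 0.

    The mode is the argmax of a Gaussian kernel density estimate; bandwidth
    defaults to Silverman's rule.  Near-ties between modes are broken toward
    the mode nearer 0 (with a warning), so a heavily aberrant arm cannot
    silently re-center the array on an aberrant state.  The subtracted
    offset is recorded in ``state["offset"]``.
    """
    x = profile.log2
    if np.ptp(x) == 0:
        warnings.warn("all log2 ratios identical; offset set to that value")
        off = float(x[0])
        return profile.with_log2(x - off, centralized=True, offset=profile.state["offset"] + off)
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if bandwidth is None:
        kde = stats.gaussian_kde(x, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(x, bw_method=bandwidth / np.std(x, ddof=1))
    lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, 2001)
    dens = kde(grid)
    # candidate modes = interior local maxima (plus the boundary argmax)
    local = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    cand = np.union1d(local, [int(np.argmax(dens))])
    peak = dens[cand].max()
    near = cand[dens[cand] >= peak * 0.98]
    if len(near) > 1:
        warnings.warn("near-tied density modes; choosing the mode nearer 0")
    off = float(grid[near][np.argmin(np.abs(grid[near]))])
    return profile.with_log2(
        x - off, centralized=True, offset=profile.state["offset"] + off
    )


def estimate_probe_noise(profile: ArrayProfile) -> float:
    """Derivative log-ratio spread (DLRS): robust per-array noise sigma.

    sigma = 1.4826 * median(|d - median(d)|) / sqrt(2), where d are
    successive probe differences taken within chromosomes (so real
    copy-number steps at chromosome boundaries are never counted).  Floored
    at 1e-6 so downstream interval scores stay finite.
    """
    if profile.design.n_probes < 3:
        raise ValueError("need >= 3 probes to estimate noise")
    diffs = []
    for sl in profile.design.chrom_slices().values():
        seg = profile.log2[sl]
        if len(seg) >= 2:
            diffs.append(np.diff(seg))
    d = np.concatenate(diffs)
    mad = np.median(np.abs(d - np.median(d)))
    return max(float(1.4826 * mad / np.sqrt(2.0)), 1e-6)
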