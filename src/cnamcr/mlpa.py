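"""MLPA peak-ratio normalization and three-state copy-number calling.

Population normalization: each probe's peak height is first scaled by the
sample's mean control-probe height (removing input-DNA and amplification
differences), then divided by the median of that same quantity across a
reference population of normal-tissue profiles.  Ratios below 0.75 call a
deletion, above 1.25 an amplification; the closed band [0.75, 1.25] is
normal copy number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MLPAProfile

__all__ = ["normalize_peaks", "call_mlpa", "call_mlpa_profile", "concordance"]

DELETION_CUT = 0.75
AMPLIFICATION_CUT = 1.25


def _control_scaled(profile: MLPAProfile) -> pd.Series:
    ctrl_mean = profile.height[profile.is_control].mean()
    if ctrl_mean == 0:
        raise ValueError(f"sample {profile.sample_id}: zero control-probe mean")
    return pd.Series(profile.height / ctrl_mean, index=profile.probe)


def normalize_peaks(
    profile: MLPAProfile, reference_population: list[MLPAProfile]
) -> pd.Series:
    """Population-normalized peak ratios, indexed by probe name."""
    if not reference_population:
        raise ValueError("reference population must be non-empty")
    sample = _control_scaled(profile)
    ref = pd.concat([_control_scaled(r) for r in reference_population], axis=1)
    ref_median = ref.median(axis=1)
    return sample / ref_median.reindex(sample.index)


def call_mlpa(ratio: float) -> str:
    """Three-state call: <0.75 deletion, >1.25 amplification, else normal."""
    if ratio < 0:
        raise ValueError("peak ratio must be >= 0")
    if ratio < DELETION_CUT:
        return "deletion"
    if ratio > AMPLIFICATION_CUT:
        return "amplification"
    return "normal"


def call_mlpa_profile(
    profile: MLPAProfile, reference_population: list[MLPAProfile]
) -> pd.DataFrame:
    """Normalize one profile and call every non-control gene probe."""
    ratios = normalize_peaks(profile, reference_population)
    rows = []
    for probe, gene, is_ctrl in zip(profile.probe, profile.gene, profile.is_control):
        if is_ctrl:
            continue
        r = float(ratios[probe])
        rows.append((profile.sample_id, probe, gene, r, call_mlpa(r)))
    return pd.DataFrame(rows, columns=["sample_id", "probe", "gene", "ratio", "status"])


def concordance(
    mlpa_calls: pd.DataFrame,
    acgh_calls: pd.DataFrame,
    size_bins: list[float] | None = None,
) -> dict:
    """Cross-tabulate MLPA vs aCGH three-state calls per (sample, gene).

    Both inputs need ``sample_id``, ``gene`` and ``status`` columns (status
    in {deletion, normal, amplification}); ``acgh_calls`` may carry a
    ``length_bp`` column for size stratification.  Returns the contingency
    table, overall agreement fraction, and per-size-bin agreement when bins
    are requested.
    """
    merged = mlpa_calls.merge(
        acgh_calls, on=["sample_id", "gene"], suffixes=("_mlpa", "_acgh")
    )
    if merged.empty:
        raise ValueError("no shared (sample, gene) keys between call sets")
    states = ["deletion", "normal", "amplification"]
    table = pd.crosstab(merged["status_mlpa"], merged["status_acgh"]).reindex(
        index=states, columns=states, fill_value=0
    )
    agree = float((merged["status_mlpa"] == merged["status_acgh"]).mean())
    out = {"table": table, "agreement": agree}
    if size_bins is not None:
        if "length_bp" not in merged:
            raise ValueError("size stratification needs a length_bp column in acgh_calls")
        labels = [f"{int(a)}-{int(b)}" if np.isfinite(b) else f">={int(a)}"
                  for a, b in zip(size_bins[:-1], size_bins[1:])]
        binned = pd.cut(merged["length_bp"], bins=size_bins, labels=labels, right=False)
        strata = {}
        for lab in labels:
            sub = merged[binned == lab]
            if len(sub):
                strata[lab] = float((sub["status_mlpa"] == sub["status_acgh"]).mean())
        out["agreement_by_size"] = strata
    return out
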