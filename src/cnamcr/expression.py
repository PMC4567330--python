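"""qPCR fold-change computation and CNA-stratified expression association.

Fold change uses the ΔΔCt method with an assumed amplification efficiency
of 2: FC = 2^(−ΔΔCt), where ΔΔCt = (Ct_gene,T − Ct_ref,T) − (Ct_gene,N −
Ct_ref,N) against the RPLP0-style reference gene.  Direction calls are a
two-sided one-sample t-test of log2 fold change against 0, labeled Up/Down
at alpha, "-" otherwise — the dichotomy used in per-gene association
tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change",
    "fc_direction_test",
    "stratified_expression_table",
    "cna_expression_correlation",
]


def fold_change(record) -> float:
    """FC = 2^−ΔΔCt for one record with fields ct_t, ct_n, ref_ct_t, ref_ct_n.

    Accepts any mapping or object with those attributes (e.g. a DataFrame
    row)."""
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    vals = [get(k) for k in ("ct_t", "ct_n", "ref_ct_t", "ref_ct_n")]
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("missing Ct value")
    ct_t, ct_n, ref_t, ref_n = map(float, vals)
    ddct = (ct_t - ref_t) - (ct_n - ref_n)
    return float(2.0 ** (-ddct))


def fold_change_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-row FC and log2 FC; rows with missing Cts are skipped with a
    warning."""
    rows = []
    for idx, rec in ct.iterrows():
        try:
            fc = fold_change(rec)
        except (ValueError, TypeError):
            warnings.warn(f"row {idx}: missing Ct value, record skipped")
            continue
        rows.append({"sample_id": rec["sample_id"], "gene": rec["gene"],
                     "fc": fc, "log2_fc": np.log2(fc)})
    return pd.DataFrame(rows, columns=["sample_id", "gene", "fc", "log2_fc"])


def fc_direction_test(log2_fcs, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided one-sample t-test of mean log2 FC against 0.

    Returns (p, label) with label "Up" when p < alpha and the mean is
    positive, "Down" when negative, "-" otherwise.  A zero-variance sample
    with nonzero mean is labeled by sign with p = 0 (degenerate t)."""
    x = np.asarray(log2_fcs, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2 observations")
    mean = x.mean()
    if np.ptp(x) == 0:
        if mean == 0:
            return 1.0, "-"
        warnings.warn("zero variance with nonzero mean; p set to 0")
        return 0.0, "Up" if mean > 0 else "Down"
    t, p = stats.ttest_1samp(x, 0.0)
    label = "-"
    if p < alpha:
        label = "Up" if mean > 0 else "Down"
    return float(p), label


def stratified_expression_table(
    log2_fc: dict[str, dict[str, float]],
    cna_status: dict[str, dict[str, bool]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene association table: overall / without-CNA / with-CNA strata.

    ``log2_fc[gene][sample]`` are log2 fold changes; ``cna_status`` flags
    whether a same-direction CNA call covers the gene in that sample.
    Strata with n < 2 report a missing p and a "-" label.
    """
    rows = []
    for gene in sorted(log2_fc):
        fcs = log2_fc[gene]
        status = cna_status.get(gene, {})
        missing = [s for s in fcs if s not in status]
        if missing:
            raise ValueError(f"gene {gene}: CNA status unknown for {missing[:3]}")
        strata = {
            "all": list(fcs.values()),
            "without_cna": [v for s, v in fcs.items() if not status[s]],
            "with_cna": [v for s, v in fcs.items() if status[s]],
        }
        row: dict = {"gene": gene}
        for name, vals in strata.items():
            row[f"n_{name}"] = len(vals)
            if len(vals) >= 2:
                p, label = fc_direction_test(vals, alpha=alpha)
            else:
                p, label = np.nan, "-"
            row[f"p_{name}"] = p
            row[f"label_{name}"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def cna_expression_correlation(cna_log2, log2_fc) -> tuple[float, float]:
    """Pearson correlation between per-sample CNA level and log2 FC."""
    x = np.asarray(cna_log2, dtype=float)
    y = np.asarray(log2_fc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("cna_log2 is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("log2_fc is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
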