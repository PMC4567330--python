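"""Clinicopathological association, clustering, and survival analyses.

Conventions shared across tests: 2x2 tables use Pearson's chi-square with
continuity correction when every expected count is >= 5 and two-sided
Fisher's exact otherwise; mixed-type samples are excluded from
diffuse-vs-intestinal comparisons; Bonferroni correction multiplies raw
p-values by the number of tested genes and caps at 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "test_2x2",
    "lauren_association",
    "gain_cooccurrence",
    "age_correlation",
    "cluster_samples",
    "km_logrank",
    "size_stratified_platform_comparison",
]

#: Size bins (bp) for the platform comparison of loss-call sizes.
DEFAULT_SIZE_BINS = [1_000, 5_000, 10_000, 50_000, 100_000, np.inf]


def test_2x2(table: np.ndarray) -> tuple[str, float]:
    """Chi-square (Yates) when all expected counts >= 5, else Fisher exact.

    Returns (test name, two-sided p); p is NaN for an empty margin."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; p undefined")
        return "none", float("nan")
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        return "chi-square", float(p)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return "fisher", float(p)


def lauren_association(
    cna_status: dict[str, dict[str, bool]], lauren_type: dict[str, str]
) -> pd.DataFrame:
    """Per-gene association of CNA presence with Lauren type.

    Builds the 2x2 table (CNA present/absent x diffuse/intestinal) per
    gene, excluding mixed-type samples, and applies the chi-square/Fisher
    switch."""
    rows = []
    for gene in sorted(cna_status):
        status = cna_status[gene]
        table = np.zeros((2, 2))
        for sid, has_cna in status.items():
            lt = lauren_type.get(sid)
            if lt not in ("diffuse", "intestinal"):
                continue
            table[0 if has_cna else 1, 0 if lt == "diffuse" else 1] += 1
        test, p = test_2x2(table)
        rows.append({"gene": gene, "test": test, "p": p,
                     "n_cna_diffuse": int(table[0, 0]), "n_cna_intestinal": int(table[0, 1]),
                     "n_no_cna_diffuse": int(table[1, 0]), "n_no_cna_intestinal": int(table[1, 1])})
    return pd.DataFrame(rows)


def gain_cooccurrence(status_a, status_b) -> float:
    """Two-sided Fisher exact p for co-occurrence of two binary CNA
    statuses across samples; NaN when a margin is empty."""
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    if len(a) != len(b):
        raise ValueError("status vectors differ in length")
    table = np.array(
        [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate co-occurrence margin; p undefined")
        return float("nan")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def age_correlation(
    cna_log2_by_gene: dict[str, np.ndarray], ages: np.ndarray, m_genes: int | None = None
) -> pd.DataFrame:
    """Per-gene Pearson correlation of CNA level with age, with Bonferroni
    correction (p x number of tested genes, capped at 1)."""
    ages = np.asarray(ages, dtype=float)
    if m_genes is None:
        m_genes = len(cna_log2_by_gene)
    if m_genes < 1:
        raise ValueError("m_genes must be >= 1")
    rows = []
    for gene in sorted(cna_log2_by_gene):
        x = np.asarray(cna_log2_by_gene[gene], dtype=float)
        if len(x) != len(ages):
            raise ValueError(f"gene {gene}: length mismatch with ages")
        if np.ptp(x) == 0 or np.ptp(ages) == 0:
            rows.append({"gene": gene, "r": np.nan, "p_raw": np.nan, "p_bonferroni": np.nan})
            continue
        r, p = stats.pearsonr(x, ages)
        rows.append({"gene": gene, "r": float(r), "p_raw": float(p),
                     "p_bonferroni": min(1.0, float(p) * m_genes)})
    return pd.DataFrame(rows)


def cluster_samples(
    cna_matrix: pd.DataFrame,
    k: int | None = None,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> dict:
    """Agglomerative hierarchical clustering of a samples x genes CNA-level
    matrix.

    Missing values are imputed as 0 (copy-neutral) and flagged.  Rows are
    sorted by sample id before linkage so the dendrogram (and any tie
    resolution inside the linkage) is invariant to input order.  Returns the
    linkage matrix, deterministic leaf order (as sample ids), the Newick
    rendering, and a k-cluster assignment when ``k`` is given.
    """
    if len(cna_matrix) < 2:
        raise ValueError("need >= 2 samples to cluster")
    mat = cna_matrix.sort_index()
    imputed = bool(mat.isna().any().any())
    if imputed:
        warnings.warn("missing CNA values imputed as 0 (copy-neutral)")
        mat = mat.fillna(0.0)
    Z = hierarchy.linkage(mat.values, method=linkage_method, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    out = {
        "linkage": Z,
        "leaf_order": [mat.index[i] for i in leaves],
        "samples": list(mat.index),
        "imputed": imputed,
        "newick": _linkage_to_newick(Z, list(mat.index)),
    }
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        out["clusters"] = dict(zip(mat.index, (int(v) for v in labels)))
    return out


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def render(node: int) -> tuple[str, float]:
        if node < n:
            return labels[node], 0.0
        a, b, height, _ = Z[node - n]
        sa, ha = render(int(a))
        sb, hb = render(int(b))
        return f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})", height

    s, _ = render(2 * n - 2)
    return s + ";"


def km_logrank(groups, survival_time, event) -> dict:
    """Kaplan-Meier curves per binary group plus the log-rank test (1 df).

    Returns {"curves": {label: survival DataFrame}, "statistic": chi2,
    "p": p}; p is NaN when no events occurred at all."""
    groups = np.asarray(groups)
    t = np.asarray(survival_time, dtype=float)
    e = np.asarray(event, dtype=int)
    labs = np.unique(groups)
    if len(labs) != 2:
        raise ValueError("need exactly two non-empty groups")
    curves = {}
    for lab in labs:
        m = groups == lab
        if m.sum() == 1:
            warnings.warn(f"group {lab!r} has a single sample")
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    if e.sum() == 0:
        warnings.warn("all observations censored; log-rank undefined")
        return {"curves": curves, "statistic": float("nan"), "p": float("nan")}
    m0 = groups == labs[0]
    res = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])
    return {"curves": curves, "statistic": float(res.test_statistic), "p": float(res.p_value)}


def size_stratified_platform_comparison(
    calls_platform1,
    calls_platform2,
    bins: list[float] | None = None,
    direction: str = "loss",
) -> pd.DataFrame:
    """Compare the size distribution of loss calls between platform groups.

    Per size bin, cross-tabulates (platform group) x (call in bin / not in
    bin) over direction-matched calls and applies the chi-square/Fisher
    switch.  Empty bins are skipped with a note column.
    """
    if bins is None:
        bins = list(DEFAULT_SIZE_BINS)
    if len(bins) < 2:
        raise ValueError("need at least one size bin (two edges)")
    sets = []
    for calls in (calls_platform1, calls_platform2):
        lengths = np.array(
            [c.length for c in calls if getattr(c, "direction", direction) == direction],
            dtype=float,
        )
        if len(lengths) == 0:
            raise ValueError("a platform group has no direction-matched calls")
        sets.append(lengths)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        label = f"{int(lo)}-{int(hi)}" if np.isfinite(hi) else f">={int(lo)}"
        in1 = int(((sets[0] >= lo) & (sets[0] < hi)).sum())
        in2 = int(((sets[1] >= lo) & (sets[1] < hi)).sum())
        if in1 + in2 == 0:
            rows.append({"bin": label, "n_platform1": 0, "n_platform2": 0,
                         "test": "skipped", "p": np.nan})
            continue
        table = np.array([[in1, len(sets[0]) - in1], [in2, len(sets[1]) - in2]])
        test, p = test_2x2(table)
        rows.append({"bin": label, "n_platform1": in1, "n_platform2": in2,
                     "test": test, "p": p})
    return pd.DataFrame(rows)
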