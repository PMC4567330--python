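"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or naive
algorithms, sharing no code path with the implementations they check.
"""

import itertools

import numpy as np

from cnamcr.types import CNACall, RecurrentRegion


def brute_force_max_interval(x, sigma):
    """O(n^2) python-loop maximizer of |sum|/(sigma*sqrt(len)); ties by
    leftmost start then shortest length."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (-1.0, 0, 0)
    for i in range(n):
        s = 0.0
        for j in range(i, n):
            s += x[j]
            sc = abs(s) / (sigma * np.sqrt(j - i + 1))
            if sc > best[0] + 1e-15:
                best = (sc, i, j)
    return best[1], best[2], best[0]


def brute_force_mcr(cnars_by_platform):
    """Naive MCR extraction: full pairwise overlap graph over all CNARs,
    transitive closure by BFS, explicit intersection over every member."""
    items = [(plat, r) for plat, rs in cnars_by_platform.items() for r in rs]
    out = set()
    for direction in ("gain", "loss"):
        idx = [k for k, (_, r) in enumerate(items) if r.direction == direction]
        adj = {k: set() for k in idx}
        for a, b in itertools.combinations(idx, 2):
            ra, rb = items[a][1], items[b][1]
            if ra.chrom == rb.chrom and min(ra.end, rb.end) > max(ra.start, rb.start):
                adj[a].add(b)
                adj[b].add(a)
        seen = set()
        for k in idx:
            if k in seen:
                continue
            comp, queue = {k}, [k]
            while queue:
                cur = queue.pop()
                for nxt in adj[cur] - comp:
                    comp.add(nxt)
                    queue.append(nxt)
            seen |= comp
            platforms = {items[c][0] for c in comp}
            if platforms != set(cnars_by_platform):
                continue
            members = [m for c in comp for m in items[c][1].member_segments]
            start = max(m.start for m in members)
            end = min(m.end for m in members)
            if end > start:
                out.add((members[0].chrom, start, end, direction))
    return out


def random_mcr_instance(seed, platforms=("p1", "p2", "p3")):
    """Random cross-platform CNAR sets around a handful of loci."""
    rng = np.random.default_rng(seed)
    n_loci = int(rng.integers(1, 4))
    cnars = {p: [] for p in platforms}
    sample_counter = 0
    for loc_i in range(n_loci):
        loc = 10_000 * (loc_i + 1)
        direction = "gain" if rng.random() < 0.5 else "loss"
        for plat in platforms:
            if rng.random() < 0.25:  # platform sometimes misses the locus
                continue
            members = []
            for _ in range(int(rng.integers(1, 4))):
                s = loc + int(rng.integers(0, 300))
                e = s + 200 + int(rng.integers(0, 300))
                mean = 0.6 if direction == "gain" else -0.6
                members.append(
                    CNACall(
                        sample_id=f"s{sample_counter}", chrom="chr1", start=s, end=e,
                        i0=0, i1=3, mean_log2=mean, score=10.0, platform_id=plat,
                        direction=direction, amplitude_class=direction,
                    )
                )
                sample_counter += 1
            cnars[plat].append(
                RecurrentRegion(
                    kind="CNAR", chrom="chr1",
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    direction=direction, member_segments=members,
                    samples={m.sample_id for m in members},
                    platforms={plat}, frequency=0.0,
                )
            )
    return cnars, max(sample_counter, 1)


def fisher_exact_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more probable than the
    observed one."""
    from math import comb

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, c1 + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def t_sf_oracle(t, df):
    """Upper-tail of Student's t via the regularized incomplete beta
    function (textbook identity), independent of scipy.stats.t."""
    from scipy.special import betainc

    x = df / (df + t * t)
    p = 0.5 * betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def logrank_permutation_p(time, event, groups, n_perm=1000, seed=0):
    """Permutation reference for the log-rank test: permute group labels,
    recompute the statistic from the standard O-E table each time."""

    def statistic(t, e, g):
        t, e, g = np.asarray(t, float), np.asarray(e, int), np.asarray(g)
        labs = np.unique(g)
        o_minus_e = 0.0
        var = 0.0
        for tt in np.unique(t[e == 1]):
            at_risk = t >= tt
            n = at_risk.sum()
            n1 = (at_risk & (g == labs[0])).sum()
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (g == labs[0])).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        return (o_minus_e**2) / var if var > 0 else 0.0

    rng = np.random.default_rng(seed)
    obs = statistic(time, event, groups)
    groups = np.asarray(groups)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if statistic(time, event, perm) >= obs - 1e-12:
            hits += 1
    return hits / n_perm, obs
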