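"""Independent reference implementations used only by the test suite.

Everything here is written from first principles (plain arithmetic over
numpy arrays, exhaustive enumeration, textbook formulas) and deliberately
shares no code path with the package: the package's statistics go through
scipy wrappers, the package's NBE goes through RDKit bond enumeration,
while these oracles work from hand-committed adjacency data and explicit
rank/sum formulas. Distribution tail functions (normal, t, F survival
functions) are taken from scipy.stats as special functions only.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import norm
from scipy.stats import t as t_dist


def midrank(values) -> np.ndarray:
    """Average (mid) ranks, 1-based, computed by explicit tie-group walking."""
    z = np.asarray(values, dtype=float)
    order = np.argsort(z, kind="mergesort")
    ranks = np.empty(z.size)
    sorted_z = z[order]
    i = 0
    while i < z.size:
        j = i
        while j + 1 < z.size and sorted_z[j + 1] == sorted_z[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_oracle(x, y) -> tuple[float, float]:
    """Spearman rho as Pearson on midranks; two-sided p from the t(n-2)
    approximation rho * sqrt((n-2)/(1-rho^2))."""
    n = len(x)
    rho = pearson(midrank(x), midrank(y))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * t_dist.sf(abs(t), df=n - 2)
    return rho, min(1.0, p)


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    v1 = a.var(ddof=1) / n1
    v2 = b.var(ddof=1) / n2
    t = (a.mean() - b.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * t_dist.sf(abs(t), df=df)
    return float(t), float(df), min(1.0, float(p))


def student_t_oracle(a, b) -> tuple[float, float]:
    """Classical pooled-variance two-sample t, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * t_dist.sf(abs(t), df=n1 + n2 - 2)
    return float(t), min(1.0, float(p))


def anova_oracle(groups) -> tuple[float, float]:
    """One-way F from explicit between/within sums of squares."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    k = len(arrays)
    n_total = all_x.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    if msw == 0.0:
        return (0.0, 1.0) if msb == 0.0 else (math.inf, 0.0)
    F = msb / msw
    p = float(f_dist.sf(F, k - 1, n_total - k))
    return float(F), p


def mwu_u1(a, b) -> float:
    """U statistic of the first sample from midranks of the pooled data."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = midrank(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def mwu_asymptotic_oracle(a, b) -> tuple[float, float]:
    """Mann-Whitney U1 plus the two-sided normal-approximation p with
    midranks, tie correction, and continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    U1 = mwu_u1(a, b)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    sigma = math.sqrt(n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1))))
    U_big = max(U1, n1 * n2 - U1)
    z = (U_big - mu - 0.5) / sigma
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return U1, p


def mwu_exact_oracle(a, b) -> tuple[float, float]:
    """Mann-Whitney U1 plus the exact two-sided p from exhaustive
    enumeration of every C(n1+n2, n1) assignment of pooled ranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = midrank(pooled)
    U1 = mwu_u1(a, b)
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            for comb in itertools.combinations(range(pooled.size), n1)
        ]
    )
    p_le = float((us <= U1 + 1e-12).mean())
    p_ge = float((us >= U1 - 1e-12).mean())
    return U1, min(1.0, 2.0 * min(p_le, p_ge))


def nbe_oracle(expected_bonds, mw, table_values: dict) -> tuple[float, float]:
    """Brute-force NBE from a hand-committed bond multiset: plain sum of
    count x table energy, divided by the hand molecular weight.

    ``table_values`` maps (element_a, element_b, order) with elements in
    either orientation to energies in kJ/mol.
    """
    total = 0.0
    for (el_a, el_b, order), count in expected_bonds:
        key = (el_a, el_b, order)
        if key not in table_values:
            key = (el_b, el_a, order)
        total += count * table_values[key]
    return total, total / mw
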