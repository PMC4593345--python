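"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity by literal enumeration of its
definition, staying independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np


def brute_sensitivity(probe_matches: dict[str, set[str]], gene: str) -> float:
    """Literal probe enumeration: matching probes / all probes."""
    n_match = 0
    for genes in probe_matches.values():
        if gene in genes:
            n_match += 1
    return n_match / len(probe_matches)


def brute_specificity(probe_matches: dict[str, set[str]], gene: str) -> float:
    """Literal enumeration with 1/k down-weighting of promiscuous probes."""
    matching_any = [genes for genes in probe_matches.values() if genes]
    if not matching_any:
        return 0.0
    total = 0.0
    for genes in probe_matches.values():
        if gene in genes:
            total += 1.0 / len(genes)
    return total / len(matching_any)


def brute_bh(p_values) -> np.ndarray:
    """Step-up BH by direct evaluation of q_(i) = min_{j≥i} p_(j)·m/j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_anova_f(groups) -> float:
    """Textbook one-way ANOVA from explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def pooled_t(a, b) -> float:
    """Two-sample pooled-variance t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    df = len(a) + len(b) - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))


def random_match_table_records(rng, max_probe_sets=4, max_probes=20, genes=("ga", "gb", "gc", "gd")):
    """Random tidy match records for property tests (≤ *max_probes* per set)."""
    records = []
    n_ps = rng.integers(1, max_probe_sets + 1)
    for i in range(n_ps):
        ps = f"ps{i}"
        n_probes = rng.integers(1, max_probes + 1)
        for j in range(n_probes):
            k = rng.integers(0, len(genes) + 1)
            matched = list(rng.choice(genes, size=k, replace=False)) if k else []
            records.append((ps, f"{ps}_p{j}", matched))
    return records
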