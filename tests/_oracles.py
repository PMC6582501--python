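"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and
elementary definitions (no pandas ranking, no scipy summation) so that
agreement with the package is a genuine dual-route check.
"""

from fractions import Fraction
from itertools import product
from math import comb, sqrt


# --- enumeration: exact signed-rank test by full sign enumeration ----------

def _mean_tie_ranks(values):
    """Fractional (mean-tie) ranks of ``values``, smallest value rank 1."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j + 2) / 2.0  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def signed_rank_p_enumeration(differences):
    """Two-sided exact signed-rank p over all 2^n sign assignments."""
    d = [float(x) for x in differences]
    assert all(x != 0 for x in d)
    ranks = _mean_tie_ranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    w_values = []
    for signs in product((1, -1), repeat=n):
        w_values.append(sum(r for r, s in zip(ranks, signs) if s > 0))
    total = len(w_values)
    lower = sum(1 for w in w_values if w <= w_obs + 1e-9) / total
    upper = sum(1 for w in w_values if w >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lower, upper))


# --- design: exact binomial tail with rational arithmetic ------------------

def binomial_tail_fraction(n, p_num, p_den, k):
    """Exact P(X >= k) as a Fraction for p = p_num/p_den."""
    p = Fraction(p_num, p_den)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


# --- selection: criteria A/B/C re-evaluated from their English rules -------

def sample_ranks(counts_by_gene, sample, floor):
    """gene -> fractional descending rank among retained genes (or None)."""
    retained = [
        (g, counts_by_gene[g][sample])
        for g in counts_by_gene
        if counts_by_gene[g][sample] > floor
    ]
    if not retained:
        return {g: None for g in counts_by_gene}
    values = [-c for _, c in retained]  # descending: rank 1 = highest count
    ranks = _mean_tie_ranks(values)
    out = {g: None for g in counts_by_gene}
    for (g, _), r in zip(retained, ranks):
        out[g] = r
    return out


def sample_quantiles(counts_by_gene, sample, floor):
    """gene -> quantile score in [0, 1]; missing entries score 0."""
    ranks = sample_ranks(counts_by_gene, sample, floor)
    g_s = sum(1 for r in ranks.values() if r is not None)
    out = {}
    for g, r in ranks.items():
        if r is None:
            out[g] = 0.0
        elif g_s == 1:
            out[g] = 1.0
        else:
            out[g] = (g_s - r) / (g_s - 1)
    return out


def _ceil_frac(frac: Fraction, n: int) -> int:
    value = frac * n
    return -((-value.numerator) // value.denominator)


def brute_force_criteria(
    counts_by_gene,
    groups,
    floor=2,
    tumor_frac=Fraction(3, 4),
    control_frac=Fraction(3, 4),
    top_b=10,
    top_c=20,
    min_tumor_c=5,
    max_control_c=1,
):
    """Evaluate criteria A, B, C by direct restatement of the rules.

    ``counts_by_gene``: {gene: {sample: count}}; ``groups``:
    {sample: 'tumor'|'control'}.  Returns {gene: set of flags}.
    """
    samples = list(groups)
    tumors = [s for s in samples if groups[s] == "tumor"]
    controls = [s for s in samples if groups[s] == "control"]
    quantiles = {s: sample_quantiles(counts_by_gene, s, floor) for s in samples}
    ranks = {s: sample_ranks(counts_by_gene, s, floor) for s in samples}
    need_t = _ceil_frac(tumor_frac, len(tumors))
    need_c = _ceil_frac(control_frac, len(controls))

    flags = {g: set() for g in counts_by_gene}
    for g in counts_by_gene:
        m = sum(quantiles[s][g] for s in samples) / len(samples)
        above = sum(1 for s in tumors if quantiles[s][g] > m)
        below = sum(1 for s in controls if quantiles[s][g] < m)
        if above >= need_t and below >= need_c:
            flags[g].add("A")

        def in_top(s, k):
            r = ranks[s][g]
            return r is not None and r <= k

        if any(in_top(s, top_b) for s in tumors) and not any(
            in_top(s, top_b) for s in controls
        ):
            flags[g].add("B")
        n_t = sum(1 for s in tumors if in_top(s, top_c))
        n_c = sum(1 for s in controls if in_top(s, top_c))
        if n_t >= min_tumor_c and n_c <= max_control_c:
            flags[g].add("C")
    return flags


# --- clustering: naive O(n^3) complete linkage -----------------------------

def complete_linkage_heights(dist):
    """Merge heights of naive complete-linkage agglomeration.

    ``dist`` is a full square matrix (list of lists).  Clusters are kept
    as frozensets of leaf indices; at each step the pair with the minimum
    of max pairwise leaf distances is merged.
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def euclidean_matrix(rows):
    """Naive double-loop Euclidean distances between rows."""
    n = len(rows)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            out[i][j] = sqrt(sum((a - b) ** 2 for a, b in zip(rows[i], rows[j])))
    return out


# --- networks: union-find connected components -----------------------------

def union_find_components(edges, universe):
    """Partition via union-find; ``edges`` is an iterable of (a, b)."""
    parent = {g: g for g in universe}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for g in parent:
        groups.setdefault(find(g), set()).add(g)
    return sorted(
        (frozenset(c) for c in groups.values()), key=lambda c: (-len(c), min(c))
    )
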