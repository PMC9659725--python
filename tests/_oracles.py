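"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive and separate from the package
code paths it checks: direct rule application for the identification
filter, union-find for grouping, closed-form two-group Poisson
likelihood ratios, step-by-step product-limit / log-rank arithmetic,
step-up BH, and quadratic-time average linkage.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# --- identification filter -------------------------------------------------

def brute_force_filter(rows):
    """rows: iterable of (peptide, evalue, protein_set).  Returns the set
    of retained proteins by literal application of the three rules."""
    best_e: dict[str, float] = {}
    maps: dict[str, set[str]] = {}
    for pep, e, prots in rows:
        best_e[pep] = min(e, best_e.get(pep, math.inf))
        maps.setdefault(pep, set()).update(prots)
    retained_peps = {p for p, e in best_e.items() if e < 0.01}
    proteins = set().union(*maps.values()) if maps else set()
    keep = set()
    for acc in proteins:
        peps = [p for p in retained_peps if acc in maps[p]]
        if len(peps) < 2:
            continue
        product = 1.0
        for p in peps:
            product *= best_e[p]
        if product < 1e-4:
            keep.add(acc)
    return keep


# --- union-find grouping ---------------------------------------------------

class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_groups(peptide_map):
    """peptide_map: dict peptide -> set of proteins.  Returns frozenset of
    frozensets: the protein partition induced by shared peptides."""
    proteins = set().union(*peptide_map.values()) if peptide_map else set()
    uf = UnionFind(proteins)
    for prots in peptide_map.values():
        prots = list(prots)
        for other in prots[1:]:
            uf.union(prots[0], other)
    groups: dict[str, set[str]] = {}
    for p in proteins:
        groups.setdefault(uf.find(p), set()).add(p)
    return frozenset(frozenset(g) for g in groups.values())


# --- two-group Poisson likelihood ratio ------------------------------------

def poisson_lrt_two_group(ya, yb):
    """Closed-form deviance LRT for equal Poisson rates in two groups
    (no offset): 2 * [sum y log(y_hat_group / y_hat_pooled)]."""
    ya, yb = np.asarray(ya, float), np.asarray(yb, float)
    sa, sb = ya.sum(), yb.sum()
    na, nb = len(ya), len(yb)
    lam_a, lam_b = sa / na, sb / nb
    lam0 = (sa + sb) / (na + nb)

    def term(s, lam):
        return s * math.log(lam / lam0) if s > 0 else 0.0

    return 2.0 * (term(sa, lam_a) + term(sb, lam_b))


# --- Kaplan-Meier and log-rank ---------------------------------------------

def km_by_hand(times, censored):
    """Step-by-step product-limit estimator.  Returns list of
    (event_time, survival_just_after)."""
    times = np.asarray(times, float)
    censored = np.asarray(censored, bool)
    out = []
    s = 1.0
    for t in sorted(set(times[~censored])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & ~censored))
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


def logrank_by_hand(ta, ca, tb, cb):
    """Mantel-Cox chi-square by summing hypergeometric moments at each
    distinct event time."""
    ta, ca = np.asarray(ta, float), np.asarray(ca, bool)
    tb, cb = np.asarray(tb, float), np.asarray(cb, bool)
    all_t = np.concatenate([ta, tb])
    all_c = np.concatenate([ca, cb])
    event_times = sorted(set(all_t[~all_c]))
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        n = n1 + n2
        d = int(np.sum((all_t == t) & ~all_c))
        d1 = int(np.sum((ta == t) & ~ca))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2


# --- Benjamini-Hochberg ----------------------------------------------------

def bh_by_hand(pvals):
    """Literal step-up: sort, p*(m/rank), cumulative minimum from the top."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# --- average linkage (UPGMA) -----------------------------------------------

def upgma_heights_by_hand(points):
    """Quadratic-time average-linkage agglomeration on Euclidean
    distances between row vectors.  Returns the sorted list of merge
    heights (cluster distance = mean pairwise point distance)."""
    points = np.asarray(points, float)
    n = len(points)
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i, j in combinations(range(n), 2)
    }
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = float(
                np.mean([dist[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)
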