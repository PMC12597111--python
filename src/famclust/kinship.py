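"""Exact Malécot kinship and meiotic genetic distance over arbitrary pedigrees.

The Malécot coefficient of kinship phi(i, j) is the probability that one
gene sampled at random from i and one from j are identical by descent.  Two
exact routes are provided and cross-checked in tests:

* :func:`kinship` — memoized pairwise recursion, valid for inbred pedigrees;
* :func:`kinship_matrix` — the tabular (additive relationship matrix) method,
  vectorised over the whole genealogy, used by the batch statistics.

:func:`brute_force_kinship` is an independent Monte-Carlo gene-dropping
estimator intended as a testing oracle, never as the production path.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Dict, Sequence, Tuple

import numpy as np

from .pedigree import Genealogy

__all__ = [
    "kinship",
    "kinship_matrix",
    "genetic_distance",
    "brute_force_kinship",
]


def kinship(g: Genealogy, i: str, j: str) -> float:
    """Exact Malécot kinship phi(i, j) by memoized recursion.

    phi(i, i) = (1 + phi(father_i, mother_i)) / 2 (so 0.5 for non-inbred i);
    for distinct individuals the recursion expands the one that cannot be an
    ancestor of the other (the one with the larger generation index):
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2, with a missing
    parent contributing 0.  Handles inbreeding loops exactly.
    """
    for k in (i, j):
        if k not in g:
            raise KeyError(f"unknown individual id: {k!r}")
    gen = g.generation_index()
    cache = g._phi_cache

    def phi(a: str, b: str) -> float:
        if a is None or b is None:
            return 0.0
        # canonical orientation: expand `a`, the individual that is not an
        # ancestor of `b` (larger generation index; ties cannot be ancestral)
        if gen[a] < gen[b] or (gen[a] == gen[b] and a > b):
            a, b = b, a
        key = (a, b)
        val = cache.get(key)
        if val is not None:
            return val
        ind = g[a]
        if a == b:
            val = 0.5 * (1.0 + phi(ind.father_id, ind.mother_id))
        else:
            val = 0.5 * (phi(ind.father_id, b) + phi(ind.mother_id, b))
        cache[key] = val
        return val

    return phi(i, j)


def _additive_matrix(g: Genealogy) -> Tuple[Dict[str, int], np.ndarray]:
    """Additive (numerator) relationship matrix A over the whole genealogy.

    Built by the tabular method in topological order: A[k,k] = 1 + A[f,m]/2,
    A[k,j] = (A[f,j] + A[m,j]) / 2.  phi = A / 2.  Cached on the genealogy.
    """
    if g._additive is not None:
        return g._additive
    topo = g.topological_order()
    pos = {ind_id: k for k, ind_id in enumerate(topo)}
    n = len(topo)
    a = np.zeros((n, n))
    for k, ind_id in enumerate(topo):
        ind = g[ind_id]
        pf = pos[ind.father_id] if ind.father_id is not None else -1
        pm = pos[ind.mother_id] if ind.mother_id is not None else -1
        if pf >= 0 and pm >= 0:
            a[k, :k] = 0.5 * (a[pf, :k] + a[pm, :k])
            a[k, k] = 1.0 + 0.5 * a[pf, pm]
        elif pf >= 0 or pm >= 0:
            p = max(pf, pm)
            a[k, :k] = 0.5 * a[p, :k]
            a[k, k] = 1.0
        else:
            a[k, k] = 1.0
        a[:k, k] = a[k, :k]
    g._additive = (pos, a)
    return g._additive


def kinship_matrix(g: Genealogy, ids: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of phi over ``ids`` (diagonal >= 0.5)."""
    for k in ids:
        if k not in g:
            raise KeyError(f"unknown individual id: {k!r}")
    pos, a = _additive_matrix(g)
    idx = np.array([pos[k] for k in ids], dtype=np.intp)
    return 0.5 * a[np.ix_(idx, idx)]


def _ancestor_depths(g: Genealogy, i: str) -> Dict[str, int]:
    """id -> minimum number of meioses from ``i`` up to each ancestor (self 0)."""
    cached = g._anc_depths.get(i)
    if cached is not None:
        return cached
    depths = {i: 0}
    queue = deque([i])
    while queue:
        cur = queue.popleft()
        d = depths[cur] + 1
        for pid in g[cur].parent_ids():
            if pid not in depths or d < depths[pid]:
                depths[pid] = d
                queue.append(pid)
    g._anc_depths[i] = depths
    return depths


def genetic_distance(g: Genealogy, i: str, j: str) -> float:
    """Minimum meioses connecting i and j through a common ancestor.

    Parent-offspring 1, siblings or grandparent-grandchild 2, avuncular 3,
    first cousins 4, second cousins 6; ``math.inf`` when the pair shares no
    recorded ancestor.  Only genealogically valid paths (ascend from each
    member to a shared ancestor) are considered — never paths through a
    spouse or a shared descendant.
    """
    if i == j:
        raise ValueError("genetic distance is defined for distinct individuals")
    for k in (i, j):
        if k not in g:
            raise KeyError(f"unknown individual id: {k!r}")
    di = _ancestor_depths(g, i)
    dj = _ancestor_depths(g, j)
    if len(dj) < len(di):
        di, dj = dj, di
    best = math.inf
    for anc, d in di.items():
        other = dj.get(anc)
        if other is not None and d + other < best:
            best = d + other
    return best


def brute_force_kinship(
    g: Genealogy, i: str, j: str, n_drops: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo gene-dropping estimate of phi(i, j) — a testing oracle.

    Every founder receives two globally unique alleles; each drop transmits
    one random allele per parent down the pedigree.  The per-drop estimate is
    the probability that one allele sampled from i and one from j match
    (averaged analytically over the four allele pairings; for i == j the two
    draws are with replacement, giving 0.5 + F_i/2 in expectation).
    """
    for k in (i, j):
        if k not in g:
            raise KeyError(f"unknown individual id: {k!r}")
    rng = np.random.default_rng(seed)
    topo = g.topological_order()
    alleles: Dict[str, np.ndarray] = {}
    label = 0
    for ind_id in topo:
        ind = g[ind_id]
        pair = np.empty((2, n_drops), dtype=np.int32)
        for slot, pid in enumerate((ind.father_id, ind.mother_id)):
            if pid is None:
                pair[slot] = label
                label += 1
            else:
                choice = rng.integers(0, 2, size=n_drops)
                pair[slot] = alleles[pid][choice, np.arange(n_drops)]
        alleles[ind_id] = pair
    ai, aj = alleles[i], alleles[j]
    if i == j:
        return 0.5 + 0.5 * float(np.mean(ai[0] == ai[1]))
    match = np.zeros(n_drops)
    for s in range(2):
        for t in range(2):
            match += ai[s] == aj[t]
    return float(np.mean(match) / 4.0)
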