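"""Neighbor-joining placement trees.

A light-weight sanity check on classification: peptides are placed on an
unrooted neighbor-joining tree built from score-derived distances

    d(a, b) = 1 - raw_score(a, b) / min(self_score(a), self_score(b)),

which is 0 for identical sequences and approaches 1 for unrelated ones.
Neighbor joining recovers the generating topology exactly whenever the
distance matrix is additive.  Tie-breaking is deterministic (the lowest index
pair wins), so trees are reproducible.
"""

from __future__ import annotations

import numpy as np

from retrocensus.align import ScoringScheme, local_align, self_score


def distance_matrix(
    peptides: dict[str, str], scheme: ScoringScheme | None = None
) -> tuple[np.ndarray, list[str]]:
    """Score-derived pairwise distances between peptides."""
    scheme = scheme or ScoringScheme()
    labels = list(peptides)
    selfs = {k: self_score(peptides[k], scheme) for k in labels}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            raw, _bit, _cov, _sp = local_align(peptides[a], peptides[b], scheme)
            denom = min(selfs[a], selfs[b])
            d = 1.0 - (raw / denom) if denom > 0 else 1.0
            D[i, j] = D[j, i] = max(0.0, d)
    return D, labels


def _argmin_q(D: np.ndarray, active: list[int]) -> tuple[int, int]:
    n = len(active)
    r = {i: sum(D[i, k] for k in active if k != i) for i in active}
    best = None
    for ai in range(n):
        for aj in range(ai + 1, n):
            i, j = active[ai], active[aj]
            q = (n - 2) * D[i, j] - r[i] - r[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
    return best[1], best[2]


def neighbor_joining(D: np.ndarray, labels: list[str]) -> str:
    """Neighbor joining on a distance matrix; returns an unrooted Newick string.

    Requires at least 3 taxa.  Branch lengths are clamped at zero.
    """
    D = np.array(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape must match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    size = 2 * n  # room for internal nodes
    full = np.zeros((size, size))
    full[:n, :n] = D
    subtree = {i: labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        i, j = _argmin_q(full, active)
        m = len(active)
        ri = sum(full[i, k] for k in active if k != i)
        rj = sum(full[j, k] for k in active if k != j)
        li = 0.5 * full[i, j] + (ri - rj) / (2 * (m - 2))
        lj = full[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        for k in active:
            if k in (i, j):
                continue
            full[nxt, k] = full[k, nxt] = max(
                0.0, 0.5 * (full[i, k] + full[j, k] - full[i, j])
            )
        subtree[nxt] = f"({subtree[i]}:{li:.6f},{subtree[j]}:{lj:.6f})"
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    a, b, c = active
    # three-point closed form for the final unrooted trifurcation
    x = max(0.0, 0.5 * (full[a, b] + full[a, c] - full[b, c]))
    y = max(0.0, full[a, b] - x)
    z = max(0.0, full[a, c] - x)
    return f"({subtree[a]}:{x:.6f},{subtree[b]}:{y:.6f},{subtree[c]}:{z:.6f});"


def nj_tree(peptides: dict[str, str], scheme: ScoringScheme | None = None) -> str:
    """Newick NJ tree over peptides using score-derived distances."""
    if len(peptides) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    D, labels = distance_matrix(peptides, scheme)
    return neighbor_joining(D, labels)
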