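"""Independent reference implementations used as test oracles.

Deliberately written with different machinery than the package: plain
neighbour-graph construction plus scipy connected components for DBSCAN,
and a scalar transcription of the Weir & Cockerham (1984) variance
components for F_ST.  They must stay independent of the code paths they
check.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def dbscan_oracle(coords: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Brute-force DBSCAN: core points by neighbour count, clusters as
    connected components of the core-core epsilon graph, border points to
    the first core neighbour in index order.  Labels 1..k in order of the
    first core point of each component; noise is -1."""
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    within = dist <= eps
    core = within.sum(1) >= min_pts

    adj = csr_matrix(within & core[:, None] & core[None, :])
    _, comp = connected_components(adj, directed=False)

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    comp_to_label: dict[int, int] = {}
    for i in range(n):
        if core[i] and comp[i] not in comp_to_label:
            next_label += 1
            comp_to_label[comp[i]] = next_label
    for i in range(n):
        if core[i]:
            labels[i] = comp_to_label[comp[i]]
    for i in range(n):
        if core[i]:
            continue
        for j in range(n):
            if core[j] and within[i, j]:
                labels[i] = labels[j]
                break
    return labels


def wc84_theta_oracle(counts1: np.ndarray, counts2: np.ndarray) -> float:
    """Scalar transcription of the Weir-Cockerham (1984) theta-hat for two
    populations, combining markers as a ratio of summed components."""
    sum_a = sum_abc = 0.0
    r = 2
    for (aa1, ab1, bb1), (aa2, ab2, bb2) in zip(counts1, counts2):
        n1 = aa1 + ab1 + bb1
        n2 = aa2 + ab2 + bb2
        if n1 == 0 or n2 == 0:
            continue
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        p1 = (ab1 + 2 * bb1) / (2 * n1)
        p2 = (ab2 + 2 * bb2) / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (ab1 / n1 * n1 + ab2 / n2 * n2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    if sum_abc == 0:
        return float("nan")
    return sum_a / sum_abc


def random_instance(rng: np.random.Generator):
    """A random 2-D clustering instance with random density parameters."""
    n = int(rng.integers(20, 300))
    kind = rng.integers(0, 3)
    if kind == 0:
        coords = rng.random((n, 2))
    elif kind == 1:
        k = int(rng.integers(2, 5))
        centers = rng.random((k, 2))
        which = rng.integers(0, k, n)
        coords = centers[which] + rng.normal(0, rng.uniform(0.01, 0.08), (n, 2))
    else:
        half = n // 2
        coords = np.vstack(
            [
                rng.normal([0.3, 0.5], 0.03, (half, 2)),
                rng.random((n - half, 2)),
            ]
        )
    eps = float(rng.uniform(0.03, 0.15))
    min_pts = int(rng.integers(3, 15))
    return coords, eps, min_pts


def canonical_partition(labels: np.ndarray) -> list[int]:
    """Relabel clusters in order of first appearance so partitions compare."""
    mapping: dict[int, int] = {}
    out = []
    for l in labels:
        if l == -1:
            out.append(-1)
        else:
            out.append(mapping.setdefault(int(l), len(mapping)))
    return out
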