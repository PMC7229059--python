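"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


def naive_upgma_cophenetic(points: np.ndarray) -> np.ndarray:
    """O(n^3) average-linkage agglomeration over row vectors.

    Returns the cophenetic distance matrix between all original rows.
    Average linkage: the distance between two clusters is the mean of all
    inter-cluster pairwise Euclidean distances; the closest pair of
    clusters merges at each step.
    """
    n = len(points)
    dist = squareform(pdist(points))
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a]
                         for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph
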