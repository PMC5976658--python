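"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's own implementations: results are
recomputed from first principles (exhaustive search, explicit member
sets) so oracle equivalence checks are meaningful.
"""

import itertools

import numpy as np


def brute_force_complete_linkage(D):
    """Exhaustive complete-linkage agglomeration in scipy merge layout.

    Maintains explicit member sets and recomputes every inter-cluster
    distance from the original matrix at each step; ties resolve to the
    lowest cluster-key pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((min(ids[a], ids[b]), max(ids[a], ids[b]), d,
                       len(clusters[a]) + len(clusters[b])))
        merged = clusters.pop(a) | clusters.pop(b)
        key = min(merged)
        clusters[key] = merged
        ids[key] = next_id
        next_id += 1
    return np.array(merges)
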