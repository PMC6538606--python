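"""Independent brute-force reference for the nested permutation pipeline.

Deliberately naive: per-point t-tests via scipy.stats.ttest_rel on
explicitly relabeled condition arrays, flood-fill clustering with a
hand-written BFS, python-loop p-value counting.  Shares no code with the
package implementation beyond numpy/scipy primitives.
"""

import itertools

import numpy as np
from scipy import stats


def tmap_bruteforce(c1, c2):
    """Pointwise paired t across subjects; t=0 where the difference is constant."""
    n_sub, n_f, n_t = c1.shape
    t = np.zeros((n_f, n_t))
    for i in range(n_f):
        for j in range(n_t):
            d = c1[:, i, j] - c2[:, i, j]
            if np.std(d, ddof=1) == 0:
                t[i, j] = 0.0
            else:
                t[i, j] = stats.ttest_rel(c1[:, i, j], c2[:, i, j]).statistic
    return t


def clusters_bruteforce(t, threshold):
    """4-connected suprathreshold components via BFS; returns (mass, sign, cells)."""
    n_f, n_t = t.shape
    out = []
    for sign in (1, -1):
        supra = t > threshold if sign == 1 else t < -threshold
        seen = np.zeros_like(supra, dtype=bool)
        for i in range(n_f):
            for j in range(n_t):
                if not supra[i, j] or seen[i, j]:
                    continue
                queue, cells = [(i, j)], []
                seen[i, j] = True
                while queue:
                    a, b = queue.pop()
                    cells.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        x, y = a + da, b + db
                        if 0 <= x < n_f and 0 <= y < n_t and supra[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            queue.append((x, y))
                out.append((sum(t[c] for c in cells), sign, cells))
    return out


def pescar_bruteforce(c1_by_pair, c2_by_pair, threshold, alpha):
    """Full nested permutation by exhaustive enumeration of condition swaps.

    ``c?_by_pair``: dict pair -> (S, F, T).  Every labeling's clusters
    are ranked against the max-|mass| null built from the non-identity
    labelings (the shared-relabeling convention).  Returns observed
    p-values and per-pair observed cluster p's.
    """
    pairs = sorted(c1_by_pair)
    n_sub = next(iter(c1_by_pair.values())).shape[0]
    labelings = list(itertools.product([False, True], repeat=n_sub))
    assert labelings[0] == tuple([False] * n_sub)  # identity first

    per_pair_clusters = {}  # pair -> list over labelings of cluster lists
    per_pair_null = {}
    for pair in pairs:
        c1, c2 = c1_by_pair[pair], c2_by_pair[pair]
        all_clusters = []
        for lab in labelings:
            a = np.array([c2[s] if lab[s] else c1[s] for s in range(n_sub)])
            b = np.array([c1[s] if lab[s] else c2[s] for s in range(n_sub)])
            all_clusters.append(clusters_bruteforce(tmap_bruteforce(a, b), threshold))
        # max |mass| per labeling, identity included: the shared ranking set
        all_max = [
            max((abs(m) for m, _, _ in cl), default=0.0) for cl in all_clusters
        ]
        per_pair_clusters[pair] = all_clusters
        per_pair_null[pair] = all_max

    def totals(lab_idx):
        a12, a21 = 0.0, 0.0
        for pair in pairs:
            all_max = per_pair_null[pair]
            best = {1: 0.0, -1: 0.0}
            for mass, sign, _ in per_pair_clusters[pair][lab_idx]:
                k_ge = sum(1 for v in all_max if v >= abs(mass))
                p_c = k_ge / len(all_max)
                if p_c < alpha and abs(mass) > best[sign]:
                    best[sign] = abs(mass)
            a12 += best[1]
            a21 += best[-1]
        return a12, a21

    obs12, obs21 = totals(0)
    null12 = [totals(i)[0] for i in range(1, len(labelings))]
    null21 = [totals(i)[1] for i in range(1, len(labelings))]
    n_p = len(labelings) - 1
    k12 = sum(1 for v in null12 if v >= obs12)
    k21 = sum(1 for v in null21 if v >= obs21)

    cluster_p = {}
    for pair in pairs:
        null = per_pair_null[pair][1:]  # reported p's rank against non-identity
        ps = []
        for mass, sign, _ in per_pair_clusters[pair][0]:
            k_ge = sum(1 for v in null if v >= abs(mass))
            ps.append(((k_ge + 1) / (len(null) + 1), mass, sign))
        cluster_p[pair] = sorted(ps)
    return {
        "A12": obs12,
        "A21": obs21,
        "p12": (k12 + 1) / (n_p + 1),
        "p21": (k21 + 1) / (n_p + 1),
        "null12": null12,
        "null21": null21,
        "cluster_p": cluster_p,
    }
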