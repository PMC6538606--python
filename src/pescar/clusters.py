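"""Cluster-based paired statistics on the time-frequency plane.

For one sub-ROI pair, the condition contrast is a paired t-map over
(frequency, time); suprathreshold points are grouped into 4-connected
components ("clusters"), each summarized by its mass (the sum of
t-values inside).  Cluster-level p-values come from the permutation
distribution of the maximum absolute cluster mass under per-subject
condition swaps, which for a paired design are sign flips of the
per-subject difference maps.  Ranking against the max statistic controls
the family-wise error over the whole TF plane, jointly for both signs.

The batched engine (:func:`batch_signflip_tmaps`,
:func:`label_clusters_batch`) evaluates all sign-flip relabelings of a
pair in one pass; it exploits the fact that the per-subject mean square
of the differences is invariant under sign flips, so only the flipped
means need recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "TMap",
    "Cluster",
    "ClusterStatResult",
    "paired_tmap",
    "cluster_forming_threshold",
    "extract_clusters",
    "cluster_pvalues",
    "make_sign_flips",
    "batch_signflip_tmaps",
    "label_clusters_batch",
]

#: 4-connectivity on the TF plane: edge-adjacent in time or frequency
STRUCT_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# 3D structure that never connects across the leading (relabeling) axis
_STRUCT_BATCH = np.zeros((3, 3, 3), dtype=bool)
_STRUCT_BATCH[1] = STRUCT_2D


@dataclass
class TMap:
    """Paired t-statistic map over (frequency, time)."""

    t: np.ndarray
    df: int
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None
    n_degenerate: int = 0


@dataclass
class Cluster:
    """One suprathreshold 4-connected component of a t-map."""

    mask: np.ndarray
    mass: float
    sign: int  # +1: C1 > C2, -1: C2 > C1
    p_cluster: float | None = None


@dataclass
class ClusterStatResult:
    """Full cluster statistics for one sub-ROI pair."""

    pair: tuple[int, int]
    tmap: TMap
    clusters: list[Cluster]
    t_threshold: float


def paired_tmap(coh_c1, coh_c2, freqs=None, times=None) -> TMap:
    """Pointwise paired t-test between conditions across subjects.

    Inputs are per-subject maps stacked on axis 0, shape (S, F, T).
    Points with zero difference variance (identical values in every
    subject) get t = 0 and are counted in ``n_degenerate``.
    """
    c1 = np.asarray(coh_c1, dtype=float)
    c2 = np.asarray(coh_c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("condition arrays must share shape")
    n_sub = c1.shape[0]
    if n_sub < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = c1 - c2
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, 0.0, m / (np.where(degenerate, 1.0, sd) / np.sqrt(n_sub)))
    return TMap(
        t=t,
        df=n_sub - 1,
        freqs=freqs,
        times=times,
        n_degenerate=int(np.count_nonzero(degenerate)),
    )


def cluster_forming_threshold(df, alpha_two_sided=0.05) -> float:
    """Two-sided parametric cluster-forming threshold on |t|.

    The 100*(1 - alpha/2) percentile of the central t-distribution, i.e.
    the critical value of a two-sided t-test at level ``alpha_two_sided``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha_two_sided / 2.0, df))


def extract_clusters(tmap, t_threshold) -> list[Cluster]:
    """4-connected suprathreshold components of a t-map, both signs.

    Positive clusters are components of {t > threshold}, negative ones of
    {t < -threshold}; the mass is the sum of t-values inside, so its sign
    matches the cluster sign.
    """
    t = tmap.t if isinstance(tmap, TMap) else np.asarray(tmap, dtype=float)
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    clusters = []
    for sign in (1, -1):
        supra = t > t_threshold if sign == 1 else t < -t_threshold
        labels, n_comp = ndimage.label(supra, structure=STRUCT_2D)
        for k in range(1, n_comp + 1):
            mask = labels == k
            clusters.append(Cluster(mask=mask, mass=float(t[mask].sum()), sign=sign))
    return clusters


def cluster_pvalues(clusters, null_max_masses) -> list[Cluster]:
    """Attach permutation p-values to clusters.

    ``p = (#{null max |mass| >= |mass|} + 1) / (n_p + 1)`` against the
    permutation distribution of the maximum absolute cluster mass.
    """
    null = np.asarray(null_max_masses, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    out = []
    for c in clusters:
        k_ge = int(np.count_nonzero(null >= abs(c.mass)))
        out.append(replace(c, p_cluster=(k_ge + 1) / (null.size + 1)))
    return out


# ---------------------------------------------------------------------
# sign-flip relabelings and the batched engine


def make_sign_flips(n_subjects, n_perm, rng=None):
    """Sign matrix (P, S) of condition relabelings; row 0 is the identity.

    Per-subject condition swaps in a paired design are sign flips of the
    difference maps.  When 2**S <= n_perm all 2**S distinct relabelings
    are enumerated (row 0 = identity, no duplicates); otherwise ``n_perm``
    rows are sampled uniformly with replacement and the identity is
    prepended.  Returns (signs, exhaustive_flag).
    """
    n_subjects = int(n_subjects)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_subjects <= 62 and 2**n_subjects <= n_perm:
        codes = np.arange(2**n_subjects, dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n_subjects, dtype=np.uint64)) & 1
        signs = 1 - 2 * bits.astype(np.int8)  # code 0 -> all +1 (identity)
        return signs.astype(float), True
    rng = np.random.default_rng(rng)
    sampled = rng.integers(0, 2, size=(int(n_perm), n_subjects)) * 2 - 1
    signs = np.vstack([np.ones((1, n_subjects)), sampled.astype(float)])
    return signs, False


def batch_signflip_tmaps(diffs, signs):
    """Paired t-maps for every sign-flip relabeling in one pass.

    ``diffs`` is (S, F, T) per-subject difference maps; ``signs`` is
    (P, S).  Sign flips leave the per-subject mean square unchanged, so
    t is recovered from the flipped mean alone.  Returns (P, F, T).
    """
    d = np.asarray(diffs, dtype=float)
    n_sub = d.shape[0]
    msq = np.mean(d**2, axis=0)
    m = np.tensordot(signs, d, axes=([1], [0])) / n_sub
    var = (msq[np.newaxis] - m**2) * (n_sub / (n_sub - 1))
    var = np.clip(var, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m * np.sqrt(n_sub) / np.sqrt(var)
    t[~np.isfinite(t)] = 0.0
    return t


def label_clusters_batch(t_batch, t_threshold):
    """Cluster all relabelings' t-maps at once.

    ``t_batch`` is (P, F, T).  Components are labeled in 3D with a
    structure that never connects across relabelings, so one call to
    ``scipy.ndimage.label`` clusters everything.  Returns a dict with the
    flat cluster arrays (signed ``mass``, owning relabeling ``perm``,
    ``sign``) and ``max_abs_mass`` per relabeling (0 where no cluster).
    """
    t_batch = np.asarray(t_batch, dtype=float)
    n_perm_total, n_f, n_t = t_batch.shape
    plane = n_f * n_t
    perm_flat = np.repeat(np.arange(n_perm_total), plane)
    masses_all, perms_all, signs_all = [], [], []
    max_abs = np.zeros(n_perm_total)
    for sign in (1, -1):
        supra = t_batch > t_threshold if sign == 1 else t_batch < -t_threshold
        labels, n_comp = ndimage.label(supra, structure=_STRUCT_BATCH)
        if n_comp == 0:
            continue
        lab_flat = labels.ravel()
        masses = np.bincount(lab_flat, weights=t_batch.ravel(), minlength=n_comp + 1)[1:]
        owner = np.zeros(n_comp + 1, dtype=np.int64)
        owner[lab_flat] = perm_flat  # every voxel of a component shares a slice
        owner = owner[1:]
        np.maximum.at(max_abs, owner, np.abs(masses))
        masses_all.append(masses)
        perms_all.append(owner)
        signs_all.append(np.full(n_comp, sign, dtype=np.int8))
    if masses_all:
        masses = np.concatenate(masses_all)
        perms = np.concatenate(perms_all)
        signs = np.concatenate(signs_all)
    else:
        masses = np.empty(0)
        perms = np.empty(0, dtype=np.int64)
        signs = np.empty(0, dtype=np.int8)
    return {"mass": masses, "perm": perms, "sign": signs, "max_abs_mass": max_abs}
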