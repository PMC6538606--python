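"""The nested permutation test for between-ROI connectivity (PeSCAR).

The test compares time-frequency coherence between two conditions for
every pair of sub-ROIs drawn from two regions of interest.  Per pair, a
paired t-map over the TF plane is thresholded and clustered, and each
cluster receives a sign-flip permutation p-value (family-wise corrected
over time and frequency via the max-|mass| statistic).  Per direction
(C1 > C2 and C2 > C1), the significant cluster masses form an N x M
"original connectivity matrix" whose absolute sum is the total
connectivity A.  The outer null distribution of A is built by re-running
the whole inner procedure under per-subject condition relabelings;
directional p-values are p = (k + 1) / (n_p + 1) with k the number of
null totals strictly exceeding the observed A, Bonferroni-corrected by 2
for the two directions.

Computational strategy: the inner (cluster-level) and outer (total
connectivity) nulls share one set of relabelings.  For each pair, the
t-maps of all relabelings are computed in a single batch; the per-pair
max-|mass| null is built from the non-identity relabelings, and every
relabeling's clusters (including the observed labeling) are ranked
against that same set.  This costs O(n_p * N * M) t-maps instead of
O(n_p^2) and preserves exchangeability.  With S subjects and
2**S <= n_p, all 2**S relabelings are enumerated, making the test exact
and fully deterministic.

Typical use::

    model = PescarModel(dataset, AnalysisConfig.reduced())
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tf as _tf
from .clusters import (
    ClusterStatResult,
    TMap,
    batch_signflip_tmaps,
    cluster_forming_threshold,
    cluster_pvalues,
    extract_clusters,
    label_clusters_batch,
    make_sign_flips,
)
from .simulate import SyntheticDataset

__all__ = [
    "AnalysisConfig",
    "ConnectivityMatrix",
    "NullDistribution",
    "PescarModel",
    "PescarResults",
    "original_matrix",
    "permutation_null",
    "pescar_pvalues",
    "tf_summary_maps",
    "run_pescar",
]

DIRECTIONS = ("C1>C2", "C2>C1")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared across the pipeline.

    ``forming_alpha`` is the two-sided level of the parametric
    cluster-forming threshold (0.05 -> the 97.5th t percentile);
    ``alpha_threshold`` is the cluster-level selection threshold applied
    to permutation cluster p-values when building the original
    connectivity matrices.  The two are deliberately independent.
    ``aggregation`` decides what a pair contributes when several
    same-direction clusters are significant: the largest-|mass| cluster
    (default) or their sum.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.arange(8.0, 46.0, 1.0))
    n_cycles: float = 7.0
    decim: int = 6
    edge_sigmas: float = 2.0
    n_perm: int = 1000
    alpha_threshold: float = 0.05
    forming_alpha: float = 0.05
    aggregation: str = "largest"
    fisher_z: bool = False
    seed: int | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.aggregation not in ("largest", "sum"):
            raise ValueError("aggregation must be 'largest' or 'sum'")
        if not 0 < self.alpha_threshold < 1 or not 0 < self.forming_alpha < 1:
            raise ValueError("thresholds must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def reduced(cls, **overrides):
        """Coarse, fast profile for desk-scale runs and power sweeps."""
        params = dict(
            freqs=np.arange(10.0, 31.0, 2.0), decim=8, n_perm=500
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class ConnectivityMatrix:
    """Directional original connectivity matrix and its total A = sum |a_ij|."""

    direction: str
    a: np.ndarray
    total: float


@dataclass
class NullDistribution:
    """Permutation null of the total connectivity for one direction."""

    direction: str
    values: np.ndarray

    @property
    def n_p(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------
# free-standing operations


def original_matrix(
    cluster_results, shape, alpha_threshold, direction, aggregation="largest"
) -> ConnectivityMatrix:
    """Original connectivity matrix for one direction.

    For each pair, among its clusters of the matching sign with
    ``p_cluster < alpha_threshold``, the entry is the mass of the
    largest-|mass| such cluster (or the sum, per ``aggregation``); zero
    otherwise.  The total is A = sum |a_ij|.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    sign = 1 if direction == "C1>C2" else -1
    a = np.zeros(shape)
    seen = set()
    for res in cluster_results:
        if res.pair in seen:
            raise ValueError(f"duplicate result for pair {res.pair}")
        seen.add(res.pair)
        sig = [
            c
            for c in res.clusters
            if c.sign == sign and c.p_cluster is not None and c.p_cluster < alpha_threshold
        ]
        if not sig:
            continue
        if aggregation == "largest":
            value = max(sig, key=lambda c: abs(c.mass)).mass
        else:
            value = sum(c.mass for c in sig)
        a[res.pair] = value
    if len(seen) != int(np.prod(shape)):
        raise ValueError(
            f"expected {int(np.prod(shape))} pair results, got {len(seen)}"
        )
    return ConnectivityMatrix(direction=direction, a=a, total=float(np.abs(a).sum()))


def pescar_pvalues(a12_total, a21_total, null12, null21):
    """Directional permutation p-values.

    k = #{null values >= A}; p = (k + 1) / (n_p + 1); Bonferroni factor 2
    for the two directions.  Ties count as exceedances, so the fully
    degenerate case (observed and null totals all zero) yields p = 1
    rather than a spurious rejection; for continuous null distributions
    the convention is indistinguishable from strict exceedance.  Returns
    a dict with k, raw and adjusted p per direction.
    """
    n12 = np.asarray(null12.values if isinstance(null12, NullDistribution) else null12)
    n21 = np.asarray(null21.values if isinstance(null21, NullDistribution) else null21)
    if n12.size == 0 or n21.size == 0:
        raise ValueError("null distributions must be populated")
    k12 = int(np.count_nonzero(n12 >= a12_total))
    k21 = int(np.count_nonzero(n21 >= a21_total))
    p12 = (k12 + 1) / (n12.size + 1)
    p21 = (k21 + 1) / (n21.size + 1)
    return {
        "k12": k12,
        "k21": k21,
        "p12": p12,
        "p21": p21,
        "p12_adj": min(1.0, 2.0 * p12),
        "p21_adj": min(1.0, 2.0 * p21),
    }


def tf_summary_maps(cluster_results, alpha_threshold, weighted=False):
    """Sum of significant cluster masks (optionally t-weighted) per direction.

    Unweighted maps count, for every TF point, how many significant
    pair-level clusters cover it; weighted maps sum mask * t-map instead,
    so the weighted map integrates to the summed significant cluster
    masses of that direction.
    """
    results = list(cluster_results)
    if not results:
        raise ValueError("no cluster results")
    shape = results[0].tmap.t.shape
    maps = {d: np.zeros(shape) for d in DIRECTIONS}
    for res in results:
        for c in res.clusters:
            if c.p_cluster is None or not c.p_cluster < alpha_threshold:
                continue
            direction = "C1>C2" if c.sign == 1 else "C2>C1"
            if weighted:
                maps[direction] += np.where(c.mask, res.tmap.t, 0.0)
            else:
                maps[direction] += c.mask.astype(float)
    return maps


def permutation_null(diffs, signs, t_threshold, alpha_threshold, aggregation="largest"):
    """Null distributions of the total connectivity for both directions.

    ``diffs`` is (n_pairs, S, F, T) per-subject condition differences per
    pair; ``signs`` is the shared (P, S) relabeling matrix with the
    identity in row 0 (excluded from the null).  Returns the two
    :class:`NullDistribution` objects; the full engine output is
    available through :class:`PescarModel`.
    """
    engine = _nested_engine(diffs, signs, t_threshold, alpha_threshold, aggregation)
    return (
        NullDistribution("C1>C2", engine["a12_totals"][1:].copy()),
        NullDistribution("C2>C1", engine["a21_totals"][1:].copy()),
    )


def _nested_engine(diffs, signs, t_threshold, alpha_threshold, aggregation):
    """Shared-relabeling nested permutation over all pairs.

    Returns the per-relabeling directional totals (index 0 = observed
    labeling), the observed per-pair t-maps, and each pair's sorted
    max-|mass| null (for attaching observed cluster p-values).
    """
    diffs = np.asarray(diffs, dtype=float)
    n_pairs, n_sub = diffs.shape[:2]
    n_total = signs.shape[0]
    n_null = n_total - 1
    if n_null < 1:
        raise ValueError("need at least one non-identity relabeling")
    a12_tot = np.zeros(n_total)
    a21_tot = np.zeros(n_total)
    t_obs = np.empty((n_pairs,) + diffs.shape[2:])
    sorted_nulls = np.empty((n_pairs, n_null))
    for p in range(n_pairs):
        t_batch = batch_signflip_tmaps(diffs[p], signs)
        t_obs[p] = t_batch[0]
        lab = label_clusters_batch(t_batch, t_threshold)
        sorted_nulls[p] = np.sort(lab["max_abs_mass"][1:])
        if lab["mass"].size == 0:
            continue
        abs_mass = np.abs(lab["mass"])
        # every relabeling's clusters (identity included) are ranked against
        # the max-|mass| set of ALL relabelings: p_c = #{max >= |m|}/n_total.
        # Symmetric across relabelings (exchangeability-preserving); for the
        # identity's clusters it equals (#{null >= |m|} + 1)/(n_null + 1)
        # because the identity's own max always ties-or-exceeds them.
        all_sorted = np.sort(lab["max_abs_mass"])
        k_ge = n_total - np.searchsorted(all_sorted, abs_mass, side="left")
        significant = k_ge / n_total < alpha_threshold
        for sign, totals in ((1, a12_tot), (-1, a21_tot)):
            sel = significant & (lab["sign"] == sign)
            if not np.any(sel):
                continue
            contrib = np.zeros(n_total)
            if aggregation == "largest":
                np.maximum.at(contrib, lab["perm"][sel], abs_mass[sel])
            else:
                np.add.at(contrib, lab["perm"][sel], abs_mass[sel])
            totals += contrib
    return {
        "a12_totals": a12_tot,
        "a21_totals": a21_tot,
        "t_obs": t_obs,
        "sorted_nulls": sorted_nulls,
        "n_null": n_null,
    }


# ---------------------------------------------------------------------
# Model / Results


class PescarModel:
    """Nested permutation test of condition differences in sub-ROI coherence.

    Parameters
    ----------
    data : SyntheticDataset, list of EpochSet, or list of CoherenceMap
        Epoched input is transformed to all-pair coherence first;
        precomputed coherence maps are used as-is.  Every subject must
        appear with exactly two conditions (sorted lexicographically;
        the first plays the role of C1).
    config : AnalysisConfig, optional
    """

    def __init__(self, data, config: AnalysisConfig | None = None):
        self.config = config if config is not None else AnalysisConfig()
        if isinstance(data, SyntheticDataset):
            data = data.epoch_sets
        data = list(data)
        if not data:
            raise ValueError("empty input")
        if isinstance(data[0], _tf.CoherenceMap):
            self._coh_maps = data
            self._epoch_sets = None
        else:
            self._epoch_sets = data
            self._coh_maps = None

    @classmethod
    def from_hdf5(cls, path, config=None):
        from .io import load_dataset

        return cls(load_dataset(path), config=config)

    def _coherence_maps(self):
        if self._coh_maps is None:
            self._coh_maps = _tf.all_pair_coherence(self._epoch_sets, self.config)
        return self._coh_maps

    def _stacked(self):
        """-> (diffs (n_pairs,S,F,T), pair_index, shape, freqs, times, subjects)."""
        maps = self._coherence_maps()
        conditions = sorted({m.condition_id for m in maps})
        if len(conditions) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conditions}")
        subjects = sorted({m.subject_id for m in maps})
        by_key = {(m.subject_id, m.condition_id): m for m in maps}
        ref = maps[0]
        c1 = np.stack([by_key[(s, conditions[0])].coh for s in subjects])
        c2 = np.stack([by_key[(s, conditions[1])].coh for s in subjects])
        if self.config.fisher_z:
            clip = 1.0 - 1e-10
            c1 = np.arctanh(np.clip(c1, 0.0, clip))
            c2 = np.arctanh(np.clip(c2, 0.0, clip))
        diffs = np.transpose(c1 - c2, (1, 0, 2, 3))
        shape = (
            max(i for i, _ in ref.pair_index) + 1,
            max(j for _, j in ref.pair_index) + 1,
        )
        return diffs, list(ref.pair_index), shape, ref.freqs, ref.times, subjects

    def fit(self, n_perm=None, seed=None) -> "PescarResults":
        cfg = self.config
        n_perm = cfg.n_perm if n_perm is None else int(n_perm)
        seed = cfg.seed if seed is None else seed
        diffs, pair_index, shape, freqs, times, subjects = self._stacked()
        n_sub = len(subjects)
        if n_sub < 2:
            raise ValueError("need at least 2 subjects")
        signs, exhaustive = make_sign_flips(n_sub, n_perm, rng=seed)
        t_threshold = cluster_forming_threshold(n_sub - 1, cfg.forming_alpha)
        engine = _nested_engine(
            diffs, signs, t_threshold, cfg.alpha_threshold, cfg.aggregation
        )
        n_null = engine["n_null"]

        # observed per-pair cluster results, ranked against the same nulls
        cluster_results = []
        for k, pair in enumerate(pair_index):
            tmap = TMap(t=engine["t_obs"][k], df=n_sub - 1, freqs=freqs, times=times)
            clusters = cluster_pvalues(
                extract_clusters(tmap, t_threshold), engine["sorted_nulls"][k]
            )
            cluster_results.append(
                ClusterStatResult(
                    pair=pair, tmap=tmap, clusters=clusters, t_threshold=t_threshold
                )
            )

        a12 = original_matrix(
            cluster_results, shape, cfg.alpha_threshold, "C1>C2", cfg.aggregation
        )
        a21 = original_matrix(
            cluster_results, shape, cfg.alpha_threshold, "C2>C1", cfg.aggregation
        )
        null12 = NullDistribution("C1>C2", engine["a12_totals"][1:].copy())
        null21 = NullDistribution("C2>C1", engine["a21_totals"][1:].copy())
        pv = pescar_pvalues(a12.total, a21.total, null12, null21)
        tf_maps = {
            "unweighted": tf_summary_maps(cluster_results, cfg.alpha_threshold, False),
            "weighted": tf_summary_maps(cluster_results, cfg.alpha_threshold, True),
        }
        return PescarResults(
            a12=a12,
            a21=a21,
            null12=null12,
            null21=null21,
            cluster_results=cluster_results,
            tf_maps=tf_maps,
            freqs=np.asarray(freqs),
            times=np.asarray(times),
            pair_shape=shape,
            pair_index=pair_index,
            subjects=list(subjects),
            t_threshold=t_threshold,
            n_null=n_null,
            exhaustive=exhaustive,
            config=replace(cfg),
            seed=seed,
            **pv,
        )


@dataclass
class PescarResults:
    """Fitted PeSCAR test: totals, nulls, p-values, per-pair diagnostics."""

    a12: ConnectivityMatrix
    a21: ConnectivityMatrix
    null12: NullDistribution
    null21: NullDistribution
    k12: int
    k21: int
    p12: float
    p21: float
    p12_adj: float
    p21_adj: float
    cluster_results: list[ClusterStatResult]
    tf_maps: dict
    freqs: np.ndarray
    times: np.ndarray
    pair_shape: tuple[int, int]
    pair_index: list[tuple[int, int]]
    subjects: list
    t_threshold: float
    n_null: int
    exhaustive: bool
    config: AnalysisConfig
    seed: int | None = None

    @property
    def A12(self) -> float:
        return self.a12.total

    @property
    def A21(self) -> float:
        return self.a21.total

    def significant(self, level=0.05) -> bool:
        """Reject the no-difference null in either direction."""
        return min(self.p12_adj, self.p21_adj) < level

    def n_significant_pairs(self, direction) -> int:
        a = self.a12.a if direction == "C1>C2" else self.a21.a
        return int(np.count_nonzero(a))

    def summary(self) -> str:
        n, m = self.pair_shape
        lines = [
            "PeSCAR nested permutation connectivity test",
            "=" * 60,
            f"subjects: {len(self.subjects)}   sub-ROI pairs: {len(self.pair_index)}"
            f" ({n} x {m})",
            f"TF grid: {self.freqs.size} freqs x {self.times.size} times"
            f" ({self.freqs.min():g}-{self.freqs.max():g} Hz,"
            f" {self.times.min():.3f}-{self.times.max():.3f} s)",
            f"cluster-forming |t| threshold: {self.t_threshold:.3f}"
            f" (df={len(self.subjects) - 1})",
            f"relabelings: {self.n_null + 1}"
            f" ({'exhaustive' if self.exhaustive else 'sampled'}),"
            f" null size {self.n_null}",
            "-" * 60,
            f"{'direction':<10}{'A':>12}{'k':>8}{'p':>10}{'p(Bonf)':>10}"
            f"{'sig pairs':>11}",
        ]
        for d, a, k, p, padj in (
            ("C1>C2", self.A12, self.k12, self.p12, self.p12_adj),
            ("C2>C1", self.A21, self.k21, self.p21, self.p21_adj),
        ):
            lines.append(
                f"{d:<10}{a:>12.4f}{k:>8d}{p:>10.4f}{padj:>10.4f}"
                f"{self.n_significant_pairs(d):>11d}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    def save(self, out_dir, plots=False):
        from .io import save_results_bundle

        return save_results_bundle(self, out_dir, plots=plots)

    def plot_matrix(self, direction="C1>C2", ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mat = self.a12.a if direction == "C1>C2" else self.a21.a
        im = ax.imshow(mat, origin="lower", cmap="viridis", aspect="auto")
        ax.set_xlabel("ROI2 sub-ROI")
        ax.set_ylabel("ROI1 sub-ROI")
        ax.set_title(f"original connectivity ({direction})")
        ax.figure.colorbar(im, ax=ax, label="cluster mass")
        return ax

    def plot_tf_map(self, direction="C1>C2", weighted=False, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        kind = "weighted" if weighted else "unweighted"
        arr = self.tf_maps[kind][direction]
        im = ax.pcolormesh(self.times, self.freqs, arr, shading="auto")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(f"{kind} TF map ({direction})")
        ax.figure.colorbar(im, ax=ax)
        return ax


def run_pescar(data, config=None, n_perm=None, seed=None) -> PescarResults:
    """End-to-end convenience wrapper: data in, fitted results out."""
    return PescarModel(data, config=config).fit(n_perm=n_perm, seed=seed)
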