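"""Conventional within-ROI-averaging comparator.

The baseline collapses each ROI to the unweighted mean of its sub-ROI
series, estimates a single TF coherence map per subject/condition, and
runs exactly one cluster-statistics contrast between conditions using
the same t-map, clustering, sign-flip null and p-value conventions as
the PeSCAR inner loop.  Any power difference between the two methods is
therefore attributable to the sub-ROI aggregation alone.  The decision
rule is two-sided at level 0.05 on the minimum cluster p-value (the
max-statistic permutation already controls the family-wise error over
time and frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

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
from .model import AnalysisConfig
from .simulate import SyntheticDataset
from .tf import averaged_roi_coherence

__all__ = ["ConventionalAveragingModel", "ConventionalResults", "run_conventional"]


@dataclass
class ConventionalResults:
    """Single-pair cluster test on the ROI-averaged series."""

    result: ClusterStatResult
    min_cluster_p: float
    null_max_masses: np.ndarray
    n_null: int
    exhaustive: bool
    config: AnalysisConfig
    seed: int | None = None

    def significant(self, level=0.05) -> bool:
        return self.min_cluster_p < level

    def summary(self) -> str:
        n_clusters = len(self.result.clusters)
        lines = [
            "Conventional ROI-averaging cluster test",
            "=" * 60,
            f"clusters: {n_clusters}   min cluster p: {self.min_cluster_p:.4f}",
            f"cluster-forming |t| threshold: {self.result.t_threshold:.3f}",
            f"relabelings: {self.n_null + 1}"
            f" ({'exhaustive' if self.exhaustive else 'sampled'})",
            "-" * 60,
            f"{'sign':<8}{'mass':>12}{'p':>10}",
        ]
        for c in sorted(self.result.clusters, key=lambda c: c.p_cluster):
            lines.append(
                f"{'C1>C2' if c.sign == 1 else 'C2>C1':<8}{c.mass:>12.4f}"
                f"{c.p_cluster:>10.4f}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)


class ConventionalAveragingModel:
    """Conventional comparator sharing PeSCAR's cluster machinery."""

    def __init__(self, data, config: AnalysisConfig | None = None):
        self.config = config if config is not None else AnalysisConfig()
        if isinstance(data, SyntheticDataset):
            data = data.epoch_sets
        self._epoch_sets = list(data)

    def fit(self, n_perm=None, seed=None, signs=None) -> ConventionalResults:
        cfg = self.config
        n_perm = cfg.n_perm if n_perm is None else int(n_perm)
        seed = cfg.seed if seed is None else seed
        maps = averaged_roi_coherence(self._epoch_sets, cfg)
        conditions = sorted({m.condition_id for m in maps})
        if len(conditions) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conditions}")
        subjects = sorted({m.subject_id for m in maps})
        by_key = {(m.subject_id, m.condition_id): m for m in maps}
        c1 = np.stack([by_key[(s, conditions[0])].coh[0] for s in subjects])
        c2 = np.stack([by_key[(s, conditions[1])].coh[0] for s in subjects])
        if cfg.fisher_z:
            clip = 1.0 - 1e-10
            c1 = np.arctanh(np.clip(c1, 0.0, clip))
            c2 = np.arctanh(np.clip(c2, 0.0, clip))
        n_sub = len(subjects)
        if signs is None:
            signs, exhaustive = make_sign_flips(n_sub, n_perm, rng=seed)
        else:
            exhaustive = False
        t_threshold = cluster_forming_threshold(n_sub - 1, cfg.forming_alpha)
        t_batch = batch_signflip_tmaps(c1 - c2, signs)
        lab = label_clusters_batch(t_batch, t_threshold)
        null = lab["max_abs_mass"][1:]
        ref = maps[0]
        tmap = TMap(t=t_batch[0], df=n_sub - 1, freqs=ref.freqs, times=ref.times)
        clusters = cluster_pvalues(extract_clusters(tmap, t_threshold), null)
        min_p = min((c.p_cluster for c in clusters), default=1.0)
        return ConventionalResults(
            result=ClusterStatResult(
                pair=(0, 0), tmap=tmap, clusters=clusters, t_threshold=t_threshold
            ),
            min_cluster_p=float(min_p),
            null_max_masses=null.copy(),
            n_null=int(null.size),
            exhaustive=exhaustive,
            config=replace(cfg),
            seed=seed,
        )


def run_conventional(data, config=None, n_perm=None, seed=None) -> ConventionalResults:
    """End-to-end convenience wrapper for the averaging baseline."""
    return ConventionalAveragingModel(data, config=config).fit(n_perm=n_perm, seed=seed)
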