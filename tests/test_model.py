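"""Original connectivity matrices, TF summary maps, nested-test behaviour."""

import dataclasses

import numpy as np
import pytest
from conftest import make_synthetic_coherence_maps

from pescar import (
    AnalysisConfig,
    Cluster,
    ClusterStatResult,
    PescarModel,
    TMap,
    original_matrix,
    pescar_pvalues,
    run_pescar,
    tf_summary_maps,
)


def _result(pair, clusters, shape=(3, 3)):
    t = np.zeros((4, 5))
    for c in clusters:
        t[c.mask] = np.sign(c.mass) * 3.0
    return ClusterStatResult(
        pair=pair, tmap=TMap(t=t, df=7), clusters=clusters, t_threshold=2.0
    )


def _cluster(mass, p, cells):
    mask = np.zeros((4, 5), dtype=bool)
    for cell in cells:
        mask[cell] = True
    return Cluster(mask=mask, mass=mass, sign=1 if mass > 0 else -1, p_cluster=p)


class TestOriginalMatrix:
    def _results_with_masses(self, masses):
        out = []
        k = 0
        for i in range(2):
            for j in range(2):
                clusters = []
                if k < len(masses):
                    m, p = masses[k]
                    clusters = [_cluster(m, p, [(0, k)])]
                out.append(_result((i, j), clusters))
                k += 1
        return out

    def test_no_significant_pairs_gives_zero_totals(self):
        res = self._results_with_masses([(5.0, 0.9), (-4.0, 0.5)])
        m12 = original_matrix(res, (2, 2), 0.05, "C1>C2")
        m21 = original_matrix(res, (2, 2), 0.05, "C2>C1")
        assert m12.total == 0.0 and m21.total == 0.0
        assert np.all(m12.a == 0.0)

    def test_mixed_signed_masses_sum_by_direction(self):
        # significant masses {+5, +3, -4} -> A12 = 8, A21 = 4
        res = self._results_with_masses([(5.0, 0.01), (3.0, 0.01), (-4.0, 0.01)])
        m12 = original_matrix(res, (2, 2), 0.05, "C1>C2")
        m21 = original_matrix(res, (2, 2), 0.05, "C2>C1")
        assert m12.total == pytest.approx(8.0)
        assert m21.total == pytest.approx(4.0)
        assert m21.a[(1, 0)] == pytest.approx(-4.0)  # signed entry

    def test_single_significant_cluster(self):
        res = self._results_with_masses([(12.5, 0.001)])
        assert original_matrix(res, (2, 2), 0.05, "C1>C2").total == pytest.approx(12.5)
        assert original_matrix(res, (2, 2), 0.05, "C2>C1").total == 0.0

    def test_largest_vs_sum_aggregation(self):
        clusters = [_cluster(5.0, 0.01, [(0, 0)]), _cluster(3.0, 0.01, [(2, 2)])]
        res = [_result((0, 0), clusters)]
        largest = original_matrix(res, (1, 1), 0.05, "C1>C2", "largest")
        summed = original_matrix(res, (1, 1), 0.05, "C1>C2", "sum")
        assert largest.total == pytest.approx(5.0)
        assert summed.total == pytest.approx(8.0)

    def test_missing_pair_is_an_error(self):
        res = self._results_with_masses([(5.0, 0.01)])[:3]
        with pytest.raises(ValueError):
            original_matrix(res, (2, 2), 0.05, "C1>C2")


class TestPescarPvalues:
    def test_formula_cases(self):
        out = pescar_pvalues(10.0, 0.0, np.linspace(0.1, 5.0, 1000), np.ones(1000))
        assert out["p12"] == pytest.approx(1 / 1001)
        assert out["p12_adj"] == pytest.approx(2 / 1001)
        assert out["p21"] == pytest.approx(1.0)  # A=0, all null values > 0
        assert out["p21_adj"] == 1.0  # min(1, 2p) caps at 1
        out2 = pescar_pvalues(1.0, 0.2, np.r_[np.full(39, 2.0), np.full(960, 0.5)],
                              np.full(999, 0.5))
        assert out2["k12"] == 39
        assert out2["p12"] == pytest.approx(0.04)
        assert out2["p21"] == pytest.approx(1.0)  # ties count as exceedances


class TestTFSummaryMaps:
    def test_counting_and_weighting(self):
        shared_cells = [(1, 1), (1, 2)]
        res = [
            _result((0, 0), [_cluster(6.0, 0.01, shared_cells)]),
            _result((0, 1), [_cluster(6.0, 0.01, shared_cells)]),
            _result((1, 0), [_cluster(-3.0, 0.5, [(3, 4)])]),  # not significant
            _result((1, 1), []),
        ]
        unw = tf_summary_maps(res, 0.05, weighted=False)
        assert unw["C1>C2"][1, 1] == 2 and unw["C1>C2"][1, 2] == 2
        assert unw["C1>C2"].sum() == 4
        assert np.all(unw["C2>C1"] == 0)
        wt = tf_summary_maps(res, 0.05, weighted=True)
        # weighted map integrates to the summed significant masses
        assert wt["C1>C2"].sum() == pytest.approx(12.0)


class TestNestedTest:
    def test_identical_conditions_give_p_of_one(self):
        rng = np.random.default_rng(0)
        maps = make_synthetic_coherence_maps(rng, n_subjects=5)
        for m in maps:  # overwrite C2 with C1's values per subject
            if m.condition_id == "C2":
                twin = next(
                    x for x in maps
                    if x.subject_id == m.subject_id and x.condition_id == "C1"
                )
                m.coh = twin.coh.copy()
        res = PescarModel(maps, AnalysisConfig(n_perm=100)).fit()
        assert res.A12 == 0.0 and res.A21 == 0.0
        assert res.p12_adj == 1.0 and res.p21_adj == 1.0

    def test_subject_order_invariance_and_determinism(self):
        rng = np.random.default_rng(1)
        maps = make_synthetic_coherence_maps(
            rng, 5, effects={(0, 0): (slice(1, 4), slice(2, 6), 0.5)}
        )
        cfg = AnalysisConfig(n_perm=100, alpha_threshold=0.2)
        r1 = PescarModel(maps, cfg).fit()
        r2 = PescarModel(list(reversed(maps)), cfg).fit()
        assert (r1.p12, r1.p21, r1.A12, r1.A21) == (r2.p12, r2.p21, r2.A12, r2.A21)
        np.testing.assert_array_equal(r1.null12.values, r2.null12.values)
        r3 = run_pescar(maps, cfg)
        assert r3.p12 == r1.p12 and r3.A12 == r1.A12

    def test_strong_effect_detected_with_minimal_p(self):
        rng = np.random.default_rng(2)
        maps = make_synthetic_coherence_maps(
            rng, 8, effects={(0, 0): (slice(1, 4), slice(2, 6), 0.5)}
        )
        res = PescarModel(maps, AnalysisConfig(n_perm=500)).fit()
        assert res.exhaustive and res.n_null == 255
        assert res.p12 == pytest.approx(1 / 256)
        assert res.significant()
        assert res.a12.a[0, 0] > 0
        # summary is printable and mentions both directions
        s = res.summary()
        assert "C1>C2" in s and "C2>C1" in s

    def test_zero_total_gives_p_one(self):
        # A = 0 can never look extreme: every null total (>= 0) ties or
        # exceeds it, so the raw p must be exactly 1
        rng = np.random.default_rng(3)
        maps = make_synthetic_coherence_maps(rng, 5)
        res = PescarModel(maps, AnalysisConfig(n_perm=100, alpha_threshold=0.3)).fit()
        for a_total, p in ((res.A12, res.p12), (res.A21, res.p21)):
            if a_total == 0.0:
                assert p == pytest.approx(1.0)

    def test_directional_p_superuniform_under_exchangeability(self):
        # exchangeable conditions: P(p12 <= q) <= q (+MC margin) on the grid
        rng = np.random.default_rng(4)
        n_rep = 200
        p12s = np.empty(n_rep)
        cfg = AnalysisConfig(n_perm=2**5, alpha_threshold=0.2)
        for r in range(n_rep):
            maps = make_synthetic_coherence_maps(rng, 5, pair_shape=(2, 2), grid=(5, 6))
            p12s[r] = PescarModel(maps, cfg).fit().p12
        for q in (1 / 8, 1 / 4, 1 / 2):
            rate = np.mean(p12s <= q)
            assert rate <= q + 3 * np.sqrt(q * (1 - q) / n_rep)
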