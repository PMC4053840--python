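"""EMD, control selection, PCA, permutation test, GSEA-like test, BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourc.epigenome_enrichment import (bh_adjust, emd_track,
                                        enrichment_score, gsea_like_test,
                                        pca_prey_control, permutation_test,
                                        select_controls, window_emd)
from fourc.interaction_windows import build_windows
from tests.conftest import make_flat_map


def _intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _single_frag_map(length=100):
    fmap = make_flat_map(1, ["cS"], frag_len=length, chrom_len=4 * length)
    return fmap


class TestEMD:
    def test_partial_coverage(self):
        fmap = _single_frag_map(100)
        track = emd_track(_intervals([("c", 10, 35)]), fmap)
        assert track.frag_density[0] == pytest.approx(0.25)

    def test_overlapping_intervals_unioned(self):
        fmap = _single_frag_map(100)
        track = emd_track(_intervals([("c", 10, 35), ("c", 20, 50)]), fmap)
        assert track.frag_density[0] == pytest.approx(0.40)

    def test_bounds_zero_and_one(self):
        fmap = _single_frag_map(100)
        assert emd_track(_intervals([]), fmap).frag_density[0] == 0.0
        full = emd_track(_intervals([("c", 0, 100)]), fmap)
        assert full.frag_density[0] == 1.0

    def test_out_of_bounds_interval_errors(self):
        fmap = _single_frag_map(100)
        with pytest.raises(ValueError):
            emd_track(_intervals([("c", 0, 10 ** 9)]), fmap)

    def test_window_mean_of_member_fragments(self):
        fmap = make_flat_map(4, ["cS"], frag_len=100)
        track = emd_track(_intervals([("c", 0, 100), ("c", 100, 150)]), fmap)
        windows = build_windows(fmap, 4, 4)
        dens = window_emd(track, windows)
        assert dens[0] == pytest.approx((1.0 + 0.5 + 0 + 0) / 4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 9990), st.integers(1, 500)),
                    min_size=0, max_size=30))
    def test_matches_per_base_mask_oracle(self, raw):
        fmap = _single_frag_map(10_000)
        iv = [("c", s, min(s + l, 10_000)) for s, l in raw]
        mask = np.zeros(10_000, dtype=bool)
        for _, s, e in iv:
            mask[s:e] = True
        track = emd_track(_intervals(iv), fmap)
        assert track.frag_density[0] == pytest.approx(mask.mean())


class TestControls:
    def _windows(self, n=40):
        t = build_windows(make_flat_map(n * 5, ["cS"]), 5, 5)
        t.df["P"] = 0.5
        return t

    def test_controls_disjoint_from_preys(self):
        t = self._windows()
        prey = np.zeros(40, dtype=bool)
        prey[:10] = True
        ctrl = select_controls(t, prey, n=20, seed=1)
        assert not set(ctrl) & set(np.flatnonzero(prey))
        assert len(ctrl) == 20

    def test_seed_determinism(self):
        t = self._windows()
        prey = np.zeros(40, dtype=bool)
        a = select_controls(t, prey, n=10, seed=4)
        b = select_controls(t, prey, n=10, seed=4)
        c = select_controls(t, prey, n=10, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_small_pool_samples_with_replacement_and_warns(self):
        t = self._windows()
        prey = np.zeros(40, dtype=bool)
        prey[:25] = True  # pool of 15 < n = 50
        with pytest.warns(UserWarning):
            ctrl = select_controls(t, prey, n=50, seed=2)
        assert len(ctrl) == 50

    def test_empty_pool_errors(self):
        t = self._windows()
        with pytest.raises(ValueError):
            select_controls(t, np.ones(40, dtype=bool), n=5, seed=0)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (6, 4)))
        _, frac, _ = pca_prey_control(X)
        assert frac.sum() == pytest.approx(1.0)

    def test_dominant_axis_matches_eigendecomposition(self, rng):
        base = rng.normal(0, 1, 50)
        X = np.column_stack([base * 3 + rng.normal(0, 0.1, 50),
                             base * -1 + rng.normal(0, 0.1, 50)])
        loadings, frac, scores = pca_prey_control(pd.DataFrame(X))
        cov = np.cov(X, rowvar=False)
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        cos = abs(np.dot(loadings[:, 0], lead))
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert frac[0] > 0.95

    def test_constant_matrix_gives_zero_scores(self):
        X = pd.DataFrame(np.full((4, 3), 2.5))
        loadings, frac, scores = pca_prey_control(X)
        assert np.all(scores == 0) and np.all(frac == 0)

    def test_anticorrelated_groups_separate_on_pc1(self, rng):
        # heterochromatin-like rows: feature A high, B low; euchromatic
        # rows mirrored
        het = np.column_stack([rng.normal(0.6, 0.03, 5),
                               rng.normal(0.1, 0.03, 5)])
        eu = np.column_stack([rng.normal(0.1, 0.03, 5),
                              rng.normal(0.6, 0.03, 5)])
        X = pd.DataFrame(np.vstack([het, eu]))
        _, _, scores = pca_prey_control(X)
        pc1 = scores[:, 0]
        assert set(np.sign(pc1[:5])) != set(np.sign(pc1[5:]))
        assert len(set(np.sign(pc1[:5]))) == 1


def _exhaustive_perm_p(prey_vals, ctrl_vals, gte=False):
    """Enumerate every split of the pooled values into two equal groups."""
    pool = np.asarray(list(prey_vals) + list(ctrl_vals), dtype=float)
    n = len(prey_vals)
    real = abs(np.mean(prey_vals) - np.mean(ctrl_vals))
    diffs = []
    for combo in itertools.combinations(range(len(pool)), n):
        g1 = pool[list(combo)]
        g2 = np.delete(pool, list(combo))
        diffs.append(abs(g1.mean() - g2.mean()))
    diffs = np.asarray(diffs)
    return ((diffs >= real) if gte else (diffs > real)).mean()


class TestPermutationTest:
    def _run(self, prey_vals, ctrl_vals, n_reps=4000, gte=False):
        emd = np.asarray(list(prey_vals) + list(ctrl_vals), dtype=float)
        sets = {"vp": {"prey": np.arange(len(prey_vals)),
                       "control_pool": np.arange(len(prey_vals), len(emd))}}
        res = permutation_test({"f": emd}, sets, n_reps=n_reps,
                               n_sample=len(prey_vals), seed=9, gte=gte)
        return res["f"]

    def test_extreme_separation_gives_p_zero(self):
        r = self._run([1.0] * 3, [0.0] * 3, n_reps=500)
        assert r.real_diff_mean == pytest.approx(1.0)
        assert r.p == 0.0

    def test_degenerate_all_equal(self):
        r = self._run([0.4] * 3, [0.4] * 3, n_reps=200)
        assert r.p == 0.0  # strict '>' finds nothing larger
        r2 = self._run([0.4] * 3, [0.4] * 3, n_reps=200, gte=True)
        assert r2.p == 1.0

    def test_three_plus_three_matches_enumeration(self):
        prey = [0.9, 0.7, 0.8]
        ctrl = [0.2, 0.4, 0.1]
        exact = _exhaustive_perm_p(prey, ctrl)
        r = self._run(prey, ctrl, n_reps=20_000)
        se = 3 * np.sqrt(max(exact * (1 - exact), 1e-4) / 20_000)
        assert abs(r.p - exact) <= max(se, 0.01)

    def test_exchangeable_data_rarely_significant(self, rng):
        hits = 0
        for trial in range(20):
            vals = rng.normal(0.5, 0.1, 60)
            emd = vals
            sets = {"vp": {"prey": np.arange(30),
                           "control_pool": np.arange(30, 60)}}
            res = permutation_test({"f": emd}, sets, n_reps=300,
                                   n_sample=25, seed=trial)
            if res["f"].p < 0.05:
                hits += 1
        assert hits <= 4  # >= 80% of exchangeable runs stay non-significant

    def test_shifted_mean_detected(self, rng):
        hits = 0
        for trial in range(20):
            prey = rng.normal(0.7, 0.1, 30)   # 2 sd shift
            ctrl = rng.normal(0.5, 0.1, 30)
            emd = np.concatenate([prey, ctrl])
            sets = {"vp": {"prey": np.arange(30),
                           "control_pool": np.arange(30, 60)}}
            res = permutation_test({"f": emd}, sets, n_reps=300,
                                   n_sample=25, seed=100 + trial)
            if res["f"].p < 0.01:
                hits += 1
        assert hits >= 19


def _exhaustive_gsea(emd, m):
    """Exact ES null by enumerating all m-subsets of the regions."""
    n = len(emd)
    out = []
    for combo in itertools.combinations(range(n), m):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        out.append(enrichment_score(emd, mask))
    return np.asarray(out)


class TestGSEALike:
    def test_hand_computed_example(self):
        # n=4, m=1, test region ranked 2nd by EMD:
        # weights (-1, 3, -1, -1) -> cumulative (-1, 2, 1, 0) -> ES = 2
        emd = np.array([0.9, 0.8, 0.7, 0.6])
        mask = np.array([False, True, False, False])
        assert enrichment_score(emd, mask) == pytest.approx(2.0)

    def test_weights_sum_to_zero_final_cumsum_zero(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(1, n))
            emd = rng.random(n)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, m, replace=False)] = True
            order = np.argsort(-emd, kind="stable")
            w = np.where(mask[order], (n - m) / m, -1.0)
            assert w.sum() == pytest.approx(0.0)
            assert np.cumsum(w)[-1] == pytest.approx(0.0)

    def test_es_invariant_to_sort_reversal(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            m = int(rng.integers(1, n))
            emd = rng.random(n)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, m, replace=False)] = True
            assert enrichment_score(emd, mask) == pytest.approx(
                enrichment_score(-emd, mask))

    def test_full_test_set_gives_zero_es(self):
        emd = np.array([0.3, 0.2, 0.1])
        sets = {"vp": {"regions": np.arange(3), "test": np.arange(3)}}
        res = gsea_like_test({"f": emd}, sets, n_rand=50, seed=0)
        assert res["f"].mean_es == 0.0

    def test_empirical_p_matches_enumeration(self):
        emd = np.array([0.95, 0.8, 0.6, 0.4])
        sets = {"vp": {"regions": np.arange(4), "test": np.array([0])}}
        res = gsea_like_test({"f": emd}, sets, n_rand=20_000, seed=3)
        null = _exhaustive_gsea(emd, 1)
        exact = (null >= res["f"].mean_es).mean()
        se = 3 * np.sqrt(max(exact * (1 - exact), 1e-4) / 20_000)
        assert abs(res["f"].p - exact) <= max(se, 0.01)

    @pytest.mark.parametrize("n,m", [(5, 2), (8, 3), (6, 1)])
    def test_null_distribution_matches_enumeration(self, n, m, rng):
        emd = np.sort(rng.random(n))[::-1].copy()
        sets = {"vp": {"regions": np.arange(n),
                       "test": np.arange(m)}}  # top-ranked regions
        res = gsea_like_test({"f": emd}, sets, n_rand=20_000, seed=7)
        null = _exhaustive_gsea(emd, m)
        exact = (null >= res["f"].mean_es).mean()
        assert abs(res["f"].p - exact) <= max(
            3 * np.sqrt(max(exact * (1 - exact), 1e-4) / 20_000), 0.01)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_and_order_preserved(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # order preservation: smaller p never gets a larger q
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
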