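"""Correlation/clustering, distance decay, arm RPM, dist0.5, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from fourc.architecture_stats import (DecayProfile, arm_class_rpm,
                                      centromere_regressions,
                                      decay_bin_centers, decay_profile,
                                      dist50_per_arm, fit_decay_exponent,
                                      loess, replicate_correlation,
                                      viewpoint_cen_distance)
from fourc.genome_digest import Viewpoint
from fourc.interaction_windows import build_windows, window_values
from fourc.read_processing import FragmentCounts
from tests.conftest import make_flat_map


def _tracks(read_sums_by_sample):
    tracks = []
    for sample, sums in read_sums_by_sample.items():
        t = build_windows(make_flat_map(len(sums) * 5, ["cS"]), 5, 5)
        t.df["read_sum"] = np.asarray(sums, dtype=float)
        t.sample = sample
        tracks.append(t)
    return tracks


class TestReplicateCorrelation:
    def test_identical_tracks_rho_one(self):
        tracks = _tracks({"a": [1, 5, 3, 9], "b": [1, 5, 3, 9]})
        cm = replicate_correlation(tracks)
        assert cm.rho[0, 1] == pytest.approx(1.0)

    def test_rank_reversed_rho_minus_one(self):
        tracks = _tracks({"a": [1, 2, 3, 4], "b": [9, 7, 5, 2]})
        cm = replicate_correlation(tracks)
        assert cm.rho[0, 1] == pytest.approx(-1.0)

    def test_replicate_pairs_merge_before_cross_pairs(self, rng):
        shared1 = rng.normal(0, 1, 200)
        shared2 = rng.normal(0, 1, 200)
        data = {
            "v1_a": shared1 + rng.normal(0, 0.1, 200),
            "v1_b": shared1 + rng.normal(0, 0.1, 200),
            "v2_a": shared2 + rng.normal(0, 0.1, 200),
            "v2_b": shared2 + rng.normal(0, 0.1, 200),
        }
        cm = replicate_correlation(_tracks(data))
        # first two merges join the planted replicate pairs
        first_merges = {frozenset(map(int, row[:2])) for row in cm.linkage[:2]}
        assert first_merges == {frozenset({0, 1}), frozenset({2, 3})}

    def test_fewer_than_two_samples_error(self):
        with pytest.raises(ValueError):
            replicate_correlation(_tracks({"a": [1, 2]}))


def _arm_map_with_vp(n=3000, frag_len=4000):
    """One chromosome, viewpoint at the start of the S arm."""
    fmap = make_flat_map(n, ["cS"], frag_len=frag_len,
                         chrom_len=2 * n * frag_len + 100)
    vp = Viewpoint("v", "c", position=50, primer_seq="AAAA", fragment=0)
    return fmap, vp


class TestDecayProfile:
    def test_default_binning_has_41_centers(self):
        centers = decay_bin_centers()
        assert len(centers) == 41
        assert centers[0] == pytest.approx(3.0)
        assert centers[-1] == pytest.approx(7.0)

    def test_point_mass_lands_in_its_bin(self):
        fmap, vp = _arm_map_with_vp(n=100, frag_len=100)
        counts = np.zeros(100)
        # fragment midpoint at 10050 -> distance 10000 from vp at 50
        counts[100 // 100 * 100 - 0 - 1] = 0  # noop, clarity only
        frag = 100  # midpoint = frag*100 + 50
        counts = np.zeros(100)
        counts[99] = 50.0  # midpoint 9950, distance 9900 -> log10 3.9957
        fc = FragmentCounts("v", "s", counts)
        prof = decay_profile(fc, vp, fmap)
        assert prof.raw_prob.sum() == pytest.approx(1.0)
        assert prof.raw_prob[np.argmin(np.abs(prof.centers - 4.0))] == \
            pytest.approx(1.0)

    def test_probabilities_normalized_on_any_input(self, rng):
        fmap, vp = _arm_map_with_vp(n=500, frag_len=2000)
        fc = FragmentCounts("v", "s", rng.poisson(3, 500).astype(float))
        prof = decay_profile(fc, vp, fmap)
        assert prof.raw_prob.sum() == pytest.approx(1.0)

    def test_no_reads_in_range_errors(self):
        fmap, vp = _arm_map_with_vp(n=100, frag_len=100)
        with pytest.raises(ValueError):
            decay_profile(FragmentCounts("v", "s", np.zeros(100)), vp, fmap)


class TestDecayFit:
    def _power_profile(self, gamma):
        centers = decay_bin_centers()
        raw = (10.0 ** centers) ** gamma
        raw /= raw.sum()
        return DecayProfile(centers, raw, raw * 0, raw * 0 + 1)

    @pytest.mark.parametrize("use_loess", [True, False])
    def test_exact_power_law_recovered(self, use_loess):
        prof = self._power_profile(-0.8)
        slope, fit_p, _ = fit_decay_exponent(prof, use_loess=use_loess)
        assert slope == pytest.approx(-0.8, abs=1e-3)

    def test_flat_profile_zero_slope(self):
        centers = decay_bin_centers()
        raw = np.full(len(centers), 1.0 / len(centers))
        prof = DecayProfile(centers, raw, raw * 0, raw * 0 + 1)
        slope, _, _ = fit_decay_exponent(prof)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_slope_invariant_to_library_scaling(self, rng):
        fmap, vp = _arm_map_with_vp(n=2500, frag_len=4000)
        d = np.abs(fmap.midpoints() - vp.position)
        w = np.maximum(d, 1e3) ** -0.73
        counts = rng.multinomial(100_000, w / w.sum()).astype(float)
        s1, _, _ = fit_decay_exponent(decay_profile(
            FragmentCounts("v", "s", counts), vp, fmap))
        s2, _, _ = fit_decay_exponent(decay_profile(
            FragmentCounts("v", "s", counts * 7.5), vp, fmap))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_loess_insensitive_to_span(self, rng):
        fmap, vp = _arm_map_with_vp(n=2500, frag_len=4000)
        d = np.abs(fmap.midpoints() - vp.position)
        w = np.maximum(d, 1e3) ** -0.73
        counts = rng.multinomial(100_000, w / w.sum()).astype(float)
        prof = decay_profile(FragmentCounts("v", "s", counts), vp, fmap)
        slopes = [fit_decay_exponent(prof, span=s)[0] for s in (0.5, 0.75, 1.0)]
        assert max(slopes) - min(slopes) < 0.05

    def test_loess_reproduces_quadratic_exactly(self):
        # local quadratic regression is exact on a global quadratic
        x = np.linspace(0, 5, 30)
        y = 2.0 - 1.5 * x + 0.3 * x ** 2
        pred = loess(x, y, x, span=0.75, degree=2)
        np.testing.assert_allclose(pred, y, atol=1e-8)


def _two_chrom_map():
    return make_flat_map(100, ["c1S", "c1L", "c2S", "c2L"], frag_len=1000,
                         chrom_len=500_000)


class TestArmClassRPM:
    def _vps(self, fmap):
        # viewpoints on c1S and c2L
        return [Viewpoint("v1", "c1", 500, "AAAA", fragment=0),
                Viewpoint("v2", "c2", 399_500, "AAAA", fragment=399)]

    def test_all_reads_on_viewpoint_arm(self):
        fmap = _two_chrom_map()
        vps = self._vps(fmap)
        counts = np.zeros(400)
        counts[:100] = 5.0   # all on c1S (v1's arm)
        cbv = {"v1": FragmentCounts("v1", "s", counts),
               "v2": FragmentCounts("v2", "s", counts)}
        arm_table, class_table, _ = arm_class_rpm(cbv, fmap, vps)
        row = class_table[class_table["viewpoint"] == "v1"].iloc[0]
        assert row["viewpoint_rpm"] == pytest.approx(1e6)
        assert row["cis_rpm"] == 0 and row["trans_rpm"] == 0

    def test_rpm_sums_to_one_million_per_viewpoint(self, rng):
        fmap = _two_chrom_map()
        vps = self._vps(fmap)
        cbv = {v.name: FragmentCounts(v.name, "s",
                                      rng.poisson(4, 400).astype(float) + 1)
               for v in vps}
        arm_table, _, _ = arm_class_rpm(cbv, fmap, vps)
        sums = arm_table.groupby("viewpoint")["rpm"].sum()
        assert np.allclose(sums, 1e6)

    def test_masking_removes_exactly_the_window(self):
        fmap = _two_chrom_map()
        vps = self._vps(fmap)
        counts = np.ones(400)
        cbv = {v.name: FragmentCounts(v.name, "s", counts.copy())
               for v in vps}
        _, class_table, _ = arm_class_rpm(cbv, fmap, vps, mask_mb=10_000)
        row = class_table[class_table["viewpoint"] == "v1"].iloc[0]
        # v1 at 500; masking keeps only midpoints strictly beyond +-10 kb:
        # fragments 0..10 (midpoints 500..10500) are removed, 89 remain
        assert row["viewpoint_masked_rpm"] == pytest.approx(
            row["viewpoint_rpm"] * 89 / 100)

    def test_paired_t_matches_closed_form(self):
        fmap = make_flat_map(50, ["c1S", "c1L", "c2S", "c2L", "c3S", "c3L"],
                             frag_len=1000, chrom_len=500_000)
        vps = [Viewpoint("v1", "c1", 500, "A", fragment=0),
               Viewpoint("v2", "c2", 500, "A", fragment=100),
               Viewpoint("v3", "c3", 500, "A", fragment=200)]
        rng = np.random.default_rng(4)
        cbv = {v.name: FragmentCounts(v.name, "s",
                                      rng.poisson(6, 300).astype(float) + 1)
               for v in vps}
        _, class_table, ttests = arm_class_rpm(cbv, fmap, vps)
        d = (class_table["viewpoint_rpm"] - class_table["cis_rpm"]).to_numpy()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert ttests["viewpoint_vs_cis"]["t"] == pytest.approx(t_hand)

    def test_single_arm_chromosome_rejected(self):
        fmap = make_flat_map(50, ["c1S", "c1L", "c2S"], frag_len=1000,
                             chrom_len=500_000)
        vps = [Viewpoint("v1", "c1", 500, "A", fragment=0),
               Viewpoint("v2", "c2", 500, "A", fragment=100)]
        cbv = {v.name: FragmentCounts(v.name, "s", np.ones(150))
               for v in vps}
        with pytest.raises(ValueError):
            arm_class_rpm(cbv, fmap, vps)


class TestDist50:
    def test_point_mass_at_relative_distance(self):
        fmap = make_flat_map(100, ["c1S", "c1L"], frag_len=1000,
                             chrom_len=200_000)
        # arm length for c1L: chrom_len - cen_end = 200000 - 100010 = 99990
        vp = Viewpoint("v", "c1", 500, "A", fragment=0)  # on c1S
        counts = np.zeros(200)
        counts[129] = 10.0  # c1L fragment with cen_dist 30000
        t = dist50_per_arm(FragmentCounts("v", "s", counts), fmap, vp)
        row = t[t["arm"] == "c1L"].iloc[0]
        assert row["dist50_abs"] == pytest.approx(30_000)
        assert row["dist50_rel"] == pytest.approx(30_000 / 99_990, rel=1e-3)

    def test_uniform_reads_give_half(self):
        fmap = make_flat_map(100, ["c1S", "c1L"], frag_len=1000,
                             chrom_len=220_000)
        vp = Viewpoint("v", "c1", 500, "A", fragment=0)
        counts = np.ones(200)
        t = dist50_per_arm(FragmentCounts("v", "s", counts), fmap, vp)
        row = t[t["arm"] == "c1L"].iloc[0]
        assert row["dist50_rel"] == pytest.approx(0.5, abs=0.05)

    def test_viewpoint_arm_excluded_and_bounds(self, rng):
        fmap = make_flat_map(100, ["c1S", "c1L"], frag_len=1000,
                             chrom_len=220_000)
        vp = Viewpoint("v", "c1", 500, "A", fragment=0)
        counts = rng.poisson(3, 200).astype(float)
        t = dist50_per_arm(FragmentCounts("v", "s", counts), fmap, vp)
        assert "c1S" not in set(t["arm"])
        ok = t["dist50_rel"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_zero_read_arm_gets_sentinel(self):
        fmap = make_flat_map(100, ["c1S", "c1L"], frag_len=1000,
                             chrom_len=220_000)
        vp = Viewpoint("v", "c1", 500, "A", fragment=0)
        t = dist50_per_arm(FragmentCounts("v", "s", np.zeros(200)), fmap, vp)
        assert t["dist50_abs"].isna().all()


class TestCentromereRegressions:
    def test_arcsine_sqrt_closed_form(self):
        assert np.arcsin(np.sqrt(0.0)) == 0.0
        assert np.arcsin(np.sqrt(1.0)) == pytest.approx(np.pi / 2)
        assert np.arcsin(np.sqrt(0.5)) == pytest.approx(np.pi / 4)

    def _fixture(self, rel_positions):
        arms = []
        vps = []
        for i, rel in enumerate(rel_positions):
            arms += [f"c{i+1}S", f"c{i+1}L"]
        fmap = make_flat_map(100, arms, frag_len=1000, chrom_len=220_000)
        # S-arm length is cen_start = 109990; place vps at given rel dist
        for i, rel in enumerate(rel_positions):
            cs, _ = fmap.centromeres[f"c{i+1}"]
            pos = int(cs - rel * cs)
            frag = fmap.fragment_at(f"c{i+1}", min(pos, 99_499))
            vps.append(Viewpoint(f"v{i+1}", f"c{i+1}", pos, "A",
                                 fragment=frag))
        return fmap, vps

    def test_monotone_construction_gives_rho_one(self):
        rels = [0.2, 0.5, 0.8]
        fmap, vps = self._fixture(rels)
        d50 = {}
        cbv = {}
        for vp, rel in zip(vps, rels):
            # dist50_rel on every non-viewpoint arm equals the viewpoint's
            # own relative distance (perfect monotone coupling)
            arms = [a for a in fmap.df["arm"].unique()
                    if a != fmap.arm_of_fragment(vp.fragment)]
            d50[vp.name] = pd.DataFrame({
                "viewpoint": vp.name, "arm": arms,
                "dist50_abs": rel * 100_000, "dist50_rel": rel,
                "n_reads": 100.0})
            rng = np.random.default_rng(sum(map(ord, vp.name)))
            cbv[vp.name] = FragmentCounts(
                vp.name, "s", rng.poisson(4, len(fmap)).astype(float) + 1)
        rep1, rep2 = centromere_regressions(d50, cbv, fmap, vps)
        assert rep1.rho == pytest.approx(1.0)
        assert rep1.slope > 0

    def test_degenerate_predictor_errors(self):
        fmap, vps = self._fixture([0.5, 0.5, 0.5])
        d50 = {vp.name: pd.DataFrame({
            "viewpoint": vp.name, "arm": ["c1L"], "dist50_abs": [1.0],
            "dist50_rel": [0.5], "n_reads": [10.0]}) for vp in vps}
        cbv = {vp.name: FragmentCounts(vp.name, "s", np.ones(len(fmap)))
               for vp in vps}
        with pytest.raises(ValueError):
            centromere_regressions(d50, cbv, fmap, vps)

    def test_viewpoint_relative_distance(self):
        fmap, vps = self._fixture([0.2, 0.5, 0.8])
        for vp, rel in zip(vps, [0.2, 0.5, 0.8]):
            _, d_rel = viewpoint_cen_distance(fmap, vp)
            assert d_rel == pytest.approx(rel, abs=0.01)
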