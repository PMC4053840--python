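"""Epigenome-interactome integration.

Epigenetic modification density (EMD) per restriction fragment is the
fraction of its bases covered by a feature's intervals; window EMD is the
mean over member fragments.  Prey windows are compared with randomly chosen
control windows by (i) covariance PCA of mean prey/control EMDs per
viewpoint, (ii) a resampled two-group permutation test of absolute EMD mean
differences, and (iii) a GSEA-like running-sum enrichment score over windows
sorted by EMD, both with empirical P-values and Benjamini-Hochberg FDR
across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_digest import FragmentMap
from .interaction_windows import WindowTrack

__all__ = [
    "EMDTrack",
    "emd_track",
    "select_controls",
    "pca_prey_control",
    "permutation_test",
    "gsea_like_test",
    "enrichment_score",
    "bh_adjust",
    "PermutationResult",
    "EnrichmentResult",
]


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

@dataclass
class EMDTrack:
    feature: str
    frag_density: np.ndarray                  # in [0,1], over genome_index
    window_density: np.ndarray | None = None  # mean over window members

    def __post_init__(self) -> None:
        d = np.asarray(self.frag_density, dtype=float)
        if ((d < 0) | (d > 1)).any():
            raise ValueError("densities must lie in [0, 1]")
        self.frag_density = d


def _merged_coverage(starts: np.ndarray, ends: np.ndarray):
    """Union of intervals -> (merged starts, merged ends, cumulative bp)."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [], []
    for a, b in zip(s, e):
        if me and a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    ms = np.asarray(ms, dtype=float)
    me = np.asarray(me, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(me - ms)])
    return ms, me, cum


def _covered_below(x: np.ndarray, ms, me, cum) -> np.ndarray:
    """Total covered bp strictly below each coordinate x."""
    i = np.searchsorted(ms, x, side="right")
    base = cum[i]
    partial = np.where(i > 0, np.maximum(me[np.maximum(i - 1, 0)] - x, 0.0), 0.0)
    return base - np.where(i > 0, np.minimum(partial, me[np.maximum(i - 1, 0)] -
                                             ms[np.maximum(i - 1, 0)]), 0.0)


def emd_track(feature_intervals: pd.DataFrame, fmap: FragmentMap,
              windows: WindowTrack | None = None,
              feature: str = "") -> EMDTrack:
    """Fragment and window densities of a feature given as coverage
    intervals (columns chrom, start, end; overlaps are unioned).

    Fragment density = |union of covering intervals within the fragment| /
    fragment length.  Window density = mean of member fragment densities.
    """
    df = fmap.df
    dens = np.zeros(len(df))
    for chrom, sub in feature_intervals.groupby("chrom", sort=False):
        length = fmap.chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"feature chromosome {chrom} not in fragment map")
        if (sub["start"] < 0).any() or (sub["end"] > length).any():
            raise ValueError(f"feature interval outside chromosome {chrom}")
        ms, me, cum = _merged_coverage(sub["start"].to_numpy(dtype=float),
                                       sub["end"].to_numpy(dtype=float))
        fsel = (df["chrom"] == chrom).to_numpy()
        fs = df.loc[fsel, "start"].to_numpy(dtype=float)
        fe = df.loc[fsel, "end"].to_numpy(dtype=float)
        covered = _covered_below(fe, ms, me, cum) - _covered_below(fs, ms, me, cum)
        dens[fsel] = covered / (fe - fs)
    dens = np.clip(dens, 0.0, 1.0)
    track = EMDTrack(feature, dens)
    if windows is not None:
        track.window_density = window_emd(track, windows)
    return track


def window_emd(track: EMDTrack, windows: WindowTrack) -> np.ndarray:
    members = windows.member_matrix()
    return track.frag_density[members].mean(axis=1)


# ---------------------------------------------------------------------------
# control selection
# ---------------------------------------------------------------------------

def select_controls(windows: WindowTrack, prey_mask: np.ndarray,
                    n: int = 50, seed: int = 0,
                    exclude_mask: np.ndarray | None = None) -> np.ndarray:
    """Seeded uniform sample of ``n`` control windows from the eligible pool
    (non-prey, not excluded, P defined).  Sampling is without replacement
    when the pool is large enough, with replacement (and a warning)
    otherwise.  Returns window row indices, disjoint from preys."""
    prey_mask = np.asarray(prey_mask, dtype=bool)
    eligible = ~prey_mask
    df = windows.df if hasattr(windows, "df") else windows
    p = df["P"].to_numpy()
    eligible &= ~np.isnan(p)
    if exclude_mask is not None:
        eligible &= ~np.asarray(exclude_mask, dtype=bool)
    pool = np.flatnonzero(eligible)
    if pool.size == 0:
        raise ValueError("control pool is empty")
    rng = np.random.default_rng(seed)
    if pool.size >= n:
        return rng.choice(pool, size=n, replace=False)
    warnings.warn(f"control pool ({pool.size}) smaller than n={n}; "
                  "sampling with replacement")
    return rng.choice(pool, size=n, replace=True)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_prey_control(matrix: pd.DataFrame, scale: bool = False):
    """Covariance-based PCA (centered, unscaled by default) of the
    (viewpoint x group) rows over feature columns.

    Returns ``(loadings, variance_fractions, scores)``: loadings has one
    column per component, scores one row per input row.  A constant matrix
    yields zero variance and zero-vector scores.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 features")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        k = min(X.shape)
        return (np.zeros((X.shape[1], k)), np.zeros(k),
                np.zeros((X.shape[0], k)))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    frac = var / var.sum()
    loadings = Vt.T
    scores = U * S
    return loadings, frac, scores


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _sample_rows(rng: np.random.Generator, pool: np.ndarray,
                 n_rows: int, n: int) -> np.ndarray:
    """n_rows independent samples of size n from pool: without replacement
    when the pool suffices, with replacement otherwise."""
    if len(pool) >= n:
        keys = rng.random((n_rows, len(pool)))
        picks = np.argpartition(keys, n - 1, axis=1)[:, :n]
        return pool[picks]
    return rng.choice(pool, size=(n_rows, n), replace=True)


@dataclass
class PermutationResult:
    feature: str
    real_diff: np.ndarray = field(repr=False)   # (i, j)
    rand_diff: np.ndarray = field(repr=False)   # (i, j)
    real_diff_mean: float = 0.0
    p: float = np.nan
    q: float = np.nan


def permutation_test(window_emds: dict[str, np.ndarray],
                     region_sets: dict[str, dict[str, np.ndarray]],
                     n_reps: int = 1000, n_sample: int = 50,
                     seed: int = 0, gte: bool = False
                     ) -> dict[str, PermutationResult]:
    """Resampled two-group permutation test per epigenetic feature.

    ``window_emds``: feature -> window EMD vector.  ``region_sets``:
    viewpoint -> {"prey": indices, "control_pool": indices}.  Each of the
    ``n_reps`` repetitions samples ``n_sample`` preys and controls per
    viewpoint, records RealDiff_ij = |mean prey - mean control| EMD, then
    pools the 2 x n_sample values and splits them at random into two groups
    of n_sample for RandDiff_ij.  p = sum(RandDiff > RealDiff_m) / (i*j)
    with RealDiff_m the grand mean (``gte=True`` switches the comparison to
    >=, avoiding p = 0 on all-constant EMDs).  q is BH-adjusted across
    features.  Viewpoints without preys are excluded from j.
    """
    vps = [v for v, rs in region_sets.items() if len(rs["prey"]) > 0]
    if not vps:
        raise ValueError("no viewpoint has prey windows")
    master = np.random.SeedSequence(seed)
    feat_seeds = master.spawn(len(window_emds))
    results = {}
    for (feature, emd), fs in zip(sorted(window_emds.items()), feat_seeds):
        rng = np.random.default_rng(fs)
        real = np.empty((n_reps, len(vps)))
        rand = np.empty((n_reps, len(vps)))
        for j, vname in enumerate(vps):
            rs = region_sets[vname]
            prey_idx = np.asarray(rs["prey"], dtype=int)
            ctrl_idx = np.asarray(rs["control_pool"], dtype=int)
            prey_s = _sample_rows(rng, prey_idx, n_reps, n_sample)
            ctrl_s = _sample_rows(rng, ctrl_idx, n_reps, n_sample)
            pv = emd[prey_s]
            cv = emd[ctrl_s]
            real[:, j] = np.abs(pv.mean(axis=1) - cv.mean(axis=1))
            pool = np.concatenate([pv, cv], axis=1)
            pool = rng.permuted(pool, axis=1)
            rand[:, j] = np.abs(pool[:, :n_sample].mean(axis=1) -
                                pool[:, n_sample:].mean(axis=1))
        rm = float(real.mean())
        # densities are O(1); the tolerance keeps exact ties from flipping
        # the strict comparison through float rounding
        tol = 1e-9
        exceed = (rand >= rm - tol) if gte else (rand > rm + tol)
        p = float(exceed.sum()) / rand.size
        results[feature] = PermutationResult(feature, real, rand, rm, p)
    qs = bh_adjust([results[f].p for f in sorted(results)])
    for f, q in zip(sorted(results), qs):
        results[f].q = float(q)
    return results


# ---------------------------------------------------------------------------
# GSEA-like test
# ---------------------------------------------------------------------------

def enrichment_score(emd: np.ndarray, test_mask: np.ndarray) -> float:
    """Running-sum enrichment score of a test set of regions.

    Regions are sorted by EMD descending (stable, ties by index); test
    regions weigh (n-m)/m, others -1 (weights sum to zero), and the ES is
    the maximum absolute value of the cumulative sum.
    """
    emd = np.asarray(emd, dtype=float)
    test_mask = np.asarray(test_mask, dtype=bool)
    n = len(emd)
    m = int(test_mask.sum())
    if m == 0 or n == 0:
        raise ValueError("empty test set")
    if m == n:
        return 0.0
    order = np.argsort(-emd, kind="stable")
    w = np.where(test_mask[order], (n - m) / m, -1.0)
    return float(np.abs(np.cumsum(w)).max())


@dataclass
class EnrichmentResult:
    feature: str
    per_viewpoint: pd.DataFrame       # viewpoint, n, m, ES
    mean_es: float
    null_mean_es: np.ndarray = field(repr=False, default=None)
    p: float = np.nan
    q: float = np.nan


def _null_es(n: int, m: int, n_rand: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES for ``n_rand`` random m-subsets of n regions (vectorized).

    A random m-subset occupies uniformly random positions in the sorted
    region list, so the EMD values themselves drop out of the null."""
    w = np.full((n_rand, n), -1.0)
    # random m-subset per draw: first m of a random permutation via argsort
    keys = rng.random((n_rand, n))
    picks = np.argpartition(keys, m - 1, axis=1)[:, :m]
    rows = np.repeat(np.arange(n_rand), m)
    w[rows, picks.ravel()] = (n - m) / m
    return np.abs(np.cumsum(w, axis=1)).max(axis=1)


def gsea_like_test(window_emds: dict[str, np.ndarray],
                   test_sets: dict[str, dict[str, np.ndarray]],
                   n_rand: int = 10_000, seed: int = 0
                   ) -> dict[str, EnrichmentResult]:
    """GSEA-like enrichment of prey regions in each feature's EMD ranking.

    ``test_sets``: viewpoint -> {"regions": window indices of the
    viewpoint's eligible regions (non-overlapping windows off the
    viewpoint's arm), "test": indices of its prey regions within that set}.
    Per viewpoint the observed ES is computed over the sorted regions; the
    null draws ``n_rand`` random m-subsets.  The observed ES and matched
    null draws are averaged across viewpoints; the empirical p is the
    fraction of null means >= the observed mean.  Viewpoints with m = 0 are
    skipped; q is BH across features.
    """
    vps = [v for v, ts in test_sets.items() if len(ts["test"]) > 0]
    if not vps:
        raise ValueError("no viewpoint has test regions")
    master = np.random.SeedSequence(seed)
    feat_seeds = master.spawn(len(window_emds))
    results = {}
    for (feature, emd), fs in zip(sorted(window_emds.items()), feat_seeds):
        rng = np.random.default_rng(fs)
        obs = []
        nulls = np.zeros(n_rand)
        rows = []
        for vname in vps:
            ts = test_sets[vname]
            regions = np.asarray(ts["regions"], dtype=int)
            test_idx = np.asarray(ts["test"], dtype=int)
            vals = emd[regions]
            mask = np.isin(regions, test_idx)
            n, m = len(regions), int(mask.sum())
            es = enrichment_score(vals, mask) if 0 < m < n else 0.0
            obs.append(es)
            rows.append((vname, n, m, es))
            if 0 < m < n:
                nulls += _null_es(n, m, n_rand, rng)
            # m == n contributes 0 to both observed and null
        nulls /= len(vps)
        mean_es = float(np.mean(obs))
        p = float((nulls >= mean_es).sum()) / n_rand
        per_vp = pd.DataFrame(rows, columns=["viewpoint", "n", "m", "ES"])
        results[feature] = EnrichmentResult(feature, per_vp, mean_es, nulls, p)
    qs = bh_adjust([results[f].p for f in sorted(results)])
    for f, q in zip(sorted(results), qs):
        results[f].q = float(q)
    return results


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
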