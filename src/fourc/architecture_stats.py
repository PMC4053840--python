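"""Chromosome-architecture statistics for 4C interactomes.

Covers replicate reproducibility (Spearman correlation of window read sums
with average-linkage clustering), the distance-dependent decay of contact
probability (41 log10 bins over 1 kb-10 Mb, LOESS smoothing, linear fit of
the decay exponent), per-arm read shares (RPM by arm class with paired
t-tests), the dist0.5 statistic (centromere distance at which half of an
arm's reads lie), and the two centromere-distance regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome_digest import FragmentMap, Viewpoint
from .read_processing import FragmentCounts

__all__ = [
    "CorrelationMatrix",
    "DecayProfile",
    "decay_bin_centers",
    "replicate_correlation",
    "decay_profile",
    "fit_decay_exponent",
    "loess",
    "arm_class_rpm",
    "dist50_per_arm",
    "centromere_regressions",
]


# ---------------------------------------------------------------------------
# replicate correlation / clustering
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    samples: list[str]
    rho: np.ndarray            # symmetric Spearman matrix, diagonal 1
    linkage: np.ndarray        # scipy linkage matrix (average, 1 - rho)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.rho, index=self.samples,
                     columns=self.samples).to_csv(path, sep="\t")


def replicate_correlation(tracks) -> CorrelationMatrix:
    """Pairwise Spearman rho of window read sums across samples, plus
    average-linkage hierarchical clustering on distance 1 - rho."""
    if len(tracks) < 2:
        raise ValueError("need at least two window tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.same_windows(first):
            raise ValueError("tracks are not on identical windows")
    data = np.column_stack([t.df["read_sum"].to_numpy() for t in tracks])
    rho, _ = stats.spearmanr(data)
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case
        r = stats.spearmanr(data[:, 0], data[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    names = [t.sample or t.viewpoint or f"s{i}" for i, t in enumerate(tracks)]
    dist = squareform(np.clip(1.0 - rho, 0.0, None), checks=False)
    Z = hierarchy.linkage(dist, method="average")
    return CorrelationMatrix(names, rho, Z)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayProfile:
    """Binned cis contact probabilities vs log10 distance.

    Bin centers are log10 d = 3.0, 3.1, ..., 7.0 (41 bins over 1 kb-10 Mb;
    bin edges at center +- 0.05).  ``raw_prob`` is the reads-per-fragment
    mass per bin normalized to sum 1, so a per-fragment contact probability
    proportional to d**gamma appears with log-log slope gamma.
    """

    centers: np.ndarray        # log10 bp
    raw_prob: np.ndarray
    n_reads: np.ndarray
    n_frags: np.ndarray
    smooth_prob: np.ndarray | None = None
    slope: float | None = None
    fit_p: float | None = None

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({
            "log10_distance": self.centers,
            "raw_prob": self.raw_prob,
            "n_reads": self.n_reads,
            "n_fragments": self.n_frags,
        })
        if self.smooth_prob is not None:
            out["smooth_prob"] = self.smooth_prob
        out.to_csv(path, sep="\t", index=False)


def decay_bin_centers(d_min: float = 1e3, d_max: float = 1e7,
                      bin_width_log10: float = 0.1) -> np.ndarray:
    """Log10 bin centers spanning [d_min, d_max] inclusively (fencepost):
    the defaults give 41 centers 3.0, 3.1, ..., 7.0."""
    lo, hi = np.log10(d_min), np.log10(d_max)
    n = int(round((hi - lo) / bin_width_log10)) + 1
    return lo + bin_width_log10 * np.arange(n)


def decay_profile(counts_list, viewpoints, fmap: FragmentMap,
                  d_min: float = 1e3, d_max: float = 1e7,
                  bin_width_log10: float = 0.1) -> DecayProfile:
    """Pool cis reads of one or more viewpoints into log10 distance bins.

    Only fragments on each viewpoint's own arm count; the distance is from
    the fragment midpoint to the viewpoint position.  Each bin's read total
    is divided by the number of fragments it contains (pooled across
    viewpoints) before the grand normalization to sum 1, so the profile
    estimates the per-fragment contact probability.  Empty bins carry 0.
    """
    if isinstance(counts_list, FragmentCounts):
        counts_list = [counts_list]
    if isinstance(viewpoints, Viewpoint):
        viewpoints = [viewpoints]
    centers = decay_bin_centers(d_min, d_max, bin_width_log10)
    edges = np.concatenate([centers - bin_width_log10 / 2,
                            [centers[-1] + bin_width_log10 / 2]])
    reads = np.zeros(len(centers))
    frags = np.zeros(len(centers))
    df = fmap.df
    mid = fmap.midpoints()
    for counts, vp in zip(counts_list, viewpoints):
        vp = fmap.resolve_viewpoint(vp) if vp.fragment is None else vp
        arm = fmap.arm_of_fragment(vp.fragment)
        sel = ((df["arm"] == arm) & df["valid"]).to_numpy()
        d = np.abs(mid[sel] - vp.position)
        ok = d > 0
        logd = np.log10(d[ok])
        inside = (logd >= edges[0]) & (logd < edges[-1])
        b = np.digitize(logd[inside], edges) - 1
        np.add.at(reads, b, counts.counts[df["genome_index"].to_numpy()[sel][ok][inside]])
        np.add.at(frags, b, 1.0)
    if reads.sum() <= 0:
        raise ValueError("no reads within the decay distance range")
    per_frag = np.zeros(len(centers))
    nz = frags > 0
    per_frag[nz] = reads[nz] / frags[nz]
    raw_prob = per_frag / per_frag.sum()
    return DecayProfile(centers, raw_prob, reads, frags)


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u ** 3) ** 3


def loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
          span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    At each evaluation point the nearest ``ceil(span * n)`` observations
    (by |x - x_eval|) receive tricube weights scaled by the span bandwidth,
    and a degree-``degree`` weighted polynomial is fitted and evaluated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < degree + 1:
        raise ValueError("too few points for local polynomial fit")
    q = max(degree + 1, int(np.ceil(span * n)))
    q = min(q, n)
    out = np.empty(len(x_eval))
    for i, xe in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - xe)
        h = np.partition(d, q - 1)[q - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = _tricube(d / h)
        use = w > 0
        deg = min(degree, use.sum() - 1)
        coeff = np.polyfit(x[use], y[use], deg, w=np.sqrt(w[use]))
        out[i] = np.polyval(coeff, xe)
    return out


def fit_decay_exponent(profile: DecayProfile, use_loess: bool = True,
                       span: float = 0.75, degree: int = 2):
    """Estimate the interaction decay exponent from a binned profile.

    log10(raw_prob) is smoothed by LOESS over the non-empty bins, predicted
    at every bin center, and an ordinary least-squares line through the
    predictions gives the slope (the exponent) and regression P.  With
    ``use_loess=False`` the line is fitted directly to the non-empty raw
    bins.  Returns ``(slope, fit_p, smooth_prob)`` and fills the profile.
    """
    nz = profile.raw_prob > 0
    if nz.sum() < 5:
        raise ValueError("need at least 5 non-empty bins")
    x = profile.centers[nz]
    y = np.log10(profile.raw_prob[nz])
    if use_loess and nz.sum() >= degree + 2:
        pred = loess(x, y, profile.centers, span=span, degree=degree)
        fit = stats.linregress(profile.centers, pred)
        smooth = 10.0 ** pred
    else:
        fit = stats.linregress(x, y)
        smooth = 10.0 ** (fit.intercept + fit.slope * profile.centers)
    profile.smooth_prob = smooth
    profile.slope = float(fit.slope)
    profile.fit_p = float(fit.pvalue)
    return profile.slope, profile.fit_p, smooth


# ---------------------------------------------------------------------------
# arm-class RPM and t-tests
# ---------------------------------------------------------------------------

def _vp_arm(fmap: FragmentMap, vp: Viewpoint) -> Viewpoint:
    return fmap.resolve_viewpoint(vp) if vp.fragment is None else vp


def arm_class_rpm(counts_by_vp: dict[str, FragmentCounts],
                  fmap: FragmentMap, viewpoints: list[Viewpoint],
                  mask_mb: float = 2e6):
    """Per-arm reads-per-million by arm class, with paired t-tests.

    For each viewpoint, rpm(arm) = 1e6 x reads on the arm's valid fragments /
    library (library = all reads on valid fragments, so rpm sums to 1e6 over
    arms).  Arm classes: the viewpoint's own arm, the other arm of its
    chromosome (cis), and all other arms (trans).  ``viewpoint_masked``
    recomputes the viewpoint arm after removing fragments within
    ``mask_mb`` of the viewpoint (same library denominator).  Class values
    are unweighted means over member arms; two-sided paired t-tests across
    viewpoints compare viewpoint vs cis, cis vs trans, and masked vs cis.

    Returns ``(arm_table, class_table, ttests)``.
    """
    df = fmap.df
    arms = [a for a in pd.unique(df["arm"]) if a is not None]
    chrom_of_arm = {a: df.loc[df["arm"] == a, "chrom"].iloc[0] for a in arms}
    arms_per_chrom = pd.Series(list(chrom_of_arm.values())).value_counts()
    if (arms_per_chrom < 2).any():
        bad = arms_per_chrom[arms_per_chrom < 2].index.tolist()
        raise ValueError(f"single-arm chromosome(s) unsupported: {bad}")
    if len(viewpoints) < 2:
        raise ValueError("need >= 2 viewpoints for paired t-tests")

    mid = fmap.midpoints()
    valid = df["valid"].to_numpy()
    gidx = df["genome_index"].to_numpy()

    arm_rows = []
    class_rows = []
    for vp in viewpoints:
        vp = _vp_arm(fmap, vp)
        counts = counts_by_vp[vp.name]
        varm = fmap.arm_of_fragment(vp.fragment)
        vchrom = chrom_of_arm[varm]
        arm_reads = {}
        for a in arms:
            sel = ((df["arm"] == a).to_numpy()) & valid
            arm_reads[a] = counts.counts[gidx[sel]].sum()
        lib = sum(arm_reads.values())
        if lib <= 0:
            raise ValueError(f"viewpoint {vp.name} has no reads on valid fragments")
        sel_masked = ((df["arm"] == varm).to_numpy()) & valid & \
            (np.abs(mid - vp.position) > mask_mb)
        masked_reads = counts.counts[gidx[sel_masked]].sum()

        rpm = {a: 1e6 * r / lib for a, r in arm_reads.items()}
        for a in arms:
            cls = ("viewpoint" if a == varm
                   else "cis" if chrom_of_arm[a] == vchrom else "trans")
            arm_rows.append((vp.name, a, cls, rpm[a]))
        cis_vals = [rpm[a] for a in arms
                    if chrom_of_arm[a] == vchrom and a != varm]
        trans_vals = [rpm[a] for a in arms if chrom_of_arm[a] != vchrom]
        class_rows.append((vp.name, rpm[varm], 1e6 * masked_reads / lib,
                           float(np.mean(cis_vals)), float(np.mean(trans_vals))))

    arm_table = pd.DataFrame(arm_rows, columns=["viewpoint", "arm", "cls", "rpm"])
    class_table = pd.DataFrame(
        class_rows, columns=["viewpoint", "viewpoint_rpm",
                             "viewpoint_masked_rpm", "cis_rpm", "trans_rpm"])
    ttests = {}
    for name, a, b in (("viewpoint_vs_cis", "viewpoint_rpm", "cis_rpm"),
                       ("cis_vs_trans", "cis_rpm", "trans_rpm"),
                       ("viewpoint_masked_vs_cis", "viewpoint_masked_rpm",
                        "cis_rpm")):
        res = stats.ttest_rel(class_table[a], class_table[b])
        ttests[name] = {"t": float(res.statistic), "p": float(res.pvalue)}
    return arm_table, class_table, ttests


# ---------------------------------------------------------------------------
# dist0.5 and centromere regressions
# ---------------------------------------------------------------------------

def _arm_length(fmap: FragmentMap, arm: str) -> float:
    chrom = fmap.df.loc[fmap.df["arm"] == arm, "chrom"].iloc[0]
    cs, ce = fmap.centromeres[chrom]
    return float(cs) if arm.endswith("S") else float(fmap.chrom_lengths[chrom] - ce)


def dist50_per_arm(counts: FragmentCounts, fmap: FragmentMap,
                   viewpoint: Viewpoint) -> pd.DataFrame:
    """dist0.5 per arm: the centromere distance at which the cumulative read
    fraction (fragments ordered by cen_dist) first reaches 0.5.  The
    viewpoint's own arm is excluded; zero-read arms get NaN sentinels.
    Returns columns viewpoint, arm, dist50_abs, dist50_rel, n_reads.
    """
    vp = _vp_arm(fmap, viewpoint)
    varm = fmap.arm_of_fragment(vp.fragment)
    df = fmap.df
    rows = []
    for arm in [a for a in pd.unique(df["arm"]) if a is not None and a != varm]:
        sub = df[(df["arm"] == arm) & df["valid"]].sort_values(
            "cen_dist", kind="stable")
        c = counts.counts[sub["genome_index"].to_numpy()]
        total = c.sum()
        if total <= 0:
            rows.append((vp.name, arm, np.nan, np.nan, 0.0))
            continue
        cum = np.cumsum(c) / total
        k = int(np.searchsorted(cum, 0.5, side="left"))
        d_abs = float(sub["cen_dist"].to_numpy()[k])
        rows.append((vp.name, arm, d_abs,
                     min(d_abs / _arm_length(fmap, arm), 1.0), float(total)))
    return pd.DataFrame(rows, columns=["viewpoint", "arm", "dist50_abs",
                                       "dist50_rel", "n_reads"])


def viewpoint_cen_distance(fmap: FragmentMap, vp: Viewpoint) -> tuple[float, float]:
    """(absolute, relative) distance of the viewpoint to its centromere."""
    vp = _vp_arm(fmap, vp)
    arm = fmap.arm_of_fragment(vp.fragment)
    chrom = vp.chrom
    cs, ce = fmap.centromeres[chrom]
    d = cs - vp.position if arm.endswith("S") else vp.position - ce
    return float(d), float(d) / _arm_length(fmap, arm)


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    p: float
    rho: float
    rho_p: float
    table: pd.DataFrame = field(repr=False, default=None)


def centromere_regressions(dist50_tables: dict[str, pd.DataFrame],
                           counts_by_vp: dict[str, FragmentCounts],
                           fmap: FragmentMap, viewpoints: list[Viewpoint]):
    """The two viewpoint-position regressions.

    (i) dist0.5 model: response arcsin(sqrt(dist50_rel)) for every
    non-viewpoint arm, predictor = the viewpoint's relative centromere
    distance; OLS slope/p plus Spearman rho.
    (ii) trans-RPKM model: per viewpoint, reads per kb per million over all
    arms except the viewpoint arm (cis arm included; kb = valid fragment
    territory of those arms) vs the viewpoint's absolute centromere
    distance; OLS plus Spearman.
    """
    if len(viewpoints) < 3:
        raise ValueError("need >= 3 viewpoints")
    df = fmap.df
    valid = df["valid"].to_numpy()
    gidx = df["genome_index"].to_numpy()

    rows1 = []
    rows2 = []
    for vp in viewpoints:
        vp = _vp_arm(fmap, vp)
        varm = fmap.arm_of_fragment(vp.fragment)
        d_abs, d_rel = viewpoint_cen_distance(fmap, vp)
        t = dist50_tables[vp.name]
        for _, r in t.dropna(subset=["dist50_rel"]).iterrows():
            rows1.append((vp.name, r["arm"], d_rel,
                          np.arcsin(np.sqrt(r["dist50_rel"]))))
        counts = counts_by_vp[vp.name]
        sel = ((df["arm"] != varm) & df["arm"].notna()).to_numpy() & valid
        reads = counts.counts[gidx[sel]].sum()
        kb = (df.loc[sel, "end"] - df.loc[sel, "start"]).sum() / 1e3
        lib = counts.counts[gidx[valid & df["arm"].notna().to_numpy()]].sum()
        rpkm = reads / kb / (lib / 1e6) if kb > 0 and lib > 0 else np.nan
        rows2.append((vp.name, d_abs, rpkm))

    t1 = pd.DataFrame(rows1, columns=["viewpoint", "arm", "x_rel_vp_dist",
                                      "y_asin_sqrt_dist50"])
    t2 = pd.DataFrame(rows2, columns=["viewpoint", "x_abs_vp_dist", "rpkm"])

    def _report(x, y, table):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.allclose(x, x[0]):
            raise ValueError("degenerate predictor: all viewpoints equidistant")
        fit = stats.linregress(x, y)
        sp = stats.spearmanr(x, y)
        return RegressionReport(float(fit.slope), float(fit.intercept),
                                float(fit.pvalue), float(sp.statistic),
                                float(sp.pvalue), table)

    rep1 = _report(t1["x_rel_vp_dist"], t1["y_asin_sqrt_dist50"], t1)
    rep2 = _report(t2["x_abs_vp_dist"], t2["rpkm"], t2)
    return rep1, rep2
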