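"""Fragment windows, interaction values, shuffle-null P-values, prey calls.

The interaction value of a window is the sum of log2 read counts over its
member fragments (log-transforming first keeps single hot fragments from
dominating a window).  Significance is assessed per chromosome arm against a
shuffle null: fragment counts are permuted among the arm's valid fragments,
all window values are recomputed, a normal distribution is fitted to each
shuffle's window values, and each observed window receives an upper-tail
preliminary P under that normal.  The final P is the mean of the preliminary
P-values over all shuffles.  Windows never cross arm boundaries (the
centromere is an interaction boundary and nulls are per-arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_digest import FragmentMap
from .read_processing import FragmentCounts

__all__ = [
    "WindowTrack",
    "build_windows",
    "window_values",
    "shuffle_pvalues",
    "call_preys",
]

log = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """Windows of consecutive valid fragments within one or more arms.

    ``df`` columns: arm, chrom, start, end (bp span, half-open), win_index,
    and after value/P computation: read_sum, value, value_scaled, P, prey.
    ``arm_frags`` maps each arm to its valid fragments' genome_index in
    arm_index order; ``arm_offsets`` gives each window's first position in
    that per-arm fragment order.  Window *i* of an arm covers fragments
    ``arm_frags[arm][off : off + size]``.
    """

    df: pd.DataFrame
    size: int
    step: int
    arm_frags: dict[str, np.ndarray] = field(default_factory=dict)
    arm_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    viewpoint: str = ""
    sample: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def members(self, row: int) -> np.ndarray:
        """genome_index of the fragments in window ``row`` of ``df``."""
        arm = self.df["arm"].iloc[row]
        k = int(self.df["win_index"].iloc[row])
        off = int(self.arm_offsets[arm][k])
        return self.arm_frags[arm][off:off + self.size]

    def member_matrix(self) -> np.ndarray:
        """(n_windows, size) array of member genome_index, in df order."""
        out = np.empty((len(self.df), self.size), dtype=np.int64)
        pos = 0
        for arm in self.df["arm"].unique():
            offs = self.arm_offsets[arm]
            frags = self.arm_frags[arm]
            idx = offs[:, None] + np.arange(self.size)[None, :]
            out[pos:pos + len(offs)] = frags[idx]
            pos += len(offs)
        return out

    def same_windows(self, other: "WindowTrack") -> bool:
        a = self.df[["arm", "chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["arm", "chrom", "start", "end"]].reset_index(drop=True)
        return self.size == other.size and self.step == other.step and a.equals(b)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path, column: str = "value_scaled") -> None:
        col = self.df[column]
        if column == "P":
            col = -np.log10(np.maximum(col, 1e-300))
        out = self.df[["chrom", "start", "end"]].copy()
        out["score"] = col
        out = out.sort_values(["chrom", "start"], kind="stable")
        out.to_csv(path, sep="\t", header=False, index=False)


def build_windows(fmap: FragmentMap, size: int, step: int,
                  viewpoint: str = "", sample: str = "") -> WindowTrack:
    """Tile each arm's valid fragments with windows of ``size`` fragments
    every ``step`` fragments (size=100/step=1 overlapping, size=step=25
    non-overlapping).  Fragments are taken in arm_index order, so windows
    never cross the centromere.  Arms with fewer than ``size`` valid
    fragments get no windows (logged, not an error).
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    df = fmap.df
    rows = []
    arm_frags: dict[str, np.ndarray] = {}
    arm_offsets: dict[str, np.ndarray] = {}
    arms = [a for a in pd.unique(df["arm"]) if a is not None]
    for arm in arms:
        sub = df[(df["arm"] == arm) & df["valid"]].sort_values(
            "arm_index", kind="stable")
        n = len(sub)
        if n < size:
            log.info("arm %s has %d < %d valid fragments; no windows", arm, n, size)
            continue
        gidx = sub["genome_index"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        offsets = np.arange(0, n - size + 1, step)
        arm_frags[arm] = gidx
        arm_offsets[arm] = offsets
        chrom = sub["chrom"].iloc[0]
        for k, off in enumerate(offsets):
            span_s = int(starts[off:off + size].min())
            span_e = int(ends[off:off + size].max())
            rows.append((arm, chrom, span_s, span_e, k))
    wdf = pd.DataFrame(rows, columns=["arm", "chrom", "start", "end", "win_index"])
    for col in ("read_sum", "value", "value_scaled", "P"):
        wdf[col] = np.nan
    wdf["prey"] = False
    return WindowTrack(wdf, size, step, arm_frags, arm_offsets,
                       viewpoint=viewpoint, sample=sample)


def _log_contrib(counts: np.ndarray) -> np.ndarray:
    """Per-fragment contribution to the interaction value: log2(count) for
    counts >= 1, zero otherwise (zero and sub-single fractional counts
    contribute nothing, keeping values non-negative)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative fragment counts")
    out = np.zeros_like(counts)
    sel = counts >= 1
    out[sel] = np.log2(counts[sel])
    return out


def _window_sums(values: np.ndarray, offsets: np.ndarray, size: int) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values)])
    return cs[offsets + size] - cs[offsets]


def window_values(track: WindowTrack, counts: FragmentCounts) -> WindowTrack:
    """Fill read_sum, value (sum of log2 counts) and value_scaled
    (value per million library reads) for every window."""
    logc = _log_contrib(counts.counts)
    raw = counts.counts
    lib = counts.library_size
    df = track.df
    value = np.empty(len(df))
    read_sum = np.empty(len(df))
    for arm in df["arm"].unique():
        sel = (df["arm"] == arm).to_numpy()
        frags = track.arm_frags[arm]
        offs = track.arm_offsets[arm]
        value[sel] = _window_sums(logc[frags], offs, track.size)
        read_sum[sel] = _window_sums(raw[frags], offs, track.size)
    df["value"] = value
    df["read_sum"] = read_sum
    df["value_scaled"] = value * 1e6 / lib if lib else 0.0
    if not track.viewpoint:
        track.viewpoint = counts.viewpoint
    if not track.sample:
        track.sample = counts.sample
    return track


def shuffle_pvalues(track: WindowTrack, counts: FragmentCounts,
                    n_shuffles: int = 1000, seed: int = 0,
                    pooled: bool = False) -> WindowTrack:
    """Assign each window a final P-value against the per-arm shuffle null.

    For each shuffle and each arm independently, fragment counts are permuted
    among the arm's valid fragments and all window values recomputed.  By
    default a normal distribution (sample mean/sd) is fitted to each
    shuffle's window values and the observed value's upper-tail P under it is
    averaged over shuffles; with ``pooled=True`` a single normal is fitted to
    all shuffles' window values pooled.  Degenerate shuffles (sd = 0) give a
    preliminary P of 1 when the value does not exceed the mean and 0
    otherwise.  Arms with fewer than two windows keep P = NaN (logged).

    One master seed; per-arm streams are derived deterministically (spawned
    in arm order), so results are bit-reproducible and arms independent.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if track.df["value"].isna().all():
        track = window_values(track, counts)
    logc = _log_contrib(counts.counts)
    df = track.df
    P = np.full(len(df), np.nan)

    arms = list(df["arm"].unique())
    streams = np.random.SeedSequence(seed).spawn(len(arms))
    for arm, ss in zip(arms, streams):
        sel = (df["arm"] == arm).to_numpy()
        offs = track.arm_offsets[arm]
        n_win = len(offs)
        if n_win < 2:
            log.info("arm %s has %d window(s); P undefined", arm, n_win)
            continue
        frag_vals = logc[track.arm_frags[arm]]
        obs = df.loc[sel, "value"].to_numpy()
        rng = np.random.default_rng(ss)
        if pooled:
            all_vals = np.empty(n_shuffles * n_win)
            for s in range(n_shuffles):
                shuf = _window_sums(frag_vals[rng.permutation(len(frag_vals))],
                                    offs, track.size)
                all_vals[s * n_win:(s + 1) * n_win] = shuf
            mu, sd = all_vals.mean(), all_vals.std(ddof=1)
            if sd == 0:
                P[sel] = np.where(obs <= mu, 1.0, 0.0)
            else:
                P[sel] = stats.norm.sf((obs - mu) / sd)
        else:
            acc = np.zeros(n_win)
            for s in range(n_shuffles):
                shuf = _window_sums(frag_vals[rng.permutation(len(frag_vals))],
                                    offs, track.size)
                mu = shuf.mean()
                sd = shuf.std(ddof=1)
                if sd == 0:
                    acc += np.where(obs <= mu, 1.0, 0.0)
                else:
                    acc += stats.norm.sf((obs - mu) / sd)
            P[sel] = acc / n_shuffles
    df["P"] = P
    return track


def call_preys(tracks, threshold: float = 0.01,
               both_replicates: bool = False,
               strict: bool | None = None) -> pd.DataFrame:
    """Flag prey windows: those meeting the P threshold in each required
    replicate.  ``strict=None`` uses '<' in both-replicate mode and '<='
    for a single track.  Returns the window table of the first track with
    the prey column set (all tracks get their prey flags updated).
    """
    if isinstance(tracks, WindowTrack):
        tracks = [tracks]
    if both_replicates and len(tracks) < 2:
        raise ValueError("both_replicates requires two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.same_windows(first):
            raise ValueError("replicate tracks have mismatched windows")
    if strict is None:
        strict = both_replicates
    required = tracks if both_replicates else tracks[:1]
    prey = np.ones(len(first.df), dtype=bool)
    for t in required:
        p = t.df["P"].to_numpy()
        hit = (p < threshold) if strict else (p <= threshold)
        prey &= hit & ~np.isnan(p)
    for t in tracks:
        t.df["prey"] = prey
    out = first.df.copy()
    out["prey"] = prey
    return out
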