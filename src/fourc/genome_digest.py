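"""In-silico restriction digest and fragment-map annotation.

Everything downstream of raw reads operates on a *fragment map*: the ordered
restriction fragments produced by cutting the genome at every occurrence of
the primary enzyme motif.  Fragments are annotated with chromosome arm,
distance to the centromere, distance from each end to the first secondary
restriction site inside the fragment, and a validity flag that encodes the
standard 4C fragment filters (viewpoint proximity, centromere proximity,
secondary-site distance).

Coordinates are 0-based half-open throughout, including BED output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "Viewpoint",
    "FragmentMap",
    "digest_genome",
    "annotate_arms",
    "annotate_secondary",
    "filter_fragments",
    "read_fasta",
    "read_centromere_bed",
]

#: Sentinel for "no secondary site inside the fragment".  Infinite distance
#: makes the >= max_sec_dist filter rule hold naturally for absent sites.
SEC_ABSENT = np.inf

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A genome as (id, sequence) pairs plus one centromere interval each.

    Parameters
    ----------
    chromosomes
        List of ``(chrom_id, sequence)``; sequences are upper-case DNA
        (alphabet A/C/G/T/N).
    centromeres
        ``chrom_id -> (start, end)`` in 0-based half-open coordinates.
        Exactly one interval per chromosome; multi-interval assemblies must
        be pre-merged.
    """

    chromosomes: list[tuple[str, str]]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")
        for chrom, (s, e) in self.centromeres.items():
            length = self.length(chrom)
            if not (0 <= s < e <= length):
                raise ValueError(
                    f"centromere [{s},{e}) outside chromosome {chrom} "
                    f"of length {length}"
                )

    @property
    def ids(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def sequence(self, chrom: str) -> str:
        for c, seq in self.chromosomes:
            if c == chrom:
                return seq
        raise KeyError(chrom)

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    @classmethod
    def from_fasta(cls, fasta_path, centromere_bed=None) -> "GenomeModel":
        chroms = read_fasta(fasta_path)
        cens = read_centromere_bed(centromere_bed) if centromere_bed else {}
        return cls(chromosomes=chroms, centromeres=cens)


@dataclass
class Viewpoint:
    """A 4C viewpoint: the anchor fragment whose interactome a library reports."""

    name: str
    chrom: str
    position: int
    primer_seq: str
    secondary_enzyme_motif: str = "GATC"
    fragment: int | None = None  # genome_index, resolved against a FragmentMap

    def __post_init__(self) -> None:
        if not self.primer_seq:
            raise ValueError(f"viewpoint {self.name}: primer_seq is empty")


class FragmentMap:
    """Ordered restriction fragments with annotations, backed by a DataFrame.

    Columns: chrom, start, end, genome_index, arm (string or None),
    centromeric (bool), arm_index (int, -1 when unassigned), cen_dist (float),
    sec_dist_5p / sec_dist_3p (float, ``inf`` = absent), valid (bool).
    """

    def __init__(self, df: pd.DataFrame, chrom_lengths: dict[str, int],
                 motif: str = "", cut_offset: int = 0,
                 centromeres: dict[str, tuple[int, int]] | None = None):
        self.df = df.reset_index(drop=True)
        self.chrom_lengths = dict(chrom_lengths)
        self.motif = motif
        self.cut_offset = cut_offset
        self.centromeres = dict(centromeres or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_fragments(self) -> int:
        return len(self.df)

    def copy(self) -> "FragmentMap":
        return FragmentMap(self.df.copy(), self.chrom_lengths,
                           self.motif, self.cut_offset, self.centromeres)

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0

    def fragment_at(self, chrom: str, position: int) -> int:
        """genome_index of the fragment containing ``position`` on ``chrom``."""
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom} not in fragment map")
        starts = sub["start"].to_numpy()
        idx = np.searchsorted(starts, position, side="right") - 1
        if idx < 0 or position >= sub["end"].iloc[idx]:
            raise KeyError(f"position {chrom}:{position} outside fragments")
        return int(sub["genome_index"].iloc[idx])

    def resolve_viewpoint(self, vp: Viewpoint) -> Viewpoint:
        """Return a copy of ``vp`` with its fragment genome_index filled in."""
        frag = self.fragment_at(vp.chrom, vp.position)
        return Viewpoint(vp.name, vp.chrom, vp.position, vp.primer_seq,
                         vp.secondary_enzyme_motif, fragment=frag)

    def arm_of_fragment(self, genome_index: int) -> str | None:
        arm = self.df.loc[self.df["genome_index"] == genome_index, "arm"]
        if arm.empty:
            raise KeyError(genome_index)
        return arm.iloc[0]

    # -- serialization ------------------------------------------------------

    def to_bed(self, path) -> None:
        """6-column BED: name = genome_index, score = arm_index, strand '.'."""
        out = self.df[["chrom", "start", "end", "genome_index"]].copy()
        out["score"] = self.df["arm_index"]
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path) -> None:
        df = self.df.copy()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chrom_lengths: dict[str, int],
                 centromeres=None) -> "FragmentMap":
        df = pd.read_csv(path, sep="\t")
        df["arm"] = df["arm"].where(df["arm"].notna(), None)
        return cls(df, chrom_lengths, centromeres=centromeres or {})


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Multi-record, wrapped-line FASTA -> list of (id, upper-case sequence)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_centromere_bed(path) -> dict[str, tuple[int, int]]:
    """3-column BED of centromere intervals, one per chromosome."""
    cens: dict[str, tuple[int, int]] = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        if chrom in cens:
            raise ValueError(f"multiple centromere intervals for {chrom}; "
                             "merge them first")
        cens[chrom] = (int(row["start"]), int(row["end"]))
    return cens


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _find_sites(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) forward-strand motif start positions.

    N never matches.  Restriction motifs used here are palindromic, so a
    forward scan covers both strands.
    """
    sites = []
    i = seq.find(motif)
    while i != -1:
        sites.append(i)
        i = seq.find(motif, i + 1)
    return sites


def _check_motif(motif: str, min_len: int = 1) -> None:
    if len(motif) < min_len:
        raise ValueError(f"motif {motif!r} shorter than {min_len}")
    if not set(motif) <= _DNA:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")


def digest_genome(genome: GenomeModel, motif: str, cut_offset: int) -> FragmentMap:
    """In-silico digest: cut at every motif occurrence, offset by the enzyme's
    cut position (HindIII A^AGCTT -> offset 1, DpnII ^GATC -> offset 0).

    Fragment boundaries are every ``site_start + cut_offset`` plus the
    chromosome ends; fragments tile each chromosome without gaps or overlaps.
    """
    _check_motif(motif, min_len=4)
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError("cut_offset must lie within the motif")
    if not genome.chromosomes:
        raise ValueError("empty genome")

    rows = []
    gidx = 0
    for chrom, seq in genome.chromosomes:
        L = len(seq)
        if L == 0:
            raise ValueError(f"chromosome {chrom} has empty sequence")
        cuts = sorted({s + cut_offset for s in _find_sites(seq, motif)
                       if 0 < s + cut_offset < L})
        bounds = [0] + cuts + [L]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, s, e, gidx))
            gidx += 1

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "genome_index"])
    df["arm"] = None
    df["centromeric"] = False
    df["arm_index"] = -1
    df["cen_dist"] = np.nan
    df["sec_dist_5p"] = np.nan
    df["sec_dist_3p"] = np.nan
    df["valid"] = True
    lengths = {c: len(s) for c, s in genome.chromosomes}
    return FragmentMap(df, lengths, motif=motif, cut_offset=cut_offset,
                       centromeres=genome.centromeres)


def annotate_arms(fmap: FragmentMap,
                  centromeres: dict[str, tuple[int, int]] | None = None
                  ) -> FragmentMap:
    """Assign each fragment to a chromosome arm by its midpoint.

    Arms are named ``<chrom>S`` (before the centromere) and ``<chrom>L``
    (after it); fragments whose midpoint falls inside the centromere are
    flagged centromeric and carry no arm.  ``cen_dist`` is the distance from
    the fragment midpoint to the nearest centromere boundary; ``arm_index``
    ranks fragments within an arm by ascending ``cen_dist``.
    """
    cens = centromeres if centromeres is not None else fmap.centromeres
    out = fmap.copy()
    out.centromeres = dict(cens)
    df = out.df

    missing = set(df["chrom"]) - set(cens)
    if missing:
        raise ValueError(f"no centromere interval for chromosome(s) {sorted(missing)}")

    mid = (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0
    arm = np.empty(len(df), dtype=object)
    centromeric = np.zeros(len(df), dtype=bool)
    cen_dist = np.full(len(df), np.nan)

    for chrom, (cs, ce) in cens.items():
        sel = (df["chrom"] == chrom).to_numpy()
        m = mid[sel]
        left = m < cs
        right = m >= ce
        inside = ~(left | right)
        a = np.empty(sel.sum(), dtype=object)
        a[left] = f"{chrom}S"
        a[right] = f"{chrom}L"
        a[inside] = None
        d = np.full(sel.sum(), np.nan)
        d[left] = cs - m[left]
        d[right] = m[right] - ce
        d[inside] = 0.0
        arm[sel] = a
        centromeric[sel] = inside
        cen_dist[sel] = d

    df["arm"] = arm
    df["centromeric"] = centromeric
    df["cen_dist"] = cen_dist

    arm_index = np.full(len(df), -1, dtype=int)
    for a in pd.unique(df["arm"].dropna()):
        sel = (df["arm"] == a).to_numpy()
        order = np.argsort(cen_dist[sel], kind="stable")
        ranks = np.empty(sel.sum(), dtype=int)
        ranks[order] = np.arange(sel.sum())
        arm_index[sel] = ranks
    df["arm_index"] = arm_index
    return out


def annotate_secondary(fmap: FragmentMap, genome: GenomeModel,
                       secondary_motif: str) -> FragmentMap:
    """Distance from each fragment end to the first secondary site within it.

    ``sec_dist_5p`` = first secondary site start minus fragment start;
    ``sec_dist_3p`` = fragment end minus last secondary site end.  A fragment
    without any fully contained secondary site gets the ``inf`` sentinel on
    both ends (absence is a value, not an error).
    """
    _check_motif(secondary_motif)
    out = fmap.copy()
    df = out.df
    mlen = len(secondary_motif)

    sec5 = np.full(len(df), SEC_ABSENT)
    sec3 = np.full(len(df), SEC_ABSENT)

    for chrom, seq in genome.chromosomes:
        sites = np.array(_find_sites(seq, secondary_motif), dtype=int)
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = df.loc[sel, "start"].to_numpy()
        ends = df.loc[sel, "end"].to_numpy()
        if sites.size:
            # first site fully inside [start, end)
            lo = np.searchsorted(sites, starts, side="left")
            hi = np.searchsorted(sites, ends - mlen, side="right")
            has = hi > lo
            s5 = np.full(sel.sum(), SEC_ABSENT)
            s3 = np.full(sel.sum(), SEC_ABSENT)
            first = sites[np.clip(lo, 0, len(sites) - 1)]
            last = sites[np.clip(hi - 1, 0, len(sites) - 1)]
            s5[has] = first[has] - starts[has]
            s3[has] = ends[has] - (last[has] + mlen)
            sec5[sel] = s5
            sec3[sel] = s3

    df["sec_dist_5p"] = sec5
    df["sec_dist_3p"] = sec3
    return out


def filter_fragments(fmap: FragmentMap, vp: Viewpoint | None,
                     min_vp_dist: int = 1000,
                     min_cen_dist: int = 100_000,
                     max_sec_dist: int = 1000) -> FragmentMap:
    """Apply the standard 4C fragment filters for one viewpoint.

    A fragment is marked invalid when (a) its nearest edge lies closer than
    ``min_vp_dist`` to the viewpoint fragment (self-circles / incomplete
    digestion), (b) its centromere distance is below ``min_cen_dist``
    (poor pericentromeric mappability), or (c) the first secondary site is
    ``max_sec_dist`` or more from *both* fragment ends (absent counts as
    infinitely far).  Centromeric fragments are always invalid.
    Idempotent: validity is recomputed from annotations each call.
    With ``vp=None`` only the viewpoint-independent rules (b) and (c)
    apply — the common grid used when comparing samples across viewpoints.
    """
    df = fmap.df
    if df["arm_index"].eq(-1).all() and not df["centromeric"].any():
        raise ValueError("fragment map must be arm-annotated before filtering")
    if df["sec_dist_5p"].isna().any():
        raise ValueError("fragment map must be secondary-annotated before filtering")

    out = fmap.copy()
    df = out.df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()

    # (a) gap between fragment and viewpoint fragment, same chromosome only
    if vp is not None:
        if vp.fragment is None:
            vp = fmap.resolve_viewpoint(vp)
        vrow = fmap.df[fmap.df["genome_index"] == vp.fragment]
        if vrow.empty:
            raise ValueError(f"viewpoint fragment {vp.fragment} not in map")
        vchrom = vrow["chrom"].iloc[0]
        vstart = int(vrow["start"].iloc[0])
        vend = int(vrow["end"].iloc[0])
        same = (df["chrom"] == vchrom).to_numpy()
        gap = np.maximum(np.maximum(starts - vend, vstart - ends), 0)
        near_vp = same & (gap < min_vp_dist)
    else:
        near_vp = np.zeros(len(df), dtype=bool)

    # (b) centromere proximity (centromeric fragments have cen_dist 0)
    near_cen = (df["cen_dist"].to_numpy() < min_cen_dist) | \
        df["centromeric"].to_numpy()

    # (c) secondary site far from both ends (absent = inf counts)
    sec_far = (df["sec_dist_5p"].to_numpy() >= max_sec_dist) & \
        (df["sec_dist_3p"].to_numpy() >= max_sec_dist)

    df["valid"] = ~(near_vp | near_cen | sec_far)
    return out
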