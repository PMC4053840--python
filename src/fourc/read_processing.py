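"""From raw 4C reads to per-fragment counts.

The stages mirror a standard 4C pre-processing chain: primer demultiplexing
with a restriction-site content check, trimming to a fixed 30 nt, exact-match
mapping against the genome (or import of externally produced alignments),
fragment-end-anchored counting, and fractional rescue of multireads within a
+-50 kb allocation distance.

Demultiplexing removes the primer and the full primary restriction site, so a
forward-strand read starts ``len(motif) - cut_offset`` bp inside its source
fragment (fragment boundaries sit at cut positions).  ``end_anchor_offsets``
computes the matching per-strand anchor offsets; ``count_fragment_reads``
defaults both offsets to 0 so it can also consume alignments that were
trimmed to start exactly at fragment boundaries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_digest import FragmentMap, GenomeModel, Viewpoint

__all__ = [
    "DemuxedRead",
    "FragmentCounts",
    "ExactMatcher",
    "demultiplex",
    "map_reads_exact",
    "count_fragment_reads",
    "allocate_multireads",
    "end_anchor_offsets",
    "read_fastq",
    "read_alignments_bed",
]

READ_LENGTH = 30
MAX_HITS = 25  # reads with more exact hits are discarded

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def end_anchor_offsets(motif: str, cut_offset: int) -> tuple[int, int]:
    """Per-strand anchor offsets for reads trimmed of primer + full site.

    With fragment boundaries at cut positions, a forward read begins
    ``len(motif) - cut_offset`` bp after the fragment 5' boundary and a
    reverse read ends ``cut_offset`` bp before the fragment 3' boundary.
    """
    return len(motif) - cut_offset, cut_offset


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DemuxedRead:
    viewpoint: str
    sample: str
    seq: str  # exactly READ_LENGTH nt

    def __post_init__(self) -> None:
        if len(self.seq) != READ_LENGTH:
            raise ValueError(f"demuxed read must be {READ_LENGTH} nt")


@dataclass
class FragmentCounts:
    """Per-viewpoint / per-sample (possibly fractional) counts over fragments.

    ``counts`` is indexed by genome_index over the whole fragment map;
    counts on invalid fragments are retained (filtering applies downstream).
    """

    viewpoint: str
    sample: str
    counts: np.ndarray
    tallies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("fragment counts must be non-negative")

    @property
    def library_size(self) -> float:
        return float(self.counts.sum())

    def scaled(self, per: float = 1e6) -> np.ndarray:
        lib = self.library_size
        return self.counts * (per / lib) if lib else self.counts.copy()

    def to_tsv(self, path, fmap: FragmentMap) -> None:
        out = fmap.df[["genome_index", "chrom", "start", "end"]].copy()
        out["count"] = self.counts
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, viewpoint: str = "", sample: str = "") -> "FragmentCounts":
        df = pd.read_csv(path, sep="\t")
        counts = np.zeros(int(df["genome_index"].max()) + 1)
        counts[df["genome_index"].to_numpy()] = df["count"].to_numpy()
        return cls(viewpoint, sample, counts)


# ---------------------------------------------------------------------------
# FASTQ / alignment IO
# ---------------------------------------------------------------------------

def read_fastq(path):
    """Yield (name, sequence) from a FASTQ file, gzip-aware."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()  # +
            fh.readline()  # quality
            yield header[1:].split()[0], seq


def read_alignments_bed(path) -> pd.DataFrame:
    """Import external alignments as BED6-like TSV.

    Columns: chrom, start, end, read_id (name), multiplicity (score), strand.
    Enters the pipeline at :func:`count_fragment_reads`.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "read_id",
                            "multiplicity", "strand"])
    return df


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(reads, viewpoints: list[Viewpoint], primary_motif: str,
                sample: str = "", require_site: bool | dict = True,
                trim_len: int = READ_LENGTH):
    """Split reads by exact primer prefix and trim to ``trim_len`` nt.

    A read is assigned iff it begins with exactly one viewpoint's primer
    (zero mismatches) and, when the site check is enabled for that
    viewpoint, the primary restriction motif directly follows the primer.
    Primer and motif are removed; the remainder is trimmed to ``trim_len``;
    shorter remainders are discarded.  Returns ``(demuxed, tallies)`` where
    tallies partition the input: assigned (per viewpoint) + no_primer +
    ambiguous + no_site + too_short = number of input reads.
    """
    primers = {}
    for vp in viewpoints:
        if vp.primer_seq in primers:
            raise ValueError(
                f"viewpoints {primers[vp.primer_seq]} and {vp.name} share "
                f"primer {vp.primer_seq}")
        primers[vp.primer_seq] = vp.name

    def _site_required(vp_name: str) -> bool:
        if isinstance(require_site, dict):
            return require_site.get(vp_name, True)
        return bool(require_site)

    tallies = {"assigned": {vp.name: 0 for vp in viewpoints},
               "no_primer": 0, "ambiguous": 0, "no_site": 0, "too_short": 0,
               "input": 0}
    out: list[DemuxedRead] = []
    mlen = len(primary_motif)

    for _, seq in reads:
        tallies["input"] += 1
        matches = [(p, name) for p, name in primers.items()
                   if seq.startswith(p)]
        if not matches:
            tallies["no_primer"] += 1
            continue
        if len(matches) > 1:
            tallies["ambiguous"] += 1
            continue
        primer, vp_name = matches[0]
        rest = seq[len(primer):]
        if _site_required(vp_name):
            if not rest.startswith(primary_motif):
                tallies["no_site"] += 1
                continue
            rest = rest[mlen:]
        elif rest.startswith(primary_motif):
            rest = rest[mlen:]
        if len(rest) < trim_len:
            tallies["too_short"] += 1
            continue
        tallies["assigned"][vp_name] += 1
        out.append(DemuxedRead(vp_name, sample, rest[:trim_len]))
    return out, tallies


# ---------------------------------------------------------------------------
# exact-match mapping
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer of an encoded sequence into uint64.

    Returns (packed codes, valid mask); windows containing N are invalid.
    k <= 31 so the packing is a perfect hash (no collisions).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    packed = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    isn = codes == 255
    for j in range(k):
        window = codes[j:j + n]
        packed = (packed << np.uint64(2)) | window.astype(np.uint64)
        bad |= isn[j:j + n]
    # N windows get an impossible sentinel so they never match a read
    packed[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return packed, ~bad


def _seq_code(seq: str, k: int) -> int | None:
    codes = _encode(seq)
    if (codes == 255).any() or len(codes) != k:
        return None
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


class ExactMatcher:
    """Exact 30-mer lookup over both genome strands.

    Genome k-mers are 2-bit packed into uint64 (a perfect hash for k <= 31)
    and sorted once; queries resolve via binary search.  Reverse-strand hits
    are found by looking up the reverse complement of the read against the
    forward-strand index.
    """

    def __init__(self, genome: GenomeModel, k: int = READ_LENGTH):
        self.k = k
        self.chrom_ids = genome.ids
        codes_all, chrom_all, pos_all = [], [], []
        for ci, (chrom, seq) in enumerate(genome.chromosomes):
            packed, valid = _kmer_codes(_encode(seq), k)
            idx = np.flatnonzero(valid)
            codes_all.append(packed[idx])
            chrom_all.append(np.full(len(idx), ci, dtype=np.int32))
            pos_all.append(idx.astype(np.int64))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._chrom = np.concatenate(chrom_all)[order] if codes_all else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_all)[order] if codes_all else np.empty(0, np.int64)

    def lookup(self, seq: str) -> list[tuple[str, int, int, str]]:
        """All exact hits of a k-mer: list of (chrom, start, end, strand)."""
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != {self.k}")
        hits = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            code = _seq_code(query, self.k)
            if code is None:
                continue
            code = np.uint64(code)
            lo = np.searchsorted(self._codes, code, side="left")
            hi = np.searchsorted(self._codes, code, side="right")
            for i in range(lo, hi):
                chrom = self.chrom_ids[self._chrom[i]]
                start = int(self._pos[i])
                hits.append((chrom, start, start + self.k, strand))
        # palindromic queries produce the same hit twice; deduplicate
        return sorted(set(hits))


def map_reads_exact(reads: list[DemuxedRead], genome: GenomeModel,
                    matcher: ExactMatcher | None = None):
    """Map demuxed 30-mers with zero mismatches on both strands.

    Returns ``(alignments, tallies)``: a DataFrame with columns read_id,
    viewpoint, sample, chrom, start, end, strand, multiplicity, and a tally
    of unmapped / unique / multi / discarded (> MAX_HITS hits) reads.
    """
    if matcher is None:
        matcher = ExactMatcher(genome)
    rows = []
    tallies = {"unmapped": 0, "unique": 0, "multi": 0, "discarded": 0}
    # deduplicate identical read sequences: look each distinct 30-mer up once
    cache: dict[str, list] = {}
    for rid, read in enumerate(reads):
        if len(read.seq) != READ_LENGTH:
            raise ValueError("reads must be trimmed to 30 nt before mapping")
        hits = cache.get(read.seq)
        if hits is None:
            hits = matcher.lookup(read.seq)
            cache[read.seq] = hits
        if not hits:
            tallies["unmapped"] += 1
            continue
        if len(hits) > MAX_HITS:
            tallies["discarded"] += 1
            continue
        tallies["unique" if len(hits) == 1 else "multi"] += 1
        for chrom, start, end, strand in hits:
            rows.append((rid, read.viewpoint, read.sample, chrom, start, end,
                         strand, len(hits)))
    alignments = pd.DataFrame(
        rows, columns=["read_id", "viewpoint", "sample", "chrom", "start",
                       "end", "strand", "multiplicity"])
    return alignments, tallies


# ---------------------------------------------------------------------------
# fragment-end counting
# ---------------------------------------------------------------------------

def count_fragment_reads(alignments: pd.DataFrame, fmap: FragmentMap,
                         fwd_offset: int = 0, rev_offset: int = 0,
                         end_tolerance: int = 0):
    """End-anchored counting of alignments onto restriction fragments.

    A hit is counted for a fragment iff it is end-anchored: a forward-strand
    hit starting at ``fragment.start + fwd_offset`` or a reverse-strand hit
    ending at ``fragment.end - rev_offset`` (within ``end_tolerance`` bp).
    Interior hits are dropped and tallied as off-end.  Unique hits increment
    counts by one; hits of multireads become candidate fragment lists for
    :func:`allocate_multireads`.

    Returns ``(unique_counts, multiread_candidates, tallies)`` where
    ``unique_counts`` is a float vector over genome_index.
    """
    df = fmap.df
    frag_by_chrom = {
        chrom: sub for chrom, sub in df.groupby("chrom", sort=False)}
    for chrom in alignments["chrom"].unique():
        if chrom not in frag_by_chrom:
            raise ValueError(f"alignment chromosome {chrom} not in fragment map")
        length = fmap.chrom_lengths.get(chrom)
        sub = alignments[alignments["chrom"] == chrom]
        if length is not None and ((sub["start"] < 0).any()
                                   or (sub["end"] > length).any()):
            raise ValueError(f"alignment beyond bounds of chromosome {chrom}")

    counts = np.zeros(len(df), dtype=float)
    tallies = {"counted_unique": 0, "off_end": 0, "multiread_hits": 0}
    candidates: dict[int, list[int]] = {}

    anchored_frag = np.full(len(alignments), -1, dtype=int)
    for chrom, sub in alignments.groupby("chrom", sort=False):
        frags = frag_by_chrom[chrom]
        fstarts = frags["start"].to_numpy()
        fends = frags["end"].to_numpy()
        gidx = frags["genome_index"].to_numpy()
        fwd = (sub["strand"] == "+").to_numpy()
        anchor = np.where(fwd,
                          sub["start"].to_numpy() - fwd_offset,
                          sub["end"].to_numpy() + rev_offset)
        # forward anchors should equal a fragment start, reverse a fragment end
        res = np.full(len(sub), -1, dtype=int)
        j = np.searchsorted(fstarts, anchor[fwd])
        for off in (0, -1, 1):  # nearest candidates under tolerance
            jj = np.clip(j + off, 0, len(fstarts) - 1)
            ok = np.abs(fstarts[jj] - anchor[fwd]) <= end_tolerance
            tgt = res[fwd]
            tgt[ok & (tgt == -1)] = gidx[jj][ok & (tgt == -1)]
            res[fwd] = tgt
        j = np.searchsorted(fends, anchor[~fwd])
        for off in (0, -1, 1):
            jj = np.clip(j + off, 0, len(fends) - 1)
            ok = np.abs(fends[jj] - anchor[~fwd]) <= end_tolerance
            tgt = res[~fwd]
            tgt[ok & (tgt == -1)] = gidx[jj][ok & (tgt == -1)]
            res[~fwd] = tgt
        anchored_frag[sub.index.to_numpy()] = res

    mult = alignments["multiplicity"].to_numpy() if len(alignments) else \
        np.empty(0, dtype=int)
    rid = alignments["read_id"].to_numpy() if len(alignments) else \
        np.empty(0, dtype=int)
    for i in range(len(alignments)):
        frag = anchored_frag[i]
        if mult[i] == 1:
            if frag >= 0:
                counts[frag] += 1.0
                tallies["counted_unique"] += 1
            else:
                tallies["off_end"] += 1
        else:
            if frag >= 0:
                candidates.setdefault(int(rid[i]), []).append(int(frag))
                tallies["multiread_hits"] += 1
            else:
                tallies["off_end"] += 1
    return counts, candidates, tallies


def allocate_multireads(candidates: dict[int, list[int]],
                        unique_counts: np.ndarray, fmap: FragmentMap,
                        allocation_distance: int = 50_000):
    """Distribute each multiread over its candidate fragments in proportion
    to the unique-read mass within ``allocation_distance`` of each candidate
    (fragment midpoints).  Multireads with zero unique support everywhere are
    discarded.  Returns ``(total_counts, tallies)`` with
    ``total_counts = unique_counts + fractional allocations`` and
    conservation: allocated mass equals the number of allocated multireads.
    """
    df = fmap.df
    mid = fmap.midpoints()
    total = np.asarray(unique_counts, dtype=float).copy()
    tallies = {"allocated": 0, "discarded_no_support": 0}

    # prefix sums of unique counts over midpoint-sorted fragments per chrom
    local_mass = np.zeros(len(df))
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        m = mid[idx]
        order = np.argsort(m, kind="stable")
        ms = m[order]
        cs = np.concatenate([[0.0], np.cumsum(unique_counts[idx[order]])])
        lo = np.searchsorted(ms, m - allocation_distance, side="left")
        hi = np.searchsorted(ms, m + allocation_distance, side="right")
        local_mass[idx] = cs[hi] - cs[lo]

    for _, frags in sorted(candidates.items()):
        frags = np.asarray(frags, dtype=int)
        w = local_mass[frags]
        s = w.sum()
        if s <= 0:
            tallies["discarded_no_support"] += 1
            continue
        total[frags] += w / s
        tallies["allocated"] += 1
    return total, tallies
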