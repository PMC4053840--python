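"""Synthetic 4C study generator.

Emulates the statistical structure the analysis assumes, at desk scale, with
full truth tables: multi-chromosome genomes with planted HindIII/DpnII sites
and centromeres, viewpoint-anchored reads whose cis contact probability
decays as a power law of genomic distance, uniform trans background, planted
enriched prey windows, and chromatin-state-dependent epigenetic feature
densities (Beta-distributed, heterochromatic marks high in heterochromatic
domains and mirrored for euchromatic marks).

One master seed; named sub-streams (genome / reads / emd / controls) are
derived deterministically so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_digest import (FragmentMap, GenomeModel, Viewpoint,
                            annotate_arms, annotate_secondary, digest_genome,
                            filter_fragments)
from .read_processing import end_anchor_offsets, revcomp

__all__ = [
    "SimulationConfig",
    "ViewpointSpec",
    "simulate_genome",
    "build_fragment_map",
    "make_viewpoints",
    "plant_prey_windows",
    "sampling_weights",
    "simulate_fragment_counts",
    "simulate_reads",
    "simulate_emd",
    "emd_to_intervals",
    "two_state_pca_fixture",
    "write_fastq",
]

# named RNG sub-streams of the master seed
_STREAM_GENOME = 1
_STREAM_READS = 2
_STREAM_EMD = 3
_STREAM_PREYS = 4
_STREAM_CONTROLS = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ViewpointSpec:
    """Where to place a synthetic viewpoint: chromosome, arm side (S/L),
    relative position along the arm (0 = centromere, 1 = telomere), and the
    chromatin state of its environment (eu/het)."""

    name: str
    chrom: str
    arm_side: str = "S"
    rel_pos: float = 0.5
    state: str = "eu"


@dataclass
class SimulationConfig:
    """Defaults define the standard synthetic study conditions.

    Five 2-Mb chromosomes with centered 100-kb centromeres; HindIII-like
    primary sites every ~4 kb (the natural 6-cutter rate) and DpnII-like
    secondary sites every ~256 bp (4-cutter rate); two viewpoints (one
    euchromatic, one heterochromatic); cis contact decay d**gamma with
    gamma = -0.73 (the pooled decay the analysis is built to recover) and
    half of each library in cis; 20 prey windows of 25 fragments planted at
    8x enrichment; 200,000 reads per viewpoint with a 5% self-ligation
    fraction.  Chromatin domains of ~200 kb are heterochromatic with a
    per-chromosome probability biased toward each viewpoint's declared
    state.
    """

    n_chrom: int = 5
    chrom_length: int = 2_000_000
    centromere_width: int = 100_000
    centromere_center_rel: float = 0.5  # relative position along the chromosome
    primary_motif: str = "AAGCTT"
    primary_cut_offset: int = 1
    secondary_motif: str = "GATC"
    secondary_cut_offset: int = 0
    primary_spacing: float | None = 4_000.0
    secondary_spacing: float | None = 256.0
    viewpoints: list[ViewpointSpec] = field(default_factory=lambda: [
        ViewpointSpec("VP_EU", "chr1", "S", 0.5, "eu"),
        ViewpointSpec("VP_HET", "chr3", "L", 0.5, "het"),
    ])
    gamma: float = -0.73
    cis_fraction: float = 0.5
    n_prey_windows: int = 20          # total across viewpoints
    prey_window_fragments: int = 25
    prey_enrichment: float = 8.0
    library_size: int = 200_000
    self_ligation_fraction: float = 0.05
    primer_length: int = 20
    domain_length: int = 200_000
    het_fraction_default: float = 0.5
    het_fraction_biased: float = 0.85  # on a viewpoint's home chromosome
    het_marks: tuple = ("H3K27me1", "H3K9me2")
    eu_marks: tuple = ("H3K36me3", "H3K4me2")
    het_mark_means: tuple = (0.6, 0.1)   # (in het domains, in eu domains)
    beta_concentration: float = 20.0
    min_vp_dist: int = 1_000
    min_cen_dist: int = 100_000
    max_sec_dist: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise ValueError("cis_fraction must lie in [0, 1]")
        if self.prey_enrichment < 1.0:
            raise ValueError("prey enrichment must be >= 1")
        if self.gamma >= 0:
            raise ValueError("decay exponent gamma must be negative")
        bad = [v.name for v in self.viewpoints
               if v.chrom not in self.chrom_ids()]
        if bad:
            raise ValueError(f"viewpoints on missing chromosomes: {bad}")

    def chrom_ids(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def centromere(self, chrom: str) -> tuple[int, int]:
        mid = int(self.chrom_length * self.centromere_center_rel)
        half = self.centromere_width // 2
        mid = min(max(mid, half), self.chrom_length - half)
        return (mid - half, mid + half)

    def het_fraction(self, chrom: str) -> float:
        """Heterochromatin probability of a chromosome's domains: biased
        up on a heterochromatic viewpoint's home chromosome, down on a
        euchromatic one's, default elsewhere."""
        for vp in self.viewpoints:
            if vp.chrom == chrom:
                return (self.het_fraction_biased if vp.state == "het"
                        else 1.0 - self.het_fraction_biased)
        return self.het_fraction_default


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode()) % 100_000


def _stream(config: SimulationConfig, stream: int, *extra: int,
            seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(
        np.random.SeedSequence([int(base) % (2 ** 31), stream, *extra]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _poisson_positions(rng, length: int, spacing: float | None,
                       margin: int, min_gap: int) -> np.ndarray:
    if spacing is None or not np.isfinite(spacing):
        return np.empty(0, dtype=int)
    if spacing <= 0:
        raise ValueError("site spacing must be positive")
    if 2 * spacing > length:
        raise ValueError(f"site spacing {spacing} incompatible with "
                         f"chromosome length {length}")
    n_draw = int(length / spacing * 1.5) + 10
    gaps = rng.exponential(spacing, size=n_draw)
    pos = margin + np.cumsum(gaps)
    pos = pos[pos < length - margin].astype(int)
    if len(pos):
        keep = np.concatenate([[True], np.diff(pos) >= min_gap])
        pos = pos[keep]
    return pos


def _find_motif_positions(seq: np.ndarray, motif_codes: np.ndarray) -> np.ndarray:
    k = len(motif_codes)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    hit = np.ones(n, dtype=bool)
    for j in range(k):
        hit &= seq[j:j + n] == motif_codes[j]
    return np.flatnonzero(hit)


def _encode_motif(motif: str) -> np.ndarray:
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    return np.array([lut[b] for b in motif.encode()], dtype=np.uint8)


def simulate_genome(config: SimulationConfig, seed: int | None = None):
    """Random genome with planted primary/secondary sites and centromeres.

    Motif occurrences exist only where planted: accidental occurrences are
    mutated away (one base inside the occurrence, outside any planted
    window, is resampled) until the scan is clean.  Deterministic under the
    seed; the same seed yields byte-identical sequences.

    Returns ``(GenomeModel, truth)`` with truth holding the planted site
    positions per chromosome.
    """
    rng = _stream(config, _STREAM_GENOME, seed=seed)
    pm = _encode_motif(config.primary_motif)
    sm = _encode_motif(config.secondary_motif)
    chroms = []
    truth = {"primary_sites": {}, "secondary_sites": {}}
    for chrom in config.chrom_ids():
        L = config.chrom_length
        prim = _poisson_positions(rng, L, config.primary_spacing,
                                  margin=100, min_gap=3 * len(pm))
        sec = _poisson_positions(rng, L, config.secondary_spacing,
                                 margin=50, min_gap=2 * len(sm))
        if len(prim) and len(sec):
            # drop secondary sites colliding with a planted primary site
            d = np.min(np.abs(sec[:, None] - prim[None, :]), axis=1)
            sec = sec[d >= len(pm) + len(sm)]
        seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        protected = np.zeros(L, dtype=bool)
        for positions, codes in ((prim, pm), (sec, sm)):
            for p in positions:
                seq[p:p + len(codes)] = codes
                protected[p:p + len(codes)] = True
        planted = {tuple(pm.tobytes()): set(prim.tolist()),
                   tuple(sm.tobytes()): set(sec.tolist())}
        for _ in range(50):
            dirty = False
            for codes in (pm, sm):
                occ = _find_motif_positions(seq, codes)
                extra = [p for p in occ
                         if p not in planted[tuple(codes.tobytes())]]
                for p in extra:
                    window = np.arange(p, p + len(codes))
                    free = window[~protected[window]]
                    if free.size == 0:
                        continue  # fully overlaps planted sites; harmless
                    j = int(free[0])
                    seq[j] = (seq[j] + 1 + rng.integers(0, 3)) % 4
                    dirty = True
            if not dirty:
                break
        chroms.append((chrom, seq))
        truth["primary_sites"][chrom] = prim
        truth["secondary_sites"][chrom] = sec
    decoded = [(c, _BASES[s].tobytes().decode()) for c, s in chroms]
    cens = {c: config.centromere(c) for c in config.chrom_ids()}
    return GenomeModel(decoded, cens), truth


def build_fragment_map(config: SimulationConfig,
                       genome: GenomeModel) -> FragmentMap:
    """Digest + arm + secondary annotation (no viewpoint filter yet)."""
    fmap = digest_genome(genome, config.primary_motif,
                         config.primary_cut_offset)
    fmap = annotate_arms(fmap)
    fmap = annotate_secondary(fmap, genome, config.secondary_motif)
    return fmap


def make_viewpoints(config: SimulationConfig, genome: GenomeModel,
                    fmap: FragmentMap, seed: int | None = None
                    ) -> list[Viewpoint]:
    """Place viewpoints on their requested arms and generate distinct
    motif-free primers for them."""
    rng = _stream(config, _STREAM_GENOME, 99, seed=seed)
    df = fmap.df
    out = []
    primers: set[str] = set()
    for spec in config.viewpoints:
        cs, ce = config.centromere(spec.chrom)
        arm_len = cs if spec.arm_side == "S" else \
            genome.length(spec.chrom) - ce
        target = (cs - spec.rel_pos * arm_len if spec.arm_side == "S"
                  else ce + spec.rel_pos * arm_len)
        target = int(np.clip(target, 1, genome.length(spec.chrom) - 2))
        sub = df[(df["chrom"] == spec.chrom) & ~df["centromeric"] &
                 ((df["end"] - df["start"]) >= 60)]
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        k = int(np.argmin(np.abs(mids - target)))
        position = int(mids[k])
        while True:
            primer = "".join("ACGT"[b] for b in
                             rng.integers(0, 4, config.primer_length))
            if (config.primary_motif not in primer
                    and config.secondary_motif not in primer
                    and primer not in primers
                    and not any(primer.startswith(p) or p.startswith(primer)
                                for p in primers)):
                break
        primers.add(primer)
        vp = Viewpoint(spec.name, spec.chrom, position, primer,
                       config.secondary_motif,
                       fragment=int(sub["genome_index"].iloc[k]))
        out.append(vp)
    return out


# ---------------------------------------------------------------------------
# prey planting and read sampling
# ---------------------------------------------------------------------------

def _filtered(config: SimulationConfig, fmap: FragmentMap,
              vp: Viewpoint) -> FragmentMap:
    return filter_fragments(fmap, vp, config.min_vp_dist,
                            config.min_cen_dist, config.max_sec_dist)


def plant_prey_windows(config: SimulationConfig, fmap: FragmentMap,
                       viewpoints: list[Viewpoint],
                       seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Choose the planted prey windows for each viewpoint.

    Preys are blocks of ``prey_window_fragments`` consecutive valid
    fragments aligned to the non-overlapping window grid, on arms other
    than the viewpoint's own (the viewpoint arm's power-law signal is true
    local interaction, so specificity is planted in trans / on the cis
    arm).  Returns viewpoint -> DataFrame(arm, win_index, fragments).
    """
    from .interaction_windows import build_windows

    rng = _stream(config, _STREAM_PREYS, seed=seed)
    per_vp = int(round(config.n_prey_windows / max(len(viewpoints), 1)))
    truth = {}
    for vp in viewpoints:
        fm = _filtered(config, fmap, vp)
        track = build_windows(fm, config.prey_window_fragments,
                              config.prey_window_fragments)
        varm = fm.arm_of_fragment(vp.fragment)
        pool = track.df[track.df["arm"] != varm]
        take = min(per_vp, len(pool))
        rows = pool.iloc[np.sort(rng.choice(len(pool), take, replace=False))]
        frags = [track.members(int(i)).tolist() for i in rows.index]
        truth[vp.name] = pd.DataFrame({
            "arm": rows["arm"].to_numpy(),
            "win_index": rows["win_index"].to_numpy(),
            "fragments": frags,
        })
    return truth


def sampling_weights(config: SimulationConfig, fmap: FragmentMap,
                     vp: Viewpoint,
                     prey_fragments: np.ndarray | None = None,
                     cis_fraction: float | None = None,
                     gamma: float | None = None) -> np.ndarray:
    """Per-fragment read sampling probabilities for one viewpoint.

    Cis (viewpoint-arm) fragments carry mass ``cis_fraction`` distributed
    proportional to d**gamma (d = midpoint distance, floored at 1 kb);
    remaining mass (minus self-ligation) is uniform per fragment over all
    other arms; prey fragments have their mass multiplied by the
    enrichment factor before the final normalization.
    """
    gamma = config.gamma if gamma is None else gamma
    cis_fraction = (config.cis_fraction if cis_fraction is None
                    else cis_fraction)
    df = fmap.df
    mid = fmap.midpoints()
    long_enough = (df["end"] - df["start"]).to_numpy() >= 60
    eligible = df["valid"].to_numpy() & long_enough
    varm = fmap.arm_of_fragment(vp.fragment)
    w = np.zeros(len(df))

    on_arm = (df["arm"] == varm).to_numpy() & eligible
    d = np.maximum(np.abs(mid - vp.position), 1e3)
    if on_arm.any() and cis_fraction > 0:
        cis_w = d[on_arm] ** gamma
        w[on_arm] = cis_w / cis_w.sum() * cis_fraction

    self_frac = config.self_ligation_fraction
    off_arm = (df["arm"] != varm).to_numpy() & df["arm"].notna().to_numpy() \
        & eligible
    off_mass = max(1.0 - cis_fraction - self_frac, 0.0)
    if off_arm.any() and off_mass > 0:
        w[off_arm] = off_mass / off_arm.sum()

    vrow = df.index[df["genome_index"] == vp.fragment]
    if len(vrow) and long_enough[vrow[0]] and self_frac > 0:
        w[vrow[0]] += self_frac

    if prey_fragments is not None and len(prey_fragments):
        sel = np.isin(df["genome_index"].to_numpy(), prey_fragments)
        w[sel] *= config.prey_enrichment
    total = w.sum()
    if total <= 0:
        raise ValueError("no eligible fragments to sample reads from")
    return w / total


def simulate_fragment_counts(config: SimulationConfig, fmap: FragmentMap,
                             vp: Viewpoint, n_reads: int,
                             seed: int | None = None,
                             prey_fragments: np.ndarray | None = None,
                             cis_fraction: float | None = None,
                             gamma: float | None = None) -> np.ndarray:
    """Multinomial fragment counts under the sampling model (the fast,
    distance-level path used for statistical experiments; the sequence
    path is :func:`simulate_reads`)."""
    rng = _stream(config, _STREAM_READS, _name_key(vp.name), seed=seed)
    w = sampling_weights(config, fmap, vp, prey_fragments,
                         cis_fraction, gamma)
    return rng.multinomial(n_reads, w).astype(float)


def simulate_reads(config: SimulationConfig, genome: GenomeModel,
                   fmap: FragmentMap, vp: Viewpoint,
                   prey_fragments: np.ndarray | None = None,
                   seed: int | None = None, n_reads: int | None = None):
    """Emit raw 4C reads (primer + primary site + 30 nt of fragment end).

    Each read's source fragment is drawn from :func:`sampling_weights`;
    the read carries the first 30 nt of the fragment's 5' end (forward) or
    the last 30 nt before its 3' end (reverse complement), offset past the
    restriction-site remainder so demultiplexed reads anchor exactly.
    Returns ``(reads, truth)``: reads as (name, sequence) pairs, truth a
    DataFrame with the source fragment and strand per read.
    """
    rng = _stream(config, _STREAM_READS, _name_key(vp.name), 7, seed=seed)
    n = config.library_size if n_reads is None else n_reads
    w = sampling_weights(config, fmap, vp, prey_fragments)
    df = fmap.df
    frag_rows = rng.choice(len(df), size=n, p=w)
    strands = rng.random(n) < 0.5
    fwd_off, rev_off = end_anchor_offsets(config.primary_motif,
                                          config.primary_cut_offset)
    seqs = {c: s for c, s in genome.chromosomes}
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    gidx = df["genome_index"].to_numpy()
    reads = []
    rows = []
    prefix = vp.primer_seq + config.primary_motif
    for i in range(n):
        r = frag_rows[i]
        seq = seqs[chroms[r]]
        if strands[i]:
            s = starts[r] + fwd_off
            insert = seq[s:s + 30]
            strand = "+"
        else:
            e = ends[r] - rev_off
            insert = revcomp(seq[e - 30:e])
            strand = "-"
        name = f"{vp.name}_r{i}"
        reads.append((name, prefix + insert))
        rows.append((name, int(gidx[r]), strand))
    truth = pd.DataFrame(rows, columns=["read", "fragment", "strand"])
    return reads, truth


def write_fastq(path, reads) -> None:
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# chromatin domains and feature densities
# ---------------------------------------------------------------------------

def simulate_emd(config: SimulationConfig, fmap: FragmentMap,
                 seed: int | None = None):
    """State-dependent feature densities per fragment.

    Chromosomes are tiled with ~``domain_length`` domains, each
    heterochromatic with the chromosome's het probability.  Every feature's
    fragment density is Beta-distributed with a state-dependent mean:
    heterochromatic marks average ``het_mark_means[0]`` in het domains and
    ``het_mark_means[1]`` in eu domains; euchromatic marks are mirrored.

    Returns ``(tracks, domains)``: feature -> density vector over
    genome_index, and a DataFrame of domain intervals with their states.
    """
    from .epigenome_enrichment import EMDTrack

    rng = _stream(config, _STREAM_EMD, seed=seed)
    df = fmap.df
    mid = fmap.midpoints()
    dom_rows = []
    frag_state = np.empty(len(df), dtype=object)
    for chrom, length in fmap.chrom_lengths.items():
        p_het = config.het_fraction(chrom)
        edges = np.arange(0, length, config.domain_length)
        edges = np.append(edges, length)
        states = np.where(rng.random(len(edges) - 1) < p_het, "het", "eu")
        for s, e, st in zip(edges[:-1], edges[1:], states):
            dom_rows.append((chrom, int(s), int(e), st))
        sel = (df["chrom"] == chrom).to_numpy()
        b = np.clip(np.searchsorted(edges, mid[sel], side="right") - 1,
                    0, len(states) - 1)
        frag_state[sel] = states[b]
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "state"])

    hi, lo = config.het_mark_means
    k = config.beta_concentration
    tracks: dict[str, EMDTrack] = {}
    is_het = frag_state == "het"
    for feature in (*config.het_marks, *config.eu_marks):
        het_mean = hi if feature in config.het_marks else lo
        eu_mean = lo if feature in config.het_marks else hi
        mean = np.where(is_het, het_mean, eu_mean)
        dens = rng.beta(mean * k, (1.0 - mean) * k)
        tracks[feature] = EMDTrack(feature, dens)
    return tracks, domains


def emd_to_intervals(track, fmap: FragmentMap) -> pd.DataFrame:
    """Presence intervals whose per-fragment coverage fraction reproduces
    the track's densities (for bedGraph/BED export and round-trips)."""
    df = fmap.df
    starts = df["start"].to_numpy()
    lens = (df["end"] - df["start"]).to_numpy()
    cov = np.round(track.frag_density * lens).astype(int)
    sel = cov > 0
    return pd.DataFrame({
        "chrom": df["chrom"].to_numpy()[sel],
        "start": starts[sel],
        "end": starts[sel] + cov[sel],
    })


# ---------------------------------------------------------------------------
# two-state PCA fixture
# ---------------------------------------------------------------------------

def two_state_pca_fixture(config: SimulationConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Mean prey/control EMD matrix for the PCA separation experiment.

    Each viewpoint's prey regions are 25-fragment windows in domains of its
    own chromatin state on other chromosomes; its control regions are
    random windows from its home chromosome, whose domain composition is
    biased toward the same state (heterochromatic viewpoints inhabit
    heterochromatic surroundings).  Rows are (viewpoint, group), columns
    features; feed to :func:`fourc.epigenome_enrichment.pca_prey_control`.
    """
    from .interaction_windows import build_windows

    genome, _ = simulate_genome(config, seed=seed)
    fmap = build_fragment_map(config, genome)
    vps = make_viewpoints(config, genome, fmap, seed=seed)
    tracks, domains = simulate_emd(config, fmap, seed=seed)
    rng = _stream(config, _STREAM_CONTROLS, seed=seed)

    rows = {}
    for vp in vps:
        spec = next(s for s in config.viewpoints if s.name == vp.name)
        fm = _filtered(config, fmap, vp)
        wt = build_windows(fm, config.prey_window_fragments,
                           config.prey_window_fragments)
        members = wt.member_matrix()
        wdf = wt.df
        mid = fmap.midpoints()
        # majority domain state per window
        dom = domains[domains["state"] == "het"]
        het_frac = np.zeros(len(wdf))
        for chrom, sub in dom.groupby("chrom"):
            csel = (wdf["chrom"] == chrom).to_numpy()
            if not csel.any():
                continue
            win_members = members[csel]
            fm_mid = mid[win_members]
            inside = np.zeros(win_members.shape, dtype=bool)
            for _, d in sub.iterrows():
                inside |= (fm_mid >= d["start"]) & (fm_mid < d["end"])
            het_frac[csel] = inside.mean(axis=1)
        want_het = spec.state == "het"
        state_match = het_frac > 0.5 if want_het else het_frac < 0.5
        off_chrom = (wdf["chrom"] != vp.chrom).to_numpy()
        on_chrom = ~off_chrom
        prey_pool = np.flatnonzero(state_match & off_chrom)
        ctrl_pool = np.flatnonzero(on_chrom)
        n_sel = 50
        prey_idx = rng.choice(prey_pool, min(n_sel, len(prey_pool)),
                              replace=len(prey_pool) < n_sel)
        ctrl_idx = rng.choice(ctrl_pool, min(n_sel, len(ctrl_pool)),
                              replace=len(ctrl_pool) < n_sel)
        for group, idx in (("prey", prey_idx), ("control", ctrl_idx)):
            vals = {}
            for feature, track in tracks.items():
                wdens = track.frag_density[members].mean(axis=1)
                vals[feature] = float(wdens[idx].mean())
            rows[(vp.name, group)] = vals
    mat = pd.DataFrame(rows).T
    mat.index.names = ["viewpoint", "group"]
    return mat
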