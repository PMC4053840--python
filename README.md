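# fourc

Analysis of circular chromosome conformation capture (4C-seq) experiments:
from restriction-fragment maps and raw viewpoint-anchored reads to genome-wide
interaction calls and their chromosome-architecture and epigenome statistics.

4C measures, for one chosen restriction fragment (the *viewpoint*), how often
every other region of the genome contacts it in the nucleus.  `fourc`
implements a complete fragment-based analysis of such libraries for compact
genomes organised around centromeric chromosome arms (the design follows
studies of the *Arabidopsis* interactome, but any FASTA + centromere BED
works), together with a synthetic-data generator that reproduces the
statistical structure of such experiments so every stage can be validated at
desk scale without any external download.

## What it computes

**Fragment map** — an in-silico digest of the genome at the primary enzyme's
motif (HindIII `A^AGCTT` by default), annotated per fragment with chromosome
arm, centromere distance, and the distance from each end to the first
secondary-enzyme site (DpnII `^GATC`).  Standard 4C filters mark fragments
invalid when they lie within 1 kb of the viewpoint, within 100 kb of a
centromere, or have no secondary site within 1 kb of either end.

**Read processing** — primer demultiplexing with zero mismatches and a
restriction-site content check, trimming to 30 nt, exact-match mapping on
both strands (or import of external alignments), fragment-end-anchored
counting, and fractional rescue of multimapping reads proportional to the
unique-read mass within ±50 kb.

**Interaction calls** — windows of w consecutive valid fragments (100
overlapping or 25 non-overlapping) scored with the interaction value
v = Σᵢ log₂(nᵢ) over member fragments.  Significance comes from a per-arm
shuffle null: fragment counts are permuted among the arm's valid fragments
1,000 times, a normal distribution is fitted to each shuffle's window
values, and the final P is the mean upper-tail probability over shuffles.
Windows with P ≤ 0.01 (or P < 0.01 in both replicates) are *preys*.

**Architecture statistics** — Spearman correlation and average-linkage
clustering of window read sums across samples; the cis contact decay
P(d) ∝ d^γ estimated from 41 log₁₀-distance bins over 1 kb–10 Mb smoothed
by LOESS and fitted by least squares; reads-per-million per chromosome-arm
class (viewpoint / cis / trans arms, with a ±2 Mb viewpoint exclusion) and
paired t-tests; dist₀.₅, the centromere distance containing half of an
arm's reads; and the two viewpoint-position regressions
(arcsin√dist₀.₅-rel vs relative viewpoint distance, trans RPKM vs absolute
viewpoint distance).

**Epigenome integration** — epigenetic modification density (EMD: the
covered fraction of each fragment's bases) per feature track, covariance
PCA of mean prey/control EMDs, a resampled 50-vs-50 permutation test of
absolute EMD differences, and a GSEA-like enrichment score (regions sorted
by EMD; test regions weigh (n−m)/m, others −1; ES = max |running sum|)
with empirical P-values and Benjamini–Hochberg FDR across features.

## Worked example

Simulate one viewpoint at the telomeric end of a ~10 Mb arm, draw 100,000
cis reads whose per-fragment contact probability decays as d^−0.73, and
recover the exponent with the binned LOESS estimator:

```python
from fourc import (FragmentCounts, SimulationConfig, ViewpointSpec,
                   build_fragment_map, decay_profile, fit_decay_exponent,
                   make_viewpoints, simulate_fragment_counts, simulate_genome)
from fourc.genome_digest import filter_fragments

cfg = SimulationConfig(
    n_chrom=1, chrom_length=10_400_000, centromere_width=200_000,
    centromere_center_rel=0.99,
    viewpoints=[ViewpointSpec("VP", "chr1", "S", 1.0, "eu")],
    cis_fraction=1.0, self_ligation_fraction=0.0, n_prey_windows=0, seed=1)

genome, _ = simulate_genome(cfg)
fmap = build_fragment_map(cfg, genome)
vp = make_viewpoints(cfg, genome, fmap)[0]
fm = filter_fragments(fmap, vp)

counts = simulate_fragment_counts(cfg, fm, vp, 100_000, gamma=-0.73)
profile = decay_profile(FragmentCounts("VP", "demo", counts), vp, fm)
slope, fit_p, _ = fit_decay_exponent(profile)

print(f"fragments: {len(fmap)}")
print(f"windows with reads: {int((profile.n_reads > 0).sum())} of 41 bins")
print(f"fitted decay exponent: {slope:.3f}  (fit P = {fit_p:.2e})")
```

prints

```
fragments: 2473
windows with reads: 31 of 41 bins
fitted decay exponent: -0.728  (fit P = 1.30e-93)
```

The ~4 kb mean fragment spacing matches the natural HindIII rate, the
low-distance bins hold at most a fragment or two (which is what the LOESS
smoothing is for), and the fitted exponent recovers the generating −0.73.

The same machinery runs end to end from a single config — genome and read
simulation, demultiplexing, mapping, counting, windows, P-values, preys,
statistics and enrichment:

```sh
fourc run --config toy.json --out results/ --seed 1
```

with a config like

```json
{"simulate": {"n_chrom": 5, "chrom_length": 2000000,
              "library_size": 200000, "n_prey_windows": 20},
 "n_shuffles": 1000, "prey_threshold": 0.01}
```

Every stage is also exposed as its own subcommand (`fourc digest`,
`fourc demux`, `fourc count`, `fourc windows`, `fourc pvalues`,
`fourc preys`, `fourc decay`, `fourc arms`, `fourc dist50`,
`fourc correlate`, `fourc emd`, `fourc enrich`, `fourc simulate`) over
plain-text formats (FASTA, FASTQ, BED, bedGraph, TSV).

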