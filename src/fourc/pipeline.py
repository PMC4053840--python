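"""End-to-end orchestration behind one configuration file.

``run_pipeline`` wires the stages in method order — digest, demultiplex +
count, windows + shuffle P-values, prey calling, architecture statistics,
epigenome enrichment — over either simulated inputs (a ``simulate`` section
in the config) or files on disk (FASTA genome, centromere BED, FASTQ reads
or imported alignments, feature bedGraphs).  Every run writes its resolved
configuration, a structured log of parameters/seeds/tallies, and a manifest
of produced files; reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture_stats as arch
from . import epigenome_enrichment as epi
from . import interaction_windows as iw
from . import read_processing as rp
from . import synthetic_data as syn
from .genome_digest import (FragmentMap, GenomeModel, Viewpoint,
                            annotate_arms, annotate_secondary, digest_genome,
                            filter_fragments)

log = logging.getLogger("fourc.pipeline")

DEFAULTS = {
    "primary_motif": "AAGCTT",
    "primary_cut_offset": 1,
    "secondary_motif": "GATC",
    "min_vp_dist": 1000,
    "min_cen_dist": 100_000,
    "max_sec_dist": 1000,
    "window_size": 100,
    "window_step": 1,
    "prey_window_size": 25,
    "prey_window_step": 25,
    "n_shuffles": 1000,
    "prey_threshold": 0.01,
    "allocation_distance": 50_000,
    "end_tolerance": 0,
    "mask_mb": 2_000_000,
    "decay_d_min": 1000,
    "decay_d_max": 10_000_000,
    "decay_bin_width": 0.1,
    "loess_span": 0.75,
    "n_controls": 50,
    "perm_reps": 1000,
    "gsea_rand": 10_000,
    "seed": 0,
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)


def _resolve(config: dict) -> dict:
    out = dict(DEFAULTS)
    out.update(config or {})
    return out


def _derive_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), *keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: dict | str, outdir=None) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    Raises on any stage failure after writing a manifest that marks the run
    incomplete; partial outputs are retained.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _resolve(config)
    outdir = Path(outdir or cfg.get("outdir", "fourc_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "files": [], "tallies": {}, "stages": []}
    t0 = time.time()

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"].append(name)

    try:
        # ------------------------------------------------------------ inputs
        sim_cfg = None
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"] or {})
            vps_spec = sim_kwargs.pop("viewpoints", None)
            if vps_spec:
                sim_kwargs["viewpoints"] = [
                    syn.ViewpointSpec(**v) for v in vps_spec]
            sim_cfg = syn.SimulationConfig(seed=cfg["seed"], **sim_kwargs)
            genome, _ = syn.simulate_genome(sim_cfg)
            cfg["primary_motif"] = sim_cfg.primary_motif
            cfg["primary_cut_offset"] = sim_cfg.primary_cut_offset
            cfg["secondary_motif"] = sim_cfg.secondary_motif
        else:
            genome = GenomeModel.from_fasta(cfg["genome_fasta"],
                                            cfg["centromere_bed"])
        manifest["stages"].append("inputs")

        # ------------------------------------------------------------ digest
        fmap = digest_genome(genome, cfg["primary_motif"],
                             cfg["primary_cut_offset"])
        fmap = annotate_arms(fmap)
        fmap = annotate_secondary(fmap, genome, cfg["secondary_motif"])
        _emit("fragments.tsv", fmap.to_tsv)
        _emit("fragments.bed", fmap.to_bed)
        manifest["stages"].append("digest")

        # -------------------------------------------------------- viewpoints
        if sim_cfg is not None:
            viewpoints = syn.make_viewpoints(sim_cfg, genome, fmap)
            prey_truth = syn.plant_prey_windows(sim_cfg, fmap, viewpoints)
        else:
            viewpoints = [Viewpoint(**v) for v in cfg["viewpoints"]]
            viewpoints = [fmap.resolve_viewpoint(v) for v in viewpoints]
            prey_truth = None

        fwd_off, rev_off = rp.end_anchor_offsets(cfg["primary_motif"],
                                                 cfg["primary_cut_offset"])

        # --------------------------------------------- reads / demux / count
        counts_by_vp: dict[str, rp.FragmentCounts] = {}
        matcher = rp.ExactMatcher(genome)
        if sim_cfg is not None:
            raw_reads = []
            for vp in viewpoints:
                prey_frags = np.concatenate(
                    [np.asarray(f) for f in
                     prey_truth[vp.name]["fragments"]]) \
                    if len(prey_truth[vp.name]) else np.empty(0, int)
                reads, _ = syn.simulate_reads(
                    sim_cfg, genome, syn._filtered(sim_cfg, fmap, vp),
                    vp, prey_frags)
                raw_reads.extend(reads)
            syn.write_fastq(outdir / "reads.fastq.gz", raw_reads)
            manifest["files"].append("reads.fastq.gz")
        else:
            raw_reads = list(rp.read_fastq(cfg["reads_fastq"]))
        demuxed, demux_tallies = rp.demultiplex(
            raw_reads, viewpoints, cfg["primary_motif"])
        _emit("demux_report.tsv", lambda p: pd.DataFrame(
            [(k, v) for k, v in demux_tallies["assigned"].items()] +
            [(k, v) for k, v in demux_tallies.items() if k != "assigned"],
            columns=["key", "count"]).to_csv(p, sep="\t", index=False))
        for vp in viewpoints:
            mine = [r for r in demuxed if r.viewpoint == vp.name]
            alignments, map_tallies = rp.map_reads_exact(mine, genome,
                                                         matcher)
            unique, cand, count_tallies = rp.count_fragment_reads(
                alignments, fmap, fwd_off, rev_off, cfg["end_tolerance"])
            total, alloc_tallies = rp.allocate_multireads(
                cand, unique, fmap, cfg["allocation_distance"])
            counts = rp.FragmentCounts(vp.name, vp.name, total)
            counts_by_vp[vp.name] = counts
            _emit(f"counts_{vp.name}.tsv",
                  lambda p, c=counts: c.to_tsv(p, fmap))
            manifest["tallies"][vp.name] = {
                "map": map_tallies, "count": count_tallies,
                "alloc": alloc_tallies}
        manifest["tallies"]["demux"] = demux_tallies
        manifest["stages"].append("count")

        # --------------------------------------- windows / P-values / preys
        tracks = {}
        prey_tables = {}
        for vp in viewpoints:
            fm = filter_fragments(fmap, vp, cfg["min_vp_dist"],
                                  cfg["min_cen_dist"], cfg["max_sec_dist"])
            track = iw.build_windows(fm, cfg["prey_window_size"],
                                     cfg["prey_window_step"],
                                     viewpoint=vp.name, sample=vp.name)
            track = iw.window_values(track, counts_by_vp[vp.name])
            track = iw.shuffle_pvalues(
                track, counts_by_vp[vp.name], cfg["n_shuffles"],
                seed=_derive_seed(cfg["seed"], 11, syn._name_key(vp.name)))
            prey_tables[vp.name] = iw.call_preys(track, cfg["prey_threshold"])
            tracks[vp.name] = track
            _emit(f"windows_{vp.name}.tsv", track.to_tsv)
            _emit(f"windows_{vp.name}.bedgraph",
                  lambda p, t=track: t.to_bedgraph(p, "value_scaled"))
            _emit(f"pvalues_{vp.name}.bedgraph",
                  lambda p, t=track: t.to_bedgraph(p, "P"))
            preys = prey_tables[vp.name]
            _emit(f"preys_{vp.name}.bed",
                  lambda p, d=preys: d[d["prey"]][["chrom", "start", "end"]]
                  .to_csv(p, sep="\t", header=False, index=False))
        manifest["stages"].append("windows")

        # common viewpoint-independent grid (filters (b)/(c) only) shared by
        # cross-sample correlation and the enrichment region sets
        common_fm = filter_fragments(fmap, None, cfg["min_vp_dist"],
                                     cfg["min_cen_dist"], cfg["max_sec_dist"])

        # ------------------------------------------------------- statistics
        decay = arch.decay_profile(
            [counts_by_vp[v.name] for v in viewpoints], viewpoints, fmap,
            cfg["decay_d_min"], cfg["decay_d_max"], cfg["decay_bin_width"])
        arch.fit_decay_exponent(decay, span=cfg["loess_span"])
        _emit("decay.tsv", decay.to_tsv)
        manifest["decay_slope"] = decay.slope

        if len(viewpoints) >= 2:
            arm_table, class_table, ttests = arch.arm_class_rpm(
                counts_by_vp, fmap, viewpoints, cfg["mask_mb"])
            _emit("arm_rpm.tsv",
                  lambda p: arm_table.to_csv(p, sep="\t", index=False))
            _emit("arm_rpm_classes.tsv",
                  lambda p: class_table.to_csv(p, sep="\t", index=False))
            manifest["ttests"] = ttests
            # correlations compare samples on a common viewpoint-independent
            # window grid (no per-viewpoint proximity exclusion)
            corr_tracks = []
            for vp in viewpoints:
                t = iw.build_windows(common_fm, cfg["prey_window_size"],
                                     cfg["prey_window_step"],
                                     viewpoint=vp.name, sample=vp.name)
                iw.window_values(t, counts_by_vp[vp.name])
                corr_tracks.append(t)
            if all(len(t) > 1 for t in corr_tracks):
                corr = arch.replicate_correlation(corr_tracks)
                _emit("correlation.tsv", corr.to_tsv)
        d50 = {v.name: arch.dist50_per_arm(counts_by_vp[v.name], fmap, v)
               for v in viewpoints}
        _emit("dist50.tsv", lambda p: pd.concat(d50.values())
              .to_csv(p, sep="\t", index=False))
        if len(viewpoints) >= 3:
            rep1, rep2 = arch.centromere_regressions(
                d50, counts_by_vp, fmap, viewpoints)
            manifest["regressions"] = {
                "dist50": {"slope": rep1.slope, "p": rep1.p, "rho": rep1.rho},
                "trans_rpkm": {"slope": rep2.slope, "p": rep2.p,
                               "rho": rep2.rho}}
        manifest["stages"].append("stats")

        # ------------------------------------------------------- enrichment
        feature_tracks = {}
        if sim_cfg is not None:
            feature_tracks, _ = syn.simulate_emd(sim_cfg, fmap)
        elif cfg.get("feature_tracks"):
            for name, path in cfg["feature_tracks"].items():
                iv = pd.read_csv(path, sep="\t", header=None, comment="#",
                                 usecols=[0, 1, 2],
                                 names=["chrom", "start", "end"])
                feature_tracks[name] = epi.emd_track(iv, fmap, feature=name)
        if feature_tracks:
            # enrichment lives on the common viewpoint-independent grid;
            # each viewpoint's prey windows are matched onto it by span
            # (windows off the viewpoint arm coincide between the grids)
            grid = iw.build_windows(common_fm, cfg["prey_window_size"],
                                    cfg["prey_window_step"])
            members = grid.member_matrix()
            window_emds = {name: ft.frag_density[members].mean(axis=1)
                           for name, ft in feature_tracks.items()}
            gdf = grid.df[["arm", "chrom", "start", "end"]].copy()
            region_sets = {}
            for vp in viewpoints:
                track = tracks[vp.name]
                merged = gdf.merge(
                    track.df[["arm", "chrom", "start", "end", "P", "prey"]],
                    on=["arm", "chrom", "start", "end"], how="left")
                prey_mask = merged["prey"].fillna(False).to_numpy(dtype=bool)
                if not prey_mask.any():
                    continue
                ctrl = epi.select_controls(
                    merged, prey_mask, cfg["n_controls"],
                    seed=_derive_seed(cfg["seed"], 23,
                                      syn._name_key(vp.name)))
                varm = fmap.arm_of_fragment(vp.fragment)
                off_arm = (merged["arm"] != varm).to_numpy()
                region_sets[vp.name] = {
                    "prey": np.flatnonzero(prey_mask),
                    "control_pool": ctrl,
                    "regions": np.flatnonzero(off_arm),
                    "test": np.flatnonzero(prey_mask & off_arm)}
            if region_sets:
                perm = epi.permutation_test(
                    window_emds, region_sets, cfg["perm_reps"],
                    cfg["n_controls"],
                    seed=_derive_seed(cfg["seed"], 31))
                gsea = epi.gsea_like_test(
                    window_emds, region_sets, cfg["gsea_rand"],
                    seed=_derive_seed(cfg["seed"], 37))
                enr = pd.DataFrame(
                    [(f, perm[f].real_diff_mean, perm[f].p, perm[f].q,
                      gsea[f].mean_es, gsea[f].p, gsea[f].q)
                     for f in sorted(window_emds)],
                    columns=["feature", "real_diff_mean", "perm_p", "perm_q",
                             "gsea_es", "gsea_p", "gsea_q"])
                _emit("enrichment.tsv",
                      lambda p: enr.to_csv(p, sep="\t", index=False))
            manifest["stages"].append("enrichment")

        manifest["complete"] = True
    finally:
        manifest["runtime_s"] = round(time.time() - t0, 2)
        (outdir / "resolved_config.json").write_text(
            json.dumps(cfg, indent=2, default=str) + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
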