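"""Shared fixtures: tiny hand-built fragment maps and one session-scoped
default synthetic study (genome, viewpoints, planted preys, counts)."""

import numpy as np
import pandas as pd
import pytest

from fourc import (FragmentCounts, SimulationConfig, ViewpointSpec,
                   build_fragment_map, make_viewpoints, plant_prey_windows,
                   simulate_genome)
from fourc.genome_digest import FragmentMap
from fourc.synthetic_data import _filtered


def make_flat_map(n_frags_per_arm: int, arms: list[str], frag_len: int = 100,
                  chrom_len: int | None = None) -> FragmentMap:
    """A synthetic fragment map built directly (no sequence): each arm is a
    run of equal-length valid fragments with arm_index = position order."""
    dfs = []
    gi = 0
    lengths = {}
    cens = {}
    for arm in arms:
        chrom = arm[:-1]
        n = n_frags_per_arm
        lengths[chrom] = chrom_len or (2 * n * frag_len + 20)
        cens.setdefault(chrom, (lengths[chrom] // 2 - 10,
                                lengths[chrom] // 2 + 10))
        # S-arm blocks occupy the low coordinates, L-arm blocks start past
        # the centromere, so fragments of one chromosome never overlap
        offset = cens[chrom][1] if arm.endswith("L") else 0
        start = offset + np.arange(n) * frag_len
        dfs.append(pd.DataFrame({
            "chrom": chrom, "start": start, "end": start + frag_len,
            "genome_index": np.arange(n) + gi, "arm": arm,
            "centromeric": False, "arm_index": np.arange(n),
            "cen_dist": (np.arange(n) + 1.0) * frag_len,
            "sec_dist_5p": 0.0, "sec_dist_3p": 0.0, "valid": True,
        }))
        gi += n
    df = pd.concat(dfs, ignore_index=True)
    return FragmentMap(df, lengths, motif="AAGCTT", cut_offset=1,
                       centromeres=cens)


@pytest.fixture(scope="session")
def default_study():
    """The standard synthetic study: 5 x 2 Mb chromosomes, two viewpoints,
    20 planted prey windows at 8x enrichment, 200k reads per viewpoint
    (counts drawn at the distance level for speed; the sequence-level read
    path is exercised separately)."""
    cfg = SimulationConfig(seed=20)
    genome, truth = simulate_genome(cfg)
    fmap = build_fragment_map(cfg, genome)
    vps = make_viewpoints(cfg, genome, fmap)
    preys = plant_prey_windows(cfg, fmap, vps)
    return {"config": cfg, "genome": genome, "fmap": fmap,
            "viewpoints": vps, "preys": preys, "site_truth": truth}


@pytest.fixture(scope="session")
def small_study():
    """A fast two-chromosome study used by read-level integration tests."""
    cfg = SimulationConfig(
        n_chrom=2, chrom_length=500_000, centromere_width=60_000,
        library_size=4000, n_prey_windows=4, seed=21,
        viewpoints=[ViewpointSpec("VP_A", "chr1", "S", 0.5, "eu"),
                    ViewpointSpec("VP_B", "chr2", "L", 0.5, "het")])
    genome, _ = simulate_genome(cfg)
    fmap = build_fragment_map(cfg, genome)
    vps = make_viewpoints(cfg, genome, fmap)
    preys = plant_prey_windows(cfg, fmap, vps)
    return {"config": cfg, "genome": genome, "fmap": fmap,
            "viewpoints": vps, "preys": preys}


def filtered_map(study, vp):
    return _filtered(study["config"], study["fmap"], vp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
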