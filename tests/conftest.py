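"""Shared fixtures: one modest synthetic world reused across test modules."""

import numpy as np
import pytest

from nucleocyclic import nucleosome_map, synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg() -> sd.SimConfig:
    return sd.SimConfig(genome_length=120_000, n_promoters=30, seed=3)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Ancestor + strains + per-tissue tags/reads/tracks for the focal strain."""
    ancestor, truth = sd.simulate_ancestor_genome(small_cfg)
    strains, subs = sd.evolve_strains(ancestor, small_cfg)
    truth.substitutions = subs
    tags = sd.simulate_tag_library(truth, small_cfg)
    reads = {
        t: sd.simulate_nucleosome_reads(truth, small_cfg, strains["focal"], t)
        for t in sd.TISSUES
    }
    tracks = {
        t: nucleosome_map.compute_dyad_scores(reads[t], small_cfg.genome_length)
        for t in sd.TISSUES
    }
    return {
        "cfg": small_cfg,
        "ancestor": ancestor,
        "truth": truth,
        "strains": strains,
        "subs": subs,
        "tags": tags,
        "reads": reads,
        "tracks": tracks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
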