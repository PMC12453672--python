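"""Shared fixtures: a hand-written toy panel with countable haplotypes, a
small simulated genome/panel for fast unit tests, and the full default
cohort (built once per session) for the performance checks."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import ploidyscope as ps

# -- hand-countable toy panel (6 haplotypes) ------------------------------

TOY_HAPS_1 = np.array([  # chrom "1", sites at 100, 200, 300
    [0, 0, 0],
    [0, 0, 1],
    [0, 1, 0],
    [1, 1, 0],
    [1, 1, 1],
    [0, 1, 1],
], dtype=np.uint8)

TOY_HAPS_2 = np.array([  # chrom "2", sites at 150, 250
    [0, 0],
    [0, 1],
    [1, 0],
    [1, 1],
    [0, 0],
    [1, 1],
], dtype=np.uint8)


@pytest.fixture(scope="session")
def toy_panel():
    def site_frame(pos, haps):
        f = haps.mean(axis=0)
        return pd.DataFrame({"pos": pos, "ref": ["A"] * len(pos),
                             "alt": ["G"] * len(pos),
                             "maf": np.minimum(f, 1 - f)})

    sites = {"1": site_frame([100, 200, 300], TOY_HAPS_1),
             "2": site_frame([150, 250], TOY_HAPS_2)}
    return ps.HaplotypePanel(sites, {"1": TOY_HAPS_1, "2": TOY_HAPS_2})


def brute_force_likelihood(reads, weights, panel, chrom):
    """Independent oracle: exhaustive k^n assignment sum with direct
    haplotype counting (no shared code with the implementation)."""
    n_hap = panel.n_haplotypes
    haps = panel.haplotypes[chrom]
    positions = list(panel.sites[chrom]["pos"])

    def freq(pattern):
        if not pattern:
            return 1.0
        count = 0
        for h in range(n_hap):
            if all(haps[h, positions.index(p)] == a for p, a in pattern):
                count += 1
        return count / n_hap if count else panel.frequency_floor

    k = len(weights)
    total = 0.0
    for assign in product(range(k), repeat=len(reads)):
        coef = 1.0
        for i in assign:
            coef *= weights[i]
        fprod = 1.0
        for i in range(k):
            fprod *= freq({reads[r] for r in range(len(reads)) if assign[r] == i})
        total += coef * fprod
    return total


# -- small simulated world -------------------------------------------------


@pytest.fixture(scope="session")
def small_genome():
    return ps.default_genome(n_autosomes=4, autosome_length=2_000_000,
                             x_length=1_000_000)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return ps.simulate_panel(small_genome, n_haplotypes=100, seed=1)


@pytest.fixture(scope="session")
def small_tracks(small_genome):
    return ps.simulate_tracks(small_genome, seed=2)


@pytest.fixture(scope="session")
def small_baseline(small_genome, small_panel, small_tracks):
    cohort = ps.simulate_cohort({"diploid": 10}, small_panel, small_genome,
                                small_tracks, seed=99)
    return ps.estimate_baseline([s.obs for s in cohort.samples], small_panel,
                                small_genome, [s.bins for s in cohort.samples])


def make_sample(panel, genome, tracks, ploidy_class, seed, **cfg_kwargs):
    cfg = ps.SimConfig(ploidy_class=ploidy_class, seed=seed, **cfg_kwargs)
    kar = ps.assemble_embryo(cfg, panel, genome)
    obs, bins = ps.sample_reads(kar, panel, genome, tracks, cfg,
                                sample_id=f"{ploidy_class}_{seed}")
    return kar, obs, bins


# -- full default cohort (the study conditions), built once ----------------


@pytest.fixture(scope="session")
def default_world():
    genome = ps.default_genome()
    ss = np.random.SeedSequence(11)
    s_panel, s_tracks, s_base, s_cohort, s_feat = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5)]
    panel = ps.simulate_panel(genome, n_haplotypes=200, seed=s_panel)
    tracks = ps.simulate_tracks(genome, seed=s_tracks)
    base = ps.simulate_cohort({"diploid": 20}, panel, genome, tracks, seed=s_base)
    baseline = ps.estimate_baseline([s.obs for s in base.samples], panel, genome,
                                    [s.bins for s in base.samples])
    return {"genome": genome, "panel": panel, "tracks": tracks,
            "baseline": baseline, "seeds": (s_cohort, s_feat)}


@pytest.fixture(scope="session")
def default_cohort_features(default_world):
    """Feature matrix for the 50/25/15 cohort at default depth/error."""
    w = default_world
    s_cohort, s_feat = w["seeds"]
    cohort = ps.simulate_cohort({"diploid": 50, "triploid": 25, "gwupd": 15},
                                w["panel"], w["genome"], w["tracks"], seed=s_cohort)
    mat = ps.cohort_features(cohort, w["panel"], w["genome"], w["baseline"],
                             seed=s_feat)
    return mat, cohort
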