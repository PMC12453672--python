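"""Copy-number stage: normalisation, HMM segmentation, state bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ploidyscope as ps
from ploidyscope.cnv import band_state, call_states, normalize_bins, segment_hmm

from conftest import make_sample


def flat_bins(genome, count=200.0, gc=0.45, mappability=1.0):
    frames = []
    for chrom in genome.chroms:
        n = genome.n_bins(chrom)
        starts = np.arange(n) * genome.bin_size + 1
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + genome.bin_size - 1,
                              genome.chrom_lengths[chrom]),
            "count": count, "gc": gc, "mappability": mappability}))
    return ps.BinnedCoverage(pd.concat(frames, ignore_index=True), "flat")


class TestNormalize:
    def test_flat_input_normalises_to_exactly_two(self, small_genome):
        norm = normalize_bins(flat_bins(small_genome), None, small_genome)
        assert np.allclose(norm.df["copy_ratio"], 2.0)

    def test_whole_genome_uniform_scaling_is_unidentifiable(self, small_genome):
        # a triploid's global x1.5 coverage is absorbed by the median
        # rescale: that is why LLR/heterozygosity evidence is needed at all
        norm1 = normalize_bins(flat_bins(small_genome, 200.0), None, small_genome)
        norm15 = normalize_bins(flat_bins(small_genome, 300.0), None, small_genome)
        assert np.allclose(norm1.df["copy_ratio"], norm15.df["copy_ratio"])

    def test_low_mappability_fraction_rejected(self, small_genome):
        bins = flat_bins(small_genome, mappability=0.1)
        with pytest.raises(ValueError, match="mappability"):
            normalize_bins(bins, None, small_genome)

    def test_trisomy_within_diploid_context_recovers_three(self):
        # dosage oracle: one trisomic chromosome among 10 diploid ones
        genome = ps.GenomeSpec(
            chrom_lengths={str(i): 6_000_000 for i in range(1, 11)})
        rng = np.random.default_rng(2)
        meds = []
        for _ in range(8):
            frames = []
            for chrom in genome.chroms:
                n = genome.n_bins(chrom)
                starts = np.arange(n) * genome.bin_size + 1
                scale = 1.5 if chrom == "2" else 1.0
                frames.append(pd.DataFrame({
                    "chrom": chrom, "start": starts,
                    "end": starts + genome.bin_size - 1,
                    "count": rng.poisson(200 * scale, n).astype(float),
                    "gc": 0.45, "mappability": 1.0}))
            bins = ps.BinnedCoverage(pd.concat(frames, ignore_index=True), "t")
            norm = normalize_bins(bins, None, genome)
            meds.append(norm.df[norm.df["chrom"] == "2"]["copy_ratio"].median())
        assert np.mean(meds) == pytest.approx(3.0, abs=0.1)


class TestSegmentation:
    def test_constant_ratio_gives_one_segment_per_chromosome(self, small_genome):
        norm = normalize_bins(flat_bins(small_genome), None, small_genome)
        segs = segment_hmm(norm, small_genome)
        assert len(segs) == len(small_genome.chroms)
        assert (segs["copy_ratio"] == 2.0).all()

    def test_unnormalized_input_rejected(self, small_genome):
        with pytest.raises(ValueError, match="normalize"):
            segment_hmm(flat_bins(small_genome), small_genome)

    def test_deletion_boundaries_recovered_within_one_bin(self):
        # 20 Mb deletion (ratio 1.0) inside a 60 Mb diploid chromosome
        genome = ps.GenomeSpec(chrom_lengths={"1": 60_000_000})
        rng = np.random.default_rng(0)
        n = genome.n_bins("1")
        starts = np.arange(n) * genome.bin_size + 1
        hits = 0
        n_seeds = 10
        del_lo, del_hi = 20_000_000, 40_000_000
        for _ in range(n_seeds):
            lam = np.where((starts >= del_lo) & (starts < del_hi), 100.0, 200.0)
            bins = ps.BinnedCoverage(pd.DataFrame({
                "chrom": "1", "start": starts,
                "end": starts + genome.bin_size - 1,
                "count": rng.poisson(lam).astype(float),
                "gc": 0.45, "mappability": 1.0}), "d")
            norm = normalize_bins(bins, None, genome)
            segs = segment_hmm(norm, genome)
            dels = segs[segs["copy_ratio"] < 1.5]
            if len(dels) == 1:
                lo, hi = int(dels["start"].iloc[0]), int(dels["end"].iloc[0])
                if (abs(lo - del_lo) <= genome.bin_size
                        and abs(hi - del_hi) <= genome.bin_size):
                    hits += 1
        assert hits >= 0.9 * n_seeds

    def test_forty_percent_mosaic_loss_lands_in_mosaic_band(self):
        # dosage mixture: 0.4 x 1 + 0.6 x 2 = 1.6, inside [1.3, 1.7)
        genome = ps.GenomeSpec(
            chrom_lengths={str(i): 15_000_000 for i in range(1, 9)})
        rng = np.random.default_rng(1)
        frames = []
        for chrom in genome.chroms:
            scale = 0.8 if chrom == "1" else 1.0  # 1.6 on the 2.0 scale
            n = genome.n_bins(chrom)
            starts = np.arange(n) * genome.bin_size + 1
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts,
                "end": starts + genome.bin_size - 1,
                "count": rng.poisson(200 * scale, n).astype(float),
                "gc": 0.45, "mappability": 1.0}))
        bins = ps.BinnedCoverage(pd.concat(frames, ignore_index=True), "m")
        norm = normalize_bins(bins, None, genome)
        segs = segment_hmm(norm, genome)
        summary = call_states(segs, norm, genome)
        states = summary.segments[summary.segments["chrom"] == "1"]["state"]
        assert "mosaic_deletion" in set(states)


class TestStateBands:
    @pytest.mark.parametrize("ratio,state", [
        (2.71, "duplication"), (2.7, "mosaic_duplication"),
        (2.31, "mosaic_duplication"), (2.3, "normal"),
        (2.0, "normal"), (1.7, "normal"),
        (1.69, "mosaic_deletion"), (1.3, "mosaic_deletion"),
        (1.29, "deletion"), (0.5, "deletion"),
    ])
    def test_band_edges(self, ratio, state):
        assert band_state(ratio) == state

    @given(st.floats(min_value=0.0, max_value=5.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, derandomize=True)
    def test_band_assignment_is_an_ordered_partition(self, ratio):
        # the bands partition the ratio axis monotonically
        order = ["deletion", "mosaic_deletion", "normal",
                 "mosaic_duplication", "duplication"]
        state = band_state(ratio)
        assert state in order
        assert order.index(band_state(ratio + 0.01)) >= order.index(state)

    def test_constant_genome_zero_count_zero_variance(self, small_genome):
        norm = normalize_bins(flat_bins(small_genome), None, small_genome)
        segs = segment_hmm(norm, small_genome)
        summary = call_states(segs, norm, small_genome)
        assert summary.aneuploidy_count == 0
        assert summary.pgta_score_variance == pytest.approx(0.0)

    def test_single_trisomic_chromosome_counts_once(self, small_genome):
        norm = normalize_bins(flat_bins(small_genome), None, small_genome)
        df = norm.df.copy()
        df.loc[df["chrom"] == "3", "copy_ratio"] = 3.0
        segs = segment_hmm(ps.BinnedCoverage(df, "t"), small_genome)
        summary = call_states(segs, ps.BinnedCoverage(df, "t"), small_genome)
        assert summary.aneuploidy_count == 1

    def test_pgta_score_variance_closed_form(self, small_genome):
        # per-chromosome medians {2.0 x 3, 3.0 x 1} over the 4 autosomes
        norm = normalize_bins(flat_bins(small_genome), None, small_genome)
        df = norm.df.copy()
        df.loc[df["chrom"] == "1", "copy_ratio"] = 3.0
        summary = call_states(segment_hmm(ps.BinnedCoverage(df, "x"), small_genome),
                              ps.BinnedCoverage(df, "x"), small_genome)
        expected = np.std([3.0, 2.0, 2.0, 2.0], ddof=1)
        assert summary.pgta_score_variance == pytest.approx(expected)


def test_whole_genome_ploidy_invisible_to_copy_number(
        small_genome, small_panel, small_tracks, small_baseline):
    # triploid and GW-UPD cohorts give aneuploidy count 0
    for cls in ("triploid_digynic", "gwupd_homozygous"):
        for seed in range(3):
            _, _, bins = make_sample(small_panel, small_genome, small_tracks,
                                     cls, 900 + seed)
            summary = ps.run_cnv(bins, small_baseline, small_genome)
            assert summary.aneuploidy_count == 0
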