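"""Karyotype simulator: meiosis, embryo assembly, evidence sampling, cohorts."""

import numpy as np
import pandas as pd
import pytest

import ploidyscope as ps
from ploidyscope.simulate import meiosis, simulate_parents

from conftest import make_sample


class TestParents:
    def test_switch_disabled_gives_verbatim_panel_haplotypes(self, small_panel):
        mother, _ = simulate_parents(small_panel, seed=3, switch_rate=0.0)
        chrom = small_panel.chroms[0]
        src = small_panel.haplotypes[chrom]
        for h in range(2):
            assert any(np.array_equal(mother.haps[chrom][h], row) for row in src)

    def test_determinism_under_fixed_seed(self, small_panel):
        a = simulate_parents(small_panel, seed=7)
        b = simulate_parents(small_panel, seed=7)
        for chrom in small_panel.chroms:
            assert np.array_equal(a[0].haps[chrom], b[0].haps[chrom])
            assert np.array_equal(a[1].haps[chrom], b[1].haps[chrom])

    def test_small_panel_rejected(self, toy_panel):
        tiny = ps.HaplotypePanel(
            {"1": toy_panel.sites["1"]}, {"1": toy_panel.haplotypes["1"][:3]})
        with pytest.raises(ValueError, match="4 haplotypes"):
            simulate_parents(tiny, seed=0)

    def test_parental_allele_frequencies_match_panel(self, small_panel):
        # binomial oracle: across replicates the parental haplotype pool is
        # a resample of the panel, so allele frequencies agree within 3 SE
        chrom = small_panel.chroms[0]
        f_panel = small_panel.alt_frequency(chrom)
        acc = []
        for seed in range(25):
            for parent in simulate_parents(small_panel, seed=seed):
                acc.append(parent.haps[chrom].mean(axis=0))
        f_emp = np.mean(acc, axis=0)  # 100 haplotypes total
        n = 2 * 2 * 25
        se = np.sqrt(f_panel * (1 - f_panel) / n) + 1e-3
        frac_within = np.mean(np.abs(f_emp - f_panel) <= 3 * se)
        assert frac_within > 0.97


class TestMeiosis:
    def test_zero_crossovers_yields_intact_homolog(self, small_panel, small_genome):
        mother, _ = simulate_parents(small_panel, seed=1)
        g = meiosis(mother, small_panel, small_genome, 0.0, seed=2)
        for chrom in small_panel.chroms:
            tracts = g.tracts[chrom]
            assert len(tracts) == 1
            hom = tracts[0][2]
            assert np.array_equal(g.haps[chrom], mother.haps[chrom][hom])

    def test_breakpoints_deterministic_under_seed(self, small_panel, small_genome):
        mother, _ = simulate_parents(small_panel, seed=1)
        g1 = meiosis(mother, small_panel, small_genome, 2.0, seed=5)
        g2 = meiosis(mother, small_panel, small_genome, 2.0, seed=5)
        assert g1.tracts == g2.tracts

    def test_mean_crossover_count_matches_poisson(self, small_panel, small_genome):
        mother, _ = simulate_parents(small_panel, seed=1)
        lam = 1.5
        counts = []
        for seed in range(600):
            g = meiosis(mother, small_panel, small_genome, lam, seed=seed)
            counts.append(len(g.tracts["1"]) - 1)
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se


class TestAssembleEmbryo:
    def test_homozygous_gwupd_has_zero_true_heterozygosity(
            self, small_panel, small_genome):
        cfg = ps.SimConfig(ploidy_class="gwupd_homozygous", seed=4)
        kar = ps.assemble_embryo(cfg, small_panel, small_genome)
        for chrom in small_genome.autosomes:
            assert kar.true_het(chrom).sum() == 0

    def test_digynic_without_recombination_has_no_tract_switches(
            self, small_panel, small_genome):
        cfg = ps.SimConfig(ploidy_class="triploid_digynic",
                           crossovers_per_chromosome=0.0, seed=4)
        kar = ps.assemble_embryo(cfg, small_panel, small_genome)
        for chrom in small_genome.autosomes:
            ibd = kar.ibd[chrom]
            length = small_genome.chrom_lengths[chrom]
            # chromosome is entirely SPH (full IBD) or entirely BPH (none)
            total = sum(e - s for s, e in ibd)
            assert total == pytest.approx(0.0) or total == pytest.approx(length)

    def test_hybrid_gwupd_ibd_fraction_matches_monte_carlo(
            self, small_panel, small_genome):
        # direct Monte-Carlo oracle: fraction of genome where two sibling
        # gametes copy the same parental homolog
        lam = 1.0
        fracs = []
        for seed in range(300):
            cfg = ps.SimConfig(ploidy_class="gwupd_hybrid",
                               crossovers_per_chromosome=lam, seed=seed)
            kar = ps.assemble_embryo(cfg, small_panel, small_genome)
            total = sum(small_genome.chrom_lengths[c] for c in small_genome.autosomes)
            ibd = sum(e - s for c in small_genome.autosomes for s, e in kar.ibd[c])
            fracs.append(ibd / total)
        # two independent gametes agree at a point with probability 1/2
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se + 0.01

    def test_loss_of_absent_homolog_rejected(self, small_panel, small_genome):
        cfg = ps.SimConfig(ploidy_class="haploid",
                           aneuploidies=(("1", "loss", 1.0), ("1", "loss", 1.0)),
                           seed=0)
        with pytest.raises(ValueError, match="absent homolog"):
            ps.assemble_embryo(cfg, small_panel, small_genome)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ps.SimConfig(ploidy_class="tetraploid")
        with pytest.raises(ValueError):
            ps.SimConfig(contamination_fraction=1.0)
        with pytest.raises(ValueError):
            ps.SimConfig(sequencing_error_rate=0.5)


class TestSampleReads:
    def test_error_free_reads_carry_true_alleles(self, small_panel, small_genome,
                                                 small_tracks):
        kar, obs, _ = make_sample(small_panel, small_genome, small_tracks,
                                  "diploid", 9, sequencing_error_rate=0.0)
        for chrom in ["1", "2"]:
            sub = obs.for_chrom(chrom)
            idx = small_panel.site_index(chrom, sub["pos"].to_numpy())
            haps = np.array([h.hap for h in kar.homologs[chrom]])
            carried = haps[:, idx] == sub["allele"].to_numpy()[None, :]
            assert carried.any(axis=0).all()

    def test_heterozygous_observations_only_at_het_genotypes(
            self, small_panel, small_genome, small_tracks):
        kar, obs, _ = make_sample(small_panel, small_genome, small_tracks,
                                  "diploid", 10, sequencing_error_rate=0.0)
        chrom = "1"
        from ploidyscope.hetroh import site_calls
        informative, het = site_calls(obs, small_panel, chrom)
        true_het = kar.true_het(chrom)
        assert np.all(true_het[het])

    def test_triploid_bin_coverage_ratio(self, small_panel, small_genome,
                                         small_tracks):
        # dosage ratio oracle: raw triploid bins / diploid bins ~= 1.5
        ratios = []
        for seed in range(8):
            _, _, b3 = make_sample(small_panel, small_genome, small_tracks,
                                   "triploid_digynic", 600 + seed)
            _, _, b2 = make_sample(small_panel, small_genome, small_tracks,
                                   "diploid", 700 + seed)
            ratios.append(b3.df["count"].mean() / b2.df["count"].mean())
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.05)

    def test_mosaic_fraction_zero_is_bitexact_base_karyotype(
            self, small_panel, small_genome, small_tracks):
        base_kar, base_obs, base_bins = make_sample(
            small_panel, small_genome, small_tracks, "diploid", 12)
        mos_kar, mos_obs, mos_bins = make_sample(
            small_panel, small_genome, small_tracks, "diploid", 12,
            aneuploidies=(("2", "gain", 0.0),))
        pd.testing.assert_frame_equal(base_obs.df, mos_obs.df)
        pd.testing.assert_frame_equal(base_bins.df, mos_bins.df)


class TestCohort:
    def test_bookkeeping_counts_and_manifest(self, small_panel, small_genome,
                                             small_tracks, tmp_path):
        cohort = ps.simulate_cohort({"diploid": 2}, small_panel, small_genome,
                                    small_tracks, seed=5, out_dir=str(tmp_path))
        assert len(cohort.samples) == 2
        assert (tmp_path / "manifest.tsv").exists()
        assert len(list(tmp_path.glob("*.obs.tsv"))) == 2

    def test_manifest_byte_identical_across_reruns(self, small_panel,
                                                   small_genome, small_tracks,
                                                   tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            ps.simulate_cohort({"diploid": 1, "gwupd": 1}, small_panel,
                               small_genome, small_tracks, seed=8, out_dir=str(d))
        assert (d1 / "manifest.tsv").read_bytes() == (d2 / "manifest.tsv").read_bytes()

    def test_coarse_classes_alternate_subtypes(self, small_panel, small_genome,
                                               small_tracks):
        cohort = ps.simulate_cohort({"triploid": 4, "gwupd": 2}, small_panel,
                                    small_genome, small_tracks, seed=5)
        subtypes = [s.ploidy_class for s in cohort.samples]
        assert subtypes == ["triploid_digynic", "triploid_diandric",
                            "triploid_digynic", "triploid_diandric",
                            "gwupd_homozygous", "gwupd_hybrid"]

    def test_negative_count_rejected(self, small_panel, small_genome, small_tracks):
        with pytest.raises(ValueError, match="non-negative"):
            ps.simulate_cohort({"diploid": -1}, small_panel, small_genome,
                               small_tracks, seed=0)


def test_homozygous_gwupd_observed_het_bounded_by_error(
        small_panel, small_genome, small_tracks):
    # observed het of a fully homozygous genome comes only from sequencing
    # error: rate <= 2e plus small-sample noise
    e = 0.002
    rates = []
    for seed in range(5):
        _, obs, _ = make_sample(small_panel, small_genome, small_tracks,
                                "gwupd_homozygous", 800 + seed,
                                sequencing_error_rate=e)
        stats = ps.het_rate(obs, small_panel, small_genome)
        rates.append(stats[stats["chrom"] == "genome"]["het_rate"].iloc[0])
    assert np.mean(rates) <= 2 * e + 0.004
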