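"""Synthetic embryo generator for every karyotype class in the study design.

The generator produces, for each sample, (i) read-level allele observations
at panel SNP sites (the ulc-WGS evidence) and (ii) binned 600 kb coverage
counts, together with the true karyotype.  Classes covered: biparental
diploid, digynic/diandric triploid with recombination, homozygous and
hybrid genome-wide uniparental diploidy (GW-UPD), haploid, whole-chromosome
and segmental aneuploidy (optionally mosaic), and admixture-contaminated
samples.

The reference panel itself is simulated with msprime (coalescent with
recombination), so joint haplotype frequencies carry realistic linkage
disequilibrium.  Parental genomes are drawn by a mosaic copy process along
the panel rather than verbatim, so embryos are not memorised panel members.

Evidence model: each SNP site receives Poisson(d) reads; each read picks a
homolog with probability proportional to its (possibly mosaic) dosage at
that position and reports the homolog's allele, flipped with the sequencing
error probability; with probability rho a read instead comes from an
unrelated diploid contaminant.  Reads cover exactly one SNP site (read
length is far below inter-SNP spacing at this coverage).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec, default_genome
from .io import BinnedCoverage, ObservationSet
from .panel import HaplotypePanel, filter_maf

PLOIDY_CLASSES = (
    "diploid", "triploid_digynic", "triploid_diandric",
    "gwupd_homozygous", "gwupd_hybrid", "haploid",
)

#: coarse truth label used for classification
COARSE_LABEL = {
    "diploid": "diploid",
    "triploid_digynic": "triploid",
    "triploid_diandric": "triploid",
    "gwupd_homozygous": "gw_upd",
    "gwupd_hybrid": "gw_upd",
    "haploid": "gw_upd",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    mean_depth is in reads per SNP site (the ulc-WGS regime concentrates
    well under one read per site at genome scale; 0.2/site at ~1.2 SNP/kb
    corresponds to a few hundredths of genome-wide coverage).
    """

    ploidy_class: str = "diploid"
    aneuploidies: tuple = ()          # (chrom, 'gain'|'loss', mosaic_fraction)
    segmental_events: tuple = ()      # (chrom, start, end, 'gain'|'loss')
    contamination_fraction: float = 0.0
    mean_depth: float = 0.2           # reads per SNP site
    sequencing_error_rate: float = 0.002
    crossovers_per_chromosome: float = 1.5
    parent_switch_rate: float = 4e-3  # per-site panel copy-process switch prob
    bin_depth: float = 200.0          # expected reads per 600 kb bin at diploid dosage
    seed: int = 0

    def __post_init__(self):
        if self.ploidy_class not in PLOIDY_CLASSES:
            raise ValueError(f"unknown ploidy class {self.ploidy_class!r}")
        if not (0 <= self.contamination_fraction < 1):
            raise ValueError("contamination fraction must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not (0 <= self.sequencing_error_rate < 0.01):
            raise ValueError("sequencing error rate must be in [0, 0.01)")
        if self.crossovers_per_chromosome < 0:
            raise ValueError("crossover rate must be non-negative")

    def digest(self) -> str:
        text = repr(sorted(self.__dict__.items()))
        return hashlib.md5(text.encode()).hexdigest()[:12]


# -- panel and genome tracks --------------------------------------------


def simulate_panel(genome: GenomeSpec, n_haplotypes: int = 200, seed: int = 1,
                   population_size: float = 5_000, mutation_rate: float = 2.4e-7,
                   hotspot_spacing: int = 60_000, block_rho: float = 0.05,
                   hotspot_rho: float = 5.0,
                   maf_band=(0.10, 0.5)) -> HaplotypePanel:
    """Coalescent reference panel over the desk genome via msprime.

    One independent ancestry per chromosome; biallelic SNPs only; sites
    filtered to the MAF band.  The defaults emulate a frequency-ascertained
    common-SNP site list (dbSNP-style) with human-like hotspot structure:
    recombination is concentrated in 1 kb hotspots every ``hotspot_spacing``
    bases (population-scaled intensity ``hotspot_rho`` per hotspot,
    ``block_rho`` across each intervening block), producing tight
    linkage-disequilibrium blocks on the scale of the 100 kb likelihood
    window while every chromosome averages over hundreds of independent
    genealogies — the same regime a genome-scale panel provides to the
    real method.
    """
    import msprime

    ss = np.random.SeedSequence(seed)
    sites, haps = {}, {}
    for chrom, child in zip(genome.chroms, ss.spawn(len(genome.chroms))):
        ms_seed = int(child.generate_state(1)[0] % (2**31 - 1)) + 1
        length = genome.chrom_lengths[chrom]
        rate_map = _hotspot_rate_map(length, population_size, hotspot_spacing,
                                     block_rho, hotspot_rho)
        ts = msprime.sim_ancestry(
            samples=n_haplotypes, ploidy=1, population_size=population_size,
            recombination_rate=rate_map, random_seed=ms_seed)
        ts = msprime.sim_mutations(
            ts, rate=mutation_rate, random_seed=ms_seed,
            model=msprime.BinaryMutationModel())
        pos, ref, alt, rows = [], [], [], []
        last = 0
        for var in ts.variants():
            if len(var.alleles) != 2:
                continue
            p = int(var.site.position) + 1  # 1-based
            if p <= last:
                continue
            last = p
            pos.append(p)
            ref.append("A")
            alt.append("G")
            rows.append(var.genotypes.astype(np.uint8))
        hap = np.array(rows, dtype=np.uint8).T if rows else np.zeros((n_haplotypes, 0), np.uint8)
        f = hap.mean(axis=0) if hap.shape[1] else np.array([])
        sites[chrom] = pd.DataFrame(
            {"pos": np.array(pos, dtype=np.int64), "ref": ref, "alt": alt,
             "maf": np.minimum(f, 1 - f)})
        haps[chrom] = hap
    return filter_maf(HaplotypePanel(sites, haps), maf_band)


def _hotspot_rate_map(length: int, population_size: float, spacing: int,
                      block_rho: float, hotspot_rho: float):
    """Alternating cold-block / 1 kb-hotspot recombination map."""
    import msprime

    hot_w = 1_000
    cold_w = spacing - hot_w
    r_cold = block_rho / (4 * population_size * cold_w)
    r_hot = hotspot_rho / (4 * population_size * hot_w)
    pos = [0.0]
    rate = []
    x = 0.0
    while x < length:
        cold_end = min(x + cold_w, length)
        pos.append(cold_end)
        rate.append(r_cold)
        x = cold_end
        if x < length:
            hot_end = min(x + hot_w, length)
            pos.append(hot_end)
            rate.append(r_hot)
            x = hot_end
    return msprime.RateMap(position=pos, rate=rate)


@dataclass
class GenomeTracks:
    """Static per-bin GC fraction and mappability, shared by a cohort."""

    gc: dict
    mappability: dict


def simulate_tracks(genome: GenomeSpec, seed: int = 0) -> GenomeTracks:
    rng = np.random.default_rng(seed)
    gc, mp = {}, {}
    for chrom in genome.chroms:
        n = genome.n_bins(chrom)
        gc[chrom] = rng.uniform(0.30, 0.60, size=n)
        m = rng.uniform(0.92, 1.0, size=n)
        low = rng.random(n) < 0.05
        m[low] = rng.uniform(0.5, 0.8, size=low.sum())
        mp[chrom] = m
    return GenomeTracks(gc, mp)


def gc_bias(gc: np.ndarray) -> np.ndarray:
    """Mild concave amplification bias around GC = 0.45."""
    return 1.0 - 4.0 * (np.asarray(gc) - 0.45) ** 2


# -- parental genomes and meiosis ----------------------------------------


@dataclass
class ParentalGenome:
    """Two phased haplotypes per chromosome."""

    haps: dict  # chrom -> (2, S) uint8


def simulate_parents(panel: HaplotypePanel, seed, switch_rate: float | None = None,
                     n_parents: int = 2) -> list:
    """Draw parental diploids by a mosaic copy process along the panel.

    Each parental haplotype copies a panel haplotype and switches to a
    fresh uniformly-drawn one with per-site probability ``switch_rate``
    (LD is preserved locally).  ``switch_rate=0`` yields verbatim panel
    haplotypes.
    """
    if panel.n_haplotypes < 4:
        raise ValueError("panel must contain at least 4 haplotypes")
    if switch_rate is None:
        switch_rate = SimConfig().parent_switch_rate
    rng = np.random.default_rng(seed)
    parents = []
    for _ in range(n_parents):
        haps = {}
        for chrom in panel.chroms:
            src = panel.haplotypes[chrom]
            n_hap, n_sites = src.shape
            out = np.empty((2, n_sites), dtype=np.uint8)
            for h in range(2):
                if n_sites == 0:
                    continue
                switches = rng.random(n_sites) < switch_rate
                switches[0] = True
                idx_at_switch = rng.integers(0, n_hap, size=int(switches.sum()))
                source = idx_at_switch[np.cumsum(switches) - 1]
                out[h] = src[source, np.arange(n_sites)]
            haps[chrom] = out
        parents.append(ParentalGenome(haps))
    return parents


@dataclass
class Gamete:
    """A recombinant haplotype with its tract provenance."""

    parent: str                     # 'mother' | 'father'
    haps: dict                      # chrom -> (S,) uint8
    tracts: dict                    # chrom -> list of (start, end, parental homolog 0/1)


def meiosis(parent: ParentalGenome, panel: HaplotypePanel, genome: GenomeSpec,
            lam: float, seed, parent_label: str = "mother") -> Gamete:
    """One gamete: Poisson(lam) crossovers per chromosome, uniform breakpoints."""
    if lam < 0:
        raise ValueError("crossover rate must be non-negative")
    rng = np.random.default_rng(seed)
    haps, tracts = {}, {}
    for chrom in panel.chroms:
        length = genome.chrom_lengths[chrom]
        pos = panel.sites[chrom]["pos"].to_numpy()
        n_x = rng.poisson(lam)
        breaks = np.sort(rng.uniform(0, length, size=n_x))
        phase0 = int(rng.integers(0, 2))
        bounds = np.concatenate([[0.0], breaks, [float(length)]])
        chrom_tracts = []
        hap = np.empty(len(pos), dtype=np.uint8)
        for i in range(len(bounds) - 1):
            hom = (phase0 + i) % 2
            s, e = bounds[i], bounds[i + 1]
            chrom_tracts.append((float(s), float(e), hom))
            in_tract = (pos > s) & (pos <= e)
            hap[in_tract] = parent.haps[chrom][hom, in_tract]
        haps[chrom] = hap
        tracts[chrom] = chrom_tracts
    return Gamete(parent_label, haps, tracts)


# -- karyotype assembly ---------------------------------------------------


@dataclass
class Homolog:
    """One inherited homolog with a (possibly mosaic) dosage profile."""

    hap: np.ndarray
    dosage: float = 1.0
    events: list = field(default_factory=list)  # (start, end, delta, fraction)
    parent: str = ""
    gamete_id: int = 0

    def weight_at(self, pos: np.ndarray) -> np.ndarray:
        w = np.full(len(pos), self.dosage, dtype=float)
        for start, end, delta, frac in self.events:
            w[(pos > start) & (pos <= end)] += delta * frac
        if np.any(w < -1e-9):
            raise ValueError("homolog dosage below zero (loss of an absent homolog)")
        return np.maximum(w, 0.0)

    def mean_weight(self, start: float, end: float) -> float:
        w = self.dosage * (end - start)
        for s, e, delta, frac in self.events:
            w += delta * frac * max(0.0, min(end, e) - max(start, s))
        return w / (end - start)


@dataclass
class TrueKaryotype:
    """Ground truth: homolog sets with dosage plus same-parent IBD tracts."""

    ploidy_class: str
    homologs: dict                 # chrom -> list of Homolog
    ibd: dict = field(default_factory=dict)  # chrom -> list of (start, end)

    @property
    def label(self) -> str:
        return COARSE_LABEL[self.ploidy_class]

    def weights(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Per-homolog effective copy weights at positions, shape (n_hom, len(pos))."""
        return np.array([h.weight_at(pos) for h in self.homologs[chrom]])

    def true_het(self, chrom: str) -> np.ndarray:
        """Boolean: does the karyotype carry both alleles at each site?"""
        homs = self.homologs[chrom]
        pos_n = len(homs[0].hap)
        carried0 = np.zeros(pos_n, dtype=bool)
        carried1 = np.zeros(pos_n, dtype=bool)
        for h in homs:
            present = h.dosage > 0 or any(d > 0 for _, _, d, _ in h.events)
            if not present:
                continue
            carried0 |= h.hap == 0
            carried1 |= h.hap == 1
        return carried0 & carried1


def _tract_ibd(t1: list, t2: list) -> list:
    """Intervals where two same-parent gametes copied the same homolog."""
    out = []
    for s1, e1, h1 in t1:
        for s2, e2, h2 in t2:
            if h1 != h2:
                continue
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    out.sort()
    merged = []
    for s, e in out:
        if merged and s <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def assemble_embryo(cfg: SimConfig, panel: HaplotypePanel,
                    genome: GenomeSpec) -> TrueKaryotype:
    """Draw parents, perform meioses, and combine gametes per the class."""
    ss = np.random.SeedSequence(cfg.seed)
    s_par, s_g1, s_g2, s_g3, s_ev = ss.spawn(5)
    mother, father = simulate_parents(panel, s_par, cfg.parent_switch_rate)
    lam = cfg.crossovers_per_chromosome

    def gam(parent, label, seed):
        return meiosis(parent, panel, genome, lam, seed, label)

    cls = cfg.ploidy_class
    ibd: dict = {}
    if cls == "diploid":
        gametes = [(gam(mother, "mother", s_g1), 1.0), (gam(father, "father", s_g2), 1.0)]
    elif cls == "triploid_digynic":
        m1, m2 = gam(mother, "mother", s_g1), gam(mother, "mother", s_g2)
        gametes = [(m1, 1.0), (m2, 1.0), (gam(father, "father", s_g3), 1.0)]
        ibd = {c: _tract_ibd(m1.tracts[c], m2.tracts[c]) for c in panel.chroms}
    elif cls == "triploid_diandric":
        p1, p2 = gam(father, "father", s_g1), gam(father, "father", s_g2)
        gametes = [(gam(mother, "mother", s_g3), 1.0), (p1, 1.0), (p2, 1.0)]
        ibd = {c: _tract_ibd(p1.tracts[c], p2.tracts[c]) for c in panel.chroms}
    elif cls == "gwupd_homozygous":
        g = gam(mother, "mother", s_g1)
        gametes = [(g, 2.0)]
        ibd = {c: [(0.0, float(genome.chrom_lengths[c]))] for c in panel.chroms}
    elif cls == "gwupd_hybrid":
        g1, g2 = gam(mother, "mother", s_g1), gam(mother, "mother", s_g2)
        gametes = [(g1, 1.0), (g2, 1.0)]
        ibd = {c: _tract_ibd(g1.tracts[c], g2.tracts[c]) for c in panel.chroms}
    elif cls == "haploid":
        gametes = [(gam(mother, "mother", s_g1), 1.0)]
    else:  # pragma: no cover - guarded by SimConfig
        raise ValueError(cls)

    homologs: dict = {}
    for chrom in panel.chroms:
        homologs[chrom] = [
            Homolog(g.haps[chrom], dosage, [], g.parent, gid)
            for gid, (g, dosage) in enumerate(gametes)]
    kar = TrueKaryotype(cls, homologs, ibd)

    rng_ev = np.random.default_rng(s_ev)
    for chrom, kind, frac in cfg.aneuploidies:
        _apply_event(kar, genome, chrom, 0, genome.chrom_lengths[chrom], kind, frac, rng_ev)
    for chrom, start, end, kind in cfg.segmental_events:
        _apply_event(kar, genome, chrom, start, end, kind, 1.0, rng_ev)
    return kar


def _apply_event(kar: TrueKaryotype, genome: GenomeSpec, chrom: str,
                 start: float, end: float, kind: str, fraction: float,
                 rng) -> None:
    homs = kar.homologs[chrom]
    delta = 1.0 if kind == "gain" else -1.0
    if kind not in ("gain", "loss"):
        raise ValueError(f"event kind must be gain or loss, got {kind!r}")
    candidates = list(range(len(homs)))
    if delta < 0:
        candidates = [i for i in candidates
                      if homs[i].mean_weight(start, end) >= fraction - 1e-9]
        if not candidates:
            raise ValueError(f"loss of an absent homolog on chrom {chrom}")
    target = homs[candidates[int(rng.integers(0, len(candidates)))]]
    target.events.append((float(start), float(end), delta, float(fraction)))


# -- read and bin sampling ------------------------------------------------


def sample_reads(kar: TrueKaryotype, panel: HaplotypePanel, genome: GenomeSpec,
                 tracks: GenomeTracks, cfg: SimConfig, seed=None,
                 sample_id: str = "sample") -> tuple:
    """Draw the ulc-WGS evidence: site-level reads and binned coverage."""
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng, rng_cont = [np.random.default_rng(s) for s in ss.spawn(2)]
    contaminant = None
    if cfg.contamination_fraction > 0:
        contaminant = simulate_parents(panel, rng_cont, cfg.parent_switch_rate,
                                       n_parents=1)[0]

    obs_frames, bin_frames = [], []
    for chrom in panel.chroms:
        pos = panel.sites[chrom]["pos"].to_numpy()
        n_sites = len(pos)
        weights = kar.weights(chrom, pos)           # (n_hom, S)
        total = weights.sum(axis=0)

        counts = rng.poisson(cfg.mean_depth, size=n_sites)
        site_idx = np.repeat(np.arange(n_sites), counts)
        n_reads = len(site_idx)
        if n_reads:
            is_cont = (rng.random(n_reads) < cfg.contamination_fraction
                       if contaminant is not None else np.zeros(n_reads, bool))
            # homolog choice proportional to dosage at the site
            tot = total[site_idx]
            ok = (tot > 0) | is_cont
            site_idx, is_cont, tot = site_idx[ok], is_cont[ok], tot[ok]
            n_reads = len(site_idx)
            cum = np.cumsum(weights, axis=0)
            denom = np.where(total > 0, total, 1.0)
            cum_n = cum / denom                      # (n_hom, S) cumulative probs
            u = rng.random(n_reads)
            hom = (u[None, :] > cum_n[:, site_idx]).sum(axis=0)
            hom = np.minimum(hom, weights.shape[0] - 1)
            alleles = np.array([h.hap for h in kar.homologs[chrom]])[hom, site_idx]
            if contaminant is not None and is_cont.any():
                c_hap = contaminant.haps[chrom]
                pick = rng.integers(0, 2, size=int(is_cont.sum()))
                alleles[is_cont] = c_hap[pick, site_idx[is_cont]]
            flip = rng.random(n_reads) < cfg.sequencing_error_rate
            alleles = np.where(flip, 1 - alleles, alleles).astype(np.int8)
            obs_frames.append(pd.DataFrame({
                "read_id": np.arange(n_reads, dtype=np.int64),
                "chrom": chrom,
                "pos": pos[site_idx],
                "allele": alleles,
            }))

        # binned coverage: Poisson around bin_depth * dosage/2, GC/mappability biased
        n_bins = genome.n_bins(chrom)
        starts = np.arange(n_bins) * genome.bin_size
        ends = np.minimum(starts + genome.bin_size, genome.chrom_lengths[chrom])
        dos = np.array([
            sum(h.mean_weight(s, e) for h in kar.homologs[chrom])
            for s, e in zip(starts, ends)])
        if contaminant is not None:
            dos = (1 - cfg.contamination_fraction) * dos + cfg.contamination_fraction * 2.0
        lam = cfg.bin_depth * (dos / 2.0) * gc_bias(tracks.gc[chrom]) \
            * tracks.mappability[chrom]
        bin_frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts + 1, "end": ends,
            "count": rng.poisson(np.maximum(lam, 0.0)),
            "gc": tracks.gc[chrom], "mappability": tracks.mappability[chrom],
        }))

    obs = pd.concat(obs_frames, ignore_index=True) if obs_frames else pd.DataFrame(
        columns=["read_id", "chrom", "pos", "allele"])
    bins = pd.concat(bin_frames, ignore_index=True)
    return (ObservationSet(obs, sample_id=sample_id),
            BinnedCoverage(bins, sample_id=sample_id))


# -- cohorts --------------------------------------------------------------


@dataclass
class SimulatedSample:
    sample_id: str
    label: str          # coarse truth: diploid | triploid | gw_upd
    ploidy_class: str   # fine truth
    obs: ObservationSet
    bins: BinnedCoverage
    karyotype: TrueKaryotype
    cfg: SimConfig


@dataclass
class Cohort:
    samples: list
    manifest: pd.DataFrame


def _expand_classes(class_counts: dict) -> list:
    """Map coarse class counts onto alternating fine classes."""
    alternates = {
        "triploid": ("triploid_digynic", "triploid_diandric"),
        "gwupd": ("gwupd_homozygous", "gwupd_hybrid"),
        "gw_upd": ("gwupd_homozygous", "gwupd_hybrid"),
    }
    out = []
    for name, count in class_counts.items():
        if count < 0:
            raise ValueError("class counts must be non-negative")
        if name in PLOIDY_CLASSES:
            out.extend([name] * count)
        elif name in alternates:
            pair = alternates[name]
            out.extend([pair[i % 2] for i in range(count)])
        else:
            raise ValueError(f"unknown class {name!r}")
    return out


def simulate_cohort(class_counts: dict, panel: HaplotypePanel, genome: GenomeSpec,
                    tracks: GenomeTracks, defaults: SimConfig | None = None,
                    seed: int = 0, out_dir=None) -> Cohort:
    """Generate a labelled cohort; optionally write per-sample TSVs + manifest."""
    defaults = defaults if defaults is not None else SimConfig()
    classes = _expand_classes(class_counts)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(classes))
    samples, rows = [], []
    for i, (cls, child) in enumerate(zip(classes, children)):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = replace(defaults, ploidy_class=cls, seed=sub)
        sid = f"S{i:04d}_{cls}"
        kar = assemble_embryo(cfg, panel, genome)
        obs, bins = sample_reads(kar, panel, genome, tracks, cfg, sample_id=sid)
        samples.append(SimulatedSample(sid, COARSE_LABEL[cls], cls, obs, bins, kar, cfg))
        rows.append({"sample_id": sid, "truth_label": COARSE_LABEL[cls],
                     "ploidy_class": cls, "cfg_hash": cfg.digest()})
    manifest = pd.DataFrame(rows, columns=["sample_id", "truth_label",
                                           "ploidy_class", "cfg_hash"])
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        for s in samples:
            s.obs.to_tsv(os.path.join(out_dir, f"{s.sample_id}.obs.tsv"), panel)
            s.bins.to_tsv(os.path.join(out_dir, f"{s.sample_id}.bins.tsv"))
        manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return Cohort(samples, manifest)
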