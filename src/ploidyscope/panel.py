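"""Phased haplotype reference panel and diploid baseline statistics.

The panel answers joint haplotype-frequency queries F(S): for a pattern S
of (position, allele) observations on one chromosome, F(S) is the fraction
of panel haplotypes carrying every listed allele.  These frequencies encode
the linkage disequilibrium that the homolog-dosage likelihoods exploit.
Zero counts are floored at ``frequency_floor`` (default 1/(2N)) so
log-likelihoods stay finite for patterns unseen in a finite panel.

Two input dialects are supported: phased VCF (GT with '|'), and a
human-readable two-file format — ``<prefix>.legend.tsv`` (chrom, pos, ref,
alt, maf) plus ``<prefix>.hap.txt`` (one haplotype per line, 0/1 characters
over all sites ordered by chrom, pos).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]


class HaplotypePanel:
    """Ordered biallelic SNP sites plus N phased haplotypes per chromosome.

    Parameters
    ----------
    sites : dict
        chrom -> DataFrame(pos, ref, alt, maf) with pos strictly increasing.
    haplotypes : dict
        chrom -> uint8 array of shape (N, n_sites), 0=ref 1=alt.
    frequency_floor : float, optional
        Probability substituted for zero joint frequencies; defaults to
        1/(2N), scale-consistent with the panel's resolution.
    """

    def __init__(self, sites: dict, haplotypes: dict, frequency_floor: float | None = None):
        self.sites = {}
        self.haplotypes = {}
        n = None
        for chrom in sites:
            s = sites[chrom].reset_index(drop=True)
            h = np.asarray(haplotypes[chrom], dtype=np.uint8)
            if h.shape[1] != len(s):
                raise ValueError(
                    f"chrom {chrom}: {h.shape[1]} haplotype columns for {len(s)} sites")
            pos = s["pos"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"chrom {chrom}: positions not strictly increasing")
            if n is None:
                n = h.shape[0]
            elif h.shape[0] != n:
                raise ValueError("haplotype count differs between chromosomes")
            self.sites[chrom] = s
            self.haplotypes[chrom] = h
        self.n_haplotypes = int(n) if n is not None else 0
        if frequency_floor is None:
            frequency_floor = 1.0 / (2 * self.n_haplotypes) if self.n_haplotypes else 1e-6
        self.frequency_floor = float(frequency_floor)
        self._pos_index = {
            chrom: pd.Index(self.sites[chrom]["pos"].to_numpy()) for chrom in self.sites
        }

    # -- lookups ---------------------------------------------------------

    @property
    def chroms(self) -> list:
        return list(self.sites)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.sites[chrom])
        return sum(len(s) for s in self.sites.values())

    def site_index(self, chrom: str, pos) -> np.ndarray:
        """Column indices for 1-based positions; raises on unknown position."""
        idx = self._pos_index[chrom].get_indexer(np.atleast_1d(pos))
        if np.any(idx < 0):
            bad = np.atleast_1d(pos)[idx < 0][:3]
            raise KeyError(f"position(s) {list(bad)} not in panel on chrom {chrom}")
        return idx

    def alt_frequency(self, chrom: str) -> np.ndarray:
        return self.haplotypes[chrom].mean(axis=0)

    def _resolve_chrom(self, positions) -> str:
        carriers = [c for c in self.sites
                    if all(p in self._pos_index[c] for p in positions)]
        if len(carriers) == 1:
            return carriers[0]
        if not carriers:
            # every position exists somewhere -> the pattern spans chromosomes
            each = [any(p in self._pos_index[c] for c in self.sites) for p in positions]
            if all(each):
                raise ValueError("pattern spans two chromosomes; joint frequency undefined")
            raise KeyError("pattern contains positions absent from the panel")
        raise ValueError(
            f"pattern position set is ambiguous across chromosomes {carriers}; pass chrom=")

    def joint_frequency(self, pattern, chrom: str | None = None,
                        floor: bool = True) -> float:
        """F(S) for a pattern of (pos, allele) pairs on one chromosome.

        F(∅) = 1.  With ``floor=True`` a zero count returns
        ``frequency_floor``; ``floor=False`` exposes the raw count/N
        (used by the antitonicity property).
        """
        pattern = list(pattern)
        if not pattern:
            return 1.0
        positions = [p for p, _ in pattern]
        if chrom is None:
            chrom = self._resolve_chrom(positions)
        idx = self.site_index(chrom, positions)
        alleles = np.array([a for _, a in pattern], dtype=np.uint8)
        match = np.all(self.haplotypes[chrom][:, idx] == alleles, axis=1)
        f = match.sum() / self.n_haplotypes
        if f == 0.0 and floor:
            return self.frequency_floor
        return float(f)

    # -- serialization ---------------------------------------------------

    def write(self, prefix: str) -> None:
        """Write ``<prefix>.legend.tsv`` + ``<prefix>.hap.txt`` (bit-exact)."""
        legend = pd.concat(
            [self.sites[c].assign(chrom=c)[SITE_COLUMNS] for c in self.sites],
            ignore_index=True)
        legend.to_csv(f"{prefix}.legend.tsv", sep="\t", index=False)
        hap = np.concatenate([self.haplotypes[c] for c in self.sites], axis=1)
        with open(f"{prefix}.hap.txt", "w") as fh:
            for row in hap:
                fh.write("".join("1" if x else "0" for x in row) + "\n")

    @classmethod
    def read(cls, prefix: str) -> "HaplotypePanel":
        legend = pd.read_csv(f"{prefix}.legend.tsv", sep="\t", dtype={"chrom": str})
        with open(f"{prefix}.hap.txt") as fh:
            rows = [np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0")
                    for line in fh if line.strip()]
        hap = np.vstack(rows).astype(np.uint8)
        sites, haps, col = {}, {}, 0
        for chrom in legend["chrom"].unique():
            sub = legend[legend["chrom"] == chrom].reset_index(drop=True)
            sites[chrom] = sub[["pos", "ref", "alt", "maf"]]
            haps[chrom] = hap[:, col:col + len(sub)]
            col += len(sub)
        return cls(sites, haps)


def load_panel(panel_file: str, maf_band=(0.01, 0.5)) -> HaplotypePanel:
    """Load a phased panel from VCF or from the legend+hap text dialect.

    Only biallelic SNPs whose empirical minor allele frequency lies inside
    ``maf_band`` are retained; multiallelic records are skipped and counted
    in a log summary; any unphased genotype aborts the load naming the
    offending record.
    """
    low, high = maf_band
    if not (0 < low <= high <= 0.5):
        raise ValueError(f"maf band {maf_band} outside (0, 0.5]")
    if str(panel_file).endswith((".vcf", ".vcf.gz")):
        panel = _load_vcf(panel_file)
    else:
        prefix = str(panel_file)
        for suffix in (".legend.tsv", ".hap.txt"):
            if prefix.endswith(suffix):
                prefix = prefix[: -len(suffix)]
        panel = HaplotypePanel.read(prefix)
    return filter_maf(panel, maf_band)


def filter_maf(panel: HaplotypePanel, maf_band=(0.01, 0.5)) -> HaplotypePanel:
    """Keep sites whose empirical MAF lies in the closed band."""
    low, high = maf_band
    sites, haps = {}, {}
    for chrom in panel.sites:
        f = panel.alt_frequency(chrom)
        maf = np.minimum(f, 1 - f)
        keep = (maf >= low) & (maf <= high)
        s = panel.sites[chrom][keep].reset_index(drop=True).copy()
        s["maf"] = maf[keep]
        sites[chrom] = s
        haps[chrom] = panel.haplotypes[chrom][:, keep]
    dropped = panel.n_sites() - sum(len(s) for s in sites.values())
    if dropped:
        logger.info("maf filter dropped %d of %d sites", dropped, panel.n_sites())
    return HaplotypePanel(sites, haps)


def _load_vcf(path: str) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    by_chrom: dict = {}
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        for g in gts:
            if len(g) > 2 and not g[-1]:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS}; panel must be phased")
        alleles = np.array([g[:-1] for g in gts], dtype=np.int8).ravel()
        rec = by_chrom.setdefault(var.CHROM, {"pos": [], "ref": [], "alt": [], "hap": []})
        rec["pos"].append(var.POS)
        rec["ref"].append(var.REF)
        rec["alt"].append(var.ALT[0])
        rec["hap"].append(alleles)
    if n_multi:
        logger.info("skipped %d multiallelic/non-SNP records", n_multi)
    sites, haps = {}, {}
    for chrom, rec in by_chrom.items():
        hap = np.array(rec["hap"], dtype=np.uint8).T  # (N, S)
        f = hap.mean(axis=0)
        sites[chrom] = pd.DataFrame({
            "pos": rec["pos"], "ref": rec["ref"], "alt": rec["alt"],
            "maf": np.minimum(f, 1 - f)})
        haps[chrom] = hap
    return HaplotypePanel(sites, haps)


# -- diploid baseline ----------------------------------------------------


@dataclass
class BaselineStats:
    """Per-chromosome heterozygosity baseline and per-bin coverage baseline.

    ``het_mean``/``het_sd`` are estimated from known diploid samples and
    standardise a sample's per-chromosome heterozygosity rate into a
    Z-score.  ``bin_baseline`` is the diploid mean coverage per 600 kb bin
    (autosomal mean scaled to 1.0), used by the CNV normalisation.
    """

    het_mean: dict
    het_sd: dict
    bin_baseline: dict = field(default_factory=dict)
    sd_floor: float = 1e-3

    def z_score(self, chrom: str, het_rate: float) -> float:
        return (het_rate - self.het_mean[chrom]) / self.het_sd[chrom]


def estimate_baseline(diploid_obs: list, panel: HaplotypePanel, genome,
                      diploid_bins: list | None = None,
                      sd_floor: float = 1e-3) -> BaselineStats:
    """Estimate the diploid baseline from >= 2 known diploid samples."""
    from .hetroh import het_rate

    if len(diploid_obs) < 2:
        raise ValueError("baseline estimation needs at least 2 diploid samples")
    rates: dict = {c: [] for c in genome.autosomes}
    for obs in diploid_obs:
        stats = het_rate(obs, panel, genome)
        for chrom in genome.autosomes:
            row = stats.loc[stats["chrom"] == chrom]
            if len(row) and not row["missing"].iloc[0]:
                rates[chrom].append(float(row["het_rate"].iloc[0]))
    empty = [c for c, r in rates.items() if not r]
    if empty:
        raise ValueError(f"no covered sites on chromosome(s) {empty} in any baseline sample")
    het_mean = {c: float(np.mean(r)) for c, r in rates.items()}
    het_sd = {c: max(float(np.std(r, ddof=1)), sd_floor) for c, r in rates.items()}

    bin_baseline: dict = {}
    if diploid_bins:
        per_chrom_sum: dict = {}
        for bc in diploid_bins:
            for chrom, sub in bc.df.groupby("chrom", sort=False):
                per_chrom_sum.setdefault(chrom, []).append(sub["count"].to_numpy(float))
        raw = {c: np.mean(v, axis=0) for c, v in per_chrom_sum.items()}
        auto = np.concatenate([raw[c] for c in raw if genome.is_autosome(c)])
        scale = auto.mean()
        if scale <= 0:
            raise ValueError("degenerate bin baseline: zero mean coverage")
        bin_baseline = {c: np.maximum(v / scale, 1e-6) for c, v in raw.items()}
    return BaselineStats(het_mean, het_sd, bin_baseline, sd_floor)
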