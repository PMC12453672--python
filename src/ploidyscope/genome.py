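"""Desk-scale genome model shared by the simulator and the analysis stages.

Coordinates are 1-based inclusive at the interface (VCF convention); all
window arithmetic is done internally on 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus the fixed analysis window sizes.

    The default genome is a scaled-down stand-in for the human karyotype:
    22 autosomes plus X, 12 Mb each.  All statistics are computed on
    autosomes only; X exists to exercise the exclusion logic.
    """

    chrom_lengths: dict = field(default_factory=dict)
    bin_size: int = 600_000       # CNV coverage windows
    llr_window: int = 100_000     # likelihood-ratio windows
    roh_window: int = 1_000_000   # heterozygosity / ROH windows

    @property
    def chroms(self) -> list:
        return list(self.chrom_lengths)

    @property
    def autosomes(self) -> list:
        return [c for c in self.chrom_lengths if c not in ("X", "Y", "chrX", "chrY")]

    def is_autosome(self, chrom: str) -> bool:
        return chrom not in ("X", "Y", "chrX", "chrY")

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return (length + self.bin_size - 1) // self.bin_size

    def total_autosome_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.autosomes)


def default_genome(n_autosomes: int = 22, autosome_length: int = 12_000_000,
                   x_length: int = 12_000_000, **kwargs) -> GenomeSpec:
    lengths = {str(i): autosome_length for i in range(1, n_autosomes + 1)}
    if x_length:
        lengths["X"] = x_length
    return GenomeSpec(chrom_lengths=lengths, **kwargs)
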