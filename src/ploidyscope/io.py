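"""Sample-level data containers and their TSV serialisations.

An :class:`ObservationSet` is the ulc-WGS evidence for one biopsy: one row
per sequencing read that covers a panel SNP site, with the observed allele.
A :class:`BinnedCoverage` is the same sample's read counts in fixed 600 kb
windows with GC/mappability annotations, feeding the copy-number stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBS_COLUMNS = ["read_id", "chrom", "pos", "allele"]
BIN_COLUMNS = ["chrom", "start", "end", "count", "gc", "mappability"]


@dataclass
class ObservationSet:
    """Read-level allele observations at panel SNP sites.

    ``df`` columns: read_id, chrom, pos (1-based), allele (0=ref, 1=alt).
    Alleles are kept numeric internally; TSV round-trips translate to the
    site's actual bases through the panel.
    """

    df: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self):
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def to_tsv(self, path, panel) -> None:
        out = self.df.copy()
        bases = np.empty(len(out), dtype=object)
        for chrom, sub in out.groupby("chrom", sort=False):
            sites = panel.sites[chrom]
            idx = panel.site_index(chrom, sub["pos"].to_numpy())
            ref = sites["ref"].to_numpy()[idx]
            alt = sites["alt"].to_numpy()[idx]
            bases[sub.index.to_numpy()] = np.where(sub["allele"].to_numpy() == 1, alt, ref)
        out["allele"] = bases
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, panel, sample_id: str | None = None) -> "ObservationSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        allele = np.zeros(len(df), dtype=np.int8)
        for chrom, sub in df.groupby("chrom", sort=False):
            sites = panel.sites[chrom]
            idx = panel.site_index(chrom, sub["pos"].to_numpy())
            alt = sites["alt"].to_numpy()[idx]
            allele[sub.index.to_numpy()] = (sub["allele"].to_numpy() == alt).astype(np.int8)
        df["allele"] = allele
        sid = sample_id if sample_id is not None else str(path)
        return cls(df[OBS_COLUMNS].reset_index(drop=True), sample_id=sid)


@dataclass
class BinnedCoverage:
    """Per-600 kb-bin read counts with GC and mappability annotations.

    After :func:`ploidyscope.cnv.normalize_bins` the frame gains a
    ``copy_ratio`` column on the diploid = 2.0 scale.
    """

    df: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self):
        missing = [c for c in BIN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"bin table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "BinnedCoverage":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        sid = sample_id if sample_id is not None else str(path)
        return cls(df, sample_id=sid)
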