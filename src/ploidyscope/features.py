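"""Engineered features feeding the ploidy classifier.

Eleven final features (the model's inputs):

- ``bph_sph_prop``        proportion of autosomal windows with LLR(BPH vs SPH) > 0
- ``bph_sph_pos_mean``    mean LLR(BPH vs SPH) of windows with LLR > 0
- ``bph_disomy_chrom_sd`` SD of per-chromosome mean LLR(BPH vs disomy) across autosomes
- ``sph_disomy_mean``     mean LLR(SPH vs disomy) across all autosomal windows
- ``chrom_zscore_sd``     SD of het-rate Z-scores across autosomes
- ``aneuploidy_count``    number of reportable PGT-A copy-number events
- ``sph_disomy_pos_mean`` mean LLR(SPH vs disomy) of windows with LLR > 0
- ``monosomy_disomy_prop``  proportion of windows with LLR(monosomy vs disomy) > 0
- ``het_rate_chrom_sd``   SD of per-chromosome het rates across autosomes
- ``monosomy_disomy_pos_mean``  mean LLR(monosomy vs disomy) of windows with LLR > 0
- ``pgta_score_variance`` SD of per-chromosome median copy ratios

The remaining 12 candidates complete the 23-candidate pool by systematic
analogy — the same statistic families (window proportion > 0, window mean,
positive-window mean, per-chromosome SD) applied to the other hypothesis
contrasts, plus genome-wide het rate, mean |Z|, and the autosomal ROH
fraction.  The reconstruction is documented in docs/methods.md; only the
eleven finals enter the shipped model.

All features are computed over autosomes only; sample SDs use n-1;
">0" means average only strictly positive window means, 0 (with a QC
flag) when the set is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .llr import PAIRS

FINAL_FEATURES = [
    "bph_sph_prop", "bph_sph_pos_mean", "bph_disomy_chrom_sd",
    "sph_disomy_mean", "chrom_zscore_sd", "aneuploidy_count",
    "sph_disomy_pos_mean", "monosomy_disomy_prop", "het_rate_chrom_sd",
    "monosomy_disomy_pos_mean", "pgta_score_variance",
]

_LLR_FAMILIES = ("prop", "mean", "pos_mean", "chrom_sd")

CANDIDATE_FEATURES = (
    [f"{pair}_{fam}" for pair in ("bph_sph", "bph_disomy", "sph_disomy", "monosomy_disomy")
     for fam in _LLR_FAMILIES]
    + ["genome_het_rate", "mean_abs_zscore", "chrom_zscore_sd", "het_rate_chrom_sd",
       "aneuploidy_count", "pgta_score_variance", "roh_fraction"]
)

MIN_USABLE_WINDOWS = 20


def _sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


@dataclass
class FeatureVector:
    values: dict
    qc_pass: bool = True
    qc_flags: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        s = pd.Series({k: self.values.get(k, 0.0) for k in CANDIDATE_FEATURES})
        s["qc_pass"] = self.qc_pass
        return s


def compute_features(window_llrs: pd.DataFrame, het_stats: pd.DataFrame,
                     cnv_summary, genome, roh_regions: pd.DataFrame | None = None,
                     min_usable_windows: int = MIN_USABLE_WINDOWS) -> FeatureVector:
    """The 23 candidate features for one sample.

    ``window_llrs`` is the :func:`ploidyscope.llr.window_llr` table,
    ``het_stats`` the :func:`ploidyscope.hetroh.het_z_scores` table, and
    ``cnv_summary`` a :class:`ploidyscope.cnv.CNVSummary`.  Samples with
    fewer than ``min_usable_windows`` non-null autosomal windows are
    marked QC-failed (the classifier reports them indeterminable).
    """
    flags: list = []
    auto = window_llrs[[genome.is_autosome(c) for c in window_llrs["chrom"]]]
    usable = auto[auto["n_draws"] > 0]
    qc_pass = len(usable) >= min_usable_windows
    if not qc_pass:
        flags.append(f"usable_windows={len(usable)}<{min_usable_windows}")

    values: dict = {}
    for pair in PAIRS:
        means = usable[f"mean_{pair}"].to_numpy(float)
        means = means[np.isfinite(means)]
        pos = means[means > 0]
        values[f"{pair}_prop"] = float(len(pos) / len(means)) if len(means) else 0.0
        values[f"{pair}_mean"] = float(means.mean()) if len(means) else 0.0
        if len(pos):
            values[f"{pair}_pos_mean"] = float(pos.mean())
        else:
            values[f"{pair}_pos_mean"] = 0.0
            flags.append(f"{pair}_pos_empty")
        chrom_means = usable.groupby("chrom", sort=False)[f"mean_{pair}"].mean()
        values[f"{pair}_chrom_sd"] = _sd(chrom_means.to_numpy())

    chrom_rows = het_stats[(het_stats["chrom"] != "genome") & (~het_stats["missing"])]
    genome_row = het_stats[het_stats["chrom"] == "genome"]
    values["genome_het_rate"] = float(genome_row["het_rate"].iloc[0]) \
        if len(genome_row) and np.isfinite(genome_row["het_rate"].iloc[0]) else 0.0
    z = chrom_rows["z_score"].to_numpy(float) if "z_score" in chrom_rows else np.array([])
    z = z[np.isfinite(z)]
    values["mean_abs_zscore"] = float(np.abs(z).mean()) if len(z) else 0.0
    values["chrom_zscore_sd"] = _sd(z)
    values["het_rate_chrom_sd"] = _sd(chrom_rows["het_rate"].to_numpy(float))
    n_missing = int(het_stats["missing"].sum()) - int(genome_row["missing"].sum())
    if n_missing:
        flags.append(f"chroms_missing_het={n_missing}")

    values["aneuploidy_count"] = float(cnv_summary.aneuploidy_count)
    values["pgta_score_variance"] = float(cnv_summary.pgta_score_variance)

    if roh_regions is not None and len(roh_regions):
        roh_len = float((roh_regions["end"] - roh_regions["start"] + 1).sum())
        values["roh_fraction"] = roh_len / genome.total_autosome_length()
    else:
        values["roh_fraction"] = 0.0

    return FeatureVector(values, qc_pass, flags)


def cohort_matrix(samples: dict, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack per-sample FeatureVectors into a labelled matrix.

    ``samples`` maps sample_id -> FeatureVector.  With a manifest
    (columns sample_id, truth_label) a ``label`` column is joined; unknown
    sample ids in the manifest raise.
    """
    if not samples:
        raise ValueError("cohort_matrix needs at least one sample")
    rows = {}
    for sid, fv in samples.items():
        missing = [k for k in CANDIDATE_FEATURES if k not in fv.values]
        if missing:
            raise ValueError(f"sample {sid} missing features: {missing}")
        rows[sid] = fv.as_series()
    mat = pd.DataFrame(rows).T
    mat.index.name = "sample_id"
    mat = mat[CANDIDATE_FEATURES + ["qc_pass"]]
    if manifest is not None:
        man = manifest.set_index("sample_id")
        unknown = [s for s in man.index if s not in mat.index]
        if unknown:
            raise ValueError(f"manifest sample ids not in cohort: {unknown}")
        mat = mat.join(man["truth_label"].rename("label"))
    return mat
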