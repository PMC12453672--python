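"""Bin-level copy-number pipeline: normalisation, HMM segmentation, state calls.

Raw 600 kb bin counts are corrected for GC content (lowess), divided by
mappability and by the diploid per-bin baseline, then rescaled so the
autosomal median copy ratio is 2.0.  A 5-state Gaussian HMM with emission
means at copy ratios {1.0, 1.5, 2.0, 2.5, 3.0} and stay probability 0.999
segments each chromosome (Viterbi); segments take the median ratio of
their member bins.  State bands on the diploid = 2.0 scale:

    ratio > 2.7            duplication
    2.3 < ratio <= 2.7     mosaic_duplication
    1.7 <= ratio <= 2.3    normal
    1.3 <= ratio < 1.7     mosaic_deletion
    ratio < 1.3            deletion

which matches a 30-70% mosaic cell fraction window.  Whole-genome events
(triploidy, GW-UPD) are invisible here — the global scale is absorbed by
the median rescale — which is exactly why the likelihood and
heterozygosity evidence exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import BinnedCoverage

HMM_MEANS = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
HMM_STAY = 0.999
MIN_EVENT_BP = 1_000_000          # minimum reportable full CNV
MIN_MOSAIC_BP = 10_000_000        # minimum reportable mosaic CNV
MAPPABILITY_FLOOR = 0.5


def normalize_bins(raw: BinnedCoverage, baseline, genome,
                   mappability_floor: float = MAPPABILITY_FLOOR,
                   lowess_frac: float = 0.5) -> BinnedCoverage:
    """GC-lowess + mappability + baseline calibration, median scaled to 2.0."""
    df = raw.df.copy()
    ok = df["mappability"] >= mappability_floor
    if ok.mean() < 0.8:
        raise ValueError("more than 20% of bins fall below the mappability floor")
    vals = df["count"].to_numpy(float) / np.maximum(df["mappability"].to_numpy(float), 1e-6)

    gc = df["gc"].to_numpy(float)
    if np.ptp(gc) > 1e-9 and np.ptp(vals) > 1e-9:
        fit = lowess(vals, gc, frac=lowess_frac, return_sorted=False)
        fit = np.maximum(fit, 1e-6)
        vals = vals / fit * np.median(fit)

    if baseline is not None and baseline.bin_baseline:
        expected = np.concatenate([
            baseline.bin_baseline[c] for c in df["chrom"].unique()])
        if len(expected) != len(df) or not np.all(expected > 0):
            raise ValueError("degenerate bin baseline")
        vals = vals / expected

    auto = np.array([genome.is_autosome(c) for c in df["chrom"]])
    med = np.median(vals[auto & ok.to_numpy()])
    if med <= 0:
        raise ValueError("degenerate coverage: zero autosomal median")
    df["copy_ratio"] = 2.0 * vals / med
    return BinnedCoverage(df, sample_id=raw.sample_id)


def _emission_sd(ratios: np.ndarray) -> float:
    resid = ratios - np.median(ratios)
    sd = 1.4826 * np.median(np.abs(resid))  # MAD, robust to real CNVs
    return float(max(sd, 0.05))


def segment_hmm(norm: BinnedCoverage, genome) -> pd.DataFrame:
    """Viterbi segmentation of normalized copy ratios per chromosome."""
    from hmmlearn.hmm import GaussianHMM

    df = norm.df
    if "copy_ratio" not in df.columns:
        raise ValueError("bins are not normalized; run normalize_bins first")
    auto = df[[genome.is_autosome(c) for c in df["chrom"]]]
    sd = _emission_sd(auto["copy_ratio"].to_numpy(float))

    n_states = len(HMM_MEANS)
    hmm = GaussianHMM(n_components=n_states, covariance_type="diag",
                      init_params="", params="")
    hmm.startprob_ = np.full(n_states, 1.0 / n_states)
    off = (1.0 - HMM_STAY) / (n_states - 1)
    hmm.transmat_ = np.full((n_states, n_states), off) \
        + np.eye(n_states) * (HMM_STAY - off)
    hmm.means_ = HMM_MEANS.reshape(-1, 1)
    hmm.covars_ = np.full((n_states, 1), sd**2)

    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        ratios = sub["copy_ratio"].to_numpy(float)
        if len(sub) < 3:
            rows.append({"chrom": chrom, "start": int(sub["start"].iloc[0]),
                         "end": int(sub["end"].iloc[-1]), "n_bins": len(sub),
                         "copy_ratio": float(np.median(ratios)),
                         "low_confidence": True})
            continue
        states = hmm.predict(ratios.reshape(-1, 1))
        change = np.flatnonzero(np.diff(states)) + 1
        bounds = np.concatenate([[0], change, [len(states)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "start": int(sub["start"].iloc[a]),
                         "end": int(sub["end"].iloc[b - 1]), "n_bins": int(b - a),
                         "copy_ratio": float(np.median(ratios[a:b])),
                         "low_confidence": False})
    return pd.DataFrame(rows)


def band_state(copy_ratio: float) -> str:
    """Copy-ratio band on the diploid = 2.0 scale; a pure function."""
    if copy_ratio > 2.7:
        return "duplication"
    if copy_ratio > 2.3:
        return "mosaic_duplication"
    if copy_ratio < 1.3:
        return "deletion"
    if copy_ratio < 1.7:
        return "mosaic_deletion"
    return "normal"


@dataclass
class CNVSummary:
    """The two classifier features contributed by the PGT-A stage."""

    aneuploidy_count: int
    pgta_score_variance: float
    segments: pd.DataFrame
    chrom_medians: pd.Series


def call_states(segments: pd.DataFrame, norm: BinnedCoverage, genome,
                min_event_bp: int = MIN_EVENT_BP,
                min_mosaic_bp: int = MIN_MOSAIC_BP) -> CNVSummary:
    """Apply state bands; count reportable events; per-chromosome score SD.

    Aneuploidy Count = number of non-normal autosomal segments at or above
    the minimum reportable size (1 Mb for full events, 10 Mb for mosaic).
    PGT-A Score Variance = sample SD of per-autosome median copy ratios.
    """
    seg = segments.copy()
    seg["state"] = [band_state(r) for r in seg["copy_ratio"]]

    count = 0
    for _, r in seg.iterrows():
        if not genome.is_autosome(r["chrom"]) or r["state"] == "normal":
            continue
        size = r["end"] - r["start"] + 1
        floor = min_mosaic_bp if "mosaic" in r["state"] else min_event_bp
        if size >= floor:
            count += 1

    df = norm.df
    medians = (df[[genome.is_autosome(c) for c in df["chrom"]]]
               .groupby("chrom", sort=False)["copy_ratio"].median())
    var = float(np.std(medians.to_numpy(), ddof=1)) if len(medians) > 1 else 0.0
    return CNVSummary(count, var, seg, medians)


def run_cnv(raw: BinnedCoverage, baseline, genome) -> CNVSummary:
    norm = normalize_bins(raw, baseline, genome)
    segments = segment_hmm(norm, genome)
    return call_states(segments, norm, genome)
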