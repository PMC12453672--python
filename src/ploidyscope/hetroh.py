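"""Heterozygosity-rate statistics, Z-scores, and runs of homozygosity.

A site is *informative* when it is autosomal and covered by at least two
reads (heterozygosity is unobservable from one read); it is heterozygous
when both alleles are observed at least once.  Per-chromosome rates are
standardised against the diploid baseline.  ROH are found with
non-overlapping 1 Mb windows: consecutive windows with het rate below the
0.02 threshold are merged (tolerating single-window gaps), and regions
with at least ``min_low_windows`` sub-threshold windows are reported.
A genome-wide-ROH (GW-ROH) flag fires when ROH cover more than 80% of the
autosome — the signature of homozygous genome-wide uniparental diploidy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_ROH_THRESHOLD = 0.02
MIN_INFORMATIVE_PER_WINDOW = 5
MIN_LOW_WINDOWS = 2
GAP_TOLERANCE = 1
GW_ROH_FRACTION = 0.80


def _site_pileup(obs, panel, chrom: str):
    """Per-site ref/alt read counts for one chromosome."""
    sub = obs.for_chrom(chrom)
    n_sites = panel.n_sites(chrom)
    ref = np.zeros(n_sites, dtype=np.int64)
    alt = np.zeros(n_sites, dtype=np.int64)
    if len(sub):
        idx = panel.site_index(chrom, sub["pos"].to_numpy())
        allele = sub["allele"].to_numpy()
        np.add.at(ref, idx[allele == 0], 1)
        np.add.at(alt, idx[allele == 1], 1)
    return ref, alt


def site_calls(obs, panel, chrom: str):
    """informative/heterozygous boolean masks over the chromosome's sites."""
    ref, alt = _site_pileup(obs, panel, chrom)
    informative = ref + alt >= 2
    het = (ref >= 1) & (alt >= 1) & informative
    return informative, het


def het_rate(obs, panel, genome, min_informative: int = 1) -> pd.DataFrame:
    """Per-autosome (plus genome-wide) heterozygosity rate.

    Chromosomes with fewer than ``min_informative`` informative sites are
    flagged missing.  The genome-wide row has chrom = 'genome'.
    """
    rows = []
    tot_inf = tot_het = 0
    for chrom in genome.autosomes:
        if chrom not in panel.sites:
            continue
        informative, het = site_calls(obs, panel, chrom)
        n_inf = int(informative.sum())
        n_het = int(het.sum())
        tot_inf += n_inf
        tot_het += n_het
        missing = n_inf < min_informative
        rows.append({"chrom": chrom, "n_informative": n_inf, "n_het": n_het,
                     "het_rate": n_het / n_inf if n_inf else np.nan,
                     "missing": missing})
    rows.append({"chrom": "genome", "n_informative": tot_inf, "n_het": tot_het,
                 "het_rate": tot_het / tot_inf if tot_inf else np.nan,
                 "missing": tot_inf < min_informative})
    return pd.DataFrame(rows)


def het_z_scores(het_stats: pd.DataFrame, baseline) -> pd.DataFrame:
    """Attach baseline Z-scores to per-chromosome het rates."""
    out = het_stats.copy()
    z = []
    for _, r in out.iterrows():
        if r["chrom"] in baseline.het_mean and not r["missing"]:
            z.append(baseline.z_score(r["chrom"], r["het_rate"]))
        else:
            z.append(np.nan)
    out["z_score"] = z
    return out


def window_het(obs, panel, genome, chrom: str,
               min_informative: int = MIN_INFORMATIVE_PER_WINDOW) -> pd.DataFrame:
    """Non-overlapping 1 Mb window het rates (NaN when under-informed)."""
    informative, het = site_calls(obs, panel, chrom)
    pos = panel.sites[chrom]["pos"].to_numpy()
    win = genome.roh_window
    length = genome.chrom_lengths[chrom]
    n_win = (length + win - 1) // win
    widx = (pos - 1) // win
    n_inf = np.bincount(widx[informative], minlength=n_win)
    n_het = np.bincount(widx[het], minlength=n_win)
    rate = np.where(n_inf >= min_informative, n_het / np.maximum(n_inf, 1), np.nan)
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n_win) * win + 1,
        "end": np.minimum((np.arange(n_win) + 1) * win, length),
        "n_informative": n_inf, "n_het": n_het, "het_rate": rate})


def detect_roh(obs, panel, genome, baseline=None,
               threshold: float = DEFAULT_ROH_THRESHOLD,
               gap_tolerance: int = GAP_TOLERANCE,
               min_low_windows: int = MIN_LOW_WINDOWS,
               gw_fraction: float = GW_ROH_FRACTION):
    """ROH regions across the autosomes plus the GW-ROH flag.

    Returns (regions DataFrame, gw_roh flag, window table).  Region columns
    include the mean window het rate, a Z-score against the chromosome
    baseline (NaN without a baseline) and the Euclidean distance between
    the region's window-het vector and the mean het level of non-ROH
    windows genome-wide.
    """
    win_frames = []
    for chrom in genome.autosomes:
        if chrom in panel.sites:
            win_frames.append(window_het(obs, panel, genome, chrom))
    windows = pd.concat(win_frames, ignore_index=True)
    windows["low"] = windows["het_rate"] < threshold

    regions = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        low = sub["low"].to_numpy()
        gidx = sub.index.to_numpy()
        i = 0
        while i < len(sub):
            if not low[i]:
                i += 1
                continue
            j = i
            gap = 0
            last_low = i
            while j + 1 < len(sub):
                if low[j + 1]:
                    j += 1
                    last_low = j
                    gap = 0
                elif gap < gap_tolerance:
                    j += 1
                    gap += 1
                else:
                    break
            j = last_low
            n_low = int(low[i:j + 1].sum())
            if n_low >= min_low_windows:
                regions.append((chrom, windows.loc[gidx[i:j + 1]]))
            i = j + 1

    roh_mask = np.zeros(len(windows), dtype=bool)
    for chrom, block in regions:
        roh_mask[block.index.to_numpy()] = True
    normal = windows.loc[~roh_mask, "het_rate"].dropna()
    normal_mean = float(normal.mean()) if len(normal) else np.nan

    rows = []
    for chrom, block in regions:
        rates = block["het_rate"].dropna().to_numpy()
        mean_het = float(rates.mean()) if len(rates) else np.nan
        z = (baseline.z_score(chrom, mean_het)
             if baseline is not None and chrom in baseline.het_mean else np.nan)
        euclid = (float(np.sqrt(np.sum((rates - normal_mean) ** 2)))
                  if len(rates) and np.isfinite(normal_mean) else np.nan)
        rows.append({"chrom": chrom, "start": int(block["start"].iloc[0]),
                     "end": int(block["end"].iloc[-1]),
                     "n_windows": len(block), "mean_het": mean_het,
                     "z_score": z, "euclid": euclid})
    region_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                            "mean_het", "z_score", "euclid"])
    roh_len = int((region_df["end"] - region_df["start"] + 1).sum()) if len(region_df) else 0
    gw_roh = roh_len > gw_fraction * genome.total_autosome_length()
    return region_df, bool(gw_roh), windows.drop(columns="low")
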