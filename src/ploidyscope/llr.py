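"""Homolog-dosage likelihood ratios from panel joint frequencies.

For a handful of reads in a 100 kb window, the likelihood of the read data
under a dosage hypothesis with k homologs and weights w is the exhaustive
sum over read-to-homolog assignments:

    L(reads | hyp) = sum over a in {1..k}^m  of
                     prod_r w_{a(r)}  *  prod_{i=1..k} F(S_i(a))

where S_i(a) is the pattern of (pos, allele) observations assigned to
homolog i, F is the panel joint haplotype frequency (F of the empty set is
1, zero counts floored at the panel epsilon).  Reads from the same homolog
must be jointly consistent with one panel haplotype, which is how linkage
disequilibrium separates e.g. three distinct homologs (BPH) from a
duplicated one (SPH).

Hypotheses: monosomy (1), disomy (1/2, 1/2), SPH (2/3, 1/3),
BPH (1/3, 1/3, 1/3).  Log-likelihood ratios are natural logs.

Window statistics follow a multiple-sampling scheme: per 100 kb window,
draw m reads without replacement n_draws times and record the mean and
variance of each pairwise LLR over the draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

#: homolog weight vectors per hypothesis
HYPOTHESES = {
    "monosomy": (1.0,),
    "disomy": (0.5, 0.5),
    "SPH": (2.0 / 3.0, 1.0 / 3.0),
    "BPH": (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
}

#: pairwise contrasts reported per window, as (numerator, denominator)
PAIRS = {
    "bph_sph": ("BPH", "SPH"),
    "bph_disomy": ("BPH", "disomy"),
    "sph_disomy": ("SPH", "disomy"),
    "monosomy_disomy": ("monosomy", "disomy"),
}


@dataclass(frozen=True)
class Hypothesis:
    name: str

    @property
    def weights(self) -> tuple:
        return HYPOTHESES[self.name]


@lru_cache(maxsize=None)
def _assignments(k: int, m: int):
    """All k^m read-to-homolog assignments, as per-homolog subset masks
    plus per-homolog read counts (for the weight product)."""
    masks, counts = [], []
    for a in product(range(k), repeat=m):
        mk = [0] * k
        ct = [0] * k
        for r, i in enumerate(a):
            mk[i] |= 1 << r
            ct[i] += 1
        masks.append(mk)
        counts.append(ct)
    return np.array(masks, dtype=np.int64), np.array(counts, dtype=np.int64)


def _subset_freqs(match: np.ndarray, floor: float) -> np.ndarray:
    """F for every nonempty subset of the m reads.

    match: (n_draws, m, N) boolean read-vs-haplotype compatibility.
    Returns (n_draws, 2**m) with index 0 = F(empty) = 1.
    """
    n_draws, m, n_hap = match.shape
    out = np.empty((n_draws, 1 << m))
    out[:, 0] = 1.0
    for s in range(1, 1 << m):
        rows = [r for r in range(m) if s >> r & 1]
        f = match[:, rows, :].all(axis=1).mean(axis=1)
        out[:, s] = np.where(f > 0, f, floor)
    return out


def _likelihoods(match: np.ndarray, floor: float) -> dict:
    """L under every hypothesis for each draw; match is (n_draws, m, N)."""
    m = match.shape[1]
    ftab = _subset_freqs(match, floor)
    out = {}
    for name, w in HYPOTHESES.items():
        k = len(w)
        masks, counts = _assignments(k, m)
        coefs = np.prod(np.power(np.array(w), counts), axis=1)   # (A,)
        terms = ftab[:, masks].prod(axis=2)                      # (n_draws, A)
        out[name] = terms @ coefs
    return out


def _match_vectors(panel, chrom: str, pos: np.ndarray, allele: np.ndarray) -> np.ndarray:
    """(n_reads, N) boolean: panel haplotype carries the read's allele."""
    idx = panel.site_index(chrom, pos)
    return (panel.haplotypes[chrom][:, idx] == allele[None, :].astype(np.uint8)).T


def likelihood(reads, hyp, panel, chrom: str | None = None) -> float:
    """L(reads | hypothesis) for a list of (pos, allele) on one chromosome."""
    reads = list(reads)
    if not reads:
        raise ValueError("likelihood of an empty read list is undefined")
    if chrom is None:
        chrom = panel._resolve_chrom([p for p, _ in reads])
    pos = np.array([p for p, _ in reads])
    allele = np.array([a for _, a in reads])
    match = _match_vectors(panel, chrom, pos, allele)[None, :, :]
    name = hyp.name if isinstance(hyp, Hypothesis) else str(hyp)
    if name not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {name!r}")
    return float(_likelihoods(match, panel.frequency_floor)[name][0])


def log_likelihood_ratio(reads, hyp_a, hyp_b, panel, chrom: str | None = None) -> float:
    return float(np.log(likelihood(reads, hyp_a, panel, chrom))
                 - np.log(likelihood(reads, hyp_b, panel, chrom)))


def window_llr(obs, panel, genome, m: int = 3, n_draws: int = 16,
               seed: int = 0) -> pd.DataFrame:
    """Per-100 kb-window LLR means/variances under multiple sampling.

    Returns one row per window and chromosome with, for each contrast in
    :data:`PAIRS`, ``mean_<pair>`` and ``var_<pair>`` over ``n_draws``
    draws of ``m`` distinct reads; windows with fewer than ``m`` usable
    reads carry NaN ("null") entries.
    """
    if m < 2:
        raise ValueError("draw size m must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    win = genome.llr_window
    for chrom in panel.chroms:
        sub = obs.for_chrom(chrom)
        length = genome.chrom_lengths[chrom]
        n_win = (length + win - 1) // win
        if len(sub):
            pos = sub["pos"].to_numpy()
            allele = sub["allele"].to_numpy()
            widx = (pos - 1) // win
        else:
            pos = np.array([], dtype=int)
            allele = np.array([], dtype=int)
            widx = np.array([], dtype=int)
        for w in range(n_win):
            sel = widx == w
            n_reads = int(sel.sum())
            row = {"chrom": chrom, "start": w * win + 1,
                   "end": min((w + 1) * win, length), "n_reads": n_reads}
            if n_reads < m:
                for pair in PAIRS:
                    row[f"mean_{pair}"] = np.nan
                    row[f"var_{pair}"] = np.nan
                row["n_draws"] = 0
            else:
                wpos, wall = pos[sel], allele[sel]
                match_all = _match_vectors(panel, chrom, wpos, wall)
                order = np.argsort(rng.random((n_draws, n_reads)), axis=1)[:, :m]
                match = match_all[order]                     # (n_draws, m, N)
                lik = _likelihoods(match, panel.frequency_floor)
                logs = {h: np.log(v) for h, v in lik.items()}
                for pair, (a, b) in PAIRS.items():
                    vals = logs[a] - logs[b]
                    row[f"mean_{pair}"] = float(vals.mean())
                    row[f"var_{pair}"] = float(vals.var(ddof=1)) if n_draws > 1 else 0.0
                row["n_draws"] = n_draws
            rows.append(row)
    return pd.DataFrame(rows)


def merge_segments(windows: pd.DataFrame, target_reads_per_segment: int = 12) -> pd.DataFrame:
    """Greedy merge of adjacent non-null windows into read-balanced segments.

    Pooled mean over k member windows is the mean of member means; pooled
    variance is the sum of member variances divided by k**2 (member means
    treated as independent); z is pooled mean over pooled standard error.
    Segments never span a chromosome boundary.
    """
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        usable = sub[sub["n_draws"] > 0]
        members: list = []
        reads = 0
        for _, r in usable.iterrows():
            members.append(r)
            reads += int(r["n_reads"])
            if reads >= target_reads_per_segment:
                rows.append(_pool(chrom, members))
                members, reads = [], 0
        if members:
            rows.append(_pool(chrom, members))
    cols = ["chrom", "start", "end", "n_windows", "n_reads"]
    for pair in PAIRS:
        cols += [f"mean_{pair}", f"var_{pair}", f"z_{pair}"]
    return pd.DataFrame(rows, columns=cols)


def _pool(chrom, members) -> dict:
    k = len(members)
    out = {"chrom": chrom, "start": int(members[0]["start"]),
           "end": int(members[-1]["end"]), "n_windows": k,
           "n_reads": int(sum(m["n_reads"] for m in members))}
    for pair in PAIRS:
        means = np.array([m[f"mean_{pair}"] for m in members])
        variances = np.array([m[f"var_{pair}"] for m in members])
        mean = means.mean()
        var = variances.sum() / k**2
        out[f"mean_{pair}"] = float(mean)
        out[f"var_{pair}"] = float(var)
        out[f"z_{pair}"] = float(mean / np.sqrt(var)) if var > 0 else np.nan
    return out
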