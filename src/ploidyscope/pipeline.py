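"""End-to-end per-sample pipeline and cohort-level statistics.

`run_pipeline` chains CNV -> heterozygosity/ROH -> window LLR -> features
-> (optionally) classification for one sample, returning a JSON-ready
report with per-stage status.  `cohort_stats` produces per-group class
counts/percentages and chi-square tests for contingency tables such as
the insemination-pattern comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import cnv as cnv_mod
from . import features as feat_mod
from . import hetroh, llr

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INDETERMINABLE = 3
EXIT_ERROR = 1

REPORT_SCHEMA_VERSION = "1"


def run_pipeline(obs, bins, panel, genome, baseline, model=None,
                 llr_m: int = 3, llr_draws: int = 16, seed: int = 0) -> dict:
    """Run all analysis stages for one sample; never raises mid-pipeline.

    Returns a report dict with keys: sample_id, stages (status per stage),
    cnv, het, roh, gw_roh, features, qc_pass, call, exit_code.
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "sample_id": obs.sample_id, "stages": {}, "seed": seed}

    def stage(name, fn):
        try:
            out = fn()
            report["stages"][name] = "ok"
            return out
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            logger.warning("stage %s failed for %s: %s", name, obs.sample_id, exc)
            report["stages"][name] = f"error: {exc}"
            return None

    summary = stage("cnv", lambda: cnv_mod.run_cnv(bins, baseline, genome))
    if summary is not None:
        report["cnv"] = {
            "aneuploidy_count": summary.aneuploidy_count,
            "pgta_score_variance": summary.pgta_score_variance,
            "segments": summary.segments.to_dict("records")}

    het = stage("hetroh", lambda: hetroh.het_z_scores(
        hetroh.het_rate(obs, panel, genome), baseline))
    roh_out = stage("roh", lambda: hetroh.detect_roh(obs, panel, genome, baseline))
    if het is not None:
        report["het"] = het.to_dict("records")
    if roh_out is not None:
        regions, gw_flag, _ = roh_out
        report["roh"] = regions.to_dict("records")
        report["gw_roh"] = gw_flag

    windows = stage("llr", lambda: llr.window_llr(
        obs, panel, genome, m=llr_m, n_draws=llr_draws, seed=seed))

    fv = None
    if windows is not None and het is not None and summary is not None:
        regions = roh_out[0] if roh_out is not None else None
        fv = stage("features", lambda: feat_mod.compute_features(
            windows, het, summary, genome, roh_regions=regions))
    if fv is not None:
        report["features"] = fv.values
        report["qc_pass"] = fv.qc_pass
        report["qc_flags"] = fv.qc_flags
    else:
        report["qc_pass"] = False

    if model is not None and fv is not None:
        X = pd.DataFrame([fv.as_series()[feat_mod.FINAL_FEATURES]])
        calls = model.call(X, qc_fail=[not fv.qc_pass])
        row = calls.iloc[0]
        report["call"] = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                          for k, v in row.items()}
    errors = [s for s in report["stages"].values() if s.startswith("error")]
    if errors:
        report["exit_code"] = EXIT_ERROR
    elif not report["qc_pass"]:
        report["exit_code"] = EXIT_INDETERMINABLE
    else:
        report["exit_code"] = EXIT_OK
    return report


def sample_features(obs, bins, panel, genome, baseline, llr_m: int = 3,
                    llr_draws: int = 16, seed: int = 0):
    """Run the analysis stages for one sample and return its FeatureVector."""
    summary = cnv_mod.run_cnv(bins, baseline, genome)
    het = hetroh.het_z_scores(hetroh.het_rate(obs, panel, genome), baseline)
    regions, _, _ = hetroh.detect_roh(obs, panel, genome, baseline)
    windows = llr.window_llr(obs, panel, genome, m=llr_m, n_draws=llr_draws, seed=seed)
    return feat_mod.compute_features(windows, het, summary, genome,
                                     roh_regions=regions)


def cohort_features(cohort, panel, genome, baseline, seed: int = 0,
                    llr_m: int = 3, llr_draws: int = 16) -> pd.DataFrame:
    """Feature matrix (with truth labels) for a simulated cohort."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort.samples))
    fvs = {}
    for s, child in zip(cohort.samples, children):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        fvs[s.sample_id] = sample_features(s.obs, s.bins, panel, genome, baseline,
                                           llr_m=llr_m, llr_draws=llr_draws, seed=sub)
    return feat_mod.cohort_matrix(fvs, cohort.manifest)


# -- cohort statistics ----------------------------------------------------


@dataclass
class CohortSummary:
    counts: pd.DataFrame        # classes x groups
    percentages: pd.DataFrame   # same shape, % within group (1 d.p. reproducible)
    tests: pd.DataFrame         # per-class 2xk chi-square


def two_by_two_test(k1: int, n1: int, k2: int, n2: int, correction: bool = False):
    """Chi-square on [[k1, n1-k1], [k2, n2-k2]] (Yates off by default)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    stat, p, dof, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p), int(dof)


def cohort_stats(calls: pd.DataFrame, group_col: str, class_col: str = "label",
                 correction: bool = False) -> CohortSummary:
    """Per-group class counts/percentages plus per-class chi-square tests."""
    counts = pd.crosstab(calls[class_col], calls[group_col])
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        pct = counts.astype(float) * np.nan
    else:
        pct = 100.0 * counts / totals
    rows = []
    if counts.shape[1] >= 2:
        for cls in counts.index:
            pos = counts.loc[cls].to_numpy()
            neg = (totals - counts.loc[cls]).to_numpy()
            table = np.array([pos, neg])
            if table.sum(axis=0).min() == 0 or pos.sum() == 0 or neg.sum() == 0:
                rows.append({"class": cls, "chi2": np.nan, "p": np.nan, "dof": np.nan})
                continue
            stat, p, dof, _ = chi2_contingency(table, correction=correction)
            rows.append({"class": cls, "chi2": float(stat), "p": float(p), "dof": int(dof)})
    tests = pd.DataFrame(rows, columns=["class", "chi2", "p", "dof"])
    return CohortSummary(counts, pct, tests)
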