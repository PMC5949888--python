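"""Growth estimation and stop-codon-calibrated classification.

Count tables from the screen are normalized (total-sum per sample, then to
the day-0 value so every trajectory starts at 1), each sequence's pooled
replicate trajectory is fitted with a robust linear model through y(0)=1,
and the resulting growth estimates are thresholded against the empirical
null formed by inserts that begin with a stop codon (truncated, necessarily
non-functional proteins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import translate_insert

HUBER_C = 1.345
MAX_ITER = 50
TOL = 1e-8


class UndefinedMetricError(ValueError):
    """A rate or ratio with a zero denominator."""


@dataclass
class GrowthFit:
    sequence: str
    slope: float
    converged: bool
    n_replicates: int
    total_raw_reads: int

    @property
    def rounded_estimate(self) -> float:
        return round_estimate(self.slope)


@dataclass
class ThresholdReport:
    threshold: float
    mode: str  # design_max_stop | target_fpr
    stop_set_size: int
    fpr_at_threshold: float
    n_functional: int = 0


# ---------------------------------------------------------------------------
# count filtering and normalization


def prefilter_counts(counts: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Drop sequences with fewer than ``min_total`` reads over all samples."""
    totals = counts.groupby("sequence")["count"].transform("sum")
    return counts[totals >= min_total].reset_index(drop=True)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a long count table to per-replicate trajectories y(t).

    Steps: (i) day-0 zeros are imputed to one raw read when the replicate
    has nonzero later counts (prevents division by zero), (ii) every count
    is divided by its (time, replicate) sample total, (iii) each replicate
    trajectory is divided by its day-0 value so y(0) = 1. Replicate
    trajectories that are all zero are dropped.

    Returns a long table ``sequence, time_day, replicate, count, y``.
    """
    df = counts.copy()
    t0 = df["time_day"].min()
    # (i) impute day-0 zeros where the replicate has later signal
    later = (
        df[df["time_day"] > t0]
        .groupby(["sequence", "replicate"])["count"]
        .sum()
        .rename("later_total")
    )
    df = df.merge(later, on=["sequence", "replicate"], how="left")
    df["later_total"] = df["later_total"].fillna(0)
    df["adj_count"] = df["count"].astype(float)
    mask = (df["time_day"] == t0) & (df["count"] == 0) & (df["later_total"] > 0)
    df.loc[mask, "adj_count"] = 1.0
    # drop all-zero replicate trajectories
    rep_total = df.groupby(["sequence", "replicate"])["adj_count"].transform("sum")
    df = df[rep_total > 0]
    # (ii) total-sum normalization per (time, replicate) sample
    sample_total = df.groupby(["time_day", "replicate"])["adj_count"].transform("sum")
    df["norm"] = df["adj_count"] / sample_total
    # (iii) divide by the replicate's day-0 value
    base = (
        df[df["time_day"] == t0]
        .set_index(["sequence", "replicate"])["norm"]
        .rename("base")
    )
    df = df.join(base, on=["sequence", "replicate"])
    df = df[df["base"].notna() & (df["base"] > 0)]
    df["y"] = df["norm"] / df["base"]
    return df[["sequence", "time_day", "replicate", "count", "y"]].reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# robust regression


def _huber_slope(t: np.ndarray, z: np.ndarray) -> tuple[float, bool]:
    """Huber M-estimate of the no-intercept slope of z on t via IRLS.

    Tuning constant 1.345, scale re-estimated each iteration from the MAD
    of residuals; converged when the slope moves by less than 1e-8 (a zero
    scale means a perfect fit and also counts as converged).
    """
    tt = float(t @ t)
    if tt == 0:
        return 0.0, True
    beta = float(t @ z) / tt
    for _ in range(MAX_ITER):
        resid = z - beta * t
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            return beta, True
        u = np.abs(resid) / scale
        w = np.where(u <= HUBER_C, 1.0, HUBER_C / np.maximum(u, 1e-300))
        denom = float((w * t) @ t)
        if denom == 0:
            return beta, False
        new_beta = float((w * t) @ z) / denom
        if abs(new_beta - beta) < TOL:
            return new_beta, True
        beta = new_beta
    return beta, False


def fit_growth(series: pd.DataFrame, sequence: str | None = None) -> GrowthFit:
    """Fit the growth estimate of one sequence from its normalized series.

    Pools all replicate points and regresses (y - 1) on t through the
    origin with a Huber M-estimator, matching the y(0) = 1 normalization
    (the intercept is fixed at 1). The slope is the growth estimate per day.
    """
    if sequence is not None:
        series = series[series["sequence"] == sequence]
    elif series["sequence"].nunique() == 1:
        sequence = series["sequence"].iloc[0]
    else:
        raise ValueError("series contains multiple sequences; pass `sequence`")
    if len(series) < 2:
        raise ValueError(f"fewer than 2 points to fit for {sequence!r}")
    t = series["time_day"].to_numpy(dtype=float)
    z = series["y"].to_numpy(dtype=float) - 1.0
    slope, converged = _huber_slope(t, z)
    return GrowthFit(
        sequence=sequence,
        slope=slope,
        converged=converged,
        n_replicates=int(series["replicate"].nunique()),
        total_raw_reads=int(series["count"].sum()),
    )


def filter_fits(fit: GrowthFit, min_reps: int = 2, min_reads: int = 10) -> bool:
    """Support filter: enough replicates, enough raw reads, converged fit."""
    return (
        fit.n_replicates >= min_reps
        and fit.total_raw_reads >= min_reads
        and fit.converged
    )


def round_estimate(beta: float) -> float:
    """Round to two decimal places, halves away from zero.

    Estimates carry at most two meaningful decimals; finer digits reflect
    regression noise.
    """
    if not math.isfinite(beta):
        raise ValueError("growth estimate must be finite")
    return math.copysign(math.floor(abs(beta) * 100 + 0.5) / 100, beta)


# ---------------------------------------------------------------------------
# thresholding and classification


def split_stop_groups(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a fits table by the ``starts_with_stop`` flag."""
    stop = fits[fits["starts_with_stop"]]
    non_stop = fits[~fits["starts_with_stop"]]
    return stop, non_stop


def threshold_select(
    stop_estimates,
    mode: str = "target_fpr",
    target_fpr: float | None = None,
) -> ThresholdReport:
    """Calibrate the functional threshold on stop-codon control estimates.

    ``design_max_stop``: the threshold is the highest stop-control estimate
    (a handful of designed truncation variants). ``target_fpr``: the
    smallest observed estimate value theta such that the fraction of stop
    estimates strictly above theta is at most ``target_fpr``.
    """
    est = np.asarray(list(stop_estimates), dtype=float)
    if est.size == 0:
        raise ValueError("empty stop-control set: cannot calibrate a threshold")
    if mode == "design_max_stop":
        theta = float(est.max())
    elif mode == "target_fpr":
        if target_fpr is None:
            raise ValueError("target_fpr mode requires a target")
        theta = None
        for cand in np.sort(np.unique(est)):
            if np.mean(est > cand) <= target_fpr:
                theta = float(cand)
                break
        if theta is None:  # pragma: no cover - max always satisfies
            theta = float(est.max())
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    fpr = float(np.mean(est > theta))
    return ThresholdReport(
        threshold=theta, mode=mode, stop_set_size=int(est.size), fpr_at_threshold=fpr
    )


def classify(estimates, theta: float) -> np.ndarray:
    """Functional iff the (rounded) estimate is strictly above the threshold.

    The strict inequality keeps a stop variant that itself defines the
    threshold in the non-functional class.
    """
    est = np.asarray(list(estimates), dtype=float)
    return est > theta


def rate_metrics(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """(TPR, FPR) = (TP/(TP+FN), FP/(FP+TN))."""
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or fp + tn == 0:
        raise UndefinedMetricError("zero denominator in TPR or FPR")
    return tp / (tp + fn), fp / (fp + tn)


def qc_stats(labels, peptides) -> dict:
    """Post-classification QC on the functional call set.

    ``short_seq_fp_fraction``: fraction of functional calls whose peptide
    has four or fewer residues (too short to plausibly be functional, hence
    an experimental false-positive estimate). ``imbalance_ratio``:
    functional/non-functional count ratio.
    """
    labels = np.asarray(list(labels), dtype=bool)
    peptides = list(peptides)
    n_func = int(labels.sum())
    n_nonfunc = int((~labels).sum())
    if n_func == 0:
        raise UndefinedMetricError("no functional sequences: QC stats undefined")
    short = sum(1 for lab, pep in zip(labels, peptides) if lab and len(pep) <= 4)
    return {
        "short_seq_fp_fraction": short / n_func,
        "imbalance_ratio": n_func / n_nonfunc if n_nonfunc else float("inf"),
        "n_functional": n_func,
        "n_nonfunctional": n_nonfunc,
    }


# ---------------------------------------------------------------------------
# table-level convenience


def growth_table(
    counts: pd.DataFrame,
    min_total: int = 3,
    min_reps: int = 2,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Fit growth estimates for every sequence in a count table.

    Applies the read-count prefilter, normalization, per-sequence robust
    fits and the support filter. Returns one row per retained sequence:
    ``sequence, slope, rounded_estimate, n_replicates, total_raw_reads,
    converged, peptide, starts_with_stop``.
    """
    filtered = prefilter_counts(counts, min_total=min_total)
    norm = normalize_counts(filtered)
    rows = []
    for seq, series in norm.groupby("sequence", sort=True):
        if len(series) < 2:
            continue
        fit = fit_growth(series, sequence=seq)
        if not filter_fits(fit, min_reps=min_reps, min_reads=min_reads):
            continue
        peptide, starts_with_stop = translate_insert(seq)
        rows.append(
            {
                "sequence": seq,
                "slope": fit.slope,
                "rounded_estimate": fit.rounded_estimate,
                "n_replicates": fit.n_replicates,
                "total_raw_reads": fit.total_raw_reads,
                "converged": fit.converged,
                "peptide": peptide,
                "starts_with_stop": starts_with_stop,
            }
        )
    return pd.DataFrame(rows)


def classify_table(
    fits: pd.DataFrame,
    mode: str = "target_fpr",
    target_fpr: float = 0.006,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, ThresholdReport]:
    """Threshold a fits table into functional/non-functional calls.

    When ``threshold`` is given it is used directly; otherwise it is
    calibrated on the stop-codon group per ``mode``. Classification uses
    rounded estimates (rounding precedes thresholding).
    """
    stop, _ = split_stop_groups(fits)
    if threshold is None:
        report = threshold_select(
            stop["rounded_estimate"], mode=mode, target_fpr=target_fpr
        )
    else:
        fpr = (
            float(np.mean(stop["rounded_estimate"] > threshold))
            if len(stop)
            else float("nan")
        )
        report = ThresholdReport(
            threshold=threshold,
            mode="fixed",
            stop_set_size=len(stop),
            fpr_at_threshold=fpr,
        )
    out = fits.copy()
    out["functional"] = classify(out["rounded_estimate"], report.threshold)
    report.n_functional = int(out["functional"].sum())
    return out, report
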