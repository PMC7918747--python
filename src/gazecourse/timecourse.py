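"""Binned looking time courses.

AOI-labelled samples are binned into 250 ms bins (30 raw samples at 120 Hz)
over the first 7500 ms of each trial, half-open ``[k*250, (k+1)*250)``. The
per-bin score is the proportion of in-AOI samples that fell in the lower face
half: ``n_lower / (n_lower + n_upper)``; samples outside both AOIs or lost to
track loss count as ``none``, and a bin with no in-AOI samples has a missing
proportion. E.g. 12 lower and 18 upper samples give 0.40.

Aggregation is strictly two-stage so that every infant contributes equally:
trial time courses average into a subject time course (available-case mean
over the subject's trials), and subject time courses average into the
subject-weighted group time course with a per-bin t-based 95% CI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .aoi import AOI_LOWER, AOI_NONE, AOI_UPPER
from .config import BinConfig
from .errors import DataError

TRIAL_KEYS = ["subject_id", "trial_number"]


def bin_trial(time_ms, aoi_codes, cfg: BinConfig | None = None) -> pd.DataFrame:
    """Bin one trial's labelled samples into lower-half proportions.

    Returns exactly ``cfg.n_bins`` rows covering ``[0, analysis_window_ms)``:
    bin_index, bin_onset_ms, bin_offset_ms, n_lower, n_upper, n_none,
    proportion_lower (NaN where the bin has no in-AOI samples). Samples at or
    beyond the analysis window are ignored.
    """
    cfg = cfg or BinConfig()
    cfg.validate()
    t = np.asarray(time_ms, dtype=float)
    codes = np.asarray(aoi_codes)
    if t.shape != codes.shape:
        raise DataError("time_ms and aoi_codes must have the same length")
    keep = (t >= 0) & (t < cfg.analysis_window_ms)
    t, codes = t[keep], codes[keep]
    bins = np.floor(t / cfg.bin_width_ms).astype(int)
    n_bins = cfg.n_bins
    n_lower = np.bincount(bins[codes == AOI_LOWER], minlength=n_bins)
    n_upper = np.bincount(bins[codes == AOI_UPPER], minlength=n_bins)
    n_none = np.bincount(bins[codes == AOI_NONE], minlength=n_bins)
    denom = n_lower + n_upper
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, n_lower / denom, np.nan)
    idx = np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_index": idx,
            "bin_onset_ms": idx * cfg.bin_width_ms,
            "bin_offset_ms": (idx + 1) * cfg.bin_width_ms,
            "n_lower": n_lower,
            "n_upper": n_upper,
            "n_none": n_none,
            "proportion_lower": prop,
        }
    )


def bin_trials(labeled_samples: pd.DataFrame, cfg: BinConfig | None = None) -> pd.DataFrame:
    """Per-trial binned time courses for every trial in a labelled sample
    table (tidy: trial keys + condition + the bin columns)."""
    cfg = cfg or BinConfig()
    code_of = {"none": AOI_NONE, "upper": AOI_UPPER, "lower": AOI_LOWER}
    frames = []
    for (subj, trial), grp in labeled_samples.groupby(TRIAL_KEYS, sort=True):
        codes = grp["aoi"].map(code_of).to_numpy()
        tc = bin_trial(grp["time_ms"].to_numpy(), codes, cfg)
        tc.insert(0, "speech_type", grp["speech_type"].iloc[0])
        tc.insert(0, "face_race", grp["face_race"].iloc[0])
        tc.insert(0, "trial_number", trial)
        tc.insert(0, "subject_id", subj)
        frames.append(tc)
    if not frames:
        raise DataError("no trials to bin")
    return pd.concat(frames, ignore_index=True)


def subject_timecourse(
    trial_bins: pd.DataFrame, by_condition: bool = False
) -> pd.DataFrame:
    """Average trial time courses into per-subject time courses.

    Per bin, the unweighted mean of the non-missing trial proportions; a bin
    is missing only if it is missing in every contributing trial. With
    ``by_condition=True``, separate time courses per stimulus condition.
    """
    keys = ["subject_id"] + (["face_race", "speech_type"] if by_condition else [])
    out = (
        trial_bins.groupby(keys + ["bin_index"], sort=True)
        .agg(
            proportion_lower=("proportion_lower", "mean"),
            n_trials=("proportion_lower", "count"),
            bin_onset_ms=("bin_onset_ms", "first"),
            bin_offset_ms=("bin_offset_ms", "first"),
        )
        .reset_index()
    )
    return out


def subject_matrix(subject_tc: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Pivot a (single-scope) subject time-course table into
    ``(subject_ids, matrix)`` with shape (n_subjects, n_bins) and NaN for
    missing bins — the input shape for the permutation test."""
    pivot = subject_tc.pivot_table(
        index="subject_id", columns="bin_index", values="proportion_lower", dropna=False
    ).sort_index()
    return list(pivot.index), pivot.to_numpy(dtype=float)


def group_timecourse(matrix: np.ndarray, confidence: float = 0.95) -> pd.DataFrame:
    """Subject-weighted group mean time course with per-bin n and t-based CI.

    ``matrix`` is subjects x bins with NaN for missing. Each subject with a
    non-missing value weighs equally. Bins with no contributing subjects are
    flagged untestable (NaN mean).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise DataError("group time course needs at least 2 subjects")
    n = np.sum(np.isfinite(m), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(np.where(np.isfinite(m), m, np.nan), axis=0), np.nan)
        sd = np.full(m.shape[1], np.nan)
        ok = n >= 2
        sd[ok] = np.nanstd(m[:, ok], axis=0, ddof=1)
    half = np.full(m.shape[1], np.nan)
    tcrit = np.full(m.shape[1], np.nan)
    tcrit[ok] = stats.t.ppf(0.5 + confidence / 2.0, n[ok] - 1)
    half[ok] = tcrit[ok] * sd[ok] / np.sqrt(n[ok])
    return pd.DataFrame(
        {
            "bin_index": np.arange(m.shape[1]),
            "mean_proportion_lower": mean,
            "n_subjects": n,
            "ci_low": mean - half,
            "ci_high": mean + half,
        }
    )
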