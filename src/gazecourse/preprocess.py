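"""Fixation detection, AOI labelling, and trial exclusion.

Fixations are identified with a dispersion-threshold (I-DT) filter: a maximal
window of consecutive valid samples whose dispersion — here the classic sum
``(max x - min x) + (max y - min y)`` — stays at or below 100 px and that
spans at least 80 ms. Each sample is taken to cover one sample period, so a
fixation's duration is ``(last sample time + period) - first sample time``;
with 120 Hz data the 80 ms minimum therefore requires 10 samples.

Track-lost samples break candidate windows by default (``max_gap_samples=0``);
a small bridging tolerance is configurable but the bridged samples never
contribute to the centroid or dispersion.

Trials enter analysis only if total fixation time reaches 1000 ms
("recorded looking" is counted as summed fixation duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS, AOI_LOWER, AOI_NONE, AOI_UPPER, DynamicAOIPair
from .config import DetectorConfig
from .errors import DataError


@dataclass
class Fixation:
    """One detected stable-gaze event within a trial."""

    start_ms: float
    end_ms: float
    centroid_x: float
    centroid_y: float
    index: int  # 1-based order within the trial
    aoi: str = "none"
    n_samples: int = 0
    #: positions (into the trial's sample arrays) of the member samples
    sample_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int), repr=False)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def dispersion(x, y) -> float:
    """I-DT dispersion of a sample window: (max x - min x) + (max y - min y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise DataError("dispersion requires at least one sample")
    return float((x.max() - x.min()) + (y.max() - y.min()))


def _sample_period(t: np.ndarray) -> float:
    if len(t) < 2:
        return 1000.0 / 120.0
    return float(np.median(np.diff(t)))


def _valid_runs(valid: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Indices of valid samples grouped into runs; a stretch of more than
    ``max_gap`` consecutive invalid samples ends a run."""
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    return np.split(idx, breaks + 1)


def detect_fixations(t, x, y, valid=None, cfg: DetectorConfig | None = None) -> list[Fixation]:
    """Run the I-DT filter over one trial's time-ordered samples.

    Emits maximal windows satisfying both thresholds, greedily left to right:
    from the current start, the window is expanded rightward for as long as
    dispersion stays within threshold (dispersion can only grow, so the
    maximal end is well defined); it is emitted if it spans the minimum
    duration, and scanning resumes after it. Fixations never overlap, are
    ordered, and carry the mean-of-member-samples centroid and a 1-based
    within-trial index.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise DataError("sample timestamps must be strictly increasing within a trial")
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    else:
        valid = np.asarray(valid).astype(bool) & np.isfinite(x) & np.isfinite(y)

    period = _sample_period(t)
    out: list[Fixation] = []
    for run in _valid_runs(valid, cfg.max_gap_samples):
        rx, ry, rt = x[run], y[run], t[run]
        n = len(run)
        i = 0
        while i < n:
            xmin = xmax = rx[i]
            ymin = ymax = ry[i]
            j = i
            while j + 1 < n:
                nxmin = min(xmin, rx[j + 1])
                nxmax = max(xmax, rx[j + 1])
                nymin = min(ymin, ry[j + 1])
                nymax = max(ymax, ry[j + 1])
                if (nxmax - nxmin) + (nymax - nymin) <= cfg.max_dispersion_px:
                    xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                    j += 1
                else:
                    break
            span = (rt[j] + period) - rt[i]
            if span >= cfg.min_duration_ms - 1e-9:
                members = run[i : j + 1]
                out.append(
                    Fixation(
                        start_ms=float(rt[i]),
                        end_ms=float(rt[j] + period),
                        centroid_x=float(rx[i : j + 1].mean()),
                        centroid_y=float(ry[i : j + 1].mean()),
                        index=len(out) + 1,
                        n_samples=len(members),
                        sample_indices=members,
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


# ---------------------------------------------------------------------------
# AOI assignment
# ---------------------------------------------------------------------------

def assign_sample_aoi(t_ms: float, x: float, y: float, aois: DynamicAOIPair) -> str:
    """AOI label of a single gaze sample against the rectangles at its time."""
    return AOI_LABELS[int(aois.label(t_ms, x, y)[0])]


def assign_fixation_aoi(fix: Fixation, sample_codes: np.ndarray) -> str:
    """Majority AOI label over a fixation's member samples.

    ``sample_codes`` are per-sample AOI codes for the whole trial. A plurality
    of out-of-AOI samples gives ``none``; an upper/lower tie is resolved by
    the temporally first member sample that is in an AOI.
    """
    codes = np.asarray(sample_codes)[fix.sample_indices]
    n_u = int((codes == AOI_UPPER).sum())
    n_l = int((codes == AOI_LOWER).sum())
    n_n = int((codes == AOI_NONE).sum())
    if n_u == 0 and n_l == 0:
        return "none"
    if n_n > max(n_u, n_l):
        return "none"
    if n_u != n_l:
        return "upper" if n_u > n_l else "lower"
    first = codes[codes != AOI_NONE][0]
    return AOI_LABELS[int(first)]


def label_samples(samples: pd.DataFrame, trajectories: dict[str, DynamicAOIPair]) -> pd.DataFrame:
    """Return a copy of the raw sample table with an ``aoi`` column.

    Labels are point-in-rectangle tests against the stimulus's AOI positions
    at each sample's timestamp; invalid samples are labelled ``none``.
    """
    out = samples.copy()
    codes = np.zeros(len(out), dtype=int)
    for stim, grp in out.groupby("stimulus_id", sort=False):
        if stim not in trajectories:
            raise DataError(f"no AOI trajectory for stimulus {stim!r}")
        traj = trajectories[stim]
        codes[grp.index.to_numpy()] = traj.label(
            grp["time_ms"].to_numpy(),
            grp["x_px"].to_numpy(),
            grp["y_px"].to_numpy(),
            grp["valid"].to_numpy(),
        )
    out["aoi"] = np.array(AOI_LABELS, dtype=object)[codes]
    out["aoi_code"] = codes
    return out


# ---------------------------------------------------------------------------
# Table-level processing
# ---------------------------------------------------------------------------

TRIAL_KEYS = ["subject_id", "trial_number"]
FIXATION_COLUMNS = [
    "subject_id",
    "trial_number",
    "stimulus_id",
    "face_race",
    "speech_type",
    "fixation_index",
    "start_ms",
    "end_ms",
    "duration_ms",
    "centroid_x",
    "centroid_y",
    "aoi",
]


def process_samples(
    samples: pd.DataFrame,
    trajectories: dict[str, DynamicAOIPair],
    cfg: DetectorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect and AOI-label fixations for every trial in a raw sample table.

    Returns ``(fixations, labeled_samples)``: the fixation table (one row per
    fixation, schema :data:`FIXATION_COLUMNS`) and the sample table with its
    ``aoi`` column. Each trial is processed independently.
    """
    cfg = cfg or DetectorConfig()
    labeled = label_samples(samples, trajectories)
    rows = []
    for (subj, trial), grp in labeled.groupby(TRIAL_KEYS, sort=True):
        grp = grp.reset_index(drop=True)
        fixes = detect_fixations(
            grp["time_ms"].to_numpy(),
            grp["x_px"].to_numpy(),
            grp["y_px"].to_numpy(),
            grp["valid"].to_numpy(),
            cfg,
        )
        codes = grp["aoi_code"].to_numpy()
        meta = grp.iloc[0]
        for fx in fixes:
            fx.aoi = assign_fixation_aoi(fx, codes)
            rows.append(
                dict(
                    subject_id=subj,
                    trial_number=trial,
                    stimulus_id=meta["stimulus_id"],
                    face_race=meta["face_race"],
                    speech_type=meta["speech_type"],
                    fixation_index=fx.index,
                    start_ms=fx.start_ms,
                    end_ms=fx.end_ms,
                    duration_ms=fx.duration_ms,
                    centroid_x=fx.centroid_x,
                    centroid_y=fx.centroid_y,
                    aoi=fx.aoi,
                )
            )
    fixations = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    return fixations, labeled.drop(columns=["aoi_code"])


def apply_trial_exclusion(trial_fixations, cfg: DetectorConfig | None = None) -> bool:
    """Keep a trial iff its summed fixation duration reaches the minimum
    recorded-looking threshold (inclusive)."""
    cfg = cfg or DetectorConfig()
    if isinstance(trial_fixations, pd.DataFrame):
        total = float(trial_fixations["duration_ms"].sum())
    else:
        total = float(sum(f.duration_ms for f in trial_fixations))
    return total >= cfg.min_trial_looking_ms


def apply_exclusions(
    fixations: pd.DataFrame, cfg: DetectorConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the minimum-looking rule trial by trial.

    Returns ``(kept_fixations, audit)`` where ``audit`` has one row per trial:
    subject_id, trial_number, total_looking_ms, kept. Excluding one trial
    never touches another trial's rows.
    """
    cfg = cfg or DetectorConfig()
    if len(fixations) == 0:
        return fixations.copy(), pd.DataFrame(
            columns=TRIAL_KEYS + ["total_looking_ms", "kept"]
        )
    totals = (
        fixations.groupby(TRIAL_KEYS, sort=True)["duration_ms"]
        .sum()
        .rename("total_looking_ms")
        .reset_index()
    )
    totals["kept"] = totals["total_looking_ms"] >= cfg.min_trial_looking_ms
    kept_keys = totals.loc[totals["kept"], TRIAL_KEYS]
    kept = fixations.merge(kept_keys, on=TRIAL_KEYS, how="inner")
    return kept, totals
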