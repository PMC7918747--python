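"""Synthetic infant eye-tracking sessions with known ground truth.

Emulates the acquisition design of the study: 120 Hz gaze sampling over
7500 ms trials, up to 8 trials per infant in blocks of four (one trial per
stimulus condition: {Asian American, White} face x {infant-, adult-directed}
speech), a face that translates smoothly on screen with its two half-face
AOIs, alternating fixations and short saccades, per-sample track loss, and a
configurable, time-varying probability that each fixation targets the lower
face half. Every generated artefact (planted fixation intervals and targets,
AOI trajectories, subject covariates) is returned as ground truth so the
downstream detector, aggregator and permutation test can be validated without
any real recording.

Randomness is keyed per (subject, trial) from the master seed, so adding or
removing subjects never perturbs the data of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .aoi import DynamicAOIPair
from .config import CONDITIONS, BiasProfile, BiasWindow, SimConfig
from .errors import ConfigError

#: The eight stimulus movies: four models (two per face race), each recorded
#: in both speech registers.
MODELS = {
    "asian_american": ("aa1", "aa2"),
    "white": ("wh1", "wh2"),
}


#: Perpendicular offset of the saccade via-point (see _simulate_trial).
_SACCADE_ARC_PX = 150.0


def stimulus_id(model: str, speech_type: str) -> str:
    return f"{model}_{speech_type}"


def all_stimulus_ids() -> list[str]:
    return [
        stimulus_id(m, s)
        for race in ("asian_american", "white")
        for m in MODELS[race]
        for s in ("infant_directed", "adult_directed")
    ]


@dataclass
class GroundTruth:
    """What the generator actually planted, for validating the pipeline.

    planted_fixations: one row per planted fixation (subject_id, trial_number,
        stimulus_id, face_race, speech_type, start_ms, end_ms, target_aoi,
        centroid_x, centroid_y, sub_threshold). ``sub_threshold`` marks
        fixations truncated by the trial end below the 80 ms detector minimum.
    aoi_trajectories: stimulus_id -> DynamicAOIPair (shared across subjects,
        one per movie).
    subjects: per-subject covariates: raw parental reports plus the true
        classification labels the reports were generated from.
    """

    planted_fixations: pd.DataFrame
    aoi_trajectories: Dict[str, DynamicAOIPair]
    subjects: pd.DataFrame


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng((int(seed), *[int(k) for k in key]))


# ---------------------------------------------------------------------------
# AOI trajectories
# ---------------------------------------------------------------------------

def make_aoi_trajectory(config: SimConfig, stimulus_index: int) -> DynamicAOIPair:
    """Trajectory of the two stacked half-face rectangles for one movie.

    The face centre translates smoothly (low-frequency sinusoids in x and y
    with per-stimulus random phase); the two equal-sized rectangles ride on
    it, the upper one's bottom edge abutting the lower one's top edge at the
    face midline. Amplitude 0 gives static rectangles.
    """
    config.validate()
    rng = _rng(config.seed, 3000 + stimulus_index)
    n = config.samples_per_trial
    t = np.arange(n) * 1000.0 / config.sample_rate

    w = config.aoi_width_px
    h = config.aoi_height_px
    cx0 = config.screen_width_px / 2.0
    cy0 = config.screen_height_px / 2.0 - h / 10.0  # face slightly above centre
    amp = config.face_motion_amplitude_px
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    # Slow planar drift; periods chosen so the face wanders rather than ticks.
    cx = cx0 + amp * np.sin(2 * np.pi * t / 2400.0 + phx)
    cy = cy0 + 0.5 * amp * np.sin(2 * np.pi * t / 3100.0 + phy)

    upper = np.column_stack([cx - w / 2, cy - h, cx + w / 2, cy])
    lower = np.column_stack([cx - w / 2, cy, cx + w / 2, cy + h])
    return DynamicAOIPair(t, upper, lower, valid_until_ms=config.trial_duration_ms)


# ---------------------------------------------------------------------------
# Bias profile manipulation
# ---------------------------------------------------------------------------

def inject_bias(
    config: SimConfig,
    window: Tuple[float, float],
    magnitude: float,
    condition: Optional[Tuple[str, str]] = None,
) -> SimConfig:
    """Return a config whose lower-AOI probability is shifted by ``magnitude``
    inside ``window`` (ms) and equals the baseline profile outside it."""
    onset, offset = window
    if not (0.0 <= onset < offset <= config.trial_duration_ms):
        raise ConfigError(
            f"bias window ({onset}, {offset}) outside trial [0, {config.trial_duration_ms}]"
        )
    if magnitude == 0.0:
        return config
    profile = config.bias_profile
    p_inside = profile.baseline + magnitude
    if not (0.0 <= p_inside <= 1.0):
        raise ConfigError(f"injected probability {p_inside} outside [0, 1]")
    new = BiasProfile(
        baseline=profile.baseline,
        windows=profile.windows + (BiasWindow(onset, offset, p_inside, condition),),
    )
    new.validate()
    return replace(config, bias_profile=new)


# ---------------------------------------------------------------------------
# Subject covariates
# ---------------------------------------------------------------------------

# Cohort composition frequencies (counts out of 98 infants).
_MOTHER_P = {"white": 48, "asian_american": 22, "other": 28}
_DIVERSITY_P = {"low": 31, "medium": 39, "high": 19, "not_reported": 9}
_LANGUAGE_P = {
    "monolingual_english": 66,
    "multilingual": 23,
    "other_monolingual": 6,
    "unreported": 3,
}
AGE_DAYS_RANGE = (217, 320)


def _choice(rng: np.random.Generator, table: dict) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _make_subject_profile(rng: np.random.Generator, subject_id: str) -> dict:
    """Draw true group labels from the cohort composition, then synthesise a
    raw parental report consistent with each label (so classification code can
    be validated against the generator)."""
    mother_group = _choice(rng, _MOTHER_P)
    diversity = _choice(rng, _DIVERSITY_P)
    language = _choice(rng, _LANGUAGE_P)

    # Raw maternal race report consistent with the classified group.
    hispanic = False
    if mother_group == "white":
        races = ["white"]
        hispanic = bool(rng.random() < 8 / 48)
    elif mother_group == "asian_american":
        races = ["asian_american", "white"] if rng.random() < 0.3 else ["asian_american"]
    else:  # other: another race, or Hispanic with race unreported
        u = rng.random()
        if u < 0.4:
            races = ["black"]
        elif u < 0.6:
            races = ["black", "white"]
        else:
            races, hispanic = [], True
    exposure_from_mother = (
        "white" if races == ["white"]
        else "asian_american" if "asian_american" in races
        else "black" if "black" in races
        else "other"
    )

    # Caregiver and questionnaire exposures consistent with diversity label.
    questionnaire_present = diversity != "not_reported"
    caregiver = ""
    exposures: set[str] = set()
    if questionnaire_present:
        pool = [g for g in ("white", "asian_american", "black") if g != exposure_from_mother]
        if diversity == "low":
            if rng.random() < 0.5:
                caregiver = exposure_from_mother
            if exposure_from_mother in ("white", "asian_american", "black"):
                exposures = {exposure_from_mother} if rng.random() < 0.7 else set()
        elif diversity == "medium":
            extra = pool[rng.integers(len(pool))]
            if rng.random() < 0.4:
                caregiver = extra
            else:
                exposures = {extra}
        else:  # high: two groups beyond the mother's
            extras = list(rng.choice(pool, size=2, replace=False))
            exposures = set(extras[1:])
            if rng.random() < 0.4:
                caregiver = extras[0]
            else:
                exposures.add(extras[0])

    # Language exposure report consistent with the language label.
    if language == "monolingual_english":
        report = {"english": float(np.round(rng.uniform(0.80, 1.00), 2))}
    elif language == "multilingual":
        u = float(np.round(rng.uniform(0.30, 0.70), 2))
        report = {"english": u, "spanish": float(np.round(1 - u, 2))}
    elif language == "other_monolingual":
        report = {"mandarin": float(np.round(rng.uniform(0.80, 1.00), 2))}
    else:
        report = {}

    return {
        "subject_id": subject_id,
        "age_days": int(rng.integers(AGE_DAYS_RANGE[0], AGE_DAYS_RANGE[1] + 1)),
        "mother_races": "|".join(races),
        "mother_hispanic": int(hispanic),
        "caregiver_group": caregiver,
        "questionnaire_present": int(questionnaire_present),
        "exposure_white": int("white" in exposures),
        "exposure_asian_american": int("asian_american" in exposures),
        "exposure_black": int("black" in exposures),
        "language_report": ";".join(f"{k}:{v}" for k, v in sorted(report.items())),
        # ground-truth labels
        "true_mother_race": mother_group,
        "true_diversity": diversity,
        "true_language": language,
    }


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def _trial_schedule(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Order of (face_race, speech_type, stimulus_id) for one subject.

    Trials run in blocks of four with one trial of each condition per block
    (order shuffled within block); across the two blocks each condition uses
    its two different models.
    """
    model_order = {}
    for race, models in MODELS.items():
        order = list(models)
        rng.shuffle(order)
        model_order[race] = order
    schedule = []
    n_blocks = int(np.ceil(config.trials_per_subject / 4))
    for block in range(n_blocks):
        conds = list(CONDITIONS)
        rng.shuffle(conds)
        for race, speech in conds:
            model = model_order[race][block % 2]
            schedule.append((race, speech, stimulus_id(model, speech)))
    return schedule[: config.trials_per_subject]


def _simulate_trial(
    config: SimConfig,
    rng: np.random.Generator,
    traj: DynamicAOIPair,
    condition: Tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[dict]]:
    """Generate one trial's samples. Returns (t, x, y, valid, fixation rows)."""
    n = config.samples_per_trial
    t = np.arange(n) * 1000.0 / config.sample_rate
    x = np.empty(n)
    y = np.empty(n)

    jit = config.fixation_jitter_sd_px
    margin = 4.0 * jit + 5.0
    fixations: list[dict] = []
    clock = 0.0
    while clock < config.trial_duration_ms - 1e-9:
        dur = rng.normal(config.fixation_duration_mean_ms, config.fixation_duration_sd_ms)
        dur = max(dur, config.fixation_duration_min_ms)
        end = min(clock + dur, config.trial_duration_ms)
        p_lower = config.bias_profile.lookup(clock, condition)
        target = "lower" if rng.random() < p_lower else "upper"
        up, lo = traj.rects_at(min(clock, config.trial_duration_ms - 1e-6))
        rect = lo if target == "lower" else up
        # Draw the centroid inside the target rectangle, rejection-sampling
        # for a real saccade-sized jump from the previous centroid.
        prev = fixations[-1] if fixations else None
        best = None
        best_d = -1.0
        for _ in range(20):
            cx = rng.uniform(rect[0] + margin, rect[2] - margin)
            cy = rng.uniform(rect[1] + margin, rect[3] - margin)
            d = (
                np.hypot(cx - prev["centroid_x"], cy - prev["centroid_y"])
                if prev is not None
                else np.inf
            )
            if d > best_d:
                best, best_d = (cx, cy), d
            if d >= config.min_saccade_px:
                break
        cx, cy = best
        fixations.append(
            dict(
                start_ms=clock,
                end_ms=end,
                target_aoi=target,
                centroid_x=cx,
                centroid_y=cy,
                sub_threshold=bool(end - clock < 80.0),
            )
        )
        clock = end + config.saccade_gap_ms

    # Fill sample coordinates: jitter around the centroid during fixations,
    # linear interpolation between centroids during saccade gaps, hold after
    # the last fixation.
    for k, fx in enumerate(fixations):
        in_fix = (t >= fx["start_ms"]) & (t < fx["end_ms"])
        m = int(in_fix.sum())
        # Truncated at 2 SD: bounds any fixation's I-DT dispersion at 8 SD
        # (80 px at the default), keeping planted fixations detectable.
        x[in_fix] = fx["centroid_x"] + np.clip(rng.normal(0.0, jit, size=m), -2 * jit, 2 * jit)
        y[in_fix] = fx["centroid_y"] + np.clip(rng.normal(0.0, jit, size=m), -2 * jit, 2 * jit)
        gap_end = fixations[k + 1]["start_ms"] if k + 1 < len(fixations) else config.trial_duration_ms
        in_gap = (t >= fx["end_ms"]) & (t < gap_end)
        if in_gap.any():
            if k + 1 < len(fixations):
                # Ballistic arc: the eye dwells briefly at the old centroid,
                # flies through a via-point offset perpendicular to the path,
                # and lands at the new centroid. The 150 px offset keeps every
                # in-flight sample more than the dispersion cap away from both
                # fixation clouds, so saccades neither merge adjacent windows
                # nor split them.
                nxt = fixations[k + 1]
                ax, ay = fx["centroid_x"], fx["centroid_y"]
                bx, by = nxt["centroid_x"], nxt["centroid_y"]
                dx, dy = bx - ax, by - ay
                norm = float(np.hypot(dx, dy)) or 1.0
                px_, py_ = -dy / norm, dx / norm
                mx, my = (ax + bx) / 2.0, (ay + by) / 2.0
                # perpendicular sign: bend the arc toward the screen centre
                sx0, sy0 = config.screen_width_px / 2.0, config.screen_height_px / 2.0
                sign = 1.0 if (mx + px_ * _SACCADE_ARC_PX - sx0) ** 2 + (
                    my + py_ * _SACCADE_ARC_PX - sy0
                ) ** 2 <= (mx - px_ * _SACCADE_ARC_PX - sx0) ** 2 + (
                    my - py_ * _SACCADE_ARC_PX - sy0
                ) ** 2 else -1.0
                vx = float(np.clip(mx + sign * px_ * _SACCADE_ARC_PX, 5, config.screen_width_px - 5))
                vy = float(np.clip(my + sign * py_ * _SACCADE_ARC_PX, 5, config.screen_height_px - 5))
                frac = (t[in_gap] - fx["end_ms"]) / max(gap_end - fx["end_ms"], 1e-9)
                gx = np.where(frac < 0.2, ax, np.where(frac < 0.65, vx, bx))
                gy = np.where(frac < 0.2, ay, np.where(frac < 0.65, vy, by))
                x[in_gap] = gx
                y[in_gap] = gy
            else:
                x[in_gap] = fx["centroid_x"]
                y[in_gap] = fx["centroid_y"]

    rate = config.trackloss_rate
    if rate > 0 and rng.random() < config.high_loss_trial_fraction:
        rate = config.high_loss_rate  # fussy trial: mostly off-screen
    burst_samples = max(config.trackloss_burst_ms / config.sample_period_ms, 1.0)
    lost = _trackloss_mask(rng, n, rate, burst_samples)
    x[lost] = np.nan
    y[lost] = np.nan
    return t, x, y, ~lost, fixations


def _trackloss_mask(
    rng: np.random.Generator, n: int, rate: float, burst_samples: float
) -> np.ndarray:
    """Bursty track loss: a two-state Markov chain with mean lost-run length
    ``burst_samples`` and stationary P(lost) = ``rate``."""
    if rate <= 0.0:
        return np.zeros(n, dtype=bool)
    if rate >= 1.0:
        return np.ones(n, dtype=bool)
    b = 1.0 / burst_samples  # P(lost -> valid)
    a = min(rate * b / (1.0 - rate), 1.0)  # P(valid -> lost)
    u = rng.random(n)
    lost = np.empty(n, dtype=bool)
    state = u[0] < rate  # stationary start
    lost[0] = state
    for k in range(1, n):
        state = (u[k] >= b) if state else (u[k] < a)
        lost[k] = state
    return lost


def simulate_session(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the full synthetic cohort.

    Returns the raw gaze-sample table (one row per 120 Hz sample per trial:
    subject_id, trial_number, stimulus_id, face_race, speech_type, time_ms,
    x_px, y_px, valid) and the :class:`GroundTruth` it was built from.
    Identical config and seed give bit-identical output.
    """
    config.validate()

    trajectories = {
        sid: make_aoi_trajectory(config, i) for i, sid in enumerate(all_stimulus_ids())
    }

    sample_frames = []
    fixation_rows = []
    profiles = []
    for s in range(config.n_subjects):
        sid = f"s{s + 1:03d}"
        profiles.append(_make_subject_profile(_rng(config.seed, 2000 + s), sid))
        schedule = _trial_schedule(config, _rng(config.seed, 4000 + s))
        for trial_idx, (race, speech, stim) in enumerate(schedule):
            rng = _rng(config.seed, 1000 + s, trial_idx)
            t, x, y, valid, fixes = _simulate_trial(
                config, rng, trajectories[stim], (race, speech)
            )
            sample_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "trial_number": trial_idx + 1,
                        "stimulus_id": stim,
                        "face_race": race,
                        "speech_type": speech,
                        "time_ms": t,
                        "x_px": x,
                        "y_px": y,
                        "valid": valid.astype(int),
                    }
                )
            )
            for fx in fixes:
                fixation_rows.append(
                    dict(
                        subject_id=sid,
                        trial_number=trial_idx + 1,
                        stimulus_id=stim,
                        face_race=race,
                        speech_type=speech,
                        **fx,
                    )
                )

    samples = pd.concat(sample_frames, ignore_index=True)
    truth = GroundTruth(
        planted_fixations=pd.DataFrame(fixation_rows),
        aoi_trajectories=trajectories,
        subjects=pd.DataFrame(profiles),
    )
    return samples, truth


def trajectories_frame(truth: GroundTruth) -> pd.DataFrame:
    """All AOI trajectories as one long CSV-ready table."""
    return pd.concat(
        [traj.to_frame(sid) for sid, traj in truth.aoi_trajectories.items()],
        ignore_index=True,
    )
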