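"""Configuration objects shared across the pipeline stages.

All durations are in milliseconds, all screen coordinates in pixels
(origin top-left, y increasing downward), all rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .errors import ConfigError

#: Screen geometry of the presentation monitor (22-in, 16:10 LCD).
SCREEN_WIDTH_PX = 1680
SCREEN_HEIGHT_PX = 1050

#: Pixels per centimetre on that monitor. The AOI sizes are specified in cm,
#: so a single conversion constant must be pinned. 35.5 px/cm follows from a
#: 22-in 16:10 panel (visible width ~47.4 cm at 1680 px). This is a stand-in:
#: the true presentation geometry of the original apparatus is not published.
PX_PER_CM = 35.5

FACE_RACES = ("asian_american", "white")
SPEECH_TYPES = ("infant_directed", "adult_directed")

#: The four stimulus conditions (face race x speech type).
CONDITIONS = tuple((r, s) for r in FACE_RACES for s in SPEECH_TYPES)


def condition_label(face_race: str, speech_type: str) -> str:
    return f"{face_race}/{speech_type}"


@dataclass(frozen=True)
class BiasWindow:
    """A time window in which fixations target the lower AOI with probability p.

    ``condition`` is a ``(face_race, speech_type)`` pair or ``None`` for all
    conditions. Later windows take precedence over earlier ones.
    """

    onset_ms: float
    offset_ms: float
    p_lower: float
    condition: Optional[Tuple[str, str]] = None


@dataclass(frozen=True)
class BiasProfile:
    """Time- and condition-resolved probability that a fixation targets the
    lower face half. ``baseline`` applies wherever no window matches."""

    baseline: float = 0.60
    windows: Tuple[BiasWindow, ...] = ()

    def lookup(self, t_ms: float, condition: Optional[Tuple[str, str]] = None) -> float:
        p = self.baseline
        for w in self.windows:
            if w.condition is not None and w.condition != condition:
                continue
            if w.onset_ms <= t_ms < w.offset_ms:
                p = w.p_lower
        return p

    def validate(self) -> None:
        probs = [self.baseline] + [w.p_lower for w in self.windows]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"bias probability {p} outside [0, 1]")
        for w in self.windows:
            if w.offset_ms <= w.onset_ms:
                raise ConfigError(
                    f"bias window ({w.onset_ms}, {w.offset_ms}) has non-positive length"
                )


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic eye-tracking session.

    Defaults reproduce the study conditions: 120 Hz sampling, 7500 ms trials,
    up to 8 trials per infant over the 4 stimulus types (2 face races x
    2 speech registers), with fixation/saccade dynamics and track loss.
    """

    n_subjects: int = 98
    trials_per_subject: int = 8
    sample_rate: float = 120.0
    trial_duration_ms: float = 7500.0
    fixation_duration_mean_ms: float = 620.0
    fixation_duration_sd_ms: float = 300.0
    fixation_duration_min_ms: float = 100.0
    saccade_gap_ms: float = 40.0
    #: Minimum distance between consecutive fixation centroids. Keeps planted
    #: saccades genuine repositioning movements (well above the detector's
    #: 100 px dispersion cap) rather than sub-threshold drifts.
    min_saccade_px: float = 200.0
    trackloss_rate: float = 0.15
    #: Mean duration of a track-loss burst. Loss follows a two-state Markov
    #: chain whose stationary invalid probability equals trackloss_rate;
    #: real loss (blinks, head turns) is bursty, not independent per sample.
    trackloss_burst_ms: float = 200.0
    #: Fraction of trials with heavy loss (fussiness / gross movement); these
    #: are the trials that fail the minimum-looking inclusion rule. No effect
    #: when trackloss_rate is 0.
    high_loss_trial_fraction: float = 0.05
    high_loss_rate: float = 0.85
    bias_profile: BiasProfile = field(default_factory=BiasProfile)
    face_motion_amplitude_px: float = 30.0
    fixation_jitter_sd_px: float = 10.0
    aoi_width_cm: float = 16.0
    aoi_height_cm: float = 8.5
    px_per_cm: float = PX_PER_CM
    screen_width_px: int = SCREEN_WIDTH_PX
    screen_height_px: int = SCREEN_HEIGHT_PX
    seed: int = 0

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def samples_per_trial(self) -> int:
        n = self.trial_duration_ms / 1000.0 * self.sample_rate
        return int(round(n))

    @property
    def aoi_width_px(self) -> float:
        return round(self.aoi_width_cm * self.px_per_cm)

    @property
    def aoi_height_px(self) -> float:
        return round(self.aoi_height_cm * self.px_per_cm)

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.trials_per_subject <= 0:
            raise ConfigError("n_subjects and trials_per_subject must be positive")
        if self.trials_per_subject > 8:
            raise ConfigError("design allows at most 8 trials per subject")
        if self.sample_rate <= 0 or self.trial_duration_ms <= 0:
            raise ConfigError("sample_rate and trial_duration_ms must be positive")
        if not (0.0 <= self.trackloss_rate <= 1.0):
            raise ConfigError(f"trackloss_rate {self.trackloss_rate} outside [0, 1]")
        if not (0.0 <= self.high_loss_rate <= 1.0):
            raise ConfigError(f"high_loss_rate {self.high_loss_rate} outside [0, 1]")
        if not (0.0 <= self.high_loss_trial_fraction <= 1.0):
            raise ConfigError("high_loss_trial_fraction outside [0, 1]")
        if self.trackloss_burst_ms <= 0:
            raise ConfigError("trackloss_burst_ms must be positive")
        if self.fixation_duration_mean_ms <= 0 or self.fixation_duration_min_ms <= 0:
            raise ConfigError("fixation durations must be positive")
        if self.saccade_gap_ms < 0 or self.face_motion_amplitude_px < 0:
            raise ConfigError("saccade_gap_ms and face_motion_amplitude_px must be >= 0")
        self.bias_profile.validate()

    def with_bias(self, profile: BiasProfile) -> "SimConfig":
        return replace(self, bias_profile=profile)


@dataclass(frozen=True)
class DetectorConfig:
    """Dispersion-threshold (I-DT) fixation filter parameters.

    A fixation is a maximal gaze window at least ``min_duration_ms`` long whose
    dispersion, (max x - min x) + (max y - min y), stays at or below
    ``max_dispersion_px``. Trials with less than ``min_trial_looking_ms`` of
    total fixation time are excluded.
    """

    min_duration_ms: float = 80.0
    max_dispersion_px: float = 100.0
    min_trial_looking_ms: float = 1000.0
    #: Maximum number of consecutive invalid samples to bridge inside a
    #: candidate window. 0 = any track loss breaks the window.
    max_gap_samples: int = 0

    def validate(self) -> None:
        if self.min_duration_ms <= 0 or self.max_dispersion_px <= 0:
            raise ConfigError("detector thresholds must be strictly positive")
        if self.min_trial_looking_ms <= 0:
            raise ConfigError("min_trial_looking_ms must be strictly positive")
        if self.max_gap_samples < 0:
            raise ConfigError("max_gap_samples must be >= 0")


@dataclass(frozen=True)
class BinConfig:
    """Time-binning of AOI-labelled samples into lower-half proportions."""

    bin_width_ms: float = 250.0
    analysis_window_ms: float = 7500.0
    sample_rate: float = 120.0
    chance: float = 0.50

    @property
    def n_bins(self) -> int:
        n = self.analysis_window_ms / self.bin_width_ms
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"analysis_window_ms {self.analysis_window_ms} is not a whole "
                f"number of {self.bin_width_ms} ms bins"
            )
        return int(round(n))

    @property
    def samples_per_bin(self) -> int:
        return int(round(self.bin_width_ms * self.sample_rate / 1000.0))

    def validate(self) -> None:
        if self.bin_width_ms <= 0 or self.analysis_window_ms <= 0:
            raise ConfigError("bin widths must be positive")
        if not (0.0 < self.chance < 1.0):
            raise ConfigError("chance must be in (0, 1)")
        self.n_bins  # raises if not integral


@dataclass(frozen=True)
class PermConfig:
    """Cluster-mass permutation test parameters.

    Per-bin one-sample t tests against ``chance`` are uncorrected two-sided
    tests at ``alpha_bin``; family-wise control comes from the max-cluster-mass
    null built from ``n_permutations`` per-subject sign flips.
    """

    n_permutations: int = 1000
    alpha_bin: float = 0.05
    alpha_cluster: float = 0.05
    chance: float = 0.50
    min_subjects_per_bin: int = 2
    #: If True, use the (+1)-corrected p-value (b+1)/(m+1); default is the
    #: pure proportion, which can print as 0.000.
    add_one_correction: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        for a in (self.alpha_bin, self.alpha_cluster):
            if not (0.0 < a < 1.0):
                raise ConfigError(f"alpha {a} outside (0, 1)")
        if self.min_subjects_per_bin < 2:
            raise ConfigError("min_subjects_per_bin must be >= 2")
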