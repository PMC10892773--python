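"""Synthetic wrist-IMU cohort generator.

Produces multi-activity six-channel recordings (tri-axial accelerometer +
tri-axial gyroscope, 200 Hz) with severity-graded, intermittently gated
tremor, bradykinesia-like amplitude reduction, and configurable class
imbalance.  Stands in for a clinical dataset in every test: recordings are
deterministic functions of (profile, seed) and round-trip through plain CSV
files plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNEL_NAMES: Tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")
CSV_COLUMNS: Tuple[str, ...] = ("t",) + CHANNEL_NAMES
ACCEL_CHANNELS = (0, 1, 2)
GRAVITY_AXIS = 2  # az carries the constant 9.81 offset
GRAVITY = 9.81

#: The twelve scripted activities of the acquisition protocol.
ACTIVITY_NAMES: Dict[int, str] = {
    1: "finger_taps",
    2: "clench_open",
    3: "rapid_alternating_hands",
    4: "hand_rotation_right",
    5: "hand_rotation_left",
    6: "finger_to_nose_left",
    7: "finger_to_nose_right",
    8: "arms_held_out",
    9: "walking",
    10: "rising_from_chair",
    11: "drinking_water",
    12: "picking_up",
}

#: Tremor phenotype dominating each activity; selects the frequency band a
#: subject's tremor is drawn from for that activity.
ACTIVITY_KIND: Dict[int, str] = {
    1: "kinetic",
    2: "kinetic",
    3: "kinetic",
    4: "kinetic",
    5: "kinetic",
    6: "kinetic",
    7: "kinetic",
    8: "postural",
    9: "kinetic",
    10: "postural",
    11: "rest",
    12: "rest",
}

#: Tremor frequency bands in Hz per phenotype.  The kinetic band is clipped
#: at 3 Hz from below so that every symptomatic subject has energy inside the
#: 3-12 Hz band that diagnostic oracles measure.
TREMOR_BANDS: Dict[str, Tuple[float, float]] = {
    "rest": (3.0, 6.0),
    "postural": (4.0, 12.0),
    "kinetic": (3.0, 7.0),
}

WINDOW_SECONDS = 1.5


class CohortFormatError(ValueError):
    """Raised when on-disk cohort files violate the expected schema."""


class UnknownActivityError(ValueError):
    """Raised for activity ids outside 1..12."""


def _check_activity(activity_id: int) -> None:
    if activity_id not in ACTIVITY_NAMES:
        raise UnknownActivityError(
            f"unknown activity id {activity_id!r}; valid ids are 1..12"
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Latent symptom parameters of one simulated subject.

    ``severity`` is the subject-level (bag-level) label: 0 healthy,
    1 mild, 2 moderate, 3 severe.  ``tremor_freq`` maps activity id to the
    tremor frequency used for that activity, drawn from the phenotype band
    of :data:`TREMOR_BANDS`.  ``brady_factor`` scales voluntary-motion
    amplitude (1 = unimpaired); ``duty_cycle`` is the target fraction of
    time spent in the symptomatic ON state.
    """

    subject_id: str
    severity: int
    tremor_freq: Mapping[int, float]
    tremor_amp: float
    brady_factor: float
    duty_cycle: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.severity not in (0, 1, 2, 3):
            raise ValueError(f"severity must be in {{0,1,2,3}}, got {self.severity}")
        if self.severity == 0:
            if self.tremor_amp != 0.0:
                raise ValueError("severity-0 profiles must have tremor_amp == 0")
            if self.brady_factor != 1.0:
                raise ValueError("severity-0 profiles must have brady_factor == 1")
        if not 0.0 < self.brady_factor <= 1.0:
            raise ValueError("brady_factor must lie in (0, 1]")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in [0, 1]")
        for activity_id, freq in self.tremor_freq.items():
            _check_activity(activity_id)
            lo, hi = TREMOR_BANDS[ACTIVITY_KIND[activity_id]]
            if not lo <= freq <= hi:
                raise ValueError(
                    f"tremor_freq {freq} Hz outside band [{lo}, {hi}] for "
                    f"activity {activity_id} ({ACTIVITY_KIND[activity_id]})"
                )


@dataclass
class SignalRecording:
    """One subject x activity multi-channel time series.

    ``data`` is an (n_samples, 6) float array ordered as
    :data:`CHANNEL_NAMES` — accelerometer in m/s^2, gyroscope in rad/s.
    """

    subject_id: str
    activity_id: int
    sample_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        _check_activity(self.activity_id)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNEL_NAMES):
            raise ValueError(
                f"data must be (n, {len(CHANNEL_NAMES)}), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNEL_NAMES.index(name)]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator.

    ``amp_ranges`` / ``brady_ranges`` give per-severity closed intervals the
    per-subject parameters are drawn from; class separation (and therefore
    task difficulty) is controlled entirely by how far apart these ranges
    sit and by ``duty_cycle_base``.
    """

    preset: str = "easy"
    activities: Tuple[int, ...] = tuple(range(1, 13))
    duration: float = 30.0
    sample_rate: float = 200.0
    noise_sd: float = 0.05
    block_seconds: float = 3.0
    duty_ranges: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {1: (0.3, 0.45), 2: (0.55, 0.7), 3: (0.8, 0.95)}
    )
    amp_ranges: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {1: (1.2, 1.6), 2: (2.2, 2.8), 3: (3.6, 4.6)}
    )
    brady_ranges: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {1: (0.78, 0.9), 2: (0.58, 0.72), 3: (0.4, 0.54)}
    )

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "GeneratorConfig":
        """``easy``: disjoint symptom-parameter ranges and high, well-graded
        duty cycles.  ``hard``: overlapping per-window amplitude ranges and
        sparse, overlapping duty cycles (~0.3), so single windows are weakly
        informative and the signal lives at bag level."""
        if preset == "easy":
            cfg = cls(preset="easy")
        elif preset == "hard":
            cfg = cls(
                preset="hard",
                duty_ranges={1: (0.15, 0.35), 2: (0.3, 0.5), 3: (0.45, 0.65)},
                amp_ranges={1: (0.4, 0.8), 2: (0.6, 1.0), 3: (0.8, 1.4)},
                brady_ranges={1: (0.7, 0.95), 2: (0.6, 0.9), 3: (0.5, 0.85)},
            )
        else:
            raise ValueError(f"unknown preset {preset!r}; expected 'easy' or 'hard'")
        return dataclasses.replace(cfg, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activities"] = list(self.activities)
        for key in ("duty_ranges", "amp_ranges", "brady_ranges"):
            d[key] = {str(k): list(v) for k, v in getattr(self, key).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["activities"] = tuple(d["activities"])
        for key in ("duty_ranges", "amp_ranges", "brady_ranges"):
            d[key] = {int(k): tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class Cohort:
    """A bundle of subject profiles and their recordings."""

    profiles: List[SubjectProfile]
    recordings: List[SignalRecording]
    config: GeneratorConfig
    class_sizes: Tuple[int, int, int, int]
    seed: int

    @property
    def labels(self) -> Dict[str, int]:
        return {p.subject_id: p.severity for p in self.profiles}

    def subject_recordings(self, subject_id: str) -> List[SignalRecording]:
        return [r for r in self.recordings if r.subject_id == subject_id]


def _base_frequency(activity_id: int) -> float:
    # activity-specific voluntary-motion fundamental, 0.5-1.8 Hz: kept well
    # below the 3 Hz tremor-band floor even after jitter and AM sidebands
    return 0.5 + 1.3 * (activity_id - 1) / 11.0


def _on_gate(n: int, block: int, duty_cycle: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous-block ON/OFF gate with ON fraction ~= duty_cycle.

    Symptom episodes occupy whole blocks so that ON samples cluster in time
    (episodes, not per-sample flicker)."""
    if duty_cycle <= 0.0:
        return np.zeros(n)
    if duty_cycle >= 1.0:
        return np.ones(n)
    n_blocks = max(1, int(np.ceil(n / block)))
    n_on = int(round(duty_cycle * n_blocks))
    on_blocks = rng.choice(n_blocks, size=n_on, replace=False)
    gate = np.zeros(n_blocks * block)
    for b in on_blocks:
        gate[b * block : (b + 1) * block] = 1.0
    return gate[:n]


def generate_recording(
    profile: SubjectProfile,
    activity_id: int,
    duration: float = 30.0,
    sample_rate: float = 200.0,
    noise_sd: float = 0.05,
    block_seconds: float = 3.0,
) -> SignalRecording:
    """Synthesize one activity recording for one subject.

    Channel model: bradykinesia-scaled voluntary oscillation at the
    activity fundamental + block-gated tremor sinusoid (coherent phase
    across channels, per-channel gain) + white noise + gravity on the az
    accelerometer axis.  Deterministic given (profile.rng_seed, activity).
    """
    _check_activity(activity_id)
    if duration < WINDOW_SECONDS:
        raise ValueError(
            f"duration {duration} s shorter than one analysis window "
            f"({WINDOW_SECONDS} s)"
        )
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng([profile.rng_seed, activity_id])
    t = np.arange(n) / sample_rate

    # Class-independent per-subject idiosyncrasy: jittered fundamental and a
    # slow amplitude-modulation envelope.  Both stay below 3 Hz so they never
    # masquerade as tremor.
    f0 = min(_base_frequency(activity_id) * (1.0 + rng.uniform(-0.15, 0.15)), 2.1)
    base_amp = profile.brady_factor * rng.uniform(0.8, 1.2, size=6)
    base_phase = rng.uniform(0, 2 * np.pi, size=6)
    am_depth = rng.uniform(0.2, 0.6)
    am_freq = rng.uniform(0.05, 0.2)
    envelope = 1.0 + am_depth * np.sin(2 * np.pi * am_freq * t + rng.uniform(0, 2 * np.pi))
    base = envelope[:, None] * base_amp * np.sin(2 * np.pi * f0 * t[:, None] + base_phase)

    # Noise scales with voluntary-motion amplitude so the per-window
    # signal-to-noise ratio alone does not reveal the class label.
    data = base + rng.normal(0.0, noise_sd * profile.brady_factor, size=(n, 6))

    if profile.tremor_amp > 0.0:
        f_tremor = profile.tremor_freq[activity_id]
        gate = _on_gate(
            n, int(round(block_seconds * sample_rate)), profile.duty_cycle, rng
        )
        # coherent phase across channels -> inter-axis correlation while ON
        tremor_phase = rng.uniform(0, 2 * np.pi)
        channel_gain = rng.uniform(0.6, 1.0, size=6)
        tremor = profile.tremor_amp * channel_gain * np.sin(
            2 * np.pi * f_tremor * t[:, None] + tremor_phase
        )
        data = data + gate[:, None] * tremor

    data[:, GRAVITY_AXIS] += GRAVITY
    return SignalRecording(
        subject_id=profile.subject_id,
        activity_id=activity_id,
        sample_rate=sample_rate,
        data=data,
    )


def generate_subject(
    profile: SubjectProfile,
    activities: Iterable[int],
    duration: float = 30.0,
    sample_rate: float = 200.0,
    noise_sd: float = 0.05,
    block_seconds: float = 3.0,
) -> List[SignalRecording]:
    """One recording per requested activity, in ascending activity order."""
    activities = sorted(set(activities))
    for a in activities:
        _check_activity(a)
    return [
        generate_recording(
            profile,
            a,
            duration=duration,
            sample_rate=sample_rate,
            noise_sd=noise_sd,
            block_seconds=block_seconds,
        )
        for a in activities
    ]


def _draw_profile(
    subject_id: str,
    severity: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> SubjectProfile:
    tremor_freq = {}
    for a in config.activities:
        lo, hi = TREMOR_BANDS[ACTIVITY_KIND[a]]
        tremor_freq[a] = float(rng.uniform(lo, hi))
    rng_seed = int(rng.integers(0, 2**31 - 1))
    if severity == 0:
        return SubjectProfile(
            subject_id=subject_id,
            severity=0,
            tremor_freq=tremor_freq,
            tremor_amp=0.0,
            brady_factor=1.0,
            duty_cycle=0.0,
            rng_seed=rng_seed,
        )
    amp_lo, amp_hi = config.amp_ranges[severity]
    brady_lo, brady_hi = config.brady_ranges[severity]
    duty_lo, duty_hi = config.duty_ranges[severity]
    duty = float(rng.uniform(duty_lo, duty_hi))
    return SubjectProfile(
        subject_id=subject_id,
        severity=severity,
        tremor_freq=tremor_freq,
        tremor_amp=float(rng.uniform(amp_lo, amp_hi)),
        brady_factor=float(rng.uniform(brady_lo, brady_hi)),
        duty_cycle=duty,
        rng_seed=rng_seed,
    )


def generate_cohort(
    class_sizes: Sequence[int] = (15, 41, 17, 12),
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
) -> Cohort:
    """Generate a cohort with the requested per-class subject counts.

    Within-class heterogeneity comes from drawing each subject's symptom
    parameters from class-conditional ranges in ``config``.  Identical
    (class_sizes, seed, config) always produce an identical cohort.
    """
    class_sizes = tuple(int(s) for s in class_sizes)
    if len(class_sizes) != 4:
        raise ValueError("class_sizes must have 4 entries (healthy/mild/moderate/severe)")
    if any(s < 0 for s in class_sizes):
        raise ValueError("class sizes must be non-negative")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    profiles: List[SubjectProfile] = []
    idx = 0
    for severity, size in enumerate(class_sizes):
        for _ in range(size):
            profiles.append(_draw_profile(f"S{idx:03d}", severity, config, rng))
            idx += 1

    recordings: List[SignalRecording] = []
    for profile in profiles:
        recordings.extend(
            generate_subject(
                profile,
                config.activities,
                duration=config.duration,
                sample_rate=config.sample_rate,
                noise_sd=config.noise_sd,
                block_seconds=config.block_seconds,
            )
        )
    return Cohort(
        profiles=profiles,
        recordings=recordings,
        config=config,
        class_sizes=class_sizes,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# On-disk format: one CSV per subject x activity + JSON manifest
# ---------------------------------------------------------------------------

def _recording_filename(subject_id: str, activity_id: int) -> str:
    return f"{subject_id}_{activity_id}.csv"


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write the cohort as CSV recordings plus a ``manifest.json``.

    Signals are serialized as float32 with enough digits to round-trip
    bitwise at float32 precision; all metadata round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for profile in cohort.profiles:
        recs = cohort.subject_recordings(profile.subject_id)
        entries = []
        for rec in recs:
            fname = _recording_filename(rec.subject_id, rec.activity_id)
            t = np.arange(rec.n_samples) / rec.sample_rate
            frame = pd.DataFrame(
                np.column_stack([t, rec.data]).astype(np.float32),
                columns=list(CSV_COLUMNS),
            )
            frame.to_csv(directory / fname, index=False, float_format="%.9g")
            entries.append({"activity_id": rec.activity_id, "file": fname,
                            "n_samples": rec.n_samples})
        subjects.append(
            {
                "subject_id": profile.subject_id,
                "severity": profile.severity,
                "tremor_freq": {str(k): v for k, v in profile.tremor_freq.items()},
                "tremor_amp": profile.tremor_amp,
                "brady_factor": profile.brady_factor,
                "duty_cycle": profile.duty_cycle,
                "rng_seed": profile.rng_seed,
                "recordings": entries,
            }
        )
    manifest = {
        "format": "pdseverity-cohort-v1",
        "sample_rate": cohort.config.sample_rate,
        "class_sizes": list(cohort.class_sizes),
        "seed": cohort.seed,
        "config": cohort.config.to_dict(),
        "subjects": subjects,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(directory) -> Cohort:
    """Load a cohort written by :func:`write_cohort`, validating the schema."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise CohortFormatError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    config = GeneratorConfig.from_dict(manifest["config"])
    sample_rate = manifest["sample_rate"]

    profiles: List[SubjectProfile] = []
    recordings: List[SignalRecording] = []
    for entry in manifest["subjects"]:
        profiles.append(
            SubjectProfile(
                subject_id=entry["subject_id"],
                severity=entry["severity"],
                tremor_freq={int(k): v for k, v in entry["tremor_freq"].items()},
                tremor_amp=entry["tremor_amp"],
                brady_factor=entry["brady_factor"],
                duty_cycle=entry["duty_cycle"],
                rng_seed=entry["rng_seed"],
            )
        )
        for rec_entry in entry["recordings"]:
            path = directory / rec_entry["file"]
            if not path.exists():
                raise CohortFormatError(f"manifest lists missing recording file: {path}")
            frame = pd.read_csv(path)
            if tuple(frame.columns) != CSV_COLUMNS:
                raise CohortFormatError(
                    f"{path}: expected columns {','.join(CSV_COLUMNS)}, "
                    f"got {','.join(frame.columns)}"
                )
            t = frame["t"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise CohortFormatError(f"{path}: time column is not strictly increasing")
            recordings.append(
                SignalRecording(
                    subject_id=entry["subject_id"],
                    activity_id=rec_entry["activity_id"],
                    sample_rate=sample_rate,
                    data=frame[list(CHANNEL_NAMES)].to_numpy(dtype=np.float32),
                )
            )
    return Cohort(
        profiles=profiles,
        recordings=recordings,
        config=config,
        class_sizes=tuple(manifest["class_sizes"]),
        seed=manifest["seed"],
    )
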