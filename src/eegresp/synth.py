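"""Synthetic resting-state EEG cohorts.

The study population this emulates: depressed patients recorded on a
19-channel 10-20 montage (A1+A2 reference) at 500 Hz, ten minutes of
eyes-open and eyes-closed resting EEG before and after an rTMS course,
labelled responder/nonresponder by a >= 50% drop in BDI-II score.

The signal model is deliberately phenomenological, not biophysical:

* a 1/f ("pink") background per channel, spatially correlated through a
  fixed mixing matrix shared by all subjects (so ICA has structure to find
  but subject identity is not encoded in the background);
* a 10 Hz alpha rhythm with posterior-dominant topography, stronger with
  eyes closed, whose amplitude carries the class and session effects:
  a subject's ``true_class_effect`` scales alpha power (and tilts the
  F3/F4 frontal asymmetry), a cohort-level ``session_effect`` scales alpha
  in the post-treatment session;
* artifacts: frontal blink transients, temporal muscle bursts, 50 Hz
  power-line interference, and sub-0.1 Hz electrode drift.

Separability between classes is therefore a tunable spectral (band-power)
difference, from 0 (exchangeable null) upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .recording import (
    CONDITIONS,
    ConfigurationError,
    EEGRecording,
    MontageSpec,
    SESSIONS,
)

__all__ = [
    "ArtifactSpec",
    "RecordingSpec",
    "SubjectProfile",
    "Cohort",
    "generate_recording",
    "generate_cohort",
    "BDI_DEFAULTS",
]


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifact content of a generated recording. Rates per minute, amplitudes in microvolts."""

    blink_rate: float = 12.0
    line_noise_amp: float = 4.0
    muscle_burst_rate: float = 3.0
    drift_amp: float = 20.0

    def __post_init__(self) -> None:
        for name in ("blink_rate", "line_noise_amp", "muscle_burst_rate", "drift_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RecordingSpec:
    """Acquisition parameters of one synthetic recording."""

    sampling_rate: float = 500.0
    duration: float = 600.0
    conditions: tuple[str, ...] = CONDITIONS
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    montage: MontageSpec = field(default_factory=MontageSpec)
    background_rms: float = 10.0
    alpha_amp: float = 12.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.sampling_rate <= 120.0:
            # everything generated lives below 60 Hz plus the 50 Hz line
            raise ConfigurationError("sampling_rate must exceed twice the highest generated frequency")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration x sampling_rate must be an integer sample count")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {c!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject metadata, including the spectral effect injected for their class."""

    subject_id: str
    sex: str
    bdi_pre: int
    bdi_post: int
    true_class_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigurationError("sex must be 'female' or 'male'")
        if self.bdi_pre <= 0:
            raise ConfigurationError("bdi_pre must be positive for a depressed cohort")
        if self.bdi_post < 0:
            raise ConfigurationError("bdi_post must be non-negative")

    @property
    def is_responder(self) -> bool:
        return (self.bdi_pre - self.bdi_post) / self.bdi_pre >= 0.5


# BDI-II group statistics (mean, SD) used as sampling defaults, keyed by
# (sex, responder): pre-treatment and post-treatment scores.
BDI_DEFAULTS: dict[tuple[str, bool], dict[str, tuple[float, float]]] = {
    ("male", True): {"pre": (30.66, 7.79), "post": (7.94, 5.43)},
    ("male", False): {"pre": (35.42, 9.12), "post": (27.14, 7.98)},
    ("female", True): {"pre": (30.45, 8.46), "post": (8.36, 5.46)},
    ("female", False): {"pre": (32.64, 7.73), "post": (20.0, 4.94)},
}


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float) -> np.ndarray:
    """Spatially mixed 1/f noise, unit RMS per channel."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    # fixed inter-channel mixing, identical for every subject
    mix_rng = np.random.default_rng(20151231)
    mixing = np.eye(n_channels) + 0.25 * mix_rng.standard_normal((n_channels, n_channels))
    y = mixing @ x
    return y / y.std(axis=1, keepdims=True)


def _alpha_topography(montage: MontageSpec, class_effect: float) -> np.ndarray:
    """Per-channel alpha weights: posterior-dominant, frontal asymmetry tilted by the class effect."""
    w = np.full(montage.n_channels, 0.25)
    for name, v in (("O1", 1.0), ("O2", 1.0), ("P3", 0.8), ("P4", 0.8),
                    ("Pz", 0.8), ("T5", 0.6), ("T6", 0.6)):
        w[montage.index(name)] = v
    # frontal alpha asymmetry: F3 down, F4 up with increasing effect
    w[montage.index("F3")] = 0.3 / (1.0 + 0.5 * max(class_effect, 0.0))
    w[montage.index("F4")] = 0.3 * (1.0 + 0.5 * max(class_effect, 0.0))
    return w


def _blink_template(fs: float) -> np.ndarray:
    """Stereotyped ~300 ms frontal blink transient (positive-going bump)."""
    t = np.arange(int(0.3 * fs)) / fs
    return np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)


def _blink_weights(montage: MontageSpec) -> np.ndarray:
    w = np.full(montage.n_channels, 0.05)
    for name, v in (("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.4), ("F3", 0.4),
                    ("Fz", 0.4), ("F4", 0.4), ("F8", 0.4)):
        w[montage.index(name)] = v
    return w


def generate_recording(profile: SubjectProfile, spec: RecordingSpec, seed: int,
                       *, session: str = "pre", condition: str = "eyes_closed",
                       session_effect: float = 0.0) -> EEGRecording:
    """Generate one continuous recording for one subject/session/condition.

    Deterministic in ``seed``. The subject's ``true_class_effect`` scales
    alpha-band amplitude by ``1 + effect`` (plus a frontal asymmetry tilt);
    ``session_effect`` applies the same scaling in the post session only.

    Returns
    -------
    EEGRecording
        ``(19, duration * sampling_rate)`` float array in microvolts.
    """
    if session not in SESSIONS:
        raise ConfigurationError(f"session must be one of {SESSIONS}")
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    n = spec.n_samples
    nc = spec.montage.n_channels
    t = np.arange(n) / fs

    data = spec.background_rms * _pink_noise(rng, nc, n, fs)

    # --- alpha rhythm ------------------------------------------------------
    effect = profile.true_class_effect
    amp = spec.alpha_amp * (1.0 + max(effect, 0.0))
    if session == "post":
        amp *= 1.0 + max(session_effect, 0.0)
    if condition == "eyes_closed":
        amp *= 1.6
    # amplitude-modulated 10 Hz with slowly drifting phase
    env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    phase_jitter = np.cumsum(rng.standard_normal(n)) * (0.05 / np.sqrt(fs))
    carrier = np.sin(2 * np.pi * 10.0 * t + phase_jitter + rng.uniform(0, 2 * np.pi))
    data += np.outer(_alpha_topography(spec.montage, effect), amp * env * carrier)

    art = spec.artifacts
    # --- blinks ------------------------------------------------------------
    if art.blink_rate > 0:
        tmpl = _blink_template(fs)
        weights = _blink_weights(spec.montage)
        n_blinks = rng.poisson(art.blink_rate * spec.duration / 60.0)
        for _ in range(n_blinks):
            start = rng.integers(0, max(n - tmpl.size, 1))
            amp_b = rng.uniform(80.0, 140.0)
            data[:, start:start + tmpl.size] += amp_b * np.outer(weights, tmpl)

    # --- muscle bursts -----------------------------------------------------
    if art.muscle_burst_rate > 0:
        m_idx = [spec.montage.index(c) for c in ("T3", "T4", "F7", "F8")]
        n_bursts = rng.poisson(art.muscle_burst_rate * spec.duration / 60.0)
        blen = int(0.5 * fs)
        for _ in range(n_bursts):
            start = rng.integers(0, max(n - blen, 1))
            burst = rng.standard_normal(blen)
            # crude 20-60 Hz emphasis via differencing + smoothing
            burst = np.diff(burst, prepend=burst[0])
            burst *= np.hanning(blen)
            burst /= max(burst.std(), 1e-12)
            ch = m_idx[rng.integers(0, len(m_idx))]
            data[ch, start:start + blen] += 15.0 * burst

    # --- 50 Hz line noise --------------------------------------------------
    if art.line_noise_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, nc)
        data += art.line_noise_amp * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None])

    # --- slow electrode drift ---------------------------------------------
    if art.drift_amp > 0:
        f_drift = rng.uniform(0.02, 0.08, nc)
        phases = rng.uniform(0, 2 * np.pi, nc)
        data += art.drift_amp * np.sin(
            2 * np.pi * f_drift[:, None] * t[None, :] + phases[:, None])

    return EEGRecording(
        data=data, sampling_rate=fs, montage=spec.montage,
        subject_id=profile.subject_id, session=session, condition=condition,
    )


@dataclass
class Cohort:
    """A generated cohort: subject profiles plus all their recordings.

    ``recordings`` maps ``(subject_id, session, condition)`` to an
    :class:`~eegresp.recording.EEGRecording`.
    """

    subjects: list[SubjectProfile]
    recordings: dict[tuple[str, str, str], EEGRecording]

    def profile(self, subject_id: str) -> SubjectProfile:
        for p in self.subjects:
            if p.subject_id == subject_id:
                return p
        raise KeyError(subject_id)

    def metadata(self) -> pd.DataFrame:
        """Long-format subject metadata table (one row per recording)."""
        rows = []
        for (sid, session, condition), rec in sorted(self.recordings.items()):
            p = self.profile(sid)
            rows.append({
                "subject_id": sid, "sex": p.sex, "session": session,
                "condition": condition, "bdi_pre": p.bdi_pre,
                "bdi_post": p.bdi_post,
            })
        return pd.DataFrame(rows)


def _draw_bdi(rng: np.random.Generator, sex: str, responder: bool) -> tuple[int, int]:
    """Draw (pre, post) BDI-II integers consistent with the intended label.

    Scores come from the group-specific normal distributions, truncated to
    non-negative integers; the post score is then nudged the minimal amount
    needed so the 50%-reduction rule reproduces the intended label exactly.
    """
    stats = BDI_DEFAULTS[(sex, responder)]
    pre = 0
    while pre <= 0:
        pre = int(round(rng.normal(*stats["pre"])))
    post = max(0, int(round(rng.normal(*stats["post"]))))
    half = pre / 2.0
    if responder and post > half:
        post = int(np.floor(half))
    if not responder and post <= half:
        post = int(np.floor(half)) + 1
    return pre, post


DEFAULT_RESPONDER_FRACTIONS: Mapping[str, float] = {"female": 11 / 25, "male": 18 / 25}


def generate_cohort(n_female: int = 25, n_male: int = 25,
                    responder_fraction_by_sex: Mapping[str, float] | None = None,
                    spec: RecordingSpec | None = None, seed: int = 0,
                    *, class_effect: float = 0.5,
                    session_effect: float = 0.5,
                    sessions: Sequence[str] = SESSIONS) -> Cohort:
    """Generate a full synthetic cohort with recordings for every
    subject x session x condition cell.

    Parameters
    ----------
    n_female, n_male
        Cohort composition (defaults: 25 + 25).
    responder_fraction_by_sex
        Fraction of responders per sex; defaults to the observed 11/25
        (female) and 18/25 (male). Counts are ``round(fraction * n)``.
    spec
        Acquisition/artifact parameters (default: 10 min at 500 Hz, both
        eye conditions, all artifact families on).
    seed
        Master seed; the cohort is bitwise reproducible given it.
    class_effect
        Alpha band-power effect injected for responders (0 = null cohort).
    session_effect
        Alpha scaling of the post-rTMS session relative to pre.
    sessions
        Which sessions to generate (default both ``pre`` and ``post``).
    """
    if n_female < 0 or n_male < 0 or n_female + n_male <= 0:
        raise ConfigurationError("cohort size must be positive")
    fractions = dict(DEFAULT_RESPONDER_FRACTIONS)
    if responder_fraction_by_sex:
        fractions.update(responder_fraction_by_sex)
    for sex, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"responder fraction for {sex} must be in [0, 1]")
    spec = spec or RecordingSpec()

    ss = np.random.SeedSequence(seed)
    bdi_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects: list[SubjectProfile] = []
    for sex, n_sex in (("female", n_female), ("male", n_male)):
        n_resp = int(round(fractions[sex] * n_sex))
        for i in range(n_sex):
            responder = i < n_resp
            pre, post = _draw_bdi(bdi_rng, sex, responder)
            subjects.append(SubjectProfile(
                subject_id=f"S{'F' if sex == 'female' else 'M'}{i + 1:03d}",
                sex=sex, bdi_pre=pre, bdi_post=post,
                true_class_effect=class_effect if responder else 0.0,
            ))

    recordings: dict[tuple[str, str, str], EEGRecording] = {}
    rec_seeds = ss.spawn(len(subjects) * len(sessions) * len(spec.conditions))
    k = 0
    for p in subjects:
        for session in sessions:
            for condition in spec.conditions:
                rec = generate_recording(
                    p, spec, seed=rec_seeds[k], session=session,
                    condition=condition, session_effect=session_effect)
                recordings[(p.subject_id, session, condition)] = rec
                k += 1
    return Cohort(subjects=subjects, recordings=recordings)
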