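"""Preprocessing chain: ICA artifact removal, filtering, segmentation,
response labelling, and assembly of the labelled data matrix.

The default chain mirrors typical offline resting-EEG cleaning for this
pipeline: ICA-based removal of ocular/muscle components, a 50 Hz notch for
power-line interference, and a 0.1-60 Hz band-pass (elliptic by default; a
Chebyshev type-II design is selectable). All filters are applied zero-phase
(forward-backward), so pass-band waveform latency is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spst
from sklearn.decomposition import FastICA

from .recording import (
    ConfigurationError,
    EEGRecording,
    SegmentTensor,
    make_meta,
)
from .synth import Cohort, SubjectProfile

__all__ = [
    "FilterSpec", "FilterDesignError", "apply_filter", "default_filter_chain",
    "ICAResult", "run_ica", "reject_artifact_components", "RejectionCriteria",
    "segment", "count_segments", "label_response", "assemble_dataset",
    "MODEL_DEFINITIONS", "preprocess_recording",
]


class FilterDesignError(ValueError):
    """Raised when a requested IIR design is unstable or infeasible."""


@dataclass(frozen=True)
class FilterSpec:
    """One IIR filter stage.

    ``kind`` selects the design: ``"notch"`` (IIR notch at ``center_hz``
    with quality factor ``q``), ``"elliptic_bandpass"`` (pass-band edges
    ``low_hz``-``high_hz``, ``passband_ripple_db`` ripple,
    ``stopband_attenuation_db`` attenuation) or ``"chebyshev2_bandpass"``
    (equiripple stop band only). Orders/ripples default to the pipeline's
    standard values.
    """

    kind: str = "elliptic_bandpass"
    low_hz: float = 0.1
    high_hz: float = 60.0
    center_hz: float = 50.0
    q: float = 30.0
    order: int = 4
    stopband_attenuation_db: float = 40.0
    passband_ripple_db: float = 1.0

    def design(self, sampling_rate: float) -> np.ndarray:
        """Return second-order sections; raise on invalid/unstable designs."""
        nyq = sampling_rate / 2.0
        if self.kind == "notch":
            if not 0 < self.center_hz < nyq:
                raise ConfigurationError("notch center must lie below Nyquist")
            b, a = sps.iirnotch(self.center_hz, self.q, fs=sampling_rate)
            sos = sps.tf2sos(b, a)
        elif self.kind in ("elliptic_bandpass", "chebyshev2_bandpass"):
            if not 0 < self.low_hz < self.high_hz < nyq:
                raise ConfigurationError(
                    "band edges must satisfy 0 < low < high < Nyquist")
            if self.order < 1:
                raise ConfigurationError("order must be >= 1")
            if self.kind == "elliptic_bandpass":
                sos = sps.ellip(self.order, self.passband_ripple_db,
                                self.stopband_attenuation_db,
                                [self.low_hz, self.high_hz],
                                btype="bandpass", fs=sampling_rate, output="sos")
            else:
                sos = sps.cheby2(self.order, self.stopband_attenuation_db,
                                 [self.low_hz, self.high_hz],
                                 btype="bandpass", fs=sampling_rate, output="sos")
        else:
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise FilterDesignError(
                f"{self.kind} design is unstable at fs={sampling_rate}")
        return sos


def apply_filter(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Apply one filter stage zero-phase (forward-backward) channel-wise."""
    sos = spec.design(rec.sampling_rate)
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out)


def default_filter_chain(bandpass: str = "elliptic_bandpass") -> tuple[FilterSpec, ...]:
    """Notch at 50 Hz followed by the 0.1-60 Hz band-pass."""
    return (FilterSpec(kind="notch"), FilterSpec(kind=bandpass))


# ---------------------------------------------------------------------------
# ICA


@dataclass
class ICAResult:
    """Fitted ICA decomposition of one recording.

    ``mixing`` is channels x components, ``sources`` components x samples;
    ``mean`` is the per-channel mean removed before unmixing. The input is
    reconstructed as ``mixing @ sources + mean`` restricted to kept
    components.
    """

    mixing: np.ndarray
    sources: np.ndarray
    mean: np.ndarray
    rejected: frozenset[int] = frozenset()
    rejection_scores: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, rec: EEGRecording) -> EEGRecording:
        """Rebuild the recording from all non-rejected components."""
        keep = [i for i in range(self.n_components) if i not in self.rejected]
        data = self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]
        return rec.copy_with(data)


def run_ica(rec: EEGRecording, n_components: int | None = None,
            seed: int = 0) -> ICAResult:
    """Decompose a recording into statistically independent components.

    Uses negentropy-maximisation ICA (FastICA) after whitening. With
    ``n_components`` equal to the channel count (the default) the
    decomposition is lossless up to numerical precision. Components are
    reduced with a warning if the data are rank-deficient.
    """
    nc = rec.n_channels
    n_components = nc if n_components is None else n_components
    centered = rec.data - rec.data.mean(axis=1, keepdims=True)
    eigvals = np.linalg.eigvalsh(centered @ centered.T)
    rank = int(np.sum(eigvals > eigvals.max() * nc * np.finfo(float).eps))
    if n_components > rank:
        warnings.warn(
            f"data rank {rank} < requested {n_components} components; reducing",
            RuntimeWarning, stacklevel=2)
        n_components = rank
    ica = FastICA(n_components=n_components, whiten="unit-variance",
                  random_state=seed, max_iter=300, tol=1e-4)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        sources = ica.fit_transform(rec.data.T).T
    return ICAResult(mixing=ica.mixing_, sources=sources, mean=ica.mean_)


@dataclass(frozen=True)
class RejectionCriteria:
    """Thresholds for flagging artifact components."""

    blink_corr_threshold: float = 0.8
    kurtosis_threshold: float = 5.0


def reject_artifact_components(ica: ICAResult, rec: EEGRecording,
                               criteria: RejectionCriteria | None = None) -> ICAResult:
    """Flag components as ocular/myogenic artifacts.

    A component is rejected when (a) its absolute correlation with the
    frontal blink proxy (mean of Fp1 and Fp2) meets the threshold, or
    (b) its excess kurtosis (transient, spiky activity) does. Scores for
    every component are kept in ``rejection_scores``.
    """
    criteria = criteria or RejectionCriteria()
    fp = [rec.montage.index("Fp1"), rec.montage.index("Fp2")]
    proxy = rec.data[fp].mean(axis=0)
    proxy = proxy - proxy.mean()
    pn = np.linalg.norm(proxy)

    rows = []
    rejected = set()
    for i, src in enumerate(ica.sources):
        s = src - src.mean()
        denom = np.linalg.norm(s) * pn
        corr = float(np.abs(s @ proxy) / denom) if denom > 0 else 0.0
        kurt = float(spst.kurtosis(src, fisher=True))
        is_blink = corr >= criteria.blink_corr_threshold
        is_spiky = abs(kurt) >= criteria.kurtosis_threshold
        if is_blink or is_spiky:
            rejected.add(i)
        rows.append({"component": i, "blink_corr": corr, "kurtosis": kurt,
                     "rejected": is_blink or is_spiky})
    return replace(ica, rejected=frozenset(rejected),
                   rejection_scores=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Segmentation and labelling


def count_segments(total_samples: int, segment_len: int) -> int:
    """Number of non-overlapping whole segments in ``total_samples``."""
    if segment_len < 1:
        raise ConfigurationError("segment_len must be >= 1")
    return total_samples // segment_len


def segment(rec: EEGRecording, segment_len: int = 500, label: int = 0) -> SegmentTensor:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than ``segment_len`` is discarded.
    Output segments are time-major (``segment_len`` x channels).
    """
    n_seg = count_segments(rec.n_samples, segment_len)
    if n_seg == 0:
        warnings.warn("segment_len exceeds recording length; empty tensor",
                      RuntimeWarning, stacklevel=2)
        return SegmentTensor.empty(segment_len, rec.n_channels)
    used = n_seg * segment_len
    segs = rec.data[:, :used].T.reshape(n_seg, segment_len, rec.n_channels)
    offsets = np.arange(n_seg) * segment_len
    meta = make_meta(n_seg, rec.subject_id, rec.session, rec.condition,
                     label, offsets)
    return SegmentTensor(segs, meta)


def label_response(bdi_pre: int, bdi_post: int) -> str:
    """Classify a subject from BDI-II change: responder iff reduction >= 50%."""
    if bdi_pre <= 0:
        raise ConfigurationError("bdi_pre must be positive to define response")
    if bdi_post < 0:
        raise ConfigurationError("bdi_post must be non-negative")
    return "responder" if (bdi_pre - bdi_post) / bdi_pre >= 0.5 else "nonresponder"


#: model_id -> (description, sex filter, session filter, labelling rule)
MODEL_DEFINITIONS = {
    1: "female, pre vs post rTMS",
    2: "male, pre vs post rTMS",
    3: "female pre-rTMS, responder vs nonresponder",
    4: "male pre-rTMS, responder vs nonresponder",
    5: "all pre-rTMS, responder vs nonresponder",
}


def _model_filter(model_id: int, profile: SubjectProfile, rec: EEGRecording):
    """Return the class label (0/1) for a recording under a model, or None to exclude.

    Session models: pre = 0, post = 1. Response models: nonresponder = 0,
    responder = 1 (pre-rTMS recordings only).
    """
    if model_id in (1, 2):
        want_sex = "female" if model_id == 1 else "male"
        if profile.sex != want_sex:
            return None
        return 0 if rec.session == "pre" else 1
    if model_id in (3, 4, 5):
        if rec.session != "pre":
            return None
        if model_id == 3 and profile.sex != "female":
            return None
        if model_id == 4 and profile.sex != "male":
            return None
        return 1 if label_response(profile.bdi_pre, profile.bdi_post) == "responder" else 0
    raise ConfigurationError(f"model_id must be in 1..5, got {model_id}")


def assemble_dataset(recordings: Iterable[tuple[SubjectProfile, EEGRecording]],
                     model_id: int, segment_len: int = 500) -> SegmentTensor:
    """Select, segment and label recordings for one of the five models.

    Both eye conditions are pooled under the recording's class label.
    Raises if either class ends up empty.
    """
    if model_id not in MODEL_DEFINITIONS:
        raise ConfigurationError(f"model_id must be in 1..5, got {model_id}")
    parts = []
    for profile, rec in recordings:
        label = _model_filter(model_id, profile, rec)
        if label is None:
            continue
        st = segment(rec, segment_len=segment_len, label=label)
        if st.n_segments:
            parts.append(st)
    if not parts:
        raise ConfigurationError(f"no recordings selected for model {model_id}")
    out = SegmentTensor.concatenate(parts)
    present = set(out.labels.tolist())
    if present != {0, 1}:
        raise ConfigurationError(
            f"model {model_id} needs both classes; found labels {sorted(present)}")
    return out


def preprocess_recording(rec: EEGRecording, *, run_artifact_ica: bool = True,
                         filters: Sequence[FilterSpec] | None = None,
                         criteria: RejectionCriteria | None = None,
                         seed: int = 0) -> EEGRecording:
    """Full per-recording cleaning: ICA artifact removal, then filtering.

    ICA component estimation comes first (on the raw signal, whose artifact
    structure is what the decomposition must isolate), then the notch and
    band-pass stages.
    """
    out = rec
    if run_artifact_ica:
        ica = run_ica(out, seed=seed)
        ica = reject_artifact_components(ica, out, criteria)
        out = ica.reconstruct(out)
    for spec in (filters if filters is not None else default_filter_chain()):
        out = apply_filter(out, spec)
    return out


def cohort_model_inputs(cohort: Cohort, model_id: int):
    """Yield ``(profile, recording)`` pairs of a cohort for assembly."""
    for (sid, _session, _condition), rec in sorted(cohort.recordings.items()):
        yield cohort.profile(sid), rec
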