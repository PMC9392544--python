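"""Core containers: 10-20 montage, continuous recordings, segment tensors.

Everything downstream (filtering, ICA, segmentation, the network) operates on
these three objects. A recording stores its signal channel-major (channels x
samples, microvolts); segments are time-major (samples x channels), the layout
the 1D convolution consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The standard 19-electrode subset of the international 10-20 system, in the
#: amplifier's channel order. Frontal-polar channels (Fp1, Fp2) lead, which the
#: ocular-artifact logic relies on.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

SESSIONS = ("pre", "post")
CONDITIONS = ("eyes_open", "eyes_closed")


class ConfigurationError(ValueError):
    """Raised for invalid montage / generator / filter configuration."""


@dataclass(frozen=True)
class MontageSpec:
    """Electrode montage: ordered channel labels plus the reference."""

    channel_names: tuple[str, ...] = CHANNELS_10_20
    reference: str = "A1+A2"

    def __post_init__(self) -> None:
        if len(self.channel_names) != 19:
            raise ConfigurationError(
                f"montage must have exactly 19 channels, got {len(self.channel_names)}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("montage channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class EEGRecording:
    """One subject/session/condition of continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    sampling_rate
        Samples per second (Hz).
    montage
        Channel labels and reference.
    subject_id, session, condition
        Provenance used for labelling and dataset assembly. ``session`` is
        ``"pre"`` or ``"post"`` (relative to the rTMS course); ``condition``
        is ``"eyes_open"`` or ``"eyes_closed"``.
    """

    data: np.ndarray
    sampling_rate: float = 500.0
    montage: MontageSpec = field(default_factory=MontageSpec)
    subject_id: str = ""
    session: str = "pre"
    condition: str = "eyes_closed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ConfigurationError(
                f"expected {self.montage.n_channels} channels, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite samples")
        if self.session not in SESSIONS:
            raise ConfigurationError(f"session must be one of {SESSIONS}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


#: Columns of the per-segment provenance table carried by SegmentTensor.
PROVENANCE_COLUMNS = (
    "subject_id", "session", "condition", "label",
    "source_offset", "is_artificial", "parent_ids",
)


@dataclass
class SegmentTensor:
    """Stacked fixed-length epochs with per-segment labels and provenance.

    ``data`` has shape ``(n_segments, segment_len, n_channels)`` (time-major,
    the layout the convolutional front end expects). ``meta`` has one row per
    segment with columns :data:`PROVENANCE_COLUMNS`; ``label`` is the integer
    class (0/1), ``source_offset`` the first sample of the segment in its
    source recording, ``parent_ids`` a ``;``-joined list of parent segment
    row indices for artificial (augmented) segments, empty otherwise.
    """

    data: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("segment data must be 3-D (segments x time x channels)")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta must have one row per segment")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def segment_len(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=np.int64)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SegmentTensor":
        idx = np.asarray(idx)
        return SegmentTensor(self.data[idx], self.meta.iloc[idx].reset_index(drop=True))

    @staticmethod
    def concatenate(parts: Iterable["SegmentTensor"]) -> "SegmentTensor":
        parts = list(parts)
        if not parts:
            raise ValueError("nothing to concatenate")
        data = np.concatenate([p.data for p in parts], axis=0)
        meta = pd.concat([p.meta for p in parts], ignore_index=True)
        return SegmentTensor(data, meta)

    @staticmethod
    def empty(segment_len: int, n_channels: int) -> "SegmentTensor":
        return SegmentTensor(
            np.empty((0, segment_len, n_channels)),
            pd.DataFrame({c: pd.Series(dtype=object) for c in PROVENANCE_COLUMNS}),
        )

    def save(self, path, provenance_path=None) -> None:
        """Write the array to ``.npz`` and provenance to a sidecar CSV."""
        np.savez_compressed(path, data=self.data)
        if provenance_path is not None:
            self.meta.to_csv(provenance_path, index=False)

    @staticmethod
    def load(path, provenance_path) -> "SegmentTensor":
        with np.load(path) as z:
            data = z["data"]
        meta = pd.read_csv(provenance_path, keep_default_na=False)
        return SegmentTensor(data, meta)


def make_meta(n: int, subject_id: str, session: str, condition: str,
              label: int, offsets: np.ndarray) -> pd.DataFrame:
    """Provenance rows for ``n`` consecutive real segments of one recording."""
    return pd.DataFrame({
        "subject_id": [subject_id] * n,
        "session": [session] * n,
        "condition": [condition] * n,
        "label": np.full(n, label, dtype=np.int64),
        "source_offset": np.asarray(offsets, dtype=np.int64),
        "is_artificial": [False] * n,
        "parent_ids": [""] * n,
    })
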