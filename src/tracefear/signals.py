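"""Core container for uniformly sampled physiological channels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = (
    "emg",
    "scr",
    "pupil_l",
    "pupil_r",
    "gaze_x",
    "gaze_y",
    "ecg",
    "respiration",
)


@dataclass
class ContinuousSignal:
    """A uniformly sampled channel with a missing-data mask.

    ``missing_mask`` is True where the sample is invalid (artifact, blink,
    US stimulation window, ...). Non-missing samples must be finite.
    """

    channel: str
    sampling_rate: float
    samples: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.samples.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.samples.shape != self.missing_mask.shape:
            raise ValueError("samples and missing_mask must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        valid = self.samples[~self.missing_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-missing samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Grid index of time ``t`` (nearest, for exact grid times)."""
        return int(round(t * self.sampling_rate))

    def interpolated(self) -> np.ndarray:
        """Samples with missing stretches linearly interpolated (edges held)."""
        y = self.samples.copy()
        bad = self.missing_mask | ~np.isfinite(y)
        if bad.any() and not bad.all():
            idx = np.arange(len(y))
            y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
        return y
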