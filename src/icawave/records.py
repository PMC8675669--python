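"""Core data containers: continuous annotated records and windowed beats."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: AAMI beat-class symbols handled throughout the package
#: (normal, supraventricular ectopic, ventricular ectopic, fusion).
AAMI_CLASSES = ("N", "S", "V", "F")


@dataclass
class ECGRecord:
    """Continuous single-lead ECG with beat annotations.

    Parameters
    ----------
    samples
        Signal in millivolts.
    sampling_rate
        Sampling frequency in Hz.
    annotations
        ``(sample_index, class_label)`` pairs, 0-based indices.
    subject_id
        Opaque identifier used for subject-aware cross-validation.
    """

    samples: np.ndarray
    sampling_rate: float
    annotations: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        n = len(self.samples)
        for idx, _label in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside record of length {n}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.samples) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "ECGRecord":
        """New record with the same metadata but different sample values."""
        return ECGRecord(
            samples=samples,
            sampling_rate=self.sampling_rate,
            annotations=list(self.annotations),
            subject_id=self.subject_id,
        )


@dataclass
class Heartbeat:
    """Fixed-width beat window aligned on the detected R wave.

    ``alpha`` is the phase-shift coefficient: the normalized distance between
    the R index and the window middle, 0 for perfect alignment and ~1 when the
    R wave sits at the window edge.
    """

    window: np.ndarray
    r_index: int
    class_label: str
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 1:
            raise ValueError("window must be one-dimensional")
        if not 0 <= self.r_index < len(self.window):
            raise ValueError("r_index outside window")

    @property
    def d(self) -> int:
        return len(self.window)

    @property
    def alpha(self) -> float:
        half = self.d // 2
        return abs(self.r_index - half) / half
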