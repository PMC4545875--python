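"""The epoched multichannel recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochedRecording", "GROUP_NAMES"]

#: Ordinal severity coding used throughout: controls=0, mild=1,
#: moderate=2, severe=3; trend models enter this code as a continuous
#: predictor.
GROUP_NAMES = ("control", "mild", "moderate", "severe")


@dataclass
class EpochedRecording:
    """One subject's artifact-free epochs plus covariates.

    ``data`` is a real tensor shaped (n_epochs, n_channels, epoch_len)
    in microvolts, channel order matching the montage used to build it.
    ``sex`` is coded 0 = male, 1 = female; ``mmse`` is the 0-30 global
    cognition score.
    """

    subject_id: str
    group: int
    sex: int
    mmse: float
    sampling_rate: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, epoch_len)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.group not in (0, 1, 2, 3):
            raise ValueError(f"group must be 0..3, got {self.group}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Epoch length in seconds (4096 samples at 500 Hz -> 8.192 s)."""
        return self.epoch_len / self.sampling_rate
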