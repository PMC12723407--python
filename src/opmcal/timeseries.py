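"""A minimal multichannel time-series container (channels x samples, tesla)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class TimeSeries:
    """Multichannel recording: ``data`` is (n_channels, n_samples) in tesla.

    ``events`` is an ordered list of (name, sample_index) markers, e.g. trial
    onsets.  Stimulus time zero is sample zero.
    """

    data: np.ndarray
    sample_rate: float
    channel_ids: list[str] | None = None
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if self.channel_ids is not None and len(self.channel_ids) != self.data.shape[0]:
            raise InvalidArgumentError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate
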