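"""Stimulation protocol for paired-recording EPSP train experiments.

The canonical protocol is a train of eight presynaptic pulses at 20 Hz
followed by a single recovery pulse 500 ms after the last train pulse,
repeated 20-60 times per connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse timing of one stimulus-response sweep.

    Parameters
    ----------
    n_pulses:
        Number of pulses in the regular train (default 8).
    frequency_hz:
        Train frequency in Hz (default 20, i.e. 50 ms inter-stimulus
        interval).
    recovery_delay_ms:
        Delay between the last train pulse and the recovery pulse.
    onset_ms:
        Time of the first pulse relative to sweep start.  The leading
        segment provides the pre-stimulus baseline window.
    """

    n_pulses: int = 8
    frequency_hz: float = 20.0
    recovery_delay_ms: float = 500.0
    onset_ms: float = 100.0
    #: cap on the post-stimulus amplitude search window (ms)
    post_window_cap_ms: float = 300.0
    #: length of the pre-stimulus minimum search window (ms)
    pre_window_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.recovery_delay_ms <= 0:
            raise ValueError("recovery_delay_ms must be positive")
        if self.onset_ms < self.pre_window_ms:
            raise ValueError("onset_ms must leave room for the pre-stimulus window")

    @property
    def isi_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def n_stimuli(self) -> int:
        """Train pulses plus the recovery pulse."""
        return self.n_pulses + 1

    @property
    def pulse_times_ms(self) -> np.ndarray:
        train = self.onset_ms + self.isi_ms * np.arange(self.n_pulses)
        recovery = train[-1] + self.recovery_delay_ms
        return np.append(train, recovery)

    def sweep_duration_ms(self, pad_ms: float = 10.0) -> float:
        return float(self.pulse_times_ms[-1] + self.post_window_cap_ms + pad_ms)

    def amplitude_windows(self) -> list[tuple[float, float, float]]:
        """Per stimulus: (pre-window start, pulse time, post-window end).

        The amplitude of EPSP *n* is measured as the maximum voltage in
        the post window minus the minimum in the 50 ms pre window.  The
        post window runs to the next pulse, capped at 300 ms (the cap
        binds only for the pre-recovery gap and the recovery pulse).
        """
        times = self.pulse_times_ms
        windows = []
        for i, t in enumerate(times):
            if i + 1 < len(times):
                post = min(times[i + 1] - t, self.post_window_cap_ms)
            else:
                post = self.post_window_cap_ms
            windows.append((t - self.pre_window_ms, float(t), float(t + post)))
        return windows

    def noise_window_ms(self, guard_ms: float = 50.0) -> tuple[float, float]:
        """Stimulus-free window used for noise calibration.

        The stretch between the last train pulse and the recovery pulse,
        starting one inter-stimulus interval plus a settling guard after
        the last train pulse (400 ms under the default protocol).
        """
        t8 = self.pulse_times_ms[self.n_pulses - 1]
        start = t8 + self.isi_ms + guard_ms
        stop = self.pulse_times_ms[-1]
        if stop <= start:
            raise ValueError("no stimulus-free window with this protocol")
        return float(start), float(stop)

    def to_dict(self) -> dict:
        return {
            "n_pulses": self.n_pulses,
            "frequency_hz": self.frequency_hz,
            "recovery_delay_ms": self.recovery_delay_ms,
            "onset_ms": self.onset_ms,
            "post_window_cap_ms": self.post_window_cap_ms,
            "pre_window_ms": self.pre_window_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)
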