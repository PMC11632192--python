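"""Uniform per-epoch series anchored at lights-off.

Both the hypnodensity-derived sleepiness score and the qEEG theta/alpha
ratio live on the same 15-second epoch grid, so one container serves both.
Epoch ``i`` covers the half-open interval ``[i*epoch_len, (i+1)*epoch_len)``
seconds after lights-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Floor applied to values before taking natural logs.  Sleepiness scores and
#: theta/alpha ratios can be arbitrarily close to zero; clipping keeps the
#: log-linear trajectory fit finite.
LOG_FLOOR = 1e-3

STAGES = ("W", "N1", "N2", "N3", "REM")


@dataclass
class EpochSeries:
    """A numeric value per epoch on a uniform grid starting at lights-off.

    Parameters
    ----------
    values : ndarray
        One value per epoch (sleepiness score or theta/alpha ratio).
    epoch_len : float
        Epoch length in seconds.
    valid : ndarray of bool, optional
        Per-epoch validity flags; invalid epochs are ignored by downstream
        fits. Defaults to all-valid.
    """

    values: np.ndarray
    epoch_len: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("EpochSeries values must be one-dimensional")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask must match values in length")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite where valid")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def centers_min(self) -> np.ndarray:
        """Epoch-center times in minutes from lights-off."""
        return (np.arange(len(self.values)) + 0.5) * self.epoch_len / 60.0

    @property
    def duration_min(self) -> float:
        return len(self.values) * self.epoch_len / 60.0
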