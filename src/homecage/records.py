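"""Core data containers for home-cage behavioural records.

A recording session covers one animal for one week: a 72-hour block of
four-channel samples on a 15-minute grid. The four channels exported by the
home-cage automated (HCA) monitoring system are distance travelled (mm),
body temperature (°C), separation from cage-mates (mm) and the number of
transitions between the RFID grid sections (a count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel order used for every (n, 4) value array in the package.
CHANNELS = ("distance_mm", "temperature_c", "separation_mm", "transitions")

#: Experimental groups and their fixed integer class labels.
GROUPS = ("naive", "injured", "sham")
CLASS_LABELS = {"naive": 0, "injured": 1, "sham": 2}

#: Default sampling grid: one sample every 15 minutes.
SAMPLE_INTERVAL_MIN = 15.0


@dataclass
class AnimalRecord:
    """One animal-week of home-cage monitoring.

    Attributes
    ----------
    animal_id : str
        Stable identifier of the animal.
    group : str
        One of :data:`GROUPS`.
    week : int
        Week index (1-based) of the recording session.
    timestamps : numpy.ndarray
        Minutes since session start, strictly increasing on a constant
        15-minute grid, shape ``(n,)``.
    values : numpy.ndarray
        Channel samples in :data:`CHANNELS` order, shape ``(n, 4)``.
    """

    animal_id: str
    group: str
    week: int
    timestamps: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.week < 1:
            raise ValueError("week must be >= 1")
        if self.values.ndim != 2 or self.values.shape[1] != len(CHANNELS):
            raise ValueError(f"values must have shape (n, {len(CHANNELS)})")
        if self.timestamps.shape[0] != self.values.shape[0]:
            raise ValueError("timestamps and values lengths differ")
        if self.n_samples > 1:
            steps = np.diff(self.timestamps)
            if not np.all(steps > 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("timestamps must lie on a constant-step grid")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def label(self) -> int:
        """Integer class label (naive→0, injured→1, sham→2)."""
        return CLASS_LABELS[self.group]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnimalRecord):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.group == other.group
            and self.week == other.week
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
        )
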