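"""Core data types for interface-pressure frames and sequences.

A pressure-sensing mat reports a ``rows x cols`` grid of interface pressures
(mmHg) at a fixed sampling frequency.  The native array modelled throughout
this package is 118 x 48 sensors at 15.9 mm pitch, reporting 5-200 mmHg at
1 Hz; sub-range readings are unreported and stored as 0.

Axis convention: the row axis is longitudinal (head to foot, the long side
of the mat), the column axis transverse.  Cell (i, j) has its physical
center at ((i + 0.5) * pitch, (j + 0.5) * pitch) mm, with the transverse
origin at the mat edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Native array geometry and sensor range of the modelled mat.
NATIVE_SHAPE = (118, 48)
NATIVE_PITCH_MM = 15.9
PRESSURE_FLOOR_MMHG = 5.0
PRESSURE_CEILING_MMHG = 200.0
NATIVE_FREQUENCY_HZ = 1.0

#: Valid static posture labels plus the label used during movements.
POSTURES = ("supine", "lateral", "high_sitting")
TRANSITION_LABEL = "transition"

#: Canonical pressure-parameter names and their units.
PARAMETER_UNITS = {
    "cop_long": "mm",
    "cop_trans": "mm",
    "contact_area_5": "cm^2",
    "contact_area_10": "cm^2",
    "contact_area_20": "cm^2",
    "peak_pressure": "mmHg",
    "peak_gradient": "mmHg",
}
PARAMETER_NAMES = tuple(PARAMETER_UNITS)


class ValidationError(ValueError):
    """An object violates one of the package's data invariants."""


class NoContactError(ValueError):
    """Raised when a quantity is undefined on an all-zero (no-contact) frame."""


@dataclass(frozen=True)
class PressureFrame:
    """One time-point snapshot of the interface-pressure distribution.

    Parameters
    ----------
    values
        2-D array of pressures in mmHg, shape ``(rows, cols)``.
    pitch
        Center-to-center sensor spacing in mm.
    floor
        Minimum reportable pressure, mmHg.  On a raw sensor frame no value
        lies strictly between 0 and ``floor`` (sub-range readings are 0).
    ceiling
        Saturation pressure, mmHg.
    floored
        Whether the sub-floor rule applies to ``values``.  Block-pooled
        frames average raw values and may legitimately hold means below the
        sensor floor; they carry ``floored=False``.
    """

    values: np.ndarray
    pitch: float = NATIVE_PITCH_MM
    floor: float = PRESSURE_FLOOR_MMHG
    ceiling: float = PRESSURE_CEILING_MMHG
    floored: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(f"frame must be a 2-D grid, got shape {values.shape}")
        if self.pitch <= 0:
            raise ValidationError(f"pitch must be positive, got {self.pitch}")
        if np.any(values < 0):
            raise ValidationError("negative pressure value")
        if np.any(values > self.ceiling):
            raise ValidationError(f"pressure above ceiling {self.ceiling} mmHg")
        if self.floored:
            bad = (values > 0) & (values < self.floor)
            if np.any(bad):
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"value {values[i, j]:g} mmHg at cell ({i}, {j}) is inside the "
                    f"unreportable band (0, {self.floor:g})"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical cell-center coordinates (longitudinal, transverse), mm.

        Returns 1-D arrays of length ``rows`` and ``cols`` respectively.
        """
        rows, cols = self.shape
        longitudinal = (np.arange(rows) + 0.5) * self.pitch
        transverse = (np.arange(cols) + 0.5) * self.pitch
        return longitudinal, transverse

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PressureFrame):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.values, other.values)
            and self.pitch == other.pitch
            and self.floor == other.floor
            and self.ceiling == other.ceiling
            and self.floored == other.floored
        )


def apply_sensor_range(
    values: np.ndarray,
    floor: float = PRESSURE_FLOOR_MMHG,
    ceiling: float = PRESSURE_CEILING_MMHG,
) -> np.ndarray:
    """Apply the sensor reporting rule: sub-floor values read 0, values
    above the ceiling saturate at the ceiling.  Negative inputs read 0."""
    out = np.asarray(values, dtype=float).copy()
    out[out < floor] = 0.0
    np.clip(out, 0.0, ceiling, out=out)
    return out


@dataclass(frozen=True)
class FrameSequence:
    """An ordered, uniformly sampled recording with ground truth attached.

    ``event_times`` are the instants (s) of the postural-change events;
    they live in continuous time and survive temporal down-sampling
    unchanged.  ``posture_labels`` give the posture of each frame
    (``supine`` / ``lateral`` / ``high_sitting``) or ``transition`` while a
    movement is in progress.
    """

    frames: tuple[PressureFrame, ...]
    frequency: float
    posture_labels: tuple[str, ...]
    event_times: tuple[float, ...] = ()
    mattress: str = "foam"
    subject: str = "s00"

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "posture_labels", tuple(self.posture_labels))
        object.__setattr__(self, "event_times", tuple(float(t) for t in self.event_times))
        if not frames:
            raise ValidationError("sequence must contain at least one frame")
        if self.frequency <= 0:
            raise ValidationError(f"frequency must be positive, got {self.frequency}")
        shape, pitch = frames[0].shape, frames[0].pitch
        for f in frames:
            if f.shape != shape or f.pitch != pitch:
                raise ValidationError(
                    f"inconsistent frame geometry: {f.shape}@{f.pitch} vs {shape}@{pitch}"
                )
        if len(self.posture_labels) != len(frames):
            raise ValidationError(
                f"{len(self.posture_labels)} labels for {len(frames)} frames"
            )
        allowed = set(POSTURES) | {TRANSITION_LABEL}
        for lab in self.posture_labels:
            if lab not in allowed:
                raise ValidationError(f"unknown posture label {lab!r}")
        t_max = (len(frames) - 1) / self.frequency
        prev = -np.inf
        for t in self.event_times:
            if t <= prev:
                raise ValidationError("event_times must be strictly increasing")
            if not (0.0 <= t <= t_max):
                raise ValidationError(
                    f"event time {t} s outside recorded span [0, {t_max}] s"
                )
            prev = t

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pitch(self) -> float:
        return self.frames[0].pitch

    @property
    def duration(self) -> float:
        """Time of the last frame, s."""
        return (len(self) - 1) / self.frequency

    def times(self) -> np.ndarray:
        """Sample times of the frames, s."""
        return np.arange(len(self)) / self.frequency

    def pressures(self) -> np.ndarray:
        """All frames stacked into one ``(n_frames, rows, cols)`` array."""
        return np.stack([f.values for f in self.frames])


@dataclass(frozen=True)
class ParameterSeries:
    """One scalar pressure parameter sampled over time.

    ``values`` may contain NaN where the parameter is undefined (COP of an
    all-zero frame); downstream consumers propagate, never zero-fill.
    """

    name: str
    values: np.ndarray
    frequency: float
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValidationError("parameter series must be 1-D")
        if self.frequency <= 0:
            raise ValidationError("frequency must be positive")
        if self.name in PARAMETER_UNITS:
            expected = PARAMETER_UNITS[self.name]
            if not self.units:
                object.__setattr__(self, "units", expected)
            elif self.units != expected:
                raise ValidationError(
                    f"units {self.units!r} inconsistent with parameter {self.name!r}"
                    f" (expected {expected!r})"
                )

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frequency
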