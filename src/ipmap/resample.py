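"""Spatial and temporal down-sampling of pressure sequences.

Spatial down-sampling pools non-overlapping k x k sensor blocks into their
arithmetic mean, emulating a coarser array: a 118 x 48 mat at k = 2, 3, 4,
5 becomes 59 x 24 (1416), 39 x 16 (624), 29 x 12 (348) and 23 x 9 (207)
sensors.  Trailing rows/columns short of a full block are discarded, which
is what those output dimensions imply.  Temporal down-sampling keeps one
frame every n samples, so a 1 Hz recording becomes 0.5, 1/3, 0.2 or 0.1 Hz
for n = 2, 3, 5, 10.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .frames import FrameSequence, PressureFrame, ValidationError

#: The configuration grid swept by the sensitivity analysis.
BLOCK_FACTORS = (1, 2, 3, 4, 5)
DECIMATION_FACTORS = (1, 2, 3, 5, 10)


@dataclass(frozen=True)
class Configuration:
    """One spatial x temporal down-sampling configuration.

    ``frequency_hz`` is exact (1/3 Hz for n = 3); ``frequency_label`` is
    the conventional one-decimal reporting form ("0.3" for 1/3 Hz).
    """

    block: int
    decimation: int
    n_sensors: int
    out_shape: tuple[int, int]
    pitch_mm: float
    frequency_hz: float
    frequency_label: str

    @staticmethod
    def make(
        block: int,
        decimation: int,
        rows: int,
        cols: int,
        pitch: float = 15.9,
        source_frequency: float = 1.0,
    ) -> "Configuration":
        if block < 1 or decimation < 1:
            raise ValidationError("block and decimation factors must be >= 1")
        out_shape = (rows // block, cols // block)
        freq = source_frequency / decimation
        label = f"{freq:.1f}".rstrip("0").rstrip(".") if freq >= 1 else f"{freq:.1f}"
        return Configuration(
            block=block,
            decimation=decimation,
            n_sensors=out_shape[0] * out_shape[1],
            out_shape=out_shape,
            pitch_mm=pitch * block,
            frequency_hz=freq,
            frequency_label=label,
        )


def block_pool(frame: PressureFrame, k: int) -> PressureFrame:
    """Pool non-overlapping k x k blocks into their arithmetic mean.

    Output cell (I, J) is the mean of input rows [I*k, (I+1)*k) and
    columns [J*k, (J+1)*k); trailing rows/columns beyond the last full
    block are discarded.  The output pitch is k times the input pitch.
    Pooled means may legitimately fall below the sensor floor, so the
    result carries ``floored=False`` and is never re-floored.
    """
    if k < 1:
        raise ValidationError(f"block factor must be >= 1, got {k}")
    rows, cols = frame.shape
    if k > rows or k > cols:
        raise ValidationError(
            f"block factor {k} exceeds frame dimension {frame.shape}"
        )
    if k == 1:
        return frame
    out_rows, out_cols = rows // k, cols // k
    cropped = frame.values[: out_rows * k, : out_cols * k]
    pooled = cropped.reshape(out_rows, k, out_cols, k).mean(axis=(1, 3))
    return PressureFrame(
        pooled,
        pitch=frame.pitch * k,
        floor=frame.floor,
        ceiling=frame.ceiling,
        floored=False,
    )


def pool_sequence(seq: FrameSequence, k: int) -> FrameSequence:
    """Apply :func:`block_pool` to every frame of a sequence."""
    if k == 1:
        return seq
    return replace(seq, frames=tuple(block_pool(f, k) for f in seq.frames))


def decimate(seq: FrameSequence, n: int) -> FrameSequence:
    """Keep frames at indices 0, n, 2n, ...; divide the frequency by n.

    Ground-truth ``event_times`` are continuous-time and pass through
    unchanged; ``posture_labels`` are subset with the frames.  Events
    beyond the shortened recorded span are dropped (an event between the
    last kept frame and the original end of the recording can no longer be
    expressed within the sequence's time span).
    """
    if n < 1:
        raise ValidationError(f"decimation factor must be >= 1, got {n}")
    if n == 1:
        return seq
    frames = seq.frames[::n]
    labels = seq.posture_labels[::n]
    frequency = seq.frequency / n
    t_max = (len(frames) - 1) / frequency
    events = tuple(t for t in seq.event_times if t <= t_max)
    return replace(
        seq,
        frames=frames,
        posture_labels=labels,
        frequency=frequency,
        event_times=events,
    )


def enumerate_configurations(
    rows: int = 118,
    cols: int = 48,
    pitch: float = 15.9,
    source_frequency: float = 1.0,
    blocks: tuple[int, ...] = BLOCK_FACTORS,
    decimations: tuple[int, ...] = DECIMATION_FACTORS,
) -> list[Configuration]:
    """The full spatial x temporal configuration grid (5 x 5 = 25 cells
    for the default factors)."""
    if rows < max(blocks) or cols < max(blocks):
        raise ValidationError(
            f"grid {rows}x{cols} too small for block factor {max(blocks)}"
        )
    return [
        Configuration.make(k, n, rows, cols, pitch, source_frequency)
        for k in blocks
        for n in decimations
    ]
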