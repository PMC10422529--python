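"""Scalar pressure parameters extracted per frame.

Seven parameters summarize each pressure distribution: the center of
pressure along the longitudinal and transverse axes (mm), contact area at
the 5, 10 and 20 mmHg thresholds (cm^2), peak pressure (mmHg) and peak
pressure gradient (mmHg), the maximum pressure difference between adjacent
sensing cells.  Applied frame-by-frame they turn a sequence into seven
time series whose first differences carry the postural-change signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frames import (
    PARAMETER_NAMES,
    FrameSequence,
    NoContactError,
    ParameterSeries,
    PressureFrame,
    ValidationError,
)


def cop(frame: PressureFrame) -> tuple[float, float]:
    """Center of pressure: the pressure-weighted centroid of the
    distribution, as (longitudinal, transverse) in mm.

    Each cell's pressure weights its physical center ((i + 0.5) * pitch,
    (j + 0.5) * pitch).  Undefined on an all-zero frame
    (:class:`NoContactError`), never silently 0.
    """
    total = frame.values.sum()
    if total <= 0:
        raise NoContactError("COP undefined: no cell registers pressure")
    longitudinal, transverse = frame.cell_centers()
    row_mass = frame.values.sum(axis=1)
    col_mass = frame.values.sum(axis=0)
    return (
        float(np.dot(row_mass, longitudinal) / total),
        float(np.dot(col_mass, transverse) / total),
    )


def contact_count(frame: PressureFrame, threshold: float) -> int:
    """Number of cells at or above ``threshold`` mmHg (inclusive)."""
    if threshold < 0:
        raise ValidationError(f"threshold must be nonnegative, got {threshold}")
    return int(np.count_nonzero(frame.values >= threshold))


def contact_area(frame: PressureFrame, threshold: float) -> float:
    """Contact area in cm^2: cells at or above ``threshold`` mmHg times
    the physical cell area (pitch/10)^2.

    Using physical area keeps values comparable across spatial
    resolutions, where a pooled cell covers k^2 times the native area;
    :func:`contact_count` gives the raw cell count.
    """
    cell_area_cm2 = (frame.pitch / 10.0) ** 2
    return contact_count(frame, threshold) * cell_area_cm2


def peak_pressure(frame: PressureFrame) -> float:
    """Maximum cell pressure, mmHg (0 for an all-zero frame)."""
    return float(frame.values.max())


def peak_pressure_gradient(frame: PressureFrame, per_mm: bool = False) -> float:
    """Maximum absolute pressure difference between 4-neighbour adjacent
    cells, mmHg.

    ``per_mm=True`` divides by the pitch, giving mmHg/mm - useful when
    comparing grids of different pitch; the default raw difference per
    cell step is the conventional definition.
    """
    rows, cols = frame.shape
    if rows * cols < 2:
        raise ValidationError("gradient undefined on a single-cell frame")
    v = frame.values
    best = 0.0
    if rows > 1:
        best = max(best, float(np.abs(np.diff(v, axis=0)).max()))
    if cols > 1:
        best = max(best, float(np.abs(np.diff(v, axis=1)).max()))
    return best / frame.pitch if per_mm else best


def extract_all(seq: FrameSequence) -> list[ParameterSeries]:
    """Extract the seven parameter series from a sequence.

    Returns, in canonical order: cop_long, cop_trans, contact_area_5,
    contact_area_10, contact_area_20, peak_pressure, peak_gradient.
    All-zero frames yield NaN in the COP series (and 0 elsewhere); the
    missing value propagates downstream.
    """
    if len(seq) == 0:
        raise ValidationError("cannot extract parameters from an empty sequence")
    n = len(seq)
    out = {name: np.empty(n) for name in PARAMETER_NAMES}
    for t, frame in enumerate(seq.frames):
        try:
            c_long, c_trans = cop(frame)
        except NoContactError:
            c_long = c_trans = np.nan
        out["cop_long"][t] = c_long
        out["cop_trans"][t] = c_trans
        out["contact_area_5"][t] = contact_area(frame, 5.0)
        out["contact_area_10"][t] = contact_area(frame, 10.0)
        out["contact_area_20"][t] = contact_area(frame, 20.0)
        out["peak_pressure"][t] = peak_pressure(frame)
        out["peak_gradient"][t] = peak_pressure_gradient(frame)
    return [
        ParameterSeries(name=name, values=out[name], frequency=seq.frequency)
        for name in PARAMETER_NAMES
    ]


def parameters_frame(seq: FrameSequence) -> pd.DataFrame:
    """Tidy long-format table of all parameters: columns
    ``time_s, parameter, value, units``."""
    rows = []
    for series in extract_all(seq):
        times = series.times()
        for t, v in zip(times, series.values):
            rows.append(
                {
                    "time_s": float(t),
                    "parameter": series.name,
                    "value": float(v),
                    "units": series.units,
                }
            )
    return pd.DataFrame(rows, columns=["time_s", "parameter", "value", "units"])
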