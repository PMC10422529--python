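"""Postural-change event discrimination by ROC/AUC.

A postural change shows up as a peak in the first difference of a pressure
parameter series: within a static posture consecutive samples differ only
by sensor noise, while a movement shifts the distribution and produces a
large step.  The magnitude of the per-sample difference is therefore used
as a score for "a movement happened here", and its ability to separate
true event windows from quiet samples is summarized by the area under the
ROC curve, computed with the tie-aware Mann-Whitney formulation (each
(positive, negative) score pair contributes 1 if the positive scores
higher, 0.5 on a tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .frames import (
    PARAMETER_NAMES,
    FrameSequence,
    ParameterSeries,
    ValidationError,
)
from .parameters import extract_all
from .resample import Configuration, pool_sequence

#: Default half-width (s) of the positive window around a ground-truth
#: event: half the default simulated transition duration, so the window
#: covers exactly the frames whose differences straddle the movement.
DEFAULT_EVENT_HALF_WINDOW_S = 2.5


@dataclass(frozen=True)
class DerivativeSeries:
    """Absolute first differences of a parameter series.

    ``magnitudes[t] = |x[t+1] - x[t]|`` (per sample pair, not per second),
    stamped at the midpoint time of the pair.  Missing parameter values
    (NaN) propagate into both adjacent differences.
    """

    magnitudes: np.ndarray
    times: np.ndarray
    source: str
    frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitudes", np.asarray(self.magnitudes, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.magnitudes.shape != self.times.shape:
            raise ValidationError("magnitudes and times must have equal length")

    def __len__(self) -> int:
        return len(self.magnitudes)


@dataclass(frozen=True)
class RocResult:
    """AUC and the ROC operating points for one score/label set."""

    auc: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (m, 2) array of (false-positive rate, sensitivity)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")


def derivative(series: ParameterSeries) -> DerivativeSeries:
    """Per-sample absolute first difference of a parameter series."""
    if len(series) < 2:
        raise ValidationError("derivative needs a series of length >= 2")
    values = series.values
    magnitudes = np.abs(np.diff(values))
    t = series.times()
    midpoints = (t[:-1] + t[1:]) / 2.0
    return DerivativeSeries(
        magnitudes=magnitudes,
        times=midpoints,
        source=series.name,
        frequency=series.frequency,
    )


def label_samples(
    deriv: DerivativeSeries,
    event_times: tuple[float, ...] | list[float],
    tolerance: float | None = None,
) -> np.ndarray:
    """Binary ground truth per derivative sample.

    Sample ``t`` is positive iff ``|times[t] - e| <= tolerance`` for some
    ground-truth event ``e``.  The default tolerance is
    ``max(DEFAULT_EVENT_HALF_WINDOW_S, one sample interval)`` - wide
    enough to cover the movement at the native rate, and at least one
    inter-sample gap when the series has been decimated below that.
    """
    if tolerance is not None and tolerance < 0:
        raise ValidationError("tolerance must be nonnegative")
    events = np.asarray(sorted(event_times), dtype=float)
    if events.size == 0:
        raise ValidationError("no ground-truth events: labelling is degenerate")
    dt = 1.0 / deriv.frequency
    if tolerance is None:
        tolerance = max(DEFAULT_EVENT_HALF_WINDOW_S, dt)
    lo, hi = deriv.times[0] - dt / 2.0, deriv.times[-1] + dt / 2.0
    for e in events:
        if not (lo <= e <= hi):
            raise ValidationError(
                f"event at {e} s outside the recorded span [{lo}, {hi}] s"
            )
    dist = np.min(np.abs(deriv.times[:, None] - events[None, :]), axis=1)
    return (dist <= tolerance).astype(int)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Tie-aware Mann-Whitney AUC plus the ROC operating points.

    AUC = (number of (positive, negative) pairs with the positive scoring
    strictly higher, plus half the tied pairs) / (n_pos * n_neg) -
    equivalently a normalized rank-sum.  The curve is the threshold sweep
    over the distinct scores, from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    if np.any(~np.isfinite(scores)):
        raise ValidationError("scores must be finite (drop missing values first)")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"need both classes to compute AUC (n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = rankdata(scores)  # average ranks handle ties with weight 0.5
    rank_sum_pos = float(ranks[labels == 1].sum())
    auc = (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        auc=float(auc), n_pos=n_pos, n_neg=n_neg, curve=np.column_stack([fpr, tpr])
    )


def scores_and_labels(
    seq: FrameSequence,
    block: int = 1,
    decimation: int = 1,
    tolerance: float | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Derivative scores and event labels per parameter for one sequence
    at one configuration.

    Missing values (COP on no-contact frames) are dropped pairwise.
    Decimation is applied to the extracted series, which is equivalent to
    decimating the frames first.
    """
    pooled = pool_sequence(seq, block)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for series in extract_all(pooled):
        if decimation > 1:
            series = ParameterSeries(
                name=series.name,
                values=series.values[::decimation],
                frequency=series.frequency / decimation,
            )
        deriv = derivative(series)
        labels = label_samples(deriv, seq.event_times, tolerance=tolerance)
        keep = np.isfinite(deriv.magnitudes)
        out[series.name] = (deriv.magnitudes[keep], labels[keep])
    return out


def auc_grid(
    cohort: list[FrameSequence],
    configs: list[Configuration] | None = None,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """AUC for every parameter x configuration, pooled over a cohort.

    Derivative samples and their labels are pooled across all subjects of
    the cohort before a single AUC is computed per cell (one grand AUC,
    matching a single-value-per-cell report).  Returns a tidy table with
    columns ``regime, parameter, block, n_sensors, frequency_hz,
    frequency_label, auc, n_pos, n_neg``.
    """
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    rows_native, cols_native = cohort[0].shape
    if configs is None:
        from .resample import enumerate_configurations

        configs = enumerate_configurations(
            rows_native, cols_native, cohort[0].pitch, cohort[0].frequency
        )
    regime = cohort[0].mattress

    by_block: dict[int, list[Configuration]] = {}
    for cfg in configs:
        by_block.setdefault(cfg.block, []).append(cfg)

    records = []
    for block, block_cfgs in sorted(by_block.items()):
        # extract once per sequence at this spatial resolution, then
        # subsample the series for each temporal factor
        extracted = [extract_all(pool_sequence(seq, block)) for seq in cohort]
        for cfg in block_cfgs:
            n = cfg.decimation
            pooled_scores: dict[str, list[np.ndarray]] = {p: [] for p in PARAMETER_NAMES}
            pooled_labels: dict[str, list[np.ndarray]] = {p: [] for p in PARAMETER_NAMES}
            for seq, series_list in zip(cohort, extracted):
                for series in series_list:
                    if n > 1:
                        series = ParameterSeries(
                            name=series.name,
                            values=series.values[::n],
                            frequency=series.frequency / n,
                        )
                    deriv = derivative(series)
                    labels = label_samples(deriv, seq.event_times, tolerance=tolerance)
                    keep = np.isfinite(deriv.magnitudes)
                    pooled_scores[series.name].append(deriv.magnitudes[keep])
                    pooled_labels[series.name].append(labels[keep])
            for name in PARAMETER_NAMES:
                scores = np.concatenate(pooled_scores[name])
                labels = np.concatenate(pooled_labels[name])
                result = roc_auc(scores, labels)
                records.append(
                    {
                        "regime": regime,
                        "parameter": name,
                        "block": cfg.block,
                        "n_sensors": cfg.n_sensors,
                        "frequency_hz": cfg.frequency_hz,
                        "frequency_label": cfg.frequency_label,
                        "auc": result.auc,
                        "n_pos": result.n_pos,
                        "n_neg": result.n_neg,
                    }
                )
    return pd.DataFrame.from_records(records)
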