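"""Synthetic labelled pressure-frame sequences.

No public recordings of body-mattress interface pressure exist for this
analysis, so the package ships a generator that emulates the statistical
structure the pipeline assumes: posture-specific pressure images on two
immersion regimes, scripted postural transitions, additive sensor noise,
and the 5-200 mmHg reporting rule.

The body is a set of weighted landmarks (head, two scapulae, sacrum, two
heels) rendered as isotropic 2-D Gaussian pressure bumps on the mat.  This
is deliberately the simplest model that produces the features the analysis
measures: posture-dependent center-of-pressure shifts, contact-area changes
and pressure gradients.  A lying posture is a per-landmark translation and
load re-weighting; a mattress's immersion behaviour is a pair of scalars
(bump spread multiplier, peak attenuation) - more immersion (air) spreads
load over a larger contact area with lower peaks than foam.

Postural transitions are linear cross-fades between the two static renders
over a fixed ``transition_duration``, plus a transient movement artifact:
repositioning in bed involves briefly pushing off with an arm or hip, which
concentrates load into a small, high-pressure contact that rises and falls
within the movement.  The artifact is a sharp Gaussian bump whose amplitude
follows sin(pi * w) across the cross-fade, so it peaks at the event midpoint
and vanishes at the segment boundaries.  This transient is what makes high
sampling rates genuinely more informative than slow ones: a sampler that
only sees the before/after states observes the net change, while a 1 Hz
sampler also sees the movement itself.  The ground-truth event time of each
movement is the cross-fade midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .frames import (
    NATIVE_FREQUENCY_HZ,
    NATIVE_PITCH_MM,
    NATIVE_SHAPE,
    PRESSURE_CEILING_MMHG,
    PRESSURE_FLOOR_MMHG,
    TRANSITION_LABEL,
    FrameSequence,
    PressureFrame,
    ValidationError,
    apply_sensor_range,
)

#: Postures the simulator can render.  ``lateral_left``/``lateral_right``
#: both carry the ground-truth label ``lateral``.
SIM_POSTURES = ("supine", "high_sitting", "lateral_left", "lateral_right")


@dataclass(frozen=True)
class Landmark:
    """One load-bearing anatomical site.

    ``longitudinal`` is the offset from the head end as a fraction of body
    length; ``transverse`` the signed offset from the body midline in mm;
    ``weight`` the dimensionless share of load; ``spread`` the Gaussian
    sigma of the pressure bump in mm.
    """

    name: str
    longitudinal: float
    transverse: float
    weight: float
    spread: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.longitudinal <= 1.0):
            raise ValidationError(
                f"landmark {self.name}: longitudinal fraction {self.longitudinal}"
                " outside [0, 1]"
            )
        if self.weight <= 0 or self.spread <= 0:
            raise ValidationError(
                f"landmark {self.name}: weight and spread must be positive"
            )


@dataclass(frozen=True)
class BodyModel:
    """A supine body as weighted pressure-bump landmarks.

    ``total_load`` sets the pressure scale: a landmark's noise-free peak
    pressure is ``total_load * weight`` mmHg (before immersion
    attenuation).  The default body produces a sacral peak of ~66 mmHg on
    the low-immersion regime, typical of supine lying on foam.
    """

    landmarks: tuple[Landmark, ...]
    body_length: float = 1720.0
    total_load: float = 30.0

    def __post_init__(self) -> None:
        if not self.landmarks:
            raise ValidationError("body must have at least one landmark")
        if self.body_length <= 0 or self.total_load <= 0:
            raise ValidationError("body_length and total_load must be positive")

    @staticmethod
    def default(
        body_length: float = 1720.0, total_load: float = 30.0
    ) -> "BodyModel":
        return BodyModel(
            landmarks=(
                Landmark("head", 0.06, 0.0, 0.8, 60.0),
                Landmark("scapula_left", 0.22, -75.0, 1.2, 80.0),
                Landmark("scapula_right", 0.22, 75.0, 1.2, 80.0),
                Landmark("sacrum", 0.52, 0.0, 2.2, 95.0),
                Landmark("heel_left", 0.93, -55.0, 0.5, 45.0),
                Landmark("heel_right", 0.93, 55.0, 0.5, 45.0),
            ),
            body_length=body_length,
            total_load=total_load,
        )


@dataclass(frozen=True)
class ImmersionModel:
    """How far the body sinks into the support surface.

    The air regime immerses more than foam: load spreads over a larger
    contact area (``spread_multiplier`` > 1) with attenuated peaks
    (``peak_attenuation`` < 1).
    """

    regime: str = "foam"
    spread_multiplier: float = 1.0
    peak_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.spread_multiplier < 1.0:
            raise ValidationError("spread_multiplier must be >= 1")
        if not (0.0 < self.peak_attenuation <= 1.0):
            raise ValidationError("peak_attenuation must be in (0, 1]")

    @staticmethod
    def foam() -> "ImmersionModel":
        return ImmersionModel("foam", 1.0, 1.0)

    @staticmethod
    def air() -> "ImmersionModel":
        return ImmersionModel("air", 1.4, 0.8)

    @staticmethod
    def for_regime(regime: str) -> "ImmersionModel":
        if regime == "foam":
            return ImmersionModel.foam()
        if regime == "air":
            return ImmersionModel.air()
        raise ValidationError(f"unknown immersion regime {regime!r}")


# Free parameters of the posture templates, exposed for configuration.
HIGH_SITTING_CAUDAL_SHIFT = {"head": 0.24, "scapula": 0.18, "sacrum": 0.03}
HIGH_SITTING_REWEIGHT = {"head": 0.5, "scapula": 0.5, "sacrum": 1.6, "heel": 1.0}
LATERAL_SHIFT_FRACTION = 0.20  # transverse COP shift, fraction of mat width
LATERAL_LOADED_REWEIGHT = 1.3
LATERAL_UNLOADED_REWEIGHT = 0.3
LATERAL_SPREAD_MULTIPLIER = 0.85


def _site(name: str) -> str:
    for key in ("head", "scapula", "sacrum", "heel"):
        if name.startswith(key):
            return key
    return name


@dataclass(frozen=True)
class PostureTemplate:
    """Per-landmark translation and load re-weighting for one posture.

    Templates are constructed by :meth:`for_posture`; the stored transform
    is an explicit per-landmark (longitudinal shift fraction, transverse
    shift mm, weight factor, spread factor) table so that rendered frames
    are a pure function of (body, template, immersion).
    """

    posture: str
    shifts: tuple[tuple[float, float, float, float], ...]

    @property
    def label(self) -> str:
        """Ground-truth posture label (folds lateral sides together)."""
        return "lateral" if self.posture.startswith("lateral") else self.posture

    def apply(self, body: BodyModel, mat_width: float) -> tuple[Landmark, ...]:
        out = []
        for lm, (dlong, dtrans, wfac, sfac) in zip(body.landmarks, self.shifts):
            out.append(
                Landmark(
                    lm.name,
                    lm.longitudinal + dlong,
                    lm.transverse + dtrans,
                    lm.weight * wfac,
                    lm.spread * sfac,
                )
            )
        return tuple(out)

    @staticmethod
    def for_posture(
        posture: str, body: BodyModel, mat_width: float = NATIVE_SHAPE[1] * NATIVE_PITCH_MM
    ) -> "PostureTemplate":
        """Build the template for ``posture`` given a body and mat width.

        supine
            Identity.
        high_sitting
            Head of bed raised: cranial landmarks slide caudally and shed
            load onto the sacral/ischial region.
        lateral_left / lateral_right
            Whole-body transverse shift of ``LATERAL_SHIFT_FRACTION`` of
            the mat width; landmarks on the supporting side take more
            load, the opposite side unloads, and bumps narrow (side lying
            presents a smaller contact surface).  The two sides are exact
            mirror images.
        """
        if posture not in SIM_POSTURES:
            raise ValidationError(f"unknown posture {posture!r}")
        shifts = []
        if posture == "supine":
            shifts = [(0.0, 0.0, 1.0, 1.0)] * len(body.landmarks)
        elif posture == "high_sitting":
            for lm in body.landmarks:
                site = _site(lm.name)
                shifts.append(
                    (
                        HIGH_SITTING_CAUDAL_SHIFT.get(site, 0.0),
                        0.0,
                        HIGH_SITTING_REWEIGHT.get(site, 1.0),
                        1.0,
                    )
                )
        else:
            sign = -1.0 if posture == "lateral_left" else 1.0
            shift = sign * LATERAL_SHIFT_FRACTION * mat_width
            for lm in body.landmarks:
                if lm.transverse * sign > 0:
                    wfac = LATERAL_LOADED_REWEIGHT
                elif lm.transverse * sign < 0:
                    wfac = LATERAL_UNLOADED_REWEIGHT
                else:
                    wfac = 1.0
                shifts.append((0.0, shift, wfac, LATERAL_SPREAD_MULTIPLIER))
        return PostureTemplate(posture=posture, shifts=tuple(shifts))


@dataclass(frozen=True)
class SimulationScript:
    """Ordered (posture, duration s) segments with a fixed cross-fade
    duration between consecutive segments."""

    segments: tuple[tuple[str, float], ...]
    transition_duration: float = 5.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("script must contain at least one segment")
        for posture, dur in self.segments:
            if posture not in SIM_POSTURES:
                raise ValidationError(f"unknown posture {posture!r} in script")
            if dur <= 0:
                raise ValidationError("segment durations must be positive")
        if self.transition_duration <= 0:
            raise ValidationError("transition_duration must be positive")

    @staticmethod
    def default(segment_duration: float = 60.0, transition_duration: float = 5.0
                ) -> "SimulationScript":
        """The study protocol: supine, high sitting, supine again, lateral."""
        return SimulationScript(
            segments=(
                ("supine", segment_duration),
                ("high_sitting", segment_duration),
                ("supine", segment_duration),
                ("lateral_right", segment_duration),
            ),
            transition_duration=transition_duration,
        )

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments) + self.transition_duration * (
            len(self.segments) - 1
        )


def render_static_frame(
    body: BodyModel,
    posture: PostureTemplate | str,
    immersion: ImmersionModel,
    shape: tuple[int, int] = NATIVE_SHAPE,
    pitch: float = NATIVE_PITCH_MM,
) -> PressureFrame:
    """Render the noise-free pressure image of one static posture.

    The frame is a sum of isotropic Gaussian bumps, one per landmark, with
    peak height ``total_load * weight * peak_attenuation`` and sigma
    ``spread * spread_multiplier``, evaluated at cell centers; the sensor
    reporting rule (values < floor read 0, saturation at the ceiling) is
    then applied.  Deterministic - no noise is added here.
    """
    if isinstance(posture, PostureTemplate):
        posture = posture.posture
    values = _render_raw(body, posture, immersion, shape, pitch, validate=True)
    return PressureFrame(apply_sensor_range(values), pitch=pitch)


def simulate_sequence(
    body: BodyModel,
    immersion: ImmersionModel,
    script: SimulationScript | None = None,
    frequency: float = NATIVE_FREQUENCY_HZ,
    noise_sd: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = NATIVE_SHAPE,
    pitch: float = NATIVE_PITCH_MM,
    subject: str = "s00",
    artifact_weight: float = 2.5,
    artifact_spread: float = 30.0,
    artifact_offset: float = 150.0,
) -> FrameSequence:
    """Simulate one recording following ``script``.

    Within a segment each frame is the posture's static render plus i.i.d.
    Gaussian sensor noise (sd ``noise_sd`` mmHg, the array's stated
    accuracy); during a transition the two renders are linearly
    cross-faded and a transient push-off bump is added, peaking at the
    fade midpoint (amplitude ``artifact_weight * total_load`` mmHg before
    immersion attenuation, sigma ``artifact_spread`` mm, offset
    ``artifact_offset`` mm to one side of the body midline at the hips;
    ``artifact_weight=0`` disables it).  Noise is added and the sensor
    reporting rule applied last.  Ground truth: ``event_times`` are
    cross-fade midpoints and frames within a cross-fade are labelled
    ``transition``.  Fully reproducible from ``seed``.
    """
    if script is None:
        script = SimulationScript.default()
    if frequency <= 0:
        raise ValidationError("frequency must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")

    # noise and cross-fades act on the un-floored physical fields; the
    # sensor reporting rule is applied once, last
    raw: dict[str, np.ndarray] = {}
    for posture in {p for p, _ in script.segments}:
        raw[posture] = _render_raw(body, posture, immersion, shape, pitch, validate=True)

    artifact = np.zeros(shape)
    if artifact_weight > 0:
        rows, cols = shape
        mat_length, mat_width = rows * pitch, cols * pitch
        head_offset = (mat_length - body.body_length) / 2.0
        x0 = head_offset + 0.5 * body.body_length  # push-off near the hips
        y0 = artifact_offset
        longitudinal = (np.arange(rows) + 0.5) * pitch
        transverse = (np.arange(cols) + 0.5) * pitch - mat_width / 2.0
        sigma = artifact_spread * immersion.spread_multiplier
        peak = artifact_weight * body.total_load * immersion.peak_attenuation
        d2 = (longitudinal - x0)[:, None] ** 2 + (transverse - y0)[None, :] ** 2
        artifact = peak * np.exp(-d2 / (2.0 * sigma**2))

    # piecewise timeline: segment_0, fade, segment_1, fade, ...
    bounds = []  # (t_start, t_end, kind, payload)
    t = 0.0
    for idx, (posture, dur) in enumerate(script.segments):
        bounds.append((t, t + dur, "static", posture))
        t += dur
        if idx < len(script.segments) - 1:
            nxt = script.segments[idx + 1][0]
            bounds.append((t, t + script.transition_duration, "fade", (posture, nxt)))
            t += script.transition_duration
    total = t
    n_frames = int(round(total * frequency))

    rng = np.random.default_rng(seed)
    frames: list[PressureFrame] = []
    labels: list[str] = []
    for i in range(n_frames):
        ti = i / frequency
        t0, t1, kind, payload = _locate(bounds, ti)
        if kind == "static":
            base = raw[payload]
            label = PostureTemplate.for_posture(payload, body).label
        else:
            a, b = payload
            w = (ti - t0) / (t1 - t0)
            base = (1.0 - w) * raw[a] + w * raw[b] + np.sin(np.pi * w) * artifact
            label = TRANSITION_LABEL
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=shape)
        frames.append(PressureFrame(apply_sensor_range(base), pitch=pitch))
        labels.append(label)

    event_times = tuple(
        (t0 + t1) / 2.0 for t0, t1, kind, _ in bounds if kind == "fade"
    )
    return FrameSequence(
        frames=tuple(frames),
        frequency=frequency,
        posture_labels=tuple(labels),
        event_times=event_times,
        mattress=immersion.regime,
        subject=subject,
    )


def _render_raw(
    body: BodyModel,
    posture: str,
    immersion: ImmersionModel,
    shape: tuple[int, int],
    pitch: float,
    validate: bool = False,
) -> np.ndarray:
    """Noise-free physical pressure field before the sensor reporting rule."""
    rows, cols = shape
    mat_length, mat_width = rows * pitch, cols * pitch
    template = PostureTemplate.for_posture(posture, body, mat_width)
    head_offset = (mat_length - body.body_length) / 2.0
    if validate and head_offset < 0:
        raise ValidationError(
            f"body length {body.body_length} mm exceeds mat length {mat_length} mm"
        )
    longitudinal = (np.arange(rows) + 0.5) * pitch
    transverse = (np.arange(cols) + 0.5) * pitch - mat_width / 2.0
    values = np.zeros(shape)
    for lm in template.apply(body, mat_width):
        x = head_offset + lm.longitudinal * body.body_length
        y = lm.transverse
        if validate and (not (0.0 <= x <= mat_length) or abs(y) > mat_width / 2.0):
            raise ValidationError(
                f"landmark {lm.name} at ({x:.0f}, {y:.0f}) mm lies off the mat"
            )
        peak = body.total_load * lm.weight * immersion.peak_attenuation
        sigma = lm.spread * immersion.spread_multiplier
        d2 = (longitudinal - x)[:, None] ** 2 + (transverse - y)[None, :] ** 2
        values += peak * np.exp(-d2 / (2.0 * sigma**2))
    return values


def _locate(bounds, t: float):
    for t0, t1, kind, payload in bounds:
        if t0 <= t < t1:
            return t0, t1, kind, payload
    return bounds[-1]


def make_cohort(
    n_subjects: int,
    regime: str = "foam",
    seed: int = 0,
    script: SimulationScript | None = None,
    noise_sd: float = 2.0,
    frequency: float = NATIVE_FREQUENCY_HZ,
    shape: tuple[int, int] = NATIVE_SHAPE,
    pitch: float = NATIVE_PITCH_MM,
) -> list[FrameSequence]:
    """Simulate a cohort of subjects on one mattress regime.

    Per-subject bodies vary in stature and load around the anthropometrics
    of a healthy adult cohort (height ~ N(1.72, 0.08) m truncated to the
    mat, load scale ~ N(30, 5) mmHg truncated at 15), with small random
    transverse landmark offsets.  Every subject performs the same script.
    Bit-reproducible from ``seed``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    immersion = ImmersionModel.for_regime(regime)
    if script is None:
        script = SimulationScript.default()
    rng = np.random.default_rng(seed)
    cohort = []
    mat_length = shape[0] * pitch
    for s in range(n_subjects):
        body_length = float(
            np.clip(rng.normal(1720.0, 80.0), 1500.0, mat_length - 60.0)
        )
        total_load = float(np.clip(rng.normal(30.0, 5.0), 15.0, 60.0))
        base = BodyModel.default(body_length=body_length, total_load=total_load)
        jitter = rng.uniform(-10.0, 10.0, size=len(base.landmarks))
        landmarks = tuple(
            replace(lm, transverse=lm.transverse + float(dj))
            for lm, dj in zip(base.landmarks, jitter)
        )
        body = replace(base, landmarks=landmarks)
        vigor = float(rng.uniform(2.0, 3.0))  # push-off strength varies by subject
        subject_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(
            simulate_sequence(
                body,
                immersion,
                script,
                frequency=frequency,
                noise_sd=noise_sd,
                seed=subject_seed,
                shape=shape,
                pitch=pitch,
                subject=f"s{s:02d}",
                artifact_weight=vigor,
            )
        )
    return cohort
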