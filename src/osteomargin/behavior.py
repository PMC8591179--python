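"""Synthetic surgeon behavior: cut placement, gaze streams, workload, time.

The study's human participants produced four kinds of data — osteotome
plane placements under each guidance condition, gaze event streams from a
wearable eye tracker, NASA-TLX questionnaire responses, and task durations.
This module generates all four from explicit stochastic models so the
analysis pipeline can be exercised end to end.

The cut-placement error model is deliberately minimal: the ideal plane sits
tangent to the tumor at the prescribed margin (10 mm in the study), and the
realized plane is perturbed by a normal offset along the plane normal, a
small tilt, and an in-plane shift, with condition-dependent standard
deviations.  For a spherical tumor and offset-only noise the intratumoral
probability has the closed form  P = Phi(-m / sigma), which
:func:`calibrate_condition_noise` inverts to pin each guidance condition's
noise to its observed intratumoral rate (20.7 / 9.4 / 1.2 / 0 percent for
unguided / AR / IN / AR+IN).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri
from scipy.spatial.transform import Rotation

from .phantom import OsteotomySite
from .segmentation import SignedDistanceField, query_distance

__all__ = [
    "GuidanceCondition",
    "ConditionNoise",
    "CutRecord",
    "GazeStream",
    "TLXResponse",
    "TLX_SUBSCALES",
    "plan_ideal_plane",
    "simulate_cut",
    "calibrate_condition_noise",
    "generate_gaze_stream",
    "generate_tlx",
    "generate_duration",
]

TLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)


class GuidanceCondition(str, enum.Enum):
    """The four guidance arms of the study, in protocol order."""

    UNGUIDED = "Unguided"
    AR = "AR"
    IN = "IN"
    AR_IN = "AR+IN"


@dataclass(frozen=True)
class ConditionNoise:
    """Cut-placement error scales for one guidance condition."""

    offset_sd: float  # mm, along the plane normal (toward/away from tumor)
    tilt_sd_deg: float = 0.0
    inplane_sd: float = 0.0  # mm, along each in-plane axis

    def __post_init__(self) -> None:
        if self.offset_sd < 0 or self.tilt_sd_deg < 0 or self.inplane_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class CutRecord:
    """One simulated osteotomy: who, where, under what guidance, and the pose."""

    surgeon_id: int
    tumor_id: int
    site_id: str
    condition: GuidanceCondition
    origin: tuple[float, float, float]
    longitudinal_axis: tuple[float, float, float]
    normal: tuple[float, float, float]
    duration_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.surgeon_id <= 5:
            raise ValueError(f"surgeon id must be 1-5, got {self.surgeon_id}")
        if not 1 <= self.tumor_id <= 4:
            raise ValueError(f"tumor id must be 1-4, got {self.tumor_id}")
        axis = np.asarray(self.longitudinal_axis, dtype=float)
        normal = np.asarray(self.normal, dtype=float)
        if abs(axis @ normal) > 1e-9:
            raise ValueError("cut longitudinal axis must be orthogonal to the normal")

    def with_duration(self, duration_s: float) -> "CutRecord":
        return replace(self, duration_s=duration_s)


def _region_offsets(
    u: np.ndarray, v: np.ndarray, half_length: float, half_width: float, step: float
) -> np.ndarray:
    su = np.arange(-half_length, half_length + step / 2, step)
    sv = np.arange(-half_width, half_width + step / 2, step)
    return su[:, None, None] * u + sv[None, :, None] * v


def _min_region_distance(
    field: SignedDistanceField,
    origin: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    step: float = 1.0,
) -> float:
    pts = origin + _region_offsets(u, v, 20.0, 10.0, step)
    return float(query_distance(field, pts.reshape(-1, 3)).min())


def plan_ideal_plane(
    site: OsteotomySite,
    field: SignedDistanceField,
    margin_target: float,
    search_range: tuple[float, float] = (-35.0, 25.0),
) -> np.ndarray:
    """Origin of the ideal cut plane: the site's nominal plane slid along its
    normal until the minimum distance of the 4 x 2 cm region to the tumor
    surface equals the margin target (1 cm in the study protocol).
    """
    if margin_target <= 0:
        raise ValueError(f"margin target must be positive, got {margin_target}")
    u = site.longitudinal_axis
    v = np.cross(site.normal, u)

    def gap(t: float) -> float:
        return (
            _min_region_distance(field, site.anchor + t * site.normal, u, v)
            - margin_target
        )

    lo, hi = search_range
    try:
        t_star = brentq(gap, lo, hi, xtol=1e-4)
    except ValueError as exc:
        raise ValueError(
            f"site {site.site_id}: could not place the nominal plane at margin "
            f"{margin_target} mm within offsets {search_range} — site/tumor mismatch"
        ) from exc
    return site.anchor + t_star * site.normal


def simulate_cut(
    site: OsteotomySite,
    field: SignedDistanceField,
    margin_target: float,
    noise: ConditionNoise,
    seed: int,
    condition: GuidanceCondition = GuidanceCondition.UNGUIDED,
    surgeon_id: int = 1,
    tumor_id: int = 1,
    ideal_origin: np.ndarray | None = None,
) -> CutRecord:
    """Place one noisy osteotome plane; deterministic given ``seed``.

    ``ideal_origin`` may be supplied to reuse a previously planned ideal
    plane (it depends only on site, tumor and margin, not on the draw).
    """
    if ideal_origin is None:
        ideal_origin = plan_ideal_plane(site, field, margin_target)
    rng = np.random.default_rng(seed)
    u = np.asarray(site.longitudinal_axis, dtype=float)
    normal = np.asarray(site.normal, dtype=float)
    v = np.cross(normal, u)

    origin = np.asarray(ideal_origin, dtype=float)
    origin = origin + rng.normal(0.0, noise.offset_sd) * normal if noise.offset_sd else origin
    if noise.tilt_sd_deg > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        tilt_axis = np.cos(phi) * u + np.sin(phi) * v
        angle = np.radians(rng.normal(0.0, noise.tilt_sd_deg))
        rot = Rotation.from_rotvec(angle * tilt_axis)
        normal = rot.apply(normal)
        u = rot.apply(u)
    if noise.inplane_sd > 0:
        origin = origin + rng.normal(0.0, noise.inplane_sd) * u
        origin = origin + rng.normal(0.0, noise.inplane_sd) * np.cross(normal, u)

    return CutRecord(
        surgeon_id=surgeon_id,
        tumor_id=tumor_id,
        site_id=site.site_id,
        condition=condition,
        origin=tuple(origin),
        longitudinal_axis=tuple(u),
        normal=tuple(normal),
        seed=seed,
    )


def calibrate_condition_noise(
    target_intratumoral_rate: float,
    margin_target: float,
    zero_rate_sd: float = 1.0,
) -> ConditionNoise:
    """Offset-only noise whose sphere-geometry intratumoral rate is the target.

    With pure offset noise against a spherical tumor, the realized plane
    enters the tumor iff the offset draw falls below ``-margin_target``, so
    P(intratumoral) = Phi(-m / sigma) and  sigma = m / Phi^{-1}(1 - rate).
    A target rate of zero has no finite solution; a configured small sd is
    returned instead.
    """
    if margin_target <= 0:
        raise ValueError("margin target must be positive")
    if not 0 <= target_intratumoral_rate < 0.5:
        raise ValueError(
            f"intratumoral rate must lie in [0, 0.5), got {target_intratumoral_rate} "
            "(rates >= 0.5 would require the ideal plane to sit inside the tumor)"
        )
    if target_intratumoral_rate == 0:
        return ConditionNoise(offset_sd=zero_rate_sd)
    sigma = margin_target / ndtri(1.0 - target_intratumoral_rate)
    return ConditionNoise(offset_sd=float(sigma))


@dataclass(frozen=True)
class GazeStream:
    """Contiguous, non-overlapping gaze events labeled screen or field."""

    events: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("gaze stream must contain at least one event")
        t_prev = 0.0
        for start, end, label in self.events:
            if label not in ("screen", "field"):
                raise ValueError(f"unknown gaze label {label!r}")
            if end <= start:
                raise ValueError(f"event [{start}, {end}] has non-positive duration")
            if abs(start - t_prev) > 1e-9:
                raise ValueError("gaze events must tile [0, total] contiguously")
            t_prev = end

    @property
    def total_duration(self) -> float:
        return self.events[-1][1]


def generate_gaze_stream(
    total_duration: float,
    screen_fraction: float,
    mean_dwell: float = 5.0,
    seed: int = 0,
) -> GazeStream:
    """Alternating-renewal gaze generator with exponential dwells.

    Screen and field dwell means are scaled so the expected screen-time
    fraction equals ``screen_fraction``; the final dwell is truncated to
    cover exactly ``[0, total_duration]``.  ``screen_fraction = 0`` models
    the AR condition, where the monitor is never consulted, and yields a
    single field event (a structural, not sampling, zero).
    """
    if total_duration <= 0:
        raise ValueError("total duration must be positive")
    if not 0 <= screen_fraction <= 1:
        raise ValueError("screen fraction must lie in [0, 1]")
    if screen_fraction == 0:
        return GazeStream(((0.0, total_duration, "field"),))
    if screen_fraction == 1:
        return GazeStream(((0.0, total_duration, "screen"),))

    rng = np.random.default_rng(seed)
    mean_screen = 2.0 * screen_fraction * mean_dwell
    mean_field = 2.0 * (1.0 - screen_fraction) * mean_dwell
    state = "screen" if rng.random() < screen_fraction else "field"
    events: list[tuple[float, float, str]] = []
    t = 0.0
    while t < total_duration:
        dwell = rng.exponential(mean_screen if state == "screen" else mean_field)
        end = min(t + dwell, total_duration)
        if end > t:
            events.append((t, end, state))
        t = end
        state = "field" if state == "screen" else "screen"
    return GazeStream(tuple(events))


@dataclass(frozen=True)
class TLXResponse:
    """One NASA-TLX questionnaire: six subscale ratings on 0-100."""

    mental_demand: float
    physical_demand: float
    temporal_demand: float
    performance: float
    effort: float
    frustration: float

    def __post_init__(self) -> None:
        for name in TLX_SUBSCALES:
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise ValueError(f"TLX subscale {name} = {value} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TLX_SUBSCALES], dtype=float)


def generate_tlx(means, sd: float, seed: int = 0) -> TLXResponse:
    """Truncated-normal TLX draw: normal per subscale, clipped to [0, 100]."""
    means = np.asarray(
        [means[k] for k in TLX_SUBSCALES] if isinstance(means, dict) else means,
        dtype=float,
    )
    if means.shape != (6,):
        raise ValueError("six subscale means required")
    if np.any((means < 0) | (means > 100)):
        raise ValueError("TLX means must lie in [0, 100]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    draws = means if sd == 0 else np.clip(
        np.random.default_rng(seed).normal(means, sd), 0.0, 100.0
    )
    return TLXResponse(*draws)


def generate_duration(mean_s: float, sd: float, seed: int = 0) -> float:
    """Truncated-normal task duration, clipped to be positive."""
    if mean_s <= 0:
        raise ValueError("mean duration must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return float(mean_s)
    return float(max(np.random.default_rng(seed).normal(mean_s, sd), 1e-6))
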