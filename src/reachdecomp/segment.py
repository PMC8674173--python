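"""Movement-element decomposition of body-axis velocity series.

Each 1D velocity series is segmented at its zero-crossings into
movement elements: sub-movements whose samples share a single sign.
Elements smaller than 1 mm or shorter than 5 ms are regarded as
potential sensor noise and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import VelocitySeries

AXES = ("AP", "ML", "RC")

#: exclusion thresholds: strictly-smaller elements are dropped
MIN_DISTANCE_M = 0.001
MIN_DURATION_S = 0.005


@dataclass
class MovementElement:
    """A 1D sub-movement between consecutive velocity zero-crossings."""

    axis: str
    start_index: int
    end_index: int  # half-open [start, end)
    duration_s: float
    signed_distance_m: float
    distance_m: float
    mean_speed_ms: float
    start_time_s: float
    profile: np.ndarray = field(repr=False)
    participant_id: str = ""
    visit_id: str = ""
    hand: str = ""


@dataclass
class ExclusionSummary:
    n_total: int
    n_retained: int
    excluded_duration_fraction: float


def _boundaries(v: np.ndarray) -> list[int]:
    """Element boundary indices (start of each element), excluding 0 and n.

    A sign change between consecutive samples opens a new element at the
    later sample; an exact zero sample closes the element it terminates
    (the zero is its last sample) and the next element opens just after.
    """
    zero_bounds = np.flatnonzero(v == 0.0) + 1
    zero_bounds = zero_bounds[zero_bounds < len(v)]
    flips = np.flatnonzero(v[:-1] * v[1:] < 0.0) + 1
    return sorted(set(zero_bounds.tolist()) | set(flips.tolist()))


def element_metrics(
    profile: np.ndarray,
    start_index: int,
    sampling_rate_hz: float,
    axis: str = "AP",
    **ids,
) -> MovementElement:
    """Compute duration, signed distance and mean speed for one element."""
    n = len(profile)
    if n == 0:
        raise ValueError("empty element profile")
    duration = n / sampling_rate_hz
    if duration <= 0:
        raise ValueError("zero-duration element")
    signed = float(np.trapezoid(profile, dx=1.0 / sampling_rate_hz))
    dist = abs(signed)
    return MovementElement(
        axis=axis,
        start_index=start_index,
        end_index=start_index + n,
        duration_s=duration,
        signed_distance_m=signed,
        distance_m=dist,
        mean_speed_ms=dist / duration,
        start_time_s=start_index / sampling_rate_hz,
        profile=np.asarray(profile, dtype=float),
        **ids,
    )


def segment_axis(
    v: np.ndarray,
    sampling_rate_hz: float,
    axis: str = "AP",
    **ids,
) -> list[MovementElement]:
    """Segment one velocity axis at its zero-crossings.

    Leading/trailing partial lobes are kept; the union of elements
    covers the full series. An all-zero series yields elements of zero
    distance only (removed downstream by the exclusion rule).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return []
    edges = [0] + _boundaries(v) + [len(v)]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            out.append(element_metrics(v[a:b], a, sampling_rate_hz, axis=axis, **ids))
    return out


def apply_exclusion(
    elements: list[MovementElement],
    min_distance_m: float = MIN_DISTANCE_M,
    min_duration_s: float = MIN_DURATION_S,
) -> tuple[list[MovementElement], ExclusionSummary]:
    """Drop elements strictly smaller than 1 mm or shorter than 5 ms."""
    retained = [
        e
        for e in elements
        if not (e.distance_m < min_distance_m or e.duration_s < min_duration_s)
    ]
    total_dur = sum(e.duration_s for e in elements)
    kept_dur = sum(e.duration_s for e in retained)
    frac = 0.0 if total_dur == 0 else (total_dur - kept_dur) / total_dur
    return retained, ExclusionSummary(len(elements), len(retained), frac)


def decompose_velocity(
    vs: VelocitySeries,
    min_distance_m: float = MIN_DISTANCE_M,
    min_duration_s: float = MIN_DURATION_S,
) -> tuple[list[MovementElement], ExclusionSummary]:
    """Segment all three body axes of one recording and apply exclusion."""
    ids = dict(participant_id=vs.participant_id, visit_id=vs.visit_id, hand=vs.hand)
    elements: list[MovementElement] = []
    for col, axis in enumerate(AXES):
        elements.extend(segment_axis(vs.v[:, col], vs.sampling_rate_hz, axis=axis, **ids))
    return apply_exclusion(elements, min_distance_m, min_duration_s)


def elements_to_frame(elements: list[MovementElement]) -> pd.DataFrame:
    """One row per element; profiles are not serialized."""
    return pd.DataFrame(
        [
            dict(
                participant_id=e.participant_id,
                visit_id=e.visit_id,
                hand=e.hand,
                axis=e.axis,
                start_time_s=e.start_time_s,
                duration_s=e.duration_s,
                signed_distance_m=e.signed_distance_m,
                distance_m=e.distance_m,
                mean_speed_ms=e.mean_speed_ms,
            )
            for e in elements
        ]
    )
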