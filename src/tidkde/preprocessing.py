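"""Session preprocessing: trimming, exclusion windows, relative intensity.

Every analysis downstream consumes the per-second *relative intensity*
series: heart rate expressed as a rounded integer percentage of the
athlete's most recently reported maximum (%HRmax).  Each retained sample
counts as exactly one second of dwell time; recording gaps are never
interpolated, so dwell-time accounting cannot invent data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AthleteProfile, EmptyInputError, HRSeries

logger = logging.getLogger(__name__)

#: Hard ceiling on %HRmax: values above this indicate a stale reported
#: maximum and are dropped with a warning rather than allowed to corrupt
#: the density estimates.
MAX_PCT = 120

#: Gaps longer than this (seconds) are recorded in the gap report.
DEFAULT_MAX_GAP_S = 10


@dataclass(frozen=True)
class RelativeIntensitySeries:
    """Ordered integer %HRmax values, one per retained second of a session."""

    session_id: str
    athlete_id: str
    values: np.ndarray  # int64, each in (0, MAX_PCT]
    gap_report: tuple[tuple[int, int], ...] = ()  # (start_s, length_s)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        if values.size == 0:
            raise EmptyInputError(
                f"session {self.session_id!r}: empty intensity series"
            )
        if np.any(values <= 0) or np.any(values > MAX_PCT):
            raise ValueError(f"%HRmax values must lie in (0, {MAX_PCT}]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gap_report", tuple(self.gap_report))

    @property
    def n_seconds(self) -> int:
        return int(self.values.size)


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, ties away from zero (74.5 -> 75)."""
    x = np.asarray(x, dtype=float)
    return (np.floor(np.abs(x) + 0.5) * np.sign(x)).astype(np.int64)


def trim_session(series: HRSeries, start_s: int, end_s: int) -> HRSeries:
    """Keep only samples with ``start_s <= t < end_s``, re-zeroed to the
    new start.

    Used to restrict a raw recording to the actual session extent (warm-up
    button presses and post-session cool-down removed by the operator).
    """
    if start_s >= end_s:
        raise ValueError(f"trim window [{start_s}, {end_s}) is empty")
    if start_s < int(series.t[0]) or end_s > int(series.t[-1]) + 1:
        raise ValueError(
            f"trim window [{start_s}, {end_s}) outside series extent "
            f"[{series.t[0]}, {series.t[-1] + 1})"
        )
    keep = (series.t >= start_s) & (series.t < end_s)
    if not keep.any():
        raise EmptyInputError(
            f"session {series.session_id!r}: trim leaves no samples"
        )
    return HRSeries(
        session_id=series.session_id,
        athlete_id=series.athlete_id,
        t=series.t[keep] - start_s,
        hr=series.hr[keep],
    )


def apply_exclusions(
    series: HRSeries, windows: tuple[tuple[int, int], ...] | list
) -> HRSeries:
    """Drop samples whose timestamp falls inside any ``[start, end)`` window.

    The canonical use is removing the rifle-zeroing block of a shooting
    session.  Remaining timestamps are NOT re-zeroed: the wall-clock gap is
    preserved and dwell time is simply the count of retained seconds.
    """
    windows = sorted((int(a), int(b)) for a, b in windows)
    for a, b in windows:
        if a >= b:
            raise ValueError(f"empty exclusion window [{a}, {b})")
        if a < int(series.t[0]) or b > int(series.t[-1]) + 1:
            raise ValueError(
                f"exclusion window [{a}, {b}) outside series extent"
            )
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1:
            raise ValueError(
                f"overlapping exclusion windows [{a1},{b1}) and [{a2},{b2})"
            )
    if not windows:
        return series
    keep = np.ones(series.n, dtype=bool)
    for a, b in windows:
        keep &= ~((series.t >= a) & (series.t < b))
    if not keep.any():
        raise EmptyInputError(
            f"session {series.session_id!r}: exclusions leave no samples"
        )
    return HRSeries(
        session_id=series.session_id,
        athlete_id=series.athlete_id,
        t=series.t[keep],
        hr=series.hr[keep],
    )


def to_relative_intensity(
    series: HRSeries,
    profile: AthleteProfile,
    max_gap_s: int = DEFAULT_MAX_GAP_S,
) -> RelativeIntensitySeries:
    """Convert a heart-rate series to rounded integer %HRmax dwell units.

    Each value is ``round(100 * hr / hr_max)`` with ties rounded away from
    zero.  Values above :data:`MAX_PCT` (stale reported maximum) are dropped
    with a warning.  Recording gaps longer than ``max_gap_s`` enter the
    gap report; no interpolation is ever performed.
    """
    if profile.hr_max <= 0:
        raise ValueError("hr_max must be positive")
    pct = round_half_away(100.0 * series.hr / profile.hr_max)
    ok = pct <= MAX_PCT
    n_capped = int((~ok).sum())
    if n_capped:
        logger.warning(
            "session %s: dropped %d sample(s) above %d%% HRmax "
            "(check reported hr_max for athlete %s)",
            series.session_id,
            n_capped,
            MAX_PCT,
            series.athlete_id,
        )
    t = series.t[ok]
    pct = pct[ok]
    if pct.size == 0:
        raise EmptyInputError(
            f"session {series.session_id!r}: no samples within %HRmax cap"
        )
    gaps: list[tuple[int, int]] = []
    dt = np.diff(t)
    for idx in np.nonzero(dt > 1)[0]:
        start = int(t[idx]) + 1
        length = int(dt[idx]) - 1
        logger.debug(
            "session %s: %d s recording gap at t=%d",
            series.session_id,
            length,
            start,
        )
        if length > max_gap_s:
            gaps.append((start, length))
    return RelativeIntensitySeries(
        session_id=series.session_id,
        athlete_id=series.athlete_id,
        values=pct,
        gap_report=tuple(gaps),
    )
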