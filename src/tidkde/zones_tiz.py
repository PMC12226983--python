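"""Zone model, time-in-zone accounting and planned-vs-performed comparison.

The default zone model is the Swedish Biathlon Federation's five-zone
%HRmax scheme (Z1 from 54, Z2 from 73, Z3 from 83, Z4 from 88, Z5 from 93),
with everything below the Z1 threshold counted as Zone 0 — sub-aerobic time
that is never prescribed but routinely accumulated, e.g. while shooting.
Intervals are half-open with inclusive lower bounds: Z2 is exactly
[73, 83) %HRmax, and the top zone is unbounded above.

Sessions are dichotomised from the *plan* only: low-intensity (LIT) if all
planned minutes sit in the first two training zones, high-intensity (HIT)
if any planned duration touches the third training zone or higher.  A
moderate-intensity category is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import EmptyInputError, SessionPlan
from .preprocessing import MAX_PCT, RelativeIntensitySeries

DEFAULT_BOUNDS = {"Z1": 54, "Z2": 73, "Z3": 83, "Z4": 88, "Z5": 93}


@dataclass(frozen=True)
class ZoneModel:
    """Ordered zone labels with %HRmax lower bounds for every label but the
    first; the first zone is unbounded below, the last unbounded above."""

    labels: tuple[str, ...] = ("Z0", "Z1", "Z2", "Z3", "Z4", "Z5")
    lower_bounds: tuple[float, ...] = (54, 73, 83, 88, 93)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.lower_bounds) + 1:
            raise ValueError("need one more label than lower bound")
        if np.any(np.diff(self.lower_bounds) <= 0):
            raise ValueError("lower bounds must be strictly increasing")

    @classmethod
    def from_config(cls, zones: dict[str, float]) -> "ZoneModel":
        """Build from a ``{label: lower_bound}`` config block; a ``Z0``-style
        catch-all label is prepended automatically."""
        ordered = sorted(zones.items(), key=lambda kv: kv[1])
        labels = ("Z0",) + tuple(k for k, _ in ordered)
        return cls(labels=labels, lower_bounds=tuple(v for _, v in ordered))

    @property
    def n_zones(self) -> int:
        return len(self.labels)

    def zone_index(self, pct: np.ndarray | float) -> np.ndarray | int:
        """Index of the half-open interval containing each %HRmax value."""
        return np.searchsorted(self.lower_bounds, pct, side="right")

    def zone_of_pct(self, pct: float) -> str:
        """Label of the zone a (steady-state) %HRmax value belongs to."""
        return self.labels[int(self.zone_index(pct))]


DEFAULT_ZONE_MODEL = ZoneModel()


@dataclass(frozen=True)
class TIZResult:
    """Seconds accumulated in each zone of one session; values sum exactly
    to the retained session seconds."""

    session_id: str
    seconds_per_zone: dict[str, int]
    total_seconds: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.seconds_per_zone.values()):
            raise ValueError("negative zone seconds")
        if sum(self.seconds_per_zone.values()) != self.total_seconds:
            raise ValueError("zone seconds do not sum to total")

    def minutes_per_zone(self) -> dict[str, float]:
        return {k: v / 60.0 for k, v in self.seconds_per_zone.items()}


@dataclass(frozen=True)
class SessionClass:
    """Plan-derived session category: LIT/HIT crossed with rifle WR/NR."""

    intensity: str  # "LIT" | "HIT"
    rifle: str  # "WR" | "NR"

    @property
    def label(self) -> str:
        return f"{self.intensity}-{self.rifle}"


def classify_zone(pct: int, model: ZoneModel = DEFAULT_ZONE_MODEL) -> str:
    """Zone label for one integer %HRmax value.

    Lower bounds are inclusive: 73 -> Z2, 93 -> Z5, 53 -> Z0 under the
    default model.
    """
    if not (0 < pct <= MAX_PCT):
        raise ValueError(f"%HRmax value {pct} outside validity range (0, {MAX_PCT}]")
    return model.labels[int(model.zone_index(pct))]


def compute_tiz(
    rel: RelativeIntensitySeries, model: ZoneModel = DEFAULT_ZONE_MODEL
) -> TIZResult:
    """Accumulate retained seconds into zones (each sample = 1 s dwell)."""
    if rel.n_seconds == 0:
        raise EmptyInputError("empty intensity series")
    idx = model.zone_index(rel.values)
    counts = np.bincount(idx, minlength=model.n_zones)
    return TIZResult(
        session_id=rel.session_id,
        seconds_per_zone={
            label: int(c) for label, c in zip(model.labels, counts)
        },
        total_seconds=rel.n_seconds,
    )


def dichotomize_session(
    plan: SessionPlan, model: ZoneModel = DEFAULT_ZONE_MODEL
) -> SessionClass:
    """Derive the LIT/HIT x WR/NR class from the plan alone.

    HIT iff any planned minutes in the third training zone (Z3) or higher
    are positive; performed data never influences the class.
    """
    plan.validate_zones(model.labels)
    if not any(v > 0 for v in plan.planned_tiz.values()):
        raise ValueError(
            f"session {plan.session_id!r}: plan has no positive planned time"
        )
    hit_labels = set(model.labels[3:])
    intensity = (
        "HIT"
        if any(
            minutes > 0
            for label, minutes in plan.planned_tiz.items()
            if label in hit_labels
        )
        else "LIT"
    )
    return SessionClass(intensity=intensity, rifle=plan.rifle)


def compare_planned_performed(
    plan: SessionPlan,
    tiz: TIZResult,
    model: ZoneModel = DEFAULT_ZONE_MODEL,
) -> pd.DataFrame:
    """Per-zone planned vs performed minutes with exact differences.

    Returns a table with one row per zone (Z0 first) and columns
    ``zone, planned_min, performed_min, diff_min, performed_pct``.
    Zone 0 is never planned, so any performed Z0 time appears as unplanned
    (positive ``diff_min``).  The session id travels in ``df.attrs``.
    """
    if plan.session_id != tiz.session_id:
        raise ValueError(
            f"plan is for session {plan.session_id!r} but TIZ is for "
            f"{tiz.session_id!r}"
        )
    performed_min = {
        label: tiz.seconds_per_zone.get(label, 0) / 60.0
        for label in model.labels
    }
    planned_min = {
        label: float(plan.planned_tiz.get(label, 0.0))
        for label in model.labels
    }
    total = tiz.total_seconds / 60.0
    df = pd.DataFrame(
        {
            "zone": list(model.labels),
            "planned_min": [planned_min[z] for z in model.labels],
            "performed_min": [performed_min[z] for z in model.labels],
        }
    )
    df["diff_min"] = df["performed_min"] - df["planned_min"]
    df["performed_pct"] = 100.0 * df["performed_min"] / total
    df.attrs["session_id"] = plan.session_id
    return df
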