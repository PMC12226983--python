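"""Readers and writers for heart-rate recordings, training plans and result tables.

Canonical HR recording format is a two-column CSV with the required header
``t_s,hr_bpm``: elapsed seconds from session start and heart rate in beats
per minute, nominally sampled at 1 Hz.  Garmin TrainingCenterDatabase v2
(TCX) files are supported read-only.  Coach plans and athlete profiles live
in a single YAML document per programme (see :func:`read_plan_file`).

Validation philosophy: implausible heart-rate values (outside the
(20, 260) bpm window, i.e. device dropouts and spikes) are dropped with a
logged count, but *ordering* problems are never silently repaired — a
non-increasing timestamp is an error, not a fix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from lxml import etree

logger = logging.getLogger(__name__)

#: Plausibility window for raw heart-rate samples, bpm (exclusive bounds).
HR_MIN_BPM = 20.0
HR_MAX_BPM = 260.0

#: Plausibility window for a reported maximum heart rate, bpm.
HRMAX_MIN_BPM = 120.0
HRMAX_MAX_BPM = 260.0


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class EmptyInputError(ValueError):
    """Raised when, after validation, no usable samples remain."""


class PlanValidationError(ValueError):
    """Raised when a session plan violates its invariants."""


class HRSample(NamedTuple):
    """One heart-rate sample: elapsed second ``t`` and rate ``hr`` in bpm."""

    t: int
    hr: float


@dataclass(frozen=True)
class HRSeries:
    """An ordered per-second heart-rate recording for one training session.

    Timestamps are elapsed seconds from session start, strictly increasing
    with nominal 1 s spacing; recording gaps are preserved as jumps in ``t``.
    """

    session_id: str
    athlete_id: str
    t: np.ndarray  # int64, strictly increasing, >= 0
    hr: np.ndarray  # float64, within (HR_MIN_BPM, HR_MAX_BPM)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.int64)
        hr = np.asarray(self.hr, dtype=np.float64)
        if t.size == 0:
            raise EmptyInputError(f"session {self.session_id!r}: no samples")
        if t.size != hr.size:
            raise ValueError("t and hr must have equal length")
        if t[0] < 0:
            raise ValueError(f"negative timestamp {t[0]}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = t[1:][dt <= 0][0]
            raise FormatError(
                f"session {self.session_id!r}: timestamps not strictly "
                f"increasing at t={bad}"
            )
        if np.any(hr <= HR_MIN_BPM) or np.any(hr >= HR_MAX_BPM):
            raise ValueError("hr outside plausibility window after validation")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "hr", hr)

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> int:
        """Wall-clock extent in seconds, counting the last sample as 1 s."""
        return int(self.t[-1] - self.t[0] + 1)

    @property
    def samples(self) -> Iterator[HRSample]:
        return (HRSample(int(a), float(b)) for a, b in zip(self.t, self.hr))


@dataclass(frozen=True)
class AthleteProfile:
    """An athlete identifier with their most recently reported maximum HR."""

    athlete_id: str
    hr_max: float

    def __post_init__(self) -> None:
        if not (HRMAX_MIN_BPM < self.hr_max < HRMAX_MAX_BPM):
            raise ValueError(
                f"hr_max={self.hr_max} outside plausible range "
                f"({HRMAX_MIN_BPM}, {HRMAX_MAX_BPM}) bpm"
            )


@dataclass(frozen=True)
class SessionPlan:
    """A coach's prescription for one session.

    ``planned_tiz`` maps zone labels to planned minutes (e.g. ``{"Z1": 90}``
    for a continuous low-intensity session, or ``{"Z4": 20, "Z2": 60}`` for
    an interval session).  Zone 0 is never prescribed.  ``exclusion_windows``
    are half-open ``[start_s, end_s)`` intervals to drop from the recording
    before analysis — typically the rifle-zeroing block.
    """

    session_id: str
    planned_tiz: dict[str, float]
    rifle: str  # "WR" | "NR"
    exclusion_windows: tuple[tuple[int, int], ...] = ()
    total_planned_min: float | None = None
    athlete_id: str | None = None

    def __post_init__(self) -> None:
        if self.rifle not in ("WR", "NR"):
            raise PlanValidationError(
                f"session {self.session_id!r}: rifle flag must be WR or NR, "
                f"got {self.rifle!r}"
            )
        for label, minutes in self.planned_tiz.items():
            if minutes < 0:
                raise PlanValidationError(
                    f"session {self.session_id!r}: negative planned minutes "
                    f"for {label}"
                )
        windows = tuple(
            (int(a), int(b)) for a, b in self.exclusion_windows
        )
        for a, b in windows:
            if a >= b:
                raise PlanValidationError(
                    f"session {self.session_id!r}: empty exclusion window "
                    f"[{a}, {b})"
                )
        ordered = sorted(windows)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise PlanValidationError(
                    f"session {self.session_id!r}: overlapping exclusion "
                    f"windows [{a1},{b1}) and [{a2},{b2})"
                )
        object.__setattr__(self, "exclusion_windows", windows)
        object.__setattr__(self, "planned_tiz", dict(self.planned_tiz))

    def validate_zones(self, labels: Sequence[str]) -> None:
        """Check planned zone labels against the active zone model."""
        for label in self.planned_tiz:
            if label == labels[0]:
                raise PlanValidationError(
                    f"session {self.session_id!r}: {label} is never "
                    "prescribed"
                )
            if label not in labels:
                raise PlanValidationError(
                    f"session {self.session_id!r}: unknown zone label "
                    f"{label!r}"
                )


@dataclass
class PlanDocument:
    """Parsed contents of one programme plan file."""

    plans: list[SessionPlan]
    athletes: dict[str, AthleteProfile]
    zones: dict[str, float] | None = None
    hr_files: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# HR recordings


def read_hr_csv(path: str | Path, session_id: str, athlete_id: str) -> HRSeries:
    """Read a canonical ``t_s,hr_bpm`` CSV into a validated :class:`HRSeries`.

    Rows with non-numeric or implausible heart rate are dropped with a
    logged count; duplicate or decreasing timestamps raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t_s", "hr_bpm"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            "header must contain t_s,hr_bpm"
        )
    t = pd.to_numeric(df["t_s"], errors="coerce")
    hr = pd.to_numeric(df["hr_bpm"], errors="coerce")
    ok = (
        t.notna()
        & hr.notna()
        & (hr > HR_MIN_BPM)
        & (hr < HR_MAX_BPM)
        & (t >= 0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d invalid row(s) (non-numeric or hr outside "
            "(%g, %g) bpm)",
            path,
            n_dropped,
            HR_MIN_BPM,
            HR_MAX_BPM,
        )
    t = t[ok].to_numpy()
    hr = hr[ok].to_numpy()
    if t.size == 0:
        raise EmptyInputError(f"{path}: no valid samples after validation")
    return HRSeries(
        session_id=session_id,
        athlete_id=athlete_id,
        t=np.rint(t).astype(np.int64),
        hr=hr,
    )


def write_hr_csv(series: HRSeries, path: str | Path) -> None:
    """Write an :class:`HRSeries` in the canonical CSV schema."""
    pd.DataFrame({"t_s": series.t, "hr_bpm": series.hr}).to_csv(
        path, index=False, float_format="%.17g"
    )


_TCX_NS = "http://www.garmin.com/xmlschemas/TrainingCenterDatabase/v2"


def read_tcx(
    path: str | Path, athlete_id: str, session_id: str | None = None
) -> HRSeries:
    """Read heart-rate trackpoints from a Garmin TCX file.

    Absolute timestamps are converted to elapsed seconds from the first
    trackpoint; recording gaps are preserved (no interpolation).
    Trackpoints without a heart-rate value are skipped.
    """
    tree = etree.parse(str(path))
    ns = {"t": _TCX_NS}
    times: list[float] = []
    hrs: list[float] = []
    for tp in tree.iter(f"{{{_TCX_NS}}}Trackpoint"):
        time_el = tp.find("t:Time", ns)
        hr_el = tp.find("t:HeartRateBpm/t:Value", ns)
        if time_el is None or hr_el is None or hr_el.text is None:
            continue
        times.append(pd.Timestamp(time_el.text).timestamp())
        hrs.append(float(hr_el.text))
    if not times:
        raise FormatError(f"{path}: no HeartRateBpm trackpoints found")
    t0 = times[0]
    elapsed = np.rint(np.asarray(times) - t0).astype(np.int64)
    return HRSeries(
        session_id=session_id or Path(path).stem,
        athlete_id=athlete_id,
        t=elapsed,
        hr=np.asarray(hrs, dtype=float),
    )


# ---------------------------------------------------------------------------
# Plan documents


def read_plan_file(path: str | Path) -> PlanDocument:
    """Parse a programme plan document (YAML).

    Expected layout::

        zones: {Z1: 54, Z2: 73, Z3: 83, Z4: 88, Z5: 93}   # optional
        athletes:
          A01: {hr_max: 195}
        sessions:
          S001:
            athlete: A01
            rifle: WR
            planned_tiz: {Z1: 90}
            total_planned_min: 90          # optional
            exclusion_windows: [[0, 120]]  # optional
            hr_file: S001.csv              # optional, defaults to <id>.csv

    Zone labels are validated against the configured zone model; planned
    time in the sub-aerobic zone (first label) is a validation error.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sessions" not in doc:
        raise FormatError(f"{path}: plan document must contain 'sessions'")
    zones = doc.get("zones")
    labels: list[str]
    if zones:
        labels = ["Z0"] + sorted(zones, key=lambda k: zones[k])
    else:
        labels = ["Z0", "Z1", "Z2", "Z3", "Z4", "Z5"]
    athletes: dict[str, AthleteProfile] = {}
    for aid, spec in (doc.get("athletes") or {}).items():
        athletes[str(aid)] = AthleteProfile(
            athlete_id=str(aid), hr_max=float(spec["hr_max"])
        )
    plans: list[SessionPlan] = []
    hr_files: dict[str, str] = {}
    for sid, spec in doc["sessions"].items():
        sid = str(sid)
        plan = SessionPlan(
            session_id=sid,
            planned_tiz={
                str(k): float(v)
                for k, v in (spec.get("planned_tiz") or {}).items()
            },
            rifle=str(spec.get("rifle", "NR")),
            exclusion_windows=tuple(
                (int(a), int(b))
                for a, b in (spec.get("exclusion_windows") or [])
            ),
            total_planned_min=(
                float(spec["total_planned_min"])
                if "total_planned_min" in spec
                else None
            ),
            athlete_id=(
                str(spec["athlete"]) if "athlete" in spec else None
            ),
        )
        plan.validate_zones(labels)
        plans.append(plan)
        hr_files[sid] = str(spec.get("hr_file", f"{sid}.csv"))
    return PlanDocument(
        plans=plans, athletes=athletes, zones=zones, hr_files=hr_files
    )


def write_plan_file(doc: PlanDocument, path: str | Path) -> None:
    """Serialize a :class:`PlanDocument` back to YAML (round-trip safe)."""
    out: dict = {}
    if doc.zones is not None:
        out["zones"] = dict(doc.zones)
    out["athletes"] = {
        aid: {"hr_max": prof.hr_max} for aid, prof in doc.athletes.items()
    }
    out["sessions"] = {}
    for plan in doc.plans:
        entry: dict = {
            "rifle": plan.rifle,
            "planned_tiz": dict(plan.planned_tiz),
        }
        if plan.athlete_id is not None:
            entry["athlete"] = plan.athlete_id
        if plan.total_planned_min is not None:
            entry["total_planned_min"] = plan.total_planned_min
        if plan.exclusion_windows:
            entry["exclusion_windows"] = [
                [a, b] for a, b in plan.exclusion_windows
            ]
        if plan.session_id in doc.hr_files:
            entry["hr_file"] = doc.hr_files[plan.session_id]
        out["sessions"][plan.session_id] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Result serialization (gridded KDE matrices; TIZ tables go through pandas)

_FMT = "%.17g"  # full double precision, text round-trip exact


def write_kde2d_text(result, path: str | Path) -> None:
    """Write a 2D KDE result as a plain-text matrix with a self-describing
    header — sufficient to re-render the heatmap bit-identically."""
    lines = [
        "# tidkde kde2d v1",
        f"# h_x={result.h_x!r} h_y={result.h_y!r}",
        f"# x_cap={result.x_cap!r} y_cap={result.y_cap!r}",
        f"# eps_rel={result.eps_rel!r} n_points={result.n_points}",
        "# grid_x " + " ".join(_FMT % v for v in result.grid_x),
        "# grid_y " + " ".join(_FMT % v for v in result.grid_y),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, result.density, fmt=_FMT)
        if result.mask is not None:
            fh.write("# mask\n")
            np.savetxt(fh, result.mask.astype(int), fmt="%d")


def write_kde1d_text(result, path: str | Path) -> None:
    """Write a 1D KDE result as two plain-text columns (grid, density)."""
    with open(path, "w") as fh:
        fh.write("# tidkde kde1d v1\n")
        fh.write(f"# bandwidth={result.bandwidth!r} n={result.n}\n")
        np.savetxt(
            fh, np.column_stack([result.grid, result.density]), fmt=_FMT
        )


def read_kde1d_text(path: str | Path):
    """Inverse of :func:`write_kde1d_text`."""
    from .kde_core import KDE1DResult

    bandwidth = None
    n = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("bandwidth="):
                        bandwidth = float(tok.split("=", 1)[1])
                    elif tok.startswith("n="):
                        n = int(tok.split("=", 1)[1])
                continue
            rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows)
    if arr.ndim != 2 or arr.shape[1] != 2 or bandwidth is None:
        raise FormatError(f"{path}: not a tidkde kde1d file")
    return KDE1DResult(
        grid=arr[:, 0], density=arr[:, 1], bandwidth=bandwidth, n=n
    )


def read_kde2d_text(path: str | Path):
    """Inverse of :func:`write_kde2d_text`."""
    from .kde_core import KDE2DResult  # local import to avoid cycle

    header: dict[str, float] = {}
    grid_x = grid_y = None
    density_rows: list[list[float]] = []
    mask_rows: list[list[int]] = []
    target = density_rows
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("grid_x"):
                    grid_x = np.array(
                        [float(v) for v in body.split()[1:]]
                    )
                elif body.startswith("grid_y"):
                    grid_y = np.array(
                        [float(v) for v in body.split()[1:]]
                    )
                elif body == "mask":
                    target = mask_rows
                else:
                    for tok in body.split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            try:
                                header[k] = float(v)
                            except ValueError:
                                pass
                continue
            target.append([float(v) for v in line.split()])
    if grid_x is None or grid_y is None or not density_rows:
        raise FormatError(f"{path}: not a tidkde kde2d file")
    density = np.asarray(density_rows)
    mask = np.asarray(mask_rows, dtype=bool) if mask_rows else None
    return KDE2DResult(
        grid_x=grid_x,
        grid_y=grid_y,
        density=density,
        h_x=header["h_x"],
        h_y=header["h_y"],
        x_cap=header["x_cap"],
        y_cap=header["y_cap"],
        mask=mask,
        n_points=int(header.get("n_points", 0)),
        eps_rel=header.get("eps_rel"),
    )
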