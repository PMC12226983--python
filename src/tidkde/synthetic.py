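"""Synthetic heart-rate session generator with known ground truth.

Emulates the phenomena that shape real biathlon HR recordings:

* first-order physiological lag — HR approaches the intensity target with
  a single time constant ``tau_s`` (default 30 s, standard HR kinetics);
* terrain-driven oscillation of low-intensity work around the target
  (sinusoidal modulation) plus slow cardiovascular drift;
* interval structure for high-intensity sessions (work blocks reaching
  the upper zones, recoveries back in Zone 1);
* shooting bouts in with-rifle sessions that drop HR below the aerobic
  range (Zone 0), including an initial rifle-zeroing block that the
  matching plan marks for exclusion;
* an additive upward intensity shift when carrying the rifle.

The noise-free target-following trajectory defines the ground truth: zone
dwell shares computed from it are what a perfect analysis should recover.
Observed heart rate is that trajectory plus white measurement noise of
standard deviation ``noise_sd_pct`` (%HRmax), so the noise level is the
actual spread of observations about the dynamic response.

Every generator is seeded; identical seeds give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import AthleteProfile, HRSeries, PlanDocument, SessionPlan
from .preprocessing import round_half_away
from .zones_tiz import DEFAULT_ZONE_MODEL, ZoneModel


@dataclass(frozen=True, kw_only=True)
class SessionSpec:
    """Full parameterisation of one simulated session (all intensities in
    %HRmax)."""

    seed: int
    kind: str = "LIT"  # "LIT" | "HIT"
    rifle: str = "NR"  # "WR" | "NR"
    duration_s: int = 5400
    hr_max: float = 195.0
    target_pct: float = 64.0  # baseline / recovery target
    tau_s: float = 30.0
    terrain_amp_pct: float = 4.0
    terrain_period_s: float = 300.0
    drift_pct_per_hour: float = 2.0
    #: (work_s, rest_s, work_target_pct, rest_target_pct) blocks, executed
    #: in sequence starting at ``interval_start_s`` (HIT sessions).
    intervals: tuple[tuple[int, int, float, float], ...] = ()
    interval_start_s: int = 600
    #: (start_s, length_s, bout_target_pct) shooting bouts (WR sessions).
    shooting_bouts: tuple[tuple[int, int, float], ...] = ()
    #: Rifle-zeroing block [0, zeroing_s) at ``zeroing_target_pct``; the
    #: generated plan carries a matching exclusion window.
    zeroing_s: int = 0
    zeroing_target_pct: float = 45.0
    rifle_offset_pct: float = 3.0
    noise_sd_pct: float = 2.0
    start_pct: float | None = None  # None -> warm-start at target(0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.kind not in ("LIT", "HIT"):
            raise ValueError(f"unknown session kind {self.kind!r}")
        if self.rifle not in ("WR", "NR"):
            raise ValueError(f"rifle must be WR or NR, got {self.rifle!r}")
        targets = [self.target_pct, self.zeroing_target_pct]
        for _, _, wt, rt in self.intervals:
            targets += [wt, rt]
        for _, _, bt in self.shooting_bouts:
            targets.append(bt)
        for v in targets:
            if not (0.0 < v < 120.0):
                raise ValueError(f"intensity target {v} outside (0, 120)")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What a perfect analysis of the noise-free session should find."""

    zone_shares: dict[str, float]  # % of retained time per zone, sums to 100
    cluster_centres: tuple[float, ...]  # steady-state %HRmax levels

    def __post_init__(self) -> None:
        total = sum(self.zone_shares.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"zone shares sum to {total}, expected 100")


@dataclass(frozen=True)
class SimulatedSession:
    series: HRSeries
    plan: SessionPlan
    truth: GroundTruth
    spec: SessionSpec


@dataclass(frozen=True)
class ProgrammeFixture:
    """A bundle of simulated athletes and sessions for one programme."""

    profiles: dict[str, AthleteProfile]
    sessions: tuple[SimulatedSession, ...]
    seed: int


# ---------------------------------------------------------------------------
# Target trajectory and dynamics


def target_trajectory(spec: SessionSpec) -> np.ndarray:
    """Noise-free per-second intensity target in %HRmax.

    Baseline + terrain sinusoid + drift, overridden in order by interval
    blocks and then shooting/zeroing bouts; the rifle offset is added to
    locomotion targets (not to stationary shooting bouts).
    """
    t = np.arange(spec.duration_s, dtype=float)
    offset = spec.rifle_offset_pct if spec.rifle == "WR" else 0.0
    target = (
        spec.target_pct
        + spec.terrain_amp_pct
        * np.sin(2.0 * np.pi * t / spec.terrain_period_s)
        + spec.drift_pct_per_hour * t / 3600.0
        + offset
    )
    cursor = spec.interval_start_s
    for work_s, rest_s, work_pct, rest_pct in spec.intervals:
        target[cursor : cursor + work_s] = work_pct + offset
        cursor += work_s
        target[cursor : cursor + rest_s] = rest_pct + offset
        cursor += rest_s
    bouts = list(spec.shooting_bouts)
    if spec.zeroing_s > 0:
        bouts.insert(0, (0, spec.zeroing_s, spec.zeroing_target_pct))
    for start, length, bout_pct in bouts:
        target[start : start + length] = bout_pct
    return target


def lagged_response(target: np.ndarray, tau_s: float, x0: float) -> np.ndarray:
    """First-order response ``x[t] = x[t-1] + (1/tau)(target[t] - x[t-1])``
    at 1 Hz, started from ``x0`` (which stands in for ``x[-1]``)."""
    alpha = 1.0 / tau_s
    # Equivalent IIR filter: x[t] = alpha*target[t] + (1-alpha)*x[t-1].
    zi = np.array([(1.0 - alpha) * x0])
    x, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], target, zi=zi)
    return x


def _plan_from_spec(
    spec: SessionSpec, session_id: str, athlete_id: str, model: ZoneModel
) -> SessionPlan:
    offset = spec.rifle_offset_pct if spec.rifle == "WR" else 0.0
    retained_s = spec.duration_s - spec.zeroing_s
    work_s = sum(w for w, *_ in spec.intervals)
    planned: dict[str, float] = {}
    if work_s:
        work_zone = model.zone_of_pct(spec.intervals[0][2] + offset)
        planned[work_zone] = planned.get(work_zone, 0.0) + work_s / 60.0
    base_zone = model.zone_of_pct(spec.target_pct + offset)
    planned[base_zone] = (
        planned.get(base_zone, 0.0) + (retained_s - work_s) / 60.0
    )
    windows = ((0, spec.zeroing_s),) if spec.zeroing_s > 0 else ()
    return SessionPlan(
        session_id=session_id,
        planned_tiz=planned,
        rifle=spec.rifle,
        exclusion_windows=windows,
        total_planned_min=retained_s / 60.0,
        athlete_id=athlete_id,
    )


def simulate_session(
    spec: SessionSpec,
    session_id: str = "SIM",
    athlete_id: str = "ATH",
    model: ZoneModel = DEFAULT_ZONE_MODEL,
) -> SimulatedSession:
    """Simulate one session: observed HR series, matching plan and ground
    truth.

    The ground truth is computed by pushing the *noise-free* trajectory
    through the same exclusion and rounding steps the analysis applies, so
    a noise-free simulation is recovered exactly.
    """
    target = target_trajectory(spec)
    x0 = spec.start_pct if spec.start_pct is not None else float(target[0])
    clean = lagged_response(target, spec.tau_s, x0)
    rng = np.random.default_rng(spec.seed)
    observed = clean + rng.normal(0.0, spec.noise_sd_pct, spec.duration_s)
    series = HRSeries(
        session_id=session_id,
        athlete_id=athlete_id,
        t=np.arange(spec.duration_s, dtype=np.int64),
        hr=observed * spec.hr_max / 100.0,
    )
    plan = _plan_from_spec(spec, session_id, athlete_id, model)

    # Ground truth from the noise-free trajectory, post-exclusion.
    keep = np.ones(spec.duration_s, dtype=bool)
    for a, b in plan.exclusion_windows:
        keep[a:b] = False
    rounded = round_half_away(clean[keep])
    idx = model.zone_index(rounded)
    counts = np.bincount(idx, minlength=model.n_zones)
    shares = {
        label: 100.0 * c / counts.sum()
        for label, c in zip(model.labels, counts)
    }
    offset = spec.rifle_offset_pct if spec.rifle == "WR" else 0.0
    if spec.intervals:
        centres = (
            spec.intervals[0][2] + offset,
            spec.intervals[0][3] + offset,
        )
    else:
        centres = (spec.target_pct + offset,)
    truth = GroundTruth(zone_shares=shares, cluster_centres=centres)
    return SimulatedSession(series=series, plan=plan, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Canonical session types


def lit_spec(seed: int, rifle: str = "NR", **overrides) -> SessionSpec:
    """Canonical continuous low-intensity session: 90 min at the Zone 1
    midpoint with terrain oscillation and drift; with-rifle variants add a
    2 min zeroing block and two mid-session shooting bouts."""
    base: dict = dict(
        seed=seed,
        kind="LIT",
        rifle=rifle,
        duration_s=5400,
        target_pct=64.0,
    )
    if rifle == "WR":
        base.update(
            zeroing_s=120,
            shooting_bouts=((2400, 150, 45.0), (4200, 150, 45.0)),
        )
    base.update(overrides)
    return SessionSpec(**base)


def hit_spec(seed: int, rifle: str = "NR", **overrides) -> SessionSpec:
    """Canonical interval session: 10 min warm-up, 5 x (4 min work at the
    Zone 4 midpoint / 3 min recovery in Zone 1), remainder easy — 20 min of
    planned work, 60 min easy, 80 min total."""
    base: dict = dict(
        seed=seed,
        kind="HIT",
        rifle=rifle,
        duration_s=4800,
        target_pct=62.0,
        terrain_amp_pct=2.0,
        intervals=tuple([(240, 180, 90.0, 62.0)] * 5),
        interval_start_s=600,
    )
    if rifle == "WR":
        base.update(
            zeroing_s=120,
            shooting_bouts=((3000, 150, 45.0), (4200, 150, 45.0)),
        )
    base.update(overrides)
    return SessionSpec(**base)


def make_programme_fixture(
    n_athletes: int,
    sessions_per_type: int,
    seed: int,
    unbalanced: bool = False,
    model: ZoneModel = DEFAULT_ZONE_MODEL,
) -> ProgrammeFixture:
    """Simulate a full programme: athletes with distinct maxima, a session
    mix over LIT/HIT x WR/NR.

    With ``unbalanced=True`` each athlete contributes a seeded-random number
    of sessions per type (1..sessions_per_type), exercising the pooling-bias
    caveat of group-level analyses.
    """
    if n_athletes < 1 or sessions_per_type < 1:
        raise ValueError("n_athletes and sessions_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    hr_maxes = rng.choice(
        np.arange(185, 185 + max(30, n_athletes)), size=n_athletes,
        replace=False,
    )
    profiles = {
        f"A{i + 1:02d}": AthleteProfile(
            athlete_id=f"A{i + 1:02d}", hr_max=float(hm)
        )
        for i, hm in enumerate(hr_maxes)
    }
    factories = {
        ("LIT", "NR"): lit_spec,
        ("LIT", "WR"): lit_spec,
        ("HIT", "NR"): hit_spec,
        ("HIT", "WR"): hit_spec,
    }
    sessions: list[SimulatedSession] = []
    counter = 0
    for aid in profiles:
        for (kind, rifle), factory in factories.items():
            k = (
                int(rng.integers(1, sessions_per_type + 1))
                if unbalanced
                else sessions_per_type
            )
            for _ in range(k):
                counter += 1
                child_seed = int(rng.integers(0, 2**31 - 1))
                jitter = float(rng.uniform(-1.5, 1.5))
                spec = factory(
                    seed=child_seed,
                    rifle=rifle,
                    hr_max=profiles[aid].hr_max,
                    target_pct=(64.0 if kind == "LIT" else 62.0) + jitter,
                )
                sessions.append(
                    simulate_session(
                        spec,
                        session_id=f"S{counter:03d}",
                        athlete_id=aid,
                        model=model,
                    )
                )
    return ProgrammeFixture(
        profiles=profiles, sessions=tuple(sessions), seed=seed
    )


def fixture_to_plan_document(
    fixture: ProgrammeFixture, zones: dict[str, float] | None = None
) -> PlanDocument:
    """Express a programme fixture as a plan document plus HR file names,
    ready to be written through the IO layer."""
    return PlanDocument(
        plans=[s.plan for s in fixture.sessions],
        athletes=dict(fixture.profiles),
        zones=zones,
        hr_files={
            s.plan.session_id: f"{s.plan.session_id}.csv"
            for s in fixture.sessions
        },
    )
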