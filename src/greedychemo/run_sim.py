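"""Quasistatic event-driven simulator of greedy cell trajectories.

A trajectory is a chain of straight "runs": after each cue absorption
the cell instantaneously reorients along the arrival direction and flies
at constant speed until the next absorption.  Because the cue density is
treated as instantaneously equilibrated (quasistatic approximation,
valid for D/(a v) >> 1), the polar angle of each arrival follows the
closed-form angular law and the run duration follows the inhomogeneous
Poisson law with rate alpha*a/distance(t).  No particles are simulated;
runs are drawn directly by exact inverse-transform sampling.

Geometric convention: ``phi`` is the angle at the cell centre between
the direction of the absorbed cue (= direction of subsequent motion) and
the direction to the source.  A run at angle phi changes the distance by
``sqrt(rs**2 + (v dt)**2 - 2 rs v dt cos phi) - rs``.  Runs that would
carry the cell surface through the source (possible when
rs*sin(phi) <= a with cos(phi) > 0) are truncated at the first crossing
time and the trajectory terminates at the source; runs crossing the
outer cut-off radius Rc are truncated there (cell deemed lost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import analytic
from .model import ModelParams

__all__ = [
    "RunEvent",
    "Trajectory",
    "sample_run",
    "sample_first_runs",
    "simulate_trajectory",
    "simulate_ensemble",
]

OUTCOME_NONE = "none"
OUTCOME_SOURCE = "source"
OUTCOME_BOUNDARY = "boundary"
OUTCOME_MAX_TIME = "max_time"


@dataclass(frozen=True)
class RunEvent:
    """One straight leg of a trajectory."""

    t_start: float
    rs_start: float
    phi: float
    dt: float
    drs: float
    terminated: str = OUTCOME_NONE


@dataclass
class Trajectory:
    """A full cell trajectory: ordered runs plus its termination cause."""

    seed: int
    params: ModelParams
    r0: float
    events: list[RunEvent] = field(default_factory=list)
    outcome: str = OUTCOME_MAX_TIME
    total_time: float = 0.0

    def distance_at(self, t) -> np.ndarray:
        """Distance to the source at arbitrary times (exact within runs).

        Before the first event the cell sits at r0; after termination the
        terminal distance is held.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.r0)
        v = self.params.v
        for ev in self.events:
            tau = np.clip(t - ev.t_start, 0.0, ev.dt)
            active = t >= ev.t_start
            dist = np.sqrt(
                ev.rs_start**2 + (v * tau) ** 2
                - 2.0 * ev.rs_start * v * tau * math.cos(ev.phi)
            )
            out[active] = dist[active]
        return out

    @property
    def final_distance(self) -> float:
        if not self.events:
            return self.r0
        last = self.events[-1]
        return last.rs_start + last.drs


def _source_crossing_time(rs: float, phi: float, a: float, v: float) -> float | None:
    """Time at which a straight run first touches distance ``a``, if ever."""
    sinphi = math.sin(phi)
    cosphi = math.cos(phi)
    if cosphi <= 0.0 or rs * sinphi > a:
        return None
    disc = a * a - (rs * sinphi) ** 2
    if disc < 0.0:
        return None
    return (rs * cosphi - math.sqrt(disc)) / v


def sample_run(rng: np.random.Generator, rs: float, p: ModelParams,
               t_start: float = 0.0) -> RunEvent:
    """Draw one run at distance ``rs``: an angle, a duration, a displacement.

    The angle comes from the arrival-angle law, the duration from exact
    inversion of the cumulative collision hazard.  If the straight run
    would dip to distance a before the sampled duration elapses, it is
    truncated at the crossing time with ``terminated="source"``.
    """
    if not rs > p.a:
        raise ValueError("rs must be > a")
    # scalar fast path: same closed forms as analytic.arrival_angle_ppf /
    # analytic.run_duration_ppf, without array dispatch (hot loop)
    a, v, eps = p.a, p.v, p.epsilon
    u1 = rng.random()
    q = 1.0 / (rs - a) - 2.0 * a * u1 / (rs * rs - a * a)
    cosphi = (rs * rs + a * a - 1.0 / (q * q)) / (2.0 * a * rs)
    cosphi = max(-1.0, min(1.0, cosphi))
    phi = math.acos(cosphi)
    sinphi = math.sin(phi)
    lam = -math.log1p(-rng.random()) / eps
    if sinphi < 1e-12:
        x = math.expm1(lam) if cosphi < 0.0 else -math.expm1(-lam)
    else:
        x = cosphi + sinphi * math.sinh(lam - math.asinh(cosphi / sinphi))
    dt = rs * max(x, 0.0) / v
    t_hit = _source_crossing_time(rs, phi, p.a, p.v)
    if t_hit is not None and t_hit <= dt:
        dt = t_hit
        drs = _drs_scalar(rs, phi, dt, p.v)
        return RunEvent(t_start, rs, phi, dt, drs, terminated=OUTCOME_SOURCE)
    drs = _drs_scalar(rs, phi, dt, p.v)
    return RunEvent(t_start, rs, phi, dt, drs)


def _drs_scalar(rs: float, phi: float, dt: float, v: float) -> float:
    ell = v * dt
    return math.sqrt(rs * rs + ell * ell - 2.0 * rs * ell * math.cos(phi)) - rs


def sample_first_runs(rng: np.random.Generator, rs: float, p: ModelParams,
                      n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised draw of ``n`` independent single runs at distance ``rs``.

    Returns (phi, dt, drs) arrays with source-crossing truncation applied,
    matching :func:`sample_run` in distribution.  Used for first-run
    ensemble statistics (chemotactic index, homing-radius estimation)
    where only one run per cell is needed.
    """
    if not rs > p.a:
        raise ValueError("rs must be > a")
    phi = analytic.arrival_angle_ppf(rng.random(n), rs, p.a)
    dt = analytic.run_duration_ppf(rng.random(n), rs, phi, p)
    sinphi = np.sin(phi)
    cosphi = np.cos(phi)
    disc = p.a**2 - (rs * sinphi) ** 2
    may_hit = (cosphi > 0.0) & (disc >= 0.0)
    t_hit = np.where(
        may_hit,
        (rs * cosphi - np.sqrt(np.where(may_hit, disc, 0.0))) / p.v,
        np.inf,
    )
    dt = np.minimum(dt, t_hit)
    drs = analytic.radial_displacement(rs, phi, dt, p)
    return phi, dt, drs


def _boundary_crossing_time(rs: float, phi: float, rc: float, v: float) -> float | None:
    """Time at which a straight run first reaches distance ``rc`` > rs."""
    cosphi = math.cos(phi)
    disc = rc * rc - (rs * math.sin(phi)) ** 2
    if disc < 0.0:
        return None
    return (rs * cosphi + math.sqrt(disc)) / v


def simulate_trajectory(rng: np.random.Generator | int, r0: float, p: ModelParams,
                        boundary_rc: float, max_time: float = np.inf,
                        seed: int | None = None) -> Trajectory:
    """Chain runs from distance ``r0`` until the source, the cut-off or time-out.

    Deterministic given the generator state.  ``boundary_rc`` is the
    radius at which the cell is deemed irretrievably lost; ``max_time``
    guards heavy-tailed wandering (essential for epsilon <= 1, where runs
    are well defined but their means diverge).
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if not (p.a < r0 < boundary_rc):
        raise ValueError("need a < r0 < boundary_rc")
    traj = Trajectory(seed=-1 if seed is None else seed, params=p, r0=r0)
    rs = r0
    t = 0.0
    while t < max_time:
        ev = sample_run(rng, rs, p, t_start=t)
        # truncate at the outer cut-off if the run crosses it
        t_rc = _boundary_crossing_time(rs, ev.phi, boundary_rc, p.v)
        if t_rc is not None and t_rc <= ev.dt and ev.terminated == OUTCOME_NONE:
            ev = RunEvent(t, rs, ev.phi, t_rc, _drs_scalar(rs, ev.phi, t_rc, p.v),
                          terminated=OUTCOME_BOUNDARY)
        if t + ev.dt > max_time:
            dt_cut = max_time - t
            ev = RunEvent(t, rs, ev.phi, dt_cut, _drs_scalar(rs, ev.phi, dt_cut, p.v),
                          terminated=OUTCOME_MAX_TIME)
        traj.events.append(ev)
        t += ev.dt
        rs += ev.drs
        if ev.terminated != OUTCOME_NONE:
            traj.outcome = ev.terminated
            break
        if rs <= p.a:  # numerical safety; capture is normally flagged on the event
            traj.outcome = OUTCOME_SOURCE
            break
    else:
        traj.outcome = OUTCOME_MAX_TIME
    traj.total_time = t
    if t >= max_time and traj.outcome not in (OUTCOME_SOURCE, OUTCOME_BOUNDARY):
        traj.outcome = OUTCOME_MAX_TIME
    return traj


def simulate_ensemble(rng: np.random.Generator | int | np.random.SeedSequence,
                      n_cells: int, r0: float, p: ModelParams,
                      boundary_rc: float, max_time: float = np.inf) -> list[Trajectory]:
    """``n_cells`` independent trajectories with per-trial derived seeds.

    Each trial gets its own child stream of the master seed sequence, so
    ensembles are reproducible and trials statistically independent.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif isinstance(rng, (int, np.integer)):
        ss = np.random.SeedSequence(int(rng))
    else:
        ss = np.random.SeedSequence(rng.integers(2**31))
    children = ss.spawn(n_cells)
    out = []
    for i, child in enumerate(children):
        traj = simulate_trajectory(np.random.default_rng(child), r0, p,
                                   boundary_rc, max_time, seed=i)
        out.append(traj)
    return out


def first_run_events(trajectories: Sequence[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    """(drs, dt) arrays of the first run of each trajectory."""
    drs = np.array([tr.events[0].drs for tr in trajectories if tr.events])
    dt = np.array([tr.events[0].dt for tr in trajectories if tr.events])
    return drs, dt
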