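"""Summary statistics over trajectory ensembles.

Mean distance-to-source curves, the empirical chemotactic index of
first-run samples, Monte-Carlo homing-radius estimation and outcome
bookkeeping.  Standard errors of the mean curve come from a
nonparametric bootstrap over trajectories; the chemotactic-index
estimator uses a delta-method standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import analytic, run_sim
from .model import ModelParams
from .run_sim import Trajectory

__all__ = [
    "EnsembleSummary",
    "mean_distance_curve",
    "empirical_ci",
    "estimate_homing_radius",
    "first_run_majority_direction",
    "outcome_fractions",
]


@dataclass
class EnsembleSummary:
    """Mean-distance curve and ensemble bookkeeping."""

    times: np.ndarray
    mean_rs: np.ndarray
    se_rs: np.ndarray
    n_alive: np.ndarray
    outcome_fractions: dict[str, float]
    censoring: str
    params: ModelParams | None = None
    r0: float | None = None
    extras: dict = field(default_factory=dict)


def outcome_fractions(trajectories: Sequence[Trajectory]) -> dict[str, float]:
    n = len(trajectories)
    out: dict[str, float] = {}
    for tr in trajectories:
        out[tr.outcome] = out.get(tr.outcome, 0.0) + 1.0 / n
    return out


def mean_distance_curve(trajectories: Sequence[Trajectory], times,
                        censoring: str = "hold",
                        n_bootstrap: int = 200,
                        rng: np.random.Generator | None = None) -> EnsembleSummary:
    """Ensemble-mean distance to the source on a time grid.

    Positions within runs are evaluated exactly from the run geometry
    (no interpolation).  ``censoring='hold'`` keeps terminated
    trajectories at their terminal distance (the ensemble size stays
    constant, as when lost cells are parked at the cut-off); ``'drop'``
    averages only trajectories still running and reports ``n_alive``.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    if censoring not in ("hold", "drop"):
        raise ValueError("censoring must be 'hold' or 'drop'")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    mat = np.vstack([tr.distance_at(times) for tr in trajectories])
    alive = np.vstack([times <= tr.total_time for tr in trajectories])
    n_alive = alive.sum(axis=0)
    rng = rng if rng is not None else np.random.default_rng(0)
    if censoring == "hold":
        mean = mat.mean(axis=0)
        idx = rng.integers(len(mat), size=(n_bootstrap, len(mat)))
        boots = mat[idx].mean(axis=1)
        se = boots.std(axis=0, ddof=1)
    else:
        with np.errstate(invalid="ignore"):
            mean = np.where(n_alive > 0, (mat * alive).sum(axis=0) / n_alive, np.nan)
        idx = rng.integers(len(mat), size=(n_bootstrap, len(mat)))
        boots = np.empty((n_bootstrap, len(times)))
        for b in range(n_bootstrap):
            m, al = mat[idx[b]], alive[idx[b]]
            cnt = al.sum(axis=0)
            with np.errstate(invalid="ignore"):
                boots[b] = np.where(cnt > 0, (m * al).sum(axis=0) / cnt, np.nan)
        se = np.nanstd(boots, axis=0, ddof=1)
    p = trajectories[0].params
    return EnsembleSummary(times, mean, se, n_alive,
                           outcome_fractions(trajectories), censoring,
                           params=p, r0=trajectories[0].r0)


def empirical_ci(drs: np.ndarray, dt: np.ndarray, v: float) -> tuple[float, float]:
    """Empirical chemotactic index -mean(drs)/(v*mean(dt)) with its SE.

    The standard error follows from the delta method on the ratio of the
    two sample means, including their covariance.
    """
    drs = np.asarray(drs, dtype=float)
    dt = np.asarray(dt, dtype=float)
    n = len(drs)
    if n < 100:
        raise ValueError("need at least 100 first-run events")
    m_r, m_t = drs.mean(), dt.mean()
    if m_t <= 0.0:
        raise ValueError("mean run duration must be positive")
    ci = -m_r / (v * m_t)
    cov = np.cov(drs, dt)
    grad = np.array([-1.0 / (v * m_t), m_r / (v * m_t**2)])
    var = grad @ cov @ grad / n
    return ci, math.sqrt(max(var, 0.0))


def _default_sampler(p: ModelParams) -> Callable[[np.random.Generator, float, int], np.ndarray]:
    def sampler(rng: np.random.Generator, rs: float, n: int) -> np.ndarray:
        _, _, drs = run_sim.sample_first_runs(rng, rs, p, n)
        return drs
    return sampler


def estimate_homing_radius(p: ModelParams,
                           sampler: Callable[[np.random.Generator, float, int], np.ndarray] | None = None,
                           n_per_point: int = 100_000,
                           bracket: tuple[float, float] | None = None,
                           rng: np.random.Generator | int | None = None,
                           z_stop: float = 2.0,
                           max_iter: int = 40) -> tuple[float, float]:
    """Monte-Carlo bracket of the homing radius.

    Bisects on the sign of the empirical mean first-run radial
    displacement (negative inside rh, positive outside), drawing
    ``n_per_point`` single runs per midpoint.  Bisection stops when the
    interval width reaches the statistical resolution limit
    ``z_stop * SE / slope`` (the distance at which the mean is no longer
    distinguishable from zero); the returned interval has at least that
    half-width, so its width shrinks as 1/sqrt(n_per_point).
    """
    p.require_finite_statistics()
    sampler = sampler if sampler is not None else _default_sampler(p)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rh = p.rh
    lo, hi = bracket if bracket is not None else (0.5 * rh, 1.5 * rh)
    if not lo > p.a:
        raise ValueError("lower bracket must exceed the cell radius")

    def signed_mean(rs: float) -> tuple[float, float]:
        d = sampler(rng, rs, n_per_point)
        return float(np.mean(d)), float(np.std(d, ddof=1) / math.sqrt(len(d)))

    m_lo, se_lo = signed_mean(lo)
    m_hi, se_hi = signed_mean(hi)
    if not (m_lo < 0.0 < m_hi):
        raise ValueError(
            f"bracket ({lo:g}, {hi:g}) does not straddle a sign change: "
            f"means {m_lo:g}, {m_hi:g}"
        )
    slope = (m_hi - m_lo) / (hi - lo)  # d(mean drs)/d(rs), positive
    delta = z_stop * max(se_lo, se_hi) / slope
    for _ in range(max_iter):
        if hi - lo <= 2.0 * delta:
            break
        mid = 0.5 * (lo + hi)
        m, se = signed_mean(mid)
        delta = z_stop * se / slope
        if m < 0.0:
            lo = mid
        else:
            hi = mid
    centre = 0.5 * (lo + hi)
    half = max(0.5 * (hi - lo), delta)
    return centre - half, centre + half


def first_run_majority_direction(drs: np.ndarray) -> float:
    """Fraction of first runs moving toward the source (drs < 0).

    At the homing radius the mean displacement vanishes, yet more than
    half of the cells step toward the source: the toward-bias of the
    angular law is balanced by the longer (heavy-tailed) away-runs.
    """
    drs = np.asarray(drs, dtype=float)
    return float(np.mean(drs < 0.0))


def theoretical_summary_row(rs: float, p: ModelParams) -> dict[str, float]:
    """Closed-form quantities at one distance (CLI table helper)."""
    row = {
        "rs": rs,
        "J_total": analytic.total_arrival_rate(rs, p),
        "veff_inf": float(analytic.veff_infinite(rs, p)),
        "epsilon": p.epsilon,
        "rh": p.rh,
    }
    if p.epsilon > 1.0 and rs > p.a:
        row["veff_alpha"] = float(analytic.veff_finite(rs, p))
        row["CI"] = float(analytic.chemotactic_index(rs, p))
        row["mean_dr"] = float(analytic.mean_run_displacement(rs, p))
        row["mean_dt"] = float(analytic.mean_run_duration(rs, p))
    else:
        row["veff_alpha"] = row["CI"] = row["mean_dr"] = row["mean_dt"] = float("nan")
    return row
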