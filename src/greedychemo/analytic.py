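"""Closed-form theory of greedy chemotaxis with discrete cues.

The steady-state cue density around a perfectly absorbing spherical cell
is obtained by the method of images; everything else follows from it:

* ``surface_flux`` — flux density of cues onto the cell surface, which
  is independent of the diffusivity D (only the release rate matters);
* ``arrival_angle_pdf`` — probability density of the polar angle of cue
  arrivals, biased toward the source;
* ``total_arrival_rate`` — the position-dependent Poisson rate
  ``alpha*a/rs`` of cue-cell collisions;
* run statistics — a run is the straight flight between two successive
  absorptions; the duration is drawn from an inhomogeneous Poisson
  process whose rate follows the cell along the run.  The cumulative
  hazard has a closed inverse-hyperbolic-sine form, inverted exactly for
  sampling;
* mean run displacement/duration, chemotactic index, effective
  velocities, and the homing radius ``rh = alpha*a**2/v`` at which the
  mean radial displacement changes sign.

All angle arguments are polar angles ``phi`` in [0, pi] measured at the
cell centre from the centre-to-source axis; ``phi = 0`` points at the
source.  Functions are vectorised over ``phi``, ``u``, ``t`` and ``dt``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

from .model import DivergentStatisticsError, ImageCharge, ModelParams
from .model import homing_radius  # noqa: F401  (re-exported, defined with ModelParams)

__all__ = [
    "image_charge",
    "cue_density",
    "surface_flux",
    "total_arrival_rate",
    "arrival_angle_pdf",
    "arrival_angle_cdf",
    "arrival_angle_ppf",
    "veff_infinite",
    "trajectory_infinite",
    "radial_displacement",
    "run_collision_rate",
    "cumulative_hazard",
    "run_duration_ppf",
    "mean_run_displacement",
    "mean_run_duration",
    "chemotactic_index",
    "veff_finite",
    "homing_radius",
    "truncated_mean_run_duration",
    "locate_divergence_threshold",
]

# below this, sin(phi) is treated as exactly 0 and logarithmic limits of
# the cumulative hazard are used instead of the arcsinh form
_SIN_TOL = 1e-12


def _require_outside(rs: float, a: float, *, strict: bool = True) -> None:
    if strict and not rs > a:
        raise ValueError(f"source must lie outside the cell: rs = {rs!r} <= a = {a!r}")
    if not strict and rs < a:
        raise ValueError(f"rs = {rs!r} < a = {a!r}")


def image_charge(rs: float, p: ModelParams) -> ImageCharge:
    """Image source that makes the cue density vanish on the cell surface.

    Strength ``-alpha*a/rs`` at distance ``a**2/rs`` from the cell
    centre, on the centre-to-source axis.
    """
    _require_outside(rs, p.a)
    return ImageCharge(strength=-p.alpha * p.a / rs, position=p.a**2 / rs)


def cue_density(x, rs_vec, p: ModelParams):
    """Steady-state cue number density at position ``x`` (cell frame).

    ``x`` is a 3-vector (or array of them, shape (..., 3)) relative to
    the cell centre; ``rs_vec`` is the source position.  The density is
    the superposition of the free source and its image charge,

        rho(x) = alpha/(4 pi D) * [ 1/|x - rs| - (a/rs)/|x - rs'| ],

    which vanishes on |x| = a and at infinity.
    """
    x = np.asarray(x, dtype=float)
    rs_vec = np.asarray(rs_vec, dtype=float)
    rs = float(np.linalg.norm(rs_vec))
    _require_outside(rs, p.a)
    r = np.linalg.norm(x, axis=-1)
    if np.any(r < p.a * (1.0 - 1e-12)):
        raise ValueError("cue_density is defined only outside the cell, |x| >= a")
    d_src = np.linalg.norm(x - rs_vec, axis=-1)
    if np.any(d_src == 0.0):
        raise ValueError("cue_density is singular at the source position")
    img = image_charge(rs, p)
    x_img = rs_vec * (img.position / rs)
    d_img = np.linalg.norm(x - x_img, axis=-1)
    return p.alpha / (4.0 * np.pi * p.D) * (1.0 / d_src - (p.a / rs) / d_img)


def surface_flux(phi, rs: float, p: ModelParams):
    """Cue flux density onto the cell surface at polar angle ``phi``.

    J(phi) = alpha/(4 pi a) * (rs**2 - a**2) / (rs**2 + a**2 - 2 a rs cos phi)**1.5.

    Strictly positive, maximal on the source-facing pole, and notably
    independent of the diffusivity D: a larger D dilutes the density but
    speeds up the particles by exactly the compensating factor.
    """
    _require_outside(rs, p.a)
    phi = np.asarray(phi, dtype=float)
    a = p.a
    denom = (rs**2 + a**2 - 2.0 * a * rs * np.cos(phi)) ** 1.5
    return p.alpha / (4.0 * np.pi * a) * (rs**2 - a**2) / denom


def total_arrival_rate(rs: float, p: ModelParams):
    """Total Poisson rate of cue arrivals on the cell, alpha*a/rs."""
    _require_outside(rs, p.a, strict=False)
    return p.alpha * p.a / rs


def arrival_angle_pdf(phi, rs: float, a: float):
    """Probability density of the arrival polar angle over [0, pi].

    Constructed as J(phi) dA(phi) normalised by the total rate alpha*a/rs:

        p(phi) = rs (rs**2 - a**2) sin(phi) / [2 (rs**2 + a**2 - 2 a rs cos phi)**1.5].

    The per-solid-angle density p(phi)/sin(phi) is maximal at phi = 0:
    arrivals are biased toward the source.
    """
    _require_outside(rs, a)
    phi = np.asarray(phi, dtype=float)
    denom = (rs**2 + a**2 - 2.0 * a * rs * np.cos(phi)) ** 1.5
    return rs * (rs**2 - a**2) * np.sin(phi) / (2.0 * denom)


def arrival_angle_cdf(phi, rs: float, a: float):
    """CDF of the arrival angle: F(0) = 0, F(pi) = 1."""
    _require_outside(rs, a)
    phi = np.asarray(phi, dtype=float)
    root = np.sqrt(rs**2 + a**2 - 2.0 * a * rs * np.cos(phi))
    return (rs**2 - a**2) / (2.0 * a) * (1.0 / (rs - a) - 1.0 / root)


def arrival_angle_ppf(u, rs: float, a: float):
    """Exact inverse of :func:`arrival_angle_cdf` (inverse-transform sampler)."""
    _require_outside(rs, a)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u > 1.0)):
        raise ValueError("u must lie in [0, 1]")
    q = 1.0 / (rs - a) - 2.0 * a * u / (rs**2 - a**2)
    cosphi = (rs**2 + a**2 - 1.0 / q**2) / (2.0 * a * rs)
    return np.arccos(np.clip(cosphi, -1.0, 1.0))


def veff_infinite(rs, p: ModelParams):
    """Effective approach speed in the infinite-release-rate limit, a*v/rs.

    With cues arriving continuously the cell's radial speed is the
    angular average v*E[cos phi]; it equals v at contact (rs = a) and
    decays as 1/rs.
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(rs < p.a):
        raise ValueError("rs must be >= a")
    return p.a * p.v / rs


def trajectory_infinite(t, r0: float, p: ModelParams):
    """Deterministic distance-to-source rs(t) = sqrt(r0**2 - 2 a v t).

    Valid for the smooth-field (infinite release rate) limit, until the
    arrival time t* = (r0**2 - a**2)/(2 a v) at which rs = a.
    """
    if r0 < p.a:
        raise ValueError("r0 must be >= a")
    t = np.asarray(t, dtype=float)
    t_star = (r0**2 - p.a**2) / (2.0 * p.a * p.v)
    if np.any(t > t_star * (1.0 + 1e-12)):
        raise ValueError(f"source reached at t* = {t_star:g}; no trajectory beyond")
    return np.sqrt(np.maximum(r0**2 - 2.0 * p.a * p.v * t, p.a**2))


def radial_displacement(rs, phi, dt, p: ModelParams):
    """Signed change of the cell-source distance over one straight run.

    The cell starts at distance ``rs``, flies at speed v for time ``dt``
    at polar angle ``phi`` from the source direction:

        drs = sqrt(rs**2 + (v dt)**2 - 2 rs v dt cos phi) - rs.

    Negative means net approach; bounded below by -rs.
    """
    rs = np.asarray(rs, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(rs <= 0.0):
        raise ValueError("rs must be positive")
    if np.any(dt < 0.0):
        raise ValueError("dt must be non-negative")
    ell = p.v * dt
    return np.sqrt(rs**2 + ell**2 - 2.0 * rs * ell * np.cos(phi)) - rs


def run_collision_rate(t, rs, phi, p: ModelParams):
    """Cue arrival rate at time ``t`` along a straight run, alpha*a/dist(t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be non-negative")
    dist = np.sqrt(rs**2 + (p.v * t) ** 2 - 2.0 * rs * p.v * t * np.cos(phi))
    return p.alpha * p.a / dist


def cumulative_hazard(dt, rs, phi, p: ModelParams):
    """Integrated collision rate Lambda(dt) along a straight run.

    Closed form with eps = alpha*a/v, c = cos(phi), s = sin(phi):

        Lambda = eps * [ asinh((v dt - rs c)/(rs s)) + asinh(c/s) ],

    with logarithmic limits for s -> 0:
    eps*ln(1 + v dt/rs) for a run straight away (phi = pi), and
    -eps*ln(1 - v dt/rs) for a run straight at the source (phi = 0),
    which diverges as the run reaches the point source at t = rs/v.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0.0):
        raise ValueError("dt must be non-negative")
    eps = p.epsilon
    c = np.cos(phi)
    s = np.sin(phi)
    x = p.v * dt / rs
    scalar = np.ndim(phi) == 0 and np.ndim(dt) == 0 and np.ndim(rs) == 0
    c, s, x = np.broadcast_arrays(np.atleast_1d(c), np.atleast_1d(s), np.atleast_1d(x))
    out = np.empty_like(x, dtype=float)
    deg = np.abs(s) < _SIN_TOL
    gen = ~deg
    out[gen] = eps * (np.arcsinh((x[gen] - c[gen]) / s[gen]) + np.arcsinh(c[gen] / s[gen]))
    away = deg & (c < 0.0)
    out[away] = eps * np.log1p(x[away])
    toward = deg & (c >= 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[toward] = np.where(
            x[toward] < 1.0, -eps * np.log1p(-x[toward]), np.inf
        )
    return float(out[0]) if scalar else out


def run_duration_ppf(u, rs, phi, p: ModelParams):
    """Sample a run duration by exact inversion of the cumulative hazard.

    Solves Lambda(dt) = -ln(1 - u) in closed form (sinh of the arcsinh
    expression; exponential limits for sin(phi) = 0).  ``u`` must lie in
    [0, 1).  Note: for source-pointing runs (rs*sin(phi) <= a with
    cos(phi) > 0) the sampled duration may exceed the time at which the
    cell surface reaches the source; truncation is the simulator's job.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u >= 1.0)):
        raise ValueError("u must lie in [0, 1)")
    eps = p.epsilon
    lam = -np.log1p(-u) / eps  # Lambda / eps
    c = np.cos(phi)
    s = np.sin(phi)
    scalar = np.ndim(u) == 0 and np.ndim(phi) == 0 and np.ndim(rs) == 0
    c, s, lam = np.broadcast_arrays(np.atleast_1d(c), np.atleast_1d(s), np.atleast_1d(lam))
    x = np.empty_like(lam)  # v*dt/rs
    deg = np.abs(s) < _SIN_TOL
    gen = ~deg
    x[gen] = c[gen] + s[gen] * np.sinh(lam[gen] - np.arcsinh(c[gen] / s[gen]))
    away = deg & (c < 0.0)
    x[away] = np.expm1(lam[away])
    toward = deg & (c >= 0.0)
    x[toward] = -np.expm1(-lam[toward])
    x = np.maximum(x, 0.0)  # guard rounding at u ~ 0
    out = np.asarray(rs) * x / p.v
    return float(out.reshape(-1)[0]) if scalar else out


def mean_run_displacement(rs, p: ModelParams):
    """Mean signed radial displacement per run, (rs - a*eps)/(eps**2 - 1).

    Negative (net approach) for rs < rh = a*eps, zero at the homing
    radius, positive beyond it.  Finite only for eps > 1.
    """
    p.require_finite_statistics()
    rs = np.asarray(rs, dtype=float)
    eps = p.epsilon
    out = (rs - p.a * eps) / (eps**2 - 1.0)
    return float(out) if out.ndim == 0 else out


def mean_run_duration(rs, p: ModelParams):
    """Mean run duration, (eps*rs - a)/(v*(eps**2 - 1)); finite for eps > 1.

    At the homing radius the mean run length is exactly one cell radius:
    v * mean_run_duration(rh) = a.
    """
    p.require_finite_statistics()
    rs = np.asarray(rs, dtype=float)
    eps = p.epsilon
    out = (eps * rs - p.a) / (p.v * (eps**2 - 1.0))
    return float(out) if out.ndim == 0 else out


def veff_finite(rs, p: ModelParams):
    """Effective approach speed at finite release rate.

    Defined as -mean_run_displacement/mean_run_duration (positive toward
    the source); equals v*(a*eps - rs)/(rs*eps - a) and converges to
    a*v/rs as eps -> infinity.
    """
    return -mean_run_displacement(rs, p) / mean_run_duration(rs, p)


def chemotactic_index(rs, p: ModelParams):
    """Chemotactic index CI = (a*eps - rs)/(rs*eps - a) in [-1, 1].

    Ratio of the mean distance gained toward the source to the mean
    distance travelled per run; +1 at contact (rs = a), 0 at the homing
    radius, negative beyond it.
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(rs <= p.a):
        raise ValueError("rs must be > a")
    return veff_finite(rs, p) / p.v


def truncated_mean_run_duration(T: float, rs: float, p: ModelParams,
                                n_phi: int = 128, n_t: int = 64) -> float:
    """E[min(run duration, T)]-type truncated expectation by quadrature.

    Integrates dt * p(phi) * p(dt | phi) over phi in (0, pi) and
    dt in (0, T) using Gauss-Legendre nodes (log-spaced in dt beyond the
    ballistic time rs/v).  Converges as T -> infinity only for eps > 1;
    used to locate the divergence threshold numerically.
    """
    total = 0.0
    edges = [0.0, min(rs / p.v, T)]
    t = edges[-1]
    while t < T:
        t = min(t * 10.0, T)
        edges.append(t)
    for lo, hi in zip(edges[:-1], edges[1:]):
        total += _truncated_panel(lo, hi, rs, p, n_phi, n_t)
    return total


_leggauss_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _leggauss_cache:
        _leggauss_cache[n] = leggauss(n)
    return _leggauss_cache[n]


def _truncated_panel(t_lo: float, t_hi: float, rs: float, p: ModelParams,
                     n_phi: int, n_t: int) -> float:
    """Integral of dt*p(phi)*p(dt|phi) over phi in (0,pi) x dt in (t_lo, t_hi)."""
    xg, wg = _nodes(n_phi)
    phi = 0.5 * np.pi * (xg + 1.0)
    wphi = 0.5 * np.pi * wg * arrival_angle_pdf(phi, rs, p.a)
    xt, wt = _nodes(n_t)
    if t_lo > 0.0:
        # log-spaced panel: t = exp(y)
        y_lo, y_hi = np.log(t_lo), np.log(t_hi)
        y = 0.5 * (y_hi - y_lo) * (xt + 1.0) + y_lo
        t = np.exp(y)
        jac = 0.5 * (y_hi - y_lo) * t * wt
    else:
        t = 0.5 * (t_hi - t_lo) * (xt + 1.0) + t_lo
        jac = 0.5 * (t_hi - t_lo) * wt
    tt = t[None, :]
    pp = phi[:, None]
    lam = run_collision_rate(tt, rs, pp, p)
    haz = cumulative_hazard(tt, rs, pp, p)
    integrand = tt * lam * np.exp(-haz)
    return float(np.sum(wphi[:, None] * integrand * jac[None, :]))


def _tail_increment_ratio(eps: float, rs: float = 2.0, a: float = 1.0, v: float = 1.0,
                          growth: float = 10.0, n_panels: int = 7) -> float:
    """Ratio of successive geometric-panel increments of the truncated mean.

    The tail of dt*p(dt) scales as dt**(-eps), so increments over panels
    [T, growth*T] scale by growth**(1-eps): the ratio exceeds 1 exactly
    when the expectation diverges (eps < 1).
    """
    p = ModelParams(a=a, v=v, alpha=eps * v / a, D=1.0)
    t0 = rs / v
    edges = t0 * growth ** np.arange(n_panels + 1)
    last = _truncated_panel(edges[-2], edges[-1], rs, p, 128, 64)
    prev = _truncated_panel(edges[-3], edges[-2], rs, p, 128, 64)
    return last / prev


def locate_divergence_threshold(eps_lo: float = 0.2, eps_hi: float = 3.0,
                                width: float = 0.01, **kwargs) -> tuple[float, float]:
    """Bracket the epsilon above which the mean run duration is finite.

    Scans the truncated expectation of the run duration with
    geometrically growing truncation limits; an epsilon is classified
    divergent when successive increments stop shrinking.  Bisects the
    convergent/divergent boundary down to ``width`` and returns the
    bracketing interval (expected to contain 1).
    """
    f_lo = _tail_increment_ratio(eps_lo, **kwargs)
    f_hi = _tail_increment_ratio(eps_hi, **kwargs)
    if not (f_lo > 1.0 > f_hi):
        raise RuntimeError("bracket does not straddle the divergence boundary")
    lo, hi = eps_lo, eps_hi
    while hi - lo > width:
        mid = 0.5 * (lo + hi)
        if _tail_increment_ratio(mid, **kwargs) > 1.0:
            lo = mid
        else:
            hi = mid
    return lo, hi
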