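"""Deterministic mean-field companion to the agent simulation.

The two-state (growing/shrinking) tip-density equations with retrograde
drift, on the radial domain [0, R]:

    d(p+)/dt = -f_cat p+ + f_res p-  -  v_g d(p+)/dr
    d(p-)/dt = +f_cat p+ - f_res p-  +  v_s d(p-)/dr

with effective speeds ``v_g = v_plus - pr*vr`` and ``v_s = v_minus + pr*vr``
(partial coupling to actin retrograde flow adds a mean drag ``pr*vr``).
Boundaries mirror the agent model: growing density reaching R converts to
shrinking density (forced catastrophe at the membrane) and shrinking density
reaching 0 converts to growing density (regrowth from the C domain), so the
system is closed and total mass is conserved.

In the bounded regime (negative mean tip drift) the interior steady state is
exponential with length constant ``lambda = 1/(f_cat/v_g - f_res/v_s)``.
The module provides a transient integrator, a direct steady-state solver,
and a self-consistent fixed point that closes the loop with the adhesion
force balance ``vr = v0/(1 + beta*p)`` — the deterministic limit of the
positive feedback that the stochastic simulation realizes, and hence an
independent oracle for its steady-state averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import (
    BOUNDED,
    Geometry,
    MTParams,
    ModelParams,
    ParameterError,
    classify_growth_regime,
    coupling_probability,
    effective_speeds,
    retrograde_speed,
)

__all__ = [
    "DensityProfile",
    "FixedPointResult",
    "analytic_length_constant",
    "pde_transient",
    "pde_steady_state",
    "self_consistent_fixed_point",
]


@dataclass(frozen=True)
class DensityProfile:
    """Tip densities on a cell-centered radial grid.

    ``p_plus``/``p_minus`` are densities per um in each cell of width
    ``dr``; ``r_grid`` holds the cell centers.
    """

    r_grid: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    dr: float

    def total_mass(self) -> float:
        return float((self.p_plus + self.p_minus).sum() * self.dr)

    def leading_edge_fraction(self, cutoff_radius: float) -> float:
        """Mass fraction beyond ``cutoff_radius`` (fractional cell overlap)."""
        edges = np.concatenate([self.r_grid - self.dr / 2, [self.r_grid[-1] + self.dr / 2]])
        overlap = np.clip(edges[1:] - np.maximum(edges[:-1], cutoff_radius), 0.0, self.dr)
        w = overlap / self.dr
        mass = (self.p_plus + self.p_minus) * self.dr
        total = mass.sum()
        return float((mass * w).sum() / total) if total > 0 else 0.0


@dataclass(frozen=True)
class FixedPointResult:
    """Self-consistent (p, vr) of the feedback loop."""

    p_star: float
    vr_star: float
    iterations: int
    residual: float


def analytic_length_constant(mt: MTParams, pr: float, vr: float) -> float:
    """Exponential length constant of the bounded-regime steady state, um.

    ``lambda = 1 / (f_cat/v_g - f_res/v_s)``, positive in the bounded regime
    with forward growth (``v_g > 0``).  Returns ``inf`` in the unbounded and
    marginal regimes (no finite decay length).
    """
    regime = classify_growth_regime(mt, pr, vr)
    if regime != BOUNDED:
        return math.inf
    v_g, v_s = effective_speeds(mt, pr, vr)
    if v_g <= 0:
        raise ParameterError(
            ["length constant undefined for non-positive effective growth speed"]
        )
    return 1.0 / (mt.f_cat / v_g - mt.f_res / v_s)


def _grid(geom: Geometry, n_cells: int) -> tuple[np.ndarray, float]:
    dr = geom.R / n_cells
    centers = (np.arange(n_cells) + 0.5) * dr
    return centers, dr


def _generator_matrix(
    mt: MTParams, pr: float, vr: float, geom: Geometry, n_cells: int
) -> sp.csr_matrix:
    """Semi-discrete generator L with dx/dt = L x, x = [p+ cells; p- cells].

    First-order upwind finite volumes; every boundary outflow re-enters the
    opposite phase, so each column of L sums to zero (exact conservation).
    """
    v_g, v_s = effective_speeds(mt, pr, vr)
    _, dr = _grid(geom, n_cells)
    n = n_cells
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    # growing phase advection
    if v_g > 0:
        a = v_g / dr
        for i in range(n):
            add(i, i, -a)
            if i + 1 < n:
                add(i + 1, i, a)
            else:
                add(n + i, i, a)  # membrane: forced catastrophe into p- at R
    elif v_g < 0:
        a = -v_g / dr
        for i in range(1, n):  # cell 0 blocked at r=0 (stays growing)
            add(i, i, -a)
            add(i - 1, i, a)

    # shrinking phase advection (always toward r=0)
    b = v_s / dr
    for i in range(1, n):
        add(n + i, n + i, -b)
        add(n + i - 1, n + i, b)
    add(n, n, -b)
    add(0, n, b)  # C domain: rescue into p+ at r=0

    # reaction exchange
    for i in range(n):
        add(i, i, -mt.f_cat)
        add(n + i, i, mt.f_cat)
        add(n + i, n + i, -mt.f_res)
        add(i, n + i, mt.f_res)

    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(2 * n, 2 * n)
    ).tocsr()


def pde_transient(
    mt: MTParams,
    pr: float,
    vr: float,
    geom: Geometry,
    n_cells: int = 400,
    t_end: float = 50.0,
    dt: float | None = None,
    record_stride: int | None = None,
    init: DensityProfile | None = None,
) -> tuple[np.ndarray, list[DensityProfile]]:
    """Explicit upwind integration of the density equations.

    Starts (by default) from all mass in the growing phase at the innermost
    cell, matching the agent initialization.  ``dt`` defaults to half the
    CFL limit; an explicit ``dt`` violating the CFL condition raises before
    stepping.  Returns recorded times and profiles (mass normalized to 1).
    """
    v_g, v_s = effective_speeds(mt, pr, vr)
    centers, dr = _grid(geom, n_cells)
    vmax = max(abs(v_g), v_s)
    cfl_dt = dr / vmax if vmax > 0 else math.inf
    if dt is None:
        dt = min(0.5 * cfl_dt, 0.1 / (mt.f_cat + mt.f_res))
    elif vmax * dt > dr * (1 + 1e-12):
        raise ParameterError(
            [f"CFL violation: dt={dt:g} exceeds dr/max_speed={cfl_dt:g}"]
        )

    n = n_cells
    if init is None:
        x = np.zeros(2 * n)
        x[0] = 1.0 / dr  # all growing, at the C domain
    else:
        x = np.concatenate([init.p_plus, init.p_minus]).astype(float)
        x /= (x.sum() * dr) or 1.0

    L = _generator_matrix(mt, pr, vr, geom, n_cells)
    n_steps = max(1, int(round(t_end / dt)))
    if record_stride is None:
        record_stride = max(1, n_steps // 100)
    times, profiles = [], []
    for step in range(1, n_steps + 1):
        x = x + dt * (L @ x)
        if step % record_stride == 0 or step == n_steps:
            times.append(step * dt)
            profiles.append(
                DensityProfile(r_grid=centers, p_plus=x[:n].copy(), p_minus=x[n:].copy(), dr=dr)
            )
    return np.array(times), profiles


def pde_steady_state(
    mt: MTParams,
    pr: float,
    vr: float,
    geom: Geometry,
    n_cells: int = 400,
    method: str = "direct",
    tol: float = 1e-8,
    max_time: float = 20000.0,
) -> DensityProfile:
    """Steady state of the density equations, mass normalized to 1.

    ``method="direct"`` solves the stationary linear system L x = 0 with the
    normalization constraint; ``method="march"`` time-integrates until the
    leading-edge mass fraction changes by less than ``tol`` per check
    interval.  The two agree to discretization accuracy.
    """
    centers, dr = _grid(geom, n_cells)
    n = n_cells
    if method == "direct":
        L = _generator_matrix(mt, pr, vr, geom, n_cells).tolil()
        L[2 * n - 1, :] = dr  # replace one redundant row with mass = 1
        rhs = np.zeros(2 * n)
        rhs[2 * n - 1] = 1.0
        x = spla.spsolve(L.tocsr(), rhs)
        x = np.clip(x, 0.0, None)
        x /= x.sum() * dr
        return DensityProfile(r_grid=centers, p_plus=x[:n], p_minus=x[n:], dr=dr)
    if method == "march":
        cutoff = geom.leading_edge_cutoff * geom.R
        prof = None
        prev = math.inf
        chunk = 50.0  # model minutes between convergence checks
        elapsed = 0.0
        while elapsed < max_time:
            _, profs = pde_transient(
                mt, pr, vr, geom, n_cells, t_end=chunk, init=prof, record_stride=10**9
            )
            prof = profs[-1]
            elapsed += chunk
            frac = prof.leading_edge_fraction(cutoff)
            if abs(frac - prev) < tol:
                mass = prof.total_mass()
                return DensityProfile(
                    r_grid=centers, p_plus=prof.p_plus / mass, p_minus=prof.p_minus / mass, dr=dr
                )
            prev = frac
        raise ParameterError(
            [f"steady-state marching did not converge within {max_time:g} min"]
        )
    raise ParameterError([f"unknown method {method!r}"])


def self_consistent_fixed_point(
    params: ModelParams,
    theta_deg: float,
    n_cells: int = 400,
    omega: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FixedPointResult:
    """Self-consistent leading-edge fraction and retrograde flow speed.

    Damped fixed-point iteration ``p <- (1-w) p + w M(vr(p))`` where
    ``vr(p) = v0/(1 + beta*p)`` is the adhesion force balance and ``M`` maps
    a flow speed to the steady-state leading-edge mass fraction of the
    density equations at the local coupling probability.  Damping guards
    against overshoot of the positive feedback at large beta.  With
    ``beta = 0`` the flow speed is fixed at ``v0`` and the map is evaluated
    once (undamped).
    """
    pr = coupling_probability(theta_deg, params.grad)
    cutoff = params.geom.leading_edge_cutoff * params.geom.R
    if params.actin.beta == 0.0:
        omega = 1.0

    def M(vr: float) -> float:
        prof = pde_steady_state(params.mt, pr, vr, params.geom, n_cells=n_cells)
        return prof.leading_edge_fraction(cutoff)

    p = 0.0
    history: list[float] = []
    for k in range(1, max_iter + 1):
        vr = retrograde_speed(p, params.actin)
        p_new = (1.0 - omega) * p + omega * M(vr)
        delta = abs(p_new - p)
        history.append(p_new)
        p = p_new
        if delta < tol:
            vr_star = retrograde_speed(p, params.actin)
            return FixedPointResult(p_star=p, vr_star=vr_star, iterations=k, residual=delta)
    lo, hi = min(history[-5:]), max(history[-5:])
    raise ParameterError(
        [
            f"fixed point did not converge in {max_iter} iterations; "
            f"last iterates bracketed in [{lo:.6g}, {hi:.6g}]"
        ]
    )
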