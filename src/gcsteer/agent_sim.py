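"""Stochastic agent-based simulation of microtubule ensembles per angle.

Each angular coordinate of the semi-circular growth cone carries an
independent ensemble of N microtubules on the 1-D radial domain [0, R].
Every time step, each MT switches phase with probability ``f_cat*dt``
(growing -> shrinking) or ``f_res*dt`` (shrinking -> growing), then its tip
moves with the effective speed ``v_plus - c*vr`` (growing) or retreats with
``v_minus + c*vr`` (shrinking), where ``c`` is the MT-actin coupling: either
the mean coupling probability ``pr`` (``coupling_mode="mean"``) or a fresh
Bernoulli(pr) draw per MT per step (``coupling_mode="bernoulli"``).
After moving, the leading-edge fraction ``p`` (tips past ``0.75*R``) is
recomputed and the retrograde flow speed is updated instantaneously from the
force balance ``vr = v0/(1 + beta*p)`` — the mechanical feedback loop.

Boundary rules: a growing tip reaching the membrane at R is clamped there
and undergoes a forced catastrophe; a shrinking tip reaching the C domain at
r = 0 is clamped and rescued (continual regrowth from the C domain).  The MT
count N is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ModelParams,
    ParameterError,
    coupling_probability,
    protrusion_speed,
    retrograde_speed,
)

__all__ = [
    "SimConfig",
    "EnsembleState",
    "AngleTimeSeries",
    "GrowthConeProfile",
    "init_ensemble",
    "leading_edge_fraction",
    "step_ensemble",
    "simulate_angle",
    "steady_state_summary",
    "simulate_growth_cone",
    "net_protrusion_angle",
    "sweep",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls.

    Attributes
    ----------
    dt : float
        Time step, min.  Must resolve both the switching rates
        (``dt*max(f_cat, f_res) <= 0.05``) and the tip motion
        (``dt*(v_plus + v_minus + v0) <= 0.1*R``).
    t_total : float
        Total simulated time per angle, min.
    burn_in : float
        Initial time excluded from steady-state averages, min.
    n_mt : int
        Number of MTs per angular coordinate.
    seed : int
        Master RNG seed; per-angle substreams are derived from it.
    coupling_mode : str
        ``"mean"`` uses the deterministic effective drift (coupling enters
        as its mean ``pr``); ``"bernoulli"`` resamples the coupling state of
        each MT every step.
    record_stride : int
        Steps between recorded samples of (t, p, vr).
    """

    dt: float = 0.005
    t_total: float = 100.0
    burn_in: float = 50.0
    n_mt: int = 1000
    seed: int = 0
    coupling_mode: str = "mean"
    record_stride: int = 10

    def violations(self, params: ModelParams | None = None) -> list[str]:
        out = []
        if not self.dt > 0:
            out.append(f"SimConfig.dt must be > 0, got {self.dt!r}")
        if not self.burn_in < self.t_total:
            out.append("SimConfig.burn_in must be < t_total")
        if not self.n_mt >= 1:
            out.append(f"SimConfig.n_mt must be >= 1, got {self.n_mt!r}")
        if self.coupling_mode not in ("mean", "bernoulli"):
            out.append(f"SimConfig.coupling_mode must be 'mean' or 'bernoulli', got {self.coupling_mode!r}")
        if not self.record_stride >= 1:
            out.append(f"SimConfig.record_stride must be >= 1, got {self.record_stride!r}")
        if params is not None and self.dt > 0:
            mt, actin, geom = params.mt, params.actin, params.geom
            if self.dt * max(mt.f_cat, mt.f_res) > 0.05 + 1e-12:
                out.append("SimConfig.dt too large: dt*max(f_cat, f_res) must be <= 0.05")
            if self.dt * (mt.v_plus + mt.v_minus + actin.v0) > 0.1 * geom.R + 1e-12:
                out.append("SimConfig.dt too large: dt*(v_plus + v_minus + v0) must be <= 0.1*R")
        return out

    def validate(self, params: ModelParams | None = None) -> "SimConfig":
        bad = self.violations(params)
        if bad:
            raise ParameterError(bad)
        return self


@dataclass
class EnsembleState:
    """State of one angular slice: N microtubule tips plus the flow speed.

    ``r`` holds tip radial positions (um, in [0, R]); ``growing`` the phase
    of each MT.  ``vr`` is the current retrograde flow speed (um/min).
    """

    r: np.ndarray
    growing: np.ndarray
    vr: float
    theta_deg: float
    t: float = 0.0

    @property
    def n_mt(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class AngleTimeSeries:
    """Recorded trajectory of one angular slice."""

    theta_deg: float
    t: np.ndarray
    p: np.ndarray
    vr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta_deg": self.theta_deg, "t_min": self.t, "p": self.p, "vr": self.vr}
        )


@dataclass(frozen=True)
class GrowthConeProfile:
    """Steady-state angular profiles and the net protrusion angle.

    ``theta_p`` is the polar angle (deg) of the vector sum of the local
    protrusion vectors, or ``None`` when the sum is degenerate (zero net
    protrusion).
    """

    theta_grid: np.ndarray
    p_mean: np.ndarray
    p_se: np.ndarray
    vr_mean: np.ndarray
    vr_se: np.ndarray
    vcell_mean: np.ndarray
    vcell_se: np.ndarray
    theta_p: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_deg": self.theta_grid,
                "p_mean": self.p_mean,
                "p_se": self.p_se,
                "vr_mean": self.vr_mean,
                "vr_se": self.vr_se,
                "vcell_mean": self.vcell_mean,
                "vcell_se": self.vcell_se,
            }
        )


def _angle_rng(seed: int, theta_deg: float) -> np.random.Generator:
    """Deterministic per-angle RNG substream.

    Keyed on the angle value (in millidegrees) rather than its grid index,
    so a slice's stream does not depend on the grid ordering or on which
    other angles are simulated.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(round(theta_deg * 1000)),))
    )


def init_ensemble(
    n_mt: int, params: ModelParams, theta_deg: float = 90.0
) -> EnsembleState:
    """Fresh ensemble: all MTs growing at r = 0 (originating in the C domain).

    With no tips yet at the leading edge, the retrograde flow starts at its
    maximum ``v0``.
    """
    if n_mt < 1:
        raise ParameterError([f"n_mt must be >= 1, got {n_mt!r}"])
    return EnsembleState(
        r=np.zeros(n_mt, dtype=float),
        growing=np.ones(n_mt, dtype=bool),
        vr=params.actin.v0,
        theta_deg=float(theta_deg),
    )


def leading_edge_fraction(ens: EnsembleState, params: ModelParams) -> float:
    """Fraction of tips strictly past the leading-edge line (r > 0.75*R)."""
    if ens.n_mt == 0:
        raise ParameterError(["ensemble is empty"])
    cutoff = params.geom.leading_edge_cutoff * params.geom.R
    return float(np.count_nonzero(ens.r > cutoff)) / ens.n_mt


def step_ensemble(
    ens: EnsembleState,
    pr: float,
    params: ModelParams,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> EnsembleState:
    """Advance the ensemble by one time step ``dt`` (in place) and return it.

    Sequence: phase switching, tip motion at the current ``vr``, boundary
    rules, then the feedback update of ``vr`` from the new leading-edge
    fraction.
    """
    mt, actin, geom = params.mt, params.actin, params.geom
    dt = cfg.dt
    r, growing = ens.r, ens.growing

    u = rng.random(ens.n_mt)
    flip = np.where(growing, u < mt.f_cat * dt, u < mt.f_res * dt)
    growing ^= flip

    if cfg.coupling_mode == "mean":
        c: float | np.ndarray = pr
    else:
        c = (rng.random(ens.n_mt) < pr).astype(float)
    drag = c * ens.vr
    dr = np.where(growing, (mt.v_plus - drag) * dt, -(mt.v_minus + drag) * dt)
    r += dr

    # membrane at R: forced catastrophe; C domain at r=0: rescue/regrowth
    at_top = r >= geom.R
    at_bottom = r <= 0.0
    np.clip(r, 0.0, geom.R, out=r)
    growing[at_top] = False
    growing[at_bottom] = True

    ens.t += dt
    p = leading_edge_fraction(ens, params)
    ens.vr = actin.v0 / (1.0 + actin.beta * p)
    return ens


def simulate_angle(
    theta_deg: float, params: ModelParams, cfg: SimConfig, pr: float | None = None
) -> AngleTimeSeries:
    """Simulate one angular slice at fixed coupling probability.

    ``pr`` defaults to the gradient formula evaluated at ``theta_deg``; pass
    it explicitly to pin the coupling (e.g. for oracle comparisons).
    Deterministic given (seed, theta_deg, config).
    """
    cfg.validate(params)
    if pr is None:
        pr = coupling_probability(theta_deg, params.grad)
    rng = _angle_rng(cfg.seed, theta_deg)
    ens = init_ensemble(cfg.n_mt, params, theta_deg)

    n_steps = int(round(cfg.t_total / cfg.dt))
    n_rec = n_steps // cfg.record_stride
    t_out = np.empty(n_rec)
    p_out = np.empty(n_rec)
    vr_out = np.empty(n_rec)
    k = 0
    for step in range(1, n_steps + 1):
        step_ensemble(ens, pr, params, cfg, rng)
        if step % cfg.record_stride == 0:
            t_out[k] = ens.t
            p_out[k] = leading_edge_fraction(ens, params)
            vr_out[k] = ens.vr
            k += 1
    return AngleTimeSeries(theta_deg=float(theta_deg), t=t_out[:k], p=p_out[:k], vr=vr_out[:k])


def final_positions(
    theta_deg: float, params: ModelParams, cfg: SimConfig, pr: float | None = None
) -> np.ndarray:
    """Run one angular slice and return the final tip positions (um).

    Convenience for distribution-level checks against the mean-field
    steady-state profile.
    """
    cfg.validate(params)
    if pr is None:
        pr = coupling_probability(theta_deg, params.grad)
    rng = _angle_rng(cfg.seed, theta_deg)
    ens = init_ensemble(cfg.n_mt, params, theta_deg)
    for _ in range(int(round(cfg.t_total / cfg.dt))):
        step_ensemble(ens, pr, params, cfg, rng)
    return ens.r.copy()


def _block_se(x: np.ndarray, n_blocks: int = 10) -> float:
    """Batch-means standard error, robust to autocorrelation in ``x``.

    The post-burn-in series is cut into ``n_blocks`` contiguous blocks; the
    spread of block means estimates the error of the overall mean provided
    blocks are longer than the correlation time.
    """
    n = x.size
    n_blocks = min(n_blocks, n)
    m = n // n_blocks
    means = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    if n_blocks < 2:
        return float("nan")
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def steady_state_summary(
    ts: AngleTimeSeries, params: ModelParams, cfg: SimConfig
) -> dict[str, float]:
    """Steady-state means and standard errors from the post-burn-in samples.

    Returns ``p_mean``, ``vr_mean``, ``vcell_mean = vp - vr_mean`` and
    block-estimator standard errors (``p_se``, ``vr_se``, ``vcell_se``).
    """
    mask = ts.t > cfg.burn_in
    if int(mask.sum()) < 100:
        raise ParameterError(
            [
                "steady-state averaging needs >= 100 recorded samples after "
                f"burn_in; got {int(mask.sum())}"
            ]
        )
    p = ts.p[mask]
    vr = ts.vr[mask]
    vr_se = _block_se(vr)
    return {
        "p_mean": float(p.mean()),
        "p_se": _block_se(p),
        "vr_mean": float(vr.mean()),
        "vr_se": vr_se,
        "vcell_mean": float(protrusion_speed(vr.mean(), params.actin)),
        "vcell_se": vr_se,
    }


def net_protrusion_angle(
    theta_grid: np.ndarray, vcell: np.ndarray, v0: float
) -> float | None:
    """Polar angle (deg) of the vector sum of local protrusion vectors.

    Each angle contributes a vector ``vcell * (cos theta, sin theta)`` with
    equal weight.  Returns ``None`` when the resultant magnitude is below
    ``1e-9 * v0 * n_angles`` (no net protrusion direction).
    """
    theta = np.deg2rad(np.asarray(theta_grid, dtype=float))
    v = np.asarray(vcell, dtype=float)
    x = float(np.sum(v * np.cos(theta)))
    y = float(np.sum(v * np.sin(theta)))
    if np.hypot(x, y) < 1e-9 * v0 * theta.size:
        return None
    return float(np.rad2deg(np.arctan2(y, x)))


def simulate_growth_cone(params: ModelParams, cfg: SimConfig) -> GrowthConeProfile:
    """Simulate every angle of the growth cone and assemble the profiles.

    Each angle runs an independent ensemble on its own RNG substream, so the
    result is invariant to grid order.  Returns steady-state profiles of
    p, vr and vcell plus the net protrusion angle ``theta_p``.
    """
    cfg.validate(params)
    grid = np.asarray(params.geom.theta_grid, dtype=float)
    rows = []
    for theta in grid:
        ts = simulate_angle(theta, params, cfg)
        rows.append(steady_state_summary(ts, params, cfg))
    cols = {key: np.array([row[key] for row in rows]) for key in rows[0]}
    theta_p = net_protrusion_angle(grid, cols["vcell_mean"], params.actin.v0)
    return GrowthConeProfile(
        theta_grid=grid,
        p_mean=cols["p_mean"],
        p_se=cols["p_se"],
        vr_mean=cols["vr_mean"],
        vr_se=cols["vr_se"],
        vcell_mean=cols["vcell_mean"],
        vcell_se=cols["vcell_se"],
        theta_p=theta_p,
    )


def sweep(
    params: ModelParams,
    cfg: SimConfig,
    A_values: Sequence[float] | None = None,
    beta_values: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Grid sweep over gradient steepness A and/or adhesion sensitivity beta.

    Runs :func:`simulate_growth_cone` at every (A, beta) grid point with a
    reproducible per-point seed (``cfg.seed`` plus the linear point index;
    a single-point grid therefore reproduces one direct call exactly).
    Returns a long-format table with one row per grid point.
    """
    A_axis = list(A_values) if A_values is not None else [params.grad.A]
    b_axis = list(beta_values) if beta_values is not None else [params.actin.beta]
    if not A_axis or not b_axis:
        raise ParameterError(["sweep axes must be non-empty"])
    records = []
    idx = 0
    for A in A_axis:
        for beta in b_axis:
            point_params = params.replace(A=float(A), beta=float(beta))
            point_cfg = replace(cfg, seed=cfg.seed + idx)
            prof = simulate_growth_cone(point_params, point_cfg)
            records.append(
                {
                    "A": float(A),
                    "beta": float(beta),
                    "seed": point_cfg.seed,
                    "theta_p": np.nan if prof.theta_p is None else prof.theta_p,
                    "p_mean_min": float(prof.p_mean.min()),
                    "p_mean_max": float(prof.p_mean.max()),
                    "vr_mean_min": float(prof.vr_mean.min()),
                    "vr_mean_max": float(prof.vr_mean.max()),
                    "vcell_mean_max": float(prof.vcell_mean.max()),
                }
            )
            idx += 1
    return pd.DataFrame.from_records(records)
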