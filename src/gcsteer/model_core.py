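"""Core parameters and closed-form relations of the growth-cone turning model.

The model couples microtubule (MT) dynamic instability to the actin-adhesion
"molecular clutch" of a neuronal growth cone.  MT tips stochastically switch
between growing and shrinking phases (catastrophe frequency ``f_cat``, rescue
frequency ``f_res``) while an angle-dependent fraction of MTs is mechanically
linked to the rearward-flowing f-actin network and dragged away from the
leading edge at the retrograde flow speed ``v_r``.  MTs that reach the leading
edge strengthen substrate adhesion, which attenuates retrograde flow
(a force balance, :func:`retrograde_speed`) and thereby lets actin
polymerization drive protrusion (:func:`protrusion_speed`).  An external
guidance-cue gradient enters only through the angular dependence of the
MT-actin coupling probability (:func:`coupling_probability`).

All angles are in degrees (0 = up the gradient, 180 = down the gradient),
speeds in um/min, frequencies in 1/min, lengths in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import numpy as np

__all__ = [
    "MTParams",
    "ActinParams",
    "GradientParams",
    "Geometry",
    "ModelParams",
    "ParameterError",
    "coupling_probability",
    "retrograde_speed",
    "protrusion_speed",
    "classify_growth_regime",
    "validate_params",
    "UNBOUNDED",
    "BOUNDED",
    "MARGINAL",
]

UNBOUNDED = "unbounded"
BOUNDED = "bounded"
MARGINAL = "marginal"

#: Tolerance used to flag the marginal growth regime (criterion exactly zero
#: up to floating-point round-off on the scale of the rates involved).
_MARGINAL_RTOL = 1e-12


class ParameterError(ValueError):
    """A model parameter violates its documented constraint.

    Carries a list of human-readable violation messages so that callers can
    report every problem with a parameter bundle at once.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class MTParams:
    """Microtubule dynamic-instability rates and speeds.

    Defaults are fluorescence-imaging estimates for Aplysia bag cell growth
    cones.

    Attributes
    ----------
    f_cat : float
        Catastrophe frequency (growing -> shrinking), 1/min.
    f_res : float
        Rescue frequency (shrinking -> growing), 1/min.
    v_plus : float
        Polymerization speed of a growing tip, um/min.
    v_minus : float
        Depolymerization speed of a shrinking tip, um/min.
    """

    f_cat: float = 0.61
    f_res: float = 1.79
    v_plus: float = 6.0
    v_minus: float = 9.6

    def violations(self) -> list[str]:
        out = []
        for name in ("f_cat", "f_res", "v_plus", "v_minus"):
            if not getattr(self, name) > 0:
                out.append(f"MTParams.{name} must be > 0, got {getattr(self, name)!r}")
        return out


@dataclass(frozen=True)
class ActinParams:
    """Actin retrograde flow / clutch parameters.

    Attributes
    ----------
    v0 : float
        Maximum actin retrograde flow speed (no leading-edge MTs), um/min.
    vp : float
        Leading-edge actin polymerization speed, um/min.  The default
        ``vp == v0`` is the treadmilling reference state: polymerization
        exactly cancels retrograde flow and net protrusion is zero until
        the clutch engages.
    beta : float
        Adhesion sensitivity: dimensionless gain relating the leading-edge
        MT fraction to the added viscous resistance opposing retrograde
        flow.  ``beta = 0`` disables the MT -> adhesion feedback.
    """

    v0: float = 5.0
    vp: float = 5.0
    beta: float = 0.1

    def violations(self) -> list[str]:
        out = []
        if not self.v0 > 0:
            out.append(f"ActinParams.v0 must be > 0, got {self.v0!r}")
        if not self.vp >= 0:
            out.append(f"ActinParams.vp must be >= 0, got {self.vp!r}")
        if not self.beta >= 0:
            out.append(f"ActinParams.beta must be >= 0, got {self.beta!r}")
        return out


@dataclass(frozen=True)
class GradientParams:
    """Guidance-cue gradient parameters.

    The external cue concentration increases linearly across the growth cone;
    it enters the model only through the MT-actin coupling probability
    ``p_r(theta) = pr0 * (1 - A cos(theta))``.

    Attributes
    ----------
    pr0 : float
        Coupling probability at theta = 90 deg (perpendicular to the
        gradient), in [0, 1].
    A : float
        Dimensionless gradient steepness in [0, 1].  ``A = 0`` is a uniform
        signal; ``A`` near 1 is maximal coupling asymmetry.  The raw cue
        slope alpha and the radius R enter only through ``A = alpha*R/pr0``.
    """

    pr0: float = 0.5
    A: float = 0.0

    def violations(self) -> list[str]:
        out = []
        if not 0.0 <= self.pr0 <= 1.0:
            out.append(f"GradientParams.pr0 must be in [0, 1], got {self.pr0!r}")
        if not 0.0 <= self.A <= 1.0:
            out.append(f"GradientParams.A must be in [0, 1], got {self.A!r}")
        if self.pr0 * (1.0 + self.A) > 1.0 + 1e-12:
            out.append(
                "GradientParams: pr0*(1+A) must be <= 1 so the coupling "
                f"probability stays in [0, 1]; got {self.pr0 * (1.0 + self.A):g}"
            )
        return out


def _default_theta_grid() -> tuple[float, ...]:
    return tuple(float(t) for t in range(0, 181, 10))


@dataclass(frozen=True)
class Geometry:
    """Semi-circular growth-cone geometry.

    The model treats the growth cone as a family of independent 1-D radial
    slices, one per angular coordinate ``theta`` in [0, 180] deg.

    Attributes
    ----------
    R : float
        Growth cone radius, um.
    leading_edge_cutoff : float
        Fraction of R beyond which a tip counts as "leading edge"
        (default 0.75: tips past the 75% line).
    theta_grid : tuple of float
        Ordered angles in degrees; must start at 0 and end at 180.
    """

    R: float = 10.0
    leading_edge_cutoff: float = 0.75
    theta_grid: tuple[float, ...] = field(default_factory=_default_theta_grid)

    def violations(self) -> list[str]:
        out = []
        if not self.R > 0:
            out.append(f"Geometry.R must be > 0, got {self.R!r}")
        if not 0.0 < self.leading_edge_cutoff < 1.0:
            out.append(
                "Geometry.leading_edge_cutoff must be in (0, 1), "
                f"got {self.leading_edge_cutoff!r}"
            )
        grid = np.asarray(self.theta_grid, dtype=float)
        if grid.size < 1 or grid[0] != 0.0 or grid[-1] != 180.0:
            out.append(
                "Geometry.theta_grid must start at 0 and end at 180, "
                f"got {self.theta_grid!r}"
            )
        elif not np.all(np.diff(grid) > 0):
            out.append("Geometry.theta_grid must be strictly increasing")
        return out


@dataclass(frozen=True)
class ModelParams:
    """Validated bundle of all model parameters.

    Construct via :func:`validate_params` (or directly, then validate).
    """

    mt: MTParams = field(default_factory=MTParams)
    actin: ActinParams = field(default_factory=ActinParams)
    grad: GradientParams = field(default_factory=GradientParams)
    geom: Geometry = field(default_factory=Geometry)

    def replace(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with flat field overrides (e.g. ``beta=0.5, A=0.9``)."""
        groups = {"mt": self.mt, "actin": self.actin, "grad": self.grad, "geom": self.geom}
        updates: dict[str, dict[str, Any]] = {g: {} for g in groups}
        for key, value in kwargs.items():
            if key in groups:
                groups[key] = value
                continue
            for gname, gval in groups.items():
                if key in {f.name for f in fields(gval)}:
                    updates[gname][key] = value
                    break
            else:
                raise KeyError(f"unknown parameter {key!r}")
        new = {g: replace(v, **updates[g]) if updates[g] else v for g, v in groups.items()}
        return ModelParams(**new)  # type: ignore[arg-type]


def coupling_probability(theta_deg, grad: GradientParams):
    """MT-actin coupling probability at angle ``theta_deg``.

    ``p_r(theta) = pr0 * (1 - A cos(theta))``: lowest up the gradient
    (theta = 0), equal to ``pr0`` at 90 deg, highest down the gradient.
    Accepts a scalar or array of angles in degrees.
    """
    bad = grad.violations()
    if bad:
        raise ParameterError(bad)
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 180):
        raise ParameterError([f"theta_deg must be in [0, 180], got {theta_deg!r}"])
    pr = grad.pr0 * (1.0 - grad.A * np.cos(np.deg2rad(theta)))
    # clip pure round-off excursions; the invariant pr0*(1+A) <= 1 guarantees
    # the exact value is in [0, 1]
    pr = np.clip(pr, 0.0, 1.0)
    return float(pr) if np.isscalar(theta_deg) else pr


def retrograde_speed(p, actin: ActinParams):
    """Actin retrograde flow speed given leading-edge MT fraction ``p``.

    Force balance on the f-actin network: the driving force is constant while
    leading-edge MTs add viscous resistance in proportion to ``beta * p``,
    giving ``v_r = v0 / (1 + beta * p)``.  Value lies in [v0/(1+beta), v0].
    """
    bad = actin.violations()
    if bad:
        raise ParameterError(bad)
    parr = np.asarray(p, dtype=float)
    if np.any(parr < 0) or np.any(parr > 1):
        raise ParameterError([f"leading-edge fraction p must be in [0, 1], got {p!r}"])
    vr = actin.v0 / (1.0 + actin.beta * parr)
    return float(vr) if np.isscalar(p) else vr


def protrusion_speed(vr, actin: ActinParams):
    """Leading-edge protrusion speed ``v_cell = vp - vr`` (clutch relation).

    Negative values mean net retraction; when ``vp == v0`` (treadmilling
    reference) the result is always >= 0 because ``vr <= v0``.
    """
    bad = actin.violations()
    if bad:
        raise ParameterError(bad)
    vcell = actin.vp - np.asarray(vr, dtype=float)
    return float(vcell) if np.isscalar(vr) else vcell


def effective_speeds(mt: MTParams, pr: float, vr: float) -> tuple[float, float]:
    """Effective tip speeds under partial coupling to retrograde flow.

    A growing tip advances at ``v_g = v_plus - pr*vr`` (polymerization minus
    mean retrograde drag); a shrinking tip retreats at ``v_s = v_minus + pr*vr``.
    """
    return mt.v_plus - pr * vr, mt.v_minus + pr * vr


def classify_growth_regime(mt: MTParams, pr: float, vr: float) -> str:
    """Classify the MT population as ``unbounded``, ``bounded`` or ``marginal``.

    The two-state tip model with effective speeds ``v_g = v_plus - pr*vr``
    and ``v_s = v_minus + pr*vr`` has positive mean tip drift iff
    ``v_g*f_res - v_s*f_cat > 0`` (unbounded growth: tips persistently reach
    the leading edge).  Negative drift gives bounded growth with a finite
    exponential length distribution.  The knife-edge case is reported as
    ``marginal``.  If ``v_g <= 0`` the drift is retrograde, hence bounded.
    """
    bad = mt.violations()
    if bad:
        raise ParameterError(bad)
    v_g, v_s = effective_speeds(mt, pr, vr)
    if v_s <= 0:
        raise ParameterError([f"effective shrink speed v_s must be > 0, got {v_s:g}"])
    if v_g <= 0:
        return BOUNDED
    crit = v_g * mt.f_res - v_s * mt.f_cat
    scale = (v_g * mt.f_res + v_s * mt.f_cat) or 1.0
    if abs(crit) <= _MARGINAL_RTOL * scale:
        return MARGINAL
    return UNBOUNDED if crit > 0 else BOUNDED


def validate_params(
    mt: MTParams | None = None,
    actin: ActinParams | None = None,
    grad: GradientParams | None = None,
    geom: Geometry | None = None,
) -> ModelParams:
    """Validate every type invariant and return a :class:`ModelParams` bundle.

    All violations are aggregated into a single :class:`ParameterError`
    naming each offending field, rather than failing on the first.
    """
    bundle = ModelParams(
        mt=mt or MTParams(),
        actin=actin or ActinParams(),
        grad=grad or GradientParams(),
        geom=geom or Geometry(),
    )
    bad: list[str] = []
    for part in (bundle.mt, bundle.actin, bundle.grad, bundle.geom):
        bad.extend(part.violations())
    if bad:
        raise ParameterError(bad)
    return bundle


def params_to_mapping(params: ModelParams) -> dict[str, Any]:
    """Flatten a parameter bundle to a plain mapping (for config files)."""
    out: dict[str, Any] = {}
    for group in (params.mt, params.actin, params.grad, params.geom):
        for f in fields(group):
            value = getattr(group, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
    return out


def params_from_mapping(mapping: Mapping[str, Any]) -> ModelParams:
    """Build a validated bundle from a flat mapping; unknown keys rejected."""
    known = {
        "mt": MTParams,
        "actin": ActinParams,
        "grad": GradientParams,
        "geom": Geometry,
    }
    groups: dict[str, dict[str, Any]] = {g: {} for g in known}
    field_owner = {
        f.name: gname for gname, cls in known.items() for f in fields(cls)
    }
    unknown = []
    for key, value in mapping.items():
        owner = field_owner.get(key)
        if owner is None:
            unknown.append(key)
            continue
        if key == "theta_grid":
            value = tuple(float(v) for v in value)
        groups[owner][key] = value
    if unknown:
        raise ParameterError([f"unknown parameter key(s): {sorted(unknown)!r}"])
    return validate_params(
        mt=MTParams(**groups["mt"]),
        actin=ActinParams(**groups["actin"]),
        grad=GradientParams(**groups["grad"]),
        geom=Geometry(**groups["geom"]),
    )
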