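"""Closed-form geometry of idealized coronary plaque shells.

Two parametric models describe the shape of an atherosclerotic plaque as a
portion of a cylindrical shell of uniform thickness wrapped around the
artery lumen:

* **Model 1** — a full cylindrical ring (external radius ``R``, internal
  radius ``r``, height ``h`` on the centerline) whose two end faces are
  planes slanted by dihedral angles ``theta1`` and ``theta2`` against the
  perpendicular cross-section.  This idealizes a mature plaque that is
  circumferentially symmetric but extends asymmetrically along the vessel.
* **Model 2** — a partial cylindrical ring spanning a circumferential
  angle ``theta`` with flat perpendicular ends, idealizing an early-stage
  patchy plaque growing on one side of the wall.

For both models the volume ``V``, surface area ``S``, the characteristic
lengths, and the ratio ``S/V`` have closed forms.  Growth hypotheses
prescribe how the parameters co-vary as a plaque enlarges; under each
hypothesis the log–log slope ``d ln S / d ln V`` (the allometric exponent
of the power law S = c·V^e) tends to a known limit:

=================  ==========  ==========
hypothesis          S–V limit   L–V limit
=================  ==========  ==========
H1.1 (isometric)     2/3          1/3
H1.2 (slant grows)   1            2/3
H2.1 (θ → 2π)        2/3          1/3
=================  ==========  ==========

These limits bracket the exponents fitted on real plaque populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Model1Params",
    "Model2Params",
    "ClosedFormMetrics",
    "GrowthHypothesis",
    "InvalidParameterError",
    "model1_metrics",
    "model2_metrics",
    "ln_ratio",
    "scale_params",
    "asymptotic_exponent",
    "sv_ratio_trajectory",
]

Pair = Literal["S_V", "L_V"]
LengthChoice = Literal["wall", "cross", "chord"]


class InvalidParameterError(ValueError):
    """A model parameter set violates a geometric constraint."""


@dataclass(frozen=True)
class Model1Params:
    """Full cylindrical ring with slanted end planes.

    Parameters
    ----------
    R, r : float
        External and internal radius in mm, ``R > r > 0``.
    h : float
        Height on the centerline in mm.
    theta1, theta2 : float
        Dihedral angles (radians, in ``[0, pi/2)``) between each end
        plane and the perpendicular cross-section.  Both planes tilt
        about the same transverse axis, so the maximal axial extension
        lies on one side of the wall (``x = +R``).
    check_extent : bool
        When True (default) require ``h > R (tan theta1 + tan theta2)``
        so the end planes do not intersect inside the shell and the
        solid is realizable (meshable).  Growth-hypothesis H1.2
        trajectories evaluate the closed forms beyond that regime and
        construct parameters with ``check_extent=False``.
    """

    R: float
    r: float
    h: float
    theta1: float = 0.0
    theta2: float = 0.0
    check_extent: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.R > self.r > 0.0):
            raise InvalidParameterError(
                f"require R > r > 0, got R={self.R}, r={self.r}"
            )
        if not self.h > 0.0:
            raise InvalidParameterError(f"require h > 0, got h={self.h}")
        for name, th in (("theta1", self.theta1), ("theta2", self.theta2)):
            if not (0.0 <= th < math.pi / 2):
                raise InvalidParameterError(
                    f"require 0 <= {name} < pi/2, got {th}"
                )
        if self.check_extent:
            slant = self.R * (math.tan(self.theta1) + math.tan(self.theta2))
            if not self.h > slant:
                raise InvalidParameterError(
                    "end planes intersect within the shell: require "
                    f"h > R*(tan(theta1)+tan(theta2)) = {slant:.6g}, got h={self.h}"
                )


@dataclass(frozen=True)
class Model2Params:
    """Partial cylindrical ring spanning azimuth ``[0, theta]``.

    ``theta`` in ``(0, 2*pi]``; early-stage plaques have ``theta < pi``.
    ``theta = 2*pi`` is the closure limit of circumferential growth and is
    flagged degenerate (the two flat radial side faces coincide).
    """

    R: float
    r: float
    h: float
    theta: float = math.pi / 2

    def __post_init__(self) -> None:
        if not (self.R > self.r > 0.0):
            raise InvalidParameterError(
                f"require R > r > 0, got R={self.R}, r={self.r}"
            )
        if not self.h > 0.0:
            raise InvalidParameterError(f"require h > 0, got h={self.h}")
        if not (0.0 < self.theta <= 2.0 * math.pi):
            raise InvalidParameterError(
                f"require 0 < theta <= 2*pi, got theta={self.theta}"
            )


@dataclass(frozen=True)
class ClosedFormMetrics:
    """Closed-form geometric quantities of one plaque shell (mm-based).

    ``L_wall``/``L_cross`` are the two Model-1 length readings (along the
    external wall vs. diagonally across the geometry); ``L`` is the
    Model-2 chord between the far corners of the partial ring.  Fields
    not defined for a model are None.
    """

    V: float
    S: float
    sv_ratio: float
    L_wall: float | None = None
    L_cross: float | None = None
    L: float | None = None

    def length(self, choice: LengthChoice) -> float:
        """Return the requested characteristic length."""
        value = {"wall": self.L_wall, "cross": self.L_cross, "chord": self.L}[choice]
        if value is None:
            raise ValueError(f"length choice {choice!r} undefined for this model")
        return value


@dataclass(frozen=True)
class GrowthHypothesis:
    """A rule for how plaque-shell parameters co-vary during growth.

    tag
        ``H1_1`` — R, r, h scale together, slant angles fixed (isometric
        growth of the full ring).
        ``H1_2`` — R, r, h and both end-plane secants 1/cos(theta_i)
        scale together (slant steepens as the plaque spreads along the
        wall); requires ``secant_base``.
        ``H2_1`` — R, r, h scale together while theta rises toward 2*pi
        (circumferential closure of the partial ring).
    """

    tag: Literal["H1_1", "H1_2", "H2_1"]
    base: Model1Params | Model2Params
    secant_base: float | None = None

    def __post_init__(self) -> None:
        if self.tag in ("H1_1", "H1_2") and not isinstance(self.base, Model1Params):
            raise InvalidParameterError(f"{self.tag} requires Model1Params")
        if self.tag == "H2_1" and not isinstance(self.base, Model2Params):
            raise InvalidParameterError("H2_1 requires Model2Params")
        if self.tag == "H1_2":
            if self.secant_base is None or self.secant_base < 1.0:
                raise InvalidParameterError(
                    "H1_2 requires secant_base >= 1 (a secant of a slant angle)"
                )


def model1_metrics(p: Model1Params) -> ClosedFormMetrics:
    """Closed-form V, S, S/V and lengths of the slanted full ring.

    V = pi*h*(R+r)*(R-r)
    S = pi*(R+r)*[2h + (R-r)*(sec(theta1)+sec(theta2))]
    S/V = 2/(R-r) + (sec(theta1)+sec(theta2))/h
    L_wall = h + R*(tan(theta1)+tan(theta2))           (along external wall)
    L_cross = sqrt((2R)^2 + (h + R tan(theta1) - R tan(theta2))^2)

    Slanting does not change the volume: each end plane passes through the
    centerline at z = ±h/2, so material gained on one side of the tilt
    axis compensates material lost on the other.
    """
    sec1 = 1.0 / math.cos(p.theta1)
    sec2 = 1.0 / math.cos(p.theta2)
    ring = (p.R + p.r) * (p.R - p.r)
    V = math.pi * p.h * ring
    S = math.pi * (p.R + p.r) * (2.0 * p.h + (p.R - p.r) * (sec1 + sec2))
    sv = 2.0 / (p.R - p.r) + (sec1 + sec2) / p.h
    t1 = math.tan(p.theta1)
    t2 = math.tan(p.theta2)
    L_wall = p.h + p.R * (t1 + t2)
    L_cross = math.hypot(2.0 * p.R, p.h + p.R * t1 - p.R * t2)
    return ClosedFormMetrics(V=V, S=S, sv_ratio=sv, L_wall=L_wall, L_cross=L_cross)


def model2_metrics(p: Model2Params) -> ClosedFormMetrics:
    """Closed-form V, S, S/V and chord length of the partial ring.

    V = (theta/2)*h*(R+r)*(R-r)
    S = theta*h*(R+r) + 2h*(R-r) + theta*(R^2 - r^2)
    S/V = 2*[2/(theta*(R+r)) + 1/h + 1/(R-r)]
    L = sqrt(h^2 + (2R sin(theta/2))^2)   (chord between far corners)

    At ``theta = 2*pi`` the flat side faces coincide; the side-face term
    ``2h(R-r)`` is retained (the closed forms vary continuously in theta)
    and a degeneracy warning is emitted.
    """
    if p.theta == 2.0 * math.pi:
        warnings.warn(
            "theta = 2*pi: side faces vanish; the 2h(R-r) side-face term is "
            "retained so S is the continuous limit of the partial-ring formula",
            RuntimeWarning,
            stacklevel=2,
        )
    ring = (p.R + p.r) * (p.R - p.r)
    V = 0.5 * p.theta * p.h * ring
    S = p.theta * p.h * (p.R + p.r) + 2.0 * p.h * (p.R - p.r) + p.theta * ring
    sv = 2.0 * (2.0 / (p.theta * (p.R + p.r)) + 1.0 / p.h + 1.0 / (p.R - p.r))
    L = math.hypot(p.h, 2.0 * p.R * math.sin(0.5 * p.theta))
    return ClosedFormMetrics(V=V, S=S, sv_ratio=sv, L=L)


def metrics_for(p: Model1Params | Model2Params) -> ClosedFormMetrics:
    """Dispatch to the matching closed-form evaluation."""
    if isinstance(p, Model1Params):
        return model1_metrics(p)
    return model2_metrics(p)


def ln_ratio(
    m: ClosedFormMetrics,
    pair: Pair = "S_V",
    length_choice: LengthChoice = "wall",
) -> float:
    """Ratio of natural logs, ln S / ln V or ln L / ln V (mm-based).

    This is the finite-size reading of the allometric exponent; it only
    equals the power-law exponent asymptotically (see
    :func:`asymptotic_exponent`).
    """
    if m.V <= 0.0:
        raise ValueError(f"V must be positive, got {m.V}")
    lnV = math.log(m.V)
    if lnV == 0.0:
        raise ValueError("ln V = 0 (V = 1 mm^3): ln-ratio undefined")
    num = m.S if pair == "S_V" else m.length(length_choice)
    if num <= 0.0:
        raise ValueError(f"numerator quantity must be positive, got {num}")
    return math.log(num) / lnV


def scale_params(
    g: GrowthHypothesis, k: float
) -> Model1Params | Model2Params:
    """Parameters of the plaque grown by scale factor ``k`` under ``g``.

    H1_1: (kR, kr, kh, theta1, theta2)
    H1_2: (kR, kr, kh) with sec(theta_i) = k * secant_base
    H2_1: (kR, kr, kh, theta(k)), theta(k) = 2*pi - (2*pi - theta0)/k

    The H2.1 schedule is one monotone, smooth, invertible approach of
    theta to 2*pi; any bounded monotone schedule gives the same limits.
    """
    if not k > 0.0:
        raise ValueError(f"scale factor must be positive, got {k}")
    b = g.base
    if g.tag == "H1_1":
        assert isinstance(b, Model1Params)
        return Model1Params(k * b.R, k * b.r, k * b.h, b.theta1, b.theta2)
    if g.tag == "H1_2":
        assert isinstance(b, Model1Params)
        sec = k * float(g.secant_base)  # type: ignore[arg-type]
        if sec < 1.0:
            raise ValueError(
                f"k*secant_base = {sec:.6g} < 1: no slant angle has that secant"
            )
        th = math.acos(1.0 / sec)
        return Model1Params(
            k * b.R, k * b.r, k * b.h, th, th, check_extent=False
        )
    assert isinstance(b, Model2Params)
    theta = 2.0 * math.pi - (2.0 * math.pi - b.theta) / k
    if theta <= 0.0:  # k < 1 can push theta negative
        raise ValueError(f"theta(k) = {theta:.6g} <= 0 at k = {k}")
    theta = min(theta, 2.0 * math.pi)
    return Model2Params(k * b.R, k * b.r, k * b.h, theta)


def _log_quantities(
    g: GrowthHypothesis,
    ks: np.ndarray,
    pair: Pair,
    length_choice: LengthChoice,
) -> tuple[np.ndarray, np.ndarray]:
    """ln(numerator quantity) and ln(V) along a growth trajectory."""
    ln_num = np.empty(ks.size)
    ln_V = np.empty(ks.size)
    for i, k in enumerate(ks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = metrics_for(scale_params(g, float(k)))
        num = m.S if pair == "S_V" else m.length(length_choice)
        if not (math.isfinite(num) and math.isfinite(m.V) and num > 0 and m.V > 0):
            raise ArithmeticError(
                f"non-finite geometric quantity at scale k = {k:.6g}"
            )
        ln_num[i] = math.log(num)
        ln_V[i] = math.log(m.V)
    return ln_num, ln_V


def asymptotic_exponent(
    g: GrowthHypothesis,
    pair: Pair = "S_V",
    length_choice: LengthChoice = "wall",
    k_max: float = 1e6,
    n_points: int = 50,
) -> float:
    """Numerical estimate of the limiting allometric exponent under ``g``.

    Evaluates the trajectory on a geometric grid of scale factors in
    ``[1, k_max]`` and returns the finite-difference slope
    ``Δln(S or L)/Δln V`` between the two largest scales.  The same
    last-interval estimator applies unchanged to mesh-measured
    populations, unlike a symbolic limit.
    """
    if k_max < 1e3:
        raise ValueError(f"k_max must be >= 1e3 for a meaningful limit, got {k_max}")
    if n_points < 10:
        raise ValueError(f"n_points must be >= 10, got {n_points}")
    ks = np.geomspace(1.0, k_max, n_points)
    ln_num, ln_V = _log_quantities(g, ks, pair, length_choice)
    return float((ln_num[-1] - ln_num[-2]) / (ln_V[-1] - ln_V[-2]))


def sv_ratio_trajectory(
    g: GrowthHypothesis, k_max: float = 1e4, n_points: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """S/V along a growth trajectory on a geometric scale grid.

    Returns ``(ks, sv)``.  Under every hypothesis S/V decreases
    monotonically to zero as the plaque grows — the geometric statement
    that large plaques have proportionally less surface.
    """
    ks = np.geomspace(1.0, k_max, n_points)
    sv = np.empty(ks.size)
    for i, k in enumerate(ks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sv[i] = metrics_for(scale_params(g, float(k))).sv_ratio
    return ks, sv
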