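"""Selectivity curve families.

Two mode-rescaled density families describe how capture probability varies
with fish length:

* mesh nets — a gamma density rescaled so its modal value is 1.  Under
  geometric similarity all nets share one curve variance ``theta2`` while
  the modal length scales with mesh size, ``mode_i = theta1 * m_i``.  The
  per-net gamma shape/scale ``(alpha_i, beta_i)`` follow from the two
  moment constraints ``(alpha-1)*beta = theta1*m`` and
  ``alpha*beta**2 = theta2``.
* predators — a lognormal density rescaled to modal value 1, with
  log-scale location ``theta3`` and spread ``theta4``; its mode is
  ``exp(theta3 - theta4**2)``.

All evaluations run in log space so extreme lengths underflow gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CatchTable, GearSpec

__all__ = [
    "SelectivityParams",
    "GammaShape",
    "solve_gamma_shape",
    "gamma_selectivity",
    "lognormal_selectivity",
    "lognormal_mode",
    "lognormal_variance",
    "curve_summary",
    "selectivity_matrix",
]


@dataclass(frozen=True)
class SelectivityParams:
    """The four estimands of the joint gillnet + predator selectivity model.

    Attributes
    ----------
    theta1 : float
        Modal length per unit mesh size (cm per mm); > 0.
    theta2 : float
        Gamma-curve variance shared by all mesh nets (cm^2); > 0.
    theta3 : float
        Lognormal log-scale location of the predator curve (log-cm).
    theta4 : float
        Lognormal log-scale spread of the predator curve; > 0.
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta1) and self.theta1 > 0):
            raise ValueError(f"theta1 must be finite and > 0, got {self.theta1}")
        if not (np.isfinite(self.theta2) and self.theta2 > 0):
            raise ValueError(f"theta2 must be finite and > 0, got {self.theta2}")
        if not np.isfinite(self.theta3):
            raise ValueError(f"theta3 must be finite, got {self.theta3}")
        if not (np.isfinite(self.theta4) and self.theta4 > 0):
            raise ValueError(f"theta4 must be finite and > 0, got {self.theta4}")

    def to_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3, self.theta4])

    @classmethod
    def from_array(cls, x) -> "SelectivityParams":
        t1, t2, t3, t4 = np.asarray(x, dtype=float)
        return cls(t1, t2, t3, t4)


@dataclass(frozen=True)
class GammaShape:
    """Gamma shape/scale for one net; mode = (alpha-1)*beta, var = alpha*beta^2."""

    alpha: float
    beta: float

    @property
    def mode(self) -> float:
        return (self.alpha - 1.0) * self.beta

    @property
    def variance(self) -> float:
        return self.alpha * self.beta**2


def solve_gamma_shape(mesh: float, params: SelectivityParams) -> GammaShape:
    """Unique (alpha, beta) with mode theta1*mesh and variance theta2.

    Eliminating alpha from the two constraints leaves the quadratic
    ``beta**2 + theta1*mesh*beta - theta2 = 0`` whose positive root is beta;
    then ``alpha = theta1*mesh/beta + 1 > 1``, so the mode is interior.
    """
    if not (np.isfinite(mesh) and mesh > 0):
        raise ValueError(f"mesh size must be finite and > 0 mm, got {mesh}")
    mode = params.theta1 * mesh
    beta = 0.5 * (-mode + np.hypot(mode, 2.0 * np.sqrt(params.theta2)))
    alpha = mode / beta + 1.0
    return GammaShape(alpha=alpha, beta=beta)


def _check_lengths(length) -> np.ndarray:
    arr = np.asarray(length, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("lengths must be finite and > 0 cm")
    return arr


def gamma_log_selectivity(length, mesh: float,
                          params: SelectivityParams) -> np.ndarray:
    """log of the mode-rescaled gamma net selectivity at ``length`` (cm)."""
    arr = _check_lengths(length)
    shape = solve_gamma_shape(mesh, params)
    mode = shape.mode
    return (shape.alpha - 1.0) * np.log(arr / mode) + (mode - arr) / shape.beta


def gamma_selectivity(length, mesh: float,
                      params: SelectivityParams) -> np.ndarray:
    """Relative net selectivity in (0, 1]; exactly 1 at length theta1*mesh."""
    return np.exp(gamma_log_selectivity(length, mesh, params))


def lognormal_mode(params: SelectivityParams) -> float:
    """Modal length (cm) of the predator curve: exp(theta3 - theta4^2)."""
    return float(np.exp(params.theta3 - params.theta4**2))


def lognormal_variance(params: SelectivityParams) -> float:
    """Variance (cm^2) of the lognormal(theta3, theta4) distribution."""
    s2 = params.theta4**2
    return float((np.exp(s2) - 1.0) * np.exp(2.0 * params.theta3 + s2))


def lognormal_log_selectivity(length, params: SelectivityParams) -> np.ndarray:
    """log of the mode-rescaled lognormal predator selectivity."""
    arr = _check_lengths(length)
    t3, t4 = params.theta3, params.theta4
    logl = np.log(arr)
    # log pdf(l) - log pdf(mode), constants cancelling
    return (t3 - t4**2) - logl - (logl - t3) ** 2 / (2.0 * t4**2) + t4**2 / 2.0


def lognormal_selectivity(length, params: SelectivityParams) -> np.ndarray:
    """Relative predator selectivity in (0, 1]; 1 at exp(theta3 - theta4^2)."""
    return np.exp(lognormal_log_selectivity(length, params))


def gear_log_selectivity(length, gear: GearSpec,
                         params: SelectivityParams) -> np.ndarray:
    if gear.family == "mesh":
        return gamma_log_selectivity(length, gear.mesh_size, params)
    return lognormal_log_selectivity(length, params)


def gear_selectivity(length, gear: GearSpec,
                     params: SelectivityParams) -> np.ndarray:
    """Family-appropriate relative selectivity for one gear."""
    return np.exp(gear_log_selectivity(length, gear, params))


def curve_summary(gear: GearSpec, params: SelectivityParams
                  ) -> tuple[float, float]:
    """(mode cm, variance cm^2) of a gear's selectivity curve."""
    if gear.family == "mesh":
        return params.theta1 * gear.mesh_size, params.theta2
    return lognormal_mode(params), lognormal_variance(params)


def selectivity_matrix(lengths_or_table, gears=None,
                       params: SelectivityParams = None,
                       log: bool = False) -> np.ndarray:
    """S_ij matrix: entry (j, i) = selectivity of gear i at length class j.

    Accepts either ``(CatchTable, params=...)`` or
    ``(lengths, gears, params)``.
    """
    if isinstance(lengths_or_table, CatchTable):
        table = lengths_or_table
        lengths, gears = table.length_classes, table.gears
        if params is None:
            raise TypeError("params is required")
    else:
        lengths = np.asarray(lengths_or_table, dtype=float)
        if gears is None or params is None:
            raise TypeError("gears and params are required")
    out = np.empty((len(lengths), len(gears)))
    for i, g in enumerate(gears):
        out[:, i] = gear_log_selectivity(lengths, g, params)
    return out if log else np.exp(out)
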