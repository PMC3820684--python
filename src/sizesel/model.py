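"""Joint maximum-likelihood fitting of net and predator selectivity curves.

The sampling model treats the catch of gear ``i`` in length class ``j`` as
Poisson with mean ``f_i * mu_j * S_ij(theta)`` where ``mu_j`` is relative
abundance, ``S_ij`` the gear's selectivity at that length and ``f_i`` its
fishing power.  Because fishing power moves only a gear's sample size, not
the length distribution within its sample, per-gear normalised frequencies
carry all the information about ``theta``; normalisation is therefore the
default pipeline step and the powers never need estimating.  With all
``f_i`` fixed to 1, the abundances maximise out in closed form,

    mu_j = sum_i n_ij / sum_i S_ij,

leaving a 4-parameter profile log-likelihood kernel

    l(theta) = sum_{ij} [ n_ij * ln(mu_j S_ij) - mu_j S_ij ]

(the parameter-free ln n_ij! term is dropped; it is undefined anyway for
non-integer frequencies).  The kernel is maximised by Nelder-Mead in
log-parameter space, which enforces positivity without constraints, and
standard errors come from the observed information (numerical Hessian in
natural parameter space).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .overlap import OverlapReport
from .overlap import curve_table as _curve_table
from .overlap import overlap as _overlap_fn
from .overlap import overlap_matrix as _overlap_matrix
from .overlap import plot_curves as _plot_curves
from .curves import (SelectivityParams, curve_summary, gear_selectivity,
                     selectivity_matrix)
from .data import CatchTable, CatchTableError, normalize, read_catch_table

__all__ = ["SelectivityModel", "SelectivityResults", "profile_mu"]

_PENALTY = 1e10

_FALLBACK_THETA2 = 10.0
_FALLBACK_THETA4 = 0.5


def profile_mu(counts: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Closed-form profile of the relative abundances.

    ``mu_j = (sum_i n_ij) / (sum_i S_ij)`` for length classes with positive
    total catch, 0 for empty classes (their likelihood terms vanish).
    """
    counts = np.asarray(counts, dtype=float)
    S = np.asarray(S, dtype=float)
    if counts.shape != S.shape:
        raise ValueError(
            f"shape mismatch: counts {counts.shape} vs S {S.shape}"
        )
    tot = counts.sum(axis=1)
    denom = S.sum(axis=1)
    mu = np.zeros(len(tot))
    pos = tot > 0
    if np.any(denom[pos] <= 0):
        raise ValueError("selectivity sums to zero in a class with catches")
    mu[pos] = tot[pos] / denom[pos]
    return mu


class SelectivityModel:
    """Size-selectivity model for a multi-gear length-frequency catch table.

    Parameters
    ----------
    table : CatchTable
        Catch counts or per-gear frequencies; needs at least one mesh gear.
    normalize : bool, default True
        Convert counts to per-gear frequencies before fitting (the standard
        pipeline, robust to unequal fishing powers).  Pass False to fit raw
        counts, which presumes all powers equal.

    Examples
    --------
    >>> from sizesel import SelectivityModel, load_perch_catches
    >>> res = SelectivityModel(load_perch_catches()).fit()
    >>> round(res.params.theta1, 2)
    0.71
    """

    def __init__(self, table: CatchTable, normalize: bool = True) -> None:
        if table.n_gears < 2 or table.n_classes < 2:
            raise CatchTableError(
                "need at least 2 gears and 2 length classes to fit"
            )
        self.raw_table = table
        self.normalized_internally = bool(normalize and not table.is_normalized)
        if self.normalized_internally:
            from .data import normalize as _norm
            table = _norm(table)
        self.table = table
        self._n = table.values
        self._lengths = table.length_classes
        self._keep = self._n.sum(axis=1) > 0
        self.has_mesh = any(g.family == "mesh" for g in table.gears)
        self.has_predator = any(g.family == "predator" for g in table.gears)
        if not self.has_mesh:
            raise CatchTableError("model requires at least one mesh gear")
        # which of (theta1..theta4) the data can identify
        self.active = np.array([True, True, self.has_predator,
                                self.has_predator])

    @classmethod
    def from_file(cls, path, layout: str = "wide", normalize: bool = True,
                  gear_declarations: Mapping[str, dict] | None = None,
                  ) -> "SelectivityModel":
        return cls(read_catch_table(path, layout=layout,
                                    gear_declarations=gear_declarations),
                   normalize=normalize)

    # -- likelihood --------------------------------------------------------
    def profile_abundance(self, params: SelectivityParams) -> pd.Series:
        """Profiled relative abundance per length class at ``params``."""
        S = selectivity_matrix(self.table, params=params)
        return pd.Series(profile_mu(self._n, S), index=self.table.counts.index,
                         name="mu")

    def nloglik(self, params) -> float:
        """Negative profile log-likelihood kernel (lower is better)."""
        x = params.to_array() if isinstance(params, SelectivityParams) \
            else np.asarray(params, dtype=float)
        if x.shape != (4,) or not np.all(np.isfinite(x)) or np.any(x <= 0):
            warnings.warn("invalid selectivity parameters; returning penalty",
                          RuntimeWarning, stacklevel=2)
            return _PENALTY
        logS = selectivity_matrix(self._lengths, self.table.gears,
                                  SelectivityParams.from_array(x), log=True)
        S = np.exp(logS)
        n = self._n
        keep = self._keep
        denom = S[keep].sum(axis=1)
        if np.any(denom <= 0):
            return _PENALTY
        mu = n[keep].sum(axis=1) / denom
        logmu = np.log(mu)
        lam = mu[:, None] * S[keep]
        # n * ln(mu S): ln S stays finite in log space even where S underflows
        ll = float(np.sum(np.where(n[keep] > 0,
                                   n[keep] * (logmu[:, None] + logS[keep]),
                                   0.0) - lam))
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    # -- initialisation ----------------------------------------------------
    def initialize(self) -> SelectivityParams:
        """Heuristic starting values from the observed frequency shapes.

        The mode of a gear's length-frequency distribution approximates its
        selectivity mode, and around two-thirds of the occupied width of
        that distribution serves as a variance-scale guess.
        """
        df = self.table.counts
        mesh_gear = next(g for g in self.table.gears if g.family == "mesh")
        col = df[mesh_gear.id].to_numpy()
        occupied = self._lengths[col > 0]
        modal = self._lengths[int(np.argmax(col))]
        theta1 = modal / mesh_gear.mesh_size
        if len(occupied) > 1:
            theta2 = (2.0 / 3.0) * (occupied.max() - occupied.min())
        else:
            theta2 = _FALLBACK_THETA2
        theta4 = _FALLBACK_THETA4
        theta3 = np.log(np.median(self._lengths)) + theta4**2
        if self.has_predator:
            pred = next(g for g in self.table.gears if g.family == "predator")
            colp = df[pred.id].to_numpy()
            occ = self._lengths[colp > 0]
            modal_p = self._lengths[int(np.argmax(colp))]
            if len(occ) > 1:
                # two-thirds-width rule mapped to the log scale via the CV
                theta4 = float(np.clip(
                    np.sqrt((2.0 / 3.0) * (occ.max() - occ.min())) / modal_p,
                    0.05, 2.0))
            theta3 = np.log(modal_p) + theta4**2
        return SelectivityParams(theta1, theta2, float(theta3), float(theta4))

    # -- fitting -----------------------------------------------------------
    def fit(self, start: SelectivityParams | None = None, *,
            xatol: float = 1e-10, fatol: float = 1e-10,
            maxfev: int = 5000, restarts: int = 1,
            compute_se: bool = True) -> "SelectivityResults":
        """Maximise the profile likelihood by Nelder-Mead.

        Parameters
        ----------
        start : SelectivityParams, optional
            Starting point; defaults to :meth:`initialize`.
        xatol, fatol : float
            Simplex convergence tolerances (log-parameter space).
        maxfev : int
            Evaluation budget per Nelder-Mead run.
        restarts : int
            Automatic restarts from the incumbent (a fresh simplex around
            the best point guards against premature shrinkage).
        compute_se : bool
            Compute observed-information standard errors at the optimum.
        """
        init = start if start is not None else self.initialize()
        x_full = init.to_array().copy()
        act = self.active

        def obj(z):
            x = x_full.copy()
            x[act] = np.exp(z)
            return self.nloglik(x)

        z = np.log(x_full[act])
        nfev = 0
        success = False
        for _ in range(restarts + 1):
            res = minimize(obj, z, method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": fatol,
                                    "maxfev": maxfev})
            z = res.x
            nfev += res.nfev
            success = bool(res.success)
        converged = bool(success and np.isfinite(res.fun)
                         and res.fun < _PENALTY)
        if not converged:
            warnings.warn("Nelder-Mead did not converge; returning best "
                          "point found", RuntimeWarning, stacklevel=2)
        xhat = x_full.copy()
        xhat[act] = np.exp(z)
        params = SelectivityParams.from_array(xhat)

        bse = np.full(4, np.nan)
        hessian_ok = False
        if compute_se and converged:
            bse_act, hessian_ok = self._standard_errors(xhat)
            bse[act] = bse_act
        mu = self.profile_abundance(params)
        return SelectivityResults(
            model=self, params=params, bse=bse, llf=-float(res.fun),
            mu=mu, converged=converged, n_evals=nfev, start=init,
            hessian_ok=hessian_ok,
            settings={"xatol": xatol, "fatol": fatol, "maxfev": maxfev,
                      "restarts": restarts,
                      "normalized": self.table.is_normalized},
        )

    def _standard_errors(self, xhat: np.ndarray) -> tuple[np.ndarray, bool]:
        """sqrt diag of the inverse numerical Hessian over active parameters."""
        act = self.active
        x_full = xhat.copy()

        def obj_nat(xa):
            x = x_full.copy()
            x[act] = xa
            return self.nloglik(x)

        k = int(act.sum())
        try:
            H = approx_hess(xhat[act], obj_nat)
            # PD check via Cholesky; a saddle or flat direction means the
            # curvature-based SEs are meaningless, so report them as undefined
            np.linalg.cholesky(H)
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError
            return np.sqrt(d), True
        except np.linalg.LinAlgError:
            warnings.warn("observed information not positive definite; "
                          "standard errors undefined", RuntimeWarning,
                          stacklevel=2)
            return np.full(k, np.nan), False


@dataclass
class SelectivityResults:
    """Results of a selectivity model fit.

    Attributes
    ----------
    params : SelectivityParams
        Maximum-likelihood estimates.
    bse : ndarray
        Standard errors per parameter (NaN where undefined/inactive).
    llf : float
        Maximised log-likelihood kernel.
    mu : pandas.Series
        Profiled relative abundance per length class.
    converged : bool
    n_evals : int
        Total objective evaluations used by the optimiser.
    start : SelectivityParams
        The starting point used.
    hessian_ok : bool
        Whether the observed information was positive definite.
    """

    model: SelectivityModel
    params: SelectivityParams
    bse: np.ndarray
    llf: float
    mu: pd.Series
    converged: bool
    n_evals: int
    start: SelectivityParams
    hessian_ok: bool
    settings: dict = field(default_factory=dict)

    # -- summaries ---------------------------------------------------------
    def curve_summaries(self) -> pd.DataFrame:
        """Mode (cm) and variance (cm^2) of each gear's fitted curve."""
        rows = [curve_summary(g, self.params) for g in self.model.table.gears]
        return pd.DataFrame(rows, columns=["mode_cm", "variance_cm2"],
                            index=self.model.table.gear_ids)

    def summary(self) -> str:
        """Plain-text fit report (parameters, SEs, diagnostics)."""
        p = self.params.to_array()
        names = ["theta1", "theta2", "theta3", "theta4"]
        units = ["cm/mm", "cm^2", "log-cm", "-"]
        t = self.model.table
        lines = [
            "         Selectivity Model Results",
            "=" * 46,
            f"Gears: {t.n_gears} ({sum(g.family == 'mesh' for g in t.gears)}"
            f" mesh, {sum(g.family == 'predator' for g in t.gears)} predator)"
            f"   Length classes: {t.n_classes}",
            f"Normalized frequencies: {t.is_normalized}",
            f"Log-likelihood kernel: {self.llf:.4f}",
            f"Converged: {self.converged}   Evaluations: {self.n_evals}",
            "-" * 46,
            f"{'param':<8}{'estimate':>10}{'std err':>10}  unit",
        ]
        for name, est, se, u in zip(names, p, self.bse, units):
            se_s = f"{se:>10.4f}" if np.isfinite(se) else f"{'--':>10}"
            lines.append(f"{name:<8}{est:>10.4f}{se_s}  {u}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- overlap / curves --------------------------------------------------
    def overlap(self, gear_a: str, gear_b: str, **kw) -> OverlapReport:
        """Overlap coefficient (%) between two gears' fitted curves."""
        t = self.model.table
        return _overlap_fn(t.gear(gear_a), t.gear(gear_b),
                           self.params, **kw)

    def overlap_matrix(self, **kw) -> pd.DataFrame:
        return _overlap_matrix(self.model.table.gears, self.params, **kw)

    def curve_table(self, **kw) -> pd.DataFrame:
        return _curve_table(self.model.table.gears, self.params, **kw)

    def plot_curves(self, ax=None, **kw):
        return _plot_curves(self.model.table.gears, self.params,
                            ax=ax, **kw)

    # -- export ------------------------------------------------------------
    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {"theta1": p.theta1, "theta2": p.theta2,
                       "theta3": p.theta3, "theta4": p.theta4},
            "std_errors": {f"theta{i+1}": (None if not np.isfinite(se)
                                           else float(se))
                           for i, se in enumerate(self.bse)},
            "loglik": self.llf,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "hessian_ok": self.hessian_ok,
            "init": {"theta1": self.start.theta1, "theta2": self.start.theta2,
                     "theta3": self.start.theta3, "theta4": self.start.theta4},
            "settings": self.settings,
            "gears": [{"id": g.id, "family": g.family,
                       "mesh_size": g.mesh_size}
                      for g in self.model.table.gears],
            "mu": {f"{k:g}": v for k, v in self.mu.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def params_frame(self) -> pd.DataFrame:
        """Parameter/SE table in the conventional two-column layout."""
        return pd.DataFrame({
            "Estimate": self.params.to_array(),
            "Std. Error": self.bse,
        }, index=["theta1", "theta2", "theta3", "theta4"])
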