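"""Cell-line adaptation by L1-regularized fold changes with AIC selection.

A new cell line inherits the calibrated base parameters p_i; deviations
are expressed as multiplicative fold changes r_i (p_i* = p_i * r_i),
penalized by lambda * sum_i |log10 r_i| so that r_i = 1 (no difference)
is favored.  Receptor abundance parameters of the new line are free and
unpenalized.  For every lambda on a fixed grid the penalized problem is
solved (the non-smooth penalty via the exact positive/negative split,
which is smooth with nonnegativity bounds), fold changes compatible
with zero are snapped to exactly zero, and the surviving active set is
refitted without penalty; the regularization strength is then selected
by AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FAILURE_OBJECTIVE, _local_fit, multistart_fit

__all__ = [
    "SNAP_THRESHOLD",
    "DEFAULT_LAMBDA_GRID",
    "FoldChangeSet",
    "RegularizationPathPoint",
    "penalized_objective",
    "fit_lambda_path",
    "select_model_aic",
]

logger = logging.getLogger("erbbsig.l1")

#: |log10 r| below this after the penalized stage is an exact L1 zero
SNAP_THRESHOLD: float = 1e-3

#: fold changes whose unpenalized refit estimate stays below this are
#: "compatible with 0" (about a 12% parameter change, the scale of the
#: measurement noise) and are dropped with a further refit
REFIT_DROP_THRESHOLD: float = 0.05

#: 20 log-spaced penalty weights
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.logspace(-2, 3, 20)
)


@dataclass
class FoldChangeSet:
    """Per-parameter log10 fold changes at one penalty weight."""

    log10_r: dict[str, float]
    lam: float
    penalized: tuple[str, ...]

    @property
    def fold_changes(self) -> dict[str, float]:
        return {k: 10.0 ** v for k, v in self.log10_r.items()}

    @property
    def zero_set(self) -> tuple[str, ...]:
        return tuple(k for k in self.penalized if self.log10_r[k] == 0.0)

    @property
    def active_set(self) -> tuple[str, ...]:
        return tuple(k for k in self.penalized if self.log10_r[k] != 0.0)


@dataclass
class RegularizationPathPoint:
    lam: float
    penalized_objective: float
    refit_objective: float
    fold_changes: FoldChangeSet
    n_active: int
    n_other_free: int
    converged: bool = True

    @property
    def aic(self) -> float:
        """AIC = (unpenalized -2 log L) + 2 (k_active + other free params)."""
        return self.refit_objective + 2.0 * (self.n_active + self.n_other_free)


def penalized_objective(theta, lam: float, spec, penalized=None) -> float:
    """chi2 at the fold-change vector plus ``lam * sum |log10 r_i|``.

    ``spec`` must be an objective in fold-change mode (``reference`` set);
    ``penalized`` restricts the penalty to a subset of the free names
    (protein abundances are fitted without the L1 prior).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    theta = np.asarray(theta, dtype=float)
    names = spec.free_names if penalized is None else tuple(penalized)
    idx = [spec.free_names.index(n) for n in names]
    value, _ = spec.objective(theta, grad=False)
    return float(value + lam * np.sum(np.abs(theta[idx])))


class _SplitPenalizedSpec:
    """Exact smooth reformulation of the L1 problem.

    Penalized coordinates rho are split as rho = z+ - z- with z+, z- >= 0
    and penalty lam * (z+ + z-); unpenalized coordinates pass through.
    """

    def __init__(self, spec, lam: float, penalized: tuple[str, ...]):
        self.spec, self.lam = spec, lam
        self.pen_idx = np.array([spec.free_names.index(n) for n in penalized],
                                dtype=int)
        self.fre_idx = np.array([i for i in range(len(spec.free_names))
                                 if i not in set(self.pen_idx)], dtype=int)
        npen, nfre = len(self.pen_idx), len(self.fre_idx)
        self.free_names = (
            tuple(f"{spec.free_names[i]}+" for i in self.pen_idx)
            + tuple(f"{spec.free_names[i]}-" for i in self.pen_idx)
            + tuple(spec.free_names[i] for i in self.fre_idx)
        )
        up = spec.upper[self.pen_idx]
        lo = spec.lower[self.pen_idx]
        self.lower = np.concatenate(
            [np.zeros(2 * npen), spec.lower[self.fre_idx]])
        self.upper = np.concatenate(
            [np.maximum(up, 0.0), np.maximum(-lo, 0.0),
             spec.upper[self.fre_idx]])

    def to_theta(self, z):
        npen = len(self.pen_idx)
        theta = np.empty(len(self.spec.free_names))
        theta[self.pen_idx] = z[:npen] - z[npen:2 * npen]
        theta[self.fre_idx] = z[2 * npen:]
        return theta

    def from_theta(self, theta):
        npen = len(self.pen_idx)
        z = np.empty(2 * npen + len(self.fre_idx))
        rho = theta[self.pen_idx]
        z[:npen] = np.maximum(rho, 0.0)
        z[npen:2 * npen] = np.maximum(-rho, 0.0)
        z[2 * npen:] = theta[self.fre_idx]
        return z

    def objective(self, z, grad: bool = True):
        npen = len(self.pen_idx)
        f, g = self.spec.objective(self.to_theta(z), grad=grad)
        value = f + self.lam * float(np.sum(z[:2 * npen]))
        if not grad:
            return value, None
        gz = np.empty_like(z)
        gz[:npen] = g[self.pen_idx] + self.lam
        gz[npen:2 * npen] = -g[self.pen_idx] + self.lam
        gz[2 * npen:] = g[self.fre_idx]
        return value, gz


class _FixedSubsetSpec:
    """Objective with a subset of coordinates frozen (for the snap-refit)."""

    def __init__(self, spec, fixed: dict[int, float]):
        self.spec, self.fixed = spec, dict(fixed)
        self.keep = np.array([i for i in range(len(spec.free_names))
                              if i not in fixed], dtype=int)
        self.free_names = tuple(spec.free_names[i] for i in self.keep)
        self.lower = spec.lower[self.keep]
        self.upper = spec.upper[self.keep]

    def full(self, th):
        out = np.empty(len(self.spec.free_names))
        out[self.keep] = th
        for i, v in self.fixed.items():
            out[i] = v
        return out

    def objective(self, th, grad: bool = True):
        f, g = self.spec.objective(self.full(th), grad=grad)
        return f, (None if g is None else g[self.keep])


def _snap_refit(spec, theta, penalized, maxiter, ftol, lam):
    """Snap fold changes compatible with zero and refit the rest.

    Exact L1 zeros from the penalized stage are fixed first; after the
    unpenalized refit, surviving fold changes whose estimates stay below
    ``REFIT_DROP_THRESHOLD`` are also judged compatible with zero (a
    correlated neighbor of a shrunken true effect typically lands at the
    noise scale), fixed, and the refit repeated to a fixed point.  At
    lam = 0 no zero-compatibility judgment is applied.
    """
    theta = np.asarray(theta, dtype=float).copy()
    pen_idx = [spec.free_names.index(n) for n in penalized]
    fixed = {i: 0.0 for i in pen_idx if abs(theta[i]) < SNAP_THRESHOLD}
    for _ in range(1 + len(pen_idx)):
        sub = _FixedSubsetSpec(spec, fixed)
        if len(sub.keep):
            res = _local_fit(sub, np.clip(theta[sub.keep], sub.lower,
                                          sub.upper),
                             maxiter, ftol)
            theta_ref = sub.full(np.asarray(res.x))
            refit_obj = float(res.fun)
        else:
            refit_obj, _ = spec.objective(sub.full(np.empty(0)), grad=False)
            theta_ref = sub.full(np.empty(0))
        if lam == 0:
            break
        small = {i: 0.0 for i in pen_idx if i not in fixed
                 and abs(theta_ref[i]) < REFIT_DROP_THRESHOLD}
        if not small:
            break
        fixed.update(small)
        theta = theta_ref
    return theta_ref, refit_obj


def fit_lambda_path(
    spec,
    lam_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    penalized: tuple[str, ...] | None = None,
    n_starts: int = 1,
    maxiter: int = 150,
    ftol: float = 1e-9,
) -> list[RegularizationPathPoint]:
    """Two-stage L1 path over an ascending lambda grid.

    ``spec`` must be a fold-change objective (``reference`` set) whose
    free names are the fold-change candidates plus any unpenalized free
    parameters (e.g. receptor abundances).  Per lambda: penalized
    multistart fit (warm-started from the previous path point), snap of
    fold changes compatible with zero, unpenalized refit of the active
    set.  Failed points are flagged and the path continues.
    """
    lam_grid = [float(l) for l in lam_grid]
    if any(l < 0 for l in lam_grid) or list(lam_grid) != sorted(lam_grid):
        raise ValueError("lam_grid must be nonnegative and ascending")
    if penalized is None:
        penalized = tuple(n for n in spec.free_names
                          if spec.reference is not None and n in spec.reference)
    penalized = tuple(penalized)
    n_other = len(spec.free_names) - len(penalized)

    path: list[RegularizationPathPoint] = []
    warm = np.zeros(len(spec.free_names))
    for i, lam in enumerate(lam_grid):
        split = _SplitPenalizedSpec(spec, lam, penalized)
        try:
            fit = multistart_fit(
                split, n_starts=n_starts, seed=seed + i,
                start=split.from_theta(warm), maxiter=maxiter, ftol=ftol)
            theta_pen = split.to_theta(fit.theta)
            theta_ref, refit_obj = _snap_refit(spec, theta_pen, penalized,
                                               maxiter, ftol, lam)
            warm = theta_ref.copy()
            fc = FoldChangeSet(
                log10_r=dict(zip(spec.free_names, theta_ref)),
                lam=lam, penalized=penalized)
            path.append(RegularizationPathPoint(
                lam=lam,
                penalized_objective=float(fit.objective),
                refit_objective=refit_obj,
                fold_changes=fc,
                n_active=len(fc.active_set),
                n_other_free=n_other,
                converged=fit.objective < FAILURE_OBJECTIVE / 2,
            ))
        except RuntimeError as exc:
            logger.warning("lambda = %g failed: %s", lam, exc)
            path.append(RegularizationPathPoint(
                lam=lam, penalized_objective=np.inf, refit_objective=np.inf,
                fold_changes=FoldChangeSet(
                    log10_r={n: np.nan for n in spec.free_names},
                    lam=lam, penalized=penalized),
                n_active=0, n_other_free=n_other, converged=False))
    return path


def select_model_aic(path) -> tuple[float, FoldChangeSet]:
    """Path point minimizing AIC; ties break toward larger lambda."""
    usable = [p for p in path if p.converged and np.isfinite(p.aic)]
    if not usable:
        raise ValueError("no successful path point")
    best = usable[0]
    for p in usable[1:]:
        if p.aic < best.aic or (p.aic == best.aic and p.lam > best.lam):
            best = p
    return best.lam, best.fold_changes


def path_table(path) -> pd.DataFrame:
    """Tidy summary of a regularization path."""
    rows = []
    for p in path:
        row = {"lambda": p.lam, "penalized_objective": p.penalized_objective,
               "refit_objective": p.refit_objective, "n_active": p.n_active,
               "aic": p.aic, "converged": p.converged}
        for name, v in p.fold_changes.log10_r.items():
            row[f"log10_r[{name}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)
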