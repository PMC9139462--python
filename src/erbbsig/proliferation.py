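"""Linking signaling dynamics to proliferation.

Signaling features (area under the curve, peak height, half-life and
maximal upward slope over the stimulation phase, 60-240 min) are
extracted from simulated trajectories of pAKT, ppERK, pS6K and the
pooled active receptor dimers.  Feature selection uses a
cross-validated L1 path with the 1-SE rule on standardized features;
the final reduced growth model is the affine law

    y = alpha1 + beta1 * AUC_pAKT + beta2 * AUC_pS6K

fitted by ordinary least squares on single-treatment data (y on the
log2 fold-change scale).  Co-treatment predictions simulate the
two-drug condition — whose dimer-formation rates carry the product
1/(1+k1) * 1/(1+k2) of the single-drug inhibition factors — and apply
the fitted law without any refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .network import DIMERS, ConditionSpec, Trajectory
from .simulate import CompiledNetwork, simulate_condition, steady_state_initialize

__all__ = [
    "PHASE_II",
    "FEATURE_STATES",
    "RegressionModel",
    "extract_features",
    "signaling_feature_table",
    "select_features_lasso",
    "fit_reduced_regression",
    "predict_growth",
]

logger = logging.getLogger("erbbsig.proliferation")

PHASE_II: tuple[float, float] = (60.0, 240.0)

#: states entering the candidate feature grid
FEATURE_STATES: tuple[str, ...] = ("pAKT", "ppERK", "pS6K", "active_dimers")

_FEATURES = ("auc", "peak", "half_life", "max_slope")


def _phase_series(traj: Trajectory, state: str):
    """Signal over phase II, resampled to the canonical 1-min grid."""
    if state == "active_dimers":
        y = np.sum([traj.state(d) for d in DIMERS], axis=0)
    else:
        y = traj.state(state)
    lo, hi = PHASE_II
    grid = np.arange(lo, hi + 1e-9, 1.0)
    return grid, np.interp(grid, traj.times, y)


def extract_features(
    traj: Trajectory,
    states=FEATURE_STATES,
) -> pd.DataFrame:
    """Per-state signaling features over the stimulation phase.

    AUC by the trapezoid rule on the trajectory grid; peak is the phase
    maximum; half-life is the time after the peak at which the signal
    first drops to half the peak (capped at the phase end, with a
    ``half_life_capped`` flag); max_slope is the largest forward
    difference.  The trajectory must cover [60, 240] min.
    """
    lo, hi = PHASE_II
    if traj.times[0] > lo or traj.times[-1] < hi:
        raise ValueError("trajectory must cover the stimulation phase "
                         f"[{lo}, {hi}] min")
    rows = {}
    for state in states:
        t, y = _phase_series(traj, state)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite trajectory for {state}")
        auc = float(np.trapezoid(y, t))
        i_peak = int(np.argmax(y))
        peak = float(y[i_peak])
        half = peak / 2.0
        capped = True
        half_life = float(t[-1] - t[i_peak])
        for j in range(i_peak + 1, len(t)):
            if y[j] <= half:
                # linear interpolation inside the bracketing interval
                if y[j] < y[j - 1]:
                    w = (y[j - 1] - half) / (y[j - 1] - y[j])
                else:
                    w = 1.0
                half_life = float(t[j - 1] + w * (t[j] - t[j - 1]) - t[i_peak])
                capped = False
                break
        slopes = np.diff(y) / np.diff(t)
        rows[state] = {
            "auc": auc,
            "peak": peak,
            "half_life": half_life,
            "half_life_capped": capped,
            "max_slope": float(np.max(slopes)) if slopes.size else 0.0,
        }
    return pd.DataFrame(rows).T


def signaling_feature_table(
    comp: CompiledNetwork,
    params: dict[str, float],
    conditions,
    x0: np.ndarray | None = None,
    grid_step: float = 1.0,
) -> pd.DataFrame:
    """Feature matrix over conditions (rows) x state-feature pairs
    (columns named ``<feature>_<state>``), simulated on a fine grid."""
    times = np.arange(0.0, PHASE_II[1] + 1e-9, grid_step)
    if x0 is None:
        x0, _ = steady_state_initialize(comp, params)
    rows = []
    index = []
    for cond in conditions:
        traj = simulate_condition(comp, params, cond, times, x0=x0)
        feats = extract_features(traj)
        row = {}
        for state in feats.index:
            for f in _FEATURES:
                row[f"{f}_{state}"] = float(feats.loc[state, f])
        rows.append(row)
        index.append(cond.label)
    return pd.DataFrame(rows, index=index)


# ---------------------------------------------------------------------------
# feature selection and the reduced model
# ---------------------------------------------------------------------------


def select_features_lasso(
    feature_table: pd.DataFrame,
    y,
    seed: int = 0,
    n_folds: int = 5,
    n_alphas: int = 100,
):
    """Cross-validated L1 feature selection with the 1-SE rule.

    Features are z-scored before penalization; constant columns are
    dropped with a warning.  Returns ``(selected_features,
    coefficients)`` where coefficients are on the original feature scale
    at the 1-SE penalty.  A constant response yields an empty selection.
    """
    y = np.asarray(y, dtype=float)
    if len(feature_table) < 8:
        raise ValueError("need at least 8 conditions for feature selection")
    if len(y) != len(feature_table):
        raise ValueError("response length does not match the feature table")
    X = feature_table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = list(feature_table.columns[~keep])
        warnings.warn(f"dropping constant feature columns: {dropped}",
                      stacklevel=2)
    cols = list(feature_table.columns[keep])
    if not cols or np.std(y) == 0:
        return [], {}
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    cv = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=n_alphas, max_iter=100_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xz, y)
    mse = model.mse_path_.mean(axis=1)
    se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    limit = mse[i_min] + se[i_min]
    # alphas_ are descending; the 1-SE alpha is the largest within one SE
    i_1se = next(i for i in range(len(model.alphas_)) if mse[i] <= limit)
    coef_path = model.path(Xz, y, alphas=model.alphas_, max_iter=100_000,
                           tol=1e-8)[1]
    coefs_z = coef_path[:, i_1se]
    nonzero = np.abs(coefs_z) > 1e-10    # coordinate-descent numerical zeros
    selected = [c for c, nz in zip(cols, nonzero) if nz]
    coefs = {c: float(b / s) for c, b, s, nz in
             zip(cols, coefs_z, sd[keep], nonzero) if nz}
    return selected, coefs


@dataclass
class RegressionModel:
    """The reduced affine growth model on the two AUC features."""

    intercept: float
    coef: dict[str, float]             # auc_pAKT, auc_pS6K
    stderr: dict[str, float]
    residual_sd: float
    nobs: int

    def predict(self, features: pd.DataFrame | pd.Series) -> np.ndarray:
        if isinstance(features, pd.Series):
            features = features.to_frame().T
        out = np.full(len(features), self.intercept)
        for name, b in self.coef.items():
            out = out + b * features[name].to_numpy(dtype=float)
        return out


REDUCED_FEATURES: tuple[str, ...] = ("auc_pAKT", "auc_pS6K")


def fit_reduced_regression(feature_table: pd.DataFrame, y) -> RegressionModel:
    """OLS fit of ``y = alpha1 + beta1 AUC_pAKT + beta2 AUC_pS6K``."""
    y = np.asarray(y, dtype=float)
    missing = [f for f in REDUCED_FEATURES if f not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table lacks {missing}")
    if len(feature_table) < 3:
        raise ValueError("need at least 3 conditions")
    X = sm.add_constant(feature_table[list(REDUCED_FEATURES)].to_numpy(float),
                        has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regression design")
    res = sm.OLS(y, X).fit()
    dof = max(res.df_resid, 1)
    return RegressionModel(
        intercept=float(res.params[0]),
        coef={f: float(b) for f, b in zip(REDUCED_FEATURES, res.params[1:])},
        stderr={f: float(s) for f, s in zip(("const",) + REDUCED_FEATURES,
                                            res.bse)},
        residual_sd=float(np.sqrt(res.ssr / dof)),
        nobs=int(res.nobs),
    )


def predict_growth(
    comp: CompiledNetwork,
    params: dict[str, float],
    regression: RegressionModel,
    cond: ConditionSpec,
    x0: np.ndarray | None = None,
) -> float:
    """Predicted log2 fold-change growth response for a (co-)treatment.

    The condition is simulated with all parameters fixed (two drugs act
    through the product of their inhibition factors), Eq-style AUC
    features are extracted, and the fitted affine law is applied — no
    refitting.
    """
    times = np.arange(0.0, PHASE_II[1] + 1e-9, 1.0)
    if x0 is None:
        x0, _ = steady_state_initialize(comp, params)
    traj = simulate_condition(comp, params, cond, times, x0=x0)
    feats = extract_features(traj, states=("pAKT", "pS6K"))
    row = pd.DataFrame({
        "auc_pAKT": [feats.loc["pAKT", "auc"]],
        "auc_pS6K": [feats.loc["pS6K", "auc"]],
    })
    return float(regression.predict(row)[0])
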