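"""Reaction fluxes and the MAPK-vs-PI3K dominance score for S6K.

The flux of a mass-action reaction is v = k_i * c_educts (effective
rate constant, including condition modifiers, times the educt
concentrations).  p70-S6K is activated by both branches —
``phos_S6K_AKT * S6K * pAKT`` via PI3K/AKT and
``phos_S6K_ERK * S6K * ppERK`` via MAPK — and the log10 ratio of the
two fluxes quantifies which branch dominates: positive means
MAPK-dominant, negative PI3K-dominant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ConditionSpec, Trajectory, condition_rates
from .simulate import CompiledNetwork

__all__ = ["reaction_flux", "flux_trace", "s6k_dominance_score"]


def _states_at(traj: Trajectory, t: float) -> np.ndarray:
    if t < traj.times[0] - 1e-9 or t > traj.times[-1] + 1e-9:
        raise ValueError(f"t = {t} outside the trajectory range")
    out = np.empty(traj.states.shape[1])
    for i in range(traj.states.shape[1]):
        out[i] = np.interp(t, traj.times, traj.states[:, i])
    return out


def _effective_k(comp, params, cond, t, reaction_name):
    k, _ = condition_rates(comp.network, params, cond, t)
    for j, r in enumerate(comp.network.reactions):
        if r.name == reaction_name:
            return k[j], r
    raise KeyError(f"unknown reaction: {reaction_name!r}")


def reaction_flux(
    comp: CompiledNetwork,
    traj: Trajectory,
    params: dict[str, float],
    reaction: str,
    t: float,
) -> float:
    """Flux of one reaction at time t along a simulated trajectory."""
    cond = traj.condition or ConditionSpec("MCF7")
    k_eff, r = _effective_k(comp, params, cond, t, reaction)
    x = _states_at(traj, t)
    sidx = {sp: i for i, sp in enumerate(traj.species)}
    v = k_eff
    for sp, m in r.educts.items():
        v *= x[sidx[sp]] ** m
    if r.activator_pool:
        v *= sum(x[sidx[sp]] for sp in r.activator_pool)
    return float(v)


def flux_trace(
    comp: CompiledNetwork,
    traj: Trajectory,
    params: dict[str, float],
    reactions=None,
) -> pd.DataFrame:
    """Fluxes of the requested reactions (default: all) at the trajectory
    times; columns are reaction names, index the times in minutes."""
    names = [r.name for r in comp.network.reactions] if reactions is None \
        else list(reactions)
    out = {name: [reaction_flux(comp, traj, params, name, t)
                  for t in traj.times] for name in names}
    return pd.DataFrame(out, index=traj.times)


def s6k_dominance_score(
    traj: Trajectory,
    params: dict[str, float],
    times=None,
    comp: CompiledNetwork | None = None,
) -> np.ndarray:
    """log10 of the ERK-driven over the AKT-driven S6K activation flux.

    Evaluated at the trajectory times (or the requested subset).  Both
    fluxes share the S6K educt, so the score reduces to
    ``log10(k_ERK * ppERK) - log10(k_AKT * pAKT)``.  Points where either
    flux vanishes are flagged as NaN rather than raising.
    """
    t_eval = traj.times if times is None else np.asarray(times, dtype=float)
    if times is None:
        pperk = traj.state("ppERK")
        pakt = traj.state("pAKT")
    else:
        pperk = np.interp(t_eval, traj.times, traj.state("ppERK"))
        pakt = np.interp(t_eval, traj.times, traj.state("pAKT"))
    v_erk = params["phos_S6K_ERK"] * pperk
    v_akt = params["phos_S6K_AKT"] * pakt
    score = np.full(t_eval.shape, np.nan)
    ok = (v_erk > 0) & (v_akt > 0)
    score[ok] = np.log10(v_erk[ok] / v_akt[ok])
    return score
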