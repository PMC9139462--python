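"""Numerical core: mass-action ODE simulation with forward sensitivities.

The reaction network is compiled once into index arrays consumed by
numba-jitted kernels (rates, right-hand side, Jacobian, augmented
sensitivity system).  Conditions are integrated in two legs with
piecewise-constant effective rate constants: phase I (drug only,
0-60 min) and phase II (drug + ligand, 60-240 min), so the ligand step
needs no event handling and state continuity is exact.

Initial values come from a steady-state transformation of the untreated
system: receptor turnover fixes the receptor layer, while each
downstream kinase pair (and the PI3K pair) is a conserved pool whose
total abundance is a parameter; the phosphorylation balance fixes the
split.  Steady states are solved by damped Newton iteration with an
integration fallback, and steady-state parameter sensitivities follow
from the implicit-function theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .network import (
    DIMERS,
    HORIZON,
    PHASE_SPLIT_TIME,
    ConditionSpec,
    ObservationMap,
    ReactionNetwork,
    Trajectory,
    condition_rates,
)

__all__ = [
    "CompiledNetwork",
    "SimulationError",
    "SteadyStateError",
    "compile_network",
    "steady_state_initialize",
    "simulate_condition",
    "observe",
]

#: conserved downstream pools: (unphosphorylated member, all members, total param)
CONSERVED_POOLS: tuple[tuple[str, tuple[str, str], str], ...] = (
    ("PI3K", ("PI3K", "aPI3K"), "total_PI3K"),
    ("cRAF", ("cRAF", "pcRAF"), "total_cRAF"),
    ("MEK", ("MEK", "pMEK"), "total_MEK"),
    ("ERK", ("ERK", "ppERK"), "total_ERK"),
    ("AKT", ("AKT", "pAKT"), "total_AKT"),
    ("S6K", ("S6K", "pS6K"), "total_S6K"),
)


class SimulationError(RuntimeError):
    """Integrator failure, annotated with the condition context."""


class SteadyStateError(RuntimeError):
    """No steady state found within the iteration budget."""


# ---------------------------------------------------------------------------
# network compilation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompiledNetwork:
    network: ReactionNetwork
    stoich: np.ndarray       # (n_species, n_reactions) float64
    educt1: np.ndarray       # (n_reactions,) int64, -1 if absent
    educt2: np.ndarray       # (n_reactions,) int64, -1 if absent
    pool_flag: np.ndarray    # (n_reactions,) bool
    pool_idx: np.ndarray     # indices of the activator pool species

    @property
    def n_species(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]


def compile_network(network: ReactionNetwork) -> CompiledNetwork:
    ns, nr = len(network.species), len(network.reactions)
    sidx = {sp: i for i, sp in enumerate(network.species)}
    stoich = np.zeros((ns, nr))
    e1 = np.full(nr, -1, dtype=np.int64)
    e2 = np.full(nr, -1, dtype=np.int64)
    pool_flag = np.zeros(nr, dtype=np.bool_)
    pool_idx = np.array([sidx[d] for d in DIMERS], dtype=np.int64)
    for j, r in enumerate(network.reactions):
        for sp, m in r.net_stoichiometry().items():
            stoich[sidx[sp], j] = m
        flat = [sidx[sp] for sp, m in r.educts.items() for _ in range(m)]
        if len(flat) > 2:
            raise ValueError(f"reaction {r.name!r}: more than two educts")
        if len(flat) >= 1:
            e1[j] = flat[0]
        if len(flat) == 2:
            e2[j] = flat[1]
        if r.activator_pool:
            if tuple(r.activator_pool) != DIMERS:
                raise ValueError("only the dimer pool is supported")
            pool_flag[j] = True
    return CompiledNetwork(network, stoich, e1, e2, pool_flag, pool_idx)


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _prods(x, e1, e2, pool_flag, pool_idx):
    nr = e1.shape[0]
    out = np.empty(nr)
    for j in range(nr):
        p = 1.0
        if e1[j] >= 0:
            p *= x[e1[j]]
        if e2[j] >= 0:
            p *= x[e2[j]]
        if pool_flag[j]:
            s = 0.0
            for q in pool_idx:
                s += x[q]
            p *= s
        out[j] = p
    return out


@njit(cache=False)
def _rhs(y, t, k, stoich, e1, e2, pool_flag, pool_idx):
    return stoich @ (k * _prods(y, e1, e2, pool_flag, pool_idx))


@njit(cache=False)
def _dv_dx(x, k, e1, e2, pool_flag, pool_idx):
    nr = e1.shape[0]
    ns = x.shape[0]
    dv = np.zeros((nr, ns))
    for j in range(nr):
        pool_s = 1.0
        if pool_flag[j]:
            pool_s = 0.0
            for q in pool_idx:
                pool_s += x[q]
        a, b = e1[j], e2[j]
        if a >= 0 and b >= 0:
            if a == b:
                dv[j, a] += 2.0 * k[j] * x[a] * pool_s
            else:
                dv[j, a] += k[j] * x[b] * pool_s
                dv[j, b] += k[j] * x[a] * pool_s
            prod = x[a] * x[b]
        elif a >= 0:
            dv[j, a] += k[j] * pool_s
            prod = x[a]
        else:
            prod = 1.0
        if pool_flag[j]:
            for q in pool_idx:
                dv[j, q] += k[j] * prod
    return dv


@njit(cache=False)
def _jac(y, t, k, stoich, e1, e2, pool_flag, pool_idx):
    return stoich @ _dv_dx(y, k, e1, e2, pool_flag, pool_idx)


@njit(cache=False)
def _jac_aug(y, t, k, dk, stoich, e1, e2, pool_flag, pool_idx):
    """Block-diagonal approximation of the augmented-system Jacobian.

    The augmented state is parameter-major (x, then one 22-vector of
    sensitivities per parameter), so each diagonal block is the state
    Jacobian.  The dJ/dx * S coupling of the sensitivity rows into the
    state columns is dropped; that only affects the implicit solver's
    Newton convergence, not the solution it converges to.
    """
    ns = stoich.shape[0]
    nf = dk.shape[1]
    n = ns * (1 + nf)
    x = y[:ns]
    jac = stoich @ _dv_dx(x, k, e1, e2, pool_flag, pool_idx)
    out = np.zeros((n, n))
    for b in range(1 + nf):
        out[b * ns:(b + 1) * ns, b * ns:(b + 1) * ns] = jac
    return out


@njit(cache=False)
def _rhs_aug(y, t, k, dk, stoich, e1, e2, pool_flag, pool_idx):
    # parameter-major layout: y = [x, S[:, 0], S[:, 1], ...]
    ns = stoich.shape[0]
    nf = dk.shape[1]
    x = y[:ns]
    prods = _prods(x, e1, e2, pool_flag, pool_idx)
    out = np.empty(ns * (1 + nf))
    out[:ns] = stoich @ (k * prods)
    jac = stoich @ _dv_dx(x, k, e1, e2, pool_flag, pool_idx)
    st = y[ns:].reshape(nf, ns)                # st[m] = S[:, m]
    sdot = st @ jac.T + (prods * dk.T) @ stoich.T
    out[ns:] = sdot.ravel()
    return out


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def _conservation_rows(comp: CompiledNetwork, params):
    """(row index to replace, member indices, total value, total name)."""
    net = comp.network
    rows = []
    for anchor, members, total_name in CONSERVED_POOLS:
        rows.append((
            net.species_index(anchor),
            np.array([net.species_index(m) for m in members]),
            float(params[total_name]),
            total_name,
        ))
    return rows


def _residual_constrained(x, k, comp, rows):
    f = _rhs(x, 0.0, k, comp.stoich, comp.educt1, comp.educt2,
             comp.pool_flag, comp.pool_idx)
    for ridx, members, total, _ in rows:
        f[ridx] = x[members].sum() - total
    return f


def _jac_constrained(x, k, comp, rows):
    jac = _jac(x, 0.0, k, comp.stoich, comp.educt1, comp.educt2,
               comp.pool_flag, comp.pool_idx)
    for ridx, members, _, _ in rows:
        jac[ridx, :] = 0.0
        jac[ridx, members] = 1.0
    return jac


def _initial_guess(comp: CompiledNetwork, params, rows) -> np.ndarray:
    net = comp.network
    x = np.full(comp.n_species, 1e-9)
    for rec in ("EGFR", "ERBB2", "ERBB3"):
        syn, deg = params[f"syn_{rec}"], params[f"deg_{rec}"]
        x[net.species_index(rec)] = max(syn / max(deg, 1e-12), 1e-9)
    for ridx, members, total, _ in rows:
        x[members] = 1e-9
        x[ridx] = max(total, 1e-9)
    return x


def steady_state_initialize(
    comp: CompiledNetwork,
    params: dict[str, float],
    grad_names: tuple[str, ...] = (),
    tol: float = 1e-10,
    max_newton: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady state of the untreated (no drug, no ligand) system.

    Returns ``(x0, dx0)`` where ``dx0[i, m]`` is the sensitivity of the
    steady state to ``log10`` of parameter ``grad_names[m]``.  Raises
    :class:`SteadyStateError` if Newton iteration (with an integration
    fallback) does not converge to ``||f||_inf < tol * max(1, max x)``.
    """
    net = comp.network
    basal = ConditionSpec(cell_line="MCF7", ligand="none", drugs=())
    # cell line only tags the condition; basal rates are cell-line-free here
    k, dk = condition_rates(net, params, basal, t=0.0, grad_names=grad_names)
    rows = _conservation_rows(comp, params)
    x = _initial_guess(comp, params, rows)

    def newton(x):
        for _ in range(max_newton):
            f = _residual_constrained(x, k, comp, rows)
            scale = max(1.0, float(np.max(np.abs(x))))
            if np.max(np.abs(f)) < tol * scale:
                return x, True
            jac = _jac_constrained(x, k, comp, rows)
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                return x, False
            lam = 1.0
            norm0 = np.linalg.norm(f)
            for _ in range(30):
                x_new = x + lam * step
                if np.all(x_new >= -1e-12):
                    f_new = _residual_constrained(np.maximum(x_new, 0.0), k,
                                                  comp, rows)
                    if np.linalg.norm(f_new) < norm0 * (1 - 1e-4 * lam) + 1e-300:
                        x = np.maximum(x_new, 0.0)
                        break
                lam *= 0.5
            else:
                return x, False
        f = _residual_constrained(x, k, comp, rows)
        return x, np.max(np.abs(f)) < tol * max(1.0, float(np.max(np.abs(x))))

    x_ss, ok = newton(x)
    if not ok:
        # relax towards the attractor by integration, then refine
        args = (k, comp.stoich, comp.educt1, comp.educt2, comp.pool_flag,
                comp.pool_idx)
        for t_end in (1e3, 1e5, 1e7):
            sol = odeint(_rhs, x, [0.0, t_end], args=args, Dfun=_jac,
                         rtol=1e-10, atol=1e-12, mxstep=100_000)
            x = np.maximum(sol[-1], 0.0)
            x_ss, ok = newton(x)
            if ok:
                break
        else:
            raise SteadyStateError(
                "no steady state within iteration budget for the untreated "
                "condition"
            )
    x_ss = np.maximum(x_ss, 0.0)

    nf = len(grad_names)
    dx0 = np.zeros((comp.n_species, nf))
    if nf:
        prods = _prods(x_ss, comp.educt1, comp.educt2, comp.pool_flag,
                       comp.pool_idx)
        dfdth = comp.stoich @ (prods.reshape(-1, 1) * dk)
        ln10 = np.log(10.0)
        for ridx, _, total, total_name in rows:
            dfdth[ridx, :] = 0.0
            if total_name in grad_names:
                dfdth[ridx, grad_names.index(total_name)] = -ln10 * total
        jac = _jac_constrained(x_ss, k, comp, rows)
        dx0 = np.linalg.solve(jac, -dfdth)
    return x_ss, dx0


# ---------------------------------------------------------------------------
# condition simulation
# ---------------------------------------------------------------------------


def _integrate_leg(comp, x0, s0, k, dk, t_grid, rtol, atol, context,
                   sens_atol=None):
    """Integrate one constant-rate leg over t_grid (t_grid[0] = start).

    With sensitivities the absolute tolerance of the sensitivity
    components may be relaxed independently (``sens_atol``): gradient
    components need far less resolution than states.
    """
    nf = 0 if dk is None else dk.shape[1]
    if len(t_grid) < 2:
        return (x0[None, :].copy(),
                None if s0 is None else s0[None, :, :].copy())
    try:
        if nf:
            ns = comp.n_species
            y0 = np.concatenate([x0, s0.T.ravel()])   # parameter-major
            atol_vec = np.concatenate([
                np.full(ns, atol),
                np.full(ns * nf, sens_atol if sens_atol is not None else atol),
            ])
            sol = odeint(
                _rhs_aug, y0, t_grid,
                args=(k, dk, comp.stoich, comp.educt1, comp.educt2,
                      comp.pool_flag, comp.pool_idx),
                Dfun=_jac_aug, rtol=rtol, atol=atol_vec, mxstep=50_000,
            )
            sens = sol[:, ns:].reshape(len(t_grid), nf, ns)
            return sol[:, :ns], np.ascontiguousarray(
                sens.transpose(0, 2, 1))
        sol = odeint(
            _rhs, x0, t_grid,
            args=(k, comp.stoich, comp.educt1, comp.educt2, comp.pool_flag,
                  comp.pool_idx),
            Dfun=_jac, rtol=rtol, atol=atol, mxstep=50_000,
        )
        return sol, None
    except Exception as exc:  # pragma: no cover - integrator failure path
        raise SimulationError(f"integration failed for {context}: {exc}") from exc


def simulate_condition(
    comp: CompiledNetwork,
    params: dict[str, float],
    cond: ConditionSpec,
    times,
    grad_names: tuple[str, ...] = (),
    x0: np.ndarray | None = None,
    dx0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate one condition on the requested time grid.

    Drugs act from t = 0, the ligand from ``cond.ligand_time``; the initial
    state is the untreated steady state (recomputed unless ``x0``/``dx0``
    are supplied, e.g. shared across the conditions of a panel).
    """
    times = np.asarray(sorted(set(float(t) for t in times)))
    if times.size == 0:
        raise ValueError("no sampling times requested")
    if times[0] < 0 or times[-1] > HORIZON:
        raise ValueError(f"times must lie within [0, {HORIZON}] min")

    nf = len(grad_names)
    if x0 is None:
        x0, dx0 = steady_state_initialize(comp, params, grad_names)
    elif dx0 is None:
        dx0 = np.zeros((comp.n_species, nf))

    split = cond.ligand_time if cond.ligand != "none" else PHASE_SPLIT_TIME
    net = comp.network
    k1, dk1 = condition_rates(net, params, cond, t=0.0, grad_names=grad_names)
    k2, dk2 = condition_rates(net, params, cond, t=split, grad_names=grad_names)
    if nf == 0:
        dk1 = dk2 = None

    t1 = times[times <= split]
    t2 = times[times > split]
    grid1 = np.unique(np.concatenate([[0.0], t1, [split] if t2.size else []]))
    states1, sens1 = _integrate_leg(comp, x0, dx0 if nf else None, k1, dk1,
                                    grid1, rtol, atol, cond.label)
    out_states = {0.0: (x0, dx0 if nf else None)}
    for i, t in enumerate(grid1):
        out_states[t] = (states1[i], None if sens1 is None else sens1[i])
    if t2.size:
        x_split, s_split = out_states[split]
        grid2 = np.concatenate([[split], t2])
        states2, sens2 = _integrate_leg(comp, x_split,
                                        s_split if nf else None, k2, dk2,
                                        grid2, rtol, atol, cond.label)
        for i, t in enumerate(grid2):
            out_states[t] = (states2[i], None if sens2 is None else sens2[i])

    states = np.stack([out_states[t][0] for t in times])
    states = np.maximum(states, 0.0)
    if not np.all(np.isfinite(states)):
        raise SimulationError(f"non-finite trajectory for {cond.label}")
    sens = None
    if nf:
        sens = np.stack([out_states[t][1] for t in times])
    return Trajectory(times=times, states=states, species=net.species,
                      condition=cond, state_sensitivities=sens,
                      free_parameters=tuple(grad_names))


# ---------------------------------------------------------------------------
# observation
# ---------------------------------------------------------------------------


def observe(
    traj: Trajectory,
    obs_map: ObservationMap,
    with_sensitivities: bool = False,
):
    """Noise-free observables ``y = log10(scale * sum(states) + offset)``.

    Returns a dict observable -> series; with ``with_sensitivities`` a
    second dict observable -> (n_times, n_free) array of derivatives with
    respect to the trajectory's free (log10) parameters.
    """
    w = obs_map.weight_matrix(traj.species)
    raw = traj.states @ w.T                      # (n_times, n_obs)
    scale = np.array([obs_map.scale[o] for o in obs_map.observables])
    offset = np.array([obs_map.offset[o] for o in obs_map.observables])
    inner = scale * raw + offset
    if np.any(inner <= 0):
        raise ValueError(
            "observation argument non-positive; use a positive offset for "
            "observables that can vanish"
        )
    y = np.log10(inner)
    out = {o: y[:, i] for i, o in enumerate(obs_map.observables)}
    if not with_sensitivities:
        return out
    if traj.state_sensitivities is None:
        raise ValueError("trajectory carries no sensitivities")
    ln10 = np.log(10.0)
    dy = {}
    for i, o in enumerate(obs_map.observables):
        ws = np.einsum("tsf,s->tf", traj.state_sensitivities, w[i])
        dy[o] = (scale[i] * ws) / (inner[:, i][:, None] * ln10)
    return out, dy
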