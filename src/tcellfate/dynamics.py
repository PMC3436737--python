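"""Integration, steady-state location and phenotype calling.

Trajectories of the influence network stay inside the unit box: at
``X_i = 0`` the rate is ``gamma_i F(...) > 0`` and at ``X_i = 1`` it is
``gamma_i (F(...) - 1) < 0``, so the box is forward-invariant and every
attractor is a fixed point inside it.  Steady states are found by
damped-Newton refinement from a multistart grid, deduplicated, and
classified by the eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import InfluenceNetwork, PhenotypeRule, CellState, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "SteadyState",
    "Trajectory",
    "integrate",
    "find_steady_states",
    "classify_phenotype",
    "newton_fixed_point",
    "stability_of",
]

#: Residual requirement on returned steady states: max |gamma (F - x)| < this.
STEADY_RESIDUAL_TOL = 1e-8
#: Eigenvalues with |Re| below this are treated as marginal.
MARGINAL_EIG_TOL = 1e-9
#: States closer than this in max-norm are merged.
DEDUP_TOL = 1e-5


@dataclass(frozen=True)
class SteadyState:
    """A fixed point with its linear stability.

    ``stability`` is "stable" (all eigenvalue real parts < 0), "saddle"
    (mixed signs) or "unstable"; marginal spectra (|Re| < 1e-9) are labelled
    "unstable" with a warning since the model only distinguishes
    stable/unstable states.
    """

    x: np.ndarray
    stability: str
    eigenvalues: np.ndarray
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class Trajectory:
    """Recorded ODE solution with the reason integration stopped."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), N)
    stopped_on: str  # "rate_tolerance" or "max_time"

    @property
    def final(self) -> CellState:
        return CellState(x=self.x[-1], t=float(self.t[-1]))


def stability_of(eigenvalues: np.ndarray, marginal_tol: float = MARGINAL_EIG_TOL) -> str:
    re = np.real(eigenvalues)
    if np.any(np.abs(re) <= marginal_tol):
        warnings.warn("marginal eigenvalue encountered; labelling state 'unstable'", stacklevel=2)
        return "unstable"
    n_pos = int(np.sum(re > 0))
    if n_pos == 0:
        return "stable"
    if n_pos == len(re):
        return "unstable"
    return "saddle"


def integrate(
    net: InfluenceNetwork,
    x0: np.ndarray | CellState,
    signals: Mapping[str, float] | None = None,
    *,
    max_time: float = 1000.0,
    rate_tolerance: float = 1e-9,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    record: bool = True,
    chunk: float = 5.0,
) -> Trajectory:
    """Integrate to rest (max |dX/dt| < ``rate_tolerance``) or to ``max_time``.

    Starting states outside [0, 1]^N are clipped with a warning; the
    trajectory itself remains in the box by construction.  Integration is
    performed in time chunks so that the stopping rule is checked without
    non-smooth event functions.
    """
    if isinstance(x0, CellState):
        x0 = x0.x
    x = np.asarray(x0, dtype=float).copy()
    if np.any(x < 0) or np.any(x > 1):
        warnings.warn("initial state outside [0,1]^N; clipping to the box", stacklevel=2)
        x = np.clip(x, 0.0, 1.0)
    svec_signals = signals  # resolved per call inside rhs

    def fun(t, y):
        return net.rhs(y, svec_signals)

    ts = [0.0]
    xs = [x.copy()]
    t = 0.0
    stopped = "max_time"
    while t < max_time:
        if np.max(np.abs(net.rhs(x, signals))) < rate_tolerance:
            stopped = "rate_tolerance"
            break
        t_end = min(t + chunk, max_time)
        sol = solve_ivp(fun, (t, t_end), x, method="LSODA", rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t:g}: {sol.message}")
        t = float(sol.t[-1])
        x = np.clip(sol.y[:, -1], 0.0, 1.0)
        if record:
            ts.extend(sol.t[1:].tolist())
            xs.extend(np.clip(sol.y[:, 1:].T, 0.0, 1.0).copy())
        else:
            ts[-1] = t
            xs[-1] = x.copy()
    else:
        if np.max(np.abs(net.rhs(x, signals))) < rate_tolerance:
            stopped = "rate_tolerance"
    if record and (ts[-1] != t or not np.array_equal(xs[-1], x)):
        ts.append(t)
        xs.append(x.copy())
    return Trajectory(t=np.asarray(ts), x=np.asarray(xs), stopped_on=stopped)


def newton_fixed_point(
    net: InfluenceNetwork,
    x0: np.ndarray,
    signals: Mapping[str, float] | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray | None:
    """Damped Newton on ``F(sigma W) - x = 0`` from one start; None on failure."""
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        g = net.fixed_point_residual(x, signals)
        if np.max(np.abs(g)) < tol:
            return x
        j = net.fixed_point_jacobian(x, signals)
        try:
            step = np.linalg.solve(j, -g)
        except np.linalg.LinAlgError:
            return None
        # Damped update, kept near the unit box.
        scale = 1.0
        norm0 = np.max(np.abs(g))
        for _ in range(30):
            x_new = np.clip(x + scale * step, -0.5, 1.5)
            if np.max(np.abs(net.fixed_point_residual(x_new, signals))) < norm0 or scale < 1e-6:
                break
            scale *= 0.5
        x = x_new
    return None


def _multistart_grid(n_nodes: int, points_per_dim: int) -> np.ndarray:
    axes = [np.linspace(0.0, 1.0, points_per_dim)] * n_nodes
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def find_steady_states(
    net: InfluenceNetwork,
    signals: Mapping[str, float] | None = None,
    *,
    points_per_dim: int = 5,
    starts: np.ndarray | None = None,
    dedup_tol: float = DEDUP_TOL,
    residual_tol: float = STEADY_RESIDUAL_TOL,
) -> list[SteadyState]:
    """Locate all fixed points reachable from a multistart grid over [0,1]^N.

    A batched, vectorized damped Newton iteration refines every start at
    once; converged roots are merged within ``dedup_tol`` (max-norm),
    classified by Jacobian eigenvalues, and returned sorted
    lexicographically by state vector so output order is reproducible.
    Non-converged starts are counted and logged, never fatal.
    """
    n = net.n_nodes
    if starts is None:
        starts = _multistart_grid(n, points_per_dim)
    x = np.array(starts, dtype=float)
    n_starts = x.shape[0]
    active = np.ones(n_starts, dtype=bool)
    converged = np.zeros(n_starts, dtype=bool)

    svec = net.signal_vector(signals)
    sig_term = svec @ net.signal_omega
    omega_t = net.omega.T
    eye = np.eye(n)

    def residual(xb):
        w = net.omega0 + xb @ omega_t + sig_term
        return sigmoid_arr(net.sigma * w) - xb

    def jac(xb):
        w = net.omega0 + xb @ omega_t + sig_term
        f = sigmoid_arr(net.sigma * w)
        slope = net.sigma * f * (1.0 - f)
        return slope[..., :, None] * net.omega[None, :, :] - eye[None, :, :]

    for _ in range(80):
        if not np.any(active):
            break
        g = residual(x[active])
        gmax = np.max(np.abs(g), axis=-1)
        done = gmax < 1e-12
        idx_active = np.flatnonzero(active)
        converged[idx_active[done]] = True
        active[idx_active[done]] = False
        if not np.any(active):
            break
        g = residual(x[active])
        j = jac(x[active])
        try:
            step = np.linalg.solve(j, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.empty_like(g)
            for k in range(g.shape[0]):
                try:
                    step[k] = np.linalg.solve(j[k], -g[k])
                except np.linalg.LinAlgError:
                    step[k], *_ = np.linalg.lstsq(j[k], -g[k], rcond=None)
        # Step damping: halve where the residual would not decrease.
        norm0 = np.max(np.abs(g), axis=-1)
        scale = np.ones(g.shape[0])
        for _ in range(20):
            x_try = np.clip(x[active] + scale[:, None] * step, -0.5, 1.5)
            norm1 = np.max(np.abs(residual(x_try)), axis=-1)
            bad = norm1 > norm0
            if not np.any(bad) or np.all(scale < 1e-6):
                break
            scale[bad] *= 0.5
        x[active] = x_try

    n_failed = int(np.sum(~converged))
    if n_failed:
        logger.debug("find_steady_states: %d/%d starts did not converge", n_failed, n_starts)

    roots: list[np.ndarray] = []
    for xi in x[converged]:
        if not any(np.max(np.abs(xi - r)) < dedup_tol for r in roots):
            roots.append(xi)
    roots.sort(key=lambda r: tuple(r))

    states = []
    for r in roots:
        rate = net.rhs(r, signals)
        res = float(np.max(np.abs(rate)))
        if res >= residual_tol:
            logger.debug("discarding root with residual %g", res)
            continue
        eig = np.linalg.eigvals(net.jacobian(r, signals))
        states.append(SteadyState(x=r, stability=stability_of(eig), eigenvalues=eig, residual=res))
    return states


def sigmoid_arr(u: np.ndarray) -> np.ndarray:
    """Batch logistic without finiteness checks (inner loops)."""
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def batch_fixed_points(
    net: InfluenceNetwork,
    sig_terms: np.ndarray,
    starts: np.ndarray,
    *,
    dedup_tol: float = DEDUP_TOL,
    residual_tol: float = STEADY_RESIDUAL_TOL,
    max_iter: int = 60,
) -> list[list[SteadyState]]:
    """Steady states for many signal conditions at once (shared network).

    ``sig_terms`` has shape ``(P, N)`` — the per-condition signal
    contribution to the effective drives — and ``starts`` shape ``(S, N)``.
    All ``P x S`` Newton iterations run as one vectorized batch; roots are
    then deduplicated and stability-classified per condition.  Used by the
    diagram grids, where per-point calls would dominate the runtime.
    """
    n = net.n_nodes
    p_cond = sig_terms.shape[0]
    s_cnt = starts.shape[0]
    x = np.broadcast_to(starts[None, :, :], (p_cond, s_cnt, n)).reshape(-1, n).copy()
    terms = np.repeat(sig_terms, s_cnt, axis=0)
    omega_t = net.omega.T
    sigma, omega = net.sigma, net.omega

    def residual(xb, tb):
        w = net.omega0 + xb @ omega_t + tb
        return sigmoid_arr(sigma * w) - xb

    def slope_of(xb, tb):
        w = net.omega0 + xb @ omega_t + tb
        f = sigmoid_arr(sigma * w)
        return sigma * f * (1.0 - f)

    active = np.ones(x.shape[0], dtype=bool)
    converged = np.zeros(x.shape[0], dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        xb, tb = x[idx], terms[idx]
        g = residual(xb, tb)
        gmax = np.max(np.abs(g), axis=-1)
        done = gmax < 1e-12
        converged[idx[done]] = True
        active[idx[done]] = False
        keep = ~done
        if not np.any(keep):
            continue
        idx = idx[keep]
        xb, tb, g = xb[keep], tb[keep], g[keep]
        slope = slope_of(xb, tb)
        if n == 2:
            # closed-form solve of (slope[:,None]*omega - I) step = -g
            a = slope[:, 0] * omega[0, 0] - 1.0
            b = slope[:, 0] * omega[0, 1]
            c = slope[:, 1] * omega[1, 0]
            d = slope[:, 1] * omega[1, 1] - 1.0
            det = a * d - b * c
            det = np.where(np.abs(det) < 1e-14, np.sign(det) * 1e-14 + (det == 0) * 1e-14, det)
            s0 = (-d * g[:, 0] + b * g[:, 1]) / det
            s1 = (c * g[:, 0] - a * g[:, 1]) / det
            step = np.stack([s0, s1], axis=-1)
        else:
            jmat = slope[:, :, None] * omega[None, :, :] - np.eye(n)[None, :, :]
            try:
                step = np.linalg.solve(jmat, -g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.stack([
                    np.linalg.lstsq(jmat[k], -g[k], rcond=None)[0] for k in range(g.shape[0])
                ])
        norm0 = np.max(np.abs(g), axis=-1)
        scale = np.ones(g.shape[0])
        for _ in range(15):
            x_try = np.clip(xb + scale[:, None] * step, -0.5, 1.5)
            norm1 = np.max(np.abs(residual(x_try, tb)), axis=-1)
            bad = norm1 > norm0
            if not np.any(bad) or np.all(scale < 1e-6):
                break
            scale[bad] *= 0.5
        x[idx] = x_try

    # stability bookkeeping, vectorized over every converged root
    out: list[list[SteadyState]] = []
    x = x.reshape(p_cond, s_cnt, n)
    conv = converged.reshape(p_cond, s_cnt)
    slope_all = None
    for p_idx in range(p_cond):
        roots: list[np.ndarray] = []
        for s_idx in np.flatnonzero(conv[p_idx]):
            xi = x[p_idx, s_idx]
            if not any(np.max(np.abs(xi - r)) < dedup_tol for r in roots):
                roots.append(xi)
        roots.sort(key=lambda r: tuple(r))
        states = []
        for r in roots:
            w = net.omega0 + r @ omega_t + sig_terms[p_idx]
            f = sigmoid_arr(sigma * w)
            rate = net.gamma * (f - r)
            res = float(np.max(np.abs(rate)))
            if res >= residual_tol:
                continue
            jmat = (net.gamma * sigma * f * (1 - f))[:, None] * omega - np.diag(net.gamma)
            eig = np.linalg.eigvals(jmat)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stab = stability_of(eig)
            states.append(SteadyState(x=r.copy(), stability=stab, eigenvalues=eig, residual=res))
        out.append(states)
    return out


def classify_phenotype(
    state: CellState | np.ndarray,
    net: InfluenceNetwork,
    rule: PhenotypeRule | None = None,
) -> str:
    """Label a state naive/XSP/YSP/DP from the designated regulator pair."""
    rule = rule or PhenotypeRule()
    x = state.x if isinstance(state, CellState) else np.asarray(state, dtype=float)
    i, j = net.regulator_indices
    return rule.label(float(x[i]), float(x[j]))
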