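"""Continuation and multistability analysis for influence networks.

One-parameter fixed-point branches are traced with pseudo-arclength
continuation (adaptive step, tangent-constrained Newton corrector).  Folds
are flagged by a sign change of the parameter component of the tangent and
refined on the extended fold system ``[g; J v; |v|^2 - 1] = 0``.  On
mirror-symmetric branches of symmetric networks, pitchforks are flagged by
a zero crossing of the swap-antisymmetric eigenvalue and refined by
bisection.  Two-parameter loci are traced by stepping the second parameter
and re-solving the fold system; the coalescence of a pitchfork-born fold
pair (a cusp) is detected when the loci approach within tolerance and its
ordinate is refined by power-law extrapolation.

Grid-based stability maps (``count_attractors_map``) provide a
continuation-free cross-check and the raw material for bidirectional
two-parameter diagrams, in which the two polarizing signals share the
primary-signal axis, one plotted upward and one downward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import root, brentq

from .network import InfluenceNetwork, PhenotypeRule
from .dynamics import (
    SteadyState,
    find_steady_states,
    newton_fixed_point,
    stability_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignalParam",
    "NetParam",
    "SharedParam",
    "Branch",
    "BranchSample",
    "SpecialPoint",
    "trace_branch",
    "classify_pitchfork",
    "PitchforkProblem",
    "solve_fold",
    "continue_fold_locus",
    "trace_pitchfork_coalescence",
    "StabilityMap",
    "BidirectionalDiagram",
    "count_attractors_map",
    "assemble_bidirectional",
]


# ---------------------------------------------------------------------------
# Free-parameter addressing


class Parameter:
    """Abstract handle for a continuable scalar parameter."""

    label: str

    def get(self, net: InfluenceNetwork, signals: Mapping[str, float]) -> float:
        raise NotImplementedError

    def apply(self, net, signals, value):
        """Return ``(net, signals)`` with the parameter set to ``value``."""
        raise NotImplementedError


@dataclass(frozen=True)
class SignalParam(Parameter):
    """An exogenous signal level used as bifurcation parameter."""

    name: str

    @property
    def label(self):
        return self.name

    def get(self, net, signals):
        return float(dict(signals or {}).get(self.name, 0.0))

    def apply(self, net, signals, value):
        new = dict(signals or {})
        new[self.name] = float(value)
        return net, new


@dataclass(frozen=True)
class NetParam(Parameter):
    """A network parameter (weight, basal weight, sigma or gamma) by address.

    ``field`` is one of ``omega``, ``omega0``, ``signal_omega``, ``sigma``,
    ``gamma``; ``index`` the array index, e.g. ``("omega", (0, 0))`` for a
    node-0 auto-activation weight.
    """

    field: str
    index: tuple

    @property
    def label(self):
        return f"{self.field}{list(self.index)}"

    def get(self, net, signals):
        return float(getattr(net, self.field)[self.index])

    def apply(self, net, signals, value):
        arr = getattr(net, self.field).copy()
        arr[self.index] = float(value)
        return net.replace(**{self.field: arr}), signals


@dataclass(frozen=True)
class SharedParam(Parameter):
    """Several network addresses tied to one value (e.g. both auto-activation
    weights of a symmetric motif)."""

    parts: tuple[NetParam, ...]
    name: str = "shared"

    @property
    def label(self):
        return self.name

    def get(self, net, signals):
        return self.parts[0].get(net, signals)

    def apply(self, net, signals, value):
        for part in self.parts:
            net, signals = part.apply(net, signals, value)
        return net, signals


def as_parameter(param) -> Parameter:
    if isinstance(param, Parameter):
        return param
    if isinstance(param, str):
        return SignalParam(param)
    raise TypeError(f"cannot interpret {param!r} as a continuation parameter")


class _Problem:
    """Fixed-point system ``g(x, p) = 0`` with one free parameter."""

    def __init__(self, net: InfluenceNetwork, signals: Mapping[str, float] | None, param):
        self.base_net = net
        self.base_signals = dict(signals or {})
        self.param = as_parameter(param)
        self._cache_p = None
        self._cache = None

    def at(self, p: float):
        if self._cache_p != p:
            self._cache = self.param.apply(self.base_net, self.base_signals, p)
            self._cache_p = p
        return self._cache

    def g(self, x, p):
        net, sig = self.at(p)
        return net.fixed_point_residual(x, sig)

    def jx(self, x, p):
        net, sig = self.at(p)
        return net.fixed_point_jacobian(x, sig)

    def gp(self, x, p, h_rel: float = 1e-6):
        h = h_rel * (1.0 + abs(p))
        return (self.g(x, p + h) - self.g(x, p - h)) / (2 * h)

    def jacobian_full(self, x, p):
        """Jacobian of the gamma-scaled rhs (for stability calls)."""
        net, sig = self.at(p)
        return net.jacobian(x, sig)


# ---------------------------------------------------------------------------
# Branches


@dataclass(frozen=True)
class BranchSample:
    param: float
    x: np.ndarray
    stability: str


@dataclass(frozen=True)
class SpecialPoint:
    kind: str  # "fold" or "pitchfork"
    param: float
    x: np.ndarray
    criticality: str | None = None  # pitchforks: supercritical/subcritical/indeterminate


@dataclass
class Branch:
    free_parameter: str
    samples: list[BranchSample]
    special_points: list[SpecialPoint] = field(default_factory=list)
    truncated: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.array([s.param for s in self.samples])

    @property
    def states(self) -> np.ndarray:
        return np.array([s.x for s in self.samples])


def _tangent(prob: _Problem, x, p, prev=None):
    """Unit tangent of the solution curve of g(x, p) = 0 in (x, p) space."""
    n = len(x)
    a = np.empty((n, n + 1))
    a[:, :n] = prob.jx(x, p)
    a[:, n] = prob.gp(x, p)
    _, _, vt = np.linalg.svd(a)
    t = vt[-1]
    t = t / np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _corrector(prob: _Problem, y_pred, t, tol=1e-11, max_iter=12):
    """Newton for [g; t.(y - y_pred)] = 0 (hyperplane orthogonal to tangent)."""
    n = len(y_pred) - 1
    y = y_pred.copy()
    for _ in range(max_iter):
        g = prob.g(y[:n], y[n])
        r = np.append(g, np.dot(t, y - y_pred))
        if np.max(np.abs(r)) < tol:
            return y
        jac = np.empty((n + 1, n + 1))
        jac[:n, :n] = prob.jx(y[:n], y[n])
        jac[:n, n] = prob.gp(y[:n], y[n])
        jac[n, :] = t
        try:
            y = y + np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            return None
    return None


def _antisym_eigenvalue(net: InfluenceNetwork, x, signals) -> float:
    """Eigenvalue of the Jacobian along the swap-antisymmetric direction.

    Exact at mirror-symmetric states of symmetric two-node networks, where
    (1, -1)/sqrt(2) is an eigenvector of the (swap-commuting) Jacobian.
    """
    i, j = net.regulator_indices
    v = np.zeros(net.n_nodes)
    v[i], v[j] = 1.0, -1.0
    v /= np.sqrt(2.0)
    jmat = net.jacobian(x, signals)
    return float(v @ (jmat @ v))


def trace_branch(
    net: InfluenceNetwork,
    signals: Mapping[str, float] | None,
    free_param,
    prange: tuple[float, float],
    start: np.ndarray | SteadyState,
    *,
    step: float = 1e-2,
    min_step: float = 1e-6,
    max_step: float = 5e-2,
    max_samples: int = 20000,
    detect_pitchforks: bool | None = None,
    classify: bool = True,
    special_tol: float = 1e-6,
) -> Branch:
    """Pseudo-arclength continuation of a fixed-point branch over ``prange``.

    ``start`` must be (close to) a steady state at ``prange[0]``; it is
    Newton-refined first and a precondition error is raised if that fails.
    Folds and — on symmetry-invariant branches of symmetric networks —
    pitchforks are detected from test-function sign changes between samples
    and refined to ``special_tol`` in the parameter.
    """
    prob = _Problem(net, signals, free_param)
    p0, p1 = float(prange[0]), float(prange[1])
    x_given = start.x if isinstance(start, SteadyState) else np.asarray(start, dtype=float)
    net0, sig0 = prob.at(p0)
    x0 = newton_fixed_point(net0, x_given, sig0)
    if x0 is None or np.max(np.abs(x0 - x_given)) > 0.2:
        raise ValueError("trace_branch: start is not (near) a steady state at the initial parameter")

    if detect_pitchforks is None:
        detect_pitchforks = net.is_symmetric()

    def sym_invariant(x):
        return np.max(np.abs(x - net.mirror_state(x))) < 1e-7

    def sample_at(x, p):
        netp, sigp = prob.at(p)
        eig = np.linalg.eigvals(netp.jacobian(x, sigp))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stab = stability_of(eig)
        return BranchSample(param=float(p), x=x.copy(), stability=stab)

    lo, hi = min(p0, p1), max(p0, p1)
    y = np.append(x0, p0)
    t = _tangent(prob, x0, p0)
    if t[-1] * np.sign(p1 - p0) < 0:
        t = -t

    branch = Branch(free_parameter=as_parameter(free_param).label, samples=[sample_at(x0, p0)])
    h = step
    psi_fold_prev = t[-1]
    netp, sigp = prob.at(p0)
    psi_pf_prev = _antisym_eigenvalue(netp, x0, sigp) if (detect_pitchforks and sym_invariant(x0)) else None

    n = len(x0)
    for _ in range(max_samples):
        y_new = None
        while h >= min_step:
            t_new = _tangent(prob, y[:n], y[n], prev=t)
            cand = _corrector(prob, y + h * t_new, t_new)
            if cand is not None:
                y_new = cand
                break
            h *= 0.5
        if y_new is None:
            branch.truncated = True
            warnings.warn("continuation step failure: branch truncated", stacklevel=2)
            break
        t_step = (y_new - y) / np.linalg.norm(y_new - y)
        # fold test: sign change of parameter direction along the branch
        psi_fold = t_step[-1]
        if psi_fold_prev is not None and psi_fold * psi_fold_prev < 0 and lo <= y_new[n] <= hi:
            fp = solve_fold(prob, 0.5 * (y[:n] + y_new[:n]), 0.5 * (y[n] + y_new[n]))
            if fp is not None:
                xf, pf = fp
                duplicate = any(
                    sp.kind == "fold"
                    and abs(sp.param - pf) < 1e-6
                    and np.max(np.abs(sp.x - xf)) < 1e-4
                    for sp in branch.special_points
                )
                if not duplicate and lo - 1e-9 <= pf <= hi + 1e-9:
                    branch.special_points.append(SpecialPoint(kind="fold", param=float(pf), x=xf))
        # pitchfork test on the symmetric branch
        if detect_pitchforks and sym_invariant(y_new[:n]):
            netp, sigp = prob.at(y_new[n])
            psi_pf = _antisym_eigenvalue(netp, y_new[:n], sigp)
            if psi_pf_prev is not None and psi_pf * psi_pf_prev < 0:
                pf_pt = _refine_pitchfork(prob, y[:n], y[n], y_new[n], tol=special_tol)
                if pf_pt is not None:
                    xp, pp = pf_pt
                    crit = None
                    if classify:
                        netb, sigb = prob.at(pp)
                        crit = classify_pitchfork(netb, sigb, prob.param, xp, pp)
                    branch.special_points.append(
                        SpecialPoint(kind="pitchfork", param=float(pp), x=xp, criticality=crit)
                    )
            psi_pf_prev = psi_pf
        else:
            psi_pf_prev = None
        psi_fold_prev = psi_fold
        y, t = y_new, t_step
        branch.samples.append(sample_at(y[:n], y[n]))
        h = min(h * 1.3, max_step)
        if not (lo - 1e-12 <= y[n] <= hi + 1e-12):
            break
    branch.special_points.sort(key=lambda sp: sp.param)
    return branch


def _refine_pitchfork(prob: _Problem, x_seed, p_lo, p_hi, tol=1e-6):
    """Bisect the antisymmetric eigenvalue along the symmetric branch."""

    def psi(p):
        netp, sigp = prob.at(p)
        x = newton_fixed_point(netp, _symmetrize(netp, x_seed), sigp)
        if x is None:
            raise RuntimeError("lost the symmetric branch while refining a pitchfork")
        return _antisym_eigenvalue(netp, x, sigp), x

    a, b = float(p_lo), float(p_hi)
    fa, xa = psi(a)
    fb, xb = psi(b)
    if fa * fb > 0:
        return None
    while b - a > tol:
        m = 0.5 * (a + b)
        fm, xm = psi(m)
        if fa * fm <= 0:
            b, fb, xb = m, fm, xm
        else:
            a, fa, xa = m, fm, xm
    p = 0.5 * (a + b)
    _, x = psi(p)
    return x, p


def _symmetrize(net: InfluenceNetwork, x):
    return 0.5 * (np.asarray(x, dtype=float) + net.mirror_state(x))


# ---------------------------------------------------------------------------
# Pitchfork criticality


@dataclass
class PitchforkProblem:
    """A pitchfork of a general Z2-equivariant vector field.

    ``g(x, p)`` is the fixed-point residual, ``reflection`` the linear
    involution ``R`` under which ``g(R x, p) = R g(x, p)``, and
    ``(x_star, p_star)`` the bifurcation point on the R-invariant branch.
    """

    g: Callable[[np.ndarray, float], np.ndarray]
    reflection: np.ndarray
    x_star: np.ndarray
    p_star: float

    def classify(self, delta: float = 1e-3, destab_direction: float | None = None) -> str:
        """Supercritical / subcritical via the emergent asymmetric branches.

        Solves for asymmetric fixed points at prescribed small amplitudes
        ``delta`` and ``2 delta`` along the anti-invariant eigendirection,
        reads off the parameter offset ``p(d) - p* ~ c d^2``, Richardson-
        extrapolates ``c``, and compares the branch side to the side on
        which the invariant state is destabilized.  Returns "indeterminate"
        for a vanishing (degenerate) cubic coefficient.
        """
        r_mat = np.atleast_2d(np.asarray(self.reflection, dtype=float))
        n = r_mat.shape[0]
        evals, evecs = np.linalg.eigh(0.5 * (r_mat + r_mat.T))
        anti = evecs[:, np.isclose(evals, -1.0)]
        inv = evecs[:, np.isclose(evals, 1.0)]
        if anti.shape[1] < 1:
            raise ValueError("reflection has no anti-invariant direction")
        v_a = anti[:, 0]
        k = inv.shape[1]

        # Refine (x*, p*) to machine precision: the d^2 branch offsets measured
        # below are easily swamped by a parameter error from coarse detection.
        def pf_system(z):
            m, p = z[:k], z[k]
            x = self.x_star + inv @ m if k else self.x_star
            jac = _fd_jacobian(lambda xx: self.g(xx, p), x)
            lam_a = float(v_a @ (jac @ v_a))
            res_inv = inv.T @ self.g(x, p) if k else np.zeros(0)
            return np.append(res_inv, lam_a)

        sol0 = root(pf_system, np.append(np.zeros(k), self.p_star), method="hybr", tol=1e-13)
        if np.max(np.abs(pf_system(sol0.x))) < 1e-8:
            self.p_star = float(sol0.x[k])
            if k:
                self.x_star = self.x_star + inv @ sol0.x[:k]

        def branch_offset(d, p_guess=None):
            def fun(z):
                m, p = z[:k], z[k]
                x = self.x_star + inv @ m + d * v_a
                return self.g(x, p)

            p0 = self.p_star if p_guess is None else p_guess
            sol = root(fun, np.append(np.zeros(k), p0), method="hybr", tol=1e-13)
            if np.max(np.abs(fun(sol.x))) > 1e-11:
                return None
            return sol.x[k] - self.p_star

        off1 = branch_offset(delta)
        # quadratic extrapolation seeds the second solve (offsets scale as d^2)
        off2 = branch_offset(2 * delta, None if off1 is None else self.p_star + 4 * off1)
        if off1 is None or off2 is None:
            return "indeterminate"
        c1 = off1 / delta**2
        c2 = off2 / (4 * delta**2)
        c = (4 * c1 - c2) / 3.0
        scale = max(abs(c1), abs(c2))
        if scale < 1e-8 or abs(c) < 0.05 * scale:
            return "indeterminate"

        if destab_direction is None:
            # side (in p) on which the invariant state is destabilized: sign of
            # d(lambda_anti)/dp at the pitchfork, via finite differences of the
            # anti-invariant eigenvalue of dg/dx along the invariant branch.
            h = 1e-5 * (1 + abs(self.p_star))

            def lam(p):
                # track the invariant branch by solving the invariant components
                if k:
                    solr = root(lambda z: inv.T @ self.g(self.x_star + inv @ z, p), np.zeros(k), tol=1e-13)
                    x = self.x_star + inv @ solr.x
                else:
                    x = self.x_star
                jac = _fd_jacobian(lambda xx: self.g(xx, p), x)
                return float(v_a @ (jac @ v_a))

            dlam = lam(self.p_star + h) - lam(self.p_star - h)
            destab_direction = np.sign(dlam) if dlam != 0 else 1.0
        return "supercritical" if np.sign(c) == np.sign(destab_direction) else "subcritical"


def _fd_jacobian(fun, x, h=1e-7):
    x = np.asarray(x, dtype=float)
    n = len(x)
    f0 = np.asarray(fun(x), dtype=float)
    jac = np.empty((len(f0), n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h * (1 + abs(x[i]))
        jac[:, i] = (np.asarray(fun(x + e)) - np.asarray(fun(x - e))) / (2 * e[i])
    return jac


def classify_pitchfork(
    net: InfluenceNetwork,
    signals: Mapping[str, float] | None,
    free_param,
    x_star: np.ndarray,
    p_star: float,
    delta: float = 1e-3,
) -> str:
    """Criticality of a pitchfork on the mirror-symmetric branch of a network."""
    prob = _Problem(net, signals, free_param)
    i, j = net.regulator_indices
    r_mat = np.eye(net.n_nodes)
    r_mat[[i, j]] = r_mat[[j, i]]
    pf = PitchforkProblem(
        g=lambda x, p: prob.g(x, p),
        reflection=r_mat,
        x_star=np.asarray(x_star, dtype=float),
        p_star=float(p_star),
    )
    return pf.classify(delta=delta)


# ---------------------------------------------------------------------------
# Folds and two-parameter loci


def solve_fold(prob: _Problem, x_seed, p_seed, v_seed=None):
    """Newton on the extended fold system [g; J v; |v|^2 - 1] = 0."""
    n = len(x_seed)
    if v_seed is None:
        jmat = prob.jx(np.asarray(x_seed, dtype=float), p_seed)
        _, _, vt = np.linalg.svd(jmat)
        v_seed = vt[-1]

    def fun(z):
        x, v, p = z[:n], z[n : 2 * n], z[2 * n]
        jmat = prob.jx(x, p)
        return np.concatenate([prob.g(x, p), jmat @ v, [v @ v - 1.0]])

    z0 = np.concatenate([x_seed, v_seed, [p_seed]])
    sol = root(fun, z0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
        return None
    return sol.x[:n].copy(), float(sol.x[2 * n])


def _fold_with_vector(prob: _Problem, x_seed, p_seed, v_seed=None):
    n = len(x_seed)
    if v_seed is None:
        jmat = prob.jx(np.asarray(x_seed, dtype=float), p_seed)
        _, _, vt = np.linalg.svd(jmat)
        v_seed = vt[-1]

    def fun(z):
        x, v, p = z[:n], z[n : 2 * n], z[2 * n]
        return np.concatenate([prob.g(x, p), prob.jx(x, p) @ v, [v @ v - 1.0]])

    sol = root(fun, np.concatenate([x_seed, v_seed, [p_seed]]), method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
        return None
    return sol.x[:n].copy(), sol.x[n : 2 * n].copy(), float(sol.x[2 * n])


@dataclass
class FoldLocus:
    """A fold curve in a two-parameter plane."""

    param1: str
    param2: str
    points: list[tuple[float, float, np.ndarray]]  # (p1, p2, state)
    terminal_event: str = "range_boundary"

    @property
    def p1(self):
        return np.array([pt[0] for pt in self.points])

    @property
    def p2(self):
        return np.array([pt[1] for pt in self.points])


def continue_fold_locus(
    net: InfluenceNetwork,
    signals: Mapping[str, float] | None,
    fold_point: tuple[np.ndarray, float],
    param_pair: tuple,
    range2: tuple[float, float],
    *,
    step2: float = 2e-2,
    min_step2: float = 1e-7,
) -> FoldLocus:
    """Trace a fold in the (param1, param2) plane by stepping param2.

    At each param2 value the fold system is re-solved in (x, v, param1),
    seeded from the previous point.  Stops at the range2 boundary or when
    the defining singularity is lost (Newton failure at the minimum step),
    reporting which.
    """
    p1_ref = as_parameter(param_pair[0])
    p2_ref = as_parameter(param_pair[1])
    x0, p1_0 = fold_point
    p2_lo, p2_hi = float(range2[0]), float(range2[1])
    direction = np.sign(p2_hi - p2_lo) or 1.0

    def problem_at(p2):
        net2, sig2 = p2_ref.apply(net, dict(signals or {}), p2)
        return _Problem(net2, sig2, p1_ref)

    p2 = p2_lo
    sol = _fold_with_vector(problem_at(p2), np.asarray(x0, dtype=float), float(p1_0))
    if sol is None:
        raise ValueError("continue_fold_locus: seed point is not a fold at range2 start")
    x, v, p1 = sol
    locus = FoldLocus(param1=p1_ref.label, param2=p2_ref.label, points=[(p1, p2, x.copy())])
    h = step2
    while (p2_hi - p2) * direction > 1e-12:
        h_try = min(h, abs(p2_hi - p2))
        advanced = False
        while h_try >= min_step2:
            p2_new = p2 + direction * h_try
            sol = _fold_with_vector(problem_at(p2_new), x, p1, v)
            if sol is not None:
                x, v, p1 = sol
                p2 = p2_new
                locus.points.append((p1, p2, x.copy()))
                advanced = True
                break
            h_try *= 0.5
        if not advanced:
            locus.terminal_event = "singularity_lost"
            logger.info("fold locus truncated at %s=%g (singularity lost)", p2_ref.label, p2)
            break
        h = min(h_try * 1.5, step2)
    return locus


@dataclass
class CoalescenceResult:
    """Two pitchfork-born fold loci and their coalescence (cusp) point."""

    locus_low: FoldLocus
    locus_high: FoldLocus
    cusp_param1: float
    cusp_param2: float
    separation_reached: float


def trace_pitchfork_coalescence(
    net: InfluenceNetwork,
    signals: Mapping[str, float] | None,
    pitchforks: Sequence[SpecialPoint],
    param_pair: tuple,
    *,
    p2_start: float = 1e-3,
    step2: float = 2e-2,
    sep_tol: float = 1e-4,
    p2_max: float = 10.0,
) -> CoalescenceResult:
    """Continue a pitchfork pair in a second (symmetry-breaking) parameter.

    Each pitchfork unfolds into a fold for ``param2 > 0``; the two fold
    loci bound the bistable arch and meet at a cusp.  Both are stepped
    upward in param2 with adaptive refinement until their param1 separation
    falls below ``sep_tol``; the cusp ordinate is then extrapolated from
    the 2/3-power law ``separation^(2/3) ~ (p2_cusp - p2)``.
    """
    if len(pitchforks) != 2:
        raise ValueError("need exactly two pitchfork points")
    pf_lo, pf_hi = sorted(pitchforks, key=lambda sp: sp.param)
    p1_ref = as_parameter(param_pair[0])
    p2_ref = as_parameter(param_pair[1])

    def problem_at(p2):
        net2, sig2 = p2_ref.apply(net, dict(signals or {}), p2)
        return _Problem(net2, sig2, p1_ref)

    def seed_fold(pf, p2):
        # Near the pitchfork the unfolded fold sits O(p2^(1/3)) away along the
        # antisymmetric direction, so try a fan of offsets.
        prob = problem_at(p2)
        i, j = net.regulator_indices
        v0 = np.zeros(net.n_nodes)
        v0[i], v0[j] = 1.0, -1.0
        v0 /= np.sqrt(2)
        for off in (0.0, 0.05, -0.05, 0.1, -0.1, 0.2, -0.2, 0.3, -0.3):
            sol = _fold_with_vector(prob, pf.x + off * v0, pf.param, v0)
            if sol is not None:
                return sol
        return None

    p2 = p2_start
    lo = seed_fold(pf_lo, p2)
    hi = seed_fold(pf_hi, p2)
    if lo is None or hi is None:
        raise RuntimeError("could not unfold the pitchforks into folds at p2_start")
    locus_lo = FoldLocus(p1_ref.label, p2_ref.label, [(lo[2], p2, lo[0].copy())])
    locus_hi = FoldLocus(p1_ref.label, p2_ref.label, [(hi[2], p2, hi[0].copy())])
    history = [(p2, abs(hi[2] - lo[2]))]
    h = step2
    while p2 < p2_max:
        sep = abs(hi[2] - lo[2])
        if sep < sep_tol:
            break
        advanced = False
        h_try = h
        while h_try >= 1e-9:
            p2_new = p2 + h_try
            lo_new = _fold_with_vector(problem_at(p2_new), lo[0], lo[2], lo[1])
            hi_new = _fold_with_vector(problem_at(p2_new), hi[0], hi[2], hi[1])
            ok = lo_new is not None and hi_new is not None
            if ok:
                sep_new = abs(hi_new[2] - lo_new[2])
                # reject steps that jump past the cusp (loci crossing)
                if sep_new > 1e-12 and (hi_new[2] - lo_new[2]) * (hi[2] - lo[2]) > 0:
                    lo, hi, p2 = lo_new, hi_new, p2_new
                    locus_lo.points.append((lo[2], p2, lo[0].copy()))
                    locus_hi.points.append((hi[2], p2, hi[0].copy()))
                    history.append((p2, sep_new))
                    advanced = True
                    break
            h_try *= 0.5
        if not advanced:
            break
        # shrink the step as the loci converge
        h = min(h * 1.4, step2, max(0.35 * history[-1][1] ** 1.5 * _sep_slope(history), 1e-9))
    # extrapolate the cusp ordinate from separation^(2/3) ~ (p2_c - p2)
    (p2_a, sep_a), (p2_b, sep_b) = history[-2], history[-1]
    ta, tb = sep_a ** (2.0 / 3.0), sep_b ** (2.0 / 3.0)
    if ta > tb:
        p2_c = p2_b + tb * (p2_b - p2_a) / (ta - tb)
    else:
        p2_c = p2_b
    p1_c = 0.5 * (lo[2] + hi[2])
    return CoalescenceResult(
        locus_low=locus_lo,
        locus_high=locus_hi,
        cusp_param1=float(p1_c),
        cusp_param2=float(p2_c),
        separation_reached=float(history[-1][1]),
    )


def _sep_slope(history):
    """d(p2)/d(sep^{3/2}) estimate used for adaptive step sizing."""
    if len(history) < 2:
        return 1.0
    (p2_a, sep_a), (p2_b, sep_b) = history[-2], history[-1]
    num = p2_b - p2_a
    den = sep_a**1.5 - sep_b**1.5
    if den <= 0:
        return 1.0
    return max(num / den, 1e-3)


# ---------------------------------------------------------------------------
# Stability maps and bidirectional diagrams


@dataclass
class StabilityMap:
    """Stable-phenotype signatures on a two-parameter grid.

    ``cells[i, j]`` (axis1 index i, axis2 index j) holds the sorted tuple
    of phenotype labels of the stable states found at that grid point.
    """

    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    cells: np.ndarray  # object array of tuples, shape (len(axis1), len(axis2))

    @property
    def n_stable(self) -> np.ndarray:
        return np.vectorize(len)(self.cells)

    def signature_strings(self) -> np.ndarray:
        return np.vectorize(lambda c: "+".join(c))(self.cells)


def count_attractors_map(
    net: InfluenceNetwork,
    axis1: tuple,
    axis2: tuple,
    signals: Mapping[str, float] | None = None,
    *,
    rule: PhenotypeRule | None = None,
    points_per_dim: int = 7,
) -> StabilityMap:
    """Run ``find_steady_states`` at every grid point; label stable states.

    Continuation-free, hence usable as an independent cross-check of the
    fold/pitchfork loci.  Per-cell solver trouble is logged, never fatal.
    """
    p1_ref = as_parameter(axis1[0])
    p2_ref = as_parameter(axis2[0])
    vals1 = np.asarray(axis1[1], dtype=float)
    vals2 = np.asarray(axis2[1], dtype=float)
    rule = rule or PhenotypeRule()
    i, j = net.regulator_indices
    cells = np.empty((len(vals1), len(vals2)), dtype=object)
    if isinstance(p1_ref, SignalParam) and isinstance(p2_ref, SignalParam):
        # fast path: the network is shared, only the signal term varies, so all
        # grid points are solved in one vectorized Newton batch
        from .dynamics import batch_fixed_points, _multistart_grid

        base = dict(signals or {})
        sig_terms = np.empty((len(vals1) * len(vals2), net.n_nodes))
        for b, v2 in enumerate(vals2):
            for a, v1 in enumerate(vals1):
                sig = dict(base)
                sig[p1_ref.name] = v1
                sig[p2_ref.name] = v2
                sig_terms[b * len(vals1) + a] = net.signal_vector(sig) @ net.signal_omega
        results = batch_fixed_points(net, sig_terms, _multistart_grid(net.n_nodes, points_per_dim))
        for b in range(len(vals2)):
            for a in range(len(vals1)):
                states = results[b * len(vals1) + a]
                labels = sorted(
                    rule.label(float(s.x[i]), float(s.x[j])) for s in states if s.is_stable
                )
                if not labels:
                    logger.warning(
                        "no stable state found at %s=%g, %s=%g", p1_ref.label, vals1[a], p2_ref.label, vals2[b]
                    )
                cells[a, b] = tuple(labels)
        return StabilityMap(axis1=(p1_ref.label, vals1), axis2=(p2_ref.label, vals2), cells=cells)
    for b, v2 in enumerate(vals2):
        net2, sig2 = p2_ref.apply(net, dict(signals or {}), v2)
        for a, v1 in enumerate(vals1):
            net12, sig12 = p1_ref.apply(net2, sig2, v1)
            states = find_steady_states(net12, sig12, points_per_dim=points_per_dim)
            labels = sorted(
                rule.label(float(s.x[i]), float(s.x[j])) for s in states if s.is_stable
            )
            if not labels:
                logger.warning("no stable state found at %s=%g, %s=%g", p1_ref.label, v1, p2_ref.label, v2)
            cells[a, b] = tuple(labels)
    return StabilityMap(axis1=(p1_ref.label, vals1), axis2=(p2_ref.label, vals2), cells=cells)


@dataclass
class BidirectionalDiagram:
    """Two stability maps sharing the primary-signal axis.

    ``upper`` spans (S1, S2) at S3 = 0 and is plotted upward; ``lower``
    spans (S1, S3) at S2 = 0 and is plotted downward.  ``loci`` may carry
    special-point curves for each half.
    """

    upper: StabilityMap
    lower: StabilityMap
    loci: dict = field(default_factory=dict)

    def combined_cells(self) -> np.ndarray:
        """Stacked signature array: upper rows (axis2 descending) above the
        shared axis row, then lower rows (axis2 ascending)."""
        up = self.upper.cells  # (n1, n2u)
        low = self.lower.cells  # (n1, n2l)
        rows = [up[:, k] for k in range(up.shape[1] - 1, -1, -1)]
        rows += [low[:, k] for k in range(1, low.shape[1])]
        return np.stack(rows, axis=1)  # (n1, n2u + n2l - 1)

    def signatures(self) -> set:
        return set(self.combined_cells().ravel())

    def n_signatures(self) -> int:
        return len(self.signatures())

    def n_regions(self) -> int:
        """Connected same-signature regions (4-neighbor) in the combined plane."""
        cells = self.combined_cells()
        n1, n2 = cells.shape
        seen = np.zeros(cells.shape, dtype=bool)
        regions = 0
        for a in range(n1):
            for b in range(n2):
                if seen[a, b]:
                    continue
                regions += 1
                stack = [(a, b)]
                seen[a, b] = True
                sig = cells[a, b]
                while stack:
                    ca, cb = stack.pop()
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = ca + da, cb + db
                        if 0 <= na < n1 and 0 <= nb < n2 and not seen[na, nb] and cells[na, nb] == sig:
                            seen[na, nb] = True
                            stack.append((na, nb))
        return regions


def assemble_bidirectional(upper: StabilityMap, lower: StabilityMap, loci: dict | None = None) -> BidirectionalDiagram:
    """Merge the (S1, S2) and (S1, S3) maps into one bidirectional diagram."""
    if upper.axis1[0] != lower.axis1[0] or not np.array_equal(upper.axis1[1], lower.axis1[1]):
        raise ValueError("upper and lower maps must share the primary-signal axis grid")
    return BidirectionalDiagram(upper=upper, lower=lower, loci=dict(loci or {}))
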