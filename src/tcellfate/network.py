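"""Influence-network model of master-regulator dynamics.

A network of ``N`` protein activities ``X_i`` in [0, 1] evolves by

    dX_i/dt = gamma_i * (F(sigma_i * W_i) - X_i),
    F(u)    = 1 / (1 + exp(-u)),
    W_i     = omega0_i + sum_j omega[i, j] * X_j + sum_s signal_omega[s, i] * S_s,

where ``omega[i, j]`` is the influence weight of node ``j`` on node ``i``,
``omega0_i`` a basal weight, ``sigma_i`` the sigmoid steepness, ``gamma_i``
the relaxation rate, and ``S_s`` the level of exogenous signal ``s``.  All
quantities are dimensionless; one model time unit corresponds to 1.5 days
of real time in the CD4+ T-cell setting the defaults emulate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "sigmoid",
    "InfluenceNetwork",
    "SignalSaturation",
    "EffectiveDrive",
    "CellState",
    "PhenotypeRule",
    "PHENOTYPES",
]

#: The four phenotype labels with respect to a (X, Y) regulator pair.
PHENOTYPES = ("naive", "XSP", "YSP", "DP")


def sigmoid(u):
    """Logistic soft-threshold ``F(u) = 1 / (1 + e^{-u})``.

    Vectorized and overflow-safe for ``|u|`` up to the float range.
    Raises ``ValueError`` on non-finite input.
    """
    u_arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u_arr)):
        raise ValueError("sigmoid: non-finite input")
    out = np.empty_like(u_arr)
    pos = u_arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u_arr[pos]))
    eu = np.exp(u_arr[~pos])
    out[~pos] = eu / (1.0 + eu)
    if np.isscalar(u) or np.ndim(u) == 0:
        return float(out)
    return out


def dsigmoid(f):
    """Derivative of the logistic in terms of its value: F' = F (1 - F)."""
    return f * (1.0 - f)


@dataclass(frozen=True)
class SignalSaturation:
    """Optional Michaelis-Menten transform of a raw signal level.

    ``s -> s_max * s / (K + s)``.  Off by default; the functional form is an
    implementation choice for saturating primary signals, not a commitment
    of the underlying model.
    """

    s_max: float
    K: float

    def __call__(self, s: float) -> float:
        return self.s_max * s / (self.K + s)


@dataclass(frozen=True)
class CellState:
    """Protein activities ``x`` (one per node, expected in [0, 1]) at time ``t``."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("CellState: non-finite activities")
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class EffectiveDrive:
    """Effective inputs ``W_i``, one per state node."""

    w: np.ndarray


@dataclass(frozen=True)
class PhenotypeRule:
    """Expression-threshold phenotype calling over a designated (X, Y) pair.

    A regulator is *expressed* when its activity is strictly greater than
    ``threshold`` (default 0.5).  naive: neither expressed; XSP/YSP: only the
    first/second regulator; DP: both.
    """

    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("PhenotypeRule: threshold must lie in (0, 1)")

    def label(self, x_val: float, y_val: float) -> str:
        x_on = x_val > self.threshold
        y_on = y_val > self.threshold
        if x_on and y_on:
            return "DP"
        if x_on:
            return "XSP"
        if y_on:
            return "YSP"
        return "naive"


@dataclass(frozen=True)
class InfluenceNetwork:
    """Parameter container for the sigmoidal influence network.

    Parameters
    ----------
    node_names
        State-node identifiers (master regulators), length ``N``.
    signal_names
        Exogenous signal identifiers (e.g. ``("S1", "S2", "S3")``).
    omega
        ``(N, N)`` interaction weights; ``omega[i, j]`` is the weight of
        node ``j`` acting on node ``i``.
    omega0
        ``(N,)`` basal weights.
    signal_omega
        ``(n_signals, N)`` signal weights; row ``s`` gives the weight of
        signal ``s`` on each node.
    sigma, gamma
        ``(N,)`` sigmoid steepness (> 0) and relaxation rates (> 0).
    regulator_pair
        The two designated master regulators used for phenotype calling;
        defaults to the first two nodes.
    primary_signal, polarizing_pair
        Metadata naming the primary differentiation signal and the two
        mirror polarizing signals (used by symmetry checks and the
        bidirectional diagram defaults).
    saturation
        Optional per-signal :class:`SignalSaturation` transforms.
    """

    node_names: tuple[str, ...]
    signal_names: tuple[str, ...]
    omega: np.ndarray
    omega0: np.ndarray
    signal_omega: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray
    regulator_pair: tuple[str, str] | None = None
    primary_signal: str | None = None
    polarizing_pair: tuple[str, str] | None = None
    saturation: Mapping[str, SignalSaturation] | None = None

    def __post_init__(self):
        node_names = tuple(str(n) for n in self.node_names)
        signal_names = tuple(str(s) for s in self.signal_names)
        n = len(node_names)
        m = len(signal_names)
        omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        omega0 = np.atleast_1d(np.asarray(self.omega0, dtype=float))
        signal_omega = np.asarray(self.signal_omega, dtype=float).reshape(m, -1) if m else np.zeros((0, n))
        sigma = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n,)).copy()
        gamma = np.broadcast_to(np.asarray(self.gamma, dtype=float), (n,)).copy()
        if omega.shape != (n, n):
            raise ValueError(f"omega must be ({n}, {n}), got {omega.shape}")
        if omega0.shape != (n,):
            raise ValueError(f"omega0 must have length {n}, got {omega0.shape}")
        if signal_omega.shape != (m, n):
            raise ValueError(f"signal_omega must be ({m}, {n}), got {signal_omega.shape}")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(gamma <= 0):
            raise ValueError("gamma must be strictly positive")
        pair = self.regulator_pair
        if pair is None and n >= 2:
            pair = (node_names[0], node_names[1])
        if pair is not None:
            pair = (str(pair[0]), str(pair[1]))
            for p in pair:
                if p not in node_names:
                    raise ValueError(f"regulator_pair member {p!r} is not a node")
        primary = self.primary_signal
        if primary is None and m >= 1:
            primary = signal_names[0]
        pol = self.polarizing_pair
        if pol is None and m >= 3:
            pol = (signal_names[1], signal_names[2])
        if pol is not None:
            pol = (str(pol[0]), str(pol[1]))
            for p in pol:
                if p not in signal_names:
                    raise ValueError(f"polarizing_pair member {p!r} is not a signal")
        object.__setattr__(self, "node_names", node_names)
        object.__setattr__(self, "signal_names", signal_names)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "omega0", omega0)
        object.__setattr__(self, "signal_omega", signal_omega)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "regulator_pair", pair)
        object.__setattr__(self, "primary_signal", primary)
        object.__setattr__(self, "polarizing_pair", pol)

    # -- basic introspection -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_signals(self) -> int:
        return len(self.signal_names)

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def signal_index(self, name: str) -> int:
        return self.signal_names.index(name)

    @property
    def regulator_indices(self) -> tuple[int, int]:
        if self.regulator_pair is None:
            raise ValueError("network does not designate a regulator pair")
        return (self.node_index(self.regulator_pair[0]), self.node_index(self.regulator_pair[1]))

    def replace(self, **changes) -> "InfluenceNetwork":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- signal handling -----------------------------------------------------

    def signal_vector(self, signals: Mapping[str, float] | None) -> np.ndarray:
        """Map a {signal name: level} dict onto the network's signal order.

        Missing signals default to 0; unknown names are a configuration
        error.  Saturation transforms, when configured, are applied here.
        """
        signals = dict(signals or {})
        for name in signals:
            if name not in self.signal_names:
                raise KeyError(f"unknown signal {name!r}; network signals are {self.signal_names}")
        vec = np.zeros(self.n_signals)
        # Negative levels are tolerated here: continuation correctors may probe
        # slightly outside the physical range.  Protocol validation enforces
        # nonnegativity at the user-facing layer.
        for idx, name in enumerate(self.signal_names):
            level = float(signals.get(name, 0.0))
            if self.saturation and name in self.saturation:
                level = self.saturation[name](level)
            vec[idx] = level
        return vec

    # -- dynamics ------------------------------------------------------------

    def effective_drive(self, x: np.ndarray, signals: Mapping[str, float] | None = None) -> np.ndarray:
        """Effective inputs ``W_i`` at state ``x`` (vectorized over leading axes)."""
        x = np.asarray(x, dtype=float)
        svec = self.signal_vector(signals)
        return self.omega0 + x @ self.omega.T + svec @ self.signal_omega

    def rhs(self, x: np.ndarray, signals: Mapping[str, float] | None = None) -> np.ndarray:
        """Right-hand side ``gamma_i (F(sigma_i W_i) - X_i)``."""
        x = np.asarray(x, dtype=float)
        w = self.effective_drive(x, signals)
        return self.gamma * (sigmoid(self.sigma * w) - x)

    def fixed_point_residual(self, x: np.ndarray, signals: Mapping[str, float] | None = None) -> np.ndarray:
        """``F(sigma_i W_i) - X_i`` — same zeros as ``rhs`` without the gamma scale."""
        x = np.asarray(x, dtype=float)
        w = self.effective_drive(x, signals)
        return sigmoid(self.sigma * w) - x

    def jacobian(self, x: np.ndarray, signals: Mapping[str, float] | None = None) -> np.ndarray:
        """Analytic Jacobian of ``rhs`` at a single state ``x``.

        ``J[i, j] = gamma_i sigma_i F'(sigma_i W_i) omega[i, j] - gamma_i delta_ij``.
        """
        x = np.asarray(x, dtype=float)
        w = self.effective_drive(x, signals)
        f = sigmoid(self.sigma * w)
        slope = self.gamma * self.sigma * dsigmoid(f)
        return slope[:, None] * self.omega - np.diag(self.gamma)

    def fixed_point_jacobian(self, x: np.ndarray, signals: Mapping[str, float] | None = None) -> np.ndarray:
        """Jacobian of ``fixed_point_residual`` (gamma-free)."""
        x = np.asarray(x, dtype=float)
        w = self.effective_drive(x, signals)
        f = sigmoid(self.sigma * w)
        slope = self.sigma * dsigmoid(f)
        return slope[:, None] * self.omega - np.eye(self.n_nodes)

    # -- symmetry ------------------------------------------------------------

    def swap_permutation(self) -> np.ndarray:
        """Node permutation exchanging the two designated regulators."""
        i, j = self.regulator_indices
        perm = np.arange(self.n_nodes)
        perm[[i, j]] = perm[[j, i]]
        return perm

    def is_symmetric(self, atol: float = 1e-12) -> bool:
        """True when the X<->Y, S2<->S3 mirror leaves all parameters unchanged.

        The mirror swaps the two designated regulators and the two polarizing
        signals simultaneously; a perfectly symmetric motif is invariant.
        """
        if self.regulator_pair is None:
            return False
        perm = self.swap_permutation()
        sperm = np.arange(self.n_signals)
        if self.polarizing_pair is not None:
            a = self.signal_index(self.polarizing_pair[0])
            b = self.signal_index(self.polarizing_pair[1])
            sperm[[a, b]] = sperm[[b, a]]
        ok = (
            np.allclose(self.omega, self.omega[np.ix_(perm, perm)], atol=atol)
            and np.allclose(self.omega0, self.omega0[perm], atol=atol)
            and np.allclose(self.sigma, self.sigma[perm], atol=atol)
            and np.allclose(self.gamma, self.gamma[perm], atol=atol)
            and np.allclose(self.signal_omega, self.signal_omega[np.ix_(sperm, perm)], atol=atol)
        )
        return bool(ok)

    def mirror_state(self, x: np.ndarray) -> np.ndarray:
        """Apply the X<->Y swap to a state vector (vectorized)."""
        perm = self.swap_permutation()
        return np.asarray(x, dtype=float)[..., perm]
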