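"""Cell-population simulation with parametric cell-to-cell variability.

A population of ``n_cells`` model cells shares the topology of a basal
("average-cell") network; every nonzero parameter of every cell is drawn
independently from a normal distribution centred on its basal value with
coefficient of variation ``cv`` (default 0.05, 200 cells).  Zero-valued
parameters encode absent edges and are never perturbed; sign-constrained
parameters (sigma, gamma) are redrawn while nonpositive.

Cells are first equilibrated without exogenous signals to their own naive
(double-negative) steady states, then driven through a staged stimulus
protocol; each stage runs to rest so that every cell arrives at its induced
phenotype.  Compositions over 2-D signal grids reproduce the heat-map
simulations of heterogeneous differentiation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import InfluenceNetwork, PhenotypeRule
from .dynamics import sigmoid_arr, classify_phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationConfig",
    "CellPopulation",
    "ProtocolStage",
    "SignalProtocol",
    "PhenotypeComposition",
    "CompositionGrid",
    "sample_population",
    "equilibrate_naive",
    "run_protocol",
    "composition",
    "composition_grid",
]

#: Parameter groups that vary from cell to cell by default (all of them).
DEFAULT_PERTURBED = ("omega", "omega0", "signal_omega", "sigma", "gamma")


class ModelError(RuntimeError):
    """A structural failure of the model (e.g. no naive state)."""


@dataclass(frozen=True)
class PopulationConfig:
    """How a population is sampled around its basal network."""

    n_cells: int = 200
    cv: float = 0.05
    seed: int | None = None
    perturbed_parameters: tuple[str, ...] = DEFAULT_PERTURBED

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for name in self.perturbed_parameters:
            if name not in DEFAULT_PERTURBED:
                raise ValueError(f"unknown parameter group {name!r}")


@dataclass
class CellPopulation:
    """Per-cell parameter arrays (leading axis = cell) plus current states."""

    basal: InfluenceNetwork
    config: PopulationConfig
    omega: np.ndarray  # (n, N, N)
    omega0: np.ndarray  # (n, N)
    signal_omega: np.ndarray  # (n, S, N)
    sigma: np.ndarray  # (n, N)
    gamma: np.ndarray  # (n, N)
    states: np.ndarray | None = None  # (n, N)
    failed: np.ndarray | None = None  # (n,) bool; cells whose integration failed

    @property
    def n_cells(self) -> int:
        return self.omega.shape[0]

    @property
    def seed(self):
        return self.config.seed

    def cell_network(self, k: int) -> InfluenceNetwork:
        """Materialize cell ``k`` as a standalone network (for inspection)."""
        return self.basal.replace(
            omega=self.omega[k],
            omega0=self.omega0[k],
            signal_omega=self.signal_omega[k],
            sigma=self.sigma[k],
            gamma=self.gamma[k],
        )

    @property
    def cells(self) -> list[InfluenceNetwork]:
        return [self.cell_network(k) for k in range(self.n_cells)]

    def rhs(self, x: np.ndarray, svec: np.ndarray) -> np.ndarray:
        """Batched rates, ``x`` shape (n, N); ``svec`` the shared signal vector."""
        w = self.omega0 + np.einsum("nij,nj->ni", self.omega, x)
        if svec.size:
            w = w + np.einsum("nsi,s->ni", self.signal_omega, svec)
        return self.gamma * (sigmoid_arr(self.sigma * w) - x)


def _perturb(rng: np.random.Generator, basal: np.ndarray, cv: float, n: int, positive: bool) -> np.ndarray:
    """Normal(mean=basal, sd=cv*|basal|) per entry; zeros stay zero."""
    out = np.broadcast_to(basal, (n,) + basal.shape).copy()
    if cv == 0:
        return out
    sd = cv * np.abs(basal)
    draw = rng.normal(out, sd)
    mask = np.broadcast_to(basal == 0, draw.shape)
    draw[mask] = 0.0
    if positive:
        bad = draw <= 0
        tries = 0
        while np.any(bad):
            tries += 1
            if tries > 100:
                raise RuntimeError("resampling positive parameters exceeded 100 redraws")
            draw[bad] = rng.normal(out[bad], np.broadcast_to(sd, draw.shape)[bad])
            bad = draw <= 0
    return draw


def sample_population(net: InfluenceNetwork, config: PopulationConfig) -> CellPopulation:
    """Draw a population around the basal network; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    groups = config.perturbed_parameters

    def maybe(name, positive=False):
        basal = getattr(net, name)
        if name in groups:
            return _perturb(rng, basal, config.cv, n, positive)
        return np.broadcast_to(basal, (n,) + basal.shape).copy()

    return CellPopulation(
        basal=net,
        config=config,
        omega=maybe("omega"),
        omega0=maybe("omega0"),
        signal_omega=maybe("signal_omega"),
        sigma=maybe("sigma", positive=True),
        gamma=maybe("gamma", positive=True),
    )


def integrate_population(
    pop: CellPopulation,
    signals: Mapping[str, float] | None = None,
    *,
    max_time: float = 1000.0,
    rate_tolerance: float = 1e-9,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> np.ndarray:
    """Integrate every cell to rest (or ``max_time``); updates ``pop.states``.

    The whole population is advanced as one stacked ODE system in adaptive
    time chunks; the stopping rule is the max rate over all cells.
    """
    if pop.states is None:
        raise ValueError("population has no states; equilibrate or assign first")
    svec = pop.basal.signal_vector(signals)
    n, n_nodes = pop.states.shape

    def fun(t, y):
        return pop.rhs(y.reshape(n, n_nodes), svec).ravel()

    x = pop.states.copy()
    t = 0.0
    chunk = 2.0
    while t < max_time:
        rate = np.max(np.abs(pop.rhs(x, svec)))
        if rate < rate_tolerance:
            break
        if rate < 1e-5:
            # close to rest: a per-cell Newton polish lands exactly on the
            # nearby fixed point (time stepping alone stalls at the ODE
            # solver's error floor above tight rate tolerances)
            x_new = _newton_polish(pop, x, svec)
            if x_new is not None and np.max(np.abs(pop.rhs(x_new, svec))) < rate_tolerance:
                x = x_new
                break
        t_end = min(t + chunk, max_time)
        sol = solve_ivp(fun, (t, t_end), x.ravel(), method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"population integration failed at t={t:g}: {sol.message}")
        t = float(sol.t[-1])
        x = np.clip(sol.y[:, -1].reshape(n, n_nodes), 0.0, 1.0)
        chunk = min(chunk * 1.6, 50.0)
    pop.states = x
    return x


def _newton_polish(pop: CellPopulation, x: np.ndarray, svec: np.ndarray, max_iter: int = 30):
    """Batched per-cell Newton on F(sigma W) - x = 0 from near-rest states."""
    x = x.copy()
    eye = np.eye(x.shape[1])
    for _ in range(max_iter):
        w = pop.omega0 + np.einsum("nij,nj->ni", pop.omega, x)
        if svec.size:
            w = w + np.einsum("nsi,s->ni", pop.signal_omega, svec)
        f = sigmoid_arr(pop.sigma * w)
        g = f - x
        if np.max(np.abs(g)) < 1e-13:
            return np.clip(x, 0.0, 1.0)
        slope = pop.sigma * f * (1.0 - f)
        jac = slope[:, :, None] * pop.omega - eye[None, :, :]
        try:
            step = np.linalg.solve(jac, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        if np.max(np.abs(step)) > 0.05:  # refuse to leave the local basin
            return None
        x = x + step
    return None


def equilibrate_naive(
    pop: CellPopulation,
    *,
    initial_value: float = 0.01,
    max_time: float = 1000.0,
    rate_tolerance: float = 1e-9,
    rule: PhenotypeRule | None = None,
) -> CellPopulation:
    """Relax every cell from small initial values with all signals off.

    Every cell must land in its naive (double-negative) state; a cell that
    does not is a structural model error and is reported together with its
    parameters.
    """
    rule = rule or PhenotypeRule()
    pop.states = np.full((pop.n_cells, pop.basal.n_nodes), float(initial_value))
    integrate_population(pop, None, max_time=max_time, rate_tolerance=rate_tolerance)
    i, j = pop.basal.regulator_indices
    labels = [rule.label(float(s[i]), float(s[j])) for s in pop.states]
    bad = [k for k, lab in enumerate(labels) if lab != "naive"]
    if bad:
        k = bad[0]
        raise ModelError(
            f"{len(bad)} cell(s) have no naive resting state; first offender is cell {k} "
            f"with omega0={pop.omega0[k]}, state={pop.states[k]}"
        )
    pop.failed = np.zeros(pop.n_cells, dtype=bool)
    return pop


@dataclass(frozen=True)
class ProtocolStage:
    """One stage of a stimulus protocol: signal levels held until rest."""

    signals: Mapping[str, float]
    max_time: float = 1000.0
    rate_tolerance: float = 1e-9

    def __post_init__(self):
        for name, level in dict(self.signals).items():
            if float(level) < 0:
                raise ValueError(f"protocol stage: signal {name!r} level must be nonnegative")
        if self.max_time <= 0:
            raise ValueError("protocol stage: max_time must be positive")


@dataclass(frozen=True)
class SignalProtocol:
    """An ordered list of stages; cell states carry over between stages."""

    stages: tuple[ProtocolStage, ...]

    def __post_init__(self):
        stages = tuple(
            st if isinstance(st, ProtocolStage) else ProtocolStage(**st) if isinstance(st, dict) else ProtocolStage(st)
            for st in self.stages
        )
        if len(stages) < 1:
            raise ValueError("protocol needs at least one stage")
        object.__setattr__(self, "stages", stages)

    @classmethod
    def simultaneous(cls, signals: Mapping[str, float], **kw) -> "SignalProtocol":
        return cls(stages=(ProtocolStage(signals=dict(signals), **kw),))

    @classmethod
    def sequential(cls, *signal_dicts: Mapping[str, float], **kw) -> "SignalProtocol":
        return cls(stages=tuple(ProtocolStage(signals=dict(s), **kw) for s in signal_dicts))


def run_protocol(pop: CellPopulation, protocol: SignalProtocol) -> np.ndarray:
    """Apply the stages in order; returns (and stores) the final states.

    A cell whose integration fails is flagged in ``pop.failed`` and frozen
    at its last state; the run continues for the rest of the population.
    """
    if pop.states is None:
        raise ValueError("population must be equilibrated (or given states) before a protocol")
    if pop.failed is None:
        pop.failed = np.zeros(pop.n_cells, dtype=bool)
    for stage in protocol.stages:
        try:
            integrate_population(
                pop, stage.signals, max_time=stage.max_time, rate_tolerance=stage.rate_tolerance
            )
        except RuntimeError:
            # retry cell by cell so one pathological cell cannot sink the run
            svec = pop.basal.signal_vector(stage.signals)
            for k in range(pop.n_cells):
                if pop.failed[k]:
                    continue
                sub = CellPopulation(
                    basal=pop.basal,
                    config=replace(pop.config, n_cells=1),
                    omega=pop.omega[k : k + 1],
                    omega0=pop.omega0[k : k + 1],
                    signal_omega=pop.signal_omega[k : k + 1],
                    sigma=pop.sigma[k : k + 1],
                    gamma=pop.gamma[k : k + 1],
                    states=pop.states[k : k + 1].copy(),
                )
                try:
                    integrate_population(
                        sub, stage.signals, max_time=stage.max_time, rate_tolerance=stage.rate_tolerance
                    )
                    pop.states[k] = sub.states[0]
                except RuntimeError:
                    pop.failed[k] = True
                    logger.warning("cell %d failed to integrate; flagged and frozen", k)
    return pop.states


@dataclass(frozen=True)
class PhenotypeComposition:
    """Cell counts per phenotype label; counts sum to the population size."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self):
        counts = {k: int(v) for k, v in dict(self.counts).items()}
        for lab in ("naive", "XSP", "YSP", "DP"):
            counts.setdefault(lab, 0)
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative phenotype count")
        if sum(counts.values()) != self.total:
            raise ValueError("phenotype counts must sum to the population size")
        object.__setattr__(self, "counts", counts)

    def fraction(self, label: str) -> float:
        return self.counts[label] / self.total if self.total else 0.0


def composition(
    states: np.ndarray,
    net: InfluenceNetwork,
    rule: PhenotypeRule | None = None,
) -> PhenotypeComposition:
    """Phenotype counts of a set of cell states."""
    rule = rule or PhenotypeRule()
    i, j = net.regulator_indices
    states = np.asarray(states, dtype=float)
    counts = {"naive": 0, "XSP": 0, "YSP": 0, "DP": 0}
    for s in states:
        counts[rule.label(float(s[i]), float(s[j]))] += 1
    return PhenotypeComposition(counts=counts, total=states.shape[0])


@dataclass
class CompositionGrid:
    """Per-grid-point phenotype compositions over two signal axes."""

    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    cells: np.ndarray  # object array of PhenotypeComposition or None (failed point)
    master_seed: int | None
    n_cells: int

    def fraction_grid(self, label: str) -> np.ndarray:
        out = np.full(self.cells.shape, np.nan)
        for idx, comp in np.ndenumerate(self.cells):
            if comp is not None:
                out[idx] = comp.fraction(label)
        return out


def _stage_signals(template: Mapping[str, object], v1: float, v2: float) -> dict:
    out = {}
    for name, val in dict(template).items():
        if val == "axis1":
            out[name] = float(v1)
        elif val == "axis2":
            out[name] = float(v2)
        else:
            out[name] = float(val)
    return out


def composition_grid(
    net: InfluenceNetwork,
    config: PopulationConfig,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    protocol_stages: Sequence[Mapping[str, object]] | None = None,
    *,
    rule: PhenotypeRule | None = None,
    resample_per_point: bool = True,
    equilibrate: bool = True,
    stage_kwargs: Mapping | None = None,
) -> CompositionGrid:
    """Simulate induced differentiation over a 2-D grid of signal strengths.

    ``protocol_stages`` is a list of signal-level templates, one per stage,
    in which the placeholder strings ``"axis1"``/``"axis2"`` are replaced by
    the grid coordinates (default: one simultaneous stage applying both).
    Every grid point uses a fresh population whose seed is spawned
    deterministically from ``config.seed`` (set ``resample_per_point=False``
    to reuse a single sampled population everywhere).  A failing point is
    logged and left empty; the grid completes.
    """
    name1, vals1 = axis1[0], np.asarray(axis1[1], dtype=float)
    name2, vals2 = axis2[0], np.asarray(axis2[1], dtype=float)
    if protocol_stages is None:
        protocol_stages = [{name1: "axis1", name2: "axis2"}]
    stage_kwargs = dict(stage_kwargs or {})
    rule = rule or PhenotypeRule()
    cells = np.empty((len(vals1), len(vals2)), dtype=object)
    n_points = len(vals1) * len(vals2)
    seed_seq = np.random.SeedSequence(config.seed)
    point_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_points)]

    shared_pop = None
    if not resample_per_point:
        shared_pop = sample_population(net, replace(config, seed=point_seeds[0]))
        if equilibrate:
            equilibrate_naive(shared_pop)
        base_states = shared_pop.states.copy() if shared_pop.states is not None else None

    for a, v1 in enumerate(vals1):
        for b, v2 in enumerate(vals2):
            k = a * len(vals2) + b
            try:
                if resample_per_point:
                    pop = sample_population(net, replace(config, seed=point_seeds[k]))
                    if equilibrate:
                        equilibrate_naive(pop)
                    else:
                        pop.states = np.full((pop.n_cells, net.n_nodes), 0.01)
                else:
                    pop = shared_pop
                    pop.states = base_states.copy()
                stages = tuple(
                    ProtocolStage(signals=_stage_signals(t, v1, v2), **stage_kwargs)
                    for t in protocol_stages
                )
                run_protocol(pop, SignalProtocol(stages=stages))
                cells[a, b] = composition(pop.states, net, rule)
            except Exception as exc:  # per-point failures never sink the grid
                logger.warning("grid point (%s=%g, %s=%g) failed: %s", name1, v1, name2, v2, exc)
                cells[a, b] = None
    return CompositionGrid(
        axis1=(name1, vals1),
        axis2=(name2, vals2),
        cells=cells,
        master_seed=config.seed,
        n_cells=config.n_cells,
    )
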