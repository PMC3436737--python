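"""Model-file parsing, tabular output and run manifests.

Model definition files are YAML (or JSON) with the network parameters laid
out by name::

    nodes: [X, Y]
    signals: [S1, S2, S3]
    omega:            # target -> source -> weight (absent entries are 0)
      X: {Y: -1.8}
      Y: {X: -1.8}
    omega0: {X: -0.64, Y: -0.64}
    signal_omega:     # signal -> target -> weight
      S1: {X: 1.0, Y: 1.0}
      S2: {X: 0.49}
      S3: {Y: 0.49}
    sigma: {X: 3.0, Y: 3.0}   # or a single number
    gamma: 5.0
    regulator_pair: [X, Y]

Unknown keys are rejected; omitted weights default to zero (logged).
Every CLI run writes exactly one JSON manifest carrying the command, model
provenance, seeds, version and output files, sufficient to reproduce the
outputs bit-identically.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .network import InfluenceNetwork, SignalSaturation
from .bifurcation import Branch, StabilityMap, BidirectionalDiagram, FoldLocus
from .population import CompositionGrid

logger = logging.getLogger(__name__)

__all__ = [
    "load_model",
    "save_model",
    "network_to_dict",
    "network_from_dict",
    "branch_to_frame",
    "map_to_frame",
    "locus_to_frame",
    "grid_to_frame",
    "trajectory_to_frame",
    "write_outputs",
    "RunManifest",
]

#: CSV numeric precision (significant digits) for reproducibility checks.
FLOAT_FORMAT = "%.12g"

_ALLOWED_KEYS = {
    "nodes",
    "signals",
    "omega",
    "omega0",
    "signal_omega",
    "sigma",
    "gamma",
    "regulator_pair",
    "primary_signal",
    "polarizing_pair",
    "saturation",
}


class ConfigError(ValueError):
    """A model/protocol configuration problem, with a path-to-field hint."""


def network_to_dict(net: InfluenceNetwork) -> dict:
    omega = {}
    for i, tgt in enumerate(net.node_names):
        row = {src: float(net.omega[i, j]) for j, src in enumerate(net.node_names) if net.omega[i, j] != 0}
        if row:
            omega[tgt] = row
    sig_omega = {}
    for s, sig in enumerate(net.signal_names):
        row = {tgt: float(net.signal_omega[s, i]) for i, tgt in enumerate(net.node_names) if net.signal_omega[s, i] != 0}
        if row:
            sig_omega[sig] = row
    out = {
        "nodes": list(net.node_names),
        "signals": list(net.signal_names),
        "omega": omega,
        "omega0": {n: float(v) for n, v in zip(net.node_names, net.omega0)},
        "signal_omega": sig_omega,
        "sigma": {n: float(v) for n, v in zip(net.node_names, net.sigma)},
        "gamma": {n: float(v) for n, v in zip(net.node_names, net.gamma)},
    }
    if net.regulator_pair:
        out["regulator_pair"] = list(net.regulator_pair)
    if net.primary_signal:
        out["primary_signal"] = net.primary_signal
    if net.polarizing_pair:
        out["polarizing_pair"] = list(net.polarizing_pair)
    if net.saturation:
        out["saturation"] = {k: {"s_max": v.s_max, "K": v.K} for k, v in net.saturation.items()}
    return out


def _per_node(value, nodes, key) -> np.ndarray:
    if isinstance(value, Mapping):
        unknown = set(value) - set(nodes)
        if unknown:
            raise ConfigError(f"{key}: unknown node(s) {sorted(unknown)}")
        return np.array([float(value.get(n, 0.0)) for n in nodes])
    return np.full(len(nodes), float(value))


def network_from_dict(cfg: Mapping) -> InfluenceNetwork:
    if not isinstance(cfg, Mapping):
        raise ConfigError("model file must contain a mapping at top level")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)}; allowed: {sorted(_ALLOWED_KEYS)}")
    for req in ("nodes", "signals"):
        if req not in cfg:
            raise ConfigError(f"missing required key {req!r}")
    nodes = [str(n) for n in cfg["nodes"]]
    signals = [str(s) for s in cfg["signals"]]
    n = len(nodes)

    omega = np.zeros((n, n))
    for tgt, row in dict(cfg.get("omega", {})).items():
        if tgt not in nodes:
            raise ConfigError(f"omega: unknown target node {tgt!r}")
        for src, wgt in dict(row).items():
            if src not in nodes:
                raise ConfigError(f"omega[{tgt}]: unknown source node {src!r}")
            omega[nodes.index(tgt), nodes.index(src)] = float(wgt)

    sig_omega = np.zeros((len(signals), n))
    sig_cfg = dict(cfg.get("signal_omega", {}))
    unknown = set(sig_cfg) - set(signals)
    if unknown:
        raise ConfigError(f"signal_omega: unknown signal(s) {sorted(unknown)}")
    for sig in signals:
        if sig not in sig_cfg:
            logger.info("signal_omega: no weights for %r; defaulting to zeros", sig)
            continue
        for tgt, wgt in dict(sig_cfg[sig]).items():
            if tgt not in nodes:
                raise ConfigError(f"signal_omega[{sig}]: unknown node {tgt!r}")
            sig_omega[signals.index(sig), nodes.index(tgt)] = float(wgt)

    sigma = _per_node(cfg.get("sigma", 1.0), nodes, "sigma")
    gamma = _per_node(cfg.get("gamma", 1.0), nodes, "gamma")
    if np.any(sigma <= 0):
        bad = [nodes[i] for i in np.flatnonzero(sigma <= 0)]
        raise ConfigError(f"sigma must be > 0 (violated for {bad})")
    if np.any(gamma <= 0):
        bad = [nodes[i] for i in np.flatnonzero(gamma <= 0)]
        raise ConfigError(f"gamma must be > 0 (violated for {bad})")

    saturation = None
    if cfg.get("saturation"):
        saturation = {}
        for sig, sat in dict(cfg["saturation"]).items():
            if sig not in signals:
                raise ConfigError(f"saturation: unknown signal {sig!r}")
            saturation[sig] = SignalSaturation(s_max=float(sat["s_max"]), K=float(sat["K"]))

    pair = cfg.get("regulator_pair")
    pol = cfg.get("polarizing_pair")
    try:
        return InfluenceNetwork(
            node_names=tuple(nodes),
            signal_names=tuple(signals),
            omega=omega,
            omega0=_per_node(cfg.get("omega0", 0.0), nodes, "omega0"),
            signal_omega=sig_omega,
            sigma=sigma,
            gamma=gamma,
            regulator_pair=tuple(pair) if pair else None,
            primary_signal=cfg.get("primary_signal"),
            polarizing_pair=tuple(pol) if pol else None,
            saturation=saturation,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_model(path: str | Path) -> InfluenceNetwork:
    """Load and validate a YAML/JSON model definition file."""
    path = Path(path)
    text = path.read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    try:
        return network_from_dict(cfg)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_model(net: InfluenceNetwork, path: str | Path) -> None:
    path = Path(path)
    cfg = network_to_dict(net)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# Tabular exports


def branch_to_frame(branch: Branch) -> pd.DataFrame:
    states = branch.states
    data = {"parameter": branch.params}
    for k in range(states.shape[1]):
        data[f"x{k}"] = states[:, k]
    data["stability"] = [s.stability for s in branch.samples]
    frame = pd.DataFrame(data)
    frame.insert(0, "arclength", np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(np.column_stack([branch.params, states]), axis=0), axis=1))]))
    return frame


def special_points_to_frame(branch: Branch) -> pd.DataFrame:
    rows = [
        {"kind": sp.kind, "parameter": sp.param, "criticality": sp.criticality or "",
         **{f"x{k}": v for k, v in enumerate(sp.x)}}
        for sp in branch.special_points
    ]
    return pd.DataFrame(rows)


def map_to_frame(smap: StabilityMap) -> pd.DataFrame:
    """Long-format stability map: axis1, axis2, n_stable, signature."""
    rows = []
    name1, vals1 = smap.axis1
    name2, vals2 = smap.axis2
    for a, v1 in enumerate(vals1):
        for b, v2 in enumerate(vals2):
            cell = smap.cells[a, b]
            rows.append({name1: v1, name2: v2, "n_stable": len(cell), "signature": "+".join(cell)})
    return pd.DataFrame(rows)


def locus_to_frame(locus: FoldLocus) -> pd.DataFrame:
    rows = [
        {locus.param1: p1, locus.param2: p2, **{f"x{k}": v for k, v in enumerate(x)}}
        for p1, p2, x in locus.points
    ]
    return pd.DataFrame(rows)


def grid_to_frame(grid: CompositionGrid, scores: Mapping[str, np.ndarray] | None = None) -> pd.DataFrame:
    """CompositionGrid CSV: axes, per-phenotype counts and fractions (+ scores)."""
    rows = []
    name1, vals1 = grid.axis1
    name2, vals2 = grid.axis2
    for a, v1 in enumerate(vals1):
        for b, v2 in enumerate(vals2):
            comp = grid.cells[a, b]
            row = {name1: v1, name2: v2}
            for lab in ("naive", "XSP", "YSP", "DP"):
                row[f"n_{lab}"] = comp.counts[lab] if comp else np.nan
                row[f"f_{lab}"] = comp.fraction(lab) if comp else np.nan
            if scores:
                for key, arr in scores.items():
                    row[f"score_{key}"] = arr[a, b]
            rows.append(row)
    return pd.DataFrame(rows)


def trajectory_to_frame(traj) -> pd.DataFrame:
    data = {"time": traj.t}
    for k in range(traj.x.shape[1]):
        data[f"x{k}"] = traj.x[:, k]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Manifests


@dataclass
class RunManifest:
    command: str
    model: str | None = None
    provenance: str | None = None
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def write(self, out_dir: str | Path) -> Path:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = self.timestamp or datetime.datetime.now().isoformat(timespec="seconds")
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return path


def write_outputs(objects: Mapping[str, pd.DataFrame], out_dir: str | Path, manifest: RunManifest) -> list[Path]:
    """Write each frame as CSV into ``out_dir``; the manifest is written last."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in objects.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        written.append(path)
        manifest.outputs.append(str(path))
    manifest.write(out_dir)
    return written
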