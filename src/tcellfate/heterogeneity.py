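"""The heterogeneity score of a phenotype composition.

For phenotypes of interest P_1..P_n (2 <= n <= 4) with cell counts C_i in a
population of N cells,

    S_H = sum_{i<j} ( C_i + C_j - 2 |C_i - C_j| ) / ((n - 1) N).

S_H is close to 1 when the phenotypes of interest are present in comparable
numbers, close to -1 when one of them dominates the whole population, and
close to 0 when few cells carry any phenotype of interest.  The score is
bounded in [-1, 1] and invariant under permutation of the phenotype list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import PHENOTYPES
from .population import PhenotypeComposition, CompositionGrid

__all__ = ["HeterogeneityResult", "heterogeneity_score", "score_grid", "SCORE_PRESETS"]

#: Named phenotype subsets matching the four standard heat-map panels.
SCORE_PRESETS = {
    "XSP+YSP": ("XSP", "YSP"),
    "XSP+DP": ("XSP", "DP"),
    "YSP+DP": ("YSP", "DP"),
    "XSP+YSP+DP": ("XSP", "YSP", "DP"),
}


@dataclass(frozen=True)
class HeterogeneityResult:
    score: float
    phenotypes: tuple[str, ...]
    composition: PhenotypeComposition

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.score <= 1.0 + 1e-12):
            raise ValueError("heterogeneity score fell outside [-1, 1]")


def heterogeneity_score(
    comp: PhenotypeComposition,
    phenotypes: Sequence[str],
) -> HeterogeneityResult:
    """Score a composition over the given distinct phenotypes of interest."""
    if isinstance(phenotypes, str):
        phenotypes = SCORE_PRESETS[phenotypes]
    phenotypes = tuple(phenotypes)
    if not (2 <= len(phenotypes) <= 4):
        raise ValueError("need between 2 and 4 phenotypes of interest")
    if len(set(phenotypes)) != len(phenotypes):
        raise ValueError("phenotypes of interest must be distinct")
    for p in phenotypes:
        if p not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {p!r}; valid labels are {PHENOTYPES}")
    n_tot = comp.total
    if n_tot <= 0:
        raise ValueError("total cell count must be positive")
    n = len(phenotypes)
    c = [comp.counts[p] for p in phenotypes]
    acc = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            acc += c[i] + c[j] - 2.0 * abs(c[i] - c[j])
    score = acc / ((n - 1) * n_tot)
    return HeterogeneityResult(score=score, phenotypes=phenotypes, composition=comp)


def score_grid(grid: CompositionGrid, phenotypes: Sequence[str]) -> np.ndarray:
    """Heterogeneity score at every grid point (NaN where the point failed)."""
    if isinstance(phenotypes, str):
        phenotypes = SCORE_PRESETS[phenotypes]
    out = np.full(grid.cells.shape, np.nan)
    for idx, comp in np.ndenumerate(grid.cells):
        if comp is not None:
            out[idx] = heterogeneity_score(comp, phenotypes).score
    return out
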