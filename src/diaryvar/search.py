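"""Exhaustive structure search for graphical VAR(1) models.

Every combination of the n(n-1) candidate directed edges and the
n(n-1)/2 candidate undirected edges is enumerated (optionally with edges
forced present or absent), each structure is fitted by constrained
conditional maximum likelihood, and structures are ranked by an
information criterion.  Models within 2 units of the minimum score are
conventionally considered competitive with the best model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fit import Moments, VarFit, fit_constrained, fit_unconstrained, _ols_beta
from .panel import LaggedDesign
from .structure import (
    GraphStructure,
    candidate_directed_edges,
    candidate_undirected_edges,
)

__all__ = [
    "ModelRanking",
    "RankingEntry",
    "enumerate_structures",
    "exhaustive_search",
    "competitive_set",
    "ranking_table",
]

#: refuse unrestricted searches above this dimension (2^30 models at n=6)
MAX_SEARCH_VARS = 5


def _normalise_undirected_input(edges: Iterable) -> set:
    return {frozenset(map(int, e)) for e in edges}


def enumerate_structures(
    n_vars: int,
    fixed_in_directed: Iterable[Tuple[int, int]] = (),
    fixed_out_directed: Iterable[Tuple[int, int]] = (),
    fixed_in_undirected: Iterable = (),
    fixed_out_undirected: Iterable = (),
) -> Iterator[GraphStructure]:
    """Yield every graphical VAR(1) structure on ``n_vars`` variables.

    Free candidate edges are toggled in binary-counter order over the
    lexicographically sorted edge list (directed edges first); edges in
    the fixed-in sets are always present, fixed-out always absent.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    fin_d = {(int(j), int(i)) for j, i in fixed_in_directed}
    fout_d = {(int(j), int(i)) for j, i in fixed_out_directed}
    fin_u = _normalise_undirected_input(fixed_in_undirected)
    fout_u = _normalise_undirected_input(fixed_out_undirected)
    if fin_d & fout_d or fin_u & fout_u:
        raise ValueError("fixed_in and fixed_out overlap")

    free_d = [e for e in candidate_directed_edges(n_vars) if e not in fin_d | fout_d]
    free_u = [
        e
        for e in candidate_undirected_edges(n_vars)
        if frozenset(e) not in fin_u | fout_u
    ]
    nd, nu = len(free_d), len(free_u)
    n_bits = nd + nu
    for code in range(1 << n_bits):
        directed = set(fin_d)
        undirected = set(fin_u)
        for b in range(nd):
            if code >> b & 1:
                directed.add(free_d[b])
        for b in range(nu):
            if code >> (nd + b) & 1:
                undirected.add(frozenset(free_u[b]))
        yield GraphStructure(n_vars, frozenset(directed), frozenset(undirected))


def n_structures(
    n_vars: int, n_fixed_directed: int = 0, n_fixed_undirected: int = 0
) -> int:
    """Number of structures in an (optionally restricted) enumeration."""
    free = n_vars * (n_vars - 1) - n_fixed_directed
    free += n_vars * (n_vars - 1) // 2 - n_fixed_undirected
    return 1 << free


@dataclass
class RankingEntry:
    structure: GraphStructure
    score: float
    delta: float
    n_params: int
    loglik: float


@dataclass
class ModelRanking:
    """Structures ordered ascending by information-criterion score."""

    entries: List[RankingEntry]
    criterion: str
    n_models_evaluated: int
    n_failures: int = 0
    variable_names: Optional[List[str]] = None

    @property
    def best(self) -> RankingEntry:
        return self.entries[0]

    def delta_of(self, structure: GraphStructure) -> float:
        for e in self.entries:
            if e.structure == structure:
                return e.delta
        raise KeyError("structure not present in ranking")


def exhaustive_search(
    design: LaggedDesign,
    criterion: Literal["aic", "bic"] = "aic",
    fixed_in_directed: Iterable[Tuple[int, int]] = (),
    fixed_out_directed: Iterable[Tuple[int, int]] = (),
    fixed_in_undirected: Iterable = (),
    fixed_out_undirected: Iterable = (),
    top: Optional[int] = None,
    progress: Optional[Callable[[int, int], None]] = None,
    force: bool = False,
    tol: float = 1e-8,
) -> ModelRanking:
    """Fit every enumerated structure and rank by criterion score.

    The ranking is exact (no heuristics); ties are broken by fewer free
    parameters, then by enumeration order.  A structure whose fit fails
    is excluded and counted in ``n_failures``.  ``top`` keeps only the
    best ``top`` entries (plus any exact ties at the cut) to bound
    memory; scores of all evaluated models still determine the minimum.
    """
    n = design.n_vars
    if n > MAX_SEARCH_VARS and not force:
        raise ValueError(
            f"unrestricted search over n={n} variables means 2^{n * (n - 1) * 3 // 2} "
            "models; pass force=True (and restrictions) if you really want this"
        )
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    mom = Moments.from_design(design)
    warm = _ols_beta(mom)
    total = n_structures(
        n,
        len(set(fixed_in_directed) | set(fixed_out_directed)),
        len(
            _normalise_undirected_input(fixed_in_undirected)
            | _normalise_undirected_input(fixed_out_undirected)
        ),
    )
    logN = float(np.log(mom.n_obs))

    records: List[Tuple[float, int, int, GraphStructure, float]] = []
    n_failures = 0
    for idx, structure in enumerate(
        enumerate_structures(
            n,
            fixed_in_directed,
            fixed_out_directed,
            fixed_in_undirected,
            fixed_out_undirected,
        )
    ):
        try:
            f = fit_constrained(
                design, structure, tol=tol, _moments=mom, _warm_beta=warm
            )
        except (np.linalg.LinAlgError, RuntimeError):
            n_failures += 1
            continue
        score = (
            -2.0 * f.loglik + 2.0 * f.n_params
            if criterion == "aic"
            else -2.0 * f.loglik + logN * f.n_params
        )
        records.append((score, f.n_params, idx, structure, f.loglik))
        if progress is not None and (idx + 1) % 1024 == 0:
            progress(idx + 1, total)

    if not records:
        raise RuntimeError("every model fit failed")
    if n_failures:
        warnings.warn(f"{n_failures} model fits failed and were excluded")
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    best_score = records[0][0]
    if top is not None:
        records = records[:top]
    entries = [
        RankingEntry(
            structure=s, score=sc, delta=sc - best_score, n_params=p, loglik=ll
        )
        for sc, p, _, s, ll in records
    ]
    return ModelRanking(
        entries=entries,
        criterion=criterion,
        n_models_evaluated=total,
        n_failures=n_failures,
        variable_names=list(design.variable_names),
    )


def competitive_set(ranking: ModelRanking, delta: float = 2.0) -> List[RankingEntry]:
    """Entries within ``delta`` criterion units of the minimum, in order."""
    if not ranking.entries:
        raise ValueError("empty ranking")
    return [e for e in ranking.entries if e.delta <= delta]


def ranking_table(
    ranking: ModelRanking,
    top_k: int = 25,
    variable_names: Optional[Sequence[str]] = None,
    include_n_params: bool = False,
) -> pd.DataFrame:
    """Tabular report of the ``top_k`` best models.

    One presence-marker column per candidate edge (``a>b`` for the lagged
    edge a -> b, ``a|b`` for the contemporaneous link), then the Δ score
    rounded to 3 decimals (best row 0.000) and the free parameter count.
    """
    if not ranking.entries:
        raise ValueError("empty ranking")
    n = ranking.entries[0].structure.n_vars
    names = list(variable_names or ranking.variable_names or [f"x{i}" for i in range(n)])
    dcols = [(j, i, f"{names[j]}>{names[i]}") for j, i in candidate_directed_edges(n)]
    ucols = [(i, j, f"{names[i]}|{names[j]}") for i, j in candidate_undirected_edges(n)]
    rows = []
    for e in ranking.entries[:top_k]:
        row = {}
        for j, i, c in dcols:
            row[c] = "*" if e.structure.has_directed(j, i) else ""
        for i, j, c in ucols:
            row[c] = "*" if e.structure.has_undirected(i, j) else ""
        row[f"delta_{ranking.criterion}"] = f"{e.delta:.3f}"
        if include_n_params:
            row["n_params"] = e.n_params
        rows.append(row)
    return pd.DataFrame(rows)
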