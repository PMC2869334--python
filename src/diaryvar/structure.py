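"""Graph structures for constrained (graphical) VAR(1) models.

A structure is a pattern of zero constraints on a VAR(1) model: directed
edges mark lagged (cross-) coefficients that are left free, undirected
edges mark contemporaneous partial associations (non-zero off-diagonal
entries of the innovation concentration matrix).  Diagonal lagged effects
(autocorrelations) are always free and are never members of the directed
edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Iterator, Sequence, Tuple

import numpy as np

DirectedEdge = Tuple[int, int]  # (source j at t-1, target i at t)
UndirectedEdge = FrozenSet[int]


def _normalise_directed(edges: Iterable[Tuple[int, int]]) -> FrozenSet[DirectedEdge]:
    out = set()
    for j, i in edges:
        if j == i:
            raise ValueError(
                f"self-pair ({j},{i}) not allowed: autocorrelations are implicitly free"
            )
        out.add((int(j), int(i)))
    return frozenset(out)


def _normalise_undirected(edges: Iterable) -> FrozenSet[UndirectedEdge]:
    out = set()
    for e in edges:
        pair = tuple(e)
        if len(set(pair)) != 2:
            raise ValueError(f"self-pair {set(pair)} not allowed in undirected edges")
        i, j = pair
        out.add(frozenset((int(i), int(j))))
    return frozenset(out)


@dataclass(frozen=True)
class GraphStructure:
    """Zero-constraint pattern of a graphical VAR(1) model.

    Parameters
    ----------
    n_vars : int
        Number of variables (n >= 1); indices are 0-based.
    directed_edges : set of (j, i) pairs
        Lagged effect of variable ``j`` at time t-1 on variable ``i`` at
        time t (an arrow j -> i in the path diagram).  ``i != j``.
    undirected_edges : set of {i, j} pairs
        Contemporaneous partial association between ``i`` and ``j``
        (a line in the path diagram), i.e. a free off-diagonal entry of
        the innovation concentration matrix.
    """

    n_vars: int
    directed_edges: FrozenSet[DirectedEdge] = field(default_factory=frozenset)
    undirected_edges: FrozenSet[UndirectedEdge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "directed_edges", _normalise_directed(self.directed_edges)
        )
        object.__setattr__(
            self, "undirected_edges", _normalise_undirected(self.undirected_edges)
        )
        n = self.n_vars
        for j, i in self.directed_edges:
            if not (0 <= j < n and 0 <= i < n):
                raise ValueError(f"directed edge ({j},{i}) out of range for n={n}")
        for e in self.undirected_edges:
            for i in e:
                if not (0 <= i < n):
                    raise ValueError(f"undirected edge {set(e)} out of range for n={n}")

    # ---- factories ---------------------------------------------------

    @classmethod
    def complete(cls, n_vars: int) -> "GraphStructure":
        """The unconstrained (saturated) structure."""
        directed = [(j, i) for i in range(n_vars) for j in range(n_vars) if i != j]
        undirected = [
            frozenset((i, j)) for i in range(n_vars) for j in range(i + 1, n_vars)
        ]
        return cls(n_vars, frozenset(directed), frozenset(undirected))

    @classmethod
    def empty(cls, n_vars: int) -> "GraphStructure":
        """Diagonal-only structure: autocorrelations and variances only."""
        return cls(n_vars, frozenset(), frozenset())

    # ---- queries -----------------------------------------------------

    @property
    def n_params(self) -> int:
        """Free parameters: |directed| + n lagged, |undirected| + n concentration."""
        return len(self.directed_edges) + len(self.undirected_edges) + 2 * self.n_vars

    def beta_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of free lagged coefficients, rows = responses."""
        n = self.n_vars
        mask = np.eye(n, dtype=bool)
        for j, i in self.directed_edges:
            mask[i, j] = True
        return mask

    def concentration_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of free concentration entries (symmetric)."""
        n = self.n_vars
        mask = np.eye(n, dtype=bool)
        for e in self.undirected_edges:
            i, j = tuple(e)
            mask[i, j] = mask[j, i] = True
        return mask

    def is_complete(self) -> bool:
        n = self.n_vars
        return (
            len(self.directed_edges) == n * (n - 1)
            and len(self.undirected_edges) == n * (n - 1) // 2
        )

    def has_directed(self, j: int, i: int) -> bool:
        return (j, i) in self.directed_edges

    def has_undirected(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.undirected_edges

    def is_subset_of(self, other: "GraphStructure") -> bool:
        return (
            self.n_vars == other.n_vars
            and self.directed_edges <= other.directed_edges
            and self.undirected_edges <= other.undirected_edges
        )

    def remove_directed(self, j: int, i: int) -> "GraphStructure":
        return GraphStructure(
            self.n_vars,
            self.directed_edges - {(j, i)},
            self.undirected_edges,
        )

    def __repr__(self) -> str:  # compact, deterministic
        d = sorted(self.directed_edges)
        u = sorted(tuple(sorted(e)) for e in self.undirected_edges)
        return f"GraphStructure(n={self.n_vars}, directed={d}, undirected={u})"


def candidate_directed_edges(n_vars: int) -> list[DirectedEdge]:
    """All n(n-1) candidate directed edges in lexicographic order."""
    return sorted((j, i) for j in range(n_vars) for i in range(n_vars) if i != j)


def candidate_undirected_edges(n_vars: int) -> list[Tuple[int, int]]:
    """All n(n-1)/2 candidate undirected edges as sorted (i, j) tuples, i < j."""
    return [(i, j) for i in range(n_vars) for j in range(i + 1, n_vars)]
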