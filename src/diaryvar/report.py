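"""Path-diagram (DOT) export and PDC/PCC association reports."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fit import AssociationEstimates, VarFit
from .structure import GraphStructure, candidate_directed_edges, candidate_undirected_edges

__all__ = ["to_dot", "association_report", "significance_stars"]


def to_dot(
    structure: GraphStructure,
    associations: Optional[AssociationEstimates] = None,
    variable_names: Optional[Sequence[str]] = None,
    dash_nonsignificant: bool = True,
    graph_name: str = "var_model",
) -> str:
    """Render a structure as a DOT path diagram.

    One node per variable; an arrow per lagged edge labelled with its PDC
    (3 decimals) and an arrowhead-free line per contemporaneous edge
    labelled with its PCC.  Self-loops (autocorrelations) are omitted.
    Non-significant edges are dashed when flags are available.  Node and
    edge order is deterministic.
    """
    n = structure.n_vars
    names = list(
        variable_names
        or (associations.variable_names if associations is not None else None)
        or [f"x{i}" for i in range(n)]
    )
    if len(names) != n:
        raise ValueError("variable_names length does not match structure")
    if associations is not None and len(associations.variable_names) != n:
        raise ValueError("associations dimension does not match structure")

    lines = [f"digraph {graph_name} {{", "  rankdir=LR;", "  node [shape=ellipse];"]
    for v in names:
        lines.append(f'  "{v}";')
    for j, i in sorted(structure.directed_edges):
        attrs = []
        if associations is not None:
            attrs.append(f'label="{associations.pdc[i, j]:.3f}"')
            if dash_nonsignificant and not associations.pdc_flags[i, j]:
                attrs.append('style="dashed"')
        a = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f'  "{names[j]}" -> "{names[i]}"{a};')
    for e in sorted(structure.undirected_edges, key=lambda e: tuple(sorted(e))):
        i, j = sorted(e)
        attrs = ["dir=none"]
        if associations is not None:
            attrs.append(f'label="{associations.pcc[i, j]:.3f}"')
            if dash_nonsignificant and not associations.pcc_flags[i, j]:
                attrs.append('style="dashed"')
        lines.append(f'  "{names[i]}" -> "{names[j]}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def significance_stars(p: float) -> str:
    """Conventional star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _p_from_estimate(est: float, n_obs: int) -> float:
    # asymptotic null distribution of a partial correlation: N(0, 1/N)
    return float(2.0 * stats.norm.sf(abs(est) * np.sqrt(n_obs)))


def association_report(
    fit: VarFit,
    associations: AssociationEstimates,
    make_figure: bool = False,
):
    """Numeric PDC/PCC table (and optional bar chart) for a fitted model.

    The table lists every link of the fitted structure with its estimate,
    the asymptotic p-value against zero and the star convention
    (* 0.05, ** 0.01, *** 0.001).  With ``make_figure=True`` a bar chart
    is returned as well, with the pointwise test bound drawn as dashed
    horizontal lines.
    """
    names = fit.variable_names
    n = len(names)
    rows = []
    for j, i in candidate_directed_edges(n):
        if not fit.structure.has_directed(j, i):
            continue
        est = associations.pdc[i, j]
        p = _p_from_estimate(est, fit.n_obs)
        rows.append(
            {
                "link": f"{names[j]} -> {names[i]}",
                "type": "PDC",
                "from": names[j],
                "to": names[i],
                "estimate": est,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    for i, j in candidate_undirected_edges(n):
        if not fit.structure.has_undirected(i, j):
            continue
        est = associations.pcc[i, j]
        p = _p_from_estimate(est, fit.n_obs)
        rows.append(
            {
                "link": f"{names[i]} -- {names[j]}",
                "type": "PCC",
                "from": names[i],
                "to": names[j],
                "estimate": est,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    table = pd.DataFrame(rows)
    if not make_figure:
        return table

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, kind in zip(axes, ["PDC", "PCC"]):
        sub = table[table["type"] == kind]
        ax.bar(range(len(sub)), sub["estimate"], color="steelblue")
        ax.axhline(associations.test_bound, linestyle="--", color="grey")
        ax.axhline(-associations.test_bound, linestyle="--", color="grey")
        ax.axhline(0.0, color="black", linewidth=0.8)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["link"], rotation=60, ha="right", fontsize=8)
        ax.set_title(kind)
        ax.set_ylabel("partial correlation")
    fig.tight_layout()
    return table, fig
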