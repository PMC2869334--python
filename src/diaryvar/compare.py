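"""Subgroup comparison of pooled VAR(1) dynamics.

Three steps: (1) a global likelihood-ratio test of one common model for
all subjects against group-specific parameter sets, (2) an independent
exhaustive structure search per group, and (3) a side-by-side contrast of
the PDC/PCC association estimates in the two selected models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fit import (
    AssociationEstimates,
    VarFit,
    estimate_associations,
    fit_constrained,
    fit_unconstrained,
)
from .panel import LaggedDesign, PanelTimeSeries, lagged_design
from .search import ModelRanking, exhaustive_search
from .structure import GraphStructure, candidate_directed_edges, candidate_undirected_edges

__all__ = [
    "LrtResult",
    "lrt_common_vs_separate",
    "per_group_search",
    "association_difference",
]


@dataclass
class LrtResult:
    """Likelihood-ratio test of common vs group-specific VAR parameters."""

    statistic: float
    df: int
    p_value: float
    loglik_common: float
    loglik_separate: float
    group_sizes: Dict[str, int]

    def __str__(self) -> str:
        return (
            f"LRT common vs separate: T = {self.statistic:.2f}, "
            f"df = {self.df}, p = {self.p_value:.4g}"
        )


def _group_designs(panel: PanelTimeSeries) -> Dict[str, LaggedDesign]:
    groups = panel.groups()
    if len(groups) < 2:
        raise ValueError("panel needs at least 2 groups for a comparison")
    return {g: lagged_design(panel.group_panel(g)) for g in groups}


def lrt_common_vs_separate(
    panel: PanelTimeSeries,
    structure: Optional[GraphStructure] = None,
    tol: float = 1e-10,
) -> LrtResult:
    """Global LRT: one pooled model for all subjects vs one per group.

    By default the saturated structure is used (the test is performed
    before any structure selection); ``structure`` allows testing on a
    reduced common structure.  The statistic is

        T = 2 (sum_g loglik_g - loglik_pooled),

    asymptotically chi-square with (G - 1) * n_params degrees of freedom.
    """
    designs = _group_designs(panel)
    pooled = lagged_design(panel)
    n = panel.n_vars

    def _fit(design: LaggedDesign) -> VarFit:
        if structure is None or structure.is_complete():
            return fit_unconstrained(design)
        return fit_constrained(design, structure, tol=tol)

    for g, d in designs.items():
        if d.n_obs <= n + 1:
            raise ValueError(f"group {g!r} too small to fit: N={d.n_obs}")
    fit_common = _fit(pooled)
    fits = {g: _fit(d) for g, d in designs.items()}
    ll_sep = float(sum(f.loglik for f in fits.values()))
    stat = 2.0 * (ll_sep - fit_common.loglik)
    if stat < -1e-8 * (1.0 + abs(ll_sep)):
        raise RuntimeError(f"negative LRT statistic {stat}: fits did not converge")
    stat = max(stat, 0.0)
    G = len(designs)
    df = (G - 1) * fit_common.n_params
    p = float(stats.chi2.sf(stat, df))
    return LrtResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        loglik_common=fit_common.loglik,
        loglik_separate=ll_sep,
        group_sizes={
            g: panel.group_panel(g).n_subjects for g in designs
        },
    )


def per_group_search(
    panel: PanelTimeSeries,
    criterion: Literal["aic", "bic"] = "aic",
    **search_kwargs,
) -> Dict[str, ModelRanking]:
    """Run the exhaustive structure search independently on each group."""
    if panel.group_labels is None:
        raise ValueError("panel has no group column")
    out: Dict[str, ModelRanking] = {}
    for g in panel.groups():
        design = lagged_design(panel.group_panel(g))
        out[g] = exhaustive_search(design, criterion=criterion, **search_kwargs)
    return out


def association_difference(
    fit_a: VarFit,
    fit_b: VarFit,
    design_a: LaggedDesign,
    design_b: LaggedDesign,
    labels: Tuple[str, str] = ("A", "B"),
    level: float = 0.95,
    variant: Literal["exact", "rescaled"] = "exact",
) -> pd.DataFrame:
    """Side-by-side PDC/PCC contrast of two fitted models.

    One row per candidate link: lagged links (``from -> to``) show the
    PDC per group, contemporaneous links (``a -- b``) the PCC.  The
    ``contrast`` column highlights edges present in one selected model
    and absent in the other.
    """
    if fit_a.variable_names != fit_b.variable_names:
        raise ValueError("fits have different variable sets")
    names = fit_a.variable_names
    n = len(names)
    la, lb = labels
    assoc_a = estimate_associations(fit_a, design_a, level=level, variant=variant)
    assoc_b = estimate_associations(fit_b, design_b, level=level, variant=variant)

    rows = []
    for j, i in candidate_directed_edges(n):
        in_a = fit_a.structure.has_directed(j, i)
        in_b = fit_b.structure.has_directed(j, i)
        ea = assoc_a.pdc[i, j] if in_a else 0.0
        eb = assoc_b.pdc[i, j] if in_b else 0.0
        rows.append(
            {
                "link": f"{names[j]} -> {names[i]}",
                "type": "lagged",
                f"est_{la}": ea,
                f"sig_{la}": bool(in_a and assoc_a.pdc_flags[i, j]),
                f"est_{lb}": eb,
                f"sig_{lb}": bool(in_b and assoc_b.pdc_flags[i, j]),
                "difference": ea - eb,
                "contrast": _contrast(in_a, in_b, la, lb),
            }
        )
    for i, j in candidate_undirected_edges(n):
        in_a = fit_a.structure.has_undirected(i, j)
        in_b = fit_b.structure.has_undirected(i, j)
        ea = assoc_a.pcc[i, j] if in_a else 0.0
        eb = assoc_b.pcc[i, j] if in_b else 0.0
        rows.append(
            {
                "link": f"{names[i]} -- {names[j]}",
                "type": "contemporaneous",
                f"est_{la}": ea,
                f"sig_{la}": bool(in_a and assoc_a.pcc_flags[i, j]),
                f"est_{lb}": eb,
                f"sig_{lb}": bool(in_b and assoc_b.pcc_flags[i, j]),
                "difference": ea - eb,
                "contrast": _contrast(in_a, in_b, la, lb),
            }
        )
    return pd.DataFrame(rows)


def _contrast(in_a: bool, in_b: bool, la: str, lb: str) -> str:
    if in_a and in_b:
        return "both"
    if in_a:
        return f"{la}-only"
    if in_b:
        return f"{lb}-only"
    return "neither"
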