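"""Pooled VAR(1) estimation under graphical zero constraints.

The model for subject k is

    X_k(t) = B X_k(t-1) + eps_k(t),   eps_k(t) ~ N(0, Sigma),

with innovations independent across occasions and subjects and all
subjects sharing one coefficient matrix B and one innovation covariance
Sigma.  A :class:`~diaryvar.structure.GraphStructure` constrains selected
off-diagonal entries of B and of the concentration matrix K = Sigma^{-1}
to zero.  Estimation is conditional (on the first occasion) maximum
likelihood: the unconstrained fit is per-equation OLS; constrained fits
alternate generalized least squares for the free coefficients with
covariance selection (Gaussian graphical model fitting) for K, each step
maximizing the same conditional Gaussian likelihood, so the likelihood
sequence is non-decreasing.

Covariance selection uses the closed-form junction-tree estimate when the
undirected graph is chordal (all graphs on <= 3 vertices, and everything
except chordless cycles for n = 4, 5) and iterative proportional scaling
over maximal cliques otherwise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .panel import LaggedDesign
from .structure import GraphStructure

__all__ = [
    "VarFit",
    "AssociationEstimates",
    "fit_unconstrained",
    "fit_constrained",
    "log_likelihood",
    "information_criterion",
    "pcc_matrix",
    "pdc_matrix",
    "significance_bounds",
    "wald_tests",
    "estimate_associations",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass
class Moments:
    """Pooled cross-product matrices of a lagged design (not divided by N)."""

    G: np.ndarray  # X'X, predictors at t-1
    M: np.ndarray  # Y'X, responses vs predictors
    S0: np.ndarray  # Y'Y
    n_obs: int

    @classmethod
    def from_design(cls, design: LaggedDesign) -> "Moments":
        X, Y = design.predictors, design.responses
        return cls(G=X.T @ X, M=Y.T @ X, S0=Y.T @ Y, n_obs=X.shape[0])


def _residual_covariance(B: np.ndarray, mom: Moments) -> np.ndarray:
    """ML residual covariance S(B) = sum_t e_t e_t' / N."""
    S = mom.S0 - B @ mom.M.T - mom.M @ B.T + B @ mom.G @ B.T
    S = (S + S.T) / 2.0
    return S / mom.n_obs


# ---------------------------------------------------------------------------
# covariance selection


@dataclass
class _CovselPattern:
    mode: str  # "complete" | "diagonal" | "chordal" | "ips"
    cliques: List[np.ndarray] = field(default_factory=list)
    separators: List[np.ndarray] = field(default_factory=list)
    pattern_mask: Optional[np.ndarray] = None  # free entries (incl. diagonal)


@functools.lru_cache(maxsize=None)
def _covsel_pattern(n: int, undirected: frozenset) -> _CovselPattern:
    n_full = n * (n - 1) // 2
    if len(undirected) == n_full:
        return _CovselPattern(mode="complete")
    mask = np.eye(n, dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for e in undirected:
        i, j = tuple(e)
        g.add_edge(i, j)
        mask[i, j] = mask[j, i] = True
    if not undirected:
        return _CovselPattern(mode="diagonal", pattern_mask=mask)
    if nx.is_chordal(g):
        cliques = [np.array(sorted(c)) for c in nx.chordal_graph_cliques(g)]
        cliques.sort(key=lambda c: (len(c), tuple(c)))
        # junction tree: maximum-weight spanning tree on clique intersections
        cg = nx.Graph()
        cg.add_nodes_from(range(len(cliques)))
        for a in range(len(cliques)):
            for b in range(a + 1, len(cliques)):
                w = len(np.intersect1d(cliques[a], cliques[b]))
                if w > 0:
                    cg.add_edge(a, b, weight=w)
        tree = nx.maximum_spanning_tree(cg)
        separators = [
            np.intersect1d(cliques[a], cliques[b]) for a, b in sorted(tree.edges())
        ]
        return _CovselPattern(
            mode="chordal", cliques=cliques, separators=separators, pattern_mask=mask
        )
    cliques = [np.array(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (len(c), tuple(c)))
    return _CovselPattern(mode="ips", cliques=cliques, pattern_mask=mask)


def covariance_selection(
    S: np.ndarray,
    structure: GraphStructure,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """ML concentration matrix K with zeros off the undirected edge set.

    Maximizes log det K - tr(K S) subject to K_ij = 0 for {i,j} not an
    undirected edge; equivalently, the inverse of K matches S on the
    diagonal and on the edge set.  Chordal patterns use the exact
    junction-tree formula; non-chordal patterns use iterative
    proportional scaling over the maximal cliques.
    """
    n = S.shape[0]
    pat = _covsel_pattern(n, structure.undirected_edges)
    if pat.mode == "complete":
        return np.linalg.inv(S)
    if pat.mode == "diagonal":
        return np.diag(1.0 / np.diag(S))
    if pat.mode == "chordal":
        K = np.zeros_like(S)
        for c in pat.cliques:
            K[np.ix_(c, c)] += np.linalg.inv(S[np.ix_(c, c)])
        for s in pat.separators:
            K[np.ix_(s, s)] -= np.linalg.inv(S[np.ix_(s, s)])
        K[~pat.pattern_mask] = 0.0  # exact zeros off the pattern
        return (K + K.T) / 2.0
    # iterative proportional scaling
    K = np.diag(1.0 / np.diag(S))
    scale = float(np.max(np.abs(S)))
    for _ in range(max_sweeps):
        for c in pat.cliques:
            Sigma = np.linalg.inv(K)
            K[np.ix_(c, c)] += np.linalg.inv(S[np.ix_(c, c)]) - np.linalg.inv(
                Sigma[np.ix_(c, c)]
            )
        Sigma = np.linalg.inv(K)
        gap = np.max(np.abs((Sigma - S)[pat.pattern_mask]))
        if gap < tol * scale:
            break
    else:
        raise RuntimeError(
            f"iterative proportional scaling did not converge in {max_sweeps} sweeps"
        )
    K[~pat.pattern_mask] = 0.0
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# fit container


@dataclass
class VarFit:
    """A fitted (possibly constrained) pooled VAR(1) model.

    ``beta[i, j]`` is the coefficient of predictor j at t-1 in the
    equation for response i at t; ``concentration`` is the innovation
    concentration matrix K, ``sigma`` its inverse.
    """

    structure: GraphStructure
    beta: np.ndarray
    concentration: np.ndarray
    sigma: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    variable_names: List[str]
    converged: bool = True
    n_iter: int = 0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params

    @property
    def n_vars(self) -> int:
        return self.beta.shape[0]

    def criterion(self, which: Literal["aic", "bic"]) -> float:
        return information_criterion(self, which)

    def to_jsonable(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "directed_edges": sorted(map(list, self.structure.directed_edges)),
            "undirected_edges": sorted(
                sorted(e) for e in map(tuple, self.structure.undirected_edges)
            ),
            "beta": self.beta.tolist(),
            "concentration": self.concentration.tolist(),
            "sigma": self.sigma.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
        }


# ---------------------------------------------------------------------------
# likelihood


def _loglik_from_moments(B: np.ndarray, K: np.ndarray, mom: Moments) -> float:
    S = _residual_covariance(B, mom)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise np.linalg.LinAlgError("concentration matrix is not positive definite")
    N, n = mom.n_obs, B.shape[0]
    return float(-0.5 * N * n * _LOG_2PI + 0.5 * N * logdet - 0.5 * N * np.sum(K * S))


def log_likelihood(fit: VarFit, design: LaggedDesign) -> float:
    """Exact conditional Gaussian log-likelihood of ``fit`` on ``design``."""
    if design.n_vars != fit.n_vars:
        raise ValueError("fit and design dimensions disagree")
    return _loglik_from_moments(fit.beta, fit.concentration, Moments.from_design(design))


def information_criterion(fit: VarFit, which: Literal["aic", "bic"] = "aic") -> float:
    """AIC = -2 loglik + 2 p; BIC = -2 loglik + log(N) p."""
    which = which.lower()
    if which == "aic":
        return -2.0 * fit.loglik + 2.0 * fit.n_params
    if which == "bic":
        return -2.0 * fit.loglik + float(np.log(fit.n_obs)) * fit.n_params
    raise ValueError(f"unknown criterion {which!r}")


# ---------------------------------------------------------------------------
# estimation


def _ols_beta(mom: Moments) -> np.ndarray:
    return np.linalg.solve(mom.G, mom.M.T).T


def fit_unconstrained(design: LaggedDesign) -> VarFit:
    """Conditional-ML (per-equation OLS) fit of the saturated VAR(1)."""
    mom = Moments.from_design(design)
    n = design.n_vars
    if mom.n_obs <= n + 1:
        raise ValueError(f"pooled sample size N={mom.n_obs} too small for n={n}")
    try:
        B = _ols_beta(mom)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular predictor cross-product matrix; variables may be collinear"
        ) from exc
    S = _residual_covariance(B, mom)
    K = np.linalg.inv(S)
    structure = GraphStructure.complete(n)
    ll = _loglik_from_moments(B, K, mom)
    return VarFit(
        structure=structure,
        beta=B,
        concentration=K,
        sigma=S,
        loglik=ll,
        n_params=structure.n_params,
        n_obs=mom.n_obs,
        variable_names=list(design.variable_names),
    )


def _gls_beta(
    K: np.ndarray, mom: Moments, rows: np.ndarray, cols: np.ndarray, n: int
) -> np.ndarray:
    """GLS solution for the free coefficients given concentration K.

    Normal equations: sum over free (i',j') of K[i,i'] G[j,j'] b[i',j']
    = (K M)[i,j] for each free (i,j).
    """
    A = K[np.ix_(rows, rows)] * mom.G[np.ix_(cols, cols)]
    b = (K @ mom.M)[rows, cols]
    theta = np.linalg.solve(A, b)
    B = np.zeros((n, n))
    B[rows, cols] = theta
    return B


def fit_constrained(
    design: LaggedDesign,
    structure: GraphStructure,
    tol: float = 1e-8,
    max_iter: int = 200,
    _moments: Optional[Moments] = None,
    _warm_beta: Optional[np.ndarray] = None,
) -> VarFit:
    """Conditional-ML fit of a graphical VAR(1) under zero constraints.

    Alternates (a) generalized least squares for the free lagged
    coefficients given the current concentration matrix with (b)
    covariance selection for the concentration matrix given the current
    residual covariance, until the relative log-likelihood increase falls
    below ``tol``.  The iterate likelihood sequence is non-decreasing and
    never exceeds the unconstrained fit's.
    """
    mom = _moments if _moments is not None else Moments.from_design(design)
    n = structure.n_vars
    if design is not None and design.n_vars != n:
        raise ValueError("structure dimension does not match design")
    if mom.n_obs <= n + 1:
        raise ValueError(f"pooled sample size N={mom.n_obs} too small for n={n}")

    beta_mask = structure.beta_mask()
    rows, cols = np.where(beta_mask)
    beta_full = beta_mask.all()
    conc_complete = len(structure.undirected_edges) == n * (n - 1) // 2

    B_ols = _ols_beta(mom) if _warm_beta is None else _warm_beta
    B = np.where(beta_mask, B_ols, 0.0)

    if beta_full:
        # all equations share the same regressors: GLS = OLS for any K,
        # so a single covariance-selection step is the joint optimum.
        S_res = _residual_covariance(B, mom)
        K = covariance_selection(S_res, structure)
        ll = _loglik_from_moments(B, K, mom)
        n_iter, converged = 1, True
    else:
        S_res = _residual_covariance(B, mom)
        K = covariance_selection(S_res, structure)
        ll = _loglik_from_moments(B, K, mom)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            B = _gls_beta(K, mom, rows, cols, n)
            S_res = _residual_covariance(B, mom)
            K = covariance_selection(S_res, structure)
            ll_new = _loglik_from_moments(B, K, mom)
            if ll_new < ll - 1e-6 * (1.0 + abs(ll)):
                raise RuntimeError(
                    f"log-likelihood decreased: {ll:.10g} -> {ll_new:.10g}"
                )
            if ll_new - ll < tol * (1.0 + abs(ll)):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if not converged:
            raise RuntimeError(
                f"constrained fit did not converge in {max_iter} iterations; "
                f"last log-likelihoods {ll:.10g}"
            )

    sigma = np.linalg.inv(K)
    return VarFit(
        structure=structure,
        beta=B,
        concentration=K,
        sigma=sigma,
        loglik=ll,
        n_params=structure.n_params,
        n_obs=mom.n_obs,
        variable_names=list(design.variable_names),
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# association measures


def pcc_matrix(fit: VarFit) -> np.ndarray:
    """Partial contemporaneous correlations from the concentration matrix.

    PCC_ij = -K_ij / sqrt(K_ii K_jj) for i != j; unit diagonal.  Entries
    are exactly zero wherever the structure has no undirected edge.
    """
    K = fit.concentration
    d = np.sqrt(np.diag(K))
    if np.any(d <= 0):
        raise ValueError("concentration matrix is not positive definite")
    pcc = -K / np.outer(d, d)
    np.fill_diagonal(pcc, 1.0)
    return pcc


def pdc_matrix(
    fit: VarFit,
    design: LaggedDesign,
    variant: Literal["exact", "rescaled"] = "exact",
) -> np.ndarray:
    """Partial directed correlations: scale-free lagged association strengths.

    Entry (i, j) measures the association between response i at time t
    and predictor j at time t-1 after removing the linear effects of all
    other predictors at t-1.  With tau_jj the conditional variance of
    predictor j given the other predictors (reciprocal j-th diagonal
    entry of the inverse pooled predictor covariance) and sigma_ii the
    residual variance of equation i:

    - ``exact``:    beta_ij sqrt(tau_jj) / sqrt(beta_ij^2 tau_jj + sigma_ii),
      the exact partial correlation, always in (-1, 1);
    - ``rescaled``: beta_ij sqrt(tau_jj / sigma_ii), the first-order
      rescaling of the coefficient (agrees with ``exact`` to first order
      for small coefficients).
    """
    mom = Moments.from_design(design)
    Gm = mom.G / mom.n_obs
    try:
        Ginv = np.linalg.inv(Gm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular pooled predictor covariance") from exc
    tau = 1.0 / np.diag(Ginv)  # conditional predictor variances
    sig = np.diag(fit.sigma)
    B = fit.beta
    if variant == "exact":
        num = B * np.sqrt(tau)[None, :]
        den = np.sqrt(B**2 * tau[None, :] + sig[:, None])
        pdc = num / den
    elif variant == "rescaled":
        pdc = B * np.sqrt(tau[None, :] / sig[:, None])
    else:
        raise ValueError(f"unknown pdc variant {variant!r}")
    return pdc


def significance_bounds(n_obs: int, level: float = 0.95) -> float:
    """Pointwise two-sided test bound for a null partial correlation.

    Under the null a partial-correlation estimate is asymptotically
    N(0, 1/N), so the bound is z_{(1+level)/2} / sqrt(N); an estimate is
    flagged significant iff its magnitude strictly exceeds the bound.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(z / np.sqrt(n_obs))


@dataclass
class AssociationEstimates:
    """PDC and PCC matrices with pointwise test bounds and flags."""

    pdc: np.ndarray
    pcc: np.ndarray
    test_bound: float
    pdc_flags: np.ndarray
    pcc_flags: np.ndarray
    level: float
    variable_names: List[str]
    variant: str = "exact"

    def to_jsonable(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "pdc": self.pdc.tolist(),
            "pcc": self.pcc.tolist(),
            "test_bound": self.test_bound,
            "pdc_flags": self.pdc_flags.tolist(),
            "pcc_flags": self.pcc_flags.tolist(),
            "level": self.level,
            "variant": self.variant,
        }


def estimate_associations(
    fit: VarFit,
    design: LaggedDesign,
    level: float = 0.95,
    variant: Literal["exact", "rescaled"] = "exact",
) -> AssociationEstimates:
    """PDC and PCC with the pointwise test bound at ``level``."""
    pdc = pdc_matrix(fit, design, variant=variant)
    pcc = pcc_matrix(fit)
    bound = significance_bounds(fit.n_obs, level)
    pdc_flags = np.abs(pdc) > bound
    np.fill_diagonal(pdc_flags, np.abs(np.diag(pdc)) > bound)
    pcc_flags = np.abs(pcc) > bound
    np.fill_diagonal(pcc_flags, False)
    return AssociationEstimates(
        pdc=pdc,
        pcc=pcc,
        test_bound=bound,
        pdc_flags=pdc_flags,
        pcc_flags=pcc_flags,
        level=level,
        variable_names=list(fit.variable_names),
        variant=variant,
    )


def wald_tests(fit: VarFit, design: LaggedDesign, alpha: float = 0.05) -> pd.DataFrame:
    """Asymptotic z-tests for every free lagged coefficient.

    Standard errors come from the inverse GLS information matrix at the
    optimum (blocks K[i,i'] (X'X)[j,j']).  Coefficients constrained to
    zero are excluded.  Parameters whose null is not rejected are
    labelled "not well identified": the data cannot distinguish the
    selected model from the smaller model without that edge.
    """
    mom = Moments.from_design(design)
    mask = fit.structure.beta_mask()
    rows, cols = np.where(mask)
    A = fit.concentration[np.ix_(rows, rows)] * mom.G[np.ix_(cols, cols)]
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular information matrix") from exc
    se = np.sqrt(np.diag(cov))
    est = fit.beta[rows, cols]
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    names = fit.variable_names
    return pd.DataFrame(
        {
            "response": [names[i] for i in rows],
            "predictor": [names[j] for j in cols],
            "estimate": est,
            "se": se,
            "z": z,
            "p_value": p,
            "well_identified": p < alpha,
            "label": np.where(p < alpha, "", "not well identified"),
        }
    )
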