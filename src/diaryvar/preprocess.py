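"""Preprocessing chain for diary panels.

The pipeline order is impute -> detrend -> standardize:

1. missing values are replaced by precision-weighted averages of
   univariate autoregressive forward and backward predictions,
2. a low-order polynomial trend is removed from each individual series,
3. each series is divided by its own sample standard deviation.

Differencing is deliberately not offered as a trend remedy: subtracting a
fitted deterministic trend keeps the serial dependence structure intact,
whereas differencing a trend-stationary series injects spurious negative
autocorrelation that a finite-order autoregression cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Tuple

import numpy as np

from .panel import PanelTimeSeries

__all__ = [
    "impute_missing",
    "detrend_polynomial",
    "standardize",
    "preprocess_pipeline",
    "PreprocessInfo",
]


# ---------------------------------------------------------------------------
# AR utilities for imputation


def _yule_walker_pairwise(x: np.ndarray, order: int) -> Tuple[np.ndarray, float]:
    """Yule-Walker AR coefficients from pairwise-complete autocovariances.

    Works on a series containing NaNs (missing entries): lag-h covariance
    is computed over the pairs where both ends are observed.  Returns
    (phi[1..p], innovation variance).
    """
    obs = np.isfinite(x)
    mu = x[obs].mean()
    xc = np.where(obs, x - mu, 0.0)
    gamma = np.empty(order + 1)
    for h in range(order + 1):
        both = obs[h:] & obs[: len(x) - h] if h else obs
        npairs = both.sum()
        if npairs < 2:
            raise ValueError("too few observed pairs for autocovariance estimation")
        if h == 0:
            gamma[0] = (xc[obs] ** 2).sum() / npairs
        else:
            gamma[h] = (xc[h:] * xc[:-h])[both].sum() / npairs
    if gamma[0] <= 0:
        raise ValueError("zero-variance series")
    R = np.empty((order, order))
    for a in range(order):
        for b in range(order):
            R[a, b] = gamma[abs(a - b)]
    phi = np.linalg.solve(R, gamma[1 : order + 1])
    # shrink towards stationarity if the pairwise estimate is explosive
    roots = np.roots(np.r_[1.0, -phi]) if order > 1 else np.array([phi[0]])
    rho = np.max(np.abs(roots)) if order > 1 else abs(phi[0])
    if rho >= 1.0:
        phi = phi * (0.98 / rho)
    sigma2 = gamma[0] - phi @ gamma[1 : order + 1]
    sigma2 = max(sigma2, 1e-12 * gamma[0])
    return phi, float(sigma2)


def _psi_weights(phi: np.ndarray, h: int) -> np.ndarray:
    """First ``h`` moving-average (impulse-response) weights of an AR(p)."""
    p = len(phi)
    psi = np.zeros(h)
    if h == 0:
        return psi
    psi[0] = 1.0
    for k in range(1, h):
        psi[k] = sum(phi[j] * psi[k - 1 - j] for j in range(min(p, k)))
    return psi


def _directional_predictions(
    x: np.ndarray, phi: np.ndarray, sigma2: float, mu: float
) -> Tuple[np.ndarray, np.ndarray]:
    """One-directional AR predictions for the missing entries of ``x``.

    Runs left to right; missing entries are predicted from the most
    recent p values (observed or already predicted within the run) and
    the cumulative h-step forecast-error variance is tracked.  Entries
    with no usable past get infinite variance (zero weight downstream).
    """
    p = len(phi)
    T = len(x)
    pred = np.full(T, np.nan)
    var = np.full(T, np.inf)
    filled = x - mu  # centred working copy; NaN where missing
    horizon = 0
    for t in range(T):
        if np.isfinite(x[t]):
            filled[t] = x[t] - mu
            horizon = 0
            continue
        horizon += 1
        past = filled[max(0, t - p) : t][::-1]  # most recent first
        if len(past) < p or not np.isfinite(past).all():
            continue  # leading run: no usable past
        val = float(phi @ past[:p])
        filled[t] = val
        pred[t] = val + mu
        psi = _psi_weights(phi, horizon)
        var[t] = sigma2 * float((psi**2).sum())
    return pred, var


def impute_missing(
    panel: PanelTimeSeries,
    ar_order: int = 1,
    weights: Literal["precision", "equal"] = "precision",
) -> PanelTimeSeries:
    """Replace missing cells by weighted AR forward/backward predictions.

    For each (subject, variable) series a univariate AR(``ar_order``) is
    estimated from the observed portion (Yule-Walker on pairwise-complete
    autocovariances).  Each missing cell receives

        w_f * forward_prediction + w_b * backward_prediction,

    with weights proportional to the inverse cumulative forecast-error
    variances at the cell's horizon (``weights="precision"``, default) or
    equal (``weights="equal"``).  Cells in a leading (trailing) run use
    the backward (forward) prediction alone.  Observed entries are
    returned unchanged; the output mask is all True.
    """
    if panel.is_fully_observed:
        return panel.copy_with_values(panel.values.copy())
    out = panel.values.copy()
    for k in range(panel.n_subjects):
        Tk = panel.t_lengths[k]
        for i in range(panel.n_vars):
            x = panel.values[k, :Tk, i].copy()
            x[~panel.observed_mask[k, :Tk, i]] = np.nan
            miss = ~np.isfinite(x)
            if not miss.any():
                out[k, :Tk, i] = x
                continue
            n_obs = int((~miss).sum())
            sid, vname = panel.subject_ids[k], panel.variable_names[i]
            if n_obs < ar_order + 2:
                raise ValueError(
                    f"series ({sid!r}, {vname!r}) too short: "
                    f"{n_obs} observed values for AR({ar_order}) imputation"
                )
            if miss.mean() >= 0.5:
                raise ValueError(
                    f"series ({sid!r}, {vname!r}) too sparse: "
                    f"{miss.mean():.0%} missing (>= 50%)"
                )
            phi, sigma2 = _yule_walker_pairwise(x, ar_order)
            mu = float(np.nanmean(x))
            fwd, var_f = _directional_predictions(x, phi, sigma2, mu)
            bwd_r, var_b_r = _directional_predictions(x[::-1], phi, sigma2, mu)
            bwd, var_b = bwd_r[::-1], var_b_r[::-1]
            for t in np.where(miss)[0]:
                vf, vb = var_f[t], var_b[t]
                if not np.isfinite(vf) and not np.isfinite(vb):
                    out[k, t, i] = mu  # isolated: fall back to series mean
                elif not np.isfinite(vf):
                    out[k, t, i] = bwd[t]
                elif not np.isfinite(vb):
                    out[k, t, i] = fwd[t]
                else:
                    if weights == "equal":
                        wf = wb = 0.5
                    else:
                        wf = (1.0 / vf) / (1.0 / vf + 1.0 / vb)
                        wb = 1.0 - wf
                    out[k, t, i] = wf * fwd[t] + wb * bwd[t]
    mask = panel.observed_mask.copy()
    for k in range(panel.n_subjects):
        mask[k, : panel.t_lengths[k]] = True
    return panel.copy_with_values(out, mask)


# ---------------------------------------------------------------------------
# detrending and scaling


@dataclass
class PreprocessInfo:
    """Sidecar of per-series trend coefficients and scale factors."""

    trend_degree: int = -1
    # trend coefficients in the shifted/scaled basis used by numpy's
    # Polynomial.fit; keyed (subject_id, variable_name)
    trend_coefficients: Dict[Tuple[str, str], List[float]] = field(default_factory=dict)
    scale_factors: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "trend_degree": self.trend_degree,
            "trend_coefficients": {
                f"{s}::{v}": c for (s, v), c in self.trend_coefficients.items()
            },
            "scale_factors": {f"{s}::{v}": c for (s, v), c in self.scale_factors.items()},
        }


def detrend_polynomial(
    panel: PanelTimeSeries, degree: int = 5
) -> Tuple[PanelTimeSeries, PreprocessInfo]:
    """Subtract a least-squares polynomial trend from every individual series.

    The fit is per (subject, variable) series in the occasion index,
    using numpy's scaled-domain polynomial basis for conditioning at
    degree 5.  Residuals are numerically orthogonal to the basis.
    """
    if not panel.is_fully_observed:
        raise ValueError("detrending requires a fully observed panel; impute first")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    info = PreprocessInfo(trend_degree=degree)
    out = panel.values.copy()
    for k in range(panel.n_subjects):
        Tk = panel.t_lengths[k]
        if Tk <= degree + 1:
            raise ValueError(
                f"subject {panel.subject_ids[k]!r} has T={Tk} <= degree+1={degree + 1}: "
                "the polynomial would interpolate the series exactly"
            )
        t = np.arange(Tk, dtype=float)
        for i in range(panel.n_vars):
            y = panel.values[k, :Tk, i]
            poly = np.polynomial.Polynomial.fit(t, y, deg=degree)
            trend = poly(t)
            out[k, :Tk, i] = y - trend
            info.trend_coefficients[(panel.subject_ids[k], panel.variable_names[i])] = [
                float(c) for c in poly.coef
            ]
    return panel.copy_with_values(out), info


def standardize(panel: PanelTimeSeries) -> Tuple[PanelTimeSeries, PreprocessInfo]:
    """Divide each individual series by its sample standard deviation (ddof=1).

    Means are not subtracted beyond what detrending removed.
    """
    if not panel.is_fully_observed:
        raise ValueError("standardization requires a fully observed panel; impute first")
    info = PreprocessInfo()
    out = panel.values.copy()
    for k in range(panel.n_subjects):
        Tk = panel.t_lengths[k]
        for i in range(panel.n_vars):
            y = panel.values[k, :Tk, i]
            sd = float(np.std(y, ddof=1))
            if sd <= 0 or not np.isfinite(sd):
                raise ValueError(
                    f"zero-variance series ({panel.subject_ids[k]!r}, "
                    f"{panel.variable_names[i]!r}) cannot be standardized"
                )
            out[k, :Tk, i] = y / sd
            info.scale_factors[(panel.subject_ids[k], panel.variable_names[i])] = sd
    return panel.copy_with_values(out), info


def preprocess_pipeline(
    panel: PanelTimeSeries,
    ar_order: int = 1,
    degree: int = 5,
    weights: Literal["precision", "equal"] = "precision",
) -> Tuple[PanelTimeSeries, PreprocessInfo]:
    """Run impute -> detrend -> standardize and merge the sidecars."""
    imputed = impute_missing(panel, ar_order=ar_order, weights=weights)
    detrended, info = detrend_polynomial(imputed, degree=degree)
    scaled, scale_info = standardize(detrended)
    info.scale_factors = scale_info.scale_factors
    return scaled, info
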