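"""MVAR model validation battery.

Three checks are applied to every fitted model before any connectivity
measure is trusted:

* **residual whiteness** — per-lag, per-channel-pair residual
  autocorrelations against the ±1.96/sqrt(N) band, plus the Li-McLeod
  Portmanteau statistic referred to a chi-squared null;
* **stability** — the log of the largest companion-matrix eigenvalue
  modulus must be negative (stationary process);
* **percent consistency** — data regenerated from the fitted model must
  reproduce the auto/cross-correlation structure of the real window
  (the pass convention used throughout is > 85%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mvar import MVARModel
from .simulate import simulate_mvar

__all__ = [
    "ValidationReport",
    "residuals",
    "acf_whiteness",
    "li_mcleod_portmanteau",
    "stability_index",
    "percent_consistency",
    "validate_model",
]


@dataclass
class ValidationReport:
    """Outcome of the three-part validation battery for one window."""

    acf_white: bool
    acf_max_abs: float
    lmp_stat: float
    lmp_p: float
    stability_index: float
    percent_consistency: float
    thresholds: dict

    @property
    def stable(self) -> bool:
        return self.stability_index < self.thresholds.get("stability", 0.0)

    @property
    def consistent(self) -> bool:
        return self.percent_consistency > self.thresholds.get("pc", 85.0)

    @property
    def lmp_white(self) -> bool:
        return self.lmp_p > self.thresholds.get("alpha", 0.05)

    @property
    def passed(self) -> bool:
        return self.stable and self.consistent and self.acf_white and self.lmp_white

    def to_dict(self) -> dict:
        return {
            "acf_white": bool(self.acf_white),
            "acf_max_abs": float(self.acf_max_abs),
            "lmp_stat": float(self.lmp_stat),
            "lmp_p": float(self.lmp_p),
            "stability_index": float(self.stability_index),
            "percent_consistency": float(self.percent_consistency),
            "passed": bool(self.passed),
            "thresholds": self.thresholds,
        }


def _as3d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    return x


def residuals(model: MVARModel, x_window: np.ndarray) -> np.ndarray:
    """Innovation estimates ``E(t) = X(t) - sum_n A(n) X(t-n)`` for t > p.

    ``x_window`` is ``(channels, samples[, trials])``; the mean over the
    window is removed first (fits are performed on demeaned data).
    Output is ``(channels, samples - p, trials)``.
    """
    x = _as3d(x_window)
    k, n, r = x.shape
    p = model.order
    if model.n_channels != k:
        raise ValueError(
            f"model has {model.n_channels} channels but window has {k}"
        )
    if n <= p:
        raise ValueError(f"window of {n} samples shorter than model order {p}")
    x = x - x.mean(axis=(1, 2), keepdims=True)
    pred = np.zeros((k, n - p, r))
    for lag in range(1, p + 1):
        pred += np.einsum("ij,jtr->itr", model.coeffs[lag - 1], x[:, p - lag : n - lag, :])
    return x[:, p:, :] - pred


def _cross_correlations(res: np.ndarray, n_lags: int) -> np.ndarray:
    """Normalized residual cross-correlation matrices R(l), l = 1..n_lags.

    R_ij(l) = c_ij(l) / sqrt(c_ii(0) c_jj(0)), with lagged products
    pooled across trials.
    """
    x = _as3d(res)
    k, n, r = x.shape
    x = x - x.mean(axis=(1, 2), keepdims=True)
    c0 = np.einsum("itr,jtr->ij", x, x) / (n * r)
    d = np.sqrt(np.outer(np.diag(c0), np.diag(c0)))
    if np.any(np.diag(c0) <= 0):
        raise ValueError("degenerate (constant) residual channel; autocorrelation undefined")
    out = np.empty((n_lags, k, k))
    for lag in range(1, n_lags + 1):
        cl = np.einsum("itr,jtr->ij", x[:, lag:, :], x[:, :-lag, :]) / (n * r)
        out[lag - 1] = cl / d
    return out


def acf_whiteness(
    res: np.ndarray, n_lags: int = 20, alpha: float = 0.05
) -> tuple[bool, float]:
    """Band test on residual autocorrelations.

    Residuals are white if the per-lag, per-channel-pair correlations
    fall inside the two-sided ``+-z_{alpha/2}/sqrt(N)`` band at the
    nominal ``1 - alpha`` rate.  Because each of the ``M = k^2 n_lags``
    correlations is *expected* to stray outside the band with
    probability ``alpha`` even under exact whiteness, the pass rule
    allows the binomial sampling slack: white iff

        fraction inside >= (1 - alpha) - 2 sqrt(alpha (1 - alpha) / M).

    Returns (white, max |correlation|).
    """
    x = _as3d(res)
    k, n, r = x.shape
    if n_lags >= n // 4:
        raise ValueError("n_lags must be below a quarter of the sample count")
    R = _cross_correlations(x, n_lags)
    n_eff = n * r
    bound = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n_eff)
    inside = np.abs(R) <= bound
    slack = 2.0 * np.sqrt(alpha * (1 - alpha) / R.size)
    return bool(inside.mean() >= (1 - alpha) - slack), float(np.max(np.abs(R)))


def li_mcleod_portmanteau(
    res: np.ndarray, h: int = 20, p: int = 0
) -> tuple[float, float]:
    """Li-McLeod Portmanteau whiteness test.

    Q = N * sum_{l=1..h} tr(C_l' C_0^-1 C_l C_0^-1) + k^2 h (h+1) / (2N),
    referred to a chi-squared distribution with ``k^2 (h - p)`` degrees
    of freedom, where ``p`` is the order of the fitted model whose
    residuals are tested.  Returns (statistic, p-value).
    """
    x = _as3d(res)
    k, n, r = x.shape
    if h <= p:
        raise ValueError(f"max lag h={h} must exceed model order p={p}")
    n_eff = n * r
    x = x - x.mean(axis=(1, 2), keepdims=True)
    c0 = np.einsum("itr,jtr->ij", x, x) / n_eff
    try:
        c0_inv = np.linalg.inv(c0)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular lag-0 residual covariance") from None
    q = 0.0
    for lag in range(1, h + 1):
        cl = np.einsum("itr,jtr->ij", x[:, lag:, :], x[:, :-lag, :]) / n_eff
        q += np.trace(cl.T @ c0_inv @ cl @ c0_inv)
    stat = n_eff * q + k * k * h * (h + 1) / (2.0 * n_eff)
    df = k * k * (h - p)
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), pval


def stability_index(model: MVARModel) -> float:
    """Log of the largest companion-matrix eigenvalue modulus.

    Negative for a stable (stationary) model; 0 marks a unit root.
    """
    eig = np.linalg.eigvals(model.companion())
    radius = float(np.max(np.abs(eig)))
    return float("-inf") if radius == 0.0 else float(np.log(radius))


def _correlation_vector(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Stacked auto/cross-correlations at lags 0..max_lag."""
    x = _as3d(x)
    k, n, r = x.shape
    x = x - x.mean(axis=(1, 2), keepdims=True)
    c0 = np.einsum("itr,jtr->ij", x, x) / (n * r)
    d = np.sqrt(np.outer(np.diag(c0), np.diag(c0)))
    d[d == 0] = 1.0
    mats = [c0 / d]
    for lag in range(1, max_lag + 1):
        cl = np.einsum("itr,jtr->ij", x[:, lag:, :], x[:, :-lag, :]) / (n * r)
        mats.append(cl / d)
    return np.concatenate([m.ravel() for m in mats])


def percent_consistency(
    x_window: np.ndarray,
    model: MVARModel,
    seed: int | np.random.Generator = 0,
    max_lag: int = 20,
) -> float:
    """Percent of the data's correlation structure reproduced by the model.

    Surrogate data of matched shape is simulated from the fitted model,
    and PC = 100 * (1 - ||R_sim - R_real|| / ||R_real||) over the
    stacked vector of all auto/cross-correlations up to ``max_lag``.
    Deterministic for a fixed seed.
    """
    x = _as3d(x_window)
    k, n, r = x.shape
    if stability_index(model) >= 0:
        raise ValueError("percent consistency requires a stable model to simulate")
    sim = simulate_mvar(model, n, r, seed=seed)
    lag = min(max_lag, n - 2)
    r_real = _correlation_vector(x, lag)
    r_sim = _correlation_vector(sim, lag)
    denom = np.linalg.norm(r_real)
    if denom == 0:
        raise ValueError("real correlation vector is zero; PC undefined")
    return float(100.0 * (1.0 - np.linalg.norm(r_sim - r_real) / denom))


def validate_model(
    model: MVARModel,
    x_window: np.ndarray,
    seed: int | np.random.Generator = 0,
    n_lags: int = 12,
    alpha: float = 0.05,
    pc_threshold: float = 85.0,
    include_pc: bool = True,
) -> ValidationReport:
    """Run the full three-part battery on one fitted window."""
    res = residuals(model, x_window)
    n_eff = res.shape[1]
    lags = max(2, min(n_lags, n_eff // 4 - 1))
    white, max_r = acf_whiteness(res, n_lags=lags, alpha=alpha)
    h = max(model.order + 1, lags)
    stat, pval = li_mcleod_portmanteau(res, h=h, p=model.order)
    si = stability_index(model)
    if include_pc and si < 0:
        pc = percent_consistency(x_window, model, seed=seed)
    elif include_pc:
        pc = float("nan")
    else:
        pc = float("nan")
    return ValidationReport(
        acf_white=white,
        acf_max_abs=max_r,
        lmp_stat=stat,
        lmp_p=pval,
        stability_index=si,
        percent_consistency=pc,
        thresholds={"stability": 0.0, "pc": pc_threshold, "alpha": alpha},
    )
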