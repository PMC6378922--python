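"""Windowed multivariate autoregressive (MVAR) model fitting.

An order-``p`` MVAR model of a ``k``-channel series ``X(t)`` is

    X(t) = sum_{n=1..p} A(n) X(t-n) + E(t),

with ``k x k`` coefficient matrices ``A(n)`` and innovation covariance
``Sigma_E``.  The module provides ensemble normalization across trials,
two fitting routes — a multichannel lattice with geometric-mean
(Vieira-Morf) reflection-coefficient normalization, and plain
multivariate least squares as an independent route — short sliding
windows for time-varying analysis, and Hannan-Quinn order selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .timeseries import SourceTimeSeries

__all__ = [
    "MVARModel",
    "WindowSpec",
    "ensemble_normalize",
    "fit_window",
    "sliding_fit",
    "select_order",
    "hq_criterion",
]


@dataclass
class MVARModel:
    """Fitted (or constructed) MVAR model for one analysis window.

    ``coeffs`` has shape ``(p, k, k)``; ``coeffs[n-1][i, j]`` is the
    influence of channel ``j`` at lag ``n`` on channel ``i``.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float
    window: tuple[float, float] | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        p, k, k2 = self.coeffs.shape
        if k != k2:
            raise ValueError("coefficient matrices must be square")
        if p < 1:
            raise ValueError("model order must be >= 1")
        if self.noise_cov.shape != (k, k):
            raise ValueError("noise covariance shape must match channel count")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """The ``k*p x k*p`` companion matrix of the model."""
        p, k, _ = self.coeffs.shape
        C = np.zeros((k * p, k * p))
        C[:k, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            C[k:, :-k] = np.eye(k * (p - 1))
        return C

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "fs": self.fs,
            "window": self.window,
            "channel_names": self.channel_names,
            "coeffs": self.coeffs.tolist(),
            "noise_cov": self.noise_cov.tolist(),
        }


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for time-varying fits.

    The window length is specified in milliseconds and realized as
    ``round(length_ms * fs / 1000)`` samples (45 at the 350 ms / 128 Hz
    defaults); the step is in samples.
    """

    length_ms: float = 350.0
    step_samples: int = 30
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.step_samples < 1:
            raise ValueError("step must be >= 1 sample")
        if self.length_samples < 2:
            raise ValueError("window too short")

    @property
    def length_samples(self) -> int:
        return int(round(self.length_ms * self.fs / 1000.0))

    def starts(self, n_samples: int) -> np.ndarray:
        """Start indices of all complete windows in a series of length n."""
        w = self.length_samples
        if n_samples < w:
            raise ValueError(
                f"series of {n_samples} samples shorter than one {w}-sample window"
            )
        return np.arange(0, n_samples - w + 1, self.step_samples)


def ensemble_normalize(ts: SourceTimeSeries, ddof: int = 1) -> SourceTimeSeries:
    """Pointwise z-score across trials.

    At every (channel, time) point the across-trial mean is removed and
    the across-trial standard deviation (``ddof=1``) divided out, so the
    normalized ensemble has mean ~0 and SD ~1 at every time point.  With
    a single trial the fallback is a per-channel z-score over time.
    """
    x = ts.data
    if x.shape[2] == 1:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=ddof, keepdims=True)
        if np.any(sd == 0):
            ch = int(np.argwhere(sd[:, 0, 0] == 0)[0][0])
            raise ValueError(f"zero variance in channel {ts.channel_names[ch]}")
        z = (x - mu) / sd
    else:
        mu = x.mean(axis=2, keepdims=True)
        sd = x.std(axis=2, ddof=ddof, keepdims=True)
        if np.any(sd == 0):
            ch, t = np.argwhere(sd[:, :, 0] == 0)[0]
            raise ValueError(
                f"zero across-trial variance at channel {ts.channel_names[ch]}, "
                f"sample {t}"
            )
        z = (x - mu) / sd
    return SourceTimeSeries(
        z, ts.fs, list(ts.channel_names), ts.condition_labels, ts.seed, dict(ts.meta)
    )


def _as_3d(x: np.ndarray | SourceTimeSeries) -> tuple[np.ndarray, float, list[str] | None]:
    if isinstance(x, SourceTimeSeries):
        return x.data, x.fs, list(x.channel_names)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr, float("nan"), None


def _vm_lattice(x: np.ndarray, p_max: int, demean: bool = True):
    """Multichannel lattice recursion with Vieira-Morf normalization.

    At each stage the forward/backward partial cross-covariance is
    normalized by the Cholesky square roots of the forward and backward
    error covariances (the geometric-mean normalization), giving
    reflection matrices with spectral norm <= 1 and hence a stable
    fitted model.  Trials contribute jointly to every stage's error
    covariances.

    Returns
    -------
    coeffs_by_order : list of (m, k, k) arrays, m = 1..p_max
    sigma_by_order : list of (k, k) residual covariances, m = 0..p_max
    """
    k, n, r = x.shape
    if n <= p_max:
        raise ValueError(f"window of {n} samples cannot support order {p_max}")
    x = x - x.mean(axis=(1, 2), keepdims=True) if demean else x
    F = x.copy()
    B = x.copy()
    n_total = n * r

    def _cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # a, b: (k, t, r) -> (1/cnt) sum a b^T
        cnt = a.shape[1] * a.shape[2]
        return np.einsum("itr,jtr->ij", a, b) / cnt

    sigma0 = _cov(x, x)
    A_prev: np.ndarray = np.zeros((0, k, k))
    B_prev: np.ndarray = np.zeros((0, k, k))
    coeffs_by_order: list[np.ndarray] = []
    sigma_by_order: list[np.ndarray] = [sigma0]

    for m in range(1, p_max + 1):
        f = F[:, m:, :]
        b = B[:, m - 1 : n - 1, :]
        Pf = _cov(f, f)
        Pb = _cov(b, b)
        Pfb = _cov(f, b)
        try:
            Sf = np.linalg.cholesky(Pf + 0.0)
            Sb = np.linalg.cholesky(Pb + 0.0)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular prediction-error covariance at lattice stage {m}"
            ) from None
        # rho = Sf^-1 Pfb Sb^-T ; geometric-mean normalized partial correlation
        rho = np.linalg.solve(Sf, np.linalg.solve(Sb, Pfb.T).T)
        Kf = Sf @ rho @ np.linalg.inv(Sb)
        Kb = Sb @ rho.T @ np.linalg.inv(Sf)
        # error update; compute both before writing (f and b are views)
        f_new = f - np.einsum("ij,jtr->itr", Kf, b)
        b_new = b - np.einsum("ij,jtr->itr", Kb, f)
        F[:, m:, :] = f_new
        B[:, m:, :] = b_new
        # Levinson-Whittle-Wiggins-Robinson coefficient update
        A_new = np.empty((m, k, k))
        B_new = np.empty((m, k, k))
        A_new[m - 1] = Kf
        B_new[m - 1] = Kb
        for i in range(m - 1):
            A_new[i] = A_prev[i] - Kf @ B_prev[m - 2 - i]
            B_new[i] = B_prev[i] - Kb @ A_prev[m - 2 - i]
        A_prev, B_prev = A_new, B_new
        coeffs_by_order.append(A_new.copy())
        sigma_by_order.append(_cov(F[:, m:, :], F[:, m:, :]))

    return coeffs_by_order, sigma_by_order


def _ols_fit(x: np.ndarray, p: int, demean: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate least-squares MVAR fit (independent reference route)."""
    k, n, r = x.shape
    if demean:
        x = x - x.mean(axis=(1, 2), keepdims=True)
    rows = []
    targets = []
    for tr in range(r):
        xt = x[:, :, tr]
        # regressor row at time t: [x(t-1); ...; x(t-p)]
        Z = np.concatenate([xt[:, p - lag : n - lag] for lag in range(1, p + 1)], axis=0)
        rows.append(Z.T)
        targets.append(xt[:, p:].T)
    Z = np.vstack(rows)
    Y = np.vstack(targets)
    if Z.shape[0] <= Z.shape[1]:
        raise ValueError(
            f"{Z.shape[0]} usable samples cannot identify order {p} with "
            f"{k} channels ({Z.shape[1]} regressors)"
        )
    coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError("ill-conditioned normal equations in MVAR fit")
    resid = Y - Z @ coef
    sigma = resid.T @ resid / resid.shape[0]
    A = coef.T.reshape(k, p, k).transpose(1, 0, 2)
    return A, sigma


def fit_window(
    x: np.ndarray | SourceTimeSeries,
    p: int,
    method: Literal["vieira_morf", "ols"] = "vieira_morf",
    fs: float | None = None,
    window: tuple[float, float] | None = None,
) -> MVARModel:
    """Fit an order-``p`` MVAR model to one data window.

    ``x`` is ``(channels, samples[, trials])``; trials are pooled.  The
    ``vieira_morf`` route is the production estimator; ``ols`` is plain
    multivariate least squares, kept as an independent cross-check.
    """
    arr, ts_fs, names = _as_3d(x)
    k, n, r = arr.shape
    if p < 1:
        raise ValueError("order must be >= 1")
    if n * r - p * r <= k * p:
        raise ValueError(
            f"window with {n} samples x {r} trials too short for order {p} "
            f"with {k} channels"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("window contains non-finite samples")
    if method == "vieira_morf":
        coeffs_by_order, sigma_by_order = _vm_lattice(arr, p)
        A, sigma = coeffs_by_order[-1], sigma_by_order[-1]
    elif method == "ols":
        A, sigma = _ols_fit(arr, p)
    else:
        raise ValueError(f"unknown fitting method {method!r}")
    sigma = 0.5 * (sigma + sigma.T)
    return MVARModel(A, sigma, fs if fs is not None else ts_fs, window, names)


def sliding_fit(
    x: np.ndarray | SourceTimeSeries,
    spec: WindowSpec | None = None,
    p: int = 16,
    method: Literal["vieira_morf", "ols"] = "vieira_morf",
) -> list[MVARModel]:
    """Fit one MVAR model per sliding-window position.

    Windows start at ``0, step, 2*step, ...``; a trailing partial
    window is dropped.
    """
    arr, ts_fs, names = _as_3d(x)
    if spec is None:
        spec = WindowSpec(fs=ts_fs if np.isfinite(ts_fs) else 128.0)
    fs = spec.fs
    w = spec.length_samples
    models = []
    for start in spec.starts(arr.shape[1]):
        seg = arr[:, start : start + w, :]
        models.append(
            fit_window(
                seg,
                p,
                method=method,
                fs=fs,
                window=(start / fs, w / fs),
            )
        )
        if names is not None:
            models[-1].channel_names = names
    return models


def hq_criterion(sigma: np.ndarray, p: int, n_total: int, k: int) -> float:
    """Hannan-Quinn criterion ``ln det Sigma + 2 p k^2 ln(ln N) / N``."""
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return float(logdet + 2.0 * p * k * k * np.log(np.log(n_total)) / n_total)


def select_order(
    x: np.ndarray | SourceTimeSeries,
    p_range: range | tuple[int, int] = (1, 40),
    criterion: Literal["hannan_quinn"] = "hannan_quinn",
    return_values: bool = False,
):
    """Select the MVAR model order by minimizing the Hannan-Quinn criterion.

    A single lattice sweep to the maximum order yields the residual
    covariance at every intermediate order, so all candidates are scored
    in one pass.  Ties go to the smallest order.
    """
    if criterion != "hannan_quinn":
        raise ValueError(f"unknown criterion {criterion!r}")
    if isinstance(p_range, range):
        orders = list(p_range)
    else:
        lo, hi = p_range
        orders = list(range(lo, hi + 1))
    if not orders:
        raise ValueError("empty order range")
    if min(orders) < 1:
        raise ValueError("orders must be >= 1")
    arr, _, _ = _as_3d(x)
    k, n, r = arr.shape
    p_max = max(orders)
    n_total = n * r
    _, sigma_by_order = _vm_lattice(arr, p_max)
    values = {p: hq_criterion(sigma_by_order[p], p, n_total, k) for p in orders}
    best = min(orders, key=lambda p: (values[p], p))
    if return_values:
        return best, values
    return best


def mean_selected_order(orders: list[int]) -> float:
    """Average of per-dataset order selections (cohort summary utility)."""
    if not orders:
        raise ValueError("no orders to average")
    return float(np.mean(orders))
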