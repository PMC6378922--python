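"""MVAR process simulation.

Iterates ``X(t) = sum_n A(n) X(t-n) + E(t)`` with independent Gaussian
innovations drawn from the model's noise covariance, discarding a
burn-in (default ten times the model order) so the output is a sample
from the stationary distribution.  Unstable models are refused rather
than simulated.
"""

from __future__ import annotations

import numpy as np

from .mvar import MVARModel

__all__ = ["simulate_mvar", "random_stable_mvar"]


def _log_spectral_radius(model: MVARModel) -> float:
    eig = np.linalg.eigvals(model.companion())
    radius = float(np.max(np.abs(eig)))
    return float("-inf") if radius == 0.0 else float(np.log(radius))


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    n_trials: int = 1,
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
) -> np.ndarray:
    """Simulate ``(channels, n_samples, n_trials)`` data from an MVAR model.

    Deterministic for a fixed integer seed.  ``burn_in`` defaults to
    ``10 * order`` samples, discarded from the start of each trial.
    """
    if n_samples < 1 or n_trials < 1:
        raise ValueError("n_samples and n_trials must be positive")
    if _log_spectral_radius(model) >= 0:
        raise ValueError(
            "refusing to simulate an unstable MVAR model "
            f"(log spectral radius = {_log_spectral_radius(model):.4f} >= 0)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, k, _ = model.coeffs.shape
    if burn_in is None:
        burn_in = 10 * p
    total = n_samples + burn_in
    chol = np.linalg.cholesky(
        model.noise_cov + 1e-12 * np.eye(k) * np.trace(model.noise_cov) / max(k, 1)
    )
    out = np.empty((k, n_samples, n_trials))
    A = model.coeffs
    for tr in range(n_trials):
        e = chol @ rng.standard_normal((k, total + p))
        x = np.zeros((k, total + p))
        for t in range(p, total + p):
            acc = e[:, t].copy()
            for n in range(1, p + 1):
                acc += A[n - 1] @ x[:, t - n]
            x[:, t] = acc
        out[:, :, tr] = x[:, p + burn_in :]
    return out


def random_stable_mvar(
    k: int,
    order: int,
    seed: int | np.random.Generator,
    fs: float = 128.0,
    coupling: float = 0.3,
    n_couplings: int | None = None,
    osc_radius: float = 0.85,
    osc_band: tuple[float, float] = (7.0, 30.0),
) -> MVARModel:
    """Construct a random stable MVAR model with a given generating order.

    Each channel is an AR(2) resonator with a random center frequency in
    ``osc_band``; sparse cross-channel couplings are placed at the
    maximum lag so the generating order is exactly ``order``.  If the
    raw construction is unstable, all coefficients are contracted
    geometrically until the log spectral radius is negative (this is a
    test-model factory, not the network realizer, which refuses to
    rescale).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if order < 1:
        raise ValueError("order must be >= 1")
    A = np.zeros((order, k, k))
    freqs = rng.uniform(osc_band[0], osc_band[1], size=k)
    theta = 2 * np.pi * freqs / fs
    A[0, np.arange(k), np.arange(k)] = 2 * osc_radius * np.cos(theta)
    if order >= 2:
        A[1, np.arange(k), np.arange(k)] = -(osc_radius**2)
    else:
        A[0, np.arange(k), np.arange(k)] = osc_radius
    if n_couplings is None:
        n_couplings = k
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    idx = rng.choice(len(pairs), size=min(n_couplings, len(pairs)), replace=False)
    for m in np.atleast_1d(idx):
        i, j = pairs[int(m)]
        A[order - 1, i, j] = coupling * rng.choice([-1.0, 1.0])
    model = MVARModel(A, np.eye(k), fs)
    while _log_spectral_radius(model) >= 0:
        A = A * 0.95
        model = MVARModel(A, np.eye(k), fs)
    return model
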