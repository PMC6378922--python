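"""Frequency-domain directed connectivity from fitted MVAR models.

From the coefficient matrices of a (stable) MVAR model the transfer
matrix ``H(f) = [I - sum_n A(n) exp(-i 2 pi f n / fs)]^-1`` and spectral
matrix ``S(f) = H Sigma_E H^H`` are formed.  Three measures follow:

* **DTF** — ``|H_ij|^2`` normalized per sink row, the classic directed
  transfer function;
* **partial coherence** — from the inverse spectral matrix, which
  suppresses indirect (mediated) links;
* **dDTF** — the product of the full-frequency-normalized DTF and
  partial coherence, giving *direct*, directed, frequency-specific flow.

dDTF is evaluated over 2-32 Hz by default and directed edges are kept
when they strictly exceed the 97.5th percentile of the off-diagonal
values at their frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mvar import MVARModel

__all__ = [
    "SpectralSet",
    "ConnectivityTensor",
    "transfer_function",
    "dtf",
    "partial_coherence",
    "ddtf",
    "threshold_edges",
]


@dataclass
class SpectralSet:
    """Transfer and spectral matrices on a frequency grid.

    ``H[f]`` and ``S[f]`` are complex ``k x k``; entry ``(i, j)``
    refers to flow from channel ``j`` to channel ``i``.
    """

    freqs: np.ndarray
    H: np.ndarray
    S: np.ndarray
    channel_names: list[str] | None = None


@dataclass
class ConnectivityTensor:
    """dDTF values indexed ``(from, to, frequency, window)``.

    ``values[j, i, f, w]`` is the direct directed flow from node ``j``
    into node ``i`` at frequency ``freqs[f]`` in window ``w``.
    Intermediate measures (dtf, ffdtf, pcoh) share the same layout
    under ``intermediates``.
    """

    values: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 3:
            self.values = self.values[:, :, :, None]
        if self.values.ndim != 4:
            raise ValueError("values must be (from, to, freq, window)")
        if np.any(self.values < -1e-12):
            raise ValueError("connectivity values must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[3]

    def band_mean(self, band: tuple[float, float] | None = None) -> np.ndarray:
        """Mean over windows and over frequencies in ``band`` -> (from, to)."""
        mask = (
            np.ones_like(self.freqs, dtype=bool)
            if band is None
            else (self.freqs >= band[0]) & (self.freqs <= band[1])
        )
        if not mask.any():
            raise ValueError(f"band {band} contains no frequency bins")
        return self.values[:, :, mask, :].mean(axis=(2, 3))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        names = self.channel_names
        for w in range(self.n_windows):
            for fi, f in enumerate(self.freqs):
                for j in range(self.n_nodes):
                    for i in range(self.n_nodes):
                        rows.append(
                            (w, float(f), names[j], names[i], float(self.values[j, i, fi, w]))
                        )
        return pd.DataFrame(
            rows, columns=["window", "freq_hz", "from_node", "to_node", "ddtf"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def transfer_function(
    model: MVARModel, freqs: np.ndarray | list[float]
) -> SpectralSet:
    """Evaluate ``H(f)`` and ``S(f)`` on a frequency grid.

    ``Abar(f) = I - sum_n A(n) exp(-i 2 pi f n / fs)``; ``H = Abar^-1``;
    ``S = H Sigma_E H^H``.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = model.fs
    if not np.isfinite(fs) or fs <= 0:
        raise ValueError("model must carry a valid sampling rate")
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError(f"frequencies must lie strictly inside (0, {fs / 2}) Hz")
    p, k, _ = model.coeffs.shape
    H = np.empty((len(freqs), k, k), dtype=complex)
    S = np.empty_like(H)
    for fi, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f * np.arange(1, p + 1) / fs)
        Abar = np.eye(k, dtype=complex) - np.tensordot(z, model.coeffs, axes=(0, 0))
        try:
            Hf = np.linalg.inv(Abar)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular characteristic matrix at {f:.3f} Hz"
            ) from None
        H[fi] = Hf
        S[fi] = Hf @ model.noise_cov @ Hf.conj().T
    return SpectralSet(freqs, H, S, model.channel_names)


def dtf(H: np.ndarray) -> np.ndarray:
    """Directed transfer function ``gamma^2_{i<-j}(f)``.

    ``H`` is ``(freqs, k, k)``; output has the same shape and each row
    (fixed sink ``i``, over sources ``j``) sums to 1 at each frequency.
    """
    H = np.asarray(H)
    power = np.abs(H) ** 2
    denom = power.sum(axis=2, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("zero transfer-function row; DTF undefined")
    return power / denom


def partial_coherence(S: np.ndarray) -> np.ndarray:
    """Partial coherence ``chi^2_ij(f)`` from the spectral matrix.

    With ``M = S(f)^-1``: ``chi^2_ij = |M_ij|^2 / (M_ii M_jj)``.
    Symmetric, values in [0, 1].
    """
    S = np.asarray(S)
    nf, k, _ = S.shape
    out = np.empty((nf, k, k))
    for fi in range(nf):
        try:
            M = np.linalg.inv(S[fi])
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular spectral matrix at frequency index {fi}"
            ) from None
        d = np.real(np.diag(M))
        out[fi] = np.abs(M) ** 2 / np.outer(d, d)
    return np.clip(out, 0.0, 1.0)


def _ffdtf_sq(H: np.ndarray) -> np.ndarray:
    """Full-frequency DTF squared: row-normalized over all frequencies."""
    power = np.abs(H) ** 2
    denom = power.sum(axis=(0, 2), keepdims=True)  # sum over f and sources
    return power / denom


def ddtf(
    models: MVARModel | list[MVARModel],
    freq_range: tuple[float, float] = (2.0, 32.0),
    freq_step: float = 1.0,
) -> ConnectivityTensor:
    """direct Directed Transfer Function per window.

    ``dDTF_{i<-j}(f) = eta_{ij}(f) * chi_{ij}(f)`` where ``eta`` is the
    full-frequency-normalized DTF and ``chi`` the partial coherence.
    Evaluated on a 1 Hz grid over ``freq_range`` by default; one window
    per model.
    """
    if isinstance(models, MVARModel):
        models = [models]
    if not models:
        raise ValueError("no models given")
    fs = models[0].fs
    if freq_range[1] >= fs / 2 or freq_range[0] <= 0:
        raise ValueError(
            f"frequency range {freq_range} outside (0, {fs / 2}) Hz Nyquist interval"
        )
    freqs = np.arange(freq_range[0], freq_range[1] + 1e-9, freq_step)
    k = models[0].n_channels
    nw = len(models)
    vals = np.empty((k, k, len(freqs), nw))
    dtf_store = np.empty_like(vals)
    ff_store = np.empty_like(vals)
    pc_store = np.empty_like(vals)
    for w, model in enumerate(models):
        spec = transfer_function(model, freqs)
        eta2 = _ffdtf_sq(spec.H)  # (f, i, j): sink i, source j
        chi2 = partial_coherence(spec.S)
        g2 = dtf(spec.H)
        d = np.sqrt(eta2) * np.sqrt(chi2)  # (f, i, j)
        # reindex to (from j, to i, f)
        vals[:, :, :, w] = d.transpose(2, 1, 0)
        dtf_store[:, :, :, w] = g2.transpose(2, 1, 0)
        ff_store[:, :, :, w] = eta2.transpose(2, 1, 0)
        pc_store[:, :, :, w] = chi2.transpose(2, 1, 0)
    names = models[0].channel_names or [f"ch{i}" for i in range(k)]
    return ConnectivityTensor(
        vals,
        freqs,
        list(names),
        intermediates={"dtf": dtf_store, "ffdtf": ff_store, "pcoh": pc_store},
    )


def threshold_edges(
    tensor: ConnectivityTensor,
    percentile: float = 97.5,
    window: int | None = None,
) -> dict[float, list[tuple[str, str, float]]]:
    """Per-frequency edge thresholding.

    For each frequency, directed pairs whose dDTF *strictly* exceeds
    the given percentile of that frequency's off-diagonal values are
    retained.  Values are averaged over windows first unless a single
    ``window`` index is requested.  Ties at the cutoff drop out, so an
    all-equal slice yields no edges.  Deterministic.
    """
    v = tensor.values.mean(axis=3) if window is None else tensor.values[:, :, :, window]
    names = tensor.channel_names
    k = tensor.n_nodes
    off = ~np.eye(k, dtype=bool)
    out: dict[float, list[tuple[str, str, float]]] = {}
    for fi, f in enumerate(tensor.freqs):
        slice_ = v[:, :, fi]
        cutoff = np.percentile(slice_[off], percentile)
        kept = []
        for j in range(k):
            for i in range(k):
                if i != j and slice_[j, i] > cutoff:
                    kept.append((names[j], names[i], float(slice_[j, i])))
        out[float(f)] = sorted(kept, key=lambda e: -e[2])
    return out
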