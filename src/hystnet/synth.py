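"""Ground-truth source-level EEG synthesis.

A :class:`~hystnet.networks.GroundTruthNetwork` is realized as a stable
MVAR process: every node is an AR(2) resonator (default 10 Hz center
frequency, i.e. alpha-band oscillations within the 7-30 Hz range of
interest) and every directed edge becomes a nonzero off-diagonal
coefficient at its lag.  Sessions are simulated at 128 Hz in the fixed
L1 -> H2 -> L3 demand order, one generating network per condition, with
per-sample condition labels — so the "true" connectivity of every
sample is known and downstream inference can be scored by structure
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mvar import MVARModel
from .networks import Condition, GroundTruthNetwork, make_ground_truth_network
from .simulate import simulate_mvar
from .timeseries import SourceTimeSeries
from .validation import stability_index

__all__ = [
    "NodeDynamics",
    "network_to_mvar",
    "simulate_source_eeg",
    "make_session",
]


@dataclass(frozen=True)
class NodeDynamics:
    """Per-node AR(2) resonator specification.

    ``center_hz`` sets the spectral peak and ``radius`` (pole modulus,
    < 1) its sharpness; ``noise_var`` is the innovation variance.
    """

    center_hz: float = 10.0
    radius: float = 0.9
    noise_var: float = 1.0

    def ar2(self, fs: float) -> tuple[float, float]:
        theta = 2.0 * np.pi * self.center_hz / fs
        return 2.0 * self.radius * np.cos(theta), -(self.radius**2)


#: Default per-region oscillators: alpha-band peaks posteriorly, beta-band
#: peaks frontally, all inside the 7-30 Hz analysis band.  Distinct center
#: frequencies also keep the coupled system comfortably stable.
DEFAULT_DYNAMICS: dict[str, NodeDynamics] = {
    "VC": NodeDynamics(10.0, 0.88),
    "dACC": NodeDynamics(20.0, 0.88),
    "vACC": NodeDynamics(18.0, 0.88),
    "dPCC": NodeDynamics(11.0, 0.88),
    "PFC": NodeDynamics(22.0, 0.88),
    "PC": NodeDynamics(12.0, 0.88),
}


def network_to_mvar(
    net: GroundTruthNetwork,
    base_dynamics: dict[str, NodeDynamics] | NodeDynamics | None = None,
    fs: float = 128.0,
) -> MVARModel:
    """Realize a ground-truth network as a stable MVAR model.

    Off-diagonal coefficients are nonzero exactly on the network's
    edges, at the edges' lags; the innovation covariance is diagonal.
    If the requested couplings destabilize the model, an error names
    the strongest edge rather than silently rescaling.
    """
    names = net.node_names
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    if base_dynamics is None:
        dyn = {n: DEFAULT_DYNAMICS.get(n, NodeDynamics()) for n in names}
    elif isinstance(base_dynamics, NodeDynamics):
        dyn = {n: base_dynamics for n in names}
    else:
        dyn = dict(base_dynamics)
        missing = set(names) - set(dyn)
        if missing:
            raise ValueError(f"base_dynamics missing nodes: {sorted(missing)}")

    p = max([2] + [e.lag for e in net.edges])
    A = np.zeros((p, k, k))
    noise = np.zeros(k)
    for n in names:
        a1, a2 = dyn[n].ar2(fs)
        if dyn[n].radius >= 1.0:
            raise ValueError(f"node {n} oscillator pole radius must be < 1")
        i = idx[n]
        A[0, i, i] = a1
        A[1, i, i] = a2
        noise[i] = dyn[n].noise_var
    for e in net.edges:
        A[e.lag - 1, idx[e.target], idx[e.source]] = e.strength

    model = MVARModel(A, np.diag(noise), fs, channel_names=names)
    si = stability_index(model)
    if si >= 0:
        worst = max(net.edges, key=lambda e: abs(e.strength), default=None)
        detail = (
            f"; strongest edge {worst.source}->{worst.target} "
            f"(strength {worst.strength})"
            if worst is not None
            else ""
        )
        raise ValueError(
            f"requested couplings destabilize the model "
            f"(stability index {si:.4f} >= 0){detail}"
        )
    return model


def simulate_source_eeg(
    model: MVARModel,
    duration_s: float,
    fs: float = 128.0,
    n_trials: int = 1,
    seed: int | np.random.Generator = 0,
    condition: str | None = None,
) -> SourceTimeSeries:
    """Simulate source-level EEG from a (stable) generating MVAR model.

    The MVAR recursion is iterated with independent Gaussian
    innovations; a burn-in of ten times the model order is discarded.
    Bit-reproducible for a fixed integer seed.
    """
    n_samples = int(round(duration_s * fs))
    if n_samples <= 10 * model.order:
        raise ValueError(
            f"duration of {n_samples} samples too short for order "
            f"{model.order} (need > {10 * model.order})"
        )
    data = simulate_mvar(model, n_samples, n_trials, seed=seed)
    names = model.channel_names or [f"ch{i}" for i in range(model.n_channels)]
    labels = (
        np.full(n_samples, condition, dtype=object) if condition is not None else None
    )
    int_seed = seed if isinstance(seed, (int, np.integer)) else None
    return SourceTimeSeries(data, fs, list(names), labels, seed=int_seed)


def make_session(
    preset: str = "default",
    condition_minutes: float = 4.0,
    fs: float = 128.0,
    n_trials: int = 1,
    seed: int = 0,
    base_dynamics: dict[str, NodeDynamics] | NodeDynamics | None = None,
) -> SourceTimeSeries:
    """Simulate a full demand-schedule session (L1, then H2, then L3).

    Each 4-minute (by default) condition block is generated from its
    own condition network and labeled per sample; segment boundaries
    and the generating networks are recorded in ``meta``.
    """
    rng = np.random.default_rng(seed)
    segments = []
    labels = []
    boundaries = []
    nets = {}
    t0 = 0.0
    for cond in Condition:
        net = make_ground_truth_network(cond, preset)
        model = network_to_mvar(net, base_dynamics, fs=fs)
        seg_seed = int(rng.integers(0, 2**31 - 1))
        seg = simulate_source_eeg(
            model, condition_minutes * 60.0, fs, n_trials, seed=seg_seed, condition=cond.value
        )
        segments.append(seg.data)
        labels.append(seg.condition_labels)
        boundaries.append(
            {"condition": cond.value, "start_s": t0, "end_s": t0 + condition_minutes * 60.0}
        )
        nets[cond.value] = net.to_dict()
        t0 += condition_minutes * 60.0
    data = np.concatenate(segments, axis=1)
    cond_labels = np.concatenate(labels)
    names = make_ground_truth_network(Condition.L1, preset).node_names
    return SourceTimeSeries(
        data,
        fs,
        names,
        cond_labels,
        seed=seed,
        meta={"preset": preset, "boundaries": boundaries, "networks": nets},
    )
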