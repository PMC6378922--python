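"""Node- and edge-level summaries of a directed connectivity tensor.

For a band-averaged dDTF tensor the module computes, per node, total
information **outflow** and **inflow**, the **asymmetry ratio**
``(outflow - inflow) / (outflow + inflow)`` (+1 for a pure causal
source, -1 for a pure causal sink, 0 for balanced flow), and a
source/sink/balanced role; per directed edge, the **connectivity
magnitude** (absolute band-mean flow).  A condition contrast compares
the final low-demand block (L3) against the first (L1) to quantify the
hysteresis left behind by the intervening high-demand block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor

__all__ = [
    "NetworkMetricsReport",
    "node_flows",
    "asymmetry_ratio",
    "connectivity_magnitude",
    "compute_report",
    "condition_contrast",
]

#: Alpha + beta band used for band-averaged network summaries, Hz.
ALPHA_BETA = (7.0, 30.0)


@dataclass
class NetworkMetricsReport:
    """Per-node and per-edge summaries for one condition and band."""

    nodes: list[str]
    outflow: dict[str, float]
    inflow: dict[str, float]
    asymmetry: dict[str, float | None]
    role: dict[str, str]
    edge_magnitude: pd.DataFrame
    condition: str | None = None
    band: tuple[float, float] = ALPHA_BETA
    role_threshold: float = 0.5

    def hub(self) -> str:
        """Node with the largest outflow."""
        return max(self.nodes, key=lambda n: self.outflow[n])

    def top_outflow(self, n: int = 2) -> list[str]:
        return sorted(self.nodes, key=lambda m: -self.outflow[m])[:n]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "band": list(self.band),
            "nodes": {
                n: {
                    "outflow": self.outflow[n],
                    "inflow": self.inflow[n],
                    "asymmetry_ratio": self.asymmetry[n],
                    "role": self.role[n],
                }
                for n in self.nodes
            },
            "edges": self.edge_magnitude.to_dict(orient="records"),
        }

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "outflow": [self.outflow[n] for n in self.nodes],
                "inflow": [self.inflow[n] for n in self.nodes],
                "asymmetry_ratio": [self.asymmetry[n] for n in self.nodes],
                "role": [self.role[n] for n in self.nodes],
            }
        )


def node_flows(
    tensor: ConnectivityTensor, band: tuple[float, float] = ALPHA_BETA
) -> tuple[dict[str, float], dict[str, float]]:
    """Band-mean outflow and inflow per node.

    ``outflow(i) = sum_{j != i}`` band-mean flow i->j; ``inflow(i)`` the
    sum of flows entering i.
    """
    bm = tensor.band_mean(band)  # (from, to)
    names = tensor.channel_names
    k = len(names)
    off = ~np.eye(k, dtype=bool)
    outflow = {names[i]: float(bm[i, :][off[i]].sum()) for i in range(k)}
    inflow = {names[i]: float(bm[:, i][off[:, i]].sum()) for i in range(k)}
    return outflow, inflow


def asymmetry_ratio(outflow: float, inflow: float) -> float | None:
    """``(outflow - inflow) / (outflow + inflow)``; ``None`` if isolated.

    +1 marks a pure causal source, -1 a pure causal sink, 0 balanced.
    """
    if outflow < 0 or inflow < 0:
        raise ValueError("flows must be nonnegative")
    total = outflow + inflow
    if total == 0:
        return None
    return (outflow - inflow) / total


def connectivity_magnitude(
    tensor: ConnectivityTensor, band: tuple[float, float] = ALPHA_BETA
) -> pd.DataFrame:
    """Absolute band-mean flow per directed pair, sorted descending."""
    bm = tensor.band_mean(band)
    names = tensor.channel_names
    rows = [
        (names[j], names[i], float(abs(bm[j, i])))
        for j in range(len(names))
        for i in range(len(names))
        if i != j
    ]
    df = pd.DataFrame(rows, columns=["from_node", "to_node", "magnitude"])
    return df.sort_values("magnitude", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _role(ratio: float | None, threshold: float) -> str:
    if ratio is None:
        return "isolated"
    if ratio > threshold:
        return "source"
    if ratio < -threshold:
        return "sink"
    return "balanced"


def compute_report(
    tensor: ConnectivityTensor,
    band: tuple[float, float] = ALPHA_BETA,
    condition: str | None = None,
    role_threshold: float = 0.5,
) -> NetworkMetricsReport:
    """Full per-node/per-edge metrics report for one condition."""
    outflow, inflow = node_flows(tensor, band)
    names = tensor.channel_names
    asym = {n: asymmetry_ratio(outflow[n], inflow[n]) for n in names}
    role = {n: _role(asym[n], role_threshold) for n in names}
    return NetworkMetricsReport(
        nodes=list(names),
        outflow=outflow,
        inflow=inflow,
        asymmetry=asym,
        role=role,
        edge_magnitude=connectivity_magnitude(tensor, band),
        condition=condition,
        band=band,
        role_threshold=role_threshold,
    )


def condition_contrast(
    reports: dict[str, NetworkMetricsReport],
) -> dict:
    """Hysteresis summary: L3 vs L1 per-node deltas and role flips.

    Also emits a compact per-condition summary reporting, for each
    condition, the hub node's asymmetry ratio and outflow and the
    largest edge magnitude.
    """
    for key in ("L1", "L3"):
        if key not in reports:
            raise ValueError(f"contrast requires an {key} report")
    l1, l3 = reports["L1"], reports["L3"]
    if set(l1.nodes) != set(l3.nodes):
        raise ValueError("node sets differ between condition reports")
    deltas = {}
    flips = []
    for n in l1.nodes:
        a1, a3 = l1.asymmetry[n], l3.asymmetry[n]
        deltas[n] = {
            "d_asymmetry": None if a1 is None or a3 is None else a3 - a1,
            "d_outflow": l3.outflow[n] - l1.outflow[n],
        }
        if l1.role[n] != l3.role[n]:
            flips.append({"node": n, "from": l1.role[n], "to": l3.role[n]})
    summary = {}
    for cond, rep in reports.items():
        hub = rep.hub()
        top_edge = rep.edge_magnitude.iloc[0] if len(rep.edge_magnitude) else None
        summary[cond] = {
            "hub": hub,
            "asymmetry_ratio": rep.asymmetry[hub],
            "outflow": rep.outflow[hub],
            "connectivity_magnitude": None
            if top_edge is None
            else float(top_edge["magnitude"]),
        }
    return {"delta_l3_minus_l1": deltas, "role_changes": flips, "per_condition": summary}
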