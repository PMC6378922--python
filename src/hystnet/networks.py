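"""Cortical node definitions and ground-truth directed networks.

The simulated sources are a small set of cortical regions that a
source-localization study of multitasking EEG would typically recover:
visual cortex, anterior/posterior cingulate subdivisions, prefrontal
cortex and parietal cortex.  Each region carries its Brodmann-area label
and the cognitive-architecture module conventionally mapped onto it
(declarative memory onto dorsolateral/prefrontal cortex, goal
maintenance onto anterior cingulate, the imaginal/problem-state buffer
onto parietal cortex, vision onto occipital/fusiform areas).

A :class:`GroundTruthNetwork` is a directed graph over those nodes with
a coupling strength, an integer lag and a frequency band per edge.  It
is the object every downstream inference stage is tested against: the
generator realizes it as a stable MVAR process and the connectivity
pipeline is expected to recover its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Condition",
    "BrainNode",
    "Edge",
    "GroundTruthNetwork",
    "NODES",
    "make_ground_truth_network",
    "register_preset",
    "available_presets",
]


class Condition(str, Enum):
    """Task-demand blocks, always presented in the fixed order L1, H2, L3."""

    L1 = "L1"
    H2 = "H2"
    L3 = "L3"

    @classmethod
    def coerce(cls, value: "Condition | str") -> "Condition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown condition {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class BrainNode:
    """A cortical source region.

    Parameters
    ----------
    name
        Short region label (``VC``, ``dACC``, ``vACC``, ``dPCC``,
        ``PFC``, ``PC``).
    brodmann_area
        Brodmann-area number of the source.
    actr_module
        Cognitive-architecture module associated with the region, or
        ``"none"``.
    """

    name: str
    brodmann_area: int
    actr_module: str = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The canonical six-node source set with fixed Brodmann-area labels and
#: module assignments.
NODES: dict[str, BrainNode] = {
    "VC": BrainNode("VC", 17, "Visual"),
    "dACC": BrainNode("dACC", 32, "Goal"),
    "vACC": BrainNode("vACC", 24, "Goal"),
    "dPCC": BrainNode("dPCC", 31, "none"),
    "PFC": BrainNode("PFC", 10, "Declarative"),
    "PC": BrainNode("PC", 7, "Imaginal"),
}

#: Default oscillatory band of the simulated sources, Hz.
DEFAULT_BAND = (7.0, 30.0)


@dataclass(frozen=True)
class Edge:
    """Directed coupling ``source -> target`` with strength and lag."""

    source: str
    target: str
    strength: float
    lag: int = 2
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge {self.source}->{self.target} not allowed")
        if self.lag < 1:
            raise ValueError(f"edge lag must be >= 1, got {self.lag}")


@dataclass
class GroundTruthNetwork:
    """Known directed network for one task-demand condition."""

    nodes: list[BrainNode]
    edges: list[Edge]
    condition: Condition

    def __post_init__(self) -> None:
        names = {n.name for n in self.nodes}
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def out_degree(self, name: str) -> int:
        return sum(1 for e in self.edges if e.source == name)

    def in_degree(self, name: str) -> int:
        return sum(1 for e in self.edges if e.target == name)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "nodes": [
                {"name": n.name, "brodmann_area": n.brodmann_area, "actr_module": n.actr_module}
                for n in self.nodes
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "strength": e.strength,
                    "lag": e.lag,
                    "band": list(e.band),
                }
                for e in self.edges
            ],
        }


def _default_edges(condition: Condition) -> list[Edge]:
    # Condition-specific edge sets.  L1: visually driven flow into the
    # cingulate; H2: dACC/PFC act as hubs with parietal-cingulate
    # coupling; L3: PFC is a pure causal source (the carryover of the
    # preceding high-demand block).
    if condition is Condition.L1:
        return [
            Edge("VC", "vACC", 0.30),
            Edge("vACC", "dPCC", 0.25),
            Edge("VC", "dACC", 0.30),
        ]
    if condition is Condition.H2:
        return [
            Edge("dACC", "PFC", 0.28),
            Edge("dACC", "PC", 0.20),
            Edge("PC", "dACC", 0.10),
            Edge("PFC", "dACC", 0.15),
        ]
    return [
        Edge("PFC", "vACC", 0.35),
        Edge("PFC", "dACC", 0.30),
    ]


_PRESETS: dict[str, dict[Condition, list[Edge]]] = {
    "default": {c: _default_edges(c) for c in Condition},
    "empty": {c: [] for c in Condition},
}


def register_preset(name: str, edges_by_condition: dict[Condition | str, Iterable[Edge]]) -> None:
    """Register a user-defined network preset.

    ``edges_by_condition`` must provide an edge list for every
    condition.
    """
    table: dict[Condition, list[Edge]] = {}
    for cond in Condition:
        key = cond if cond in edges_by_condition else cond.value
        if key not in edges_by_condition:
            raise ValueError(f"preset {name!r} missing condition {cond.value}")
        table[cond] = list(edges_by_condition[key])
    _PRESETS[name] = table


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def make_ground_truth_network(
    condition: Condition | str, preset: str = "default"
) -> GroundTruthNetwork:
    """Return the known directed network for one condition.

    Parameters
    ----------
    condition
        ``"L1"``, ``"H2"`` or ``"L3"``.
    preset
        Name of a registered preset.  ``"default"`` encodes the
        condition-dependent six-node networks used throughout the test
        battery; ``"empty"`` is the disconnected control.
    """
    cond = Condition.coerce(condition)
    try:
        edges = _PRESETS[preset][cond]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {available_presets()}"
        ) from None
    return GroundTruthNetwork(nodes=list(NODES.values()), edges=list(edges), condition=cond)
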