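"""Edge latency budget model, device-to-node offloading, and alerting.

Latency is a *budget*, not a measurement: each pipeline stage carries a
configured (min, max) millisecond range and totals are pure arithmetic over
those ranges, so no wall-clock timing enters correctness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LatencyBudget",
    "DEFAULT_LATENCY_BUDGET",
    "EdgeTopology",
    "AlertDecision",
    "total_latency",
    "assign_offloading",
    "process_and_alert",
]

_COMPONENTS = (
    "sensing",
    "edge_transmission",
    "edge_processing",
    "inference",
    "game_decision",
    "alert_dispatch",
)


@dataclass(frozen=True)
class LatencyBudget:
    """Six per-stage delay ranges in milliseconds (min, max)."""

    sensing: tuple[float, float] = (5.0, 10.0)
    edge_transmission: tuple[float, float] = (1.0, 5.0)
    edge_processing: tuple[float, float] = (5.0, 8.0)
    inference: tuple[float, float] = (8.0, 12.0)
    game_decision: tuple[float, float] = (3.0, 6.0)
    alert_dispatch: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        for name in _COMPONENTS:
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"component {name}: need 0 <= min <= max, got ({lo}, {hi})")

    def components(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in _COMPONENTS}


#: Default budget: typical per-stage delay ranges for a 5G edge deployment.
DEFAULT_LATENCY_BUDGET = LatencyBudget()


def total_latency(
    budget: LatencyBudget,
    mode: str = "max",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Total end-to-end latency in ms.

    ``min``/``max`` sum the respective bounds; ``sample`` draws each
    component uniformly within its range (seeded) and sums.
    """
    ranges = list(budget.components().values())
    if mode == "min":
        return float(sum(lo for lo, _ in ranges))
    if mode == "max":
        return float(sum(hi for _, hi in ranges))
    if mode == "sample":
        if rng is None:
            rng = np.random.default_rng(seed)
        return float(sum(rng.uniform(lo, hi) for lo, hi in ranges))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EdgeTopology:
    """Edge nodes with capacities plus devices, on abstract 2-D coordinates."""

    node_positions: np.ndarray  # (n_nodes, 2)
    node_capacities: np.ndarray  # (n_nodes,) max concurrent devices
    device_positions: np.ndarray  # (n_devices, 2)
    device_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_positions = np.atleast_2d(np.asarray(self.node_positions, dtype=float))
        self.device_positions = np.atleast_2d(np.asarray(self.device_positions, dtype=float))
        self.node_capacities = np.asarray(self.node_capacities, dtype=int)
        if len(self.node_positions) < 1:
            raise ValueError("need at least one edge node")
        if np.any(self.node_capacities < 0):
            raise ValueError("capacities must be nonnegative")
        if len(self.node_capacities) != len(self.node_positions):
            raise ValueError("capacities and node positions disagree")
        if not self.device_ids:
            self.device_ids = [f"D{i}" for i in range(len(self.device_positions))]

    @property
    def distances(self) -> np.ndarray:
        """(n_devices, n_nodes) Euclidean distance matrix."""
        diff = self.device_positions[:, None, :] - self.node_positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def assign_offloading(topology: EdgeTopology, policy: str = "nearest") -> np.ndarray:
    """Map each device to an edge node; returns an array of node indices.

    ``nearest`` ignores capacities; ``capacity_aware`` minimizes the total
    device-node distance subject to per-node capacity (optimal assignment via
    the Hungarian algorithm on capacity-expanded node slots).
    """
    d = topology.distances
    if policy == "nearest":
        return d.argmin(axis=1)
    if policy == "capacity_aware":
        n_dev = d.shape[0]
        if topology.node_capacities.sum() < n_dev:
            raise ValueError(
                f"total capacity {int(topology.node_capacities.sum())} < {n_dev} devices"
            )
        slot_owner = np.repeat(np.arange(len(topology.node_capacities)), topology.node_capacities)
        cost = d[:, slot_owner]
        rows, cols = linear_sum_assignment(cost)
        mapping = np.empty(n_dev, dtype=int)
        mapping[rows] = slot_owner[cols]
        return mapping
    raise ValueError(f"unknown policy {policy!r}")


@dataclass
class AlertDecision:
    device_id: str
    risk_score: float
    threshold: float
    alert: bool
    end_to_end_ms: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def process_and_alert(
    scores: dict[str, float],
    threshold: float,
    budget: LatencyBudget = DEFAULT_LATENCY_BUDGET,
    mode: str = "max",
    seed: int | None = None,
) -> list[AlertDecision]:
    """Turn per-device risk scores into alert decisions with latency stamps.

    An alert fires iff ``score > threshold`` (strict: a tie does not alert).
    Each decision carries a total latency drawn per the chosen mode.
    """
    rng = np.random.default_rng(seed)
    decisions = []
    for device_id, score in scores.items():
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"device {device_id}: score {score} outside [0, 1]")
        ms = total_latency(budget, mode=mode, rng=rng if mode == "sample" else None)
        decisions.append(
            AlertDecision(
                device_id=device_id,
                risk_score=float(score),
                threshold=float(threshold),
                alert=bool(score > threshold),
                end_to_end_ms=ms,
            )
        )
    return decisions
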