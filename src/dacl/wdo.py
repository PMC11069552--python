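"""Intelligent-water-drops graph optimization and hyperparameter tuning.

Drops travel from a source to a sink over a directed graph, preferring edges
with little "soil".  Traversing an edge speeds a drop up by
``p_u / (q_u + o_u * soil^2)``, erodes the edge by
``soil <- (1 - g_y) * soil - g_y * dsoil`` with
``dsoil = p_u / (q_u + o_u * time^2)`` and time = cost / velocity, and the
iteration's best path is reinforced by ``soil <- (1 + g_m) * soil``.  Because
erosion drives well-travelled soils negative and the fitness used for edge
choice decreases with soil, the reinforcement amplifies negative (attractive)
soil — the multiplicative update is kept in that literal form; the classical
variant that subtracts the drop's carried soil is available behind
``classic_global_update``.

The tuner builds a layered graph — one layer per hyperparameter, one node
per candidate value, full bipartite links between consecutive layers — so a
source-to-sink path picks one value per grid, and path quality is the cached
validation score of that configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import networkx as nx
import numpy as np

__all__ = ["IWDConfig", "IWDGraph", "WaterDrop", "IWDResult",
           "init_soil", "transition_probability", "update_velocity",
           "soil_delta", "local_soil_update", "iteration_best_path",
           "global_soil_reinforce", "iwd_optimize", "tune_loss_parameter",
           "enumerate_paths"]


@dataclass(frozen=True)
class IWDConfig:
    n_drops: int = 20
    max_iterations: int = 50
    p_u: float = 1.0
    q_u: float = 0.01
    o_u: float = 1.0
    initial_soil: float = 1.0
    initial_velocity: float = 4.0
    local_soil_rate: float = 0.9      # g_y
    global_soil_rate: float = 0.9     # g_m
    epsilon_prob: float = 0.5
    velocity_floor: float = 1e-6
    classic_global_update: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.q_u <= 0:
            raise ValueError("q_u must be positive")
        if not 0.0 < self.local_soil_rate < 1.0:
            raise ValueError("local_soil_rate must lie in (0, 1)")


class IWDGraph:
    """Directed graph with per-edge cost and soil, plus source and sink."""

    def __init__(self, edges: Sequence[tuple[Hashable, Hashable, float]],
                 source: Hashable, sink: Hashable):
        self.g = nx.DiGraph()
        for i, j, cost in edges:
            if cost <= 0:
                raise ValueError(f"edge ({i}, {j}) has non-positive cost {cost}")
            self.g.add_edge(i, j, cost=float(cost), soil=0.0)
        self.source, self.sink = source, sink
        if source not in self.g or sink not in self.g \
                or not nx.has_path(self.g, source, sink):
            raise ValueError("sink must be reachable from source")

    def soil(self, i, j) -> float:
        return self.g.edges[i, j]["soil"]

    def set_soil(self, i, j, value: float) -> None:
        self.g.edges[i, j]["soil"] = float(value)

    def cost(self, i, j) -> float:
        return self.g.edges[i, j]["cost"]

    def successors(self, i):
        return list(self.g.successors(i))

    def path_cost(self, path: Sequence) -> float:
        return sum(self.cost(i, j) for i, j in zip(path, path[1:]))


@dataclass
class WaterDrop:
    node: Hashable
    velocity: float
    soil: float = 0.0
    visited: list = field(default_factory=list)

    def __post_init__(self):
        if not self.visited:
            self.visited = [self.node]


@dataclass
class IWDResult:
    best_path: list
    best_quality: float
    history: list[float]          # running best quality per iteration


def init_soil(graph: IWDGraph, config: IWDConfig) -> IWDGraph:
    for i, j in graph.g.edges:
        graph.set_soil(i, j, config.initial_soil)
    return graph


def transition_probability(drop: WaterDrop, candidates: Sequence,
                           graph: IWDGraph, config: IWDConfig) -> np.ndarray:
    """Edge-choice distribution over unvisited neighbors, 1/(eps + soil)-shaped.

    Soils are shifted by the candidate minimum when that minimum is negative,
    keeping every fitness argument non-negative once erosion has driven soils
    below zero.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set (dead end)")
    soils = np.array([graph.soil(drop.node, c) for c in candidates])
    mn = soils.min()
    shifted = soils - mn if mn < 0 else soils
    fit = 1.0 / (config.epsilon_prob + shifted)
    return fit / fit.sum()


def update_velocity(drop: WaterDrop, edge: tuple, graph: IWDGraph,
                    config: IWDConfig) -> float:
    soil = graph.soil(*edge)
    return drop.velocity + config.p_u / (config.q_u + config.o_u * soil * soil)


def soil_delta(edge: tuple, velocity: float, graph: IWDGraph,
               config: IWDConfig) -> float:
    t = graph.cost(*edge) / max(velocity, config.velocity_floor)
    return config.p_u / (config.q_u + config.o_u * t * t)


def local_soil_update(edge: tuple, dsoil: float, graph: IWDGraph,
                      config: IWDConfig, drop: WaterDrop | None = None) -> float:
    g_y = config.local_soil_rate
    new = (1.0 - g_y) * graph.soil(*edge) - g_y * dsoil
    graph.set_soil(*edge, new)
    if drop is not None:
        drop.soil += dsoil
    return new


def iteration_best_path(paths: Sequence[Sequence],
                        quality: Callable[[Sequence], float]) -> list:
    """Arg-max of quality over completed paths; cost ties broken by
    lexicographically smaller node sequence."""
    if not paths:
        raise ValueError("no completed paths")
    keyed = sorted(paths, key=lambda p: [str(x) for x in p])
    best = max(keyed, key=quality)
    return list(best)


def global_soil_reinforce(path: Sequence, graph: IWDGraph, config: IWDConfig,
                          carried_soil: float = 0.0) -> IWDGraph:
    g_m = config.global_soil_rate
    n_edges = max(len(path) - 1, 1)
    for i, j in zip(path, path[1:]):
        if config.classic_global_update:
            new = (1.0 + g_m) * graph.soil(i, j) \
                - g_m * carried_soil / n_edges
        else:
            new = (1.0 + g_m) * graph.soil(i, j)
        graph.set_soil(i, j, new)
    return graph


def _walk(graph: IWDGraph, config: IWDConfig,
          rng: np.random.Generator) -> WaterDrop | None:
    """Send one drop from source toward sink; None if it dead-ends."""
    drop = WaterDrop(graph.source, config.initial_velocity)
    visited = {graph.source}
    while drop.node != graph.sink:
        candidates = [c for c in graph.successors(drop.node) if c not in visited]
        if not candidates:
            return None
        probs = transition_probability(drop, candidates, graph, config)
        nxt = candidates[rng.choice(len(candidates), p=probs)]
        edge = (drop.node, nxt)
        drop.velocity = update_velocity(drop, edge, graph, config)
        dsoil = soil_delta(edge, drop.velocity, graph, config)
        local_soil_update(edge, dsoil, graph, config, drop)
        drop.node = nxt
        drop.visited.append(nxt)
        visited.add(nxt)
    return drop


def iwd_optimize(graph: IWDGraph, config: IWDConfig,
                 quality: Callable[[Sequence], float] | None = None) -> IWDResult:
    """Run the full drop/erode/reinforce loop; deterministic per seed.

    ``quality`` defaults to 1 / total path cost (shorter is better).
    """
    if quality is None:
        quality = lambda p: 1.0 / graph.path_cost(p)
    rng = np.random.default_rng(config.seed)
    init_soil(graph, config)
    best_path: list | None = None
    best_q = -np.inf
    history: list[float] = []
    for _ in range(config.max_iterations):
        completed: list[WaterDrop] = []
        for _ in range(config.n_drops):
            drop = _walk(graph, config, rng)
            if drop is not None:
                completed.append(drop)
        if completed:
            paths = [d.visited for d in completed]
            it_best = iteration_best_path(paths, quality)
            it_q = quality(it_best)
            carried = next(d.soil for d in completed if d.visited == it_best)
            global_soil_reinforce(it_best, graph, config, carried_soil=carried)
            if it_q > best_q:
                best_q, best_path = it_q, it_best
        history.append(best_q)
    if best_path is None:
        raise RuntimeError("no drop ever reached the sink")
    return IWDResult(best_path, best_q, history)


def enumerate_paths(graph: IWDGraph) -> list[list]:
    """All simple source-to-sink paths (the oracle for small graphs)."""
    return [list(p) for p in nx.all_simple_paths(graph.g, graph.source, graph.sink)]


def tune_loss_parameter(candidate_grids: dict[str, Sequence],
                        evaluate: Callable[[dict], float],
                        config: IWDConfig | None = None) -> tuple[dict, float]:
    """Pick one value per grid by water-drop search over a layered graph.

    Each hyperparameter becomes a layer of nodes (one per candidate value);
    consecutive layers are fully connected, so each source-to-sink path is a
    configuration.  Path quality is ``evaluate`` on that configuration,
    cached so each configuration is scored at most once.  Returns
    (best configuration dict, its score); higher scores are better.
    """
    if not candidate_grids or any(len(v) == 0 for v in candidate_grids.values()):
        raise ValueError("every candidate grid must be non-empty")
    config = config or IWDConfig()
    names = list(candidate_grids)
    edges: list[tuple] = []
    prev = ["source"]
    for li, name in enumerate(names):
        layer = [("node", li, vi) for vi in range(len(candidate_grids[name]))]
        for a in prev:
            for b in layer:
                edges.append((a, b, 1.0))
        prev = layer
    for a in prev:
        edges.append((a, "sink", 1.0))
    graph = IWDGraph(edges, "source", "sink")

    cache: dict[tuple, float] = {}

    def path_config(path) -> dict:
        cfg = {}
        for node in path[1:-1]:
            _, li, vi = node
            cfg[names[li]] = candidate_grids[names[li]][vi]
        return cfg

    def quality(path) -> float:
        key = tuple(path[1:-1])
        if key not in cache:
            try:
                cache[key] = float(evaluate(path_config(path)))
            except Exception:
                cache[key] = -np.inf
        return cache[key]

    result = iwd_optimize(graph, config, quality)
    return path_config(result.best_path), result.best_quality
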