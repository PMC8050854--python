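"""Multiplex modularity and a shared-partition Louvain optimizer.

The quality function is the sum over layers of Newman-Girvan modularities
evaluated under one partition common to all layers, with the resolution
parameter gamma multiplying the null term identically in every layer:

    Q(c; gamma) = sum_s (1/(2 m_s)) sum_{i,j} [A^(s)_ij
                  - gamma * k^(s)_i k^(s)_j / (2 m_s)] * delta(c_i, c_j)

where m_s is layer s's total edge weight and k^(s) its (weighted) degree
vector; nodes absent from a layer have degree 0 there and contribute nothing
to its terms.  Layers are summed, not averaged: a 1/L rescaling would not
change the optima.  Sweeping gamma over a grid exposes multiscale community
structure — larger gamma favours more, smaller communities.

The optimizer is a Louvain-style greedy heuristic: repeated local-move
passes over a seeded random node order, each node joining the neighbouring
community with maximal positive modularity gain (ties broken by smallest
community id), followed by graph aggregation applied to every layer with the
same super-nodes, until no move improves Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json
import numpy as np

from .core import MultiplexNetwork, MultitrajError, ValidationError

__all__ = [
    "Partition",
    "ResolutionProfile",
    "multiplex_modularity",
    "louvain_multiplex",
    "resolution_sweep",
    "enumerate_partitions",
    "exhaustive_max_modularity",
    "write_partition",
    "write_profile",
    "load_profile",
]

#: move-acceptance threshold: a local move must improve Q by more than this
TOLERANCE = 1e-12

#: default resolution grid gamma = 1..50
DEFAULT_GRID = tuple(float(g) for g in range(1, 51))


@dataclass
class Partition:
    """A node -> community assignment at one resolution.

    ``history`` records the modularity after each local-move pass of the
    optimizer (non-decreasing by construction); it is empty for partitions
    built directly from an assignment.
    """

    assignment: dict[str, int]
    resolution: float
    quality: float
    history: list[float] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def canonicalize(self, node_order: Sequence[str]) -> "Partition":
        """Renumber communities 0,1,2,... by first appearance in node order."""
        remap: dict[int, int] = {}
        new: dict[str, int] = {}
        for node in node_order:
            c = self.assignment[node]
            if c not in remap:
                remap[c] = len(remap)
            new[node] = remap[c]
        return Partition(new, self.resolution, self.quality, list(self.history))

    def communities(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return {c: frozenset(m) for c, m in out.items()}


@dataclass
class ResolutionProfile:
    """One canonical partition per point of a strictly increasing gamma grid."""

    grid: tuple[float, ...]
    partitions: list[Partition]
    seed: int

    def __post_init__(self) -> None:
        if len(self.partitions) != len(self.grid):
            raise ValidationError("profile grid and partition list lengths differ")

    @property
    def n_resolutions(self) -> int:
        return len(self.grid)


def _layer_arrays(net: MultiplexNetwork, weighted: bool) -> list[dict]:
    """Index nodes and build per-layer edge arrays used by Q and Louvain."""
    index = {n: i for i, n in enumerate(net.nodes)}
    n = len(net.nodes)
    layers = []
    for name in net.layer_names:
        edges = net.layers[name]
        if not edges:
            raise ValidationError(f"layer {name!r} has no edges; 1/(2m) is undefined")
        adj: list[dict[int, float]] = [dict() for _ in range(n)]
        k = np.zeros(n)
        m = 0.0
        for (u, v), (w, _ann) in edges.items():
            wt = w if weighted else 1.0
            i, j = index[u], index[v]
            adj[i][j] = adj[i].get(j, 0.0) + wt
            adj[j][i] = adj[j].get(i, 0.0) + wt
            k[i] += wt
            k[j] += wt
            m += wt
        layers.append({"adj": adj, "k": k, "m": m})
    return layers


def multiplex_modularity(
    net: MultiplexNetwork,
    assignment: Mapping[str, int],
    gamma: float,
    weighted: bool = False,
) -> float:
    """Evaluate the multiplex modularity of ``assignment`` at resolution gamma.

    gamma = 0 is allowed (null term vanishes; useful for testing).  Raises if
    any node lacks an assignment or any layer has zero edges.
    """
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    missing = [n for n in net.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"assignment misses {len(missing)} node(s), e.g. {missing[0]!r}")
    index = {n: i for i, n in enumerate(net.nodes)}
    comm = np.array([assignment[n] for n in net.nodes])
    q = 0.0
    for name in net.layer_names:
        edges = net.layers[name]
        if not edges:
            raise ValidationError(f"layer {name!r} has no edges; 1/(2m) is undefined")
        k = np.zeros(len(net.nodes))
        m = 0.0
        within = 0.0
        for (u, v), (w, _ann) in edges.items():
            wt = w if weighted else 1.0
            i, j = index[u], index[v]
            k[i] += wt
            k[j] += wt
            m += wt
            if comm[i] == comm[j]:
                within += wt
        ktot: dict[int, float] = {}
        for i, c in enumerate(comm):
            ktot[c] = ktot.get(c, 0.0) + k[i]
        null = sum(kc * kc for kc in ktot.values()) / (4.0 * m * m)
        q += within / m - gamma * null
    return float(q)


def _level_modularity(layers: list[dict], comm: list[int], gamma: float) -> float:
    """Q of the current (possibly aggregated) level; loops count once as A_ii."""
    q = 0.0
    for lay in layers:
        adj, k, m = lay["adj"], lay["k"], lay["m"]
        within2 = 0.0  # sum_ij A_ij delta, loops counted once
        for i, nbrs in enumerate(adj):
            ci = comm[i]
            for j, w in nbrs.items():
                if comm[j] == ci:
                    within2 += w
        ktot: dict[int, float] = {}
        for i, c in enumerate(comm):
            ktot[c] = ktot.get(c, 0.0) + k[i]
        null = sum(kc * kc for kc in ktot.values()) / (4.0 * m * m)
        q += within2 / (2.0 * m) - gamma * null
    return q


def _local_moves(layers: list[dict], gamma: float, rng: np.random.Generator) -> tuple[list[int], list[float], bool]:
    """Louvain phase 1 on one level; returns (assignment, Q-per-pass, moved?)."""
    n = len(layers[0]["adj"])
    L = len(layers)
    comm = list(range(n))
    ktot = [lay["k"].copy() for lay in layers]  # per-layer community degree totals
    inv_m = [1.0 / lay["m"] for lay in layers]
    history: list[float] = []
    any_move = False
    while True:
        moved = 0
        for i in rng.permutation(n):
            ci = comm[i]
            # weights to neighbouring communities, per layer (self-loops excluded)
            nbr_w: dict[int, list[float]] = {}
            for s in range(L):
                for j, w in layers[s]["adj"][i].items():
                    if j == i:
                        continue
                    nbr_w.setdefault(comm[j], [0.0] * L)[s] += w
            # detach i from its community
            for s in range(L):
                ktot[s][ci] -= layers[s]["k"][i]
            nbr_w.setdefault(ci, [0.0] * L)

            def gain(c: int) -> float:
                ws = nbr_w[c]
                g = 0.0
                for s in range(L):
                    g += ws[s] * inv_m[s] - gamma * layers[s]["k"][i] * ktot[s][c] * (0.5 * inv_m[s] * inv_m[s])
                return g

            stay = gain(ci)
            best_c, best_g = ci, stay
            for c in sorted(nbr_w):
                if c == ci:
                    continue
                g = gain(c)
                # strict improvement; iterating in increasing id order makes
                # ties resolve to the smallest community id
                if g > best_g + TOLERANCE:
                    best_c, best_g = c, g
            comm[i] = best_c
            for s in range(L):
                ktot[s][best_c] += layers[s]["k"][i]
            if best_c != ci:
                moved += 1
        history.append(_level_modularity(layers, comm, gamma))
        if moved == 0:
            break
        any_move = True
    return comm, history, any_move


def _aggregate(layers: list[dict], comm: list[int]) -> tuple[list[dict], list[int]]:
    """Louvain phase 2: contract communities into super-nodes in every layer."""
    remap: dict[int, int] = {}
    for c in comm:
        if c not in remap:
            remap[c] = len(remap)
    new_comm = [remap[c] for c in comm]
    nc = len(remap)
    new_layers = []
    for lay in layers:
        adj: list[dict[int, float]] = [dict() for _ in range(nc)]
        for i, nbrs in enumerate(lay["adj"]):
            ci = new_comm[i]
            for j, w in nbrs.items():
                if j < i:
                    continue  # each undirected pair (and each loop) once
                cj = new_comm[j]
                if i == j:
                    adj[ci][ci] = adj[ci].get(ci, 0.0) + w  # existing loop, already 2x internal
                elif ci == cj:
                    adj[ci][ci] = adj[ci].get(ci, 0.0) + 2.0 * w
                else:
                    adj[ci][cj] = adj[ci].get(cj, 0.0) + w
                    adj[cj][ci] = adj[cj].get(ci, 0.0) + w
        k = np.array([sum(nbrs.values()) for nbrs in adj])
        new_layers.append({"adj": adj, "k": k, "m": lay["m"]})
    return new_layers, new_comm


def louvain_multiplex(
    net: MultiplexNetwork,
    gamma: float,
    seed: int,
    weighted: bool = False,
) -> Partition:
    """Greedy multiplex-modularity maximization at one resolution.

    Deterministic given ``seed`` (which shuffles the node visit order).  The
    returned partition's ``quality`` is recomputed with
    :func:`multiplex_modularity` on the original network, and ``history``
    holds Q after each local-move pass across all levels (non-decreasing).
    """
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    if not net.nodes:
        raise ValidationError("empty network")
    rng = np.random.default_rng(seed)
    layers = _layer_arrays(net, weighted)
    node_to_top = list(range(len(net.nodes)))  # original node -> current level node
    history: list[float] = []
    while True:
        n_level = len(layers[0]["adj"])
        comm, level_hist, moved = _local_moves(layers, gamma, rng)
        history.extend(level_hist)
        if not moved:
            break
        layers, new_comm = _aggregate(layers, comm)
        node_to_top = [new_comm[t] for t in node_to_top]
        if len(layers[0]["adj"]) >= n_level:  # no contraction: nothing left to gain
            break
    assignment = {node: int(node_to_top[i]) for i, node in enumerate(net.nodes)}
    quality = multiplex_modularity(net, assignment, gamma, weighted=weighted)
    part = Partition(assignment, float(gamma), quality, history)
    return part.canonicalize(net.nodes)


def resolution_sweep(
    net: MultiplexNetwork,
    grid: Sequence[float] = DEFAULT_GRID,
    seed: int = 0,
    weighted: bool = False,
) -> ResolutionProfile:
    """Run :func:`louvain_multiplex` at every gamma of a strictly increasing grid.

    The run at grid index t uses seed ``seed + t``; partitions are
    canonicalized (communities renumbered by first-node appearance).
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValidationError("empty resolution grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("resolution grid must be strictly increasing")
    if grid[0] < 0:
        raise ValidationError("resolutions must be >= 0")
    parts = [louvain_multiplex(net, g, seed + t, weighted=weighted) for t, g in enumerate(grid)]
    return ResolutionProfile(grid, parts, seed)


# ---------------------------------------------------------------------------
# brute-force oracle (practical only for tiny graphs)
# ---------------------------------------------------------------------------

def enumerate_partitions(items: Sequence[str]) -> Iterable[dict[str, int]]:
    """Yield every set partition of ``items`` as an assignment mapping.

    Grows as the Bell numbers (203 for 6 items, 4140 for 8); intended as an
    exhaustive oracle on tiny graphs only.
    """
    items = list(items)

    def rec(idx: int, blocks: list[list[str]]):
        if idx == len(items):
            yield {x: b for b, block in enumerate(blocks) for x in block}
            return
        x = items[idx]
        for block in blocks:
            block.append(x)
            yield from rec(idx + 1, blocks)
            block.pop()
        blocks.append([x])
        yield from rec(idx + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def exhaustive_max_modularity(
    net: MultiplexNetwork, gamma: float, weighted: bool = False
) -> tuple[float, dict[str, int]]:
    """Exact maximum multiplex modularity by enumerating all set partitions."""
    best_q, best_a = -np.inf, None
    for assignment in enumerate_partitions(net.nodes):
        q = multiplex_modularity(net, assignment, gamma, weighted=weighted)
        if q > best_q:
            best_q, best_a = q, dict(assignment)
    return best_q, best_a


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_partition(part: Partition, tsv_path: str | Path, sidecar_path: str | Path | None = None, seed: int | None = None) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("node\tcommunity\n")
        for node, c in part.assignment.items():
            fh.write(f"{node}\t{c}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump({"gamma": part.resolution, "Q": part.quality, "seed": seed}, fh, indent=2)


def write_profile(profile: ResolutionProfile, path: str | Path) -> None:
    """Write the genes x gamma community-label table consumed downstream."""
    nodes = list(profile.partitions[0].assignment)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(f"{g:g}" for g in profile.grid) + "\n")
        for node in nodes:
            labels = "\t".join(str(p.assignment[node]) for p in profile.partitions)
            fh.write(f"{node}\t{labels}\n")


def load_profile(path: str | Path, seed: int = -1) -> ResolutionProfile:
    """Read a genes x gamma label table back into a profile (Q unset)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        grid = tuple(float(g) for g in header[1:])
        assignments: list[dict[str, int]] = [dict() for _ in grid]
        for raw in fh:
            cols = raw.rstrip("\n").split("\t")
            if not cols or not cols[0]:
                continue
            for t, lab in enumerate(cols[1:]):
                assignments[t][cols[0]] = int(lab)
    parts = [Partition(a, g, float("nan")) for a, g in zip(assignments, grid)]
    return ResolutionProfile(grid, parts, seed)
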