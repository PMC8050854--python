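"""Per-gene community trajectories across a resolution sweep.

A gene's trajectory is the ordered sequence of communities it belongs to as
the modularity resolution increases.  Two genes are compared position-wise:
they differ at grid point t iff they sit in different communities there
(co-membership comparison, invariant to any per-column relabelling of
community ids).  The count of differing positions is the Hamming trajectory
distance dH, an integer in [0, T] for a grid of length T; genes with dH = 0
never separate anywhere along the sweep.

Communities themselves can be tracked along the grid as dynamic objects,
identified by their exact member set: a community is *born* when its member
set first appears, *dies* when it vanishes, and *resurges* when the very
same member set reappears later.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .core import ValidationError
from .community import ResolutionProfile

__all__ = [
    "TrajectoryMatrix",
    "TrajectoryDistanceMatrix",
    "CommunityEventLog",
    "build_trajectories",
    "trajectory_hamming",
    "trajectory_distance_matrix",
    "community_events",
    "trajectory_dendrogram",
    "linkage_to_newick",
    "write_trajectories",
    "load_trajectories",
    "write_distance_matrix",
    "write_event_log",
]


@dataclass
class TrajectoryMatrix:
    """genes x resolutions matrix of canonical community labels."""

    genes: list[str]
    grid: tuple[float, ...]
    labels: np.ndarray  # int array, shape (n_genes, n_resolutions)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.genes), len(self.grid)):
            raise ValidationError("trajectory matrix shape does not match genes x grid")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.labels[self._index[gene]]

    def subset_indices(self, genes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in genes], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"unknown gene {exc.args[0]!r}") from None


@dataclass
class TrajectoryDistanceMatrix:
    """Symmetric pairwise Hamming distances between gene trajectories."""

    genes: list[str]
    values: np.ndarray  # shape (n, n), integer counts (float if normalized)
    grid_length: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match gene list")

    def condensed(self) -> np.ndarray:
        return squareform(self.values.astype(float), checks=False)


@dataclass
class CommunityEventLog:
    """Birth/death/resurgence accounting for exact-member-set communities.

    ``intervals`` maps each unique community (sorted member tuple) to the
    list of maximal runs of consecutive grid indices where it is present.
    With k presence intervals, a community has k births and k - 1
    resurgences; it has k deaths if absent at the final grid point, else
    k - 1 (a terminal death is only counted when ``terminal_death`` is set).
    """

    intervals: dict[tuple[str, ...], list[tuple[int, int]]]
    grid_length: int
    terminal_death: bool = False

    @property
    def n_communities(self) -> int:
        return len(self.intervals)

    def per_community(self) -> dict[tuple[str, ...], dict[str, int]]:
        out = {}
        for members, runs in self.intervals.items():
            k = len(runs)
            alive_at_end = runs[-1][1] == self.grid_length - 1
            deaths = k if (self.terminal_death or not alive_at_end) else k - 1
            out[members] = {"births": k, "deaths": deaths, "resurgences": k - 1}
        return out

    def totals(self) -> dict[str, int]:
        per = self.per_community()
        return {
            "communities": len(per),
            "births": sum(v["births"] for v in per.values()),
            "deaths": sum(v["deaths"] for v in per.values()),
            "resurgences": sum(v["resurgences"] for v in per.values()),
        }


def build_trajectories(profile: ResolutionProfile) -> TrajectoryMatrix:
    """Stack a profile's canonical partitions into a genes x gamma label matrix."""
    if not profile.partitions:
        raise ValidationError("empty resolution profile")
    genes = list(profile.partitions[0].assignment)
    labels = np.empty((len(genes), len(profile.grid)), dtype=np.int64)
    for t, part in enumerate(profile.partitions):
        labels[:, t] = [part.assignment[g] for g in genes]
    return TrajectoryMatrix(genes, tuple(profile.grid), labels)


def trajectory_hamming(traj_a: Sequence[int], traj_b: Sequence[int]) -> int:
    """Number of grid positions at which two genes are in different communities."""
    a = np.asarray(traj_a)
    b = np.asarray(traj_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("trajectories must be 1-D and of equal length")
    return int(np.count_nonzero(a != b))


def trajectory_distance_matrix(
    traj: TrajectoryMatrix,
    subset: Sequence[str] | None = None,
    normalized: bool = False,
    chunk: int = 256,
) -> TrajectoryDistanceMatrix:
    """All pairwise Hamming distances, optionally on a gene subset.

    Computed in row chunks to bound memory on large gene lists.  With
    ``normalized`` the counts are divided by the grid length T.
    """
    genes = list(traj.genes) if subset is None else list(subset)
    idx = traj.subset_indices(genes)
    lab = traj.labels[idx]
    n, T = lab.shape
    out = np.zeros((n, n), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = lab[start:stop]  # (b, T)
        out[start:stop] = (block[:, None, :] != lab[None, :, :]).sum(axis=2)
    values: np.ndarray = out
    if normalized:
        values = out / float(T)
    return TrajectoryDistanceMatrix(genes, values, T, normalized)


def community_events(profile: ResolutionProfile, terminal_death: bool = False) -> CommunityEventLog:
    """Track exact-member-set communities along the grid and log their events."""
    if not profile.partitions:
        raise ValidationError("empty resolution profile")
    presence: dict[tuple[str, ...], list[int]] = {}
    for t, part in enumerate(profile.partitions):
        for members in part.communities().values():
            presence.setdefault(tuple(sorted(members)), []).append(t)
    intervals: dict[tuple[str, ...], list[tuple[int, int]]] = {}
    for members, steps in presence.items():
        runs: list[tuple[int, int]] = []
        start = prev = steps[0]
        for t in steps[1:]:
            if t == prev + 1:
                prev = t
            else:
                runs.append((start, prev))
                start = prev = t
        runs.append((start, prev))
        intervals[members] = runs
    return CommunityEventLog(intervals, profile.n_resolutions, terminal_death)


def trajectory_dendrogram(
    dist: TrajectoryDistanceMatrix, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate genes on their trajectory distances.

    Returns the scipy linkage matrix and the leaf order (gene names).  The
    default linkage is average (UPGMA); the computation is deterministic for
    a fixed input order.
    """
    if len(dist.genes) < 2:
        raise ValidationError("dendrogram requires at least 2 genes")
    z = linkage(dist.condensed(), method=method)
    from scipy.cluster.hierarchy import leaves_list

    order = [dist.genes[i] for i in leaves_list(z)]
    return z, order


def linkage_to_newick(z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix to a newick string."""
    tree = TreeNode.from_linkage_matrix(z, list(leaf_names))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_trajectories(traj: TrajectoryMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(f"{g:g}" for g in traj.grid) + "\n")
        for i, gene in enumerate(traj.genes):
            fh.write(gene + "\t" + "\t".join(str(int(x)) for x in traj.labels[i]) + "\n")


def load_trajectories(path: str | Path) -> TrajectoryMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        grid = tuple(float(g) for g in header[1:])
        genes: list[str] = []
        rows: list[list[int]] = []
        for raw in fh:
            cols = raw.rstrip("\n").split("\t")
            if not cols or not cols[0]:
                continue
            genes.append(cols[0])
            rows.append([int(x) for x in cols[1:]])
    return TrajectoryMatrix(genes, grid, np.array(rows, dtype=np.int64))


def write_distance_matrix(dist: TrajectoryDistanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(dist.genes) + "\n")
        for i, gene in enumerate(dist.genes):
            vals = "\t".join(
                f"{v:g}" if dist.normalized else str(int(v)) for v in dist.values[i]
            )
            fh.write(f"{gene}\t{vals}\n")


def write_event_log(log: CommunityEventLog, path: str | Path) -> None:
    payload = {
        "grid_length": log.grid_length,
        "terminal_death": log.terminal_death,
        "totals": log.totals(),
        "communities": [
            {"members": list(members), "intervals": [list(r) for r in runs]}
            for members, runs in log.intervals.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
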