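"""Confidence assessment for the patient dendrogram's internal nodes.

Two complementary procedures, both operating on the binary patients x
selected-genes incidence matrix (rows are patients, columns the union of
the minimal gene sets at the optimal (theta, lambda)):

* **Multiscale bootstrap (AU)**: for each scale factor r, gene columns are
  resampled with replacement at round(r * n_features) draws, the weighted
  Jaccard distances and Ward tree recomputed, and BP(r) recorded as the
  fraction of replicates containing each original clade.  The approximately
  unbiased value follows from the signed-distance model: fitting
  Phi^-1(1 - BP(r)) ~ v*sqrt(r) + c/sqrt(r) by weighted least squares gives
  AU = 1 - Phi(v - c).  High AU means high confidence in a clade.

* **Monte Carlo p values**: each internal node with >= 3 members is scored
  by a two-group separation index — the ratio of between-children to total
  dispersion of the node's member rows in a whitened classical (Torgerson)
  embedding of the full patient distance matrix, truncated to its leading
  d = min(rank, max(2, n//4)) axes.  The null draws M complete datasets of
  n points from a standard d-dimensional Gaussian, builds each replicate's
  Ward tree, and harvests the same index from every null clade; an observed
  node is compared against the null clades of matching size (the size
  window grows symmetrically until at least 19 null values are pooled).
  Size-matching is what keeps the p values calibrated: Ward clades are
  selected to be compact, so comparing a node against unconditioned
  Gaussian samples of the same size would be sharply anti-conservative in
  reverse.  Reported are the add-one empirical p,
  (1 + #{null >= observed}) / (pool + 1), and a Gaussian approximate p from
  the pooled nulls' mean and SD.  This construction is this package's own
  explicit design: it exposes the empirical/Gaussian-p interface of Monte
  Carlo cluster-significance tests whose exact statistic is not
  standardized in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import json
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .core import ValidationError

__all__ = [
    "NodeSignificance",
    "feature_matrix",
    "weighted_jaccard_distance",
    "au_pvalues",
    "monte_carlo_pvalues",
    "monte_carlo_from_distances",
    "write_node_table",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass
class NodeSignificance:
    """Per-clade confidence annotations on one patient dendrogram.

    ``nodes`` is keyed by the clade's member frozenset; values may carry
    ``au``, ``bp`` (scale -> bootstrap probability), ``empirical_p`` and
    ``gaussian_p`` (absent for nodes where a quantity is undefined).
    """

    patients: list[str]
    linkage: np.ndarray
    nodes: dict[frozenset[str], dict]
    scales: tuple[float, ...] = ()
    n_bootstrap: int = 0
    n_null: int = 0
    seed: int = 0

    def clades(self) -> list[frozenset[str]]:
        return list(self.nodes)


def feature_matrix(selected_sets: Mapping[str, frozenset[str]]) -> tuple[list[str], list[str], np.ndarray]:
    """Binary patients x union-of-selected-genes incidence matrix."""
    patients = sorted(selected_sets)
    genes = sorted(set().union(*[selected_sets[p] for p in patients]))
    if len(genes) < 2:
        raise ValidationError("need at least 2 distinct selected genes")
    gene_idx = {g: j for j, g in enumerate(genes)}
    X = np.zeros((len(patients), len(genes)), dtype=np.int8)
    for i, p in enumerate(patients):
        for g in selected_sets[p]:
            X[i, gene_idx[g]] = 1
    return patients, genes, X


def weighted_jaccard_distance(X: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pairwise 1 - J on binary rows, with optional column multiplicities.

    With integer weights c_j this equals the Jaccard distance of the matrix
    whose columns are repeated c_j times; two all-zero rows get distance 0.
    """
    Xf = X.astype(float)
    if weights is not None:
        Xw = Xf * weights
    else:
        Xw = Xf
    inter = Xw @ Xf.T  # sum of weights over shared 1-columns
    row = Xw.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    D = 1.0 - J
    np.fill_diagonal(D, 0.0)
    return D


def _clades(z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Member index sets of every internal node of a scipy linkage tree."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for t, (a, b, _h, _c) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + t] = merged
        out.append(merged)
    return out


def _children(z: np.ndarray, n: int) -> dict[frozenset[int], tuple[frozenset[int], frozenset[int]]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = {}
    for t, (a, b, _h, _c) in enumerate(z):
        left, right = members[int(a)], members[int(b)]
        merged = left | right
        members[n + t] = merged
        out[merged] = (left, right)
    return out


def au_pvalues(
    selected_sets: Mapping[str, frozenset[str]],
    scales: Sequence[float] = DEFAULT_SCALES,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> NodeSignificance:
    """Multiscale-bootstrap AU/BP values for the Ward tree of the cohort.

    Resamples gene columns of the incidence matrix at each scale, rebuilds
    the weighted-Jaccard/Ward tree, and converts the per-scale clade
    recovery probabilities BP(r) into AU values via the weighted
    least-squares fit described in the module docstring.  Degenerate clades
    (recovered always or never at every scale) are clamped to AU 1 or 0.
    """
    if n_bootstrap < 100:
        raise ValidationError("use at least 100 bootstrap replicates per scale")
    if any(r <= 0 for r in scales):
        raise ValidationError("scales must be positive")
    patients, genes, X = feature_matrix(selected_sets)
    n, p = X.shape
    if n < 3:
        raise ValidationError("need at least 3 patients")
    rng = np.random.default_rng(seed)
    z0 = linkage(squareform(weighted_jaccard_distance(X), checks=False), method="ward")
    clades0 = _clades(z0, n)
    counts = {c: {float(r): 0 for r in scales} for c in clades0}
    for r in scales:
        p_r = max(2, int(round(r * p)))
        for _b in range(n_bootstrap):
            cols = rng.integers(0, p, size=p_r)
            w = np.bincount(cols, minlength=p).astype(float)
            D = weighted_jaccard_distance(X, w)
            zb = linkage(squareform(D, checks=False), method="ward")
            found = set(_clades(zb, n))
            for c in clades0:
                if c in found:
                    counts[c][float(r)] += 1
    rs = np.array([float(r) for r in scales])
    nodes: dict[frozenset[str], dict] = {}
    for c in clades0:
        bp = {r: counts[c][r] / n_bootstrap for r in rs}
        bps = np.array([bp[r] for r in rs])
        usable = (bps > 0) & (bps < 1)
        if usable.sum() >= 2:
            zvals = norm.ppf(1.0 - bps[usable])
            sq = np.sqrt(rs[usable])
            design = np.column_stack([sq, 1.0 / sq])
            w = n_bootstrap * norm.pdf(zvals) ** 2 / (bps[usable] * (1.0 - bps[usable]))
            wsqrt = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], zvals * wsqrt, rcond=None)
            v, cc = coef
            au = float(np.clip(1.0 - norm.cdf(v - cc), 0.0, 1.0))
        elif bps.mean() >= 0.5:
            au = 1.0
        else:
            au = 0.0
        key = frozenset(patients[i] for i in c)
        nodes[key] = {"au": au, "bp": {float(r): float(bp[r]) for r in rs}}
    return NodeSignificance(patients, z0, nodes, tuple(float(r) for r in rs), n_bootstrap, 0, seed)


def _embed_reduce_whiten(D: np.ndarray) -> np.ndarray:
    """Whitened leading-axes classical embedding of a distance matrix.

    Keeps the d = min(rank, max(2, n//4)) largest positive eigen-axes of the
    Torgerson embedding and scales each to unit sample variance.  Truncation
    well below n is essential: whitening a full-rank embedding collapses any
    point set onto a regular simplex and destroys all cluster geometry.
    """
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    pos = vals > 1e-10 * max(float(vals.max()), 1e-30)
    if not pos.any():
        return np.zeros((n, 1))
    vals, vecs = vals[pos], vecs[:, pos]
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    d = min(len(vals), max(2, n // 4))
    X = vecs[:, :d] * np.sqrt(vals[:d])
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _separation_index(X: np.ndarray, group_a: np.ndarray) -> float:
    """Between-children / total dispersion of a two-group split of rows of X."""
    mean = X.mean(axis=0)
    total = float(((X - mean) ** 2).sum())
    if total <= 0:
        return 0.0
    between = 0.0
    for mask in (group_a, ~group_a):
        if mask.sum() == 0:
            return 0.0
        gm = X[mask].mean(axis=0)
        between += mask.sum() * float(((gm - mean) ** 2).sum())
    return between / total


def _clade_stats_from_distances(D: np.ndarray, z: np.ndarray) -> dict[frozenset[int], float]:
    """Separation index of every clade (>= 3 members) of tree ``z``.

    Stats are evaluated on the rows of the whitened reduced embedding of the
    *full* matrix D — sub-clades are never re-embedded on their own.
    """
    n = len(D)
    emb = _embed_reduce_whiten(D)
    out: dict[frozenset[int], float] = {}
    for merged, (left, _right) in _children(z, n).items():
        if len(merged) < 3:
            continue
        idx = sorted(merged)
        pos = {i: t for t, i in enumerate(idx)}
        mask = np.zeros(len(idx), dtype=bool)
        for i in left:
            mask[pos[i]] = True
        out[merged] = _separation_index(emb[idx], mask)
    return out


def monte_carlo_pvalues(
    selected_sets: Mapping[str, frozenset[str]],
    n_null: int = 1000,
    seed: int = 0,
    tree: np.ndarray | None = None,
    min_null_pool: int = 19,
) -> NodeSignificance:
    """Empirical and Gaussian-approximate p values per dendrogram node.

    Wrapper over :func:`monte_carlo_from_distances` using the weighted
    Jaccard distances of the binary incidence matrix.
    """
    patients, _genes, X = feature_matrix(selected_sets)
    return monte_carlo_from_distances(
        weighted_jaccard_distance(X), patients, n_null=n_null, seed=seed,
        tree=tree, min_null_pool=min_null_pool,
    )


def monte_carlo_from_distances(
    D0: np.ndarray,
    patients: Sequence[str],
    n_null: int = 1000,
    seed: int = 0,
    tree: np.ndarray | None = None,
    min_null_pool: int = 19,
) -> NodeSignificance:
    """Monte Carlo cluster-significance on an arbitrary patient distance matrix.

    A node needs >= 3 members; smaller nodes are reported without p values.
    ``tree`` may supply a precomputed linkage over the given patient order;
    by default the Ward tree of ``D0`` is built internally.  Each of the
    ``n_null`` replicates is a complete standard-Gaussian dataset whose Ward
    clades contribute to the size-matched null pools.
    """
    if n_null < 19:
        raise ValidationError("need at least 19 null replicates")
    patients = list(patients)
    n = len(patients)
    if n < 3:
        raise ValidationError("need at least 3 patients")
    rng = np.random.default_rng(seed)
    z0 = tree if tree is not None else linkage(squareform(D0, checks=False), method="ward")
    observed = _clade_stats_from_distances(D0, z0)
    d = _embed_reduce_whiten(D0).shape[1]
    null_by_size: dict[int, list[float]] = {}
    for _b in range(n_null):
        Y = rng.standard_normal((n, d))
        Dy = np.sqrt(np.maximum(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2), 0.0))
        zy = linkage(squareform(Dy, checks=False), method="ward")
        for merged, s in _clade_stats_from_distances(Dy, zy).items():
            null_by_size.setdefault(len(merged), []).append(s)
    nodes: dict[frozenset[str], dict] = {}
    for merged in _children(z0, n):
        key = frozenset(patients[i] for i in merged)
        if merged not in observed:
            nodes[key] = {}
            continue
        m = len(merged)
        width = 0
        pool: list[float] = []
        while True:
            pool = [s for mm in range(m - width, m + width + 1) for s in null_by_size.get(mm, [])]
            if len(pool) >= min_null_pool or width > n:
                break
            width += 1
        arr = np.asarray(pool)
        obs = observed[merged]
        emp = (1.0 + float((arr >= obs - 1e-12).sum())) / (len(arr) + 1.0)
        mu, sd = float(arr.mean()), float(arr.std(ddof=1))
        gauss = float(norm.sf((obs - mu) / sd)) if sd > 0 else (0.0 if obs > mu else 1.0)
        nodes[key] = {
            "statistic": float(obs),
            "empirical_p": emp,
            "gaussian_p": gauss,
            "null_pool": len(arr),
        }
    return NodeSignificance(patients, z0, nodes, (), 0, n_null, seed)


def write_node_table(sig: NodeSignificance, path) -> None:
    """TSV node table keyed by sorted member lists, one row per clade."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("members\tau\tempirical_p\tgaussian_p\n")
        for key, vals in sig.nodes.items():
            members = ",".join(sorted(key))
            au = vals.get("au")
            ep = vals.get("empirical_p")
            gp = vals.get("gaussian_p")
            fmt = lambda x: f"{x:.6g}" if x is not None else "NA"
            fh.write(f"{members}\t{fmt(au)}\t{fmt(ep)}\t{fmt(gp)}\n")
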