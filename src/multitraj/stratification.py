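"""Patient stratification from community-trajectory gene selection.

For each patient, the altered genes are grouped by the similarity of their
community trajectories: at persistence threshold theta = 0 the groups are
exact trajectory-equivalence classes (pairwise Hamming distance 0); at
theta > 0 they are complete-linkage clusters of the patient-restricted
Hamming matrix cut at height theta.  The patient's *minimal gene set* keeps
the genes lying in groups of size s with smin <= s <= lambda — small groups
of genes that never (or rarely) separate across resolutions.  Grouping does
not depend on lambda, so selections are nested: raising lambda only adds
genes.

Patients are then compared by the Jaccard index of their minimal sets,
clustered by Ward-style agglomeration on the Jaccard distance 1 - J, with
the number of clusters chosen by PAM (k-medoids) under the average
silhouette criterion, and scored against reference subgroup labels by
accuracy and the multiclass (Gorodkin) Matthews correlation coefficient.
The (theta, lambda) pair is optimized by exhaustive grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import matthews_corrcoef, silhouette_score

from .core import Cohort, ValidationError
from .trajectories import TrajectoryMatrix, trajectory_distance_matrix

__all__ = [
    "SelectionParams",
    "PatientSimilarity",
    "ClusteringScore",
    "ClusteringResult",
    "OptimizationResult",
    "HeldoutResult",
    "select_patient_genes",
    "patient_similarity",
    "pam",
    "cluster_cohort",
    "score_clustering",
    "optimize_parameters",
    "classify_heldout",
    "selection_summary",
]


@dataclass(frozen=True)
class SelectionParams:
    """Gene-selection parameters.

    theta: maximum trajectory Hamming distance within a group (resolution
    steps); lam: maximum group size; smin: minimum group size (2 by default —
    selected genes must be tightly associated with at least one co-member).
    """

    theta: int = 0
    lam: int = 6
    smin: int = 2

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValidationError("theta must be >= 0")
        if self.lam < 1:
            raise ValidationError("lambda must be >= 1")
        if self.smin < 1:
            raise ValidationError("smin must be >= 1")


@dataclass
class PatientSimilarity:
    """Symmetric Jaccard-index matrix over a sorted patient list."""

    patients: list[str]
    values: np.ndarray  # J in [0, 1]

    def distance(self) -> np.ndarray:
        return 1.0 - self.values

    def condensed_distance(self) -> np.ndarray:
        return squareform(self.distance(), checks=False)


@dataclass
class ClusteringScore:
    accuracy: float  # percent, micro (per-patient)
    macro_accuracy: float  # percent, mean per-reference-class recall
    mcc: float
    k: int
    confusion: pd.DataFrame  # clusters x reference labels
    cluster_to_label: dict[int, str]


@dataclass
class ClusteringResult:
    patients: list[str]
    labels: dict[str, int]  # patient -> cluster id (1..k)
    k: int
    linkage: np.ndarray
    silhouettes: dict[int, float]  # candidate k -> average silhouette width


@dataclass
class OptimizationResult:
    best: SelectionParams
    table: pd.DataFrame
    best_score: ClusteringScore
    best_clustering: ClusteringResult
    best_selected: dict[str, frozenset[str]]


@dataclass
class HeldoutResult:
    patient: str
    assigned_cluster: int | None
    ranking: pd.DataFrame  # columns: patient, jaccard, cluster; non-increasing J
    unclassifiable: bool


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def _group_patient_genes(
    patient_genes: Sequence[str], traj: TrajectoryMatrix, theta: int
) -> list[frozenset[str]]:
    """Trajectory-coherence groups among one patient's genes (lambda-free)."""
    genes = sorted(patient_genes)
    if theta == 0:
        # exact equivalence classes: identical label rows
        buckets: dict[bytes, list[str]] = {}
        for g in genes:
            buckets.setdefault(traj.row(g).tobytes(), []).append(g)
        return [frozenset(b) for b in buckets.values()]
    if len(genes) == 1:
        return [frozenset(genes)]
    dist = trajectory_distance_matrix(traj, subset=genes)
    z = linkage(dist.condensed(), method="complete")
    flat = fcluster(z, t=theta, criterion="distance")
    groups: dict[int, set[str]] = {}
    for g, c in zip(genes, flat):
        groups.setdefault(int(c), set()).add(g)
    return [frozenset(v) for v in groups.values()]


def select_patient_genes(
    patient_genes: frozenset[str] | set[str],
    traj: TrajectoryMatrix,
    params: SelectionParams,
) -> tuple[frozenset[str], list[frozenset[str]]]:
    """Minimal gene set of one patient plus the qualifying groups.

    Genes are grouped by trajectory distance (complete linkage at height
    theta; exact equivalence classes at theta = 0) and the groups of size s
    with smin <= s <= lambda are kept.
    """
    if not patient_genes:
        raise ValidationError("empty patient gene set")
    groups = _group_patient_genes(patient_genes, traj, params.theta)
    kept = [g for g in groups if params.smin <= len(g) <= params.lam]
    selected = frozenset().union(*kept) if kept else frozenset()
    return selected, kept


# ---------------------------------------------------------------------------
# similarity and clustering
# ---------------------------------------------------------------------------

def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A n B| / |A u B|; defined as 1 when both sets are empty."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def patient_similarity(selected_sets: Mapping[str, frozenset[str]]) -> PatientSimilarity:
    """Pairwise Jaccard indices over patients (sorted by id for determinism)."""
    if len(selected_sets) < 2:
        raise ValidationError("need at least 2 patients")
    if all(not s for s in selected_sets.values()):
        raise ValidationError("all selected gene sets are empty; no signal at these parameters")
    patients = sorted(selected_sets)
    n = len(patients)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard(selected_sets[patients[i]], selected_sets[patients[j]])
    return PatientSimilarity(patients, values)


def pam(dist: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """Deterministic PAM (k-medoids, BUILD + SWAP) on a precomputed distance matrix.

    Returns (labels in 0..k-1 by medoid order, medoid indices).  Ties are
    broken toward smaller indices throughout.
    """
    n = len(dist)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    # BUILD: first medoid minimizes total distance; later ones maximize gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(nearest - dist[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    # SWAP: steepest descent on total cost
    def cost(meds: list[int]) -> float:
        return dist[:, meds].min(axis=1).sum()

    current = cost(medoids)
    while True:
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                delta = cost(trial) - current
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        current += best_delta
    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, medoids


def _choose_k(dist: np.ndarray, kmax: int) -> tuple[int, dict[int, float]]:
    """Average-silhouette-maximizing k over PAM solutions for k = 2..kmax."""
    sils: dict[int, float] = {}
    best_k, best_s = 2, -np.inf
    for k in range(2, kmax + 1):
        labels, _ = pam(dist, k)
        if len(set(labels.tolist())) < 2:
            sils[k] = -1.0
            continue
        s = float(silhouette_score(dist, labels, metric="precomputed"))
        sils[k] = s
        if s > best_s + 1e-12:  # ties keep the smallest k
            best_k, best_s = k, s
    return best_k, sils


def cluster_cohort(
    sim: PatientSimilarity, kmax: int = 8, pam_direct: bool = False
) -> ClusteringResult:
    """Ward tree on 1 - J, cut at the PAM/silhouette-selected cluster count.

    With ``pam_direct`` the PAM labels themselves are returned instead of the
    tree cut.  Deterministic; independent of patient input order (patients
    are sorted inside :func:`patient_similarity`).
    """
    n = len(sim.patients)
    if n < 3:
        raise ValidationError("need at least 3 patients to cluster")
    if not 2 <= kmax < n:
        raise ValidationError(f"kmax must satisfy 2 <= kmax < {n}")
    dist = sim.distance()
    z = linkage(sim.condensed_distance(), method="ward")
    k, sils = _choose_k(dist, kmax)
    if pam_direct:
        flat, _ = pam(dist, k)
        flat = flat + 1
    else:
        flat = fcluster(z, t=k, criterion="maxclust")
    labels = {p: int(c) for p, c in zip(sim.patients, flat)}
    return ClusteringResult(sim.patients, labels, k, z, sils)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_clustering(clusters: Mapping[str, int], reference: Mapping[str, str]) -> ClusteringScore:
    """Map each cluster to its majority reference label and score the mapping.

    accuracy: percent of patients whose mapped label matches their reference
    (micro).  macro_accuracy: mean per-reference-class recall, in percent.
    mcc: multiclass (Gorodkin) Matthews correlation of mapped vs reference
    labels, 0 when its denominator degenerates.
    """
    if not clusters:
        raise ValidationError("empty clustering")
    patients = sorted(clusters)
    if set(patients) != set(reference):
        raise ValidationError("cluster and reference labelings cover different patients")
    cl = pd.Series({p: clusters[p] for p in patients}, name="cluster")
    ref = pd.Series({p: reference[p] for p in patients}, name="reference")
    confusion = pd.crosstab(cl, ref)
    mapping: dict[int, str] = {}
    for c in confusion.index:
        row = confusion.loc[c]
        top = row[row == row.max()]
        mapping[int(c)] = sorted(top.index)[0]  # tie -> lexicographically smallest
    mapped = cl.map(mapping)
    accuracy = 100.0 * float((mapped == ref).mean())
    recalls = [float((mapped[ref == lab] == lab).mean()) for lab in sorted(ref.unique())]
    macro = 100.0 * float(np.mean(recalls))
    mcc = float(matthews_corrcoef(ref.to_numpy(), mapped.to_numpy()))
    return ClusteringScore(accuracy, macro, mcc, int(cl.nunique()), confusion, mapping)


# ---------------------------------------------------------------------------
# optimization and held-out classification
# ---------------------------------------------------------------------------

def optimize_parameters(
    cohort: Cohort,
    traj: TrajectoryMatrix,
    theta_grid: Sequence[int] = (0, 1, 2, 3),
    lambda_grid: Sequence[int] = tuple(range(2, 11)),
    kmax: int = 8,
    smin: int = 2,
    pam_direct: bool = False,
) -> OptimizationResult:
    """Grid-search (theta, lambda) for the selection that best recovers the labels.

    Only labelled patients participate.  For every pair: select genes, build
    the Jaccard similarity, cluster, and score; the winner maximizes accuracy
    with ties resolved by max MCC, then min average genes per patient, then
    min lambda, then min theta.
    """
    if not theta_grid or not lambda_grid:
        raise ValidationError("parameter grids must be non-empty")
    labelled = cohort.labelled()
    if len(labelled.patients) < 3:
        raise ValidationError("need at least 3 labelled patients")
    # grouping is lambda-independent: compute per theta once
    groups_by_theta: dict[int, dict[str, list[frozenset[str]]]] = {}
    for theta in theta_grid:
        groups_by_theta[theta] = {
            pid: _group_patient_genes(genes, traj, theta)
            for pid, genes in labelled.patients.items()
        }
    rows = []
    best_key = None
    best: tuple | None = None
    for theta in theta_grid:
        for lam in lambda_grid:
            params = SelectionParams(theta=theta, lam=lam, smin=smin)
            selected = {}
            for pid in labelled.patients:
                kept = [g for g in groups_by_theta[theta][pid] if smin <= len(g) <= lam]
                selected[pid] = frozenset().union(*kept) if kept else frozenset()
            avg_genes = float(np.mean([len(s) for s in selected.values()]))
            try:
                sim = patient_similarity(selected)
            except ValidationError:
                rows.append({"theta": theta, "lambda": lam, "avg_genes": avg_genes,
                             "accuracy": np.nan, "macro_accuracy": np.nan,
                             "mcc": np.nan, "k": 0})
                continue
            clustering = cluster_cohort(sim, kmax=kmax, pam_direct=pam_direct)
            score = score_clustering(clustering.labels, labelled.labels)
            rows.append({"theta": theta, "lambda": lam, "avg_genes": avg_genes,
                         "accuracy": score.accuracy, "macro_accuracy": score.macro_accuracy,
                         "mcc": score.mcc, "k": score.k})
            key = (score.accuracy, score.mcc, -avg_genes, -lam, -theta)
            if best_key is None or key > best_key:
                best_key = key
                best = (params, score, clustering, selected)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValidationError("every (theta, lambda) pair produced all-empty selections")
    params, score, clustering, selected = best
    return OptimizationResult(params, table, score, clustering, selected)


def classify_heldout(
    patient: str,
    heldout_genes: frozenset[str] | set[str],
    traj: TrajectoryMatrix,
    params: SelectionParams,
    trained_selected: Mapping[str, frozenset[str]],
    trained_clusters: Mapping[str, int],
) -> HeldoutResult:
    """Assign a held-out patient to the cluster of its most Jaccard-similar trainee.

    The held-out gene set is put through the same (theta, lambda) selection;
    an empty selection yields an explicit unclassifiable outcome.
    """
    selected, _groups = select_patient_genes(heldout_genes, traj, params)
    rows = []
    for pid in sorted(trained_selected):
        rows.append({
            "patient": pid,
            "jaccard": jaccard(selected, trained_selected[pid]) if selected else 0.0,
            "cluster": trained_clusters[pid],
        })
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["jaccard", "patient"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    if not selected:
        return HeldoutResult(patient, None, ranking, True)
    top = ranking.iloc[0]
    return HeldoutResult(patient, int(top["cluster"]), ranking, False)


def selection_summary(
    cohort: Cohort,
    selected_sets: Mapping[str, frozenset[str]],
    clusters: Mapping[str, int] | None = None,
) -> dict:
    """Per-patient selection sizes, dimensionality reduction, and cohort stats.

    reduction % = 100 * (1 - |selected| / |altered|).  With cluster labels,
    also reports each cluster's uniquely selected genes: genes selected in
    every patient of that cluster and in no patient of any other cluster.
    """
    rows = []
    for pid in sorted(selected_sets):
        n_alt = len(cohort.patients[pid])
        n_sel = len(selected_sets[pid])
        rows.append({
            "patient": pid,
            "n_altered": n_alt,
            "n_selected": n_sel,
            "reduction_pct": 100.0 * (1.0 - n_sel / n_alt),
        })
    per_patient = pd.DataFrame(rows)
    out = {
        "per_patient": per_patient,
        "mean_selected": float(per_patient["n_selected"].mean()),
        "sd_selected": float(per_patient["n_selected"].std(ddof=1)) if len(rows) > 1 else 0.0,
        "mean_reduction_pct": float(per_patient["reduction_pct"].mean()),
        "sd_reduction_pct": float(per_patient["reduction_pct"].std(ddof=1)) if len(rows) > 1 else 0.0,
    }
    if clusters is not None:
        unique: dict[int, frozenset[str]] = {}
        ids = sorted(set(clusters.values()))
        for c in ids:
            members = [p for p in selected_sets if clusters[p] == c]
            others = [p for p in selected_sets if clusters[p] != c]
            common = frozenset.intersection(*[selected_sets[p] for p in members]) if members else frozenset()
            elsewhere = frozenset().union(*[selected_sets[p] for p in others]) if others else frozenset()
            unique[c] = common - elsewhere
        out["unique_per_cluster"] = unique
    return out
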