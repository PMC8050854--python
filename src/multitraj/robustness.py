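"""Null-model and depletion robustness checks for the stratification.

Two procedures probe whether the recovered patient clusters reflect real
gene-subgroup structure:

* **Cohort shuffling** redistributes the altered genes across patients while
  preserving both marginals exactly — each patient keeps its gene-set size
  and the pooled gene multiset is unchanged — and re-runs selection,
  clustering and scoring at fixed (theta, lambda).  On informative cohorts
  the shuffled accuracies fall far below the unshuffled one.

* **Iterative exclusion** repeats the full (theta, lambda) optimization,
  removing each patient's selected genes from its altered set after every
  round, until selection dries up or accuracy collapses.  A graceful decay
  indicates that the signal is spread over many gene groups rather than
  hinging on a single one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Cohort, ValidationError
from .trajectories import TrajectoryMatrix
from .stratification import (
    SelectionParams,
    cluster_cohort,
    optimize_parameters,
    patient_similarity,
    score_clustering,
    select_patient_genes,
)

__all__ = [
    "ShuffleResult",
    "ExclusionTrace",
    "shuffle_cohort",
    "shuffle_analysis",
    "iterative_exclusion",
]

#: replicate count used in the original study's shuffling analysis
DEFAULT_SHUFFLES = 10_000


@dataclass
class ShuffleResult:
    accuracies: list[float]  # percent, one per replicate
    params: SelectionParams
    seed: int
    flagged: list[int] = field(default_factory=list)  # replicates with all-empty selections

    @property
    def n(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass
class ExclusionTrace:
    records: pd.DataFrame  # iteration, theta, lambda, accuracy, mcc, k, genes_removed
    removed: dict[str, list[frozenset[str]]]  # per patient, per iteration

    @property
    def n_iterations(self) -> int:
        return len(self.records)


def shuffle_cohort(cohort: Cohort, seed: int, max_repair_rounds: int = 1000) -> Cohort:
    """Permute the pooled (patient, gene) incidence, preserving both marginals.

    The pooled gene list is randomly permuted across the patient slots; any
    within-patient duplicates this creates are repaired by random pairwise
    swaps with non-duplicating partners.  Gene-set sizes per patient and the
    pooled gene multiset are preserved exactly.
    """
    if len(cohort.patients) < 2:
        raise ValidationError("need at least 2 patients to shuffle")
    from collections import Counter

    rng = np.random.default_rng(seed)
    pids = sorted(cohort.patients)
    sizes = [len(cohort.patients[p]) for p in pids]
    pool: list[str] = []
    for p in pids:
        pool.extend(sorted(cohort.patients[p]))
    pool = list(np.array(pool)[rng.permutation(len(pool))])
    slot_owner = [int(o) for o in np.repeat(np.arange(len(pids)), sizes)]
    counts: list[Counter] = [Counter() for _ in pids]
    for owner, gene in zip(slot_owner, pool):
        counts[owner][gene] += 1
    n_slots = len(pool)
    # repair within-patient duplicates by swapping with random compatible slots
    for _round in range(max_repair_rounds):
        dup_slots = [i for i, (o, g) in enumerate(zip(slot_owner, pool)) if counts[o][g] > 1]
        if not dup_slots:
            break
        for idx in dup_slots:
            a, g = slot_owner[idx], pool[idx]
            if counts[a][g] <= 1:
                continue  # already repaired via an earlier swap this round
            for j in rng.integers(0, n_slots, size=200):
                j = int(j)
                b, h = slot_owner[j], pool[j]
                # swap must not create duplicates on either side
                if b == a or h == g or counts[a][h] > 0 or counts[b][g] > 0:
                    continue
                pool[idx], pool[j] = h, g
                counts[a][g] -= 1
                counts[a][h] += 1
                counts[b][h] -= 1
                counts[b][g] += 1
                break
    else:
        raise ValidationError("could not repair within-patient duplicates; pathological gene multiset")
    patients = {p: set() for p in pids}
    for owner, gene in zip(slot_owner, pool):
        patients[pids[owner]].add(gene)
    shuffled = Cohort({p: frozenset(g) for p, g in patients.items()}, dict(cohort.labels))
    for p in pids:  # exact marginal contract
        assert len(shuffled.patients[p]) == len(cohort.patients[p])
    return shuffled


def shuffle_analysis(
    cohort: Cohort,
    traj: TrajectoryMatrix,
    params: SelectionParams,
    n_replicates: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    kmax: int = 8,
) -> ShuffleResult:
    """Accuracy distribution over shuffled cohorts at fixed (theta, lambda).

    Replicates whose selections are all empty score 0 and are flagged.
    Replicate r uses shuffle seed ``seed + r``.
    """
    if n_replicates < 1:
        raise ValidationError("need at least one replicate")
    labelled = cohort.labelled()
    accuracies: list[float] = []
    flagged: list[int] = []
    for r in range(n_replicates):
        shuffled = shuffle_cohort(labelled, seed + r)
        selected = {
            pid: select_patient_genes(genes, traj, params)[0]
            for pid, genes in shuffled.patients.items()
        }
        if all(not s for s in selected.values()):
            accuracies.append(0.0)
            flagged.append(r)
            continue
        sim = patient_similarity(selected)
        clustering = cluster_cohort(sim, kmax=kmax)
        score = score_clustering(clustering.labels, shuffled.labels)
        accuracies.append(score.accuracy)
    return ShuffleResult(accuracies, params, seed, flagged)


def iterative_exclusion(
    cohort: Cohort,
    traj: TrajectoryMatrix,
    theta_grid: Sequence[int] = (0, 1, 2, 3),
    lambda_grid: Sequence[int] = tuple(range(2, 11)),
    kmax: int = 8,
    smin: int = 2,
    max_iterations: int = 50,
) -> ExclusionTrace:
    """Re-optimize after removing each round's selected genes from each patient.

    Stops when every selection is empty, any patient's altered set would
    empty out, accuracy reaches 0, or ``max_iterations`` is hit.  Removed
    sets are disjoint across iterations per patient by construction.
    """
    current = cohort.labelled()
    rows = []
    removed: dict[str, list[frozenset[str]]] = {p: [] for p in current.patients}
    for it in range(1, max_iterations + 1):
        try:
            res = optimize_parameters(current, traj, theta_grid, lambda_grid, kmax=kmax, smin=smin)
        except ValidationError:
            break  # selection dried up everywhere
        n_removed = int(sum(len(s) for s in res.best_selected.values()))
        rows.append({
            "iteration": it,
            "theta": res.best.theta,
            "lambda": res.best.lam,
            "accuracy": res.best_score.accuracy,
            "mcc": res.best_score.mcc,
            "k": res.best_score.k,
            "genes_removed": n_removed,
        })
        if res.best_score.accuracy <= 0.0 or n_removed == 0:
            break
        next_patients = {}
        emptied = False
        for pid, genes in current.patients.items():
            sel = res.best_selected.get(pid, frozenset())
            removed[pid].append(sel)
            remaining = genes - sel
            if not remaining:
                emptied = True
                break
            next_patients[pid] = remaining
        if emptied:
            break
        current = Cohort(next_patients, dict(current.labels))
    return ExclusionTrace(pd.DataFrame(rows), removed)
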