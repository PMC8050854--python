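"""Gene selection, Jaccard similarity, Ward+PAM clustering, and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multitraj import (
    SelectionParams,
    ValidationError,
    classify_heldout,
    cluster_cohort,
    jaccard,
    optimize_parameters,
    pam,
    patient_similarity,
    score_clustering,
    select_patient_genes,
    selection_summary,
)
from multitraj.core import Cohort
from multitraj.stratification import PatientSimilarity
from multitraj.trajectories import TrajectoryMatrix


def traj_from_rows(rows):
    genes = sorted(rows)
    labels = np.array([rows[g] for g in genes])
    return TrajectoryMatrix(genes, tuple(map(float, range(1, labels.shape[1] + 1))), labels)


def test_select_single_qualifying_group():
    traj = traj_from_rows({
        "A": [0, 0, 0], "B": [0, 0, 0],  # dH(A,B) = 0
        "C": [1, 2, 1], "D": [2, 1, 2],  # far from everything
    })
    selected, groups = select_patient_genes({"A", "B", "C", "D"}, traj, SelectionParams(0, 6))
    assert selected == frozenset({"A", "B"})
    assert frozenset({"A", "B"}) in groups


def test_select_size_cap_excludes_large_coherent_group():
    rows = {f"G{i}": [0, 0] for i in range(7)}  # 7 identical trajectories
    traj = traj_from_rows(rows)
    selected, _ = select_patient_genes(set(rows), traj, SelectionParams(0, 6))
    assert selected == frozenset()


def test_select_contradictory_bounds_empty():
    traj = traj_from_rows({"A": [0], "B": [0]})
    selected, _ = select_patient_genes({"A", "B"}, traj, SelectionParams(0, lam=1, smin=2))
    assert selected == frozenset()


def test_select_theta_positive_uses_complete_linkage():
    # dH(A,B)=1, dH(A,C)=dH(B,C)=4: at theta=1 {A,B} group; C stays out
    traj = traj_from_rows({
        "A": [0, 0, 0, 0, 0], "B": [0, 1, 0, 0, 0],
        "C": [2, 2, 2, 2, 0],
    })
    selected, groups = select_patient_genes({"A", "B", "C"}, traj, SelectionParams(theta=1, lam=6))
    assert selected == frozenset({"A", "B"})


def test_selection_monotone_in_lambda(scenario):
    """With theta fixed, raising lambda only ever adds genes."""
    cohort = scenario["cohort"]
    traj = scenario["traj"]
    pid = sorted(cohort.patients)[0]
    genes = cohort.patients[pid]
    previous = frozenset()
    for lam in (2, 4, 6, 10):
        selected, _ = select_patient_genes(genes, traj, SelectionParams(0, lam))
        assert previous <= selected
        previous = selected


def test_select_empty_patient_rejected(scenario):
    with pytest.raises(ValidationError):
        select_patient_genes(frozenset(), scenario["traj"], SelectionParams())


@pytest.mark.parametrize(
    "a, b, expected",
    [({"a", "b"}, {"b", "c"}, 1 / 3), ({"a"}, {"a"}, 1.0),
     ({"a"}, {"b"}, 0.0), (set(), set(), 1.0), (set(), {"a"}, 0.0)],
)
def test_jaccard_examples(a, b, expected):
    assert jaccard(a, b) == pytest.approx(expected)


def test_patient_similarity_all_empty_rejected():
    with pytest.raises(ValidationError, match="no signal"):
        patient_similarity({"p1": frozenset(), "p2": frozenset()})


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_jaccard_distance_satisfies_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    universe = list("abcdefgh")
    sets = [frozenset(g for g in universe if rng.random() < 0.5) or frozenset("a")
            for _ in range(4)]
    d = [[1.0 - jaccard(x, y) for y in sets] for x in sets]
    for i in range(4):
        assert d[i][i] == 0.0
        for j in range(4):
            assert d[i][j] == pytest.approx(d[j][i])
            assert 0.0 <= d[i][j] <= 1.0
            for k in range(4):
                assert d[i][j] <= d[i][k] + d[k][j] + 1e-12


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def two_group_similarity():
    """6 patients, two clean groups: within-distance 0.1, between 0.9."""
    n = 6
    values = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same = (i < 3) == (j < 3)
            values[i, j] = 1.0 - (0.1 if same else 0.9)
    return PatientSimilarity([f"p{i}" for i in range(n)], values)


def test_cluster_cohort_recovers_two_groups():
    """Silhouette arithmetic favours k=2: width (0.9-0.1)/0.9 within each group."""
    sim = two_group_similarity()
    result = cluster_cohort(sim, kmax=4)
    assert result.k == 2
    groups = {}
    for p, c in result.labels.items():
        groups.setdefault(c, set()).add(p)
    assert sorted(map(sorted, groups.values())) == [["p0", "p1", "p2"], ["p3", "p4", "p5"]]
    assert result.silhouettes[2] == pytest.approx((0.9 - 0.1) / 0.9)
    assert result.silhouettes[2] > max(result.silhouettes[3], result.silhouettes[4])


def test_cluster_cohort_tie_rule_on_uniform_distances():
    n = 5
    values = np.full((n, n), 1.0 - 0.5)
    np.fill_diagonal(values, 1.0)
    sim = PatientSimilarity([f"p{i}" for i in range(n)], values)
    result = cluster_cohort(sim, kmax=4)
    assert all(s <= 0 for s in result.silhouettes.values())
    assert result.k == 2  # smallest k wins the tie


def test_cluster_cohort_invariant_to_patient_order():
    sim = two_group_similarity()
    sets = {p: frozenset() for p in sim.patients}
    # patient_similarity sorts ids, so feed shuffled dicts through it
    rng = np.random.default_rng(0)
    base = {"pa": frozenset("abc"), "pb": frozenset("abd"), "pc": frozenset("abe"),
            "pd": frozenset("xyz"), "pe": frozenset("xyw"), "pf": frozenset("xyv")}
    items = list(base.items())
    ref = None
    for _ in range(3):
        rng.shuffle(items)
        result = cluster_cohort(patient_similarity(dict(items)), kmax=4)
        if ref is None:
            ref = result.labels
        assert result.labels == ref


def test_pam_build_swap_is_deterministic():
    d = two_group_similarity().distance()
    labels1, med1 = pam(d, 2)
    labels2, med2 = pam(d, 2)
    assert (labels1 == labels2).all() and med1 == med2


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_perfect_match():
    clusters = {f"p{i}": i % 4 + 1 for i in range(12)}
    reference = {f"p{i}": f"S{i % 4}" for i in range(12)}
    score = score_clustering(clusters, reference)
    assert score.accuracy == pytest.approx(100.0)
    assert score.mcc == pytest.approx(1.0)


def test_score_single_cluster_majority_and_degenerate_mcc():
    """One cluster with 3 X + 2 Y: accuracy 60, MCC 0 (denominator degenerates
    because every patient receives the same mapped label)."""
    clusters = {f"p{i}": 1 for i in range(5)}
    reference = {"p0": "X", "p1": "X", "p2": "X", "p3": "Y", "p4": "Y"}
    score = score_clustering(clusters, reference)
    assert score.accuracy == pytest.approx(60.0)
    assert score.mcc == pytest.approx(0.0)


def test_score_one_mismatch_in_ten():
    clusters = {f"p{i}": (i % 2) + 1 for i in range(10)}
    reference = {f"p{i}": "AB"[i % 2] for i in range(10)}
    reference["p0"] = "B"  # one patient swapped
    score = score_clustering(clusters, reference)
    assert score.accuracy == pytest.approx(90.0)


def test_score_invariant_under_cluster_relabeling():
    clusters = {f"p{i}": (i % 3) for i in range(9)}
    relabeled = {p: {0: 7, 1: 5, 2: 9}[c] for p, c in clusters.items()}
    reference = {f"p{i}": f"S{(i * 2) % 3}" for i in range(9)}
    s1, s2 = score_clustering(clusters, reference), score_clustering(relabeled, reference)
    assert s1.accuracy == s2.accuracy and s1.mcc == pytest.approx(s2.mcc)


def test_score_majority_tie_breaks_lexicographically():
    clusters = {"p0": 1, "p1": 1}
    reference = {"p0": "B", "p1": "A"}
    score = score_clustering(clusters, reference)
    assert score.cluster_to_label[1] == "A"


# ---------------------------------------------------------------------------
# optimization, held-out, summary
# ---------------------------------------------------------------------------

def test_optimize_table_shape_and_single_cell_grid(scenario):
    res = optimize_parameters(scenario["cohort"], scenario["traj"],
                              theta_grid=(0,), lambda_grid=(6,))
    assert len(res.table) == 1
    assert res.best.theta == 0 and res.best.lam == 6


def test_optimize_full_grid_row_count(optimized):
    assert len(optimized.table) == 4 * 9  # |theta_grid| x |lambda_grid|


def test_optimize_recovers_planted_subgroups(optimized):
    assert optimized.best_score.accuracy >= 90.0
    assert optimized.best.theta == 0


def test_classify_identical_patient_gets_its_cluster(optimized, scenario):
    traj = scenario["traj"]
    pid = sorted(optimized.best_selected)[0]
    genes = scenario["cohort"].patients[pid]
    result = classify_heldout("copycat", genes, traj, optimized.best,
                              optimized.best_selected, optimized.best_clustering.labels)
    assert not result.unclassifiable
    assert result.assigned_cluster == optimized.best_clustering.labels[pid]
    assert result.ranking.iloc[0]["jaccard"] == pytest.approx(1.0)


def test_classify_ranking_covers_all_trainees_non_increasing(optimized, scenario):
    pid = sorted(optimized.best_selected)[-1]
    genes = scenario["cohort"].patients[pid]
    result = classify_heldout("x", genes, scenario["traj"], optimized.best,
                              optimized.best_selected, optimized.best_clustering.labels)
    assert len(result.ranking) == len(optimized.best_selected)
    j = result.ranking["jaccard"].to_numpy()
    assert (np.diff(j) <= 1e-12).all()


def test_classify_heldout_planted_signature_assigned_to_own_subgroup(optimized, scenario):
    from multitraj import simulate_cohort

    extra = simulate_cohort(scenario["truth"], seed=777)
    mapping = optimized.best_score.cluster_to_label
    pid = "P2_01"  # a fresh patient drawn from subgroup S2's signature
    result = classify_heldout(pid, extra.patients[pid], scenario["traj"], optimized.best,
                              optimized.best_selected, optimized.best_clustering.labels)
    assert not result.unclassifiable
    assert mapping[result.assigned_cluster] == "S2"


def test_selection_summary_reduction_and_uniqueness():
    cohort = Cohort({"p1": frozenset(f"g{i}" for i in range(100)),
                     "p2": frozenset(f"g{i}" for i in range(100))})
    selected = {"p1": frozenset(f"g{i}" for i in range(20)),
                "p2": frozenset(f"g{i}" for i in range(20))}
    out = selection_summary(cohort, selected, clusters={"p1": 1, "p2": 2})
    row = out["per_patient"].set_index("patient")
    assert row.loc["p1", "reduction_pct"] == pytest.approx(80.0)
    assert out["sd_selected"] == pytest.approx(0.0)
    # identical selections: nothing is unique to either cluster
    assert out["unique_per_cluster"] == {1: frozenset(), 2: frozenset()}
    selected2 = {"p1": frozenset({"a", "b"}), "p2": frozenset({"b", "c"})}
    cohort2 = Cohort({"p1": frozenset("abz"), "p2": frozenset("bcz")})
    out2 = selection_summary(cohort2, selected2, clusters={"p1": 1, "p2": 2})
    assert out2["unique_per_cluster"] == {1: frozenset({"a"}), 2: frozenset({"c"})}
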