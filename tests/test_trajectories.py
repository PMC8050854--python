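"""Trajectory matrices, Hamming distances, events, and the dendrogram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multitraj import (
    ValidationError,
    build_trajectories,
    community_events,
    resolution_sweep,
    trajectory_dendrogram,
    trajectory_distance_matrix,
    trajectory_hamming,
)
from multitraj.community import Partition, ResolutionProfile
from multitraj.trajectories import (
    TrajectoryMatrix,
    linkage_to_newick,
    load_trajectories,
    write_trajectories,
)


def profile_from_labels(labels):
    """Build a ResolutionProfile from a genes x T label array."""
    labels = np.asarray(labels)
    genes = [f"g{i}" for i in range(labels.shape[0])]
    grid = tuple(float(t + 1) for t in range(labels.shape[1]))
    parts = [Partition({g: int(labels[i, t]) for i, g in enumerate(genes)}, grid[t], 0.0)
             for t in range(labels.shape[1])]
    return ResolutionProfile(grid, parts, seed=0)


def test_build_trajectories_matches_partitions(bridged_triangles):
    profile = resolution_sweep(bridged_triangles, (0.1, 1.0), seed=2)
    traj = build_trajectories(profile)
    assert traj.labels.shape == (6, 2)
    for t, part in enumerate(profile.partitions):
        for i, g in enumerate(traj.genes):
            assert traj.labels[i, t] == part.assignment[g]


def test_single_resolution_profile_gives_one_column():
    traj = build_trajectories(profile_from_labels([[0], [0], [1]]))
    assert traj.labels.shape == (3, 1)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((1, 1, 2), (1, 2, 2), 1),  # together at t1, apart at t2, together at t3
        ((0, 1, 2, 3), (0, 1, 2, 3), 0),
        (tuple(range(10)), tuple(range(10, 20)), 10),  # never co-clustered
    ],
)
def test_hamming_examples(a, b, expected):
    assert trajectory_hamming(a, b) == expected


def test_hamming_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        trajectory_hamming((1, 2), (1, 2, 3))


def test_distance_matrix_identical_genes_zero():
    traj = TrajectoryMatrix(["g0", "g1"], (1.0, 2.0), np.array([[3, 4], [3, 4]]))
    dist = trajectory_distance_matrix(traj)
    assert (dist.values == 0).all()


def test_distance_matrix_equals_bruteforce_pairwise():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 5, size=(20, 8))
    traj = TrajectoryMatrix([f"g{i}" for i in range(20)], tuple(map(float, range(1, 9))), labels)
    dist = trajectory_distance_matrix(traj)
    for i in range(20):
        for j in range(20):
            assert dist.values[i, j] == trajectory_hamming(labels[i], labels[j])


def test_distance_matrix_subset_and_unknown_gene():
    traj = TrajectoryMatrix(["g0", "g1", "g2"], (1.0,), np.array([[0], [0], [1]]))
    sub = trajectory_distance_matrix(traj, subset=["g2", "g0"])
    assert sub.genes == ["g2", "g0"]
    assert sub.values[0, 1] == 1
    with pytest.raises(ValidationError, match="unknown gene"):
        trajectory_distance_matrix(traj, subset=["nope"])


def test_normalized_variant_divides_by_grid_length():
    traj = TrajectoryMatrix(["a", "b"], (1.0, 2.0, 3.0, 4.0), np.array([[0, 0, 0, 0], [0, 1, 1, 0]]))
    dist = trajectory_distance_matrix(traj, normalized=True)
    assert dist.values[0, 1] == pytest.approx(0.5)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_hamming_is_a_pseudometric(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, size=(6, 7))
    traj = TrajectoryMatrix([f"g{i}" for i in range(6)], tuple(map(float, range(1, 8))), labels)
    d = trajectory_distance_matrix(traj).values
    assert (np.diag(d) == 0).all()
    assert (d == d.T).all()
    assert (d >= 0).all() and (d <= 7).all()
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert d[i, j] <= d[i, k] + d[k, j]


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_hamming_invariant_under_per_column_relabeling(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, size=(5, 6))
    relabeled = labels.copy()
    for t in range(6):
        perm = rng.permutation(4)
        relabeled[:, t] = perm[labels[:, t]]
    genes = [f"g{i}" for i in range(5)]
    grid = tuple(map(float, range(1, 7)))
    d1 = trajectory_distance_matrix(TrajectoryMatrix(genes, grid, labels)).values
    d2 = trajectory_distance_matrix(TrajectoryMatrix(genes, grid, relabeled)).values
    assert (d1 == d2).all()


# ---------------------------------------------------------------------------
# community events
# ---------------------------------------------------------------------------

def test_events_single_interval():
    # community {g0,g1} present at steps 0-2 of 5, then dissolved
    labels = np.array([[0, 0, 0, 0, 1],
                       [0, 0, 0, 1, 2],
                       [1, 1, 1, 2, 3]])
    log = community_events(profile_from_labels(labels))
    per = log.per_community()
    key = ("g0", "g1")
    assert per[key] == {"births": 1, "deaths": 1, "resurgences": 0}


def test_events_resurgence_alive_at_end():
    # {g0,g1} present at steps {0,1} and {3,4(end)}: 2 births, 1 death, 1 resurgence
    labels = np.array([[0, 0, 0, 0, 0],
                       [0, 0, 1, 0, 0],
                       [1, 1, 2, 1, 1]])
    log = community_events(profile_from_labels(labels))
    per = log.per_community()
    assert per[("g0", "g1")] == {"births": 2, "deaths": 1, "resurgences": 1}
    with_terminal = community_events(profile_from_labels(labels), terminal_death=True)
    assert with_terminal.per_community()[("g0", "g1")]["deaths"] == 2


def test_events_accounting_identity_on_random_profiles():
    """deaths - resurgences is 0 or 1 per community; 1 iff absent at the end;
    and total resurgences = total intervals - unique communities."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        labels = rng.integers(0, 3, size=(6, 8))
        log = community_events(profile_from_labels(labels))
        per = log.per_community()
        total_intervals = 0
        for members, counts in per.items():
            diff = counts["deaths"] - counts["resurgences"]
            alive_at_end = log.intervals[members][-1][1] == log.grid_length - 1
            assert diff == (0 if alive_at_end else 1)
            total_intervals += len(log.intervals[members])
        assert log.totals()["resurgences"] == total_intervals - log.n_communities


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------

def test_dendrogram_zero_distance_pair_merges_first():
    traj = TrajectoryMatrix(
        ["g1", "g2", "g3"], tuple(map(float, range(1, 6))),
        np.array([[0, 0, 0, 0, 0], [0, 0, 0, 0, 0], [1, 1, 1, 1, 1]]))
    dist = trajectory_distance_matrix(traj)
    z, order = trajectory_dendrogram(dist)
    assert z[0, 2] == pytest.approx(0.0)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


def test_average_linkage_heights_match_hand_computation():
    """d = (0,2,4 / 2,0,6 / 4,6,0): first merge at 2, second at (4+6)/2 = 5."""
    from multitraj.trajectories import TrajectoryDistanceMatrix

    d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
    dist = TrajectoryDistanceMatrix(["a", "b", "c"], d, grid_length=6)
    z, _ = trajectory_dendrogram(dist, method="average")
    assert z[0, 2] == pytest.approx(2.0)
    assert z[1, 2] == pytest.approx(5.0)


def test_newick_output_contains_all_leaves(scenario):
    genes = scenario["traj"].genes[:12]
    dist = trajectory_distance_matrix(scenario["traj"], subset=genes)
    z, _ = trajectory_dendrogram(dist)
    nwk = linkage_to_newick(z, dist.genes)
    assert nwk.endswith(";")
    for g in genes:
        assert g in nwk
    import skbio

    tree = skbio.TreeNode.read([nwk])
    assert {t.name for t in tree.tips()} == set(genes)


def test_dendrogram_requires_two_genes():
    from multitraj.trajectories import TrajectoryDistanceMatrix

    dist = TrajectoryDistanceMatrix(["a"], np.zeros((1, 1)), grid_length=3)
    with pytest.raises(ValidationError):
        trajectory_dendrogram(dist)


def test_trajectory_tsv_round_trip(tmp_path, scenario):
    traj = scenario["traj"]
    p = tmp_path / "traj.tsv"
    write_trajectories(traj, p)
    again = load_trajectories(p)
    assert again.genes == traj.genes
    assert again.grid == traj.grid
    assert (again.labels == traj.labels).all()
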