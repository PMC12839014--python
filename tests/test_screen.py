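"""Library scoring, hit filtering, diversity clustering, hit picking."""

import numpy as np
import pandas as pd
import pytest

from cdk9screen import features as F
from cdk9screen import models as M
from cdk9screen import screen as SC
from conftest import partition_of


def brute_force_average_linkage(dist, cut):
    """Exhaustive reference agglomerator: recompute every inter-cluster
    average from the raw distance matrix at each step."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                key = (d, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        if d > cut:
            break
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(sorted(clusters, key=min)):
        for m in members:
            labels[m] = c
    return labels


@pytest.fixture(scope="module")
def fingerprint_model():
    """A path-fingerprint RF trained on a tiny separable problem."""
    rng = np.random.default_rng(0)
    actives = ["Nc1ncnc2cc(-c3ccccc3)ccc12", "Nc1ncnc2cc(C)ccc12",
               "Nc1nc2ccccc2s1", "Nc1nc2cc(C)ccc2s1", "Nc1ncnc2ccccc12"]
    inactives = ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "c1ccncc1", "C1CCCCC1"]
    smiles = actives + inactives
    X = F.featurize_matrix(smiles, "path_fp")
    y = np.array([1] * 5 + [0] * 5)
    spec = M.ModelSpec("RF", "path_fp", {"n_estimators": 100, "max_features": None}, 1)
    return M.fit_final(spec, X, y), actives, inactives


def library_frame(smiles, available=None):
    return pd.DataFrame(
        {
            "compound_id": [f"L{i}" for i in range(len(smiles))],
            "smiles": smiles,
            "available": available if available is not None else [True] * len(smiles),
        }
    )


class TestScoring:
    def test_standardize_logs_rejects_and_continues(self):
        lib = library_frame(["CCO", "C1CC", "c1ccccc1"])
        std, rejects = SC.standardize_library(lib)
        assert len(std) == 2
        assert rejects.reason.tolist() == ["unparseable_smiles"]

    def test_scoring_deterministic_and_order_preserving(self, fingerprint_model):
        model, actives, inactives = fingerprint_model
        std, _ = SC.standardize_library(library_frame(actives + inactives))
        a = SC.score_library(model, std)
        b = SC.score_library(model, std)
        assert a.ps.tolist() == b.ps.tolist()
        assert a.compound_id.tolist() == std.compound_id.tolist()

    def test_batch_size_invariance(self, fingerprint_model):
        model, actives, inactives = fingerprint_model
        std, _ = SC.standardize_library(library_frame(actives + inactives))
        one = SC.score_library(model, std, batch_size=1)
        big = SC.score_library(model, std, batch_size=1000)
        assert np.array_equal(one.ps.to_numpy(), big.ps.to_numpy())

    def test_training_actives_score_above_half(self, fingerprint_model):
        model, actives, _ = fingerprint_model
        std, _ = SC.standardize_library(library_frame(actives))
        scored = SC.score_library(model, std)
        assert (scored.ps > 0.5).all()


class TestHitFilter:
    def _scored(self, ps):
        frame = library_frame(["CCO"] * len(ps))
        frame["parent_smiles"] = frame["smiles"]
        frame["ps"] = ps
        return frame

    def test_inclusive_boundary(self):
        hits = SC.filter_hits(self._scored([0.8, 0.79]), ps_min=0.8)
        assert hits.ps.tolist() == [0.8]

    def test_strict_comparator_option(self):
        hits = SC.filter_hits(self._scored([0.8, 0.81]), ps_min=0.8, inclusive=False)
        assert hits.ps.tolist() == [0.81]

    def test_zero_threshold_keeps_all_sorted(self):
        hits = SC.filter_hits(self._scored([0.3, 0.9, 0.5]), ps_min=0.0)
        assert hits.ps.tolist() == [0.9, 0.5, 0.3]

    def test_count_monotone_in_threshold(self, rng):
        scored = self._scored(list(rng.random(50)))
        counts = [len(SC.filter_hits(scored, ps_min=t)) for t in (0.5, 0.8, 0.9)]
        assert counts[0] >= counts[1] >= counts[2]


class TestClustering:
    def test_identical_compounds_single_cluster(self):
        labels = SC.average_linkage_labels(np.zeros((2, 2)), cut=0.3)
        assert labels.tolist() == [0, 0]

    def test_three_point_hand_case(self):
        # d(A,B)=0.1 merges; {A,B}-C average = (0.9+0.8)/2 = 0.85 > 0.3
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        labels = SC.average_linkage_labels(d, cut=0.30)
        assert labels.tolist() == [0, 0, 1]

    def test_matches_bruteforce_oracle_on_small_instances(self, rng):
        """Partition equality with the exhaustive agglomerator on all
        instances of <= 8 random fingerprints."""
        for trial in range(40):
            n = int(rng.integers(2, 9))
            fps = rng.integers(0, 2, (n, 32))
            dist = SC.tanimoto_distance_matrix(fps)
            cut = float(rng.uniform(0.1, 0.9))
            mine = SC.average_linkage_labels(dist, cut)
            ref = brute_force_average_linkage(dist, cut)
            assert partition_of(mine) == partition_of(ref), f"trial {trial}"

    def test_cluster_count_nonincreasing_in_cut(self, rng):
        fps = rng.integers(0, 2, (25, 64))
        dist = SC.tanimoto_distance_matrix(fps)
        counts = [
            SC.average_linkage_labels(dist, cut).max() + 1
            for cut in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_agreement_with_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        for _ in range(10):
            pts = rng.random((int(rng.integers(4, 12)), 5))
            dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            cut = float(rng.uniform(0.3, 0.9))
            mine = SC.average_linkage_labels(dist, cut)
            Z = linkage(squareform(dist, checks=False), method="average")
            ref = fcluster(Z, t=cut, criterion="distance")
            assert partition_of(mine) == partition_of(ref)

    def test_cluster_hits_on_smiles(self):
        hits = pd.DataFrame(
            {
                "compound_id": ["a", "b", "c"],
                "parent_smiles": ["Cc1ccccc1", "CCc1ccccc1", "OC1CCNCC1"],
                "ps": [0.9, 0.85, 0.99],
                "available": [True, True, True],
            }
        )
        assignment = SC.cluster_hits(hits, cut=0.9)
        assert len(assignment.labels) == 3
        assert assignment.n_clusters >= 1

    def test_empty_hits(self):
        assignment = SC.cluster_hits(pd.DataFrame(columns=["parent_smiles"]), cut=0.3)
        assert assignment.n_clusters == 0


class TestRepresentatives:
    def _hits(self):
        return pd.DataFrame(
            {
                "compound_id": ["a", "b", "c", "d"],
                "parent_smiles": ["C", "CC", "CCC", "CCCC"],
                "ps": [0.95, 0.91, 0.90, 0.85],
                "available": [False, True, True, True],
            }
        )

    def test_availability_overrides_ps(self):
        assignment = SC.ClusterAssignment(np.array([0, 0, 1, 1]), 0.3, 2)
        reps, log = SC.select_representatives(assignment, self._hits())
        assert reps.compound_id.tolist() == ["b", "c"]  # 0.95 unavailable
        assert log == []

    def test_all_available_plain_argmax(self):
        hits = self._hits().assign(available=True)
        assignment = SC.ClusterAssignment(np.array([0, 0, 0, 0]), 0.3, 1)
        reps, _ = SC.select_representatives(assignment, hits)
        assert reps.compound_id.tolist() == ["a"]
        assert reps.cluster_size.tolist() == [4]

    def test_ps_tie_breaks_lexicographically(self):
        hits = self._hits().assign(ps=[0.9, 0.9, 0.9, 0.9], available=True)
        assignment = SC.ClusterAssignment(np.array([0, 0, 0, 0]), 0.3, 1)
        reps, _ = SC.select_representatives(assignment, hits)
        assert reps.compound_id.tolist() == ["a"]

    def test_fully_unavailable_cluster_logged(self):
        hits = self._hits().assign(available=[False, False, True, True])
        assignment = SC.ClusterAssignment(np.array([0, 0, 1, 1]), 0.3, 2)
        reps, log = SC.select_representatives(assignment, hits)
        assert reps.compound_id.tolist() == ["c"]
        assert len(log) == 1 and "cluster 0" in log[0]

    def test_empty_assignment(self):
        reps, log = SC.select_representatives(
            SC.ClusterAssignment(np.zeros(0, dtype=int), 0.3, 0),
            pd.DataFrame(columns=["compound_id", "parent_smiles", "ps", "available"]),
        )
        assert reps.empty and log == []
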