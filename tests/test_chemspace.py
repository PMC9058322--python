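"""PCA reduction, SOM clustering, stratified splitting, Tanimoto diversity."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from caco2qspr.chemspace import (
    SOMGrid,
    diversity_report,
    pca_reduce,
    som_cluster,
    stratified_split,
    tanimoto_matrix,
)
from caco2qspr.datatable import InputError
from caco2qspr.synthetic import generate_blobs
from tests.conftest import make_table


class TestPCA:
    def test_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        X = np.column_stack([base, base, base]) + rng.normal(0, 1e-6, (50, 3))
        proj, scores = pca_reduce(make_table(X, rng.normal(size=50)))
        assert proj.K == 1
        assert scores.shape == (50, 1)

    def test_isotropic_gaussian_needs_nine_of_ten(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 10))
        proj, _ = pca_reduce(make_table(X, rng.normal(size=2000)), var_target=0.90)
        # equal eigenvalues: each component explains ~1/10 of variance
        assert proj.K == 9

    def test_full_reconstruction_of_standardized_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        t = make_table(X, rng.normal(size=40))
        proj, _ = pca_reduce(t, var_target=1.0)
        Z = (X - proj.mean) / proj.std
        recon = (Z @ proj.component_loadings) @ proj.component_loadings.T
        np.testing.assert_allclose(recon, Z, atol=1e-8)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(InputError):
            pca_reduce(make_table(X, np.arange(10.0)))


class TestSOM:
    def test_nine_separated_blobs_recovered(self):
        aris = []
        for seed in range(5):
            X, labels = generate_blobs(n=270, K_dims=4, n_blobs=9, separation=10.0,
                                       seed=seed)
            pred = som_cluster(X, SOMGrid(rows=3, cols=3, epochs=60, seed=seed))
            aris.append(adjusted_rand_score(labels, pred))
        assert np.mean(aris) > 0.9

    def test_identical_rows_map_to_one_unit(self):
        X = np.tile([1.0, 2.0], (20, 1))
        pred = som_cluster(X, SOMGrid(rows=3, cols=3, epochs=20, seed=0))
        assert len(set(pred.tolist())) == 1

    def test_same_seed_gives_identical_labels(self):
        X, _ = generate_blobs(n=60, K_dims=3, n_blobs=4, separation=6.0, seed=3)
        grid = lambda: SOMGrid(rows=2, cols=2, epochs=30, seed=7)  # noqa: E731
        np.testing.assert_array_equal(som_cluster(X, grid()), som_cluster(X, grid()))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            som_cluster(np.zeros((4, 2)), SOMGrid(rows=3, cols=3))


class TestStratifiedSplit:
    def test_cluster_of_ten_tests_positions_three_and_eight(self):
        y = np.linspace(-7, -4, 10)
        t = make_table(np.arange(10.0).reshape(-1, 1), y)
        split = stratified_split(t, np.zeros(10, dtype=int))
        test_pos = sorted(split.positions[i] for i in range(10)
                          if split.labels[i] == "test")
        assert test_pos == [3, 8]

    def test_cluster_of_two_has_no_test_compounds(self):
        t = make_table(np.arange(2.0).reshape(-1, 1), [-6.0, -5.0])
        split = stratified_split(t, np.zeros(2, dtype=int))
        assert split.labels == ["train", "train"]

    def test_whole_table_test_fraction_in_expected_band(self):
        rng = np.random.default_rng(4)
        n = 500
        t = make_table(rng.normal(size=(n, 3)), rng.uniform(-8, -3.5, n))
        clusters = rng.integers(0, 9, size=n)
        split = stratified_split(t, clusters)
        frac = split.test_mask.mean()
        assert 0.16 <= frac <= 0.22

    def test_split_is_partition_with_balanced_cluster_counts(self):
        rng = np.random.default_rng(5)
        n = 200
        t = make_table(rng.normal(size=(n, 3)), rng.uniform(-8, -3.5, n))
        clusters = rng.integers(0, 5, size=n)
        split = stratified_split(t, clusters)
        assert all(lab in ("train", "test") for lab in split.labels)
        for c in np.unique(clusters):
            size = int((clusters == c).sum())
            n_test = sum(1 for i in range(n)
                         if clusters[i] == c and split.labels[i] == "test")
            assert abs(n_test - size // 5) <= 1

    def test_extremes_stay_in_training(self):
        y = np.linspace(-7.9, -3.6, 50)
        t = make_table(np.arange(50.0).reshape(-1, 1), y)
        split = stratified_split(t, np.zeros(50, dtype=int))
        test_y = t.y[split.test_mask]
        train_y = t.y[split.train_mask]
        assert test_y.min() > train_y.min() and test_y.max() < train_y.max()


class TestTanimoto:
    def sim_of(self, rows):
        X = np.asarray(rows, dtype=float)
        # identity scaling: columns already span [0, 1]
        t = make_table(X, np.zeros(X.shape[0]) - 6)
        return tanimoto_matrix(t)

    def test_identical_nonzero_vectors_similarity_one(self):
        s = self.sim_of([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert s[0, 1] == pytest.approx(1.0)

    def test_orthogonal_vectors_similarity_zero(self):
        s = self.sim_of([[1.0, 0.0], [0.0, 1.0]])
        assert s[0, 1] == pytest.approx(0.0)

    def test_half_overlap_hand_case(self):
        # a=(1,0), b=(1,1): 1 / (1 + 2 - 1) = 0.5
        # (third row keeps both columns non-constant under min-max scaling)
        s = self.sim_of([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        assert s[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(6)
        t = make_table(rng.uniform(0, 5, size=(30, 8)), rng.normal(size=30))
        s = tanimoto_matrix(t)
        np.testing.assert_allclose(s, s.T)
        np.testing.assert_allclose(np.diag(s), 1.0)
        assert s.min() >= 0.0 and s.max() <= 1.0 + 1e-12


class TestDiversityReport:
    def test_single_pair_mean(self):
        sim = np.array([[1.0, 0.4], [0.4, 1.0]])
        rep = diversity_report(sim)
        assert rep.mean_overall == pytest.approx(0.4)

    def test_identical_compounds_all_means_one(self):
        sim = np.ones((4, 4))
        rep = diversity_report(sim)
        assert rep.mean_overall == pytest.approx(1.0)

    def test_split_means_match_brute_force_double_loop(self):
        from caco2qspr.chemspace import SplitAssignment

        rng = np.random.default_rng(7)
        n = 20
        A = rng.uniform(0, 1, size=(n, n))
        sim = (A + A.T) / 2
        np.fill_diagonal(sim, 1.0)
        labels = ["test" if i % 4 == 0 else "train" for i in range(n)]
        split = SplitAssignment(labels=labels, cluster_ids=np.zeros(n, int),
                                positions=np.zeros(n, int))
        rep = diversity_report(sim, split)

        def brute(idx_a, idx_b=None):
            tot, cnt = 0.0, 0
            if idx_b is None:
                for i in idx_a:
                    for j in idx_a:
                        if i != j:
                            tot += sim[i, j]
                            cnt += 1
            else:
                for i in idx_a:
                    for j in idx_b:
                        tot += sim[i, j]
                        cnt += 1
            return tot / cnt

        tr = [i for i in range(n) if labels[i] == "train"]
        te = [i for i in range(n) if labels[i] == "test"]
        assert rep.mean_train == pytest.approx(brute(tr), abs=1e-12)
        assert rep.mean_test == pytest.approx(brute(te), abs=1e-12)
        assert rep.mean_cross == pytest.approx(brute(tr, te), abs=1e-12)

    def test_endpoint_histogram_counts_sum_to_n(self):
        from caco2qspr.chemspace import SplitAssignment

        rng = np.random.default_rng(8)
        n = 40
        sim = np.eye(n)
        y = rng.uniform(-8, -3.5, n)
        labels = ["test" if i % 5 == 2 else "train" for i in range(n)]
        split = SplitAssignment(labels=labels, cluster_ids=np.zeros(n, int),
                                positions=np.zeros(n, int))
        rep = diversity_report(sim, split, y=y)
        assert sum(rep.endpoint_histogram["all"]) == n
        assert (sum(rep.endpoint_histogram["train"])
                + sum(rep.endpoint_histogram["test"])) == n
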