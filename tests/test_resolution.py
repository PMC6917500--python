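import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from probeseq.resolution import (
    OriginClusterTable,
    entropy_score,
    fisher_resample,
    mean_silhouette,
    select_cluster_number,
)


def brute_entropy(counts: np.ndarray) -> float:
    """Straightforward double-loop evaluation of the normalized
    cluster/origin entropy; independent of the vectorized implementation."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    num = 0.0
    for i in range(counts.shape[0]):
        row = counts[i].sum()
        if row == 0:
            continue
        f_i = row / total
        h = 0.0
        for j in range(counts.shape[1]):
            d = counts[i, j] / row
            if d > 0:
                h += d * np.log(d)
        num += f_i * h
    den = 0.0
    for j in range(counts.shape[1]):
        f_j = counts[:, j].sum() / total
        if f_j > 0:
            den += f_j * np.log(f_j)
    return num / den


class TestEntropyScore:
    def test_pure_clusters_zero(self):
        t = OriginClusterTable(pd.DataFrame({"A": [10, 0], "B": [0, 25]}))
        assert entropy_score(t) == pytest.approx(0.0)

    def test_single_cluster_one(self):
        t = OriginClusterTable(pd.DataFrame({"A": [10], "B": [20], "C": [5]}))
        assert entropy_score(t) == pytest.approx(1.0)

    def test_hand_value(self):
        t = OriginClusterTable(pd.DataFrame({"A": [10, 10], "B": [10, 0]}))
        expected = (2 / 3 * np.log(2)) / -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3))
        assert entropy_score(t) == pytest.approx(expected)
        assert entropy_score(t) == pytest.approx(0.72598, abs=1e-5)

    def test_single_origin_rejected(self):
        t = OriginClusterTable(pd.DataFrame({"A": [10, 5]}))
        with pytest.raises(ValueError):
            entropy_score(t)

    def test_relabeling_and_duplication_invariance(self, rng):
        counts = rng.integers(0, 20, size=(5, 3))
        counts[0, 0] += 1  # ensure nonempty
        t = OriginClusterTable(pd.DataFrame(counts, columns=list("ABC")))
        perm = rng.permutation(5)
        t_perm = OriginClusterTable(pd.DataFrame(counts[perm], columns=list("ABC")))
        t_dup = OriginClusterTable(pd.DataFrame(counts * 7, columns=list("ABC")))
        assert entropy_score(t) == pytest.approx(entropy_score(t_perm))
        assert entropy_score(t) == pytest.approx(entropy_score(t_dup))

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 15, size=(rng.integers(1, 6), rng.integers(2, 4)))
            if counts.sum() == 0 or (counts.sum(axis=0) > 0).sum() < 2:
                continue
            counts = counts[counts.sum(axis=1) > 0]
            if counts.shape[0] == 0:
                continue
            t = OriginClusterTable(pd.DataFrame(counts))
            assert entropy_score(t) == pytest.approx(brute_entropy(counts), rel=1e-12)

    def test_merging_never_decreases_score(self, rng):
        """Pooling two clusters can only blur origins (concavity of entropy)."""
        for _ in range(30):
            counts = rng.integers(0, 12, size=(4, 2)) + np.eye(4, 2, dtype=int)
            counts[0] += 1
            t = OriginClusterTable(pd.DataFrame(counts))
            merged = np.vstack([counts[0] + counts[1], counts[2:]])
            tm = OriginClusterTable(pd.DataFrame(merged))
            assert entropy_score(tm) >= entropy_score(t) - 1e-12

    def test_splitting_pure_cluster_unchanged(self):
        t = OriginClusterTable(pd.DataFrame({"A": [20, 10], "B": [0, 10]}))
        t_split = OriginClusterTable(pd.DataFrame({"A": [12, 8, 10], "B": [0, 0, 10]}))
        assert entropy_score(t_split) == pytest.approx(entropy_score(t))


class TestFisherResample:
    def test_perfect_association(self, rng):
        labels = np.repeat([0, 1], 100)
        origins = np.repeat(["x", "y"], 100)
        mean_p, se_p = fisher_resample(labels, origins, n_cells=150, n_repeats=20,
                                       n_mc_tables=500, seed=0)
        assert mean_p <= 1 / 501 + 1e-9

    def test_seed_determinism(self, rng):
        labels = rng.integers(0, 3, 400)
        origins = rng.choice(["a", "b", "c"], 400)
        r1 = fisher_resample(labels, origins, n_repeats=10, n_mc_tables=200, seed=5)
        r2 = fisher_resample(labels, origins, n_repeats=10, n_mc_tables=200, seed=5)
        assert r1 == r2

    def test_null_calibration(self, rng):
        """Independent labels and origins: no more than 8% of repeats reach
        p < 0.05 (the p-values are stochastically >= uniform)."""
        labels = rng.integers(0, 3, 600)
        origins = rng.choice(["a", "b", "c"], 600)
        _, _, pvals = fisher_resample(
            labels, origins, n_repeats=100, n_mc_tables=500, seed=1, return_pvalues=True
        )
        assert (pvals < 0.05).mean() <= 0.08

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            fisher_resample([0, 1] * 10, ["a", "b"] * 10, n_cells=150)

    def test_agrees_with_r_fisher_test(self):
        """Independent oracle: R's fisher.test with simulate.p.value on the
        same table reproduces the Monte-Carlo p within simulation noise."""
        table = np.array([[30, 10, 8], [12, 25, 9], [9, 11, 36]])
        labels = np.repeat([0, 1, 2], table.sum(axis=1))
        origins = np.concatenate(
            [np.repeat(["a", "b", "c"], row) for row in table]
        )
        n = labels.size
        mean_p, _ = fisher_resample(
            labels, origins, n_cells=n, n_repeats=1, n_mc_tables=20000, seed=0
        )
        rscript = textwrap.dedent(
            """
            m <- matrix(c(30,12,9, 10,25,11, 8,9,36), nrow=3)
            set.seed(1)
            cat(fisher.test(m, simulate.p.value=TRUE, B=20000)$p.value)
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_p = float(out.stdout.strip())
        assert mean_p == pytest.approx(r_p, abs=0.01)


class TestSilhouette:
    def test_two_distant_masses(self):
        coords = np.vstack([np.zeros((20, 2)), np.full((20, 2), 100.0)])
        coords += np.random.default_rng(0).normal(0, 0.01, coords.shape)
        labels = [0] * 20 + [1] * 20
        assert mean_silhouette(coords, labels) > 0.99

    def test_random_labels_near_zero(self, rng):
        coords = rng.standard_normal((200, 2))
        labels = rng.integers(0, 2, 200)
        assert abs(mean_silhouette(coords, labels)) < 0.1

    def test_swapped_labels_negative(self, rng):
        coords = np.vstack(
            [rng.normal(0, 0.5, (30, 2)), rng.normal(10, 0.5, (30, 2))]
        )
        labels = [1] * 30 + [0] * 30
        swapped = np.array([1] * 15 + [0] * 15 + [0] * 15 + [1] * 15)
        assert mean_silhouette(coords, swapped) < 0

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_silhouette(rng.standard_normal((10, 2)), np.zeros(10))


class TestSelectClusterNumber:
    @staticmethod
    def _scan(rows):
        return pd.DataFrame(
            rows,
            columns=["resolution", "n_clusters", "entropy_score", "fisher_mean_p",
                     "fisher_se_p", "mean_silhouette"],
        )

    def test_single_row(self):
        scan = self._scan([(0.5, 4, 0.5, 0.01, 0.001, 0.3)])
        assert select_cluster_number(scan)["n_clusters"] == 4

    def test_minimal_k_among_flat_fisher(self):
        scan = self._scan(
            [
                (0.2, 4, 0.9, 0.500, 0.01, 0.50),  # silhouette optimum -> k*=4
                (0.5, 8, 0.5, 0.001, 0.001, 0.40),
                (0.8, 10, 0.5, 0.001, 0.001, 0.30),
                (1.1, 12, 0.5, 0.001, 0.001, 0.20),
                (1.5, 20, 0.4, 0.001, 0.001, 0.10),  # outside 3*k window
            ]
        )
        assert select_cluster_number(scan)["n_clusters"] == 8

    def test_entropy_breaks_ties(self):
        scan = self._scan(
            [
                (0.2, 4, 0.9, 0.10, 0.01, 0.50),
                (0.5, 8, 0.7, 0.001, 0.001, 0.40),
                (0.8, 8, 0.3, 0.001, 0.001, 0.40),
            ]
        )
        chosen = select_cluster_number(scan)
        assert chosen["row"]["entropy_score"] == pytest.approx(0.3)

    def test_fallback_outside_window(self):
        scan = self._scan(
            [
                (0.2, 4, 0.9, 0.5, 0.01, 0.50),
                (1.5, 30, 0.2, 0.001, 0.001, 0.10),
            ]
        )
        # only k=4 and k=30 exist; window [4,12] contains k=4 which IS in scan
        assert select_cluster_number(scan)["n_clusters"] == 4

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            select_cluster_number(pd.DataFrame())
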