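"""Diversity, ordination and PERMANOVA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from qmpipe.ecology import (
    DistanceMatrix,
    bray_curtis,
    pcoa,
    permanova,
    shannon,
    shannon_per_sample,
)


class TestShannon:
    def test_uniform_closed_form(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_single_taxon_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_hand_computation(self):
        # -(0.25 ln 0.25 * 2 + 0.5 ln 0.5)
        assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_configurable_base(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_per_sample_matches_scalar(self, tiny_counts):
        per = shannon_per_sample(tiny_counts)
        assert per["s1"] == pytest.approx(shannon(tiny_counts["s1"].values))


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert bray_curtis(m).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        m = pd.DataFrame({"a": [1, 0], "b": [0, 5]})
        assert bray_curtis(m).values[0, 1] == pytest.approx(1.0)

    def test_hand_computation(self):
        m = pd.DataFrame({"x": [1, 2], "y": [3, 0]})
        assert bray_curtis(m).values[0, 1] == pytest.approx(1 - 2 * 1 / 6)

    def test_scale_invariance_on_proportions(self, small_cohort):
        from qmpipe.qmp import to_relative

        counts = small_cohort.counts.iloc[:, :12]
        d1 = bray_curtis(to_relative(counts))
        d2 = bray_curtis(to_relative(counts * 7))
        assert np.allclose(d1.values, d2.values, atol=1e-12)

    def test_two_all_zero_samples_error(self):
        m = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
        with pytest.raises(ValueError):
            bray_curtis(m)


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [6.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(list("abcd"), d))
        axis1 = res.coordinates[:, 0]
        rec = np.abs(axis1[:, None] - axis1[None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_duplicate_samples_identical_coordinates(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [4, 1, 0]})
        res = pcoa(bray_curtis(m))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_euclidean_configuration_roundtrip(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(4, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(list("abcd"), d))
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d, atol=1e-9)

    def test_matches_skbio_reference(self):
        """Cross-check coordinates against the scikit-bio implementation
        on a Euclidean configuration (axes defined up to sign)."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 4))
        d = squareform(pdist(pts))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        theirs = skbio_ord.pcoa(d, number_of_dimensions=4)
        ref = theirs.samples.values[:, :4]
        for ax in range(4):
            dot = np.dot(ours.coordinates[:, ax], ref[:, ax])
            assert np.allclose(
                ours.coordinates[:, ax], np.sign(dot) * ref[:, ax], atol=1e-8
            )

    def test_axes_ordered_by_eigenvalue(self, small_cohort):
        from qmpipe.qmp import to_relative

        d = bray_curtis(to_relative(small_cohort.counts.iloc[:, :20]))
        res = pcoa(d)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)


def naive_pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Two-loop PERMANOVA pseudo-F, straight from the definition."""
    n = len(labels)
    groups = np.unique(labels)
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))


class TestPermanova:
    def test_pseudo_f_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            pts = rng.normal(size=(10, 4))
            d = squareform(pdist(pts))
            labels = np.array(list("aaabbbccdd"))
            res = permanova(
                DistanceMatrix([str(i) for i in range(10)], d),
                labels, n_permutations=9, seed=0,
            )
            assert res.pseudo_F == pytest.approx(
                naive_pseudo_f(d, labels), abs=1e-12
            )

    def test_monte_carlo_equals_exhaustive_enumeration(self):
        """n=6, two groups of three: every Monte-Carlo permutation
        statistic lives in the exhaustive null set, and the exhaustive
        p is recovered."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        d = squareform(pdist(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix([str(i) for i in range(6)], d)
        f_obs = naive_pseudo_f(d, labels)
        null = [
            naive_pseudo_f(d, np.array(perm))
            for perm in itertools.permutations(labels)
        ]
        exhaustive_p = sum(f >= f_obs - 1e-12 for f in null) / len(null)
        res = permanova(dm, labels, n_permutations=4999, seed=3)
        # All 720 label orderings collapse onto C(6,3)=20 partitions, so
        # a large Monte-Carlo run hits the exhaustive value closely.
        assert res.p == pytest.approx(exhaustive_p, abs=0.02)

    def test_equal_distances_degenerate_geometry(self):
        """With all pairwise distances equal, R2 is label-independent
        (it equals (g-1)/(n-1)) and no labelling beats any other."""
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        res1 = permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=0)
        res2 = permanova(dm, list("abab") * 2, n_permutations=99, seed=1)
        assert res1.p == pytest.approx(1.0)
        assert res1.R2 == pytest.approx(res2.R2) == pytest.approx(1 / 7)

    def test_separated_clouds_minimal_p(self):
        """Well-separated clouds attain the smallest possible p: only
        permutations recreating the observed partition tie the observed
        statistic (counted by replaying the seeded generator)."""
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(25, 1, (10, 2))])
        d = squareform(pdist(pts))
        dm = DistanceMatrix([str(i) for i in range(20)], d)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(dm, labels, n_permutations=199, seed=0)
        replay = np.random.default_rng(0)
        _, codes = np.unique(labels, return_inverse=True)
        orig = frozenset(np.flatnonzero(codes == 0))
        mirror = frozenset(range(20)) - orig
        n_same = 0
        for _ in range(199):
            s = frozenset(np.flatnonzero(replay.permutation(codes) == 0))
            if s in (orig, mirror):
                n_same += 1
        assert res.p == pytest.approx((1 + n_same) / 200)
        assert res.p <= 2 / 200

    def test_r2_additivity(self, small_cohort):
        from qmpipe.qmp import to_relative

        counts = small_cohort.counts.iloc[:, :24]
        d = bray_curtis(to_relative(counts))
        labels = ["a", "b", "c"] * 8
        res = permanova(d, labels, n_permutations=9, seed=1)
        assert res.ss_between + res.ss_within == pytest.approx(
            res.ss_total, abs=1e-9
        )
        assert res.R2 == pytest.approx(res.ss_between / res.ss_total)

    def test_matches_skbio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        d = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(
            DistanceMatrix([str(i) for i in range(12)], d),
            labels, n_permutations=9, seed=0,
        )
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d, [str(i) for i in range(12)]),
            grouping=labels, permutations=9,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_constant_labels_error(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova(DistanceMatrix(list("abcd"), d), ["x"] * 4)
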