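"""QMP matrix construction: copy-number correction, rarefaction to even
sampling depth, low-depth exclusion, proportions and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qmpipe.qmp import (
    aggregate,
    copy_number_correct,
    qmp_transform,
    rarefy_counts,
    sampling_depth,
    to_relative,
)


class TestCopyNumberCorrect:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s": [40, 60]}, index=["a", "b"])
        cn = pd.Series([2.0, 3.0], index=["a", "b"])
        corrected = copy_number_correct(counts, cn)
        assert corrected["s"].tolist() == [20.0, 20.0]
        assert corrected["s"].sum() == 40.0

    def test_unit_copy_numbers_are_identity(self, tiny_counts):
        cn = pd.Series(1.0, index=tiny_counts.index)
        out = copy_number_correct(tiny_counts, cn)
        assert np.array_equal(out.values, tiny_counts.values.astype(float))

    def test_zero_counts_stay_zero(self, tiny_counts):
        cn = pd.Series([2.0, 5.0, 11.0], index=tiny_counts.index)
        out = copy_number_correct(tiny_counts, cn)
        assert np.all((tiny_counts.values == 0) == (out.values == 0))

    def test_missing_copy_number_errors_with_taxa(self, tiny_counts):
        cn = pd.Series([2.0], index=["ASV_1"])
        with pytest.raises(ValueError, match="ASV_2"):
            copy_number_correct(tiny_counts, cn)


class TestSamplingDepth:
    def test_hand_arithmetic(self):
        assert sampling_depth(40.0, 1e9) == pytest.approx(4e-8)

    def test_inverse_proportionality_in_load(self):
        assert sampling_depth(500.0, 2e9) == sampling_depth(500.0, 1e9) / 2

    def test_zero_depth_gives_zero(self):
        assert sampling_depth(0.0, 1e9) == 0.0

    def test_nonpositive_load_errors(self):
        with pytest.raises(ValueError):
            sampling_depth(10.0, 0.0)


class TestRarefactionDistribution:
    def test_matches_multivariate_hypergeometric(self):
        """Seeded rarefaction draws follow the exact multivariate
        hypergeometric law (chi-square goodness of fit)."""
        urn = np.array([6, 3, 2])
        target = 5
        rng = np.random.default_rng(424242)
        draws = [tuple(rarefy_counts(urn, target, rng)) for _ in range(10000)]

        # Exhaustive enumeration of outcome probabilities.
        outcomes, probs = [], []
        for a in range(min(urn[0], target) + 1):
            for b in range(min(urn[1], target - a) + 1):
                c = target - a - b
                if 0 <= c <= urn[2]:
                    outcomes.append((a, b, c))
                    p = (
                        sps.hypergeom.pmf(a, urn.sum(), urn[0], target)
                        * sps.hypergeom.pmf(
                            b, urn.sum() - urn[0], urn[1], target - a
                        )
                    )
                    probs.append(p)
        probs = np.array(probs)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

        observed = np.array([draws.count(o) for o in outcomes], dtype=float)
        expected = probs * len(draws)
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_target_above_total_errors(self):
        with pytest.raises(ValueError):
            rarefy_counts(np.array([3, 2]), 6, np.random.default_rng(0))


class TestQmpTransform:
    def _inputs(self, counts):
        cn = pd.Series(1.0, index=counts.index)
        loads = pd.Series(1e9, index=counts.columns)
        return cn, loads

    def test_one_taxon_hand_computation(self):
        counts = pd.DataFrame(
            {"s1": [500], "s2": [5000]}, index=["a"]
        )
        cn = pd.Series([1.0], index=["a"])
        loads = pd.Series({"s1": 1e9, "s2": 1e10})
        q = qmp_transform(counts, cn, loads, seed=0)
        # Both samples sit at s_i = 5e-7: no downsizing beyond rounding.
        assert q.even_sampling_depth == pytest.approx(5e-7)
        assert q.cells_per_gram.loc["a", "s1"] == pytest.approx(1e9)
        assert q.cells_per_gram.loc["a", "s2"] == pytest.approx(1e10)

    def test_column_sums_equal_loads(self, small_cohort):
        q = qmp_transform(
            small_cohort.counts, small_cohort.copy_numbers,
            small_cohort.loads, seed=7,
        )
        sums = q.cells_per_gram.sum(axis=0)
        loads = small_cohort.loads[sums.index]
        assert np.allclose(sums.values, loads.values, rtol=0.005)

    def test_identical_samples_identical_with_fixed_seed(self):
        counts = pd.DataFrame(
            {"s1": [300, 200, 100], "s2": [300, 200, 100]},
            index=["a", "b", "c"],
        )
        cn, loads = self._inputs(counts)
        q1 = qmp_transform(counts, cn, loads, seed=5)
        q2 = qmp_transform(counts, cn, loads, seed=5)
        assert q1.cells_per_gram.equals(q2.cells_per_gram)

    def test_engineered_shallow_sample_is_excluded(self):
        # s3's sampling depth is so small that its rarefaction target
        # falls below the 150-read floor.
        counts = pd.DataFrame(
            {"s1": [4000, 4000], "s2": [5000, 3000], "s3": [60, 40]},
            index=["a", "b"],
        )
        cn = pd.Series(1.0, index=counts.index)
        loads = pd.Series({"s1": 1e9, "s2": 1e9, "s3": 1e9})
        q = qmp_transform(counts, cn, loads, min_rarefied_reads=150, seed=1)
        assert [s for s, _ in q.excluded_samples] == ["s3"]
        assert "< 150" in q.excluded_samples[0][1]
        assert list(q.cells_per_gram.columns) == ["s1", "s2"]

    def test_exclusion_fixed_point(self):
        """Re-running the transform on the retained samples changes
        nothing (exclusion is stable)."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(300, size=(5, 6)),
            index=list("abcde"),
            columns=[f"s{i}" for i in range(6)],
        )
        counts["s0"] = [20, 10, 5, 3, 2]  # shallow sample
        cn = pd.Series(1.0, index=counts.index)
        loads = pd.Series(1e9, index=counts.columns)
        q1 = qmp_transform(counts, cn, loads, seed=9)
        retained = list(q1.cells_per_gram.columns)
        q2 = qmp_transform(counts[retained], cn, loads[retained], seed=9)
        assert q2.excluded_samples == []
        assert q1.cells_per_gram.equals(q2.cells_per_gram)

    def test_all_excluded_errors(self):
        counts = pd.DataFrame({"s1": [10], "s2": [20]}, index=["a"])
        cn = pd.Series([1.0], index=["a"])
        loads = pd.Series({"s1": 1e9, "s2": 1e9})
        with pytest.raises(ValueError, match="all samples"):
            qmp_transform(counts, cn, loads, min_rarefied_reads=150)


class TestRelative:
    def test_even_column(self):
        out = to_relative(pd.DataFrame({"s": [2, 2]}))
        assert out["s"].tolist() == [0.5, 0.5]

    def test_hand_proportions(self):
        out = to_relative(pd.DataFrame({"s": [1, 3]}))
        assert out["s"].tolist() == [0.25, 0.75]

    def test_scale_invariance(self, tiny_counts):
        a = to_relative(tiny_counts)
        b = to_relative(tiny_counts * 10)
        assert np.allclose(a.values, b.values)

    def test_columns_sum_to_one(self, tiny_counts):
        out = to_relative(tiny_counts)
        assert np.allclose(out.sum(axis=0).values, 1.0, atol=1e-12)

    def test_zero_column_errors_with_sample_name(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            to_relative(counts)


class TestAggregate:
    def test_same_genus_rows_sum(self, tiny_counts, tiny_taxonomy):
        out = aggregate(tiny_counts, tiny_taxonomy, "genus")
        assert out.loc["Prevotella", "s1"] == 100

    def test_family_totals_conserved(self, tiny_counts, tiny_taxonomy):
        out = aggregate(tiny_counts, tiny_taxonomy, "family")
        assert np.array_equal(
            out.sum(axis=0).values, tiny_counts.sum(axis=0).values
        )

    def test_unclassified_bucket(self, tiny_counts, tiny_taxonomy):
        tax = tiny_taxonomy.copy()
        tax.loc["ASV_3", "genus"] = ""
        out = aggregate(tiny_counts, tax, "genus")
        assert out.loc["unclassified_genus", "s3"] == 95

    def test_unknown_taxon_errors(self, tiny_counts, tiny_taxonomy):
        with pytest.raises(ValueError, match="ASV_3"):
            aggregate(tiny_counts, tiny_taxonomy.drop("ASV_3"), "genus")
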