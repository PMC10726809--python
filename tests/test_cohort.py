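"""Aggregation, two-group/ANOVA tests, stars, histograms, mito-otyping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mitomorph.cohort import (
    aggregate_per_animal,
    anova_lsd,
    compare_two,
    histogram_percent,
    mitotype_order,
    round_percent_display,
    stars,
)
from mitomorph.errors import DegenerateDataError, DomainError, ValidationError
from mitomorph.morphometry3d import Morph3DRecord


def tidy(rows):
    return pd.DataFrame(rows, columns=["animal_id", "tissue", "group", "metric", "value"])


class TestAggregate:
    def test_simple_means(self):
        t = tidy([("A", "g", "young", "v", x) for x in (1, 2, 3)]
                 + [("B", "g", "aged", "v", x) for x in (4, 5, 6)])
        out = aggregate_per_animal(t, "v")
        assert dict(zip(out.animal_id, out.mean_value)) == {"A": 2.0, "B": 5.0}

    def test_matches_groupby_oracle_on_random_tables(self, rng):
        animals = rng.choice(list("ABCD"), size=200)
        vals = rng.normal(size=200)
        t = tidy([(a, "g", "young", "v", v) for a, v in zip(animals, vals)])
        out = aggregate_per_animal(t, "v").set_index("animal_id")["mean_value"]
        for a in "ABCD":
            assert out[a] == pytest.approx(vals[animals == a].mean(), rel=1e-12)

    def test_missing_metric_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_per_animal(tidy([("A", "g", "young", "v", 1.0)]), "other")


class TestCompareTwo:
    def test_identical_groups_give_p_one(self):
        r = compare_two([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_pooled_t_against_closed_form_oracle(self):
        # pooled t for (1,2,3,4) vs (3,4,5,6): t = -2.1909 on df = 6
        r = compare_two([1, 2, 3, 4], [3, 4, 5, 6])
        sp2 = (3 * np.var([1, 2, 3, 4], ddof=1) + 3 * np.var([3, 4, 5, 6], ddof=1)) / 6
        t_oracle = (2.5 - 4.5) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert r.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert r.statistic == pytest.approx(-2.1909, abs=1e-4)
        assert r.p_value == pytest.approx(2 * sps.t.sf(abs(t_oracle), 6), rel=1e-12)

    def test_mann_whitney_exact_small_sample(self):
        r = compare_two([1, 2], [3, 4], test="mann_whitney")
        assert r.p_value == pytest.approx(1.0 / 3.0, rel=1e-12)

    @given(st.data())
    def test_mann_whitney_exact_matches_scipy_for_untied_samples(self, data):
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, 10 - n1))
        pool = data.draw(
            st.lists(st.integers(0, 1000), min_size=n1 + n2, max_size=n1 + n2,
                     unique=True)
        )
        x, y = pool[:n1], pool[n1:]
        ours = compare_two(x, y, test="mann_whitney").p_value
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_degenerate_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            compare_two([2, 2], [3, 3])

    def test_welch_flag_changes_df(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 30.0, 50.0, 70.0]
        pooled = compare_two(a, b).p_value
        welch = compare_two(a, b, welch=True).p_value
        assert pooled != pytest.approx(welch)


class TestAnovaLsd:
    def test_identical_groups(self):
        r = anova_lsd([[1, 2], [1, 2], [1, 2]])
        assert r.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_against_sum_of_squares_oracle(self):
        groups = [[1, 2], [1, 2], [5, 6]]
        r = anova_lsd(groups)
        # explicit decomposition
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 3)
        assert r.f_statistic == pytest.approx(f_oracle, rel=1e-12)
        assert r.p_value == pytest.approx(sps.f.sf(f_oracle, 2, 3), rel=1e-12)
        msw = ssw / 3
        t01 = (np.mean(groups[0]) - np.mean(groups[1])) / math.sqrt(msw * (1 / 2 + 1 / 2))
        assert r.pairwise_p.iloc[0, 1] == pytest.approx(2 * sps.t.sf(abs(t01), 3), rel=1e-12)

    def test_two_groups_reduce_to_pooled_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0, 8.0]
        r2 = anova_lsd([a, b])
        t = compare_two(a, b)
        assert r2.f_statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert r2.p_value == pytest.approx(t.p_value, rel=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_lsd([[1, 2], [3], [4, 5]])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.03, "*"), (0.2, "ns"), (0.0001, "****"), (0.05, "*"),
         (0.001, "***"), (0.01, "**"), (0.051, "ns")],
    )
    def test_caption_mapping(self, p, expected):
        assert stars(p) == expected

    @given(p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0))
    def test_monotone(self, p1, p2):
        lo, hi = sorted((p1, p2))
        order = ["ns", "*", "**", "***", "****"]
        assert order.index(stars(lo)) >= order.index(stars(hi))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            stars(1.5)


class TestHistogramPercent:
    def test_even_split(self):
        np.testing.assert_allclose(
            histogram_percent([1, 1, 2, 2], [0, 1.5, 3]), [50.0, 50.0]
        )

    def test_all_in_one_bin_and_closed_last_edge(self):
        np.testing.assert_allclose(histogram_percent([5, 5, 5], [0, 2, 5]), [0.0, 100.0])

    @given(st.lists(st.floats(0.0, 9.99), min_size=1, max_size=60))
    def test_sums_to_100(self, values):
        pct = histogram_percent(values, np.linspace(0, 10, 6))
        assert pct.sum() == pytest.approx(100.0)
        disp = round_percent_display(pct, decimals=0)
        assert disp.sum() == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            histogram_percent([], [0, 1])


def rec(i, v):
    return Morph3DRecord(object_id=i, volume_um3=v, surface_um2=1, perimeter_um=1,
                         perimeter_total_um=1, length_um=1, sphericity=0.9, mci=1,
                         mci_variant="vincent", n_slices=1)


class TestMitotypeOrder:
    def test_sorted_by_volume(self):
        layout = mitotype_order([rec(0, 3.0), rec(1, 1.0), rec(2, 2.0)], columns=2)
        assert [o for o, _, _ in layout] == [1, 2, 0]
        assert layout[2] == (0, 1, 0)  # third object wraps to second row

    def test_ties_break_by_object_id_and_shuffle_invariance(self, rng):
        records = [rec(i, 1.0 if i < 3 else 2.0) for i in range(6)]
        base = mitotype_order(records, columns=3)
        for _ in range(5):
            shuffled = list(records)
            rng.shuffle(shuffled)
            assert mitotype_order(shuffled, columns=3) == base

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mitotype_order([], columns=3)


class TestNullCalibration:
    def test_t_on_null_cohort_uniform_p(self):
        """Aggregate-then-test under a true null keeps p roughly uniform."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            y = rng.lognormal(0, 0.3, size=3)
            a = rng.lognormal(0, 0.3, size=3)
            pvals.append(compare_two(y, a).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_mann_whitney_exact_property_all_small_n(self, rng):
        """Exact p agrees with full enumeration for every combined n <= 10."""
        for n1 in range(1, 6):
            for n2 in range(1, min(6, 11 - n1)):
                x = rng.integers(0, 6, size=n1).astype(float)
                y = rng.integers(0, 6, size=n2).astype(float)
                ours = compare_two(x, y, test="mann_whitney").p_value
                combined = np.concatenate([x, y])
                mu = n1 * n2 / 2

                def u_of(pick):
                    g1 = combined[list(pick)]
                    g2 = np.delete(combined, list(pick))
                    d = g1[:, None] - g2[None, :]
                    return (d > 0).sum() + 0.5 * (d == 0).sum()

                obs = abs(u_of(range(n1)) - mu)
                devs = [abs(u_of(p) - mu) for p in
                        itertools.combinations(range(n1 + n2), n1)]
                expect = np.mean([d >= obs - 1e-12 for d in devs])
                assert ours == pytest.approx(expect, rel=1e-12)
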