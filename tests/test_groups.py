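"""Group statistics: Duncan's multiple range test against independent
oracles (published significant-range tables, numerical integration of the
studentized-range distribution, and a direct pairwise sweep), plus the
dose-response and heat-map summaries."""

import numpy as np
import pytest
from scipy import integrate, stats

from mtintegrity import (
    TreatmentGroup,
    dose_response,
    duncan_mrt,
    heatmap_summary,
    summarize_group,
)
from mtintegrity.groups import _least_significant_ranges

# Duncan's 5% significant studentized ranges (classical published tables)
DUNCAN_TABLE_5PCT = {
    # df: {span p: q*}
    10: {2: 3.151, 3: 3.293, 4: 3.376},
    20: {2: 2.950, 3: 3.097, 4: 3.190},
    30: {2: 2.888, 3: 3.035, 4: 3.131},
}


def grp(scores, **kw):
    return TreatmentGroup(scores=np.asarray(scores, float), **kw)


def studentized_range_cdf(q, p, df):
    """Independent oracle: direct double integration of the range CDF."""

    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (p - 1)
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return p * val

    # s = sqrt(chi2_df / df)
    def outer(s):
        chi_pdf = stats.chi2.pdf(s ** 2 * df, df) * 2 * s * df
        return chi_pdf * inner(s)

    val, _ = integrate.quad(outer, 1e-6, 4, limit=200)
    return val


class TestSummarizeGroup:
    def test_no_spread(self):
        s = summarize_group(grp([60, 60, 60]))
        assert (s.mean, s.se, s.n) == (60.0, 0.0, 3)

    def test_two_scores_hand_arithmetic(self):
        s = summarize_group(grp([50, 60]))
        assert s.mean == pytest.approx(55.0)
        assert s.se == pytest.approx(5.0)

    def test_permutation_invariance(self, rng):
        scores = rng.uniform(20, 70, size=11)
        a = summarize_group(grp(scores))
        b = summarize_group(grp(rng.permutation(scores)))
        assert a.mean == pytest.approx(b.mean) and a.se == pytest.approx(b.se)

    def test_single_score_rejected(self):
        with pytest.raises(ValueError):
            summarize_group(grp([42.0]))


class TestDuncanCriticalValues:
    @pytest.mark.parametrize("df", sorted(DUNCAN_TABLE_5PCT))
    def test_matches_published_duncan_tables(self, df):
        ranges = _least_significant_ranges(4, df, mse=1.0, n_h=1.0, alpha=0.05)
        for p, expected in DUNCAN_TABLE_5PCT[df].items():
            assert ranges[p - 2] == pytest.approx(expected, abs=5e-3)

    def test_matches_numerical_integration(self):
        # protection level for span 3 at alpha 0.05 is 1 - 0.95^2
        q = _least_significant_ranges(3, 20, mse=1.0, n_h=1.0, alpha=0.05)[1]
        assert studentized_range_cdf(q, 3, 20) == pytest.approx(0.95 ** 2, abs=1e-4)


class TestDuncanLetters:
    def test_identical_constant_groups_share_letter(self):
        groups = [grp([50, 50.2, 49.8]), grp([50, 50.2, 49.8])]
        assert len(set(duncan_mrt(groups))) == 1

    def test_huge_separation_distinct_letters(self):
        groups = [grp([10, 10.01, 9.99]), grp([90, 90.01, 89.99])]
        letters = duncan_mrt(groups)
        assert not set(letters[0]) & set(letters[1])

    def test_zero_mse_with_tied_means_shares_one_letter(self):
        groups = [grp([5, 5, 5]), grp([5, 5, 5]), grp([5, 5, 5])]
        assert len(set(duncan_mrt(groups))) == 1

    def test_relabelling_invariance(self, rng):
        groups = [grp(rng.normal(m, 3, size=8)) for m in (40, 44, 52, 60)]
        letters = duncan_mrt(groups)
        for perm in ([3, 1, 0, 2], [2, 3, 1, 0]):
            permuted = duncan_mrt([groups[i] for i in perm])
            assert [permuted[perm.index(i)] for i in range(4)] == letters

    def test_matches_brute_force_pairwise_oracle(self):
        """Letters reproduce an independent range-test sweep on 50 random
        4-group datasets: the oracle recomputes every R_p from the published
        critical values and tests all pairs with the step-down rule."""
        df_expected = 20  # 4 groups x 6 -> df = 20, matching the table
        for seed in range(50):
            rng = np.random.default_rng(seed)
            means = np.sort(rng.uniform(20, 70, size=4))
            groups = [grp(rng.normal(m, rng.uniform(1, 8), size=6))
                      for m in means]
            letters = duncan_mrt(groups, alpha=0.05)

            gm = np.array([g.scores.mean() for g in groups])
            order = np.argsort(gm)
            sm = gm[order]
            mse = sum(((g.scores - g.scores.mean()) ** 2).sum()
                      for g in groups) / df_expected
            rp = {p: DUNCAN_TABLE_5PCT[df_expected][p] * np.sqrt(mse / 6.0)
                  for p in (2, 3, 4)}
            # step-down homogeneity: widest spans first
            homog = set()
            for span in (4, 3, 2):
                for lo in range(0, 4 - span + 1):
                    hi = lo + span - 1
                    if any(a <= lo and hi <= b for a, b in homog):
                        homog.add((lo, hi))
                        continue
                    if sm[hi] - sm[lo] <= rp[span]:
                        homog.add((lo, hi))
            for i in range(4):
                for j in range(i + 1, 4):
                    expect_same = (i, j) in homog or any(
                        a <= i and j <= b for a, b in homog)
                    same = bool(set(letters[order[i]]) & set(letters[order[j]]))
                    assert same == expect_same, (seed, i, j)

    def test_two_group_decision_equals_fisher_lsd(self):
        """With two groups Duncan's protection level equals alpha, so the
        decision must coincide with Fisher's LSD t-test."""
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n1, n2 = rng.integers(3, 12, size=2)
            delta = rng.uniform(0, 6)
            a = rng.normal(50, 3, size=n1)
            b = rng.normal(50 + delta, 3, size=n2)
            letters = duncan_mrt([grp(a), grp(b)], alpha=0.05)
            duncan_differ = not set(letters[0]) & set(letters[1])

            df = n1 + n2 - 2
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
            lsd = stats.t.ppf(0.975, df) * np.sqrt(sp2 * (1 / n1 + 1 / n2))
            lsd_differ = abs(a.mean() - b.mean()) > lsd
            assert duncan_differ == lsd_differ, seed

    def test_letters_transitively_consistent_on_monotone_sweep(self, rng):
        groups = [grp(rng.normal(m, 2.5, size=10))
                  for m in np.linspace(30, 60, 6)]
        letters = duncan_mrt(groups)
        order = np.argsort([g.scores.mean() for g in groups])
        shared = {(i, j): bool(set(letters[order[i]]) & set(letters[order[j]]))
                  for i in range(6) for j in range(i + 1, 6)}
        # if two means share a letter, every mean between them shares one too
        for (i, j), same in shared.items():
            if same:
                for k in range(i + 1, j):
                    assert shared[(i, k)] and shared[(k, j)]


class TestDoseResponse:
    def test_no_effect_anywhere(self, rng):
        control = grp(rng.normal(60, 1, 10), fraction="control")
        groups = [grp(rng.normal(60, 1, 10), dose=d) for d in (1.0, 3.0, 10.0)]
        table = dose_response(groups, control)
        assert table.lowest_significant_dose is None
        assert table.saturation_dose is None

    def test_forced_monotone_separation(self):
        control = grp([60, 60.1, 59.9], fraction="control")
        groups = [grp([m, m + 0.1, m - 0.1], dose=d)
                  for m, d in zip((50, 40, 30), (1.0, 3.0, 10.0))]
        table = dose_response(groups, control)
        assert table.lowest_significant_dose == 1.0
        assert table.saturation_dose == 10.0  # only the top dose, vacuously

    def test_onset_at_third_dose_with_hill_truth(self, rng):
        """Generator-truth oracle: the Hill midpoint is placed so only the
        third and later doses produce a real drop."""
        doses = (0.1, 0.3, 1.0, 3.0, 10.0)
        true_drop = {0.1: 0.0, 0.3: 0.05, 1.0: 12.0, 3.0: 22.0, 10.0: 25.0}
        control = grp(rng.normal(60, 1.2, 20), fraction="control")
        groups = [grp(rng.normal(60 - true_drop[d], 1.2, 20), dose=d)
                  for d in doses]
        table = dose_response(groups, control)
        assert table.lowest_significant_dose == 1.0

    def test_unordered_doses_rejected(self, rng):
        control = grp(rng.normal(60, 1, 5), fraction="control")
        groups = [grp(rng.normal(50, 1, 5), dose=d) for d in (3.0, 1.0, 10.0)]
        with pytest.raises(ValueError, match="increasing"):
            dose_response(groups, control)


class TestHeatmapSummary:
    def test_constant_groups_constant_matrix(self):
        groups = [grp([42.0, 42.0], tissue=t, site=s)
                  for t in ("leaf", "bark") for s in ("A", "B")]
        hm = heatmap_summary(groups)
        assert (hm.table.to_numpy() == 42.0).all()

    def test_site_potency_ordering(self, rng):
        """Mirrors the finding that one collection site is uniformly more
        active: every tissue row orders site A below site B."""
        groups = []
        for tissue in ("leaf", "bark", "root"):
            groups.append(grp(rng.normal(33, 1, 12), tissue=tissue, site="A"))
            groups.append(grp(rng.normal(52, 1, 12), tissue=tissue, site="B"))
        hm = heatmap_summary(groups)
        assert (hm.table["A"] < hm.table["B"]).all()

    def test_shape_and_labels_preserved(self, rng):
        groups = [grp(rng.uniform(30, 60, 4), tissue=t, site=s)
                  for t in ("leaf", "bark", "root") for s in ("A", "B")]
        hm = heatmap_summary(groups)
        assert hm.table.shape == (3, 2)
        assert list(hm.table.index) == ["leaf", "bark", "root"]
        assert list(hm.table.columns) == ["A", "B"]
        assert (hm.anchor_eliminated, hm.anchor_intact) == (30.0, 60.0)

    def test_missing_cell_is_nan_duplicate_rejected(self, rng):
        groups = [grp(rng.uniform(30, 60, 4), tissue="leaf", site="A"),
                  grp(rng.uniform(30, 60, 4), tissue="bark", site="B")]
        hm = heatmap_summary(groups)
        assert np.isnan(hm.table.loc["leaf", "B"])
        with pytest.raises(ValueError, match="duplicate"):
            heatmap_summary(groups + [grp([1.0, 2.0], tissue="leaf", site="A")])
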