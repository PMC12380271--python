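import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from whitecast.group_stats import (
    dunn_posthoc,
    kruskal_wallis,
    significance_stars,
    tabulate_questionnaire,
    wilcoxon_signed_rank,
)


class TestKruskalWallis:
    def test_identical_groups_are_degenerate_not_an_error(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_hand_rank_computation(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_wallis(groups)
        # ranks 1..6; rank sums 3, 7, 11; H = 12/(6*7) * sum(R^2/n) - 3*7
        h_oracle = 12 / (6 * 7) * (9 / 2 + 49 / 2 + 121 / 2) - 21
        assert res.statistic == pytest.approx(h_oracle)

    def test_fully_separated_groups_attain_maximal_h(self):
        """No overlap gives the largest H achievable for the design."""
        separated = kruskal_wallis([[1.0, 2.0], [10.0, 11.0], [20.0, 21.0]])
        h_max = max(
            kruskal_wallis(
                [list(perm[0:2]), list(perm[2:4]), list(perm[4:6])]
            ).statistic
            for perm in itertools.permutations(range(1, 7))
        )
        assert separated.statistic == pytest.approx(h_max)

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.5)]
        base = kruskal_wallis(groups)
        warped = kruskal_wallis([np.exp(g) for g in groups])
        assert warped.statistic == pytest.approx(base.statistic)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestDunnPosthoc:
    def test_identical_groups_give_unit_adjusted_p(self):
        results = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert all(r.adjusted_p == 1.0 for r in results)
        assert all(r.degenerate for r in results)

    def test_toy_z_matches_stepwise_formula(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [8.0, 9.0, 10.0]]
        results = dunn_posthoc(groups, ["a", "b", "c"])
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        mean_ranks = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
        var_unit = n * (n + 1) / 12.0  # no ties here
        z_ab = (mean_ranks[0] - mean_ranks[1]) / math.sqrt(
            var_unit * (1 / 3 + 1 / 3)
        )
        by_pair = {r.groups: r for r in results}
        assert by_pair[("a", "b")].statistic == pytest.approx(z_ab)
        raw = 2 * stats.norm.sf(abs(z_ab))
        assert by_pair[("a", "b")].p_value == pytest.approx(raw)
        assert by_pair[("a", "b")].adjusted_p == pytest.approx(
            min(1.0, 3 * raw)
        )

    def test_tie_correction_enters_the_variance(self):
        tied = [[1.0, 1.0, 2.0], [1.0, 2.0, 2.0]]
        res = dunn_posthoc(tied)[0]
        pooled = np.concatenate(tied)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (12 * (len(pooled) - 1))
        var_unit = len(pooled) * (len(pooled) + 1) / 12 - tie_term
        ranks = stats.rankdata(pooled)
        z_oracle = (ranks[:3].mean() - ranks[3:].mean()) / math.sqrt(
            var_unit * (2 / 3)
        )
        assert res.statistic == pytest.approx(z_oracle)

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.3, 1.0, 2.5)]
        results = dunn_posthoc(groups)
        raw = [r.p_value for r in results]
        adj = [r.adjusted_p for r in results]
        order = np.argsort(raw)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-12
            for i in range(len(order) - 1)
        )
        assert all(a >= p for a, p in zip(adj, raw))

    def test_two_groups_reduce_to_single_comparison(self):
        results = dunn_posthoc([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert len(results) == 1

    def test_synthetic_study_contrast_pattern(self, vivo_study):
        """On the default study the 30% vs 0% contrast is significant
        while 5% vs 0% is not — the published contrast pattern."""
        measurements, _ = vivo_study
        post = measurements[measurements["timepoint"] == "after"]
        labels, groups = zip(
            *[
                (fid, g["L"].to_numpy())
                for fid, g in post.groupby("formulation_id")
            ]
        )
        by_pair = {
            frozenset(r.groups): r for r in dunn_posthoc(groups, labels)
        }
        assert by_pair[frozenset(("zno_30", "zno_0"))].adjusted_p < 0.05
        assert by_pair[frozenset(("zno_5", "zno_0"))].adjusted_p > 0.05


def _wilcoxon_exact_enumeration(diffs, alternative="two-sided"):
    """Brute-force exact p over all 2^n sign assignments (zeros dropped)."""
    d = np.asarray([x for x in diffs if x != 0.0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    if alternative == "greater":
        return np.mean(ws >= w_obs)
    if alternative == "less":
        return np.mean(ws <= w_obs)
    return min(1.0, 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs)))


class TestWilcoxonSignedRank:
    def test_no_change_is_degenerate_and_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_six_positive_shifts_one_sided(self):
        before = np.zeros(6)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_signed_rank(before, after, alternative="greater")
        assert res.p_value == pytest.approx(1.0 / 64.0)

    @pytest.mark.parametrize("n", [5, 8, 12])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_exact_p_matches_full_enumeration(self, n, alternative):
        rng = np.random.default_rng(n)
        diffs = rng.normal(0.3, 1.0, n)
        diffs = np.where(np.abs(diffs) < 1e-6, 0.5, diffs)
        res = wilcoxon_signed_rank(
            np.zeros(n), diffs, alternative=alternative
        )
        assert res.p_value == pytest.approx(
            _wilcoxon_exact_enumeration(diffs, alternative)
        )

    def test_zero_differences_dropped_by_default(self):
        res = wilcoxon_signed_rank(
            [1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 3.0, 4.0, 5.0, 6.0]
        )
        oracle = _wilcoxon_exact_enumeration([0.0, 1.0, 1.0, 1.0, 1.0])
        assert res.p_value == pytest.approx(oracle)


class TestStars:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.2, "ns"), (0.04, "*"), (0.009, "**"),
            (0.0009, "***"), (0.00009, "****"),
        ],
    )
    def test_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestTabulateQuestionnaire:
    def _frame(self, counts, item="concern"):
        rows = []
        v = 0
        for level, n in counts.items():
            for _ in range(n):
                v += 1
                rows.append(
                    {"volunteer_id": f"S{v:02d}", "item_id": item,
                     "response": level}
                )
        return pd.DataFrame(rows)

    def test_percentages_of_thirteen(self):
        frame = self._frame({"strongly_agree": 7, "agree": 4, "disagree": 2})
        out = tabulate_questionnaire(frame).set_index("response")
        assert out.loc["strongly_agree", "pct"] == 53.8
        assert out.loc["agree", "pct"] == 30.8
        assert out.loc["disagree", "pct"] == 15.4

    def test_zero_count_level_listed_when_levels_given(self):
        frame = self._frame({"strongly_agree": 13})
        out = tabulate_questionnaire(
            frame, levels={"concern": ["strongly_agree", "strongly_disagree"]}
        ).set_index("response")
        assert out.loc["strongly_agree", "n"] == 13
        assert out.loc["strongly_agree", "pct"] == 100.0
        assert out.loc["strongly_disagree", "n"] == 0
        assert out.loc["strongly_disagree", "pct"] == 0.0

    def test_missing_responses_counted_explicitly(self):
        frame = self._frame({"agree": 12})
        frame.loc[len(frame)] = {"volunteer_id": "S13", "item_id": "concern",
                                 "response": None}
        out = tabulate_questionnaire(frame).set_index("response")
        assert out.loc["missing", "n"] == 1

    def test_duplicate_response_rejected(self):
        frame = self._frame({"agree": 2})
        frame.loc[1, "volunteer_id"] = "S01"
        with pytest.raises(ValueError, match="more than one"):
            tabulate_questionnaire(frame)
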