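"""Descriptive summaries, rank tests against enumeration oracles, ROC/Youden."""
import itertools

import numpy as np
import pytest
from scipy import stats as sps

import hepquant as hq

# ---------------------------------------------------------------------------
# independent oracles (coded against the definitions, not the implementation)


def pairwise_u(a, b):
    """U for sample a by direct pair counting, ties counting 1/2."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating label assignments,
    with U computed by pair counting on the raw values."""
    pooled = list(a) + list(b)
    na = len(a)
    mu = na * len(b) / 2.0
    u_obs = pairwise_u(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(pairwise_u(grp_a, grp_b) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_oracle(before, after):
    """Two-sided exact signed-rank p by enumerating the 2^n sign flips,
    recomputing W+ from scratch for every flip."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


def kw_h_oracle(samples):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offs = np.cumsum([0] + [len(s) for s in samples])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[offs[i]:offs[i + 1]].sum() ** 2 / len(s) for i, s in enumerate(samples)
    ) - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    return h / (1.0 - np.sum(t**3 - t) / (n**3 - n))


def kw_permutation_oracle(samples):
    """Exact permutation p = P(H >= H_obs) by enumerating all assignments."""
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    h_obs = kw_h_oracle(samples)
    count = total = 0
    for perm in set(itertools.permutations(range(len(pooled)))):
        groups, start = [], 0
        vals = pooled[list(perm)]
        for k in sizes:
            groups.append(vals[start:start + k])
            start += k
        total += 1
        if kw_h_oracle(groups) >= h_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestGroupSummary:
    def test_g1_reduction_rate_mean_sd(self, rr_and_grades):
        rr, grades = rr_and_grades
        s = hq.group_summary(rr, grades)["G1"]
        assert s.n == 14
        assert hq.round_half_up(s.mean) == 0.40
        assert hq.round_half_up(s.sd) == 0.15
        assert s.mean == pytest.approx(0.405, abs=5e-4)
        assert s.sd == pytest.approx(0.151, abs=5e-4)

    def test_medium_irs_median(self, cohort):
        rr = [r.reduction_rate for r in cohort if hq.score_lesion(r).category == "medium"]
        s = hq.summarize(rr)
        assert s.n == 7
        assert s.median == pytest.approx(0.47)

    def test_single_value(self):
        s = hq.summarize([5.0])
        assert (s.mean, s.median, s.sd) == (5.0, 5.0, None)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            hq.summarize([])

    def test_quantiles_use_weighted_average_convention(self):
        # position (n+1)p with linear interpolation
        s = hq.summarize([1.0, 2.0, 3.0, 4.0])
        assert s.q1 == pytest.approx(1.25)
        assert s.median == pytest.approx(2.5)
        assert s.q3 == pytest.approx(3.75)


class TestKruskalWallis:
    def test_all_equal_observations(self):
        res = hq.kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_sample_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # ties on purpose: draws from a small integer support
        values = rng.integers(0, 5, size=8).astype(float)
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 2, dtype=object)
        res = hq.kruskal_wallis(values, labels)  # auto -> exact permutation here
        samples = [values[labels == g] for g in ("a", "b", "c")]
        assert res.p_value == pytest.approx(kw_permutation_oracle(samples), abs=0.005)

    def test_cohort_h_and_p_match_rank_formula_oracle(self, rr_and_grades):
        rr, grades = rr_and_grades
        res = hq.kruskal_wallis(rr, grades)
        samples = [rr[grades == g] for g in ("G1", "G2", "G3")]
        h = kw_h_oracle(samples)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.p_value == pytest.approx(sps.chi2.sf(h, 2), abs=1e-10)

    def test_pairwise_table_covers_all_pairs_with_bonferroni(self, rr_and_grades):
        rr, grades = rr_and_grades
        table = hq.kruskal_wallis(rr, grades).pairwise
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["p_raw"]).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            hq.kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestMannWhitney:
    def test_complete_separation(self):
        res = hq.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0  # U counts a > b pairs

    def test_identical_samples_give_p_one(self):
        res = hq.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 7), rng.integers(2, 7)
        a = rng.integers(0, 6, size=na).astype(float)  # heavy ties
        b = rng.integers(0, 6, size=nb).astype(float)
        res = hq.mann_whitney(a, b, method="exact")
        assert res.p_value == mw_exact_oracle(a, b)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            hq.mann_whitney([], [1.0])


class TestWilcoxon:
    def test_uniform_shift_one_sided_p(self):
        before = np.arange(1.0, 11.0)
        after = before - 0.5
        res = hq.wilcoxon_signed_rank(before, after, method="exact")
        assert res.details["p_one_sided"] == pytest.approx(1.0 / 1024.0)

    def test_no_change_is_degenerate(self):
        res = hq.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        before = rng.integers(0, 8, size=8).astype(float)
        after = before + rng.integers(-3, 4, size=8)
        if np.all(after == before):
            after[0] += 1.0
        res = hq.wilcoxon_signed_rank(before, after, method="exact")
        assert res.p_value == wilcoxon_exact_oracle(before, after)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hq.wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestRoc:
    def test_perfect_separation(self):
        assert hq.roc_auc([1, 2, 3, 4], [False, False, True, True]) == 1.0

    def test_uninformative_scores(self):
        assert hq.roc_auc([5, 5, 5, 5], [False, True, False, True]) == 0.5

    def test_cohort_auc_equals_pair_enumeration(self, rr_and_grades):
        rr, grades = rr_and_grades
        pos, neg = rr[grades == "G1"], rr[grades != "G1"]
        oracle = pairwise_u(pos, neg) / (len(pos) * len(neg))
        assert hq.roc_auc(rr, grades == "G1") == pytest.approx(oracle, abs=1e-14)

    def test_label_flip_symmetry(self, rr_and_grades):
        rr, grades = rr_and_grades
        lab = grades == "G1"
        assert hq.roc_auc(rr, ~lab) == pytest.approx(1.0 - hq.roc_auc(rr, lab), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hq.roc_auc([1.0, 2.0], [True, True])


class TestYoudenCutoff:
    def test_cohort_cutoff(self, rr_and_grades):
        rr, grades = rr_and_grades
        assert hq.youden_cutoff(rr, grades == "G1") == pytest.approx(0.385)

    def test_perfect_separation_midpoint(self):
        assert hq.youden_cutoff([1.0, 2.0, 4.0, 5.0], [False, False, True, True]) == 3.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_candidate_search(self, seed):
        rng = np.random.default_rng(seed + 20)
        scores = rng.integers(0, 10, size=12).astype(float)
        labels = rng.random(12) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        pos, neg = scores[labels], scores[~labels]
        distinct = np.unique(scores)
        best = None
        for c in (distinct[:-1] + distinct[1:]) / 2.0:
            j = np.mean(pos >= c) + np.mean(neg < c) - 1.0
            spec = np.mean(neg < c)
            key = (j, spec, c)
            if best is None or key > best:
                best = key
        assert hq.youden_cutoff(scores, labels) == best[2]


class TestOperatingPoint:
    def test_cohort_operating_point(self, rr_and_grades):
        rr, grades = rr_and_grades
        op = hq.operating_point(rr, grades == "G1", 0.385)
        assert op.sensitivity == pytest.approx(50.0)
        assert op.specificity == pytest.approx(100.0)
        assert op.ppv == pytest.approx(100.0)
        assert round(op.npv) == 73

    def test_cutoff_below_all_scores(self):
        op = hq.operating_point([1, 2, 3, 4], [False, True, False, True], 0.0)
        assert (op.sensitivity, op.specificity) == (100.0, 0.0)
        assert op.npv is None

    def test_cutoff_above_all_scores(self):
        op = hq.operating_point([1, 2, 3, 4], [False, True, False, True], 10.0)
        assert (op.sensitivity, op.specificity) == (0.0, 100.0)
        assert op.ppv is None

    def test_sens_nonincreasing_spec_nondecreasing_in_cutoff(self, rr_and_grades):
        rr, grades = rr_and_grades
        cuts = np.linspace(rr.min() - 0.01, rr.max() + 0.01, 25)
        ops = [hq.operating_point(rr, grades == "G1", c) for c in cuts]
        sens = [o.sensitivity for o in ops]
        spec = [o.specificity for o in ops]
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)

    def test_youden_identity(self, rr_and_grades):
        rr, grades = rr_and_grades
        res = hq.roc_analysis(rr, grades == "G1")
        assert res.youden_j == pytest.approx(
            res.sensitivity / 100 + res.specificity / 100 - 1.0
        )
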