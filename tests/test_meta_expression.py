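import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xtalk.mcode_clustering import ComplexResult
from xtalk.meta_expression import (
    ExpressionStudy,
    call_degs,
    combine_studies,
    differential_expression,
    fisher_combine,
    map_degs_to_clusters,
    pd_clusters,
)
from xtalk.synthetic_data import generate_expression


def make_study(case, ctrl, study_id="s1"):
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    cols = [f"c{i}" for i in range(case.shape[1])] + \
           [f"k{i}" for i in range(ctrl.shape[1])]
    matrix = pd.DataFrame(np.hstack([case, ctrl]),
                          index=[f"g{i}" for i in range(case.shape[0])],
                          columns=cols)
    groups = pd.Series(["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
                       index=cols)
    return ExpressionStudy(matrix, groups, study_id)


class TestDifferentialExpression:
    def test_identical_groups_give_null_statistic(self):
        study = make_study([[1, 1, 1]], [[1, 1, 1]])
        res = differential_expression(study)
        assert res.loc["g0", "statistic"] == 0.0
        assert res.loc["g0", "p"] == 1.0

    def test_exact_separation_hits_epsilon_guard(self):
        study = make_study([[2, 2, 2]], [[1, 1, 1]])
        res = differential_expression(study)
        assert res.loc["g0", "p"] < 1e-15

    def test_matches_independent_t_test(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(size=(200, 6)), rng.normal(size=(200, 8)))
        res = differential_expression(study)
        t_ref, p_ref = stats.ttest_ind(
            study.matrix.iloc[:, :6], study.matrix.iloc[:, 6:], axis=1,
            equal_var=True,
        )
        np.testing.assert_allclose(res["statistic"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_small_group_rejected(self):
        study = make_study([[1.0]], [[1, 2, 3]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(study)

    def test_variance_moderation_shrinks_extreme_statistics(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(300, 8))
        data[0, :4] += 2.0
        data[0] *= 0.01  # tiny-variance gene with a shift
        study = make_study(data[:, :4], data[:, 4:])
        plain = differential_expression(study)
        moderated = differential_expression(study, moderate_variance=True)
        assert abs(moderated.loc["g0", "statistic"]) < abs(plain.loc["g0", "statistic"])


class TestFisherCombine:
    def test_single_study_identity(self):
        for p in (0.01, 0.3, 0.77):
            _, df, combined = fisher_combine([p])
            assert df == 2
            assert combined == pytest.approx(p, abs=1e-12)

    def test_two_half_p_values_closed_form(self):
        x2, df, combined = fisher_combine([0.5, 0.5])
        assert df == 4
        assert x2 == pytest.approx(-2 * (math.log(0.5) + math.log(0.5)))
        # df-4 chi-square upper tail: e^{-x/2} (1 + x/2)
        expected = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert combined == pytest.approx(expected, abs=1e-12)
        assert combined == pytest.approx(0.5966, abs=1e-4)

    def test_all_ones_combine_to_one(self):
        x2, _, combined = fisher_combine([1.0, 1.0, 1.0])
        assert x2 == 0.0
        assert combined == 1.0

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            x2, _, combined = fisher_combine([0.0, 0.5])
        assert math.isfinite(x2) and 0 <= combined <= 1
        assert "clamp" in caplog.text

    @pytest.mark.parametrize("bad", [[1.5], [-0.1], []])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 6))
            x2, _, combined = fisher_combine(p)
            ref = stats.combine_pvalues(p, method="fisher")
            assert x2 == pytest.approx(ref.statistic)
            assert combined == pytest.approx(ref.pvalue)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, p_list, rnd):
        _, _, base = fisher_combine(p_list)
        shuffled = list(p_list)
        rnd.shuffle(shuffled)
        assert fisher_combine(shuffled)[2] == pytest.approx(base, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
           st.integers(0, 5), st.floats(0.1, 0.99))
    def test_lowering_any_p_never_raises_combined_p(self, p_list, idx, factor):
        _, _, base = fisher_combine(p_list)
        lowered = list(p_list)
        i = idx % len(lowered)
        lowered[i] = lowered[i] * factor
        assert fisher_combine(lowered)[2] <= base + 1e-12


class TestCombineStudies:
    def test_missing_genes_combined_over_available_studies(self):
        r1 = pd.DataFrame({"statistic": [1.0, 1.0], "p": [0.1, 0.2]},
                          index=["a", "b"])
        r2 = pd.DataFrame({"statistic": [1.0], "p": [0.3]}, index=["a"])
        meta = combine_studies({"s1": r1, "s2": r2})
        assert meta.loc["a", "df"] == 4
        assert meta.loc["b", "df"] == 2
        assert meta.loc["b", "combined_p"] == pytest.approx(0.2, abs=1e-12)

    def test_combined_p_matches_fisher_combine(self):
        r1 = pd.DataFrame({"statistic": [0.5], "p": [0.04]}, index=["a"])
        r2 = pd.DataFrame({"statistic": [0.5], "p": [0.6]}, index=["a"])
        meta = combine_studies({"s1": r1, "s2": r2})
        assert meta.loc["a", "combined_p"] == pytest.approx(
            fisher_combine([0.04, 0.6])[2]
        )


class TestCallDegs:
    def test_strict_inequality_at_alpha(self):
        meta = pd.DataFrame({"combined_p": [0.05, 0.049999]}, index=["a", "b"])
        assert call_degs(meta, alpha=0.05) == {"b"}

    def test_bh_mode_is_more_conservative(self):
        rng = np.random.default_rng(4)
        meta = pd.DataFrame({"combined_p": rng.uniform(size=500)},
                            index=[f"g{i}" for i in range(500)])
        assert call_degs(meta, 0.05, adjust="bh") <= call_degs(meta, 0.05)

    def test_null_call_rate_matches_alpha(self):
        studies, _ = generate_expression(
            [f"g{i}" for i in range(1000)], n_studies=3, n_per_group=10,
            deg_fraction=0.1, delta=0.0, noise_sd=1.0, seed=5,
        )
        meta = combine_studies(
            {s.study_id: differential_expression(s) for s in studies}
        )
        rate = len(call_degs(meta, 0.05)) / len(meta)
        assert 0.030 <= rate <= 0.070  # 0.05 +/- ~4 binomial SE at n=1000


def make_complex(members, rank):
    return ComplexResult(members=frozenset(members), seed=sorted(members)[0],
                         score=1.0, rank=rank, edge_count=0)


class TestMapDegsToClusters:
    def test_no_overlap_yields_no_pd_clusters(self):
        mapped = map_degs_to_clusters([make_complex({"a", "b"}, 1)], {"z"})
        assert pd_clusters(mapped) == []

    def test_full_overlap_counts_every_member(self):
        c = make_complex({"a", "b", "c"}, 1)
        mapped = map_degs_to_clusters([c], {"a", "b", "c"})
        assert mapped[0]["n_hits"] == 3 and mapped[0]["is_pd"]

    def test_hand_built_overlap_of_seven(self):
        members = {f"m{i}" for i in range(20)}
        degs = {f"m{i}" for i in range(7)} | {"x", "y"}
        mapped = map_degs_to_clusters([make_complex(members, 1)], degs, min_hits=5)
        assert mapped[0]["n_hits"] == 7 and mapped[0]["is_pd"]

    def test_min_hits_threshold(self):
        c = make_complex({"a", "b"}, 1)
        assert not map_degs_to_clusters([c], {"a"}, min_hits=2)[0]["is_pd"]
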