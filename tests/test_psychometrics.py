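import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casco import (
    PsychometricsError,
    bonferroni,
    concurrent_validity,
    cronbach_alpha,
    discriminant_test,
    rank_correlation,
)


def alpha_oracle(mat):
    """Independent variance-formula evaluation of Cronbach's alpha."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    item_vars = [np.mean((mat[:, j] - mat[:, j].mean()) ** 2) for j in range(k)]
    totals = mat.sum(axis=1)
    total_var = np.mean((totals - totals.mean()) ** 2)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


def midrank(values):
    """Brute-force mid-ranks (average rank over ties)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def test_alpha_identical_columns_is_one():
    mat = np.tile(np.arange(1, 6, dtype=float)[:, None], (1, 3))
    assert cronbach_alpha(mat).alpha == pytest.approx(1.0)


def test_alpha_frozen_small_matrix():
    # hand-evaluated: item variances 1.25 + 1.25, total variance 5.0
    mat = [[1, 2], [2, 3], [3, 4], [4, 5]]
    assert alpha_oracle(mat) == pytest.approx(1.0)
    assert cronbach_alpha(mat).alpha == pytest.approx(1.0, abs=1e-12)


def test_alpha_listwise_deletion_and_errors():
    mat = pd.DataFrame({"a": [1, 2, 3, np.nan], "b": [2, 3, 4, 5]})
    result = cronbach_alpha(mat)
    assert result.n_used == 3
    with pytest.raises(PsychometricsError):
        cronbach_alpha([[1], [2]])
    with pytest.raises(PsychometricsError):
        cronbach_alpha([[1, 2]])
    with pytest.raises(PsychometricsError):
        cronbach_alpha([[1, 2], [2, 1]])  # zero total variance


@given(st.integers(0, 10 ** 6))
@settings(max_examples=25, deadline=None)
def test_alpha_shift_invariance(seed):
    rng = np.random.default_rng(seed)
    mat = rng.normal(size=(12, 4))
    shifted = mat + rng.normal(size=4)  # constant per item
    a1 = cronbach_alpha(mat).alpha
    a2 = cronbach_alpha(shifted).alpha
    assert a1 == pytest.approx(a2, abs=1e-9)


def test_ttest_frozen_small_vectors():
    """Textbook pooled-variance formula as the oracle."""
    a, b = [1, 2, 3, 4], [3, 4, 5, 6]
    sa2 = np.var(a, ddof=1)
    sb2 = np.var(b, ddof=1)
    sp2 = ((len(a) - 1) * sa2 + (len(b) - 1) * sb2) / (len(a) + len(b) - 2)
    t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    result = discriminant_test(a, b, equal_var=True)
    assert result.t_stat == pytest.approx(t_oracle)
    assert result.df == pytest.approx(6)
    assert result.effect_r == pytest.approx(
        math.sqrt(t_oracle ** 2 / (t_oracle ** 2 + 6))
    )


def test_ttest_identical_groups_and_shift():
    same = discriminant_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert same.t_stat == pytest.approx(0.0)
    assert same.ci_low < 0 < same.ci_high
    shifted = discriminant_test([3, 4, 5, 6], [1, 2, 3, 4])
    assert shifted.t_stat > 0


def test_ttest_antisymmetric_in_group_order():
    rng = np.random.default_rng(5)
    a, b = rng.normal(10, 3, 30), rng.normal(12, 6, 20)
    fwd = discriminant_test(a, b)
    rev = discriminant_test(b, a)
    assert fwd.t_stat == pytest.approx(-rev.t_stat)
    assert fwd.p_value == pytest.approx(rev.p_value)
    assert fwd.ci_low == pytest.approx(-rev.ci_high)


def test_ttest_needs_two_per_group():
    with pytest.raises(PsychometricsError):
        discriminant_test([1], [1, 2])


def test_spearman_extremes():
    x = [1, 2, 3, 4, 5]
    assert rank_correlation(x, [2, 4, 6, 8, 10]).r == pytest.approx(1.0)
    assert rank_correlation(x, [10, 8, 6, 4, 2]).r == pytest.approx(-1.0)


def test_spearman_tied_toy_matches_midrank_oracle():
    x, y = [1, 2, 2, 3], [1, 3, 2, 4]
    rx, ry = midrank(x), midrank(y)
    r_oracle = np.corrcoef(rx, ry)[0, 1]
    assert rank_correlation(x, y).r == pytest.approx(r_oracle, abs=1e-12)


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    base = rank_correlation(x, y).r
    assert rank_correlation(np.exp(x), y).r == pytest.approx(base)
    assert rank_correlation(x, y ** 3 + 5 * y).r == pytest.approx(base)


def test_spearman_errors():
    with pytest.raises(PsychometricsError):
        rank_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(PsychometricsError):
        rank_correlation([1, 2], [1, 2])


def test_bonferroni_decisions():
    assert list(bonferroni([0.02, 0.04], 0.05)) == [True, False]
    assert list(bonferroni([0.04], 0.05)) == [True]   # m = 1: raw test
    assert not bonferroni([1.0, 1.0, 1.0], 0.05).any()
    with pytest.raises(PsychometricsError):
        bonferroni([])
    with pytest.raises(PsychometricsError):
        bonferroni([1.5])


def test_concurrent_validity_self_criterion_and_flags():
    rng = np.random.default_rng(8)
    totals = rng.uniform(0, 100, 60)
    scores = pd.DataFrame({"total": totals})
    crits = pd.DataFrame({"self": totals, "noise": rng.normal(size=60)})
    results = concurrent_validity(scores, crits)
    by_name = {r.name: r for r in results}
    assert by_name["self"].r == pytest.approx(1.0)
    assert by_name["self"].significant is True


def test_concurrent_validity_type_one_control_under_permutation():
    """Independent criterion: family-wise false-positive rate ~ nominal 0.05."""
    rng = np.random.default_rng(123)
    n, reps = 50, 200
    false_hits = 0
    for _ in range(reps):
        totals = rng.uniform(0, 100, n)
        crit = rng.permutation(totals)
        scores = pd.DataFrame({"total": totals})
        results = concurrent_validity(
            scores, pd.DataFrame({"perm": crit}), mcasco_total=None
        )
        if results[0].significant:
            false_hits += 1
    # binomial 99.9% upper bound around 0.05 at 200 reps
    assert false_hits / reps <= 0.05 + 3.29 * math.sqrt(0.05 * 0.95 / reps)
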