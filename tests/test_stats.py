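"""Rank tests against enumeration/permutation oracles; battery structure."""

from itertools import combinations as iter_combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fibrequant import (
    PipelineConfig,
    SimulationConfig,
    bonferroni_alpha,
    mann_whitney,
    run_study_battery,
    simulate_summary_cohort,
    spearman,
)
from fibrequant.stats import wilcoxon_signed_rank

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating every assignment of the pooled
    values to the two groups (tie-free data: all assignments equally likely).
    Returns (U_a, p)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_of(a, b)
    n1n2 = n1 * len(b)
    side_obs = min(u_obs, n1n2 - u_obs)
    hits = total = 0
    for idx in iter_combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(ga, gb)
        hits += min(u, n1n2 - u) <= side_obs
        total += 1
    return u_obs, hits / total


def test_identical_constant_samples():
    r = mann_whitney([5, 5, 5], [5, 5, 5])
    assert r.statistic == pytest.approx(4.5)  # n1*n2/2
    assert r.p_value == 1.0


def test_disjoint_tiny_samples_exact():
    r = mann_whitney([1, 2], [3, 4], mode="exact")
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(1 / 3)


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 5)])
def test_exact_p_matches_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    a = rng.normal(0, 1, n1)
    b = rng.normal(0.5, 1, n2)
    r = mann_whitney(a, b, mode="exact")
    u_oracle, p_oracle = mwu_enumeration_oracle(a, b)
    assert r.statistic == pytest.approx(u_oracle)
    assert r.p_value == pytest.approx(p_oracle)


def test_exact_and_approx_agree_at_moderate_n():
    rng = np.random.default_rng(0)
    for _ in range(5):
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.3, 1, 7)
        p_ex = mann_whitney(a, b, mode="exact").p_value
        p_ap = mann_whitney(a, b, mode="approx").p_value
        assert abs(p_ex - p_ap) < 0.02


def test_exact_with_ties_uses_conditional_enumeration():
    r = mann_whitney([1, 2, 2], [2, 3, 4], mode="exact")
    # oracle: exhaustive permutation of group labels conditional on ties
    u_null = []
    pooled = [1, 2, 2, 2, 3, 4]
    for idx in iter_combinations(range(6), 3):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(6) if i not in idx]
        u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
        u_null.append(u)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in [1, 2, 2] for y in [2, 3, 4])
    side = min(u_obs, 9 - u_obs)
    p_oracle = np.mean([min(u, 9 - u) <= side for u in u_null])
    assert r.p_value == pytest.approx(p_oracle)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n1=st.integers(2, 8), n2=st.integers(2, 8), seed=st.integers(0, 1000)
)
def test_u_statistics_sum_to_n1n2(n1, n2, seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=n1), rng.normal(size=n2)
    u_ab = mann_whitney(a, b).statistic
    u_ba = mann_whitney(b, a).statistic
    assert u_ab + u_ba == pytest.approx(n1 * n2)
    assert 0 <= u_ab <= n1 * n2


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_perfect_monotone_relationships():
    x = [3.0, 1.0, 4.0, 1.5, 9.0]
    r = spearman(x, np.exp(x))
    assert r.statistic == pytest.approx(1.0)
    r2 = spearman([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5])
    assert r2.statistic == pytest.approx(-1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman(x, y).statistic
    assert spearman(np.exp(x), y).statistic == pytest.approx(base)
    assert spearman(x, y ** 3).statistic == pytest.approx(base)


def test_zero_variance_rejected():
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_t_approximation_close_to_permutation_oracle():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    r = spearman(x, y, method="t")
    # oracle: 1e5 random permutations, ranks computed by double argsort
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    prng = np.random.default_rng(99)
    perms = np.argsort(prng.random((100_000, 10)), axis=1)
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    null = (ry_c[perms] @ rx_c) / np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    p_perm = np.mean(np.abs(null) >= abs(rho_obs) - 1e-12)
    assert abs(r.p_value - p_perm) < 0.02


def test_builtin_permutation_method_matches_t():
    rng = np.random.default_rng(11)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    p_t = spearman(x, y, method="t").p_value
    p_perm = spearman(x, y, method="permutation", n_permutations=20_000,
                      rng=np.random.default_rng(1)).p_value
    assert abs(p_t - p_perm) < 0.03


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


def test_bonferroni_thresholds():
    exact, reported = bonferroni_alpha(0.05, 7)
    assert exact == pytest.approx(0.05 / 7)
    assert reported == 0.007
    assert bonferroni_alpha(0.05, 1) == (0.05, 0.05)
    assert bonferroni_alpha(0.05, 10)[0] == pytest.approx(0.005)
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# the study battery
# ---------------------------------------------------------------------------


def test_battery_structure_and_thresholds():
    summaries = simulate_summary_cohort(
        SimulationConfig(n_participants=20), np.random.default_rng(0)
    )
    results = run_study_battery(summaries)
    fams = {r.family for r in results}
    assert fams == {"tissue", "sex", "age"}
    assert sum(r.family == "tissue" for r in results) == 8
    assert sum(r.family == "sex" for r in results) == 24
    assert sum(r.family == "age" for r in results) == 14
    for r in results:
        if r.family == "age":
            assert r.alpha_adjusted == pytest.approx(0.05 / 7)
        else:
            assert r.alpha_adjusted == pytest.approx(0.05)
        if not r.error:
            assert 0.0 <= r.p_value <= 1.0
            assert r.significant == (r.p_value < r.alpha_adjusted)


def test_planted_tissue_difference_is_detected():
    """Connective density ~4x myocyte density: the tissue test must fire."""
    cfg = SimulationConfig(
        n_participants=30,
        fibre_density_per_mm2={"connective": 800.0, "myocyte": 200.0},
    )
    summaries = simulate_summary_cohort(cfg, np.random.default_rng(3))
    res = {r.name: r for r in run_study_battery(summaries)}
    r = res["tissue:density"]
    assert r.significant
    assert r.p_value < 0.001


def test_wilcoxon_tissue_alternative_runs():
    summaries = simulate_summary_cohort(
        SimulationConfig(n_participants=16), np.random.default_rng(4)
    )
    cfg = PipelineConfig(tissue_test="wilcoxon")
    res = [r for r in run_study_battery(summaries, cfg) if r.family == "tissue"]
    assert all(r.test == "wilcoxon" for r in res)
    assert res[0].significant  # planted density difference

    r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p_value == 1.0


def test_battery_records_errors_and_continues():
    summaries = simulate_summary_cohort(
        SimulationConfig(n_participants=4), np.random.default_rng(5)
    )
    results = run_study_battery(summaries)  # 2 per sex: age tests impossible
    age_errors = [r for r in results if r.family == "age" and r.error]
    assert len(age_errors) == 14
    assert all(not r.significant for r in age_errors)
    assert any(r.family == "tissue" and not r.error for r in results)
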