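"""Statistical suite: oracle equivalence, invariants and calibration checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phagecodon import stats as ps
from phagecodon.errors import UndefinedMetricError, ValidationError


# ---------------------------------------------------------------------------
# Kruskal-Wallis + rank effect sizes


def test_kw_identical_groups_gives_zero_H():
    kw = ps.kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
    assert kw.H == 0 and kw.p == 1.0


def test_kw_matches_bruteforce_formula(rng):
    groups = [rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)]
    kw = ps.kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    h = 12 / (N * (N + 1)) * sum(
        8 * (ranks[i * 8 : (i + 1) * 8].mean() - (N + 1) / 2) ** 2 for i in range(3)
    )
    assert kw.H == pytest.approx(h, abs=1e-10)  # no ties: correction vanishes


def test_kw_agrees_with_scipy_with_ties(rng):
    groups = [rng.integers(0, 5, size=12).astype(float) for _ in range(3)]
    kw = ps.kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert kw.H == pytest.approx(ref.statistic, abs=1e-10)
    assert kw.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_kw_two_groups_equals_squared_mannwhitney_z(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=12)
    kw = ps.kruskal_wallis([x, y])
    n1, n2 = len(x), len(y)
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    mu = n1 * n2 / 2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    N = n1 + n2
    sigma = math.sqrt(n1 * n2 / 12 * ((N + 1) - tie / (N * (N - 1))))
    z = (u - mu) / sigma
    assert kw.H == pytest.approx(z**2, abs=1e-9)


def test_rank_effect_size_inequality(rng):
    groups = [rng.normal(loc=i, size=10) for i in range(3)]
    kw = ps.kruskal_wallis(groups)
    assert kw.eta2 >= kw.epsilon2


# ---------------------------------------------------------------------------
# Dunn


def test_dunn_z_null_case():
    contrasts = ps.dunn_posthoc([[1, 4, 5, 8], [2, 3, 6, 7]], ["a", "b"])
    assert contrasts[0].z == pytest.approx(0.0)
    assert contrasts[0].p_raw == pytest.approx(1.0)


def test_dunn_posthoc_z_matches_direct_formula(rng):
    groups = [rng.normal(size=10), rng.normal(size=14), rng.normal(size=9)]
    out = ps.dunn_posthoc(groups, ["g1", "g2", "g3"])
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    bounds = np.cumsum([0] + [len(g) for g in groups])
    means = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(3)]
    sizes = [len(g) for g in groups]
    for c, (i, j) in zip(out, [(0, 1), (0, 2), (1, 2)]):
        se = math.sqrt(N * (N + 1) / 12 * (1 / sizes[i] + 1 / sizes[j]))
        assert c.z == pytest.approx((means[i] - means[j]) / se, abs=1e-10)
        assert c.p_holm >= c.p_raw
        assert c.p_holm <= c.p_bonferroni + 1e-15


def test_dunn_direction_names_higher_mean_rank():
    out = ps.dunn_posthoc([[1, 2, 3], [10, 11, 12]], ["low", "high"])
    assert out[0].direction == "high > low"


# ---------------------------------------------------------------------------
# Mann-Whitney and Cliff's delta


def test_mann_whitney_exact_small_sample():
    u, p = ps.mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)  # 2/20 splits as extreme


def test_mann_whitney_identical_samples():
    _, p = ps.mann_whitney([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_mann_whitney_exact_vs_asymptotic_agree(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)  # n1*n2 > 400 -> asymptotic path
    _, p_asym = ps.mann_whitney(x, y)
    p_exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p_asym == pytest.approx(p_exact, abs=0.005)


def test_cliffs_delta_complete_separation():
    d, mag = ps.cliffs_delta([1, 2, 3], [4, 5, 6])
    assert d == -1.0 and mag == "large"


def test_cliffs_delta_symmetry():
    d, mag = ps.cliffs_delta([1, 2, 3], [1, 2, 3])
    assert d == 0.0 and mag == "negligible"


@pytest.mark.parametrize(
    "value,expected",
    [(0.30, "small"), (0.40, "moderate"), (0.50, "large"), (0.10, "negligible")],
)
def test_cliffs_magnitude_thresholds(value, expected):
    assert ps.cliffs_magnitude(value) == expected


def test_cliffs_delta_matches_double_loop_oracle(rng):
    x = rng.integers(0, 6, size=23).astype(float)
    y = rng.integers(0, 6, size=17).astype(float)
    wins = sum(int(xi > yj) - int(xi < yj) for xi in x for yj in y)
    d, _ = ps.cliffs_delta(x, y)
    assert d == pytest.approx(wins / (len(x) * len(y)), abs=1e-12)


# ---------------------------------------------------------------------------
# Holm / BH


def _holm_oracle(p):
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _bh_oracle(p):
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adj[idx] = min(1.0, running)
    return adj


def test_holm_single_value_identity():
    assert ps.holm_adjust([0.002])[0] == pytest.approx(0.002)


def test_corrections_match_definition_oracles(rng):
    p = rng.uniform(size=20)
    assert ps.holm_adjust(p) == pytest.approx(_holm_oracle(p), abs=1e-12)
    assert ps.bh_adjust(p) == pytest.approx(_bh_oracle(p), abs=1e-12)


def test_corrections_reject_out_of_range():
    with pytest.raises(ValidationError):
        ps.holm_adjust([0.5, 1.2])
    with pytest.raises(ValidationError):
        ps.bh_adjust([-0.1])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
def test_corrections_dominate_raw_and_preserve_order(p):
    holm = ps.holm_adjust(p)
    bh = ps.bh_adjust(p)
    assert np.all(holm >= np.asarray(p) - 1e-15)
    assert np.all(bh >= np.asarray(p) - 1e-15)
    assert np.all(holm <= 1.0) and np.all(bh <= 1.0)
    # adjusted values are ordered consistently with the raw values
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(np.asarray(holm)[order]) >= -1e-15)
    assert np.all(np.diff(np.asarray(bh)[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Spearman machinery


def test_spearman_monotone_extremes():
    x = np.arange(10, dtype=float)
    assert ps.spearman(x, x).rho == pytest.approx(1.0)
    assert ps.spearman(x, -x).rho == pytest.approx(-1.0)


def test_spearman_constant_vector_rejected():
    with pytest.raises(UndefinedMetricError):
        ps.spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_bootstrap_ci_deterministic_under_seed(rng):
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    assert ps.bootstrap_ci(x, y, B=200, seed=5) == ps.bootstrap_ci(x, y, B=200, seed=5)
    assert ps.bootstrap_ci(x, y, B=200, seed=5) != ps.bootstrap_ci(x, y, B=200, seed=6)


def test_bootstrap_ci_covers_true_rho():
    # bivariate normal with rho 0.6: the 95% percentile CI should cover the
    # population Spearman value (~0.58) in nearly all seeded replications
    rho_true = 0.6
    rho_s = 6 / math.pi * math.asin(rho_true / 2)  # Pearson->Spearman for normals
    master = np.random.default_rng(99)
    covered = 0
    reps = 60
    for _ in range(reps):
        z = master.multivariate_normal(
            [0, 0], [[1, rho_true], [rho_true, 1]], size=50
        )
        lo, hi = ps.bootstrap_ci(z[:, 0], z[:, 1], B=200, seed=int(master.integers(2**31)))
        covered += lo <= rho_s <= hi
    assert covered / reps >= 0.90


def test_partial_spearman_independent_covariate_is_noop(rng):
    n = 200
    x = rng.normal(size=n)
    y = 0.6 * x + rng.normal(size=n)
    z = rng.normal(size=n)  # independent of both
    raw = ps.spearman(x, y).rho
    partial = ps.partial_spearman(x, y, z[:, None]).rho
    assert abs(partial - raw) < 0.05


def test_partial_spearman_perfect_confounder_zeroes_rho(rng):
    n = 200
    z = rng.normal(size=n)
    x = 0.8 * z + 0.2 * rng.normal(size=n)
    y = z.copy()  # y IS the covariate
    partial = ps.partial_spearman(x, y, z[:, None])
    assert abs(partial.rho) < 0.05


def test_partial_spearman_collinear_covariates_rejected(rng):
    n = 50
    z = rng.normal(size=n)
    Z = np.column_stack([z, 2 * z])  # identical ranks -> rank-deficient
    with pytest.raises(ValidationError, match="collinear"):
        ps.partial_spearman(rng.normal(size=n), rng.normal(size=n), Z)


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare


def test_srh_constant_values_all_zero():
    res = ps.scheirer_ray_hare(
        [3.0] * 8, ["a", "a", "b", "b"] * 2, ["x"] * 4 + ["y"] * 4
    )
    assert res.h_factor_a == res.h_factor_b == res.h_interaction == 0


def test_srh_hand_computed_2x2_example():
    # values 1..8 are their own ranks; SS_total = 42, MS_total = 6;
    # A means 3.5/5.5 -> SS_A = 8; B means 2.5/6.5 -> SS_B = 32;
    # cell means 1.5/3.5/5.5/7.5 -> SS_cells = 40 -> SS_AB = 0
    values = [1, 2, 3, 4, 5, 6, 7, 8]
    a = ["a", "a", "b", "b", "a", "a", "b", "b"]
    b = ["x", "x", "x", "x", "y", "y", "y", "y"]
    res = ps.scheirer_ray_hare(values, a, b)
    assert res.h_factor_a == pytest.approx(8 / 6, abs=1e-10)
    assert res.h_factor_b == pytest.approx(32 / 6, abs=1e-10)
    assert res.h_interaction == pytest.approx(0.0, abs=1e-10)
    assert res.df_a == res.df_b == res.df_interaction == 1


def test_srh_detects_pure_factor_a_shift(rng):
    n = 40
    a = np.repeat(["lo", "hi"], n)
    b = np.tile(np.repeat(["x", "y"], n // 2), 2)
    values = rng.normal(size=2 * n) + np.where(a == "hi", 3.0, 0.0)
    res = ps.scheirer_ray_hare(values, a, b)
    assert res.h_factor_a > 10 * max(res.h_factor_b, res.h_interaction)
    assert res.p_factor_a < 0.001


def test_srh_single_level_factor_rejected():
    with pytest.raises(ValidationError):
        ps.scheirer_ray_hare([1, 2, 3], ["a", "a", "a"], ["x", "y", "x"])


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


def _exhaustive_permanova_p(X, labels):
    """Exact permutation p by enumerating every labelling of the same sizes."""
    from phagecodon.stats import _permanova_ss, _squared_distances, _zscore

    Xz = _zscore(np.asarray(X, dtype=float))
    d2 = _squared_distances(Xz)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    n = len(labels)
    k = len(groups)
    n1 = int(np.sum(labels == groups[0]))

    def f_stat(lab):
        ind = [(lab == g).astype(float) for g in groups]
        ssb, ssw = _permanova_ss(d2, ind)
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(labels)
    count = 0
    total = 0
    for subset in itertools.combinations(range(n), n1):
        lab = np.array([groups[1]] * n, dtype=object)
        lab[list(subset)] = groups[0]
        total += 1
        if f_stat(lab) >= f_obs - 1e-12:
            count += 1
    return count / total, f_obs


def test_permanova_small_n_matches_exhaustive_enumeration(rng):
    X = rng.normal(size=(6, 3))
    X[:3] += 1.0
    labels = ["a"] * 3 + ["b"] * 3
    p_exact, f_exact = _exhaustive_permanova_p(X, labels)
    res = ps.permanova(X, labels, n_perm=999, seed=1, with_dispersion=False)
    assert res.pseudo_f == pytest.approx(f_exact, abs=1e-10)
    assert res.p == pytest.approx(p_exact, abs=0.1)


def test_permanova_statistic_matches_skbio(rng):
    skbio_distance = pytest.importorskip("skbio").DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova
    from phagecodon.stats import _squared_distances, _zscore

    X = rng.normal(size=(20, 4))
    labels = ["a"] * 10 + ["b"] * 10
    Xz = _zscore(X)
    dm = skbio_distance(np.sqrt(_squared_distances(Xz)), ids=[str(i) for i in range(20)])
    ref = skbio_permanova(dm, grouping=labels, permutations=99)
    res = ps.permanova(X, labels, n_perm=99, seed=0, with_dispersion=False)
    assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-8)


def test_permanova_detects_strong_shift(rng):
    X = rng.normal(size=(200, 5))
    X[:100, 0] += 3.0
    labels = ["a"] * 100 + ["b"] * 100
    res = ps.permanova(X, labels, n_perm=999, seed=3, with_dispersion=False)
    assert res.p == pytest.approx(0.001)
    assert res.r2 > 0.1


def test_permanova_null_p_roughly_uniform():
    rng = np.random.default_rng(11)
    pvals = []
    for _ in range(200):
        X = rng.normal(size=(24, 3))
        labels = ["a"] * 12 + ["b"] * 12
        res = ps.permanova(
            X, labels, n_perm=199, seed=int(rng.integers(2**31)), with_dispersion=False
        )
        pvals.append(res.p)
    d = sps.kstest(pvals, "uniform").statistic
    assert d < 0.1


def test_permanova_subsample_seeded_and_bounded(rng):
    X = rng.normal(size=(60, 3))
    labels = ["a"] * 30 + ["b"] * 30
    r1 = ps.permanova(X, labels, n_perm=99, subsample_n=10, seed=7, with_dispersion=False)
    r2 = ps.permanova(X, labels, n_perm=99, subsample_n=10, seed=7, with_dispersion=False)
    assert (r1.pseudo_f, r1.p) == (r2.pseudo_f, r2.p)
    with pytest.raises(ValidationError):
        ps.permanova(X, labels, subsample_n=31, seed=7)


def test_permdisp_detects_scale_difference(rng):
    X = np.vstack([rng.normal(size=(100, 4)), 3.0 * rng.normal(size=(100, 4))])
    labels = ["tight"] * 100 + ["wide"] * 100
    f, p = ps.permdisp(X, labels, n_perm=199, seed=2)
    assert p < 0.01


def test_permdisp_null_not_significant(rng):
    X = rng.normal(size=(80, 4))
    labels = ["a"] * 40 + ["b"] * 40
    _, p = ps.permdisp(X, labels, n_perm=199, seed=4)
    assert p > 0.05


def test_permdisp_single_member_group_rejected(rng):
    X = rng.normal(size=(3, 2))
    with pytest.raises(UndefinedMetricError):
        ps.permdisp(X, ["a", "b", "c"])
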