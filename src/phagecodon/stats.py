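"""Nonparametric statistical suite for lifestyle-group comparisons.

Omnibus Kruskal-Wallis with rank-based effect sizes (eta2 = (H-k+1)/(N-k),
epsilon2 = (H-k+1)/(N-1)), Dunn's post-hoc z contrasts with Bonferroni/Holm
correction, Mann-Whitney U with Cliff's delta effect sizes, Holm and
Benjamini-Hochberg adjustment, Spearman correlation with seeded bootstrap
percentile CIs and a rank-residualization partial variant, the
Scheirer-Ray-Hare two-factor rank test, and permutation-based multivariate
tests (PERMANOVA on z-scored Euclidean distances with seeded subsampling,
plus PERMDISP for dispersion). All tests are two-sided; all stochastic
operations are reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# effect-size labels

#: Rank epsilon-squared interpretation thresholds.
EPSILON2_THRESHOLDS = (0.01, 0.08, 0.26)
#: Cliff's delta interpretation thresholds.
CLIFFS_THRESHOLDS = (0.147, 0.33, 0.474)


def epsilon2_label(e2: float) -> str:
    """negligible < 0.01 <= small < 0.08 <= moderate <= 0.26 < large."""
    if e2 < EPSILON2_THRESHOLDS[0]:
        return "negligible"
    if e2 < EPSILON2_THRESHOLDS[1]:
        return "small"
    if e2 <= EPSILON2_THRESHOLDS[2]:
        return "moderate"
    return "large"


def cliffs_magnitude(delta: float) -> str:
    a = abs(delta)
    if a < CLIFFS_THRESHOLDS[0]:
        return "negligible"
    if a < CLIFFS_THRESHOLDS[1]:
        return "small"
    if a < CLIFFS_THRESHOLDS[2]:
        return "moderate"
    return "large"


# ---------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    eta2: float
    epsilon2: float
    k: int
    N: int
    tie_corrected: bool


@dataclass(frozen=True)
class PairwiseContrast:
    group_1: str
    group_2: str
    mean_rank_1: float
    mean_rank_2: float
    z: float | None
    p_raw: float
    p_bonferroni: float
    p_holm: float
    cliffs_delta: float | None
    magnitude: str | None
    direction: str


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    p_fdr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    partial: bool = False
    covariates: tuple[str, ...] = ()
    n: int = 0


@dataclass(frozen=True)
class SRHResult:
    h_factor_a: float
    h_factor_b: float
    h_interaction: float
    df_a: int
    df_b: int
    df_interaction: int
    p_factor_a: float
    p_factor_b: float
    p_interaction: float


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    subsample_n: int
    seed: int | None
    dispersion_f: float | None = None
    dispersion_p: float | None = None
    groups: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# rank effect sizes and Kruskal-Wallis


def rank_effect_sizes(H: float, k: int, N: int) -> tuple[float, float]:
    """eta2 = (H - k + 1)/(N - k); epsilon2 = (H - k + 1)/(N - 1)."""
    return (H - k + 1) / (N - k), (H - k + 1) / (N - 1)


def _tie_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(
    groups: Sequence[Sequence[float]], tie_correction: bool = True
) -> KWResult:
    """Kruskal-Wallis H over pooled mid-ranks, with the rank effect sizes."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group")
    pooled = np.concatenate(arrays)
    N = pooled.size
    k = len(arrays)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * (r.mean() - (N + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (N * (N + 1))
    if tie_correction:
        divisor = 1.0 - _tie_sum(pooled) / (N**3 - N)
        if divisor <= 0:  # all values identical
            h = 0.0
        else:
            h /= divisor
    p = float(sps.chi2.sf(h, k - 1)) if h > 0 else 1.0
    eta2, eps2 = rank_effect_sizes(h, k, N)
    return KWResult(
        H=float(h), df=k - 1, p=p, eta2=eta2, epsilon2=eps2,
        k=k, N=N, tie_corrected=tie_correction,
    )


# ---------------------------------------------------------------------------
# Dunn's post-hoc


def dunn_z(
    mean_rank_1: float,
    mean_rank_2: float,
    n1: int,
    n2: int,
    N: int,
    tie_sum: float = 0.0,
) -> float:
    """Dunn's z from group mean ranks.

    z = (R1 - R2) / sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n1 + 1/n2)), with
    T the tie sum (vanishes with no ties).
    """
    se = np.sqrt(
        (N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))) * (1.0 / n1 + 1.0 / n2)
    )
    return (mean_rank_1 - mean_rank_2) / se


def dunn_posthoc(
    groups: Sequence[Sequence[float]], labels: Sequence[str]
) -> list[PairwiseContrast]:
    """All pairwise Dunn contrasts on pooled mid-ranks, with Cliff's delta.

    Bonferroni and Holm adjustments (on unrounded p-values) cover the full
    family of contrasts; the direction string names the group with the higher
    mean rank.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group")
    if len(arrays) != len(labels):
        raise ValidationError("labels must match groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    tie_sum = _tie_sum(pooled)
    mean_ranks, sizes, offsets = [], [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        sizes.append(a.size)
        offsets.append(start)
        start += a.size
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    z_values, raw_p = [], []
    for i, j in pairs:
        z = dunn_z(mean_ranks[i], mean_ranks[j], sizes[i], sizes[j], N, tie_sum)
        z_values.append(float(z))
        raw_p.append(float(2.0 * sps.norm.sf(abs(z))))
    holm = holm_adjust(raw_p)
    m = len(pairs)
    out = []
    for (i, j), z, p, ph in zip(pairs, z_values, raw_p, holm):
        delta, magnitude = cliffs_delta(arrays[i], arrays[j])
        if mean_ranks[i] == mean_ranks[j]:
            direction = f"{labels[i]} = {labels[j]}"
        elif mean_ranks[i] > mean_ranks[j]:
            direction = f"{labels[i]} > {labels[j]}"
        else:
            direction = f"{labels[j]} > {labels[i]}"
        out.append(
            PairwiseContrast(
                group_1=labels[i], group_2=labels[j],
                mean_rank_1=mean_ranks[i], mean_rank_2=mean_ranks[j],
                z=z, p_raw=p, p_bonferroni=min(1.0, m * p), p_holm=float(ph),
                cliffs_delta=delta, magnitude=magnitude, direction=direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney and Cliff's delta


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Cliff's delta = (#{x_i > y_j} - #{x_i < y_j}) / (n1 n2), with magnitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty sample")
    # U with midrank tie handling equals #{x>y} + 0.5 #{x=y}
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    delta = 2.0 * float(u) / (x.size * y.size) - 1.0
    return delta, cliffs_magnitude(delta)


def pairwise_mannwhitney(
    groups: Sequence[Sequence[float]], labels: Sequence[str]
) -> list[PairwiseContrast]:
    """All pairwise Mann-Whitney contrasts with Holm correction and Cliff's delta."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    raw_p, stats_u = [], []
    for i, j in pairs:
        u, p = mann_whitney(arrays[i], arrays[j])
        stats_u.append(u)
        raw_p.append(p)
    holm = holm_adjust(raw_p)
    m = len(pairs)
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        start += a.size
    out = []
    for (i, j), p, ph in zip(pairs, raw_p, holm):
        delta, magnitude = cliffs_delta(arrays[i], arrays[j])
        if delta > 0:
            direction = f"{labels[i]} > {labels[j]}"
        elif delta < 0:
            direction = f"{labels[j]} > {labels[i]}"
        else:
            direction = f"{labels[i]} = {labels[j]}"
        out.append(
            PairwiseContrast(
                group_1=labels[i], group_2=labels[j],
                mean_rank_1=mean_ranks[i], mean_rank_2=mean_ranks[j],
                z=None, p_raw=p, p_bonferroni=min(1.0, m * p), p_holm=float(ph),
                cliffs_delta=delta, magnitude=magnitude, direction=direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# multiplicity corrections


def _check_pvalues(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Spearman machinery


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho (Pearson correlation of mid-ranks) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("paired vectors of length >= 4 required")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size))


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 1000,
    seed: int | None = None,
    max_redraws: int = 10_000,
) -> tuple[float, float]:
    """Percentile 95% CI for Spearman's rho over B paired resamples.

    Degenerate resamples (a constant vector, where rho is undefined) are
    redrawn and counted in the log. Deterministic under a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    rhos = np.empty(B)
    redraws = 0
    got = 0
    while got < B:
        idx = rng.integers(0, n, size=n)
        xs, ys = x[idx], y[idx]
        if np.unique(xs).size < 2 or np.unique(ys).size < 2:
            redraws += 1
            if redraws > max_redraws:
                raise UndefinedMetricError("too many degenerate bootstrap resamples")
            continue
        rhos[got] = sps.spearmanr(xs, ys)[0]
        got += 1
    if redraws:
        logger.info("bootstrap_ci: %d degenerate resamples redrawn", redraws)
    return float(np.percentile(rhos, 2.5)), float(np.percentile(rhos, 97.5))


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray,
    covariate_names: Sequence[str] = (),
) -> CorrelationResult:
    """Partial Spearman correlation by rank residualization.

    All variables are rank-transformed; x and y ranks are each regressed on
    the ranked covariates (with intercept) by least squares; Spearman's rho is
    computed between the residuals. The p-value uses the t approximation with
    degrees of freedom reduced by the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    n, k = Z.shape
    if n != x.size or n != y.size:
        raise ValidationError("x, y and covariates must share the sample dimension")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = np.column_stack([sps.rankdata(Z[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), rz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("ranked covariates are collinear (rank-deficient design)")
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    df = n - 2 - k
    # perfect confounding: a variable fully explained by the covariates leaves
    # (numerically) zero residual variance — no residual association remains
    tol = 1e-8 * n
    if np.std(res_x) < tol or np.std(res_y) < tol:
        return CorrelationResult(
            rho=0.0, p=1.0, partial=True, covariates=tuple(covariate_names), n=n
        )
    rho = float(sps.spearmanr(res_x, res_y)[0])
    if df <= 0:
        raise ValidationError("not enough observations for the covariate count")
    denom = max(1.0 - rho * rho, np.finfo(float).tiny)
    t = rho * np.sqrt(df / denom)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        rho=rho, p=p, partial=True, covariates=tuple(covariate_names), n=n
    )


# ---------------------------------------------------------------------------
# Scheirer-Ray-Hare


def scheirer_ray_hare(
    values: Sequence[float], factor_a: Sequence[str], factor_b: Sequence[str]
) -> SRHResult:
    """Scheirer-Ray-Hare rank two-way test (main effects + interaction).

    Global mid-ranks; H_effect = SS_effect / MS_total with
    MS_total = SS_total / (N - 1); p from chi-square at the effect df.
    Requires >= 2 levels per factor and >= 1 observation in every cell.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (v.size == a.size == b.size):
        raise ValidationError("values and factors must align")
    levels_a = np.unique(a)
    levels_b = np.unique(b)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValidationError("each factor needs at least two levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ValidationError(f"empty cell: ({la}, {lb})")
    r = sps.rankdata(v)
    grand = r.mean()
    ss_total = float(np.sum((r - grand) ** 2))
    if ss_total == 0:
        return SRHResult(0.0, 0.0, 0.0,
                         levels_a.size - 1, levels_b.size - 1,
                         (levels_a.size - 1) * (levels_b.size - 1),
                         1.0, 1.0, 1.0)
    ms_total = ss_total / (v.size - 1)
    ss_a = sum(
        np.sum(a == la) * (r[a == la].mean() - grand) ** 2 for la in levels_a
    )
    ss_b = sum(
        np.sum(b == lb) * (r[b == lb].mean() - grand) ** 2 for lb in levels_b
    )
    ss_cells = 0.0
    for la in levels_a:
        for lb in levels_b:
            m = (a == la) & (b == lb)
            ss_cells += m.sum() * (r[m].mean() - grand) ** 2
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
    df_a = levels_a.size - 1
    df_b = levels_b.size - 1
    df_ab = df_a * df_b
    h_a, h_b, h_ab = ss_a / ms_total, ss_b / ms_total, ss_ab / ms_total
    return SRHResult(
        h_factor_a=float(h_a), h_factor_b=float(h_b), h_interaction=float(h_ab),
        df_a=df_a, df_b=df_b, df_interaction=df_ab,
        p_factor_a=float(sps.chi2.sf(h_a, df_a)),
        p_factor_b=float(sps.chi2.sf(h_b, df_b)),
        p_interaction=float(sps.chi2.sf(h_ab, df_ab)),
    )


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _permanova_ss(d2: np.ndarray, indicators: list[np.ndarray]) -> tuple[float, float]:
    """(SS_between, SS_within) from a squared-distance matrix and group indicators."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for u in indicators:
        ng = u.sum()
        ss_within += float(u @ d2 @ u) / (2.0 * ng)
    return ss_total - ss_within, ss_within


def permanova(
    features: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 999,
    subsample_n: int | None = None,
    seed: int | None = None,
    with_dispersion: bool = True,
) -> PermanovaResult:
    """One-way PERMANOVA on z-scored Euclidean distances.

    Columns are z-scored (after the optional seeded per-group subsample
    without replacement), squared Euclidean distances computed, and
    pseudo-F = (SS_between/(k-1)) / (SS_within/(N-k)). The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) over label permutations;
    R2 = SS_between/SS_total. PERMDISP on the same standardized subsample is
    reported as a companion when ``with_dispersion``.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    if len(groups) < 2:
        raise ValidationError("need at least two label groups")
    rng = np.random.default_rng(seed)
    if subsample_n is not None:
        idx_parts = []
        for g in groups:
            gi = np.flatnonzero(labels == g)
            if subsample_n > gi.size:
                raise ValidationError(
                    f"subsample_n={subsample_n} exceeds group {g} size {gi.size}"
                )
            idx_parts.append(rng.choice(gi, size=subsample_n, replace=False))
        idx = np.concatenate(idx_parts)
        X, labels = X[idx], labels[idx]
    N = X.shape[0]
    k = len(groups)
    Xz = _zscore(X)
    d2 = _squared_distances(Xz)
    obs_ind = [(labels == g).astype(float) for g in groups]
    ss_between, ss_within = _permanova_ss(d2, obs_ind)
    ss_total = ss_between + ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (N - k))
    # batched permutations: SS_within per perm via one GEMM per group
    perm_idx = np.array([rng.permutation(N) for _ in range(n_perm)])
    row_sum = d2.sum(axis=1)
    total_sum = d2.sum()
    ss_within_perm = np.zeros(n_perm)
    sizes = {g: float(np.sum(labels == g)) for g in groups}
    if len(groups) == 2:
        # one GEMM; the second group's quadratic form follows by complement
        u1 = (labels == groups[0]).astype(float)
        U1 = u1[perm_idx].T  # N x n_perm
        quad1 = np.einsum("ip,ip->p", U1, d2 @ U1)
        quad2 = total_sum - 2.0 * (row_sum @ U1) + quad1
        ss_within_perm = quad1 / (2.0 * sizes[groups[0]]) + quad2 / (
            2.0 * sizes[groups[1]]
        )
    else:
        for g in groups:
            base = (labels == g).astype(float)
            U = base[perm_idx].T
            quad = np.einsum("ip,ip->p", U, d2 @ U)
            ss_within_perm += quad / (2.0 * sizes[g])
    ss_between_perm = (total_sum / (2.0 * N)) - ss_within_perm
    f_perm = (ss_between_perm / (k - 1)) / (ss_within_perm / (N - k))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    disp_f = disp_p = None
    if with_dispersion:
        disp_f, disp_p = permdisp(Xz, labels, n_perm=n_perm, seed=seed, standardize=False)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ss_between / ss_total),
        p=float(p),
        n_perm=n_perm,
        subsample_n=subsample_n if subsample_n is not None else min(
            int(np.sum(labels == g)) for g in groups
        ),
        seed=seed,
        dispersion_f=disp_f,
        dispersion_p=disp_p,
        groups=tuple(str(g) for g in groups),
    )


def _dispersion_f(X: np.ndarray, labels: np.ndarray, groups: list) -> float:
    dists = np.empty(X.shape[0])
    for g in groups:
        m = labels == g
        centroid = X[m].mean(axis=0)
        dists[m] = np.linalg.norm(X[m] - centroid, axis=1)
    return float(sps.f_oneway(*[dists[labels == g] for g in groups]).statistic)


def permdisp(
    features: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = True,
) -> tuple[float, float]:
    """Permutation test for multivariate dispersion differences.

    Each observation's Euclidean distance to its group centroid (in the
    z-scored space) is computed and a one-way F on those distances is
    permuted over labels.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    if len(groups) < 2:
        raise ValidationError("need at least two label groups")
    if any(np.sum(labels == g) < 2 for g in groups):
        raise UndefinedMetricError("dispersion F undefined for a single-member group")
    if standardize:
        X = _zscore(X)
    rng = np.random.default_rng(seed)
    f_obs = _dispersion_f(X, labels, groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _dispersion_f(X, perm, groups) >= f_obs:
            count += 1
    return f_obs, (1.0 + count) / (1.0 + n_perm)
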