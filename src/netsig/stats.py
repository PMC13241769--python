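"""Permutation tests, split-plot ANOVA, χ² tables and BH-FDR control.

Group comparisons of continuous features use a two-sided permutation
test (label shuffling without replacement, 10 000 iterations by default)
with the +1 finite-sample correction, optionally wrapped in the
repeated-mode procedure (`modal_p`) that reports the most frequent
p-value over 100 re-seeded repetitions. Band × group designs are
analysed with a classical split-plot (mixed) ANOVA — Band as the
within-subject factor, Group between subjects — with Greenhouse–Geisser
sphericity correction, Mauchly's W and Bartlett's homogeneity check.
Multiplicity is controlled with Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from netsig.errors import ParameterError


@dataclass
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    seed: int | None = None
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    exact: bool = False


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: float
    ms: float
    f: float
    p: float
    p_gg: float | None = None


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    bartlett_stat: float
    bartlett_p: float
    ss_residual_between: float = 0.0
    ss_residual_within: float = 0.0


@dataclass
class FdrResult:
    pvals: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    q: float


def _stat_mean_diff(x, y):
    return float(np.mean(x) - np.mean(y))


def permutation_test(x, y, stat=_stat_mean_diff, n_perm: int = 10_000,
                     seed: int | None = None, exact: bool = False,
                     ) -> PermutationResult:
    """Two-sided two-sample permutation test.

    p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1); with
    ``exact=True`` (or automatically when all label splits number fewer
    than n_perm) every split is enumerated and p is the exact
    permutation p-value #{|stat_perm| >= |stat_obs|} / n_splits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    nx = x.size
    obs = stat(x, y)
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled sample; p = 1")
        return PermutationResult(observed=obs, p=1.0, n_perm=0, seed=seed)

    n_splits = comb(pooled.size, nx)
    if exact or n_splits <= n_perm:
        null = np.array([
            stat(pooled[list(idx)],
                 np.delete(pooled, list(idx)))
            for idx in combinations(range(pooled.size), nx)])
        tol = 1e-12 * max(1.0, abs(obs))
        p = float(np.mean(np.abs(null) >= abs(obs) - tol))
        return PermutationResult(observed=obs, p=max(p, 1.0 / n_splits),
                                 n_perm=n_splits, seed=seed,
                                 null_mean=float(null.mean()),
                                 null_sd=float(null.std()), exact=True)

    rng = np.random.default_rng(seed)
    if stat is _stat_mean_diff:
        # vectorized fast path for the default statistic
        order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[order]
        null = perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.permutation(pooled.size)
            null[i] = stat(pooled[idx[:nx]], pooled[idx[nx:]])
    tol = 1e-12 * max(1.0, abs(obs))
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - tol)) / (n_perm + 1.0)
    return PermutationResult(observed=obs, p=float(p), n_perm=n_perm, seed=seed,
                             null_mean=float(null.mean()),
                             null_sd=float(null.std()))


def modal_p(test_closure, n_repeats: int = 100, seed: int | None = None,
            decimals: int = 3) -> float:
    """Most frequent p-value over re-seeded repetitions of a stochastic test.

    ``test_closure(seed) -> p``. P-values are rounded to ``decimals``
    before taking the mode (a mode over continuous values is otherwise
    degenerate); ties resolve to the smallest modal p. With the
    +1-corrected permutation estimator this stabilization is
    statistically redundant but implemented for procedure fidelity.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
             for s in ss.spawn(n_repeats)]
    ps = [round(float(test_closure(s)), decimals) for s in seeds]
    counts = Counter(ps)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def chi2_contingency(table, correction: bool = False):
    """Pearson χ² on an r×c nonnegative integer table.

    Continuity (Yates) correction off by default; zero marginals raise.
    Returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ParameterError("table entries must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mixed_anova(data, groups) -> AnovaResult:
    """Classical split-plot ANOVA: within-subject Band, between-subject Group.

    Parameters
    ----------
    data : array [n_subjects, k]
        One row per subject, one column per within-subject level.
    groups : array [n_subjects]
        Between-subject labels (two or more levels, each with >= 2
        subjects; unbalanced designs supported via cell-mean weighted
        sums of squares).

    The decomposition: between-subject SS splits into Group and
    subject-within-group error; within-subject SS splits into Band,
    Group×Band and Band×subject error. Greenhouse–Geisser ε comes from
    the double-centred pooled within-group covariance; Mauchly's W tests
    sphericity; Bartlett's test checks between-group homogeneity of the
    subject means.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if data.ndim != 2:
        raise ParameterError("data must be subjects x bands")
    if not np.all(np.isfinite(data)):
        raise ParameterError("missing cells are not supported")
    n, k = data.shape
    levels = list(dict.fromkeys(groups.tolist()))
    ng = {g: int(np.sum(groups == g)) for g in levels}
    if any(v < 2 for v in ng.values()):
        raise ParameterError("every group needs at least 2 subjects")
    G = len(levels)

    grand = data.mean()
    subj_means = data.mean(axis=1)
    group_means = {g: data[groups == g].mean() for g in levels}
    band_means = data.mean(axis=0)
    cell_means = {g: data[groups == g].mean(axis=0) for g in levels}

    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * sum(ng[g] * (group_means[g] - grand) ** 2 for g in levels)
    ss_err_between = ss_between_subj - ss_group

    ss_within = np.sum((data - subj_means[:, None]) ** 2)
    ss_band = n * np.sum((band_means - grand) ** 2)
    ss_inter = sum(ng[g] * np.sum((cell_means[g] - group_means[g]
                                   - band_means + grand) ** 2)
                   for g in levels)
    ss_err_within = ss_within - ss_band - ss_inter

    df_group, df_eb = G - 1, n - G
    df_band, df_inter, df_ew = k - 1, (G - 1) * (k - 1), (n - G) * (k - 1)

    ms_eb = ss_err_between / df_eb
    ms_ew = ss_err_within / df_ew

    def effect(name, ss, df, ms_err, df_err, eps=None):
        ms = ss / df
        f = ms / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, df, df_err)) if ms_err > 0 else 1.0
        p_gg = None
        if eps is not None:
            p_gg = float(sps.f.sf(f, df * eps, df_err * eps)) if ms_err > 0 else 1.0
        return AnovaEffect(name=name, ss=float(ss), df=df, ms=float(ms),
                           f=float(f), p=p, p_gg=p_gg)

    # Greenhouse-Geisser epsilon from the pooled within-group covariance
    resid = np.vstack([data[groups == g] - cell_means[g] for g in levels])
    S = resid.T @ resid / (n - G)
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    tr = np.trace(Sc)
    denom = (k - 1) * np.sum(Sc * Sc)
    eps = float(tr ** 2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    # Mauchly's sphericity test on the k-1 nonzero eigenvalues
    eig = np.sort(np.linalg.eigvalsh(Sc))[::-1][: k - 1]
    eig = np.clip(eig, 1e-300, None)
    W = float(np.prod(eig / eig.mean()))
    d = k - 1
    nr = n - G
    chi2 = -(nr - (2 * d ** 2 + d + 2) / (6.0 * d)) * np.log(W)
    dof_m = d * (d + 1) // 2 - 1
    mauchly_p = float(sps.chi2.sf(chi2, dof_m)) if dof_m > 0 else 1.0

    bart_stat, bart_p = sps.bartlett(*[subj_means[groups == g] for g in levels])

    effects = {
        "group": effect("group", ss_group, df_group, ms_eb, df_eb),
        "band": effect("band", ss_band, df_band, ms_ew, df_ew, eps=eps),
        "interaction": effect("interaction", ss_inter, df_inter, ms_ew,
                              df_ew, eps=eps),
    }
    return AnovaResult(effects=effects, gg_epsilon=eps, mauchly_w=W,
                       mauchly_p=mauchly_p, bartlett_stat=float(bart_stat),
                       bartlett_p=float(bart_p),
                       ss_residual_between=float(ss_err_between),
                       ss_residual_within=float(ss_err_within))


def twoway_anova(values, factor_a, factor_b) -> dict:
    """Two-between-factor ANOVA on a single response (Type-II SS).

    Used per frequency band for designs like group × structural-brain-
    abnormality status. Factors may be unbalanced; effects use sum
    coding and Type-II model comparisons:
    SS(A) = RSS(1+B) − RSS(1+A+B), SS(A×B) = RSS(1+A+B) − RSS(full).

    Returns {"a" | "b" | "interaction": {"ss", "df", "F", "p"}, "df_err"}.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if y.ndim != 1 or len(y) != len(fa) or len(y) != len(fb):
        raise ParameterError("values and factors must be equal-length 1-D")

    def code(f):
        levels = list(dict.fromkeys(f.tolist()))
        k = len(levels)
        if k < 2:
            raise ParameterError("each factor needs at least 2 levels")
        cols = np.zeros((len(f), k - 1))
        for i, lev in enumerate(levels[:-1]):
            cols[f == lev, i] = 1.0
            cols[f == levels[-1], i] = -1.0
        return cols

    A = code(fa)
    B = code(fb)
    AB = np.stack([A[:, i] * B[:, j] for i in range(A.shape[1])
                   for j in range(B.shape[1])], axis=1)
    one = np.ones((len(y), 1))

    def rss(Xd):
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        r = y - Xd @ beta
        return float(r @ r)

    rss_full = rss(np.hstack([one, A, B, AB]))
    rss_ab = rss(np.hstack([one, A, B]))
    rss_a = rss(np.hstack([one, A]))
    rss_b = rss(np.hstack([one, B]))

    df_a, df_b = A.shape[1], B.shape[1]
    df_int = AB.shape[1]
    df_err = len(y) - (1 + df_a + df_b + df_int)
    if df_err < 1:
        raise ParameterError("not enough residual degrees of freedom")
    ms_err = rss_full / df_err

    def eff(ss, df):
        f = (ss / df) / ms_err if ms_err > 0 else 0.0
        return {"ss": float(ss), "df": df, "F": float(f),
                "p": float(sps.f.sf(f, df, df_err))}

    return {"a": eff(rss_b - rss_ab, df_a),
            "b": eff(rss_a - rss_ab, df_b),
            "interaction": eff(rss_ab - rss_full, df_int),
            "df_err": df_err}


def bh_fdr(pvals, q: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up FDR control.

    Adjusted p_i = min over ranks j >= rank(i) of m·p_(j)/j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj, 0, 1)
    rejected = adjusted <= q
    return FdrResult(pvals=p, adjusted=adjusted, rejected=rejected, q=q)


def channelwise_group_test(values, groups, n_perm: int = 10_000,
                           seed: int | None = None, q: float = 0.05):
    """Per-channel permutation tests with BH correction across channels.

    Parameters
    ----------
    values : array [n_subjects, n_channels] or dict band -> such array
        Channel-wise feature values (same channels for all subjects).
    groups : binary labels per subject.

    Returns a dict with raw p-values, BH-adjusted p-values and rejection
    flags, stacked over bands when a dict is passed (correction spans
    channels × bands jointly).
    """
    if isinstance(values, dict):
        names, mats = list(values), list(values.values())
    else:
        names, mats = [None], [np.asarray(values)]
    groups = np.asarray(groups)
    if any(m.shape[1] == 0 for m in mats):
        raise ParameterError("no channels to test")
    ss = np.random.SeedSequence(seed)
    all_p, index = [], []
    for name, mat in zip(names, mats):
        mat = np.asarray(mat, dtype=float)
        for c in range(mat.shape[1]):
            s = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            res = permutation_test(mat[groups == groups[0], c],
                                   mat[groups != groups[0], c],
                                   n_perm=n_perm, seed=s)
            all_p.append(res.p)
            index.append((name, c))
    fdr = bh_fdr(np.array(all_p), q=q)
    return {"index": index, "p": fdr.pvals, "p_adjusted": fdr.adjusted,
            "rejected": fdr.rejected, "q": q}
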