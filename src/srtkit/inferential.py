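"""Classical inferential layer: t tests, effect sizes, repeated-measures
ANOVA with Greenhouse-Geisser correction, post-hocs, ICC and Pearson CIs.

Everything here is computed from the defining formulas (sums of squares,
mean squares, noncentral-t inversion) rather than delegated to a stats
package, so every reported number can be audited against a textbook.
scipy supplies only the reference distributions.

Degenerate inputs (zero variance) yield results flagged ``degenerate`` with
no p-value rather than a division-by-zero artefact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TestResult",
    "AnovaEffect",
    "IccResult",
    "one_sample_t",
    "paired_t",
    "cohens_d_ci",
    "rm_anova_within",
    "pairwise_posthoc",
    "icc_absolute_agreement",
    "pearson_r_ci",
]


@dataclass
class TestResult:
    """One two-tailed test: statistic, df, p, effect size with CI."""

    statistic: float | None
    df: float | None
    p: float | None
    effect: float | None = None
    effect_name: str = ""
    ci: tuple[float, float] | None = None
    tails: str = "two"
    label: str = ""
    degenerate: bool = False
    note: str = ""


@dataclass
class AnovaEffect:
    """One within-subject effect from a repeated-measures ANOVA."""

    name: str
    ss_effect: float
    ss_error: float
    df_num: float
    df_den: float
    f: float
    p: float
    eta_p2: float
    epsilon: float
    df_num_gg: float
    df_den_gg: float
    p_gg: float
    n_subjects: int


@dataclass
class IccResult:
    """Two-way random, absolute-agreement, average-measure ICC (A,k)."""

    icc: float
    model: str
    ci: tuple[float, float]
    f: float
    df1: float
    df2: float
    p: float
    n_items: int
    n_raters: int


def one_sample_t(
    values: Sequence[float], mu0: float = 0.0, ci_level: float = 0.95
) -> TestResult:
    """Classical one-sample t test against mu0, two-tailed.

    Cohen's d = (mean - mu0) / sd, with a noncentral-t CI when n >= 3.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one_sample_t needs n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return TestResult(
            statistic=None, df=float(n - 1), p=None, effect_name="cohen_d",
            degenerate=True, note="zero variance: t undefined",
        )
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    d = (mean - mu0) / sd
    ci = cohens_d_ci(d, n, ci_level) if n >= 3 else None
    return TestResult(
        statistic=t, df=float(n - 1), p=float(p),
        effect=d, effect_name="cohen_d", ci=ci,
    )


def paired_t(a: Sequence[float], b: Sequence[float], ci_level: float = 0.95) -> TestResult:
    """Paired t test: one-sample t on the differences a - b against zero."""
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t needs equal-length samples")
    return one_sample_t(x - y, 0.0, ci_level)


def cohens_d_ci(d: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for a one-sample/paired Cohen's d via noncentral-t inversion.

    The observed t = d*sqrt(n) is pivoted on the noncentrality parameter:
    the bounds are the ncp values whose noncentral t(df = n-1) places the
    observed t at the (1 +/- level)/2 tail, divided back by sqrt(n).
    """
    if n < 3:
        raise ValueError("cohens_d_ci needs n >= 3")
    t_obs = d * math.sqrt(n)
    df = n - 1
    lo_tail = (1.0 - level) / 2.0

    def sf_minus(nc, target):
        return stats.nct.sf(t_obs, df, nc) - target

    span = 10.0 + 2.0 * abs(t_obs)
    # sf is increasing in nc: lower bound has sf = lo_tail, upper sf = 1 - lo_tail
    nc_lo = optimize.brentq(sf_minus, t_obs - span, t_obs + span, args=(lo_tail,))
    nc_hi = optimize.brentq(sf_minus, t_obs - span, t_obs + span, args=(1.0 - lo_tail,))
    lo, hi = nc_lo / math.sqrt(n), nc_hi / math.sqrt(n)
    return (min(lo, hi), max(lo, hi))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (Helmert, normalised)."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -float(i)
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _gg_epsilon(cells: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one effect.

    cells: subjects x cells matrix; contrast: orthonormal rows spanning the
    effect. Epsilon = (sum lambda)^2 / (df * sum lambda^2) over eigenvalues
    of the contrast-projected covariance, clamped to [1/df, 1].
    """
    df = contrast.shape[0]
    if df == 1:
        return 1.0
    s = np.cov(cells, rowvar=False, ddof=1)
    m = contrast @ s @ contrast.T
    lam = np.linalg.eigvalsh(m)
    num = lam.sum() ** 2
    den = df * (lam ** 2).sum()
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / df, 1.0))


def _effect_result(name, ss_e, ss_err, df1, df2, eps, n) -> AnovaEffect:
    ss_e, ss_err = max(ss_e, 0.0), max(ss_err, 0.0)  # guard subtraction roundoff
    ms_e = ss_e / df1
    ms_err = ss_err / df2
    f = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e <= 1e-12 else math.inf)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    p_gg = float(stats.f.sf(f, eps * df1, eps * df2)) if math.isfinite(f) else 0.0
    eta = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
    return AnovaEffect(
        name=name, ss_effect=float(ss_e), ss_error=float(ss_err),
        df_num=float(df1), df_den=float(df2), f=float(f), p=p,
        eta_p2=float(eta), epsilon=float(eps),
        df_num_gg=float(eps * df1), df_den_gg=float(eps * df2), p_gg=p_gg,
        n_subjects=n,
    )


def rm_anova_within(
    table: pd.DataFrame,
    factors: Sequence[str],
    subject: str = "subject",
    value: str = "value",
) -> dict[str, AnovaEffect]:
    """Repeated-measures ANOVA with one or two within-subject factors.

    ``table`` is long-format with a subject column, one or two factor
    columns and a value column. Subjects missing any cell are dropped
    listwise with a loud warning. Each effect uses its own subject-by-
    effect interaction as error term; partial eta-squared is
    SS_effect / (SS_effect + SS_error); the Greenhouse-Geisser epsilon is
    estimated from the sample covariance of the cell scores and both the
    uncorrected and the epsilon-corrected p are reported.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("rm_anova_within supports 1 or 2 within-subject factors")
    levels = [sorted(table[f].unique()) for f in factors]
    cells = [tuple(c) for c in _cartesian(levels)]
    wide = table.pivot_table(
        index=subject, columns=list(factors), values=value, aggfunc="mean"
    )
    # order columns as the cartesian product of sorted levels
    wide = wide.reindex(columns=[c if len(c) > 1 else c[0] for c in cells])
    complete = wide.dropna()
    if len(complete) < len(wide):
        dropped = sorted(set(wide.index) - set(complete.index))
        warnings.warn(
            f"listwise deletion: subjects {dropped} lack complete cells and are "
            "excluded from the ANOVA", stacklevel=2,
        )
    y = complete.to_numpy(dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("rm_anova_within needs at least 2 complete subjects")

    if len(factors) == 1:
        k = len(levels[0])
        grand = y.mean()
        subj_m = y.mean(axis=1)
        lev_m = y.mean(axis=0)
        ss_a = n * 0.0 + y.shape[0] * ((lev_m - grand) ** 2).sum()
        ss_subj = k * ((subj_m - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_a - ss_subj
        c = _orthonormal_contrasts(k)
        eps = _gg_epsilon(y, c)
        return {
            factors[0]: _effect_result(
                factors[0], ss_a, ss_err, k - 1, (n - 1) * (k - 1), eps, n
            )
        }

    a_lv, b_lv = levels
    a, b = len(a_lv), len(b_lv)
    cube = y.reshape(n, a, b)
    grand = cube.mean()
    m_i = cube.mean(axis=(1, 2))            # subject means
    m_j = cube.mean(axis=(0, 2))            # factor-A level means
    m_l = cube.mean(axis=(0, 1))            # factor-B level means
    m_jl = cube.mean(axis=0)                # A x B cell means
    m_ij = cube.mean(axis=2)                # subject x A means
    m_il = cube.mean(axis=1)                # subject x B means

    ss_a_ = n * b * ((m_j - grand) ** 2).sum()
    ss_b_ = n * a * ((m_l - grand) ** 2).sum()
    ss_ab = n * ((m_jl - m_j[:, None] - m_l[None, :] + grand) ** 2).sum()
    ss_subj = a * b * ((m_i - grand) ** 2).sum()
    ss_err_a = b * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_err_b = a * ((m_il - m_i[:, None] - m_l[None, :] + grand) ** 2).sum()
    ss_tot = ((cube - grand) ** 2).sum()
    ss_err_ab = ss_tot - ss_subj - ss_a_ - ss_err_a - ss_b_ - ss_err_b - ss_ab

    ca, cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    ua = np.full((1, a), 1.0 / math.sqrt(a))
    ub = np.full((1, b), 1.0 / math.sqrt(b))
    eps_a = _gg_epsilon(y, np.kron(ca, ub))
    eps_b = _gg_epsilon(y, np.kron(ua, cb))
    eps_ab = _gg_epsilon(y, np.kron(ca, cb))

    fa, fb = factors
    return {
        fa: _effect_result(fa, ss_a_, ss_err_a, a - 1, (n - 1) * (a - 1), eps_a, n),
        fb: _effect_result(fb, ss_b_, ss_err_b, b - 1, (n - 1) * (b - 1), eps_b, n),
        f"{fa}*{fb}": _effect_result(
            f"{fa}*{fb}", ss_ab, ss_err_ab, (a - 1) * (b - 1),
            (n - 1) * (a - 1) * (b - 1), eps_ab, n,
        ),
    }


def _cartesian(levels: list[list]) -> list[tuple]:
    out = [()]
    for lv in levels:
        out = [c + (x,) for c in out for x in lv]
    return out


def pairwise_posthoc(
    table: pd.DataFrame,
    factor: str,
    method: str = "bonferroni",
    factors: Sequence[str] | None = None,
    subject: str = "subject",
    value: str = "value",
) -> list[TestResult]:
    """Pairwise post-hoc comparisons of one factor's marginal means.

    Both methods compare marginal means with the ANOVA's subject-by-factor
    error term (t = diff / sqrt(2*MS_error/m), df = df_error, m = number
    of scores per marginal mean). Fisher's LSD leaves the p uncorrected;
    Bonferroni multiplies each p by the number of comparisons, capped at 1.
    With two levels the methods coincide.
    """
    if method not in ("bonferroni", "fisher_lsd"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    factors = list(factors) if factors else [factor]
    if factor not in factors:
        raise ValueError(f"factor {factor!r} not among factors {factors}")
    effects = rm_anova_within(table, factors, subject=subject, value=value)
    eff = effects[factor]
    ms_err = eff.ss_error / eff.df_den
    n = eff.n_subjects
    other = [f for f in factors if f != factor]
    n_other = 1
    for f in other:
        n_other *= table[f].nunique()
    m = n * n_other  # scores per marginal mean

    lv = sorted(table[factor].unique())
    wide = table.pivot_table(index=subject, columns=list(factors), values=value,
                             aggfunc="mean").dropna()
    marg = {
        l: float(
            wide.loc[
                :, [c for c in wide.columns
                    if (c == l if not isinstance(c, tuple) else c[factors.index(factor)] == l)]
            ].to_numpy().mean()
        )
        for l in lv
    }
    pairs = list(combinations(lv, 2))
    n_comp = len(pairs)
    results = []
    for x, yv in pairs:
        diff = marg[x] - marg[yv]
        se = math.sqrt(2.0 * ms_err / m)
        if se == 0:
            results.append(TestResult(
                statistic=None, df=eff.df_den, p=None, label=f"{x} vs {yv}",
                degenerate=True, note="zero error variance",
            ))
            continue
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), eff.df_den)
        if method == "bonferroni":
            p = min(1.0, p * n_comp)
        results.append(TestResult(
            statistic=float(t), df=float(eff.df_den), p=float(p),
            effect=float(diff), effect_name="mean_difference",
            label=f"{x} vs {yv}", note=method,
        ))
    return results


def icc_absolute_agreement(
    ratings, ci_level: float = 0.95
) -> IccResult:
    """ICC(A,k): two-way random effects, absolute agreement, mean of k raters.

    ``ratings`` is a complete items x raters matrix. The estimate, F test
    and CI come from the two-way ANOVA mean squares (rows = items,
    columns = raters): the single-measure bounds are computed first and
    stepped up to the average-measure scale by the Spearman-Brown relation.
    Incomplete matrices are a domain error — no imputation.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters matrix")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 items")
    if np.isnan(x).any():
        raise ValueError("ratings matrix is incomplete; no imputation is performed")

    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    icc_k = (msr - mse) / (msr + (msc - mse) / n) if msr + (msc - mse) / n != 0 else 1.0
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    f = msr / mse if mse > 0 else math.inf
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0

    alpha = 1.0 - ci_level
    if mse == 0:
        lo_k = hi_k = 1.0
    else:
        r = icc_1
        a_ = k * r / (n * (1.0 - r))
        b_ = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r))
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1.0) + (b_ * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo_1 = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi_1 = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        lo_k = k * lo_1 / (1.0 + (k - 1.0) * lo_1)
        hi_k = k * hi_1 / (1.0 + (k - 1.0) * hi_1)

    return IccResult(
        icc=float(icc_k),
        model="two-way random, absolute agreement, average of k raters (A,k)",
        ci=(float(lo_k), float(hi_k)),
        f=float(f), df1=df1, df2=df2, p=p,
        n_items=n, n_raters=k,
    )


def pearson_r_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, tuple[float, float], TestResult]:
    """Pearson correlation with a Fisher-z confidence interval."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 4:
        raise ValueError("pearson_r_ci needs n >= 4")
    if xa.std(ddof=1) == 0 or ya.std(ddof=1) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    r = float(r)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    ci = (math.tanh(z - zc * se), math.tanh(z + zc * se))
    t = r * math.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else math.inf
    result = TestResult(
        statistic=float(t), df=float(n - 2), p=float(p),
        effect=r, effect_name="pearson_r", ci=ci,
    )
    return r, ci, result
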