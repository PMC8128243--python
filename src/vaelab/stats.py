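"""Second-level inference for the ventriloquism-aftereffect analysis.

Implements the group-level statistical procedure: one-sample/paired t-tests
with Hedges' g_av or Cohen's d_z effect sizes and default-prior (JZS) Bayes
factors, Holm step-down multiplicity correction, two-way repeated-measures
and mixed-design ANOVAs with Greenhouse-Geisser sphericity correction and
partial/generalized eta-squared effect sizes, orthogonal polynomial
contrasts tested against the pooled subject-by-factor interaction error,
and power computations from the noncentral t distribution.

ANOVA sums of squares are computed from the full balanced decomposition
(one observation per subject x cell); missing cells raise rather than being
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult", "ttest_effects", "holm_adjust", "gg_epsilon",
    "rm_anova_two_way", "mixed_anova", "one_way_rm_anova",
    "polynomial_contrast", "orthogonal_poly_coefficients",
    "power_paired_t", "cohens_f_from_F", "jzs_bf_ttest",
]


# ---------------------------------------------------------------------------
# t-tests and effect sizes

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d_z: float
    g_av: float | None = None
    bf10: float | None = None


def _hedges_J(df: float) -> float:
    """Exact small-sample bias correction J = Gamma(df/2)/(sqrt(df/2) Gamma((df-1)/2))."""
    return math.exp(special.gammaln(df / 2) - special.gammaln((df - 1) / 2)
                    - 0.5 * math.log(df / 2))


def ttest_effects(x, y=None, kind: str = "paired",
                  bayes: bool = False) -> TTestResult:
    """Two-tailed one-sample or paired t-test with paired-design effect sizes.

    For paired data, d_z divides the mean difference by the SD of the
    differences, while Hedges' g_av divides it by the mean of the two
    conditions' SDs, corrected for small-sample bias with df = 2(n - 1).
    For one-sample data (e.g. precomputed pairwise differences) only d_z is
    defined.  ``bayes`` adds the default-prior JZS Bayes factor.
    """
    x = np.asarray(x, float)
    if kind == "paired":
        if y is None:
            raise ValueError("paired test requires both samples")
        y = np.asarray(y, float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        diff = x - y
        sd_av = (np.std(x, ddof=1) + np.std(y, ddof=1)) / 2
    elif kind == "one_sample":
        if y is not None:
            raise ValueError("one-sample test takes a single sample")
        diff = x
        sd_av = None
    else:
        raise ValueError(f"kind must be 'paired' or 'one_sample', got {kind!r}")
    n = len(diff)
    if n < 2:
        raise ValueError("need at least 2 observations")
    df = n - 1
    sd = np.std(diff, ddof=1)
    m = float(np.mean(diff))
    if sd == 0:
        t = 0.0 if m == 0 else math.copysign(math.inf, m)
        p = 1.0 if m == 0 else 0.0
        d_z = 0.0 if m == 0 else math.copysign(math.inf, m)
    else:
        t = m / (sd / math.sqrt(n))
        p = 2 * sps.t.sf(abs(t), df)
        d_z = m / sd
    g_av = None
    if sd_av is not None:
        g_av = 0.0 if sd_av == 0 else m / sd_av * _hedges_J(2 * (n - 1))
    bf = jzs_bf_ttest(t, n=n) if bayes and math.isfinite(t) else None
    return TTestResult(t=float(t), df=df, p=float(p), d_z=float(d_z),
                       g_av=g_av, bf10=bf)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# sphericity

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to the mean."""
    c = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(c)
    return u[:, :k - 1].T


def _epsilon_from_projected(m: np.ndarray) -> float:
    d = m.shape[0]
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, tr ** 2 / (d * tr2)))


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a within-condition covariance matrix.

    Computed from the double-centred covariance; bounded by 1/(k-1) and 1,
    and exactly 1 under compound symmetry or k = 2.
    """
    s = np.asarray(cov, float)
    k = s.shape[0]
    if s.shape != (k, k) or k < 2:
        raise ValueError("covariance must be square with k >= 2")
    c = _orthonormal_contrasts(k)
    return _epsilon_from_projected(c @ s @ c.T)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _anova_row(effect, ss, df_num, ss_err, df_den, eps, ss_g_denom) -> dict:
    ms, ms_e = ss / df_num, ss_err / df_den
    f = ms / ms_e if ms_e > 0 else math.inf if ms > 0 else 0.0
    p_unc = sps.f.sf(f, df_num, df_den)
    p_gg = sps.f.sf(f, df_num * eps, df_den * eps)
    return {
        "effect": effect, "F": f,
        "df_num": df_num, "df_den": df_den, "gg_epsilon": eps,
        "df_num_gg": df_num * eps, "df_den_gg": df_den * eps,
        "p_gg": p_gg, "p_uncorrected": p_unc,
        "ss": ss, "ss_error": ss_err,
        "partial_eta_sq": ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
        "generalized_eta_sq": ss / ss_g_denom if ss_g_denom > 0 else 0.0,
    }


def _pivot_cube(data: pd.DataFrame, dv: str, subject: str,
                within: tuple[str, ...]) -> np.ndarray:
    """Pivot a tidy table to an (n_subjects, k1[, k2]) cell-mean array."""
    wide = data.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="mean", sort=True)
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing cells for within levels {missing}")
    shape = (len(wide),) + tuple(len(data[w].unique()) for w in within)
    return wide.to_numpy().reshape(shape)


def rm_anova_two_way(
    data: pd.DataFrame | np.ndarray,
    dv: str = "value",
    subject: str = "participant",
    within: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA with GG correction.

    Accepts a tidy table (one observation per subject x cell) or an
    (n, a, b) array.  Each effect is tested against its own
    subject-by-effect interaction error; Greenhouse-Geisser epsilon is
    estimated per effect from the corresponding contrast-projected
    between-subject covariance.  Generalized eta-squared places all
    subject-variance terms in the denominator (all factors manipulated).
    """
    y = data if isinstance(data, np.ndarray) else _pivot_cube(data, dv, subject, within)
    if y.ndim != 3:
        raise ValueError("expected an (n_subjects, a, b) layout")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_total = ((y - grand) ** 2).sum()
    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs

    # per-effect GG epsilon from contrast-projected covariances
    ca, cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    cov_a = np.cov(m_sa, rowvar=False)
    cov_b = np.cov(m_sb, rowvar=False)
    cov_ab = np.cov(y.reshape(n, a * b), rowvar=False)
    eps_a = _epsilon_from_projected(ca @ np.atleast_2d(cov_a) @ ca.T)
    eps_b = _epsilon_from_projected(cb @ np.atleast_2d(cov_b) @ cb.T)
    cab = np.kron(ca, cb)
    eps_ab = _epsilon_from_projected(cab @ cov_ab @ cab.T)

    g_denom_tail = ss_s + ss_as + ss_bs + ss_abs
    rows = [
        _anova_row(within[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a,
                   ss_a + g_denom_tail),
        _anova_row(within[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b,
                   ss_b + g_denom_tail),
        _anova_row(f"{within[0]} * {within[1]}", ss_ab, (a - 1) * (b - 1),
                   ss_abs, (a - 1) * (b - 1) * (n - 1), eps_ab,
                   ss_ab + g_denom_tail),
    ]
    out = pd.DataFrame(rows)
    out.attrs["ss_subject"] = float(ss_s)
    out.attrs["ss_total"] = float(ss_total)
    return out


def one_way_rm_anova(y: np.ndarray | pd.DataFrame, dv: str = "value",
                     subject: str = "participant",
                     within: str = "A") -> pd.DataFrame:
    """One-way repeated-measures ANOVA with GG correction ((n, k) layout)."""
    if isinstance(y, pd.DataFrame):
        y = _pivot_cube(y, dv, subject, (within,))
    n, k = y.shape
    grand = y.mean()
    m_s, m_c = y.mean(axis=1), y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_s = k * ((m_s - grand) ** 2).sum()
    ss_c = n * ((m_c - grand) ** 2).sum()
    ss_err = ss_total - ss_s - ss_c
    eps = gg_epsilon(np.cov(y, rowvar=False))
    row = _anova_row(within, ss_c, k - 1, ss_err, (k - 1) * (n - 1), eps,
                     ss_c + ss_s + ss_err)
    out = pd.DataFrame([row])
    out.attrs["ss_subject"] = float(ss_s)
    out.attrs["ms_error"] = float(ss_err / ((k - 1) * (n - 1)))
    return out


def mixed_anova(
    data: pd.DataFrame | list[np.ndarray],
    dv: str = "value",
    subject: str = "participant",
    within: str = "W",
    between: str = "group",
) -> pd.DataFrame:
    """Mixed-design ANOVA: one between-subjects and one within-subjects factor.

    Accepts a tidy table or a list of per-group (n_g, k) arrays.  The
    between effect is tested against subjects-within-groups; the within and
    interaction effects are GG-corrected using the pooled within-group
    covariance.  Group sizes may differ (split-plot decomposition with
    weighted group means).
    """
    if isinstance(data, pd.DataFrame):
        if (data.groupby(subject)[between].nunique() > 1).any():
            raise ValueError("each subject must belong to exactly one group")
        groups = [_pivot_cube(gdf, dv, subject, (within,))
                  for _, gdf in data.groupby(between, sort=True)]
    else:
        groups = [np.asarray(g, float) for g in data]
    k = groups[0].shape[1]
    if any(g.shape[1] != k for g in groups):
        raise ValueError("all groups must share the within-factor levels")
    ns = [g.shape[0] for g in groups]
    n_total, n_groups = sum(ns), len(groups)
    all_y = np.vstack(groups)

    grand = all_y.mean()
    ss_total = ((all_y - grand) ** 2).sum()
    subj_means = all_y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    group_means = np.array([g.mean() for g in groups])
    ss_g = k * sum(n * (gm - grand) ** 2 for n, gm in zip(ns, group_means))
    ss_s_in_g = ss_between_subj - ss_g

    level_means = all_y.mean(axis=0)
    ss_w = n_total * ((level_means - grand) ** 2).sum()
    cell_means = np.array([g.mean(axis=0) for g in groups])  # (g, k)
    ss_cells = sum(n * ((cm - grand) ** 2).sum()
                   for n, cm in zip(ns, cell_means))
    ss_gw = ss_cells - ss_g - ss_w
    ss_err_w = ss_total - ss_between_subj - ss_w - ss_gw

    df_g, df_sg = n_groups - 1, n_total - n_groups
    df_w, df_gw = k - 1, (n_groups - 1) * (k - 1)
    df_err = (n_total - n_groups) * (k - 1)

    pooled = sum((n - 1) * np.cov(g, rowvar=False)
                 for n, g in zip(ns, groups)) / (n_total - n_groups)
    eps = gg_epsilon(pooled)

    err_tail = ss_s_in_g + ss_err_w
    rows = [
        _anova_row(between, ss_g, df_g, ss_s_in_g, df_sg, 1.0, ss_g + err_tail),
        _anova_row(within, ss_w, df_w, ss_err_w, df_err, eps, ss_w + err_tail),
        _anova_row(f"{between} * {within}", ss_gw, df_gw, ss_err_w, df_err,
                   eps, ss_gw + err_tail),
    ]
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = float(ss_total)
    out.attrs["ss_subjects_within_groups"] = float(ss_s_in_g)
    return out


# ---------------------------------------------------------------------------
# polynomial contrasts

def orthogonal_poly_coefficients(k: int, order: int) -> np.ndarray:
    """Integer-scaled orthogonal polynomial contrast over k equally spaced levels."""
    if not (1 <= order <= k - 1):
        raise ValueError(f"order must be in 1..{k - 1}")
    x = np.arange(k, dtype=float) - (k - 1) / 2
    basis = np.vander(x, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    c = q[:, order]
    c = c / np.min(np.abs(c[np.abs(c) > 1e-12]))  # integer-like scaling
    c = np.round(c, 10)
    if c[-1] < 0:
        c = -c
    return c


_ORDERS = {"linear": 1, "quadratic": 2, "cubic": 3}


def polynomial_contrast(y: np.ndarray, order: str | int = "linear") -> TTestResult:
    """Trend contrast across within-subject factor levels ((n, k) means).

    The orthogonal-polynomial contrast of the level means is tested against
    the pooled subject-by-factor interaction error of the one-way
    repeated-measures ANOVA, df = (k - 1)(n - 1).
    """
    y = np.asarray(y, float)
    n, k = y.shape
    ordn = _ORDERS[order] if isinstance(order, str) else int(order)
    c = orthogonal_poly_coefficients(k, ordn)
    est = float(c @ y.mean(axis=0))

    tbl = one_way_rm_anova(y)
    ms_err = tbl.attrs["ms_error"]
    df = (k - 1) * (n - 1)
    se = math.sqrt(ms_err * (c @ c) / n)
    if se == 0:
        t = 0.0 if est == 0 else math.copysign(math.inf, est)
    else:
        t = est / se
    p = 2 * sps.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    scores = y @ c
    sd = np.std(scores, ddof=1)
    d_z = float(np.mean(scores) / sd) if sd > 0 else 0.0
    return TTestResult(t=float(t), df=df, p=float(p), d_z=d_z)


# ---------------------------------------------------------------------------
# power and effect-size conversions

def power_paired_t(d_z: float, alpha: float = 0.05,
                   target_power: float = 0.80, n_max: int = 10_000) -> int:
    """Smallest n giving a two-tailed paired t-test >= target power.

    Power is computed exactly from the noncentral t distribution with
    noncentrality d_z * sqrt(n) and df = n - 1.
    """
    if d_z <= 0:
        raise ValueError("d_z must be > 0")
    if not (0 < alpha < 1 and 0 < target_power < 1):
        raise ValueError("alpha and target_power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        tc = sps.t.ppf(1 - alpha / 2, df)
        nc = d_z * math.sqrt(n)
        power = sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc)
        if power >= target_power:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches the target power")


def paired_t_power(n: int, d_z: float, alpha: float = 0.05) -> float:
    """Exact two-tailed paired t-test power at sample size n."""
    df = n - 1
    tc = sps.t.ppf(1 - alpha / 2, df)
    nc = d_z * math.sqrt(n)
    return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))


def cohens_f_from_F(F: float, df_num: float, df_den: float) -> float:
    """Cohen's f from an observed F ratio via the partial eta-squared identity.

    eta_p^2 = df_num F / (df_num F + df_den) and f = sqrt(eta_p^2/(1-eta_p^2)),
    which collapses to f = sqrt(df_num * F / df_den).
    """
    if F < 0 or df_num <= 0 or df_den <= 0:
        raise ValueError("F must be >= 0 and dfs > 0")
    return math.sqrt(df_num * F / df_den)


# ---------------------------------------------------------------------------
# JZS Bayes factor

def jzs_bf_ttest(t: float, n: int | None = None,
                 n1: int | None = None, n2: int | None = None,
                 r: float = math.sqrt(2) / 2) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a t statistic.

    The standardized effect size has a zero-centred Cauchy prior with scale
    ``r``; marginalizing its mixing variable g (inverse-gamma(1/2, 1/2))
    gives the one-dimensional integral evaluated here by adaptive
    quadrature.  ``n`` for one-sample/paired designs; ``n1``/``n2`` for
    two-sample, where the effective sample size is n1 n2/(n1 + n2) and
    df = n1 + n2 - 2.
    """
    if n is not None:
        neff, df = float(n), n - 1
    elif n1 is not None and n2 is not None:
        neff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2
    else:
        raise ValueError("provide n, or n1 and n2")
    if df < 1:
        raise ValueError("need df >= 1")

    t2 = t * t

    def log_likelihood(scale2: float) -> float:
        # log of (1 + t^2 / (scale2 * df))^(-(df+1)/2) / sqrt(scale2)
        return -0.5 * math.log(scale2) - (df + 1) / 2 * math.log1p(t2 / (scale2 * df))

    log_null = -(df + 1) / 2 * math.log1p(t2 / df)

    def integrand(g: float) -> float:
        scale2 = 1.0 + neff * g * r * r
        log_prior = -0.5 * math.log(2 * math.pi) - 1.5 * math.log(g) - 1.0 / (2 * g)
        return math.exp(log_likelihood(scale2) + log_prior - log_null)

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(num)
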