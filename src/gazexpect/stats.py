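"""Statistical battery: repeated-measures ANOVA, paired / signed-rank
tests, and subject-level (clustered) categorical tests.

Every routine returns a :class:`StatResult` carrying the statistic, degrees
of freedom, p-value, an effect size with its name, a confidence interval
where the test defines one, and a correction tag.

The clustered tests treat the participant as the sampling unit: category
proportions are estimated as unweighted means of per-cluster proportions
(robust to informative cluster size) and their sampling variability is
taken from the empirical between-cluster spread.  Because only a few dozen
clusters are available, reference distributions account for the estimated
covariance: the goodness-of-fit Wald statistic is referred to the
Hotelling T-squared F distribution and the one-sample proportion z to a
t distribution with (clusters - 1) degrees of freedom.  With one
observation per cluster both reduce to their classical one-sample
analogues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "rm_anova",
    "paired_tests",
    "wilcoxon_signed_rank",
    "clustered_gof",
    "clustered_prop_test",
    "gg_epsilon",
    "cramers_v",
    "cohens_h",
]


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple | float
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (np.isnan(self.p_value)
                                             or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for an (n_subjects, k_levels) matrix.

    Computed from the double-centred covariance matrix; clamped to
    ``[1/(k-1), 1]``.  With two levels sphericity cannot be violated and
    epsilon is 1.
    """
    k = data.shape[1]
    if k <= 2:
        return 1.0
    s = np.cov(data, rowvar=False, ddof=1)
    # double centring
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    dc = s - row - col + s.mean()
    num = np.trace(dc) ** 2
    den = (k - 1) * np.sum(dc * dc)
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def _long_to_cells(table, subject, factors, value):
    """Pivot a long table to per-subject cell means; error on missing cells."""
    import pandas as pd
    df = table[[subject, *factors, value]].copy()
    grouped = df.groupby([subject, *factors], sort=True)[value].mean()
    wide = grouped.unstack(factors if len(factors) > 1 else factors[0])
    if wide.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    return wide


def rm_anova(table, subject: str, factors: list[str], value: str) -> list[StatResult]:
    """Within-subject ANOVA (one or two factors) from sums of squares.

    ``table`` is long format; replicate rows per cell are averaged first
    (the design must be complete).  Returns one :class:`StatResult` per
    effect, each with uncorrected and Greenhouse-Geisser-corrected
    p-values (the headline ``p_value`` is the corrected one), plus
    generalized and partial eta-squared.
    """
    wide = _long_to_cells(table, subject, factors, value)
    y = wide.to_numpy(dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")

    if len(factors) == 1:
        k = y.shape[1]
        grand = y.mean()
        ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_a = n * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_tot = np.sum((y - grand) ** 2)
        ss_err = ss_tot - ss_subj - ss_a
        df_a, df_e = k - 1, (k - 1) * (n - 1)
        ms_a, ms_e = ss_a / df_a, ss_err / df_e
        f = ms_a / ms_e if ms_e > 0 else 0.0
        eps = gg_epsilon(y)
        p_unc = float(sps.f.sf(f, df_a, df_e)) if ms_e > 0 else 1.0
        p_gg = float(sps.f.sf(f, df_a * eps, df_e * eps)) if ms_e > 0 else 1.0
        eta_p = ss_a / (ss_a + ss_err) if (ss_a + ss_err) > 0 else 0.0
        eta_g = ss_a / (ss_a + ss_subj + ss_err) if (ss_a + ss_subj + ss_err) > 0 else 0.0
        return [StatResult(
            name=factors[0], statistic=float(f),
            df=(df_a * eps, df_e * eps), p_value=p_gg,
            effect_size=float(eta_g), effect_size_name="eta2_generalized",
            correction="greenhouse_geisser",
            extra={"p_uncorrected": p_unc, "df_uncorrected": (df_a, df_e),
                   "epsilon": eps, "eta2_partial": float(eta_p),
                   "ss_effect": float(ss_a), "ss_error": float(ss_err),
                   "ss_subject": float(ss_subj)},
        )]

    if len(factors) != 2:
        raise ValueError("rm_anova supports one or two within-subject factors")

    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    cube = y.reshape(n, a, b)
    grand = cube.mean()
    subj_m = cube.mean(axis=(1, 2))
    a_m = cube.mean(axis=(0, 2))
    b_m = cube.mean(axis=(0, 1))
    ab_m = cube.mean(axis=0)
    as_m = cube.mean(axis=2)
    bs_m = cube.mean(axis=1)

    ss_subj = a * b * np.sum((subj_m - grand) ** 2)
    ss_a = n * b * np.sum((a_m - grand) ** 2)
    ss_b = n * a * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = b * np.sum((as_m - a_m[None, :] - subj_m[:, None] + grand) ** 2)
    ss_bs = a * np.sum((bs_m - b_m[None, :] - subj_m[:, None] + grand) ** 2)
    ss_tot = np.sum((cube - grand) ** 2)
    ss_abs = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    # orthonormal within-factor contrasts for the per-effect epsilons
    from scipy.linalg import helmert
    ca = helmert(a).T                     # (a, a-1), orthonormal columns
    cb = helmert(b).T
    m_a = np.kron(ca, np.ones((b, 1)) / b)
    m_b = np.kron(np.ones((a, 1)) / a, cb)
    m_ab = np.kron(ca, cb)
    flat = cube.reshape(n, a * b)

    def eps_for(mat_c):
        if mat_c.shape[1] <= 1:
            return 1.0
        sig = np.cov(flat @ mat_c, rowvar=False, ddof=1)
        sig = np.atleast_2d(sig)
        den = mat_c.shape[1] * np.sum(sig * sig)
        if den <= 0:
            return 1.0
        return float(min(1.0, max(1.0 / mat_c.shape[1],
                                  np.trace(sig) ** 2 / den)))

    results = []
    specs = [
        (factors[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), m_a),
        (factors[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), m_b),
        (f"{factors[0]}*{factors[1]}", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1), m_ab),
    ]
    ss_all_err = ss_as + ss_bs + ss_abs
    for name, ss_eff, df_eff, ss_err, df_err, mat_c in specs:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        eps = eps_for(mat_c)
        p_unc = float(sps.f.sf(f, df_eff, df_err)) if ms_err > 0 else 1.0
        p_gg = float(sps.f.sf(f, df_eff * eps, df_err * eps)) if ms_err > 0 else 1.0
        eta_p = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        denom_g = ss_eff + ss_subj + ss_all_err
        eta_g = ss_eff / denom_g if denom_g > 0 else 0.0
        results.append(StatResult(
            name=name, statistic=float(f),
            df=(df_eff * eps, df_err * eps), p_value=p_gg,
            effect_size=float(eta_p), effect_size_name="eta2_partial",
            correction="greenhouse_geisser",
            extra={"p_uncorrected": p_unc, "df_uncorrected": (df_eff, df_err),
                   "epsilon": eps, "eta2_generalized": float(eta_g),
                   "ss_effect": float(ss_eff), "ss_error": float(ss_err)},
        ))
    return results


# ---------------------------------------------------------------------------
# paired t and Wilcoxon
# ---------------------------------------------------------------------------

def paired_tests(x, y, alternative: str = "two-sided",
                 k_bonferroni: int = 1) -> StatResult:
    """Paired t-test with Cohen's d and a CI on the mean difference.

    ``d = mean(diff) / sd(diff)``; the Bonferroni family size multiplies
    the p-value (capped at 1).  Zero-variance differences leave d and the
    CI undefined (flagged in ``extra``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    diff = x - y
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        return StatResult(name="paired_t", statistic=float("nan"), df=n - 1,
                          p_value=float("nan"), effect_size=None,
                          effect_size_name="cohens_d",
                          correction=f"bonferroni_{k_bonferroni}" if k_bonferroni > 1 else "none",
                          extra={"degenerate": "zero variance of differences"})
    res = sps.ttest_rel(x, y, alternative=alternative)
    se = sd / math.sqrt(n)
    d = diff.mean() / sd
    if alternative == "two-sided":
        tcrit = sps.t.ppf(0.975, n - 1)
        ci = (diff.mean() - tcrit * se, diff.mean() + tcrit * se)
    elif alternative == "greater":
        ci = (diff.mean() - sps.t.ppf(0.95, n - 1) * se, float("inf"))
    else:
        ci = (float("-inf"), diff.mean() + sps.t.ppf(0.95, n - 1) * se)
    p = min(1.0, float(res.pvalue) * k_bonferroni)
    return StatResult(
        name="paired_t", statistic=float(res.statistic), df=n - 1, p_value=p,
        effect_size=float(d), effect_size_name="cohens_d",
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        correction=f"bonferroni_{k_bonferroni}" if k_bonferroni > 1 else "none",
        extra={"p_unadjusted": float(res.pvalue), "mean_diff": float(diff.mean())},
    )


def wilcoxon_signed_rank(x, y=None, mu0: float = 0.0,
                         alternative: str = "two-sided",
                         k_bonferroni: int = 1) -> StatResult:
    """(One-sample or paired) Wilcoxon signed-rank test with effect size r.

    Differences ``x - y`` (or ``x - mu0``) with zeros removed; the exact
    null distribution is used for n <= 25 without ties, otherwise the
    normal approximation with continuity and tie correction.  The effect
    size is ``r = |z| / sqrt(n)`` from the (always computed) approximation.
    """
    x = np.asarray(x, dtype=float)
    diff = x - (np.asarray(y, dtype=float) if y is not None else mu0)
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return StatResult(name="wilcoxon", statistic=float("nan"), df=n,
                          p_value=float("nan"), effect_size=None,
                          effect_size_name="wilcoxon_r",
                          extra={"degenerate": "all differences zero"})
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")

    ranks = sps.rankdata(np.abs(diff))
    v_plus = float(ranks[diff > 0].sum())

    # normal approximation (continuity + tie corrected) for z and r
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (v_plus - mu - 0.5 * np.sign(v_plus - mu)) / sigma if v_plus != mu else 0.0
    elif alternative == "greater":
        z = (v_plus - mu - 0.5) / sigma
    else:
        z = (v_plus - mu + 0.5) / sigma

    exact_ok = n <= 25 and np.unique(np.abs(diff)).size == n
    if exact_ok:
        p = float(sps.wilcoxon(diff, alternative=alternative, method="exact").pvalue)
        method = "exact"
    else:
        if alternative == "two-sided":
            p = 2.0 * float(sps.norm.sf(abs(z)))
            p = min(1.0, p)
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        method = "normal_approx"
    p = min(1.0, p * k_bonferroni)
    r = abs(z) / math.sqrt(n)
    return StatResult(
        name="wilcoxon", statistic=v_plus, df=n, p_value=p,
        effect_size=float(r), effect_size_name="wilcoxon_r",
        correction=f"bonferroni_{k_bonferroni}" if k_bonferroni > 1 else "none",
        extra={"z": float(z), "method": method},
    )


# ---------------------------------------------------------------------------
# clustered categorical tests
# ---------------------------------------------------------------------------

def cramers_v(chi2: float, n_obs: int, k: int) -> float:
    """Cramer's V for a goodness-of-fit chi-square: sqrt(chi2 / (N (k-1))).

    ``n_obs`` is the total observation (trial) count, not the number of
    clusters.
    """
    return math.sqrt(chi2 / (n_obs * (k - 1)))


def cohens_h(p1: float, p2: float) -> float:
    """Effect size for a difference of proportions (arcsine scale)."""
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))


def clustered_gof(counts, pi, n_obs: int | None = None) -> StatResult:
    """Subject-level chi-square goodness-of-fit test for clustered data.

    ``counts`` is an (m_clusters, k_categories) array of category counts
    per cluster; ``pi`` the null category proportions.  Per-cluster
    proportions are averaged with equal cluster weight and a Wald
    statistic is formed with their empirical between-cluster covariance;
    with few clusters the p-value comes from the Hotelling T-squared
    F reference.  Cramer's V uses the total observation count.
    Clusters with zero observations are dropped.
    """
    counts = np.asarray(counts, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != pi.size:
        raise ValueError("counts must be (clusters x categories) matching pi")
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("null proportions must sum to 1")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        import warnings
        warnings.warn("dropping clusters with zero observations")
        counts = counts[totals > 0]
        totals = totals[totals > 0]
    m, k = counts.shape
    if m < 2:
        raise ValueError("need at least two non-empty clusters")
    props = counts / totals[:, None]
    pbar = props.mean(axis=0)
    d = (pbar - pi)[: k - 1]
    s = np.cov(props[:, : k - 1], rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    chi2 = float(m * d @ np.linalg.pinv(s) @ d)
    # small-sample reference: Hotelling T2 -> F
    q = k - 1
    if m > q:
        f_stat = chi2 * (m - q) / ((m - 1) * q)
        p = float(sps.f.sf(f_stat, q, m - q))
    else:
        p = float(sps.chi2.sf(chi2, q))
    n_total = int(n_obs if n_obs is not None else totals.sum())
    v = cramers_v(chi2, n_total, k)
    return StatResult(
        name="clustered_gof", statistic=chi2, df=q, p_value=p,
        effect_size=float(v), effect_size_name="cramers_v",
        extra={"n_clusters": m, "n_obs": n_total, "estimate": pbar.tolist()},
    )


def clustered_prop_test(successes, totals, pi0: float,
                        alternative: str = "two-sided",
                        k_bonferroni: int = 1) -> StatResult:
    """One-sample test of a marginal proportion for clustered data.

    The estimate is the unweighted mean of per-cluster proportions; its
    standard error is the between-cluster sample SD over sqrt(m).  The z
    statistic is referred to a t distribution with m - 1 degrees of
    freedom (exactly the classical one-sample t when clusters have size
    one).  Effect size: the average of per-cluster Cohen's h against
    ``pi0``.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if successes.shape != totals.shape:
        raise ValueError("successes and totals must have equal length")
    keep = totals > 0
    successes, totals = successes[keep], totals[keep]
    m = successes.size
    if m < 2:
        raise ValueError("need at least two clusters with observations")
    if not 0.0 < pi0 < 1.0:
        raise ValueError("pi0 must be in (0, 1)")
    props = successes / totals
    est = float(props.mean())
    sd = float(props.std(ddof=1))
    se = sd / math.sqrt(m)
    if se == 0:
        z = 0.0 if est == pi0 else math.inf * np.sign(est - pi0)
    else:
        z = (est - pi0) / se
    if alternative == "two-sided":
        p = 2.0 * float(sps.t.sf(abs(z), m - 1)) if np.isfinite(z) else 0.0
        tcrit = sps.t.ppf(0.975, m - 1)
        ci = (est - tcrit * se, est + tcrit * se)
    elif alternative == "greater":
        p = float(sps.t.sf(z, m - 1)) if np.isfinite(z) else 0.0
        ci = (est - sps.t.ppf(0.95, m - 1) * se, 1.0)
    else:
        p = float(sps.t.cdf(z, m - 1)) if np.isfinite(z) else 0.0
        ci = (0.0, est + sps.t.ppf(0.95, m - 1) * se)
    if est == pi0 and se == 0:
        p = 1.0
    p_adj = min(1.0, p * k_bonferroni)
    h = float(np.mean([cohens_h(pc, pi0) for pc in props]))
    return StatResult(
        name="clustered_prop", statistic=float(z), df=m - 1, p_value=p_adj,
        effect_size=h, effect_size_name="cohens_h_mean",
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        correction=f"bonferroni_{k_bonferroni}" if k_bonferroni > 1 else "none",
        extra={"estimate": est, "se": se, "n_clusters": m,
               "p_unadjusted": p},
    )
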