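"""Statistical tests used across the analysis arms.

Implements the group-comparison layer: Pearson chi-square tests of
independence with standardized-residual post hocs, the semi-parametric
one-way MANOVA based on the modified ANOVA-type statistic (MATS) with
parametric-bootstrap p-values, a mixed-design (repeated-measures) ANOVA for
neighbor-rank profiles, the two-sample Wilcoxon rank-sum test, and the
Bonferroni / Benjamini-Hochberg multiplicity adjustments.

The MATS is the key piece: for ``a`` groups with mean vectors ``mu_i`` of
dimension ``p`` it tests H0: ``mu_1 = ... = mu_a`` without assuming
multivariate normality or covariance homogeneity,

    Q_N = N * ybar' T (T D_N T)^+ T ybar,

where ``ybar`` stacks the group sample means, ``T = (I_a - J_a/a) (x) I_p``
is the centering contrast projection, and ``D_N`` is the diagonal of the
block-diagonal estimated covariance of ``ybar`` (group covariances scaled by
``N / n_i``).  Its null distribution is approximated by a parametric
bootstrap that redraws each group from a centered multivariate normal with
that group's empirical covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "adjust",
    "chisq_independence",
    "mats_manova",
    "rm_anova",
    "rank_sum",
]


@dataclass
class GroupTestResult:
    """Outcome of a group comparison.

    Attributes
    ----------
    statistic_name, statistic : name and value of the test statistic.
    p_value : overall p-value of the test.
    df : degrees of freedom where the statistic has a classical reference
        distribution; ``None`` for bootstrap-calibrated statistics.
    posthoc : table of follow-up comparisons (comparison, raw p,
        adjusted p, adjustment method); empty when not requested.
    alpha : significance level attached to the analysis arm.
    bootstrap : metadata (``B``, ``seed``) for bootstrap-based p-values.
    """

    statistic_name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05
    bootstrap: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# multiplicity adjustment
# ---------------------------------------------------------------------------

def adjust(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``bonferroni``: ``min(1, m * p)``.  ``BH``: Benjamini-Hochberg step-up,
    ``p_(i) * m / i`` with a cumulative minimum from the largest p downward.
    Both are monotone and never smaller than the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method.lower() == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method.upper() == "BH":
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method: {method!r}")


# ---------------------------------------------------------------------------
# chi-square independence with standardized-residual post hoc
# ---------------------------------------------------------------------------

def chisq_independence(
    table: pd.DataFrame | np.ndarray,
    *,
    pairwise_columns: bool = False,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction is applied.  The post-hoc table reports the
    standardized residual of every cell,

        r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - p_i.)(1 - p_.j)),

    with two-sided normal p-values Bonferroni-corrected by the cell count.
    With ``pairwise_columns=True`` each pair of columns is additionally
    compared by its own chi-square test, Bonferroni-corrected over pairs.
    """
    tab = pd.DataFrame(table)
    obs = tab.to_numpy(dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")

    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)

    n = obs.sum()
    prow = obs.sum(axis=1, keepdims=True) / n
    pcol = obs.sum(axis=0, keepdims=True) / n
    resid = (obs - expected) / np.sqrt(expected * (1 - prow) * (1 - pcol))
    praw = 2 * stats.norm.sf(np.abs(resid))
    padj = adjust(praw.ravel(), "bonferroni").reshape(praw.shape)

    rows = []
    for i, ri in enumerate(tab.index):
        for j, cj in enumerate(tab.columns):
            rows.append(
                {
                    "comparison": f"cell[{ri},{cj}]",
                    "residual": resid[i, j],
                    "p_raw": praw[i, j],
                    "p_adj": padj[i, j],
                    "method": "bonferroni",
                }
            )
    posthoc = pd.DataFrame(rows)

    if pairwise_columns:
        cols = list(tab.columns)
        pair_rows, pair_p = [], []
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                sub = obs[:, [a, b]]
                keep = sub.sum(axis=1) > 0
                c2, pp, dd, _ = stats.chi2_contingency(sub[keep], correction=False)
                pair_rows.append(
                    {"comparison": f"{cols[a]} vs {cols[b]}", "statistic": c2, "df": dd}
                )
                pair_p.append(pp)
        pair_adj = adjust(pair_p, "bonferroni")
        for row, pr, pa in zip(pair_rows, pair_p, pair_adj):
            row.update(p_raw=pr, p_adj=pa, method="bonferroni")
        posthoc = pd.concat([posthoc, pd.DataFrame(pair_rows)], ignore_index=True)

    return GroupTestResult("X-squared", chi2, p, df=dof, posthoc=posthoc, alpha=alpha)


# ---------------------------------------------------------------------------
# semi-parametric MANOVA (MATS + parametric bootstrap)
# ---------------------------------------------------------------------------

def _mats_statistic(means: np.ndarray, covs: np.ndarray, ns: np.ndarray) -> float:
    """MATS for group means (a x p), group covariances (a x p x p), sizes."""
    a, p = means.shape
    N = ns.sum()
    ybar = means.ravel()
    # covariance of the stacked mean vector, scaled by N
    dvec = np.concatenate([(N / ns[i]) * np.diag(covs[i]) for i in range(a)])
    Pa = np.eye(a) - np.full((a, a), 1.0 / a)
    T = np.kron(Pa, np.eye(p))
    Ty = T @ ybar
    M = T @ np.diag(dvec) @ T
    return float(N * Ty @ np.linalg.pinv(M) @ Ty)


def mats_manova(
    data: pd.DataFrame | np.ndarray,
    groups: Sequence,
    *,
    B: int = 999,
    seed: int | None = None,
    exclude: Sequence[str] = (),
    posthoc: bool = True,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Semi-parametric one-way MANOVA via the MATS statistic.

    Neither multivariate normality nor covariance homogeneity is assumed.
    The p-value comes from ``B`` parametric-bootstrap replicates drawn
    group-wise from ``N(0, S_i)`` with each group's empirical covariance
    ``S_i``; p = (1 + #{Q* >= Q}) / (B + 1).

    ``exclude`` drops columns (by name) from the variable set before
    testing — used to remove shape moments that duplicate the first moment.
    The post hoc runs the same statistic per variable on every group pair,
    Bonferroni-corrected over (pair, variable) comparisons.
    """
    df = pd.DataFrame(data).drop(columns=list(exclude), errors="ignore")
    cols = list(df.columns)
    X = df.to_numpy(dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    idx = [np.flatnonzero(g == lab) for lab in labels]
    if min(len(i) for i in idx) < 2:
        raise ValueError("need at least 2 observations per group")

    means = np.stack([X[i].mean(axis=0) for i in idx])
    covs = np.stack([np.cov(X[i], rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
                     for i in idx])
    ns = np.array([len(i) for i in idx])
    for j, c in enumerate(cols):
        if np.all(covs[:, j, j] == 0):
            raise ValueError(f"zero-variance variable: {c!r}")

    Q = _mats_statistic(means, covs, ns)

    rng = np.random.default_rng(seed)
    chols = [np.linalg.cholesky(covs[i] + 1e-12 * np.eye(len(cols)))
             for i in range(len(labels))]
    exceed = 0
    for _ in range(B):
        bmeans = np.empty_like(means)
        bcovs = np.empty_like(covs)
        for i in range(len(labels)):
            z = rng.standard_normal((ns[i], len(cols))) @ chols[i].T
            bmeans[i] = z.mean(axis=0)
            bcovs[i] = np.cov(z, rowvar=False, ddof=1).reshape(len(cols), len(cols))
        if _mats_statistic(bmeans, bcovs, ns) >= Q:
            exceed += 1
    p = (1 + exceed) / (B + 1)

    post = pd.DataFrame()
    if posthoc:
        rows, praw = [], []
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                for j, c in enumerate(cols):
                    m2 = means[np.ix_([ai, bi], [j])]
                    c2 = covs[np.ix_([ai, bi], [j], [j])]
                    n2 = ns[[ai, bi]]
                    q = _mats_statistic(m2, c2, n2)
                    # univariate bootstrap under the pair's null
                    s = np.sqrt(np.array([c2[0, 0, 0], c2[1, 0, 0]]))
                    qb = _pairwise_univariate_null(s, n2, B, rng)
                    pj = (1 + int(np.sum(qb >= q))) / (B + 1)
                    rows.append(
                        {"comparison": f"{labels[ai]} vs {labels[bi]}: {c}",
                         "statistic": q}
                    )
                    praw.append(pj)
        if rows:
            padj = adjust(praw, "bonferroni")
            for row, pr, pa in zip(rows, praw, padj):
                row.update(p_raw=pr, p_adj=pa, method="bonferroni")
            post = pd.DataFrame(rows)

    return GroupTestResult(
        "MATS", Q, p, df=None, posthoc=post, alpha=alpha,
        bootstrap={"B": B, "seed": seed},
    )


def _pairwise_univariate_null(sd: np.ndarray, ns: np.ndarray, B: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Vectorized bootstrap null of the univariate two-group MATS."""
    N = ns.sum()
    z1 = rng.standard_normal((B, ns[0])) * sd[0]
    z2 = rng.standard_normal((B, ns[1])) * sd[1]
    d = z1.mean(axis=1) - z2.mean(axis=1)
    v1 = z1.var(axis=1, ddof=1)
    v2 = z2.var(axis=1, ddof=1)
    # MATS for a = 2, p = 1 reduces to N * d^2 / (2 * (N/n1 v1 + N/n2 v2) / 2)
    denom = 0.5 * (N / ns[0] * v1 + N / ns[1] * v2)
    return N * (d / 2) ** 2 * 2 / denom


# ---------------------------------------------------------------------------
# mixed-design (repeated-measures) ANOVA
# ---------------------------------------------------------------------------

def rm_anova(
    data: pd.DataFrame,
    *,
    subject: str = "subject",
    within: str = "k",
    between: str = "group",
    value: str = "value",
    alpha: float = 0.05,
    correction: bool = False,
) -> GroupTestResult:
    """Mixed-design ANOVA: between-subject group, within-subject level.

    Subjects missing any within-level are dropped with a warning.  The
    reported statistic is the F for the between-group effect.  The post-hoc
    table compares groups at every within-level (Welch t-tests), with
    Benjamini-Hochberg adjustment across all comparisons.  Sphericity
    correction is off by default (``correction=True`` enables
    Greenhouse-Geisser via pingouin).
    """
    import warnings

    import pingouin as pg

    df = data[[subject, within, between, value]].dropna().copy()
    levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    bad = counts[counts < levels].index
    if len(bad):
        warnings.warn(f"dropping {len(bad)} subject(s) with missing within-levels")
        df = df[~df[subject].isin(bad)]

    with warnings.catch_warnings():
        # degenerate (zero-residual) designs trigger harmless 0/0 warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(
            data=df, dv=value, within=within, subject=subject, between=between,
            correction=correction,
        )
    row = aov[aov["Source"] == between].iloc[0]
    F = float(row["F"])
    p = float(row["p_unc"] if "p_unc" in aov.columns else row["p-unc"])
    dfs = (float(row["DF1"]), float(row["DF2"]))

    groups = sorted(df[between].unique())
    rows, praw = [], []
    for k, sub in df.groupby(within):
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                xa = sub.loc[sub[between] == groups[a], value]
                xb = sub.loc[sub[between] == groups[b], value]
                t, pp = stats.ttest_ind(xa, xb, equal_var=False)
                rows.append(
                    {"comparison": f"{within}={k}: {groups[a]} vs {groups[b]}",
                     "statistic": float(t)}
                )
                praw.append(float(pp))
    padj = adjust(praw, "BH")
    for row_, pr, pa in zip(rows, praw, padj):
        row_.update(p_raw=pr, p_adj=pa, method="BH")

    res = GroupTestResult("F", F, p, df=dfs, posthoc=pd.DataFrame(rows), alpha=alpha)
    res.bootstrap = {"anova_table": aov}
    return res


# ---------------------------------------------------------------------------
# two-sample Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def rank_sum(x: Sequence[float], y: Sequence[float], *, alpha: float = 0.05) -> GroupTestResult:
    """Two-sample Wilcoxon (Mann-Whitney) rank-sum test, two-sided.

    Exact p for small samples without ties; normal approximation with
    midrank tie correction otherwise (no continuity correction, so equal
    samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto",
                             use_continuity=False)
    return GroupTestResult("W", float(res.statistic), float(res.pvalue), alpha=alpha)
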