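"""Cross-study differential expression between Gleason grade groups.

Per study: log fold change (mean log2 expression of grade >=8 minus grade
<=6) with an empirical-Bayes moderated t-test — per-gene variances are shrunk
toward a prior (d0, s0^2) estimated by moment-matching the distribution of
log sample variances (digamma/trigamma inversion).  Across studies: Fisher's
method on two-sided p-values, Benjamini-Hochberg adjustment, and a
sign-consistency filter (logFC > 0 in every study = up, < 0 in every = down).
Also the cross-study correlation analyses: pairwise logFC correlation and
Spearman correlation of per-gene anchor-correlation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .studydata import StudyBundle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the Newton step is taken on the reciprocal
    scale for stability.  Large y -> small x (~1/sqrt(y) start); tiny y ->
    x ~ 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Given per-gene sample variances ``s2`` on ``df`` degrees of freedom, the
    log-variances satisfy E[log s2_g] = log s0^2 + psi(d_g/2) - log(d_g/2)
    - (psi(d0/2) - log(d0/2)) and Var[log s2_g] = psi'(d_g/2) + psi'(d0/2).
    Returns (d0, s0^2); d0 = inf when the excess variance of log s2 is
    non-positive (no evidence of variance heterogeneity beyond sampling).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df[ok] / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def posterior_variance(s2, df, d0: float, s0_2: float):
    """Shrunken variance: convex combination (d0*s0^2 + d*s2)/(d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


@dataclass
class StudyDE:
    """Per-gene moderated-t differential expression for one study."""

    study: str
    table: pd.DataFrame  # index gene; logfc, t, p, df, s2, n_high, n_low
    d0: float
    s0_2: float
    high_label: str = ">=8"
    low_label: str = "<=6"
    excluded: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def moderated_t_table(
    high: pd.DataFrame,
    low: pd.DataFrame,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Moderated two-group comparison of two genes-x-samples frames.

    Complete-case per gene per group.  ``prior_df`` overrides the estimated
    d0: 0 recovers the ordinary pooled-variance t-test, inf a normal test on
    the pooled prior variance.
    """
    genes = high.index
    h = high.to_numpy(dtype=float)
    l = low.to_numpy(dtype=float)
    nh = np.sum(~np.isnan(h), axis=1)
    nl = np.sum(~np.isnan(l), axis=1)
    usable = (nh >= 2) & (nl >= 2)

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mh = np.nanmean(h, axis=1)
        ml = np.nanmean(l, axis=1)
        ssh = np.nansum((h - mh[:, None]) ** 2, axis=1)
        ssl = np.nansum((l - ml[:, None]) ** 2, axis=1)
    df = nh + nl - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, (ssh + ssl) / df, np.nan)
    logfc = mh - ml

    s2_u = s2[usable]
    df_u = df[usable]
    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2_u, df_u)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.nan)
    elif np.isinf(prior_df):
        _, s0_2 = estimate_variance_prior(s2_u, df_u)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2_u, df_u)

    if d0 == 0:
        s2_post = s2_u
    else:
        s2_post = posterior_variance(s2_u, df_u, d0, s0_2)
    se = np.sqrt(s2_post * (1.0 / nh[usable] + 1.0 / nl[usable]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc[usable] / se, 0.0)
    df_total = df_u + (0.0 if d0 == 0 else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "logfc": logfc[usable],
            "t": t,
            "p": p,
            "df": df_u,
            "s2": s2_u,
            "s2_post": s2_post,
            "n_high": nh[usable].astype(int),
            "n_low": nl[usable].astype(int),
        },
        index=genes[usable],
    )
    return out, d0, (s0_2 if d0 != 0 else float("nan"))


def differential_expression(
    study: StudyBundle,
    high_label: str = ">=8",
    low_label: str = "<=6",
    group_field: str = "grade_group",
    prior_df: float | None = None,
) -> StudyDE:
    """Moderated-t DE between two grade groups of one study's expression."""
    if study.expression is None:
        raise ValueError(f"study {study.name!r} has no expression assay")
    clin = study.clinical.data
    groups = clin.set_index("sample_id")[group_field]
    expr = study.expression.data
    groups = groups.reindex(expr.columns)
    high_ids = groups.index[groups == high_label]
    low_ids = groups.index[groups == low_label]
    if len(high_ids) < 2 or len(low_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(high_ids)} {high_label!r} "
            f"and {len(low_ids)} {low_label!r}"
        )
    all_missing = expr.isna().all(axis=1)
    excluded = list(expr.index[all_missing])
    if excluded:
        logger.warning("excluding %d all-missing gene(s)", len(excluded))
        expr = expr.loc[~all_missing]
    table, d0, s0_2 = moderated_t_table(
        expr[high_ids], expr[low_ids], prior_df=prior_df
    )
    excluded += [g for g in expr.index if g not in table.index]
    return StudyDE(
        study=study.name, table=table, d0=d0, s0_2=s0_2,
        high_label=high_label, low_label=low_label, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Cross-study combination


def fisher_combine(pvals) -> tuple[float, float]:
    """Fisher's method: X2 = -2 sum(ln p), upper tail of chi-square(2k)."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.sum(np.log(p)))
    combined = float(stats.chi2.sf(statistic, 2 * p.size))
    return statistic, combined


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Meta-analysis table: per-study logFC/p, Fisher statistic/p, BH q,
    sign-consistency, and the selected up/down gene sets."""

    table: pd.DataFrame
    q_threshold: float
    studies: list[str]

    @property
    def up_genes(self) -> list[str]:
        t = self.table
        return list(t.index[(t["q"] < self.q_threshold) & (t["sign_consistent"] == "up")])

    @property
    def down_genes(self) -> list[str]:
        t = self.table
        return list(t.index[(t["q"] < self.q_threshold) & (t["sign_consistent"] == "down")])


def meta_de(studies: list[StudyDE], q_threshold: float = 0.01) -> DEResult:
    """Fisher-combine per-study p-values over the common gene set, BH-adjust,
    and flag genes consistently up- or down-regulated in every study."""
    if len(studies) < 2:
        raise ValueError("need >= 2 studies for meta-analysis")
    common = studies[0].genes
    for s in studies[1:]:
        common = common.intersection(s.genes)
    if len(common) == 0:
        raise ValueError("empty gene intersection across studies")
    common = pd.Index(sorted(common))

    logfc = np.column_stack([s.table.loc[common, "logfc"].to_numpy() for s in studies])
    pmat = np.column_stack([s.table.loc[common, "p"].to_numpy() for s in studies])
    k = len(studies)
    statistic = -2.0 * np.sum(np.log(pmat), axis=1)
    fisher_p = stats.chi2.sf(statistic, 2 * k)
    fisher_p = np.clip(fisher_p, np.finfo(float).tiny, 1.0)
    q = bh_adjust(fisher_p)
    sign = np.where(
        (logfc > 0).all(axis=1), "up", np.where((logfc < 0).all(axis=1), "down", "mixed")
    )
    table = pd.DataFrame(
        {
            **{f"logfc_{s.study}": logfc[:, i] for i, s in enumerate(studies)},
            **{f"p_{s.study}": pmat[:, i] for i, s in enumerate(studies)},
            "fisher_stat": statistic,
            "fisher_p": fisher_p,
            "q": q,
            "sign_consistent": sign,
            "n_studies": k,
        },
        index=common,
    )
    return DEResult(table=table, q_threshold=q_threshold, studies=[s.study for s in studies])


def pairwise_logfc_correlation(a: StudyDE, b: StudyDE) -> tuple[float, float, int]:
    """Pearson correlation of two studies' logFC vectors over their common genes."""
    common = a.genes.intersection(b.genes)
    if len(common) < 3:
        raise ValueError(f"need >= 3 common genes, got {len(common)}")
    r, p = stats.pearsonr(
        a.table.loc[common, "logfc"], b.table.loc[common, "logfc"]
    )
    return float(r), float(p), len(common)


def anchor_correlation_profile(matrix, anchor_gene: str) -> pd.Series:
    """Pearson correlation of every other gene with an anchor gene (e.g. AR,
    ERG) across samples; constant genes are recorded as missing."""
    data = matrix.data
    if anchor_gene not in data.index:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from matrix")
    if data.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = data.loc[anchor_gene].to_numpy(dtype=float)
    others = data.drop(index=anchor_gene)
    arr = others.to_numpy(dtype=float)
    xc = x - x.mean()
    denom_x = np.sqrt(np.sum(xc**2))
    yc = arr - arr.mean(axis=1, keepdims=True)
    denom_y = np.sqrt(np.sum(yc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (denom_y * denom_x)
    n_const = int(np.sum(denom_y == 0))
    if n_const or denom_x == 0:
        logger.warning("constant gene(s) in correlation profile recorded as missing")
    if denom_x == 0:
        r = np.full(arr.shape[0], np.nan)
    return pd.Series(r, index=others.index, name=f"corr_{anchor_gene}")


def cross_study_profile_correlation(profiles: dict[str, pd.Series]) -> pd.DataFrame:
    """Spearman correlation matrix between studies' anchor-correlation profiles."""
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need >= 2 studies")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            pa, pb = profiles[a].dropna(), profiles[b].dropna()
            common = pa.index.intersection(pb.index)
            if len(common) < 3:
                logger.warning("insufficient overlap between %s and %s", a, b)
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            rho = stats.spearmanr(pa.loc[common], pb.loc[common])[0]
            out.loc[a, b] = out.loc[b, a] = float(rho)
    return out
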