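"""Moderated differential expression with fold-change and FDR gates.

Per gene, a one-way fixed-effects model (condition means by ordinary least
squares) is fitted and the residual variance is shrunk towards a prior by the
standard empirical-Bayes argument: if s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g
and 1/sigma2_g ~ chi2(d0)/(d0*s2_prior), the posterior variance is

    s2_tilde_g = (d0 * s2_prior + d_g * s2_g) / (d0 + d_g)

and the moderated t statistic  t_g = log2fc_g / (s_tilde_g * c)  follows a
t-distribution on d0 + d_g degrees of freedom under the null (c is the
contrast scaling sqrt(1/n_A + 1/n_B)).  The hyperparameters (s2_prior, d0)
are estimated by matching the first two moments of log s2_g to a scaled log-F
distribution — the classical moment estimator.

A gene is called differentially expressed when its BH-adjusted p-value is
below ``fdr_threshold`` *and* its absolute linear fold change is at least
``fc_threshold`` (default gates 0.1 and 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ValidationError
from .ratio import adjust_fdr

DEFAULT_FDR = 0.1
DEFAULT_FC = 1.5


@dataclass
class ModerationParams:
    """Empirical-Bayes hyperparameters of the variance prior."""

    s2_prior: float
    d0: float  # prior degrees of freedom; may be inf

    def posterior_variance(self, s2_g: np.ndarray, d_g: np.ndarray) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2_g, dtype=float), self.s2_prior)
        return (self.d0 * self.s2_prior + d_g * s2_g) / (self.d0 + d_g)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, monotone target)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2_g, d_g) -> ModerationParams:
    """Moment estimator of (s2_prior, d0) from per-gene variances and residual df.

    Matches mean and variance of log s2_g against the scaled log-F model:
    E[log s2] = log sigma2 + digamma(d/2) - log(d/2) and the excess variance of
    log s2 beyond trigamma(d/2) identifies trigamma(d0/2).
    """
    s2 = np.asarray(s2_g, dtype=float)
    d = np.asarray(d_g, dtype=float)
    ok = (d > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValidationError("need at least two genes with positive residual df")
    s2, d = s2[ok], d[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s2_prior = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s2_prior = np.exp(emean)
    return ModerationParams(float(s2_prior), float(d0))


def _group_stats(matrix: pd.DataFrame, design: pd.Series):
    """Per-gene condition means, pooled residual variance and residual df."""
    samples = [s for s in matrix.columns if s in design.index and not pd.isna(design[s])]
    if len(samples) < len(matrix.columns):
        missing = sorted(set(matrix.columns) - set(samples))
        raise ValidationError(f"sample {missing[0]!r} has no condition in the design")
    X = matrix[samples]
    cond = design.reindex(samples)
    groups = {c: X.loc[:, cond == c] for c in cond.unique()}
    means = pd.DataFrame({c: g.mean(axis=1) for c, g in groups.items()})
    counts = pd.DataFrame({c: g.notna().sum(axis=1) for c, g in groups.items()})
    rss = pd.Series(0.0, index=X.index)
    for c, g in groups.items():
        resid = g.sub(means[c], axis=0)
        rss = rss + (resid**2).sum(axis=1, skipna=True)
    k_used = (counts > 0).sum(axis=1)
    d_g = counts.sum(axis=1) - k_used
    s2_g = rss.where(d_g > 0) / d_g.where(d_g > 0)
    return means, counts, s2_g, d_g.astype(float)


def fit_moderated(
    matrix: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    fdr_threshold: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated test of contrast (A, B): log2fc = mean_B - mean_A.

    ``matrix`` must be on the log2 scale (genes x samples); ``design`` maps
    sample -> condition.  Residual variance is pooled across *all* design
    conditions.  ``d0_override`` forces the prior df (0 recovers the ordinary
    equal-variance t; inf fixes every posterior variance at the prior).
    Genes without residual df or without >=2 samples in each contrasted
    condition are dropped with a warning.
    """
    cond_a, cond_b = contrast
    for c in contrast:
        if c not in set(design.dropna().unique()):
            raise ValidationError(f"condition {c!r} absent from the design")
    means, counts, s2_g, d_g = _group_stats(matrix, design)
    usable = (counts[cond_a] >= 2) & (counts[cond_b] >= 2) & (d_g > 0)
    if not usable.any():
        raise ValidationError(f"no gene has residual df for contrast {cond_b} vs {cond_a}")
    if (~usable).any():
        warnings.warn(f"dropping {(~usable).sum()} gene(s) without residual df for the contrast",
                      stacklevel=2)
    means, counts, s2_g, d_g = means[usable], counts[usable], s2_g[usable], d_g[usable]

    if d0_override is not None:
        params = ModerationParams(float(np.nanmedian(s2_g)) if np.isinf(d0_override) else 1.0,
                                  float(d0_override))
        if np.isinf(d0_override):
            params = ModerationParams(float(estimate_moderation(s2_g, d_g).s2_prior), np.inf)
    else:
        try:
            params = estimate_moderation(s2_g, d_g)
        except ValidationError:
            warnings.warn("hyperparameter estimation failed; falling back to ordinary t",
                          stacklevel=2)
            params = ModerationParams(1.0, 0.0)

    log2fc = means[cond_b] - means[cond_a]
    scale = np.sqrt(1.0 / counts[cond_a] + 1.0 / counts[cond_b])
    s2_post = params.posterior_variance(s2_g.to_numpy(), d_g.to_numpy())
    t = log2fc.to_numpy() / (np.sqrt(s2_post) * scale.to_numpy())
    df_total = params.d0 + d_g.to_numpy()
    if np.isinf(params.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fdr = adjust_fdr(p)
    abs_fc = 2.0 ** np.abs(log2fc.to_numpy())
    passes = (fdr < fdr_threshold) & (abs_fc >= fc_threshold)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_moderated": t,
            "p_value": p,
            "fdr": fdr,
            "abs_linear_fc": abs_fc,
            "passes": passes,
            "s2_residual": s2_g,
            "df_residual": d_g,
            "df_total": df_total,
        },
        index=means.index,
    )
    out.index.name = "gene_id"
    out.attrs["moderation"] = params
    out.attrs["contrast"] = f"{cond_b}_vs_{cond_a}"
    return out


def patient_grade_contrast(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    pair: tuple[str, str],
    fdr_threshold: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC,
) -> pd.DataFrame:
    """Grade contrast on patient expression: log2(count+1)-transformed, then moderated fit.

    ``pair`` is e.g. ('II', 'IV'): log2fc is grade IV relative to the lower
    grade.  Variance is pooled over all grades present in the clinical table.
    """
    grades = clinical.set_index("sample_id")["grade"]
    for g in pair:
        if g not in set(grades.unique()):
            raise ValidationError(f"grade {g!r} absent from the clinical table")
    common = [s for s in matrix.columns if s in grades.index]
    logm = np.log2(matrix[common].astype(float) + 1.0)
    return fit_moderated(logm, grades.loc[common], pair,
                         fdr_threshold=fdr_threshold, fc_threshold=fc_threshold)


def spearman_exact_p(x, y, exact_limit: int = 9) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p for small n.

    For n <= ``exact_limit`` with untied data the p-value is the exact tail of
    the permutation distribution of rho (all n! rank orderings); otherwise the
    t-approximation is used.  Constant input gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p_approx = stats.spearmanr(x, y)
    n = x.size
    tied = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n > exact_limit or tied:
        return float(rho), float(p_approx)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = n * (n * n - 1) / 6.0
    obs = np.sum((rx - ry) ** 2)
    count = 0
    total = 0
    base = np.arange(1, n + 1, dtype=float)
    rho_obs = 1.0 - obs / denom
    for perm in permutations(base):
        d2 = np.sum((rx - np.asarray(perm)) ** 2)
        r = 1.0 - d2 / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total


def validate_against_qpcr(array_log2fc: pd.Series, qpcr_log2fc: pd.Series) -> tuple[float, float]:
    """Rank correlation between array and qPCR fold-change estimates.

    Spearman rho with exact permutation p for small untied panels, the
    t-approximation otherwise; needs >= 3 paired genes.
    """
    common = array_log2fc.index.intersection(qpcr_log2fc.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 paired genes")
    return spearman_exact_p(array_log2fc.loc[common].to_numpy(),
                            qpcr_log2fc.loc[common].to_numpy())
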