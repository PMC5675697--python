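"""Per-sample isoform-ratio statistics and grade-wise group tests.

The central covariate of the whole analysis is the per-patient ratio of the
alternative to the canonical splice isoform (GFAPδ/GFAPα).  This module
computes that ratio, compares isoform levels and the ratio between tumour
grades with Mann-Whitney U tests (Benjamini-Hochberg adjusted within each
measure's three pairwise contrasts), and houses the normalized-proportion
comparison used for proliferation-assay style readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

GRADE_CONTRASTS = (("II", "III"), ("II", "IV"), ("III", "IV"))


@dataclass
class GroupTestResult:
    """One two-group Mann-Whitney contrast."""

    contrast: str
    u_statistic: float
    p_value: float
    fdr: float | None
    percent_change_mean: float
    percent_change_median: float
    method: str


def compute_ratio(isoforms: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Add the delta/alpha ratio column; exclude (and report) samples with alpha == 0.

    ``isoforms`` is indexed by sample id with columns ``alpha`` and ``delta``
    of non-negative normalized isoform expression.  The ratio is undefined
    where alpha is zero; those samples are dropped from the returned table
    rather than coerced to infinity.
    """
    if not {"alpha", "delta"}.issubset(isoforms.columns):
        raise ValidationError("isoform table needs 'alpha' and 'delta' columns")
    if (isoforms[["alpha", "delta"]] < 0).any().any():
        raise ValidationError("isoform expression must be non-negative")
    excluded = list(isoforms.index[isoforms["alpha"] == 0])
    if excluded:
        warnings.warn(f"excluded {len(excluded)} sample(s) with zero alpha expression", stacklevel=2)
    kept = isoforms.loc[isoforms["alpha"] > 0].copy()
    kept["ratio"] = kept["delta"] / kept["alpha"]
    return kept, excluded


def shapiro_wilk_gate(values, alpha: float = 0.05) -> str:
    """Label a sample 'normal' / 'non-normal' by the Shapiro-Wilk test at ``alpha``."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("Shapiro-Wilk gate needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: treated as non-normal", stacklevel=2)
        return "non-normal"
    _, p = stats.shapiro(x)
    return "normal" if p > alpha else "non-normal"


def mann_whitney(group_a, group_b, alternative: str = "two-sided") -> GroupTestResult:
    """Two-group Mann-Whitney U test.

    Exact p by enumeration when n_a + n_b <= 20 and there are no ties across
    the pooled sample; otherwise the tie-corrected normal approximation with
    continuity correction.  Identical pooled values give U = n_a*n_b/2, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupTestResult("B_vs_A", a.size * b.size / 2.0, 1.0, None, 100.0, 100.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    pct_mean = 100.0 * np.mean(b) / np.mean(a) if np.mean(a) != 0 else np.nan
    med_a = np.median(a)
    pct_med = 100.0 * np.median(b) / med_a if med_a != 0 else np.nan
    return GroupTestResult("B_vs_A", float(res.statistic), float(res.pvalue), None, pct_mean, pct_med, method)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to FDR adjustment")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def grade_isoform_tests(isoforms: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pairwise grade contrasts for alpha, delta and the ratio.

    Returns one row per (measure, contrast) with U, p, BH q (adjusted within
    each measure's three pairwise contrasts) and mean/median-based percent
    change (the level in the higher grade as a percentage of the lower one).
    """
    table, _ = compute_ratio(isoforms[["alpha", "delta"]])
    grade = clinical.set_index("sample_id")["grade"]
    table = table.loc[table.index.intersection(grade.index)]
    rows = []
    for measure in ("alpha", "delta", "ratio"):
        pvals = []
        for lo, hi in GRADE_CONTRASTS:
            va = table.loc[grade.reindex(table.index) == lo, measure].to_numpy()
            vb = table.loc[grade.reindex(table.index) == hi, measure].to_numpy()
            r = mann_whitney(va, vb)
            rows.append(
                {
                    "measure": measure,
                    "contrast": f"{hi}_vs_{lo}",
                    "u_statistic": r.u_statistic,
                    "p_value": r.p_value,
                    "percent_change_mean": r.percent_change_mean,
                    "percent_change_median": r.percent_change_median,
                    "method": r.method,
                }
            )
            pvals.append(r.p_value)
        q = adjust_fdr(pvals)
        for i in range(len(GRADE_CONTRASTS)):
            rows[-3 + i]["fdr"] = q[i]
    out = pd.DataFrame(rows)
    return out[
        ["measure", "contrast", "u_statistic", "p_value", "fdr",
         "percent_change_mean", "percent_change_median", "method"]
    ]


def compare_normalized_proportions(treated_fractions, control_fractions) -> float:
    """Two-sided paired t p-value for normalized proportions, paired by experiment.

    A Shapiro-Wilk gate is run on the paired differences (warning only — the
    comparison is reported either way, as n is typically tiny).  Degenerate
    cases (identical vectors, zero-variance differences) return p = 1 with a
    warning instead of a NaN.
    """
    t = np.asarray(treated_fractions, dtype=float)
    c = np.asarray(control_fractions, dtype=float)
    if t.size != c.size:
        raise ValidationError("paired comparison needs equal-length vectors")
    if t.size < 2:
        raise ValidationError("paired comparison needs n >= 2")
    diffs = t - c
    if np.ptp(diffs) == 0:
        if np.all(diffs == 0):
            warnings.warn("identical vectors: no difference to test (p = 1)", stacklevel=2)
            return 1.0
        warnings.warn("zero-variance differences: paired t undefined (p = 1)", stacklevel=2)
        return 1.0
    if diffs.size >= 3:
        label = shapiro_wilk_gate(diffs)
        if label == "non-normal":
            warnings.warn("paired differences fail the Shapiro-Wilk normality gate", stacklevel=2)
    res = stats.ttest_rel(t, c)
    return float(res.pvalue)
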