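"""Median-split survival screening: Kaplan-Meier curves and log-rank tests.

Patients within one grade are dichotomized at the median expression of a gene
(values equal to the median go to the "low" stratum) and their overall or
progression-free survival curves are compared with the two-group log-rank
test; per-gene p-values are BH-adjusted over the screened gene family with
significance called at FDR < 0.05 and a trend at FDR < 0.1.  Estimation and
testing are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ValidationError
from .ratio import adjust_fdr

ENDPOINTS = {"OS": ("os_days", "os_event"), "PFS": ("pfs_days", "pfs_event")}


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator (censoring removes from later risk sets)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("need at least one record")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index.to_numpy(dtype=float)[mask.to_numpy()]
    at_risk = table["at_risk"].to_numpy(dtype=float)[mask.to_numpy()]
    n_events = table["observed"].to_numpy(dtype=float)[mask.to_numpy()]
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return KMCurve(ev_times, at_risk, n_events, surv)


def logrank_test(times_low, events_low, times_high, events_high) -> tuple[float, float]:
    """Two-group log-rank statistic (chi-square, 1 df) and p-value."""
    tl = np.asarray(times_low, dtype=float)
    th = np.asarray(times_high, dtype=float)
    el = np.asarray(events_low, dtype=int)
    eh = np.asarray(events_high, dtype=int)
    if tl.size == 0 or th.size == 0:
        raise ValidationError("both strata must be non-empty")
    if (tl < 0).any() or (th < 0).any():
        raise ValidationError("negative survival time")
    if el.sum() + eh.sum() == 0:
        warnings.warn("no events in either stratum: log-rank undefined (p = 1)", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(tl, th, event_observed_A=el, event_observed_B=eh)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        warnings.warn("degenerate log-rank statistic (p = 1)", stacklevel=2)
        return 0.0, 1.0
    return chi2, p


def median_split(values) -> pd.Series:
    """Stratum labels: 'low' where value <= median, 'high' above (ties go low)."""
    v = pd.Series(values, dtype=float)
    if v.size < 4:
        raise ValidationError("median split needs n >= 4")
    if np.ptp(v.to_numpy()) == 0:
        raise ValidationError("constant expression: single stratum")
    med = float(v.median())
    return pd.Series(np.where(v <= med, "low", "high"), index=v.index, name="stratum")


def screen_genes(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    genes,
    grade: str,
    endpoint: str = "OS",
    fdr_threshold: float = 0.05,
    trend_threshold: float = 0.1,
) -> pd.DataFrame:
    """Median-split log-rank screen of ``genes`` within one grade and endpoint.

    Patients lacking the endpoint are dropped; genes that cannot be split
    (constant expression, < 4 patients) are recorded as skipped.  BH FDR over
    the screened family; ``fdr = p`` when a single gene is screened.
    """
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    days_col, event_col = ENDPOINTS[endpoint]
    sub = clinical.loc[(clinical["grade"] == grade) & clinical[days_col].notna()]
    if len(sub) == 0:
        raise ValidationError(f"no {endpoint} data for grade {grade}")
    samples = [s for s in sub["sample_id"] if s in matrix.columns]
    if len(samples) < 4:
        raise ValidationError(f"fewer than 4 patients with {endpoint} data in grade {grade}")
    sub = sub.set_index("sample_id").loc[samples]
    times = sub[days_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=int)
    rows = []
    for gene in genes:
        if gene not in matrix.index:
            rows.append((gene, np.nan, np.nan, "absent from matrix"))
            continue
        expr = matrix.loc[gene, samples]
        try:
            strata = median_split(expr)
        except ValidationError as err:
            rows.append((gene, np.nan, np.nan, str(err)))
            continue
        lo = strata == "low"
        if lo.all() or (~lo).all():
            rows.append((gene, np.nan, np.nan, "single stratum"))
            continue
        chi2, p = logrank_test(times[lo.to_numpy()], events[lo.to_numpy()],
                               times[~lo.to_numpy()], events[~lo.to_numpy()])
        rows.append((gene, chi2, p, ""))
    out = pd.DataFrame(rows, columns=["gene_id", "chi2", "p_value", "note"]).set_index("gene_id")
    tested = out["p_value"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = adjust_fdr(out.loc[tested, "p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out["trend"] = out["fdr"] < trend_threshold
    out.attrs["n_patients"] = len(samples)
    out.attrs["grade"] = grade
    out.attrs["endpoint"] = endpoint
    return out
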