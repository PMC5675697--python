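"""Two-colour microarray preprocessing: flag filtering, quantile normalization,
probe collapsing and the low-intensity gene filter.

Each (array, channel) is treated as an independent single-channel sample
(intensity-based analysis of two-colour arrays); no ratio-of-channels model is
fitted.  The pipeline order is fixed by :func:`preprocess`:

    flag filter -> log2 -> quantile normalize -> collapse probes -> intensity filter

Spots flagged saturated / non-uniform / artefact are omitted and downstream
statistics use the remaining spots only; a transcript losing all of its spots
in every sample of a condition is recorded as missing for that condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, MicroarrayBatch, PreprocessReport, ValidationError

INTENSITY_THRESHOLD = 6.0  # log2 units; genes need one condition mean strictly above this


def filter_flagged_spots(batch: MicroarrayBatch) -> tuple[MicroarrayBatch, PreprocessReport]:
    """Remove flagged spots; report per-flag counts and condition-missing transcripts."""
    df = batch.spots
    report = PreprocessReport(total_spots=len(df))
    flagged = df["flags"].ne(".") & df["flags"].ne("")
    for entry in df.loc[flagged, "flags"]:
        for f in str(entry).split(";"):
            report.omitted_by_flag[f] = report.omitted_by_flag.get(f, 0) + 1
    kept = df.loc[~flagged].reset_index(drop=True)
    report.retained_spots = len(kept)
    # transcripts with no surviving spot in any sample of some condition
    for cond, sub in df.groupby("condition"):
        all_t = set(sub["transcript_id"])
        kept_t = set(kept.loc[kept["condition"] == cond, "transcript_id"])
        lost = all_t - kept_t
        if lost:
            report.missing_by_condition[cond] = lost
    report.probes_per_transcript = kept.groupby("transcript_id")["probe_id"].nunique().to_dict()
    if flagged.any():
        out = MicroarrayBatch(kept)
    else:
        out = MicroarrayBatch(df.copy())
    return out, report


def spot_log2_matrix(batch: MicroarrayBatch) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Pivot spots to a probes x samples log2 matrix.

    Returns (matrix, probe->transcript map, sample->condition map).  Samples
    are keyed ``array_id:channel``.  A probe absent from a sample (flag-
    filtered) becomes NaN.
    """
    df = batch.spots.assign(
        sample=batch.spots["array_id"] + ":" + batch.spots["channel"],
        log2=np.log2(batch.spots["intensity"].astype(float).clip(lower=2.0**-10)),
    )
    mat = df.pivot_table(index="probe_id", columns="sample", values="log2", aggfunc="mean")
    mat = mat.sort_index().sort_index(axis=1)
    probe_map = df.drop_duplicates("probe_id").set_index("probe_id")["transcript_id"]
    conditions = batch.sample_conditions()
    return mat, probe_map.reindex(mat.index), conditions.reindex(mat.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (arrays/samples) of a log2 intensity matrix.

    Every column's sorted non-missing values are mapped onto the reference
    quantile vector (the per-rank mean of the sorted columns); rank ties share
    the tied-rank mean.  Missing entries stay missing — each column is
    normalized on its own non-missing ranks against quantiles interpolated
    from the reference vector, so nothing is imputed.  Idempotent on complete
    matrices.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 arrays")
    counts = matrix.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValidationError(f"array {bad!r} has fewer than 2 usable values")
    X = matrix.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    complete = not np.isnan(X).any()

    if complete:
        order = np.argsort(X, axis=0, kind="stable")
        sorted_vals = np.take_along_axis(X, order, axis=0)
        reference = sorted_vals.mean(axis=1)  # per-rank mean across arrays
        out = np.empty_like(X)
        for j in range(n_cols):
            ranks = stats.rankdata(X[:, j], method="average")  # 1-based, ties averaged
            out[:, j] = np.interp(ranks, np.arange(1, n_rows + 1), reference)
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)

    # missing-value path: build the reference quantile curve on a common
    # probability grid from each column's own empirical quantiles
    m = int(counts.max())
    grid = (np.arange(m) + 0.5) / m
    curves = np.empty((m, n_cols))
    for j in range(n_cols):
        vals = np.sort(X[~np.isnan(X[:, j]), j])
        pj = (np.arange(vals.size) + 0.5) / vals.size
        curves[:, j] = np.interp(grid, pj, vals)
    reference = curves.mean(axis=1)
    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(X[:, j])
        vals = X[mask, j]
        ranks = stats.rankdata(vals, method="average")
        p = (ranks - 0.5) / vals.size
        out[mask, j] = np.interp(p, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_to_transcript: pd.Series) -> pd.DataFrame:
    """Average redundant probes detecting the same transcript (per sample).

    Arithmetic mean of the probes' log2 intensities, skipping missing spots;
    a transcript with no surviving probe in a sample stays missing there.
    """
    mapping = probe_to_transcript.reindex(matrix.index)
    if mapping.isna().any():
        probe = mapping.index[mapping.isna()][0]
        raise ValidationError(f"probe {probe!r} has no transcript mapping")
    collapsed = matrix.groupby(mapping).mean()
    collapsed.index.name = "gene_id"
    return collapsed.sort_index()


def intensity_filter(
    matrix: pd.DataFrame,
    conditions: pd.Series,
    threshold: float = INTENSITY_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Retain genes whose best per-condition mean log2 intensity is > threshold.

    ``conditions`` maps sample -> condition label and must cover every column.
    """
    unknown = [c for c in matrix.columns if c not in conditions.index or pd.isna(conditions.get(c))]
    if unknown:
        raise ValidationError(f"sample {unknown[0]!r} has no condition label")
    cond = conditions.reindex(matrix.columns)
    cond_means = matrix.T.groupby(cond).mean().T  # genes x conditions
    keep = cond_means.max(axis=1) > threshold
    removed = sorted(matrix.index[~keep])
    return matrix.loc[keep], removed


def preprocess(
    batch: MicroarrayBatch, threshold: float = INTENSITY_THRESHOLD
) -> tuple[ExpressionMatrix, pd.Series, PreprocessReport]:
    """Full preprocessing chain; returns (log2 expression matrix, sample->condition, report)."""
    filtered, report = filter_flagged_spots(batch)
    mat, probe_map, conditions = spot_log2_matrix(filtered)
    normed = quantile_normalize(mat)
    collapsed = collapse_probes(normed, probe_map)
    kept, removed = intensity_filter(collapsed, conditions, threshold=threshold)
    report.genes_removed_by_intensity = removed
    return ExpressionMatrix(kept, scale="log2"), conditions, report
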