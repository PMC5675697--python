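"""Readers/writers for the tabular formats shared by all pipeline stages.

All interchange files are plain TSV: UTF-8, '.' decimal separator, no quoting,
``NA`` for missing values.  Readers validate and *reject* malformed input with
a message naming the offending row/column; they never coerce.  Writers produce
files their readers accept unchanged (round-trip identity).

Gene and sample identifiers are opaque strings; no symbol/Entrez mapping is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GRADES = ("II", "III", "IV")
VALID_FLAGS = ("saturated", "non-uniform", "artefact")
VALID_SCALES = ("linear", "log2")

_NA = "NA"


class ValidationError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples table of expression values.

    ``data`` has gene identifiers as the index and sample identifiers as
    columns.  ``scale`` says whether values are linear normalized counts or
    log2 intensities; missing values (NaN) are only meaningful on the log2
    scale (e.g. fully flagged microarray spots).
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        validate_expression_frame(self.data, scale=self.scale, allow_missing=self.scale == "log2")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class MicroarrayBatch:
    """Spot-level two-colour array data, one row per spot.

    Columns: probe_id, transcript_id, array_id, channel, condition, intensity
    (linear scale), flags (subset of ``saturated;non-uniform;artefact``, ``.``
    when clean).  Each (array_id, channel) is one biological sample carrying
    exactly one condition label; every probe maps to exactly one transcript.
    """

    spots: pd.DataFrame

    def __post_init__(self) -> None:
        validate_microarray_frame(self.spots)

    @property
    def sample_ids(self) -> list[str]:
        key = self.spots["array_id"] + ":" + self.spots["channel"]
        return sorted(key.unique())

    def sample_conditions(self) -> pd.Series:
        """Condition label per sample key ``array_id:channel``."""
        df = self.spots.assign(sample=self.spots["array_id"] + ":" + self.spots["channel"])
        return df.drop_duplicates("sample").set_index("sample")["condition"].sort_index()


@dataclass
class PreprocessReport:
    """Bookkeeping emitted by the microarray preprocessing chain."""

    total_spots: int = 0
    omitted_by_flag: dict = field(default_factory=dict)
    retained_spots: int = 0
    probes_per_transcript: dict = field(default_factory=dict)
    missing_by_condition: dict = field(default_factory=dict)
    genes_removed_by_intensity: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total_spots": self.total_spots,
            "omitted_by_flag": dict(self.omitted_by_flag),
            "retained_spots": self.retained_spots,
            "n_transcripts": len(self.probes_per_transcript),
            "missing_by_condition": {k: sorted(v) for k, v in self.missing_by_condition.items()},
            "genes_removed_by_intensity": sorted(self.genes_removed_by_intensity),
        }


def validate_expression_frame(df: pd.DataFrame, scale: str = "linear", allow_missing: bool = False) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        where = f"gene {bad.index[0]!r}, sample {col!r}" if len(bad) else f"sample {col!r}"
        raise ValidationError(f"non-numeric expression value at {where}")
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        i, j = np.argwhere(np.isinf(values))[0]
        raise ValidationError(f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if not allow_missing and np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if scale == "linear" and np.nanmin(values, initial=0.0) < 0:
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative linear expression at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )


def read_expression(path, scale: str = "linear", allow_missing: bool | None = None) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header row of sample ids, first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if allow_missing is None:
        allow_missing = scale == "log2"
    validate_expression_frame(df, scale=scale, allow_missing=allow_missing)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep=_NA, float_format="%.10g")


_CLINICAL_COLUMNS = ["sample_id", "grade", "os_days", "os_event", "pfs_days", "pfs_event"]


def validate_clinical(df: pd.DataFrame) -> None:
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    bad_grade = ~df["grade"].isin(VALID_GRADES)
    if bad_grade.any():
        raise ValidationError(f"unknown grade {df.loc[bad_grade, 'grade'].iloc[0]!r}")
    for days_col, event_col in (("os_days", "os_event"), ("pfs_days", "pfs_event")):
        days = pd.to_numeric(df[days_col], errors="coerce")
        if ((days < 0) & df[days_col].notna()).any():
            raise ValidationError(f"negative {days_col}")
        if (days.isna() & df[days_col].notna()).any():
            raise ValidationError(f"non-numeric {days_col}")
        ev = df[event_col]
        ok = ev.isna() | ev.isin([0, 1, 0.0, 1.0])
        if not ok.all():
            raise ValidationError(f"{event_col} must be 0/1/NA, got {ev[~ok].iloc[0]!r}")
        if (days.notna() != ev.notna()).any():
            raise ValidationError(f"{days_col} and {event_col} must be missing together")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    df["sample_id"] = df["sample_id"].astype(str)
    validate_clinical(df)
    for c in ("os_days", "pfs_days", "os_event", "pfs_event"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df)
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


_SPOT_COLUMNS = ["probe_id", "transcript_id", "array_id", "channel", "condition", "intensity", "flags"]


def validate_microarray_frame(df: pd.DataFrame) -> None:
    missing = [c for c in _SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"microarray table missing columns {missing}")
    probe_map = df.groupby("probe_id")["transcript_id"].nunique()
    if (probe_map > 1).any():
        probe = probe_map[probe_map > 1].index[0]
        raise ValidationError(f"probe {probe!r} maps to multiple transcripts")
    sample_cond = df.groupby([df["array_id"], df["channel"]])["condition"].nunique()
    if (sample_cond > 1).any():
        arr, ch = sample_cond[sample_cond > 1].index[0]
        raise ValidationError(f"array {arr!r} channel {ch!r} carries multiple condition labels")
    intens = pd.to_numeric(df["intensity"], errors="coerce")
    if intens.isna().any() or np.isinf(intens.to_numpy(dtype=float)).any():
        raise ValidationError("non-numeric or non-finite spot intensity")
    if (intens < 0).any():
        raise ValidationError("negative spot intensity")
    for entry in df["flags"].unique():
        if entry in (".", ""):
            continue
        for f in str(entry).split(";"):
            if f not in VALID_FLAGS:
                raise ValidationError(f"unknown spot flag {f!r}")


def read_microarray(path) -> MicroarrayBatch:
    df = pd.read_csv(path, sep="\t", dtype={"flags": str}, na_values=[_NA], keep_default_na=False)
    df["flags"] = df["flags"].fillna(".")
    batch = MicroarrayBatch(df)
    batch.spots["intensity"] = batch.spots["intensity"].astype(float)
    return batch


def write_microarray(batch: MicroarrayBatch, path) -> None:
    batch.spots.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a pipeline TSV without pandas' permissive NA coercion.

    Only the literal ``NA`` marks a missing value; strings such as gene class
    labels survive untouched.  Numeric columns are inferred as usual.
    """
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[_NA],
                       keep_default_na=False)


def read_go_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, go_id) -> gene -> set-of-terms map, deduplicated."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValidationError(f"annotation file must have 2 columns, found {df.shape[1]}")
    gene_col, term_col = df.columns
    out: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col].astype(str), df[term_col].astype(str)):
        out.setdefault(gene, set()).add(term)
    return out


def write_go_annotations(annotations: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene_id", "go_id"]).to_csv(path, sep="\t", index=False)


def read_ontology_edges(path) -> list[tuple[str, str]]:
    """Two-column TSV (child, parent) edge list for a GO-style DAG."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValidationError(f"ontology edge file must have 2 columns, found {df.shape[1]}")
    return [(str(c), str(p)) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]
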