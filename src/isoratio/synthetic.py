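"""Seeded synthetic cohorts and microarray batches with planted structure.

The cohort generator emulates the graded astrocytoma study population: 55
grade II, 105 grade III and 150 grade IV patients; canonical-isoform (GFAPα)
expression drawn log-normally with its grade-IV mean planted at a configurable
fraction (default 0.55, a 45% decrease) of the grade II/III mean while the
alternative isoform (GFAPδ) stays constant across grades, so the per-patient
δ/α ratio rises in grade IV.  Planted "low-malignant" genes co-vary positively
with GFAPα (and hence negatively with the ratio) through a shared Gaussian
latent at a target correlation; "high-malignant" genes mirror the sign; null
genes are independent.  Survival times are exponential with grade-specific
baseline hazards; designated survival-effect genes multiply a patient's
hazard by a configurable ratio when the patient's expression is above the
within-grade median, and administrative censoring is applied per grade.

The microarray generator produces spot-level two-colour intensities for the
perturbation experiment (recombinant GFAPα+/GFAPδ+ vs control at 8 replicates
each; GFAPα−/GFAPpan− knockdowns at 5/5 vs 6 non-targeting controls) with
redundant probes, array-specific monotone distortions (to exercise quantile
normalization), a fixed fraction of flagged spots, and planted per-gene log2
fold changes recorded in the ground truth.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MicroarrayBatch, ValidationError

GRADES = ("II", "III", "IV")

RECOMBINANT_CONDITIONS = {"control": 8, "GFAPalpha_plus": 8, "GFAPdelta_plus": 8}
KNOCKDOWN_CONDITIONS = {"NTC": 6, "GFAPalpha_minus": 5, "GFAPpan_minus": 5}

GENE_CLASSES = ("null", "low-malignant", "high-malignant", "survival-effect")


@dataclass
class CohortSpec:
    """Parameters of the synthetic patient cohort.

    Counts and planted effect sizes default to the printed study conditions
    (55/105/150 patients; grade-IV α at 55% of the lower-grade level).  The
    within-grade dispersions are free parameters of the log-normal noise
    model.  ``ratio_grade4_multiplier`` left unset means the ratio increase
    implied by the α decrease alone (1/alpha_grade4_fraction, δ constant); an
    explicit larger value tilts grade-IV δ by the residual factor.
    """

    n_grade2: int = 55
    n_grade3: int = 105
    n_grade4: int = 150
    n_null_genes: int = 2000
    n_low_malignant: int = 40
    n_high_malignant: int = 40
    n_survival_genes: int = 4
    alpha_grade4_fraction: float = 0.55
    ratio_grade4_multiplier: float | None = None
    correlation_strength: float = 0.6
    log_sd_alpha: float = 0.5
    log_sd_delta: float = 0.5
    gene_log_sd: float = 1.0
    survival_hazard_ratio: float = 2.0
    censor_rate_by_grade: tuple[float, float, float] = (0.90, 0.05, 0.35)
    os_median_days_by_grade: tuple[float, float, float] = (3000.0, 1500.0, 400.0)
    pfs_median_fraction: float = 0.6
    surv_n_by_grade: tuple[int, int, int] = (41, 91, 150)
    seed: int = 0
    max_cells: int = 50_000_000

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer (reproducible RNG state required)")
        for name in ("n_grade2", "n_grade3", "n_grade4"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("n_null_genes", "n_low_malignant", "n_high_malignant", "n_survival_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.alpha_grade4_fraction <= 1:
            raise ValidationError("alpha_grade4_fraction must lie in (0, 1]")
        if self.ratio_grade4_multiplier is not None and self.ratio_grade4_multiplier < 1:
            raise ValidationError("ratio_grade4_multiplier must be >= 1")
        if not 0 < self.correlation_strength < 1:
            raise ValidationError("correlation_strength must lie in (0, 1)")
        for name in ("log_sd_alpha", "log_sd_delta", "gene_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.survival_hazard_ratio <= 0:
            raise ValidationError("survival_hazard_ratio must be > 0")
        if any(not 0 <= c < 1 for c in self.censor_rate_by_grade):
            raise ValidationError("censor rates must lie in [0, 1)")
        n_genes = self.n_null_genes + self.n_low_malignant + self.n_high_malignant + self.n_survival_genes
        n_samples = self.n_grade2 + self.n_grade3 + self.n_grade4
        if n_genes * n_samples > self.max_cells:
            raise ValidationError(
                f"requested {n_genes * n_samples} matrix cells exceeds the {self.max_cells} guard"
            )

    @property
    def n_samples(self) -> int:
        return self.n_grade2 + self.n_grade3 + self.n_grade4


@dataclass
class ArraySpec:
    """Parameters of one synthetic two-colour microarray experiment."""

    conditions: dict[str, int] = field(default_factory=lambda: dict(RECOMBINANT_CONDITIONS))
    reference_condition: str = "control"
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    genes: list[str] | None = None
    n_genes: int = 300
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    planted_baseline_range: tuple[float, float] = (8.0, 11.0)
    two_probe_fraction: float = 0.3
    flagged_fraction: float = 0.05
    distortion: bool = True
    distortion_slope_range: tuple[float, float] = (0.85, 1.15)
    distortion_offset_range: tuple[float, float] = (-0.6, 0.6)
    spot_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if self.reference_condition not in self.conditions:
            raise ValidationError("reference condition must appear among the conditions")
        for cond, n in self.conditions.items():
            if n < 2:
                raise ValidationError(f"condition {cond!r} has {n} replicate(s); variance undefined")
        if not 0 <= self.flagged_fraction < 1:
            raise ValidationError("flagged_fraction must lie in [0, 1)")
        for gene, per_cond in self.planted_log2fc.items():
            for cond in per_cond:
                if cond not in self.conditions:
                    raise ValidationError(f"planted fold change for unknown condition {cond!r} ({gene})")


def _alpha_pooled_moments(spec: CohortSpec, mu0: float) -> tuple[float, float]:
    """Theoretical pooled mean and sd of log alpha under the planted grade shifts."""
    w = np.array([spec.n_grade2, spec.n_grade3, spec.n_grade4], dtype=float) / spec.n_samples
    shifts = np.array([0.0, 0.0, math.log(spec.alpha_grade4_fraction)])
    mean = mu0 + float(w @ shifts)
    between = float(w @ (mu0 + shifts - mean) ** 2)
    return mean, math.sqrt(spec.log_sd_alpha**2 + between)


def generate_cohort(spec: CohortSpec):
    """Generate (ExpressionMatrix, isoform table, clinical table, ground truth).

    See the module docstring for the planted structure.  The isoform table is
    indexed by sample with columns alpha/delta/ratio; the clinical table has
    the standard sample_id/grade/os/pfs columns (OS missing outside the
    per-grade survival-analysis subset); the ground truth has one row per
    generated gene with its class and planted directions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    grades = np.array(["II"] * spec.n_grade2 + ["III"] * spec.n_grade3 + ["IV"] * spec.n_grade4)
    sample_ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    is4 = grades == "IV"

    mu_alpha = math.log(20000.0)
    mu_delta = math.log(2000.0)
    z_alpha = rng.standard_normal(n)
    log_alpha = mu_alpha + math.log(spec.alpha_grade4_fraction) * is4 + spec.log_sd_alpha * z_alpha

    mult = spec.ratio_grade4_multiplier
    delta_shift = 0.0 if mult is None else math.log(mult * spec.alpha_grade4_fraction)
    log_delta = mu_delta + delta_shift * is4 + spec.log_sd_delta * rng.standard_normal(n)

    alpha = np.exp(log_alpha)
    delta = np.exp(log_delta)
    isoforms = pd.DataFrame(
        {"alpha": alpha, "delta": delta, "ratio": delta / alpha},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    pooled_mean, pooled_sd = _alpha_pooled_moments(spec, mu_alpha)
    z_std = (log_alpha - pooled_mean) / pooled_sd

    gene_ids: list[str] = []
    classes: list[str] = []
    rows: list[np.ndarray] = []
    rho = spec.correlation_strength
    s = spec.gene_log_sd

    def planted_block(prefix: str, count: int, sign: int, klass: str) -> None:
        for i in range(count):
            mu_g = rng.uniform(math.log(50.0), math.log(5000.0))
            eps = rng.standard_normal(n)
            logx = mu_g + s * (sign * rho * z_std + math.sqrt(1 - rho**2) * eps)
            gene_ids.append(f"{prefix}{i + 1:04d}")
            classes.append(klass)
            rows.append(np.exp(logx))

    def independent_block(prefix: str, count: int, klass: str) -> None:
        for i in range(count):
            mu_g = rng.uniform(math.log(50.0), math.log(5000.0))
            logx = mu_g + s * rng.standard_normal(n)
            gene_ids.append(f"{prefix}{i + 1:04d}")
            classes.append(klass)
            rows.append(np.exp(logx))

    planted_block("LM", spec.n_low_malignant, +1, "low-malignant")
    planted_block("HM", spec.n_high_malignant, -1, "high-malignant")
    independent_block("SV", spec.n_survival_genes, "survival-effect")
    independent_block("NG", spec.n_null_genes, "null")

    expr = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )

    # survival: exponential baseline per grade, hazard multiplied per
    # survival-effect gene for patients above that gene's within-grade median
    # (medians taken over the survival-analysis subpopulation, on which the
    # planted effect is defined)
    hr = spec.survival_hazard_ratio
    sv_genes = [g for g, k in zip(gene_ids, classes) if k == "survival-effect"]
    os_available = np.zeros(n, dtype=bool)
    for gi, grade in enumerate(GRADES):
        m = np.flatnonzero(grades == grade)
        keep = rng.choice(m, size=min(spec.surv_n_by_grade[gi], m.size), replace=False)
        os_available[keep] = True

    log_mult = np.zeros(n)
    for g in sv_genes:
        x = expr.loc[g].to_numpy()
        above = np.zeros(n, dtype=bool)
        for grade in GRADES:
            m = grades == grade
            ref = m & os_available if (m & os_available).any() else m
            above[m] = x[m] > np.median(x[ref])
        log_mult += math.log(hr) * (above.astype(float) - 0.5)  # centred exponent

    os_days = np.empty(n)
    os_event = np.empty(n)
    pfs_days = np.full(n, np.nan)
    pfs_event = np.full(n, np.nan)
    for gi, grade in enumerate(GRADES):
        m = np.flatnonzero(grades == grade)
        lam0 = math.log(2.0) / spec.os_median_days_by_grade[gi]
        lam = lam0 * np.exp(log_mult[m])
        t = rng.exponential(1.0 / lam)
        c = spec.censor_rate_by_grade[gi]
        tau = np.inf if c == 0 else -math.log(c) / lam0
        os_days[m] = np.minimum(t, tau)
        os_event[m] = (t <= tau).astype(float)
        if grade in ("II", "III"):
            lamp0 = lam0 / spec.pfs_median_fraction
            lamp = lamp0 * np.exp(log_mult[m])
            tp = rng.exponential(1.0 / lamp)
            taup = np.inf if c == 0 else -math.log(c) / lamp0
            pfs_days[m] = np.minimum(tp, taup)
            pfs_event[m] = (tp <= taup).astype(float)

    os_days = np.round(os_days, 1)
    pfs_days = np.round(pfs_days, 1)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "grade": grades,
            "os_days": np.where(os_available, os_days, np.nan),
            "os_event": np.where(os_available, os_event, np.nan),
            "pfs_days": np.where(os_available, pfs_days, np.nan),
            "pfs_event": np.where(os_available, pfs_event, np.nan),
        }
    )

    dir_alpha = {"low-malignant": 1, "high-malignant": -1, "null": 0, "survival-effect": 0}
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": classes,
            "direction_alpha": [dir_alpha[k] for k in classes],
            "direction_ratio": [-dir_alpha[k] for k in classes],
            "survival_direction": [1 if k == "survival-effect" else 0 for k in classes],
        }
    ).set_index("gene_id")

    return ExpressionMatrix(expr, scale="linear"), isoforms, clinical, truth


def generate_microarray_batch(spec: ArraySpec) -> tuple[MicroarrayBatch, pd.DataFrame]:
    """Generate spot-level intensities plus a (gene, condition) -> log2fc truth table."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes) if spec.genes is not None else [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    if len(set(genes)) != len(genes):
        raise ValidationError("duplicate gene ids in array spec")

    baseline = {}
    for g in genes:
        if g in spec.planted_log2fc:
            baseline[g] = rng.uniform(*spec.planted_baseline_range)
        else:
            baseline[g] = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd)

    n_probes = {g: 2 if rng.random() < spec.two_probe_fraction else 1 for g in genes}

    samples: list[tuple[str, str, str]] = []  # (array_id, channel, condition)
    flat = [cond for cond, k in spec.conditions.items() for _ in range(k)]
    for i, cond in enumerate(flat):
        samples.append((f"A{i // 2 + 1:02d}", "Cy3" if i % 2 == 0 else "Cy5", cond))

    distort = {}
    for array_id, channel, _ in samples:
        key = (array_id, channel)
        if key not in distort:
            if spec.distortion:
                distort[key] = (
                    rng.uniform(*spec.distortion_slope_range),
                    rng.uniform(*spec.distortion_offset_range),
                )
            else:
                distort[key] = (1.0, 0.0)

    records = []
    for g in genes:
        fc = spec.planted_log2fc.get(g, {})
        for p in range(n_probes[g]):
            probe_id = f"{g}_p{p + 1}"
            for array_id, channel, cond in samples:
                true = baseline[g] + fc.get(cond, 0.0)
                x = true + rng.normal(0.0, spec.spot_sd)
                slope, offset = distort[(array_id, channel)]
                records.append((probe_id, g, array_id, channel, cond, 2.0 ** (slope * x + offset), "."))

    df = pd.DataFrame(records, columns=["probe_id", "transcript_id", "array_id", "channel",
                                        "condition", "intensity", "flags"])
    n_flag = round(spec.flagged_fraction * len(df))
    if n_flag:
        idx = rng.choice(len(df), size=n_flag, replace=False)
        flags = rng.choice(["saturated", "non-uniform", "artefact"], size=n_flag)
        df.loc[idx, "flags"] = flags

    truth_rows = [
        {"gene_id": g, "condition": cond,
         "log2fc": spec.planted_log2fc.get(g, {}).get(cond, 0.0)}
        for g in genes
        for cond in spec.conditions
        if cond != spec.reference_condition
    ]
    truth = pd.DataFrame(truth_rows)
    return MicroarrayBatch(df), truth


def default_invitro_specs(truth: pd.DataFrame, invitro_log2fc: float = 1.0,
                          n_extra_null: int = 150, seed: int = 0) -> tuple[ArraySpec, ArraySpec]:
    """Array specs for the two perturbation experiments matching a cohort's truth.

    Planted genes respond in vitro consistently with their patient class: a
    low-malignant gene (positively coupled to GFAPα) goes up under GFAPα+,
    down under the α-targeting knockdowns and down under GFAPδ+ (which raises
    the δ/α ratio); high-malignant genes mirror the signs.  A subset of null
    genes is carried on the arrays unperturbed.
    """
    planted = truth.loc[truth["gene_class"].isin(["low-malignant", "high-malignant"])]
    nulls = truth.loc[truth["gene_class"] == "null"].index[:n_extra_null]
    genes = list(planted.index) + list(nulls)
    fc_rec: dict[str, dict[str, float]] = {}
    fc_kd: dict[str, dict[str, float]] = {}
    for g, row in planted.iterrows():
        d = float(row["direction_alpha"])
        fc_rec[g] = {"GFAPalpha_plus": d * invitro_log2fc, "GFAPdelta_plus": -d * invitro_log2fc}
        fc_kd[g] = {"GFAPalpha_minus": -d * invitro_log2fc, "GFAPpan_minus": -d * invitro_log2fc}
    rec = ArraySpec(conditions=dict(RECOMBINANT_CONDITIONS), reference_condition="control",
                    planted_log2fc=fc_rec, genes=genes, seed=seed)
    kd = ArraySpec(conditions=dict(KNOCKDOWN_CONDITIONS), reference_condition="NTC",
                   planted_log2fc=fc_kd, genes=genes, seed=seed + 1)
    return rec, kd


def make_go_annotations(truth: pd.DataFrame, n_random_terms: int = 40,
                        term_size: tuple[int, int] = (10, 40), seed: int = 0):
    """Synthetic gene->term annotations with two planted enriched terms and a tiny DAG.

    Returns (annotations dict, (child, parent) edge list, term name map).  The
    planted terms collect most of the low-/high-malignant genes respectively
    (plus background genes), so over-representation is recoverable; random
    terms draw uniformly from the whole gene universe.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.index)
    ann: dict[str, set[str]] = {g: set() for g in genes}
    names: dict[str, str] = {}
    for i in range(n_random_terms):
        term = f"T{i + 1:04d}"
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            ann[g].add(term)
        names[term] = f"random process {i + 1}"
    for klass, term, name in (("low-malignant", "T_LOW", "low-malignant program"),
                              ("high-malignant", "T_HIGH", "high-malignant program")):
        members = list(truth.index[truth["gene_class"] == klass])
        chosen = rng.choice(members, size=max(1, int(0.8 * len(members))), replace=False) if members else []
        background = rng.choice(genes, size=min(10, len(genes)), replace=False)
        for g in list(chosen) + list(background):
            ann[g].add(term)
        names[term] = name
    names["T_ROOT"] = "biological process root"
    edges = [(t, "T_ROOT") for t in sorted(names) if t != "T_ROOT"]
    for g in genes:
        if ann[g]:
            ann[g].add("T_ROOT")
    return {g: t for g, t in ann.items() if t}, edges, names
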