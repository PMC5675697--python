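"""Cross-dataset concordance and correlation-sign classification.

In-vitro perturbation responses are harmonized to a signed direction per unit
increase of a covariate (the canonical isoform GFAPα, or the GFAPδ/α ratio),
intersected with patient grade contrasts under direction concordance, and the
surviving genes are classified by their correlation-sign pattern:

* low-malignant:  positive correlation to GFAPα, negative to GFAPδ/α (both at
  FDR < 0.01) and no correlation to GFAPδ (FDR > 0.1);
* high-malignant: the mirrored pattern;
* anything else:  unclassified.

The reported coefficient is Spearman's rho; the significance test is the
slope test of a simple linear regression of gene expression on the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import ValidationError
from .ratio import adjust_fdr, compute_ratio

COVARIATES = ("alpha", "delta", "ratio")

# conditions informative for each covariate, with the sign the condition
# imposes on that covariate (knockdown lowers alpha; recombinant delta raises
# the ratio; recombinant alpha raises alpha hence lowers the ratio; ...)
CONDITION_SIGNS = {
    "alpha": {"GFAPalpha_minus": -1, "GFAPpan_minus": -1, "GFAPalpha_plus": +1},
    "ratio": {"GFAPdelta_plus": +1, "GFAPalpha_plus": -1, "GFAPalpha_minus": +1},
}

# direction of each covariate in grade IV relative to grade II/III patients
PATIENT_GRADE4_SIGN = {"alpha": -1, "ratio": +1}


@dataclass
class RegulatedGeneSet:
    """Genes responding to a covariate in vitro, with harmonized direction."""

    covariate: str
    directions: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    conflicts: list[str] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.directions)


def harmonize_direction(
    de_results: dict[str, pd.DataFrame], covariate: str
) -> RegulatedGeneSet:
    """Re-express per-condition DE directions per unit increase of ``covariate``.

    ``de_results`` maps condition name -> DE table (``log2fc``/``passes``).
    A gene up under a condition that lowers the covariate gets direction -1,
    etc.  Genes significant in several conditions with conflicting harmonized
    signs are excluded and recorded.
    """
    if covariate not in CONDITION_SIGNS:
        raise ValidationError(f"unknown covariate {covariate!r}")
    signs = CONDITION_SIGNS[covariate]
    votes: dict[str, set[int]] = {}
    for condition, table in de_results.items():
        if condition not in signs:
            continue
        hits = table.loc[table["passes"]]
        for gene, lfc in hits["log2fc"].items():
            direction = int(np.sign(lfc)) * signs[condition]
            if direction == 0:
                continue
            votes.setdefault(gene, set()).add(direction)
    out = RegulatedGeneSet(covariate)
    for gene, ds in votes.items():
        if len(ds) == 1:
            out.directions[gene] = next(iter(ds))
        else:
            out.conflicts.append(gene)
    out.conflicts.sort()
    return out


def concordant_overlap(
    in_vitro: RegulatedGeneSet,
    patient_de: dict[str, pd.DataFrame],
    covariate_patient_sign: int | None = None,
) -> pd.DataFrame:
    """Direction-concordant intersection of in-vitro and patient DE gene sets.

    ``patient_de`` maps contrast label (e.g. ``IV_vs_II``) -> DE table whose
    log2fc is grade IV relative to a lower grade.  A gene is concordant when
    its patient direction equals harmonized in-vitro direction x the
    covariate's own grade-IV direction; the union over the patient contrasts
    is taken, genes with conflicting patient directions are excluded.
    """
    if covariate_patient_sign is None:
        covariate_patient_sign = PATIENT_GRADE4_SIGN[in_vitro.covariate]
    patient_dir: dict[str, set[int]] = {}
    for table in patient_de.values():
        hits = table.loc[table["passes"]]
        for gene, lfc in hits["log2fc"].items():
            d = int(np.sign(lfc))
            if d:
                patient_dir.setdefault(gene, set()).add(d)
    rows = []
    for gene, direction in in_vitro.directions.items():
        if gene not in patient_dir:
            continue
        if len(patient_dir[gene]) != 1:
            rows.append((gene, direction, 0, False, "conflicting patient direction"))
            continue
        pdir = next(iter(patient_dir[gene]))
        predicted = direction * covariate_patient_sign
        rows.append((gene, direction, pdir, pdir == predicted, ""))
    out = pd.DataFrame(
        rows, columns=["gene_id", "invitro_direction", "patient_direction", "concordant", "note"]
    ).set_index("gene_id").sort_index()
    return out


def correlate_genes(
    matrix: pd.DataFrame,
    isoforms: pd.DataFrame,
    genes=None,
) -> pd.DataFrame:
    """Per-gene correlation to GFAPα, GFAPδ and the δ/α ratio over all patients.

    Returns, per gene and covariate, Spearman's rho, the regression-slope
    p-value, and BH FDR adjusted within each covariate's gene family.
    Zero-variance genes are skipped with a record (``skipped`` column).
    """
    iso, _ = compute_ratio(isoforms[["alpha", "delta"]])
    samples = matrix.columns.intersection(iso.index)
    if len(samples) < 3:
        raise ValidationError("need at least 3 patients shared by matrix and isoform table")
    genes = list(matrix.index) if genes is None else [g for g in genes if g in matrix.index]
    X = matrix.loc[genes, samples].to_numpy(dtype=float)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["skipped"] = X.std(axis=1) == 0
    for cov in COVARIATES:
        y = iso.loc[samples, cov].to_numpy(dtype=float)
        rho = np.full(len(genes), np.nan)
        pval = np.full(len(genes), np.nan)
        for i, g in enumerate(genes):
            if out["skipped"].iloc[i]:
                continue
            rho[i] = stats.spearmanr(X[i], y).statistic
            pval[i] = stats.linregress(y, X[i]).pvalue  # slope test of the simple regression
        ok = ~np.isnan(pval)
        fdr = np.full(len(genes), np.nan)
        if ok.any():
            fdr[ok] = adjust_fdr(pval[ok])
        out[f"rho_{cov}"] = rho
        out[f"p_{cov}"] = pval
        out[f"fdr_{cov}"] = fdr
    return out


def classify(
    correlations: pd.DataFrame,
    class_fdr: float = 0.01,
    delta_null_fdr: float = 0.1,
) -> pd.DataFrame:
    """Label genes low-/high-malignant/unclassified from their correlation pattern.

    low-malignant:  rho_alpha > 0 & fdr_alpha < class_fdr & rho_ratio < 0 &
                    fdr_ratio < class_fdr & fdr_delta > delta_null_fdr.
    high-malignant: the mirrored sign pattern.  Pure function of its inputs;
    the three labels partition the gene list.
    """
    needed = [f"{k}_{c}" for c in COVARIATES for k in ("rho", "fdr")]
    missing = [c for c in needed if c not in correlations.columns]
    if missing:
        raise ValidationError(f"correlation table missing columns {missing}")
    df = correlations.copy()
    complete = df[needed].notna().all(axis=1)
    strong_alpha = df["fdr_alpha"] < class_fdr
    strong_ratio = df["fdr_ratio"] < class_fdr
    delta_null = df["fdr_delta"] > delta_null_fdr
    low = complete & strong_alpha & strong_ratio & delta_null & (df["rho_alpha"] > 0) & (df["rho_ratio"] < 0)
    high = complete & strong_alpha & strong_ratio & delta_null & (df["rho_alpha"] < 0) & (df["rho_ratio"] > 0)
    df["label"] = "unclassified"
    df.loc[low, "label"] = "low-malignant"
    df.loc[high, "label"] = "high-malignant"
    df.loc[~complete, "label"] = "unclassified"
    df["reason"] = ""
    df.loc[~complete, "reason"] = "missing covariate"
    return df


def cluster_abs_correlations(correlations: pd.DataFrame, n_clusters: int = 2):
    """Average-linkage clustering of genes on their |rho| vectors.

    Euclidean distance on (|rho_alpha|, |rho_delta|, |rho_ratio|); genes are
    sorted lexicographically first so the dendrogram and the ``n_clusters``
    cut are deterministic under permutation of the input.  Returns
    (linkage matrix, labels Series).
    """
    cols = [f"rho_{c}" for c in COVARIATES]
    df = correlations.loc[correlations[cols].notna().all(axis=1), cols].abs()
    df = df.sort_index()
    if len(df) == 0:
        raise ValidationError("no genes with complete correlation vectors")
    if len(df) == 1:
        return None, pd.Series([1], index=df.index, name="cluster")
    Z = hierarchy.linkage(df.to_numpy(), method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=min(n_clusters, len(df)), criterion="maxclust")
    return Z, pd.Series(labels, index=df.index, name="cluster")


def within_grade_correlation(
    matrix: pd.DataFrame,
    isoforms: pd.DataFrame,
    clinical: pd.DataFrame,
    genes=None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """correlate_genes restricted to each grade; FDR within grade x covariate.

    Grades with fewer than 3 usable patients are skipped with a record.
    Returns a long table (gene, grade) x covariate statistics with a
    ``significant_<cov>`` flag at ``fdr_threshold``.
    """
    grade = clinical.set_index("sample_id")["grade"]
    pieces = []
    skipped_grades = []
    for g in ("II", "III", "IV"):
        samp = [s for s in matrix.columns if grade.get(s) == g]
        if len(samp) < 3:
            skipped_grades.append(g)
            continue
        sub = correlate_genes(matrix[samp], isoforms.loc[isoforms.index.intersection(samp)], genes)
        sub.insert(0, "grade", g)
        for cov in COVARIATES:
            sub[f"significant_{cov}"] = sub[f"fdr_{cov}"] < fdr_threshold
        pieces.append(sub.reset_index())
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    out.attrs["skipped_grades"] = skipped_grades
    return out
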