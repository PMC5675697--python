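"""End-to-end orchestration: simulate -> preprocess -> DE -> ratio tests ->
concordance/classification -> survival screen -> GO enrichment.

One validated configuration drives every stage; all intermediate results are
written as the same TSVs the standalone CLI subcommands exchange, so each
stage can be re-run independently, and a JSON manifest records the config
hash, per-file checksums and per-stage gene counts.  Re-running with an
identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import arrays as arrays_mod
from . import concordance, diffexp, enrichment, io, ratio, survival
from . import synthetic
from .io import ValidationError

log = logging.getLogger("isoratio.pipeline")

ARRAY_CONTRASTS = {
    "recombinant": [("control", "GFAPalpha_plus"), ("control", "GFAPdelta_plus"),
                    ("GFAPalpha_plus", "GFAPdelta_plus")],
    "knockdown": [("NTC", "GFAPalpha_minus"), ("NTC", "GFAPpan_minus")],
}
CONDITION_EXPERIMENT = {
    "GFAPalpha_plus": "recombinant", "GFAPdelta_plus": "recombinant",
    "GFAPalpha_minus": "knockdown", "GFAPpan_minus": "knockdown",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "isoratio_run"
    de_fdr: float = 0.1
    de_fc: float = 1.5
    class_fdr: float = 0.01
    delta_null_fdr: float = 0.1
    within_grade_fdr: float = 0.05
    surv_fdr: float = 0.05
    surv_trend_fdr: float = 0.1
    go_min_hits: int = 5
    invitro_log2fc: float = 1.0
    survival_grades: tuple = ("III",)
    survival_endpoints: tuple = ("OS", "PFS")
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("de_fdr", "class_fdr", "delta_null_fdr", "within_grade_fdr",
                     "surv_fdr", "surv_trend_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"threshold {name}={v} outside (0, 1)")
        if self.de_fc <= 1:
            raise ValidationError(f"fold-change gate must exceed 1, got {self.de_fc}")
        if self.go_min_hits < 0:
            raise ValidationError("go_min_hits must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run the full chain on a simulated cohort + arrays; return the manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": _config_hash(config),
                      "stages": {}, "files": {}}

    def emit(name: str, writer, obj) -> None:
        path = out / name
        writer(obj, path)
        manifest["files"][name] = _sha256(path)

    # stage 1: simulate
    spec = synthetic.CohortSpec(seed=config.seed, **config.cohort)
    expr, isoforms, clinical, truth = synthetic.generate_cohort(spec)
    emit("expression.tsv", io.write_expression, expr)
    emit("isoforms.tsv", lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), isoforms)
    emit("clinical.tsv", lambda df, p: io.write_clinical(df, p), clinical)
    emit("ground_truth.tsv", lambda df, p: df.to_csv(p, sep="\t"), truth)
    rec_spec, kd_spec = synthetic.default_invitro_specs(
        truth, invitro_log2fc=config.invitro_log2fc, seed=config.seed + 1)
    batches = {"recombinant": synthetic.generate_microarray_batch(rec_spec),
               "knockdown": synthetic.generate_microarray_batch(kd_spec)}
    manifest["stages"]["simulate"] = {
        "n_patients": spec.n_samples, "n_genes": len(expr.gene_ids),
        "n_spots": {k: len(b.spots) for k, (b, _) in batches.items()},
    }
    log.info("simulated cohort (%d patients, %d genes) and arrays", spec.n_samples, len(expr.gene_ids))

    # stage 2: isoform-ratio grade statistics
    ratio_report = ratio.grade_isoform_tests(isoforms, clinical)
    emit("ratio_tests.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.10g"),
         ratio_report)
    manifest["stages"]["ratio_stats"] = {"n_contrasts": len(ratio_report)}

    # stage 3+4: microarray preprocessing and in-vitro DE
    invitro_de: dict[str, pd.DataFrame] = {}
    for exp_name, (batch, _) in batches.items():
        mat, conditions, report = arrays_mod.preprocess(batch)
        emit(f"arrays_{exp_name}.tsv", io.write_expression, mat)
        (out / f"prep_report_{exp_name}.json").write_text(json.dumps(report.as_dict(), indent=2))
        manifest["files"][f"prep_report_{exp_name}.json"] = _sha256(out / f"prep_report_{exp_name}.json")
        for ref, cond in ARRAY_CONTRASTS[exp_name]:
            de = diffexp.fit_moderated(mat.data, conditions, (ref, cond),
                                       fdr_threshold=config.de_fdr, fc_threshold=config.de_fc)
            name = f"de_{cond}_vs_{ref}.tsv"
            emit(name, lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), de)
            if cond in CONDITION_EXPERIMENT and ref in ("control", "NTC"):
                invitro_de[cond] = de
    manifest["stages"]["invitro_de"] = {c: int(t["passes"].sum()) for c, t in invitro_de.items()}

    # stage 5: patient grade contrasts
    patient_de = {}
    for pair in (("II", "IV"), ("III", "IV")):
        de = diffexp.patient_grade_contrast(expr.data, clinical, pair,
                                            fdr_threshold=config.de_fdr, fc_threshold=config.de_fc)
        patient_de[f"IV_vs_{pair[0]}"] = de
        emit(f"de_patient_IV_vs_{pair[0]}.tsv",
             lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), de)
    manifest["stages"]["patient_de"] = {k: int(t["passes"].sum()) for k, t in patient_de.items()}

    # stage 6: concordance + classification
    overlap_genes: set[str] = set()
    overlap_counts = {}
    for covariate in ("alpha", "ratio"):
        harmonized = concordance.harmonize_direction(invitro_de, covariate)
        table = concordance.concordant_overlap(harmonized, patient_de)
        concordant = set(table.index[table["concordant"]])
        overlap_genes |= concordant
        overlap_counts[covariate] = {
            "in_vitro": len(harmonized.directions), "conflicts": len(harmonized.conflicts),
            "concordant": len(concordant),
        }
        emit(f"overlap_{covariate}.tsv", lambda df, p: df.to_csv(p, sep="\t"), table)
    correlations = concordance.correlate_genes(expr.data, isoforms, sorted(overlap_genes))
    classified = concordance.classify(correlations, class_fdr=config.class_fdr,
                                      delta_null_fdr=config.delta_null_fdr)
    emit("classification.tsv", lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), classified)
    label_counts = classified["label"].value_counts().to_dict()
    manifest["stages"]["classification"] = {"overlap": overlap_counts,
                                            "labels": {k: int(v) for k, v in label_counts.items()}}
    class_genes = list(classified.index[classified["label"] != "unclassified"])

    # stage 7: within-grade correlations of the classified genes
    if class_genes:
        wg = concordance.within_grade_correlation(expr.data, isoforms, clinical, class_genes,
                                                  fdr_threshold=config.within_grade_fdr)
        emit("within_grade.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False,
                                                         float_format="%.10g"), wg)
        manifest["stages"]["within_grade"] = {"n_rows": len(wg)}

    # stage 8: survival screen of classified genes
    surv_counts = {}
    for grade in config.survival_grades:
        for endpoint in config.survival_endpoints:
            if not class_genes:
                continue
            try:
                screen = survival.screen_genes(expr.data, clinical, class_genes, grade,
                                               endpoint=endpoint, fdr_threshold=config.surv_fdr,
                                               trend_threshold=config.surv_trend_fdr)
            except ValidationError as err:
                log.warning("survival screen %s/%s skipped: %s", grade, endpoint, err)
                continue
            emit(f"survival_{grade}_{endpoint}.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", float_format="%.10g"), screen)
            surv_counts[f"{grade}_{endpoint}"] = int(screen["significant"].sum())
    manifest["stages"]["survival"] = surv_counts

    # stage 9: GO over-representation of the classified gene sets
    ann, edges, names = synthetic.make_go_annotations(truth, seed=config.seed + 2)
    universe = set(correlations.index)
    go_counts = {}
    for label in ("low-malignant", "high-malignant"):
        genes = [g for g in class_genes if classified.loc[g, "label"] == label and g in universe]
        if not genes:
            continue
        res = enrichment.elim_decorrelate(genes, universe, ann, edges,
                                          min_hits=config.go_min_hits, term_names=names)
        emit(f"go_{label}.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False,
                                                        float_format="%.10g"), res)
        go_counts[label] = int((res["p_value"] < 0.05).sum())
    manifest["stages"]["go"] = go_counts

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


STAGE_CONTRACTS = [
    ("simulate", "CohortSpec/ArraySpec -> expression, isoforms, clinical, ground truth, spot tables"),
    ("ratio_stats", "isoforms + clinical -> per-measure grade contrasts (U, p, BH q, percent change)"),
    ("microarray_prep", "spots -> flag filter -> quantile normalize -> collapse probes -> intensity filter"),
    ("diffexp", "log2 matrix + design -> moderated t, BH FDR, 1.5-fold gate"),
    ("concordance", "in-vitro + patient DE -> direction-concordant overlap -> correlation classification"),
    ("survival", "median-split log-rank screen per grade/endpoint, BH FDR 0.05 (trend 0.1)"),
    ("go", "classified gene sets -> hypergeometric over-representation with elim decorrelation"),
]
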