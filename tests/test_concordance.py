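import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoratio.concordance import (
    PATIENT_GRADE4_SIGN,
    classify,
    cluster_abs_correlations,
    concordant_overlap,
    correlate_genes,
    harmonize_direction,
    within_grade_correlation,
)
from oracles import regression_slope_test


def _de_table(entries):
    """entries: {gene: (log2fc, passes)}"""
    return pd.DataFrame(
        {
            "log2fc": {g: v[0] for g, v in entries.items()},
            "passes": {g: v[1] for g, v in entries.items()},
        }
    )


class TestHarmonize:
    def test_up_under_knockdown_is_negative_direction(self):
        de = {"GFAPalpha_minus": _de_table({"g1": (1.2, True)})}
        out = harmonize_direction(de, "alpha")
        assert out.directions == {"g1": -1}

    def test_recombinant_alpha_covariate_definitions(self):
        de = {"GFAPalpha_plus": _de_table({"g1": (0.9, True)})}
        assert harmonize_direction(de, "alpha").directions == {"g1": +1}
        assert harmonize_direction(de, "ratio").directions == {"g1": -1}

    def test_conflicting_conditions_excluded(self):
        de = {
            "GFAPalpha_plus": _de_table({"g1": (1.0, True)}),
            "GFAPalpha_minus": _de_table({"g1": (1.0, True)}),  # up under both: conflict wrt alpha
        }
        out = harmonize_direction(de, "alpha")
        assert out.directions == {}
        assert out.conflicts == ["g1"]

    def test_consistent_conditions_counted_once(self):
        de = {
            "GFAPalpha_minus": _de_table({"g1": (1.0, True)}),
            "GFAPpan_minus": _de_table({"g1": (0.8, True)}),
        }
        out = harmonize_direction(de, "alpha")
        assert out.directions == {"g1": -1}


class TestConcordantOverlap:
    def test_sign_algebra(self):
        in_vitro = harmonize_direction({"GFAPalpha_plus": _de_table({"down4": (1.0, True),
                                                                     "up4": (1.0, True)})}, "alpha")
        patient = {"IV_vs_II": _de_table({"down4": (-2.0, True), "up4": (2.0, True)})}
        out = concordant_overlap(in_vitro, patient)
        # +1 wrt alpha, alpha down in IV -> predicted down in IV
        assert bool(out.loc["down4", "concordant"]) is True
        assert bool(out.loc["up4", "concordant"]) is False

    def test_flipping_patient_direction_flips_every_decision(self, rng):
        genes = {f"g{i}": (float(rng.normal()), True) for i in range(12)}
        in_vitro = harmonize_direction({"GFAPalpha_plus": _de_table(genes)}, "alpha")
        patient = {"IV_vs_II": _de_table({g: (float(rng.normal()), True) for g in genes})}
        base = concordant_overlap(in_vitro, patient, covariate_patient_sign=-1)
        flipped = concordant_overlap(in_vitro, patient, covariate_patient_sign=+1)
        assert (base["concordant"] ^ flipped["concordant"]).all()

    def test_empty_inputs_give_empty_output(self):
        in_vitro = harmonize_direction({}, "alpha")
        out = concordant_overlap(in_vitro, {"IV_vs_II": _de_table({})})
        assert out.empty

    def test_planted_concordant_genes_recovered_exactly(self, rng):
        n = 30
        truth_dir = {f"g{i}": (1 if i % 2 else -1) for i in range(n)}
        invitro = _de_table({g: (d * 1.0, True) for g, d in truth_dir.items()})
        # patient change in IV = direction * alpha's own IV sign (negative)
        patient = _de_table({g: (d * PATIENT_GRADE4_SIGN["alpha"] * 1.0, True)
                             for g, d in truth_dir.items()})
        hv = harmonize_direction({"GFAPalpha_plus": invitro}, "alpha")
        out = concordant_overlap(hv, {"IV_vs_II": patient})
        assert out["concordant"].sum() == n


class TestCorrelateGenes:
    def _fixture(self, rng, n=20):
        alpha = rng.lognormal(9, 0.5, n)
        delta = rng.lognormal(7, 0.5, n)
        iso = pd.DataFrame({"alpha": alpha, "delta": delta},
                           index=[f"p{i}" for i in range(n)])
        return iso

    def test_gene_equal_to_alpha_has_rho_one(self, rng):
        iso = self._fixture(rng)
        matrix = pd.DataFrame([iso["alpha"].to_numpy()], index=["same"], columns=iso.index)
        out = correlate_genes(matrix, iso)
        assert out.loc["same", "rho_alpha"] == pytest.approx(1.0)
        assert out.loc["same", "p_alpha"] < 1e-10

    def test_slope_test_matches_closed_form(self, rng):
        iso = self._fixture(rng)
        gene = rng.normal(100, 10, len(iso))
        matrix = pd.DataFrame([gene], index=["g"], columns=iso.index)
        out = correlate_genes(matrix, iso)
        for cov in ("alpha", "delta", "ratio"):
            y = iso["delta"] / iso["alpha"] if cov == "ratio" else iso[cov]
            _, p = regression_slope_test(y.to_numpy(), gene)
            assert out.loc["g", f"p_{cov}"] == pytest.approx(p, rel=1e-9)

    def test_null_gene_p_uniform_over_seeds(self):
        """Independent gene: regression p over 200 seeded repeats is uniform."""
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            iso = self._fixture(r, n=30)
            gene = r.normal(50, 5, 30)
            matrix = pd.DataFrame([gene], index=["g"], columns=iso.index)
            pvals.append(correlate_genes(matrix, iso).loc["g", "p_alpha"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_gene_skipped(self, rng):
        iso = self._fixture(rng)
        matrix = pd.DataFrame([np.full(len(iso), 7.0)], index=["flat"], columns=iso.index)
        out = correlate_genes(matrix, iso)
        assert bool(out.loc["flat", "skipped"]) is True
        assert np.isnan(out.loc["flat", "rho_alpha"])


class TestClassify:
    def _row(self, **kw):
        base = {"rho_alpha": 0.8, "fdr_alpha": 0.001, "p_alpha": 1e-5,
                "rho_ratio": -0.7, "fdr_ratio": 0.002, "p_ratio": 1e-5,
                "rho_delta": 0.05, "fdr_delta": 0.5, "p_delta": 0.4}
        base.update(kw)
        return pd.DataFrame(base, index=["g"])

    def test_low_malignant_pattern(self):
        assert classify(self._row()).loc["g", "label"] == "low-malignant"

    def test_high_malignant_mirrored_pattern(self):
        row = self._row(rho_alpha=-0.8, rho_ratio=0.7)
        assert classify(row).loc["g", "label"] == "high-malignant"

    def test_delta_null_filter(self):
        row = self._row(fdr_delta=0.05)
        assert classify(row).loc["g", "label"] == "unclassified"

    def test_labels_partition_genes(self, default_cohort):
        expr, isoforms, _, truth = default_cohort
        genes = list(truth.index[truth["gene_class"] != "null"])
        out = classify(correlate_genes(expr.data.loc[genes], isoforms))
        assert set(out["label"]) <= {"low-malignant", "high-malignant", "unclassified"}
        assert out["label"].notna().all()
        assert len(out) == len(genes)

    def test_missing_covariate_unclassified_with_reason(self):
        row = self._row(fdr_delta=np.nan)
        out = classify(row)
        assert out.loc["g", "label"] == "unclassified"
        assert out.loc["g", "reason"] == "missing covariate"


class TestClustering:
    def test_identical_vectors_merge_first(self):
        corr = pd.DataFrame(
            {"rho_alpha": [0.9, 0.9, 0.1], "rho_delta": [0.0, 0.0, 0.0],
             "rho_ratio": [-0.9, -0.9, 0.1]},
            index=["a", "b", "c"],
        )
        Z, labels = cluster_abs_correlations(corr)
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at distance zero
        assert labels["a"] == labels["b"] != labels["c"]

    def test_planted_two_block_structure_recovered(self, rng):
        strong = pd.DataFrame(
            {"rho_alpha": rng.uniform(0.7, 0.9, 8), "rho_delta": rng.uniform(0, 0.05, 8),
             "rho_ratio": -rng.uniform(0.7, 0.9, 8)},
            index=[f"s{i}" for i in range(8)],
        )
        weak = pd.DataFrame(
            {"rho_alpha": rng.uniform(0, 0.1, 8), "rho_delta": rng.uniform(0, 0.05, 8),
             "rho_ratio": rng.uniform(0, 0.1, 8)},
            index=[f"w{i}" for i in range(8)],
        )
        corr = pd.concat([strong, weak])
        _, labels = cluster_abs_correlations(corr)
        assert len(set(labels[strong.index])) == 1
        assert len(set(labels[weak.index])) == 1
        assert labels["s0"] != labels["w0"]

    def test_gene_order_invariance(self, rng):
        corr = pd.DataFrame(rng.uniform(-1, 1, size=(10, 3)),
                            columns=["rho_alpha", "rho_delta", "rho_ratio"],
                            index=[f"g{i}" for i in range(10)])
        _, labels1 = cluster_abs_correlations(corr)
        _, labels2 = cluster_abs_correlations(corr.sample(frac=1.0, random_state=3))
        groups1 = {g: set(labels1.index[labels1 == labels1[g]]) for g in corr.index}
        groups2 = {g: set(labels2.index[labels2 == labels2[g]]) for g in corr.index}
        assert groups1 == groups2

    def test_single_gene_singleton(self):
        corr = pd.DataFrame({"rho_alpha": [0.5], "rho_delta": [0.1], "rho_ratio": [-0.4]},
                            index=["only"])
        Z, labels = cluster_abs_correlations(corr)
        assert Z is None and labels.tolist() == [1]


class TestWithinGrade:
    def _cohort(self, rng, per_grade=40):
        grades = ["II"] * per_grade + ["III"] * per_grade + ["IV"] * per_grade
        ids = [f"p{i}" for i in range(len(grades))]
        clinical = pd.DataFrame({"sample_id": ids, "grade": grades,
                                 "os_days": 100.0, "os_event": 1,
                                 "pfs_days": np.nan, "pfs_event": np.nan})
        alpha = rng.lognormal(9, 0.5, len(ids))
        iso = pd.DataFrame({"alpha": alpha, "delta": rng.lognormal(7, 0.5, len(ids))}, index=ids)
        return clinical, iso

    def test_gene_correlated_only_within_one_grade(self, rng):
        clinical, iso = self._cohort(rng)
        ids = clinical["sample_id"]
        m3 = clinical["grade"] == "III"
        gene = rng.normal(100, 10, len(ids))
        gene[m3.to_numpy()] = 50 + 0.02 * iso.loc[ids[m3], "alpha"].to_numpy()
        matrix = pd.DataFrame([gene], index=["g"], columns=ids)
        out = within_grade_correlation(matrix, iso, clinical).set_index("grade")
        assert bool(out.loc["III", "significant_alpha"]) is True
        assert bool(out.loc["II", "significant_alpha"]) is False
        assert bool(out.loc["IV", "significant_alpha"]) is False

    def test_grade_mean_driven_gene_not_significant_within_grades(self, rng):
        """A pooled correlation driven purely by grade offsets vanishes within grade."""
        clinical, iso = self._cohort(rng)
        ids = clinical["sample_id"]
        offsets = clinical["grade"].map({"II": 200.0, "III": 150.0, "IV": 100.0}).to_numpy()
        iso2 = iso.copy()
        iso2.loc[:, "alpha"] = iso["alpha"] * clinical["grade"].map(
            {"II": 1.0, "III": 1.0, "IV": 0.5}).to_numpy()
        gene = offsets + rng.normal(0, 1.0, len(ids))
        matrix = pd.DataFrame([gene], index=["g"], columns=ids)
        pooled = correlate_genes(matrix, iso2)
        assert pooled.loc["g", "p_alpha"] < 0.01  # Simpson-style pooled signal
        out = within_grade_correlation(matrix, iso2, clinical)
        assert not out["significant_alpha"].any()

    def test_constant_gene_skipped_everywhere(self, rng):
        clinical, iso = self._cohort(rng, per_grade=10)
        matrix = pd.DataFrame([np.full(30, 5.0)], index=["flat"], columns=clinical["sample_id"])
        out = within_grade_correlation(matrix, iso, clinical)
        assert out["skipped"].all()
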