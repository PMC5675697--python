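import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from isoratio.diffexp import (
    ModerationParams,
    estimate_moderation,
    fit_moderated,
    patient_grade_contrast,
    spearman_exact_p,
    trigamma_inverse,
    validate_against_qpcr,
)
from isoratio.io import ValidationError
from oracles import moderated_t_direct, spearman_permutation_p


def _two_group_matrix(rng, n_genes=30, na=4, nb=4, shift=0.0):
    data = rng.normal(8.0, 1.0, size=(n_genes, na + nb))
    data[:, na:] += shift
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    design = pd.Series(["A"] * na + ["B"] * nb, index=cols)
    return pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)], columns=cols), design


class TestModeratedLimits:
    def test_d0_zero_equals_classical_t(self, rng):
        matrix, design = _two_group_matrix(rng)
        res = fit_moderated(matrix, design, ("A", "B"), d0_override=0.0)
        for gene in matrix.index:
            a = matrix.loc[gene, design == "A"]
            b = matrix.loc[gene, design == "B"]
            classic = stats.ttest_ind(b, a, equal_var=True)
            assert res.loc[gene, "t_moderated"] == pytest.approx(classic.statistic, abs=1e-10)
            assert res.loc[gene, "p_value"] == pytest.approx(classic.pvalue, abs=1e-10)

    def test_d0_infinite_pins_posterior_at_prior(self, rng):
        matrix, design = _two_group_matrix(rng)
        res = fit_moderated(matrix, design, ("A", "B"), d0_override=np.inf)
        params = res.attrs["moderation"]
        assert np.isinf(params.d0)
        # all genes share one scale: t proportional to log2fc / contrast scale
        ratio = res["t_moderated"] / res["log2fc"]
        assert ratio.std() < 1e-12
        assert ratio.iloc[0] == pytest.approx(1.0 / np.sqrt(params.s2_prior * (1 / 4 + 1 / 4)))

    def test_monotone_in_effect_and_variance(self):
        p = ModerationParams(s2_prior=0.5, d0=4.0)
        s2 = np.array([0.2, 0.5, 1.0])
        post = p.posterior_variance(s2, np.full(3, 6.0))
        assert np.all(np.diff(post) > 0)  # larger residual variance, larger posterior
        # moderated t monotone in |logfc| at fixed variance
        t = np.array([0.1, 0.5, 1.0]) / np.sqrt(post[0] * 0.5)
        assert np.all(np.diff(t) > 0)


class TestModeratedAgainstOracles:
    def test_matches_direct_formula(self, rng):
        """t and p equal a plain-loop implementation of the posterior-variance formula."""
        matrix, design = _two_group_matrix(rng, n_genes=50)
        res = fit_moderated(matrix, design, ("A", "B"))
        params = res.attrs["moderation"]
        for gene in matrix.index:
            t, p = moderated_t_direct(
                matrix.loc[gene, design == "A"], matrix.loc[gene, design == "B"],
                params.s2_prior, params.d0,
            )
            assert res.loc[gene, "t_moderated"] == pytest.approx(t, rel=1e-10)
            assert res.loc[gene, "p_value"] == pytest.approx(p, rel=1e-8)

    def test_matches_limma_reference(self, rng, tmp_path):
        """Moderated t, p and the variance prior agree with the Bioconductor reference."""
        matrix, design = _two_group_matrix(rng, n_genes=40, na=4, nb=4)
        res = fit_moderated(matrix, design, ("A", "B"))
        in_tsv = tmp_path / "m.tsv"
        out_tsv = tmp_path / "limma.tsv"
        matrix.to_csv(in_tsv, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{in_tsv}", row.names=1))
            design <- cbind(A=1, B=c(rep(0,4), rep(1,4)))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(gene=rownames(m), t=fit$t[,"B"], p=fit$p.value[,"B"],
                              d0=fit$df.prior, s2_prior=fit$s2.prior)
            write.table(out, "{out_tsv}", sep="\t", row.names=FALSE, quote=FALSE)
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_tsv, sep="\t", index_col=0)
        params = res.attrs["moderation"]
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert params.s2_prior == pytest.approx(ref["s2_prior"].iloc[0], rel=1e-4)
        assert res["t_moderated"].to_numpy() == pytest.approx(ref["t"].to_numpy(), rel=1e-6)
        assert res["p_value"].to_numpy() == pytest.approx(ref["p"].to_numpy(), rel=1e-6)


class TestHyperparameterEstimator:
    def test_trigamma_inverse_round_trip(self):
        for x in (0.05, 0.5, 2.0, 25.0):
            assert special.polygamma(1, trigamma_inverse(special.polygamma(1, x))) == pytest.approx(
                special.polygamma(1, x), rel=1e-8
            )

    def test_recovers_known_hyperparameters(self):
        """Moment estimator recovers (s2_prior, d0) within 10% at 5000 genes."""
        rng = np.random.default_rng(123)
        s2_prior, d0, dg, n = 0.8, 6.0, 4.0, 5000
        sigma2 = s2_prior * d0 / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(dg, size=n) / dg
        est = estimate_moderation(s2, np.full(n, dg))
        assert est.s2_prior == pytest.approx(s2_prior, rel=0.10)
        assert est.d0 == pytest.approx(d0, rel=0.10)


class TestPatientContrast:
    def test_planted_alpha_decrease_detected(self, default_cohort):
        """The canonical isoform passes the DE gates, down in grade IV."""
        expr, isoforms, clinical, _ = default_cohort
        with_iso = pd.concat(
            [expr.data, isoforms[["alpha", "delta"]].T.set_axis(["GFAP_ALPHA", "GFAP_DELTA"])]
        )
        de = patient_grade_contrast(with_iso, clinical, ("II", "IV"))
        assert de.loc["GFAP_ALPHA", "passes"]
        assert de.loc["GFAP_ALPHA", "log2fc"] < 0
        assert not de.loc["GFAP_DELTA", "passes"]

    def test_fc_gate_blocks_small_fold_change(self, rng):
        """Tiny-variance gene with linear FC 1.4 fails on the fold-change gate."""
        n = 40
        clinical = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(2 * n)],
            "grade": ["II"] * n + ["IV"] * n,
            "os_days": 100.0, "os_event": 1, "pfs_days": np.nan, "pfs_event": np.nan,
        })
        base = np.full(2 * n, 1000.0) + rng.normal(0, 1.0, 2 * n)
        gene = base.copy()
        gene[n:] *= 1.4
        matrix = pd.DataFrame([gene], index=["g"], columns=clinical["sample_id"])
        de = patient_grade_contrast(matrix, clinical, ("II", "IV"))
        assert de.loc["g", "fdr"] < 0.1
        assert de.loc["g", "abs_linear_fc"] < 1.5
        assert not de.loc["g", "passes"]

    def test_missing_grade_rejected(self, small_cohort):
        expr, _, clinical, _ = small_cohort
        clin2 = clinical[clinical["grade"] != "IV"]
        with pytest.raises(ValidationError, match="grade"):
            patient_grade_contrast(expr.data, clin2, ("II", "IV"))


class TestSpearmanValidation:
    def test_identical_and_reversed(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rho, _ = validate_against_qpcr(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = validate_against_qpcr(x, x.iloc[::-1].set_axis(list("abcd")))
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = spearman_exact_p(x, y)
            assert p == pytest.approx(spearman_permutation_p(x, y), abs=1e-12)

    def test_constant_vector_reported_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_exact_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)
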