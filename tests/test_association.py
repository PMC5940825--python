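"""Summary-statistic gene association: summation form, matrix form, exact factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sumxcan.association import (
    AlleleFrameError,
    ScaledWeights,
    bonferroni_threshold,
    compute_zscore,
    compute_zscore_exact,
    compute_zscore_matrix_form,
    effect_size,
)
from sumxcan.covariance import SnpCovariance, compute_covariance
from sumxcan.gwas import GwasRecord, records_index
from sumxcan.models import ModelWeight, PredictionModel
from sumxcan.oracle import association, gwas_scan, predict_expression
from sumxcan.simulate import SimScenario, simulate_study


def model_for(weights: dict[str, float], gene="G"):
    return PredictionModel(
        gene_id=gene,
        weights={
            vid: ModelWeight(weight=w, effect_allele="A", other_allele="G")
            for vid, w in weights.items()
        },
    )


def gwas_for(zscores: dict[str, float]):
    return {
        vid: GwasRecord(vid, "A", "G", zscore=z, beta=z * 0.1, se=0.1)
        for vid, z in zscores.items()
    }


def random_instance(rng, p=5):
    """Random weights, Z-scores, and a PSD covariance over p SNPs."""
    ids = [f"rs{i}" for i in range(p)]
    A = rng.normal(size=(p, p))
    matrix = A @ A.T + 0.1 * np.eye(p)
    weights = dict(zip(ids, rng.normal(size=p)))
    zscores = dict(zip(ids, rng.normal(size=p)))
    cov = SnpCovariance("G", ids, matrix)
    return model_for(weights), gwas_for(zscores), cov


class TestComputeZscore:
    def test_single_snp_gene_z_is_signed_gwas_z(self):
        for w, expected in [(0.7, 3.1), (-0.7, -3.1)]:
            result = compute_zscore(
                model_for({"rs1": w}), gwas_for({"rs1": 3.1}),
                SnpCovariance("G", ["rs1"], np.array([[0.42]])),
            )
            assert result.zscore == expected  # exact, not approximate
            assert result.pvalue == pytest.approx(2 * stats.norm.sf(3.1), abs=1e-15)

    def test_all_model_snps_absent_gives_no_snps_status(self):
        result = compute_zscore(
            model_for({"rs1": 1.0}), {}, SnpCovariance("G", ["rs1"], np.array([[1.0]]))
        )
        assert result.status == "no_snps"
        assert np.isnan(result.zscore)

    def test_zero_variance_status(self):
        result = compute_zscore(
            model_for({"rs1": 1.0}), gwas_for({"rs1": 2.0}),
            SnpCovariance("G", ["rs1"], np.array([[0.0]])),
        )
        assert result.status == "zero_variance"

    def test_unharmonized_input_raises(self):
        gwas = {"rs1": GwasRecord("rs1", "G", "A", zscore=1.0)}
        with pytest.raises(AlleleFrameError):
            compute_zscore(
                model_for({"rs1": 1.0}), gwas, SnpCovariance("G", ["rs1"], np.array([[1.0]]))
            )

    def test_partial_overlap_recomputes_sigma_on_subset(self, rng):
        model, gwas, cov = random_instance(rng, p=4)
        partial = {k: v for k, v in list(gwas.items())[:2]}
        result = compute_zscore(model, partial, cov)
        assert result.n_snps_used == 2 and result.n_snps_in_model == 4
        sub = cov.subset(list(partial))
        w = model.weight_vector(list(partial))
        assert result.sigma_g2 == pytest.approx(float(w @ sub.matrix @ w), abs=1e-12)

    def test_scale_invariance_of_weights(self, rng):
        model, gwas, cov = random_instance(rng)
        base = compute_zscore(model, gwas, cov).zscore
        for c in (3.7, -2.0):
            scaled = model_for({v: c * w.weight for v, w in model.weights.items()})
            z = compute_zscore(scaled, gwas, cov).zscore
            assert z == pytest.approx(np.sign(c) * base, abs=1e-10)

    def test_against_individual_level_oracle(self):
        """Summary Z from a cohort's own GWAS matches the direct regression,
        and restoring the per-SNP correction factor makes the match exact."""
        study = simulate_study(
            SimScenario(seed=42, n_individuals=2000, n_genes=3, snps_per_gene=3,
                        n_causal_snps=3, architecture="null")
        )
        records = gwas_scan(study.dosages, study.phenotype, study.variants)
        idx = records_index(records)
        sigma_y2 = study.phenotype.var(ddof=1)
        for model in study.models:
            cov = compute_covariance(study.dosages, model)
            summary = compute_zscore(model, idx, cov)
            t, _ = predict_expression(study.dosages, model)
            oracle = association(t, study.phenotype)
            assert summary.zscore == pytest.approx(oracle.zscore, abs=5e-3)
            exact = compute_zscore_exact(
                model, idx, cov, phenotype_variance=sigma_y2, n=len(study.phenotype)
            )
            assert exact.zscore == pytest.approx(oracle.zscore, abs=1e-10)


class TestMatrixForm:
    def test_identity_correlation_picks_weighted_z(self):
        scaled = ScaledWeights("G", ["a", "b"], np.array([1.0, 0.0]), np.eye(2))
        assert compute_zscore_matrix_form(scaled, [2.5, 9.0]) == pytest.approx(2.5)

    def test_permutation_symmetry_for_exchangeable_snps(self):
        corr = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        scaled = ScaledWeights("G", list("abc"), np.ones(3), corr)
        z = np.array([1.0, -2.0, 0.5])
        base = compute_zscore_matrix_form(scaled, z)
        for perm in ([2, 0, 1], [1, 2, 0]):
            assert compute_zscore_matrix_form(scaled, z[perm]) == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_summation_form(self, seed):
        rng = np.random.default_rng(seed)
        model, gwas, cov = random_instance(rng)
        summation = compute_zscore(model, gwas, cov).zscore
        scaled = ScaledWeights.from_model(model, cov)
        z = [gwas[v].zscore for v in cov.variant_ids]
        assert compute_zscore_matrix_form(scaled, z) == pytest.approx(summation, abs=1e-10)

    def test_zero_denominator_is_nan(self):
        scaled = ScaledWeights("G", ["a"], np.array([0.0]), np.eye(1))
        assert np.isnan(compute_zscore_matrix_form(scaled, [1.0]))


class TestExactFactor:
    def test_single_snp_factor_is_exactly_one(self):
        model = model_for({"rs1": 1.0})
        gwas = {"rs1": GwasRecord("rs1", "A", "G", beta=0.05, se=0.01, zscore=5.0)}
        cov = SnpCovariance("G", ["rs1"], np.array([[0.5]]))
        approx = compute_zscore(model, gwas, cov)
        exact = compute_zscore_exact(model, gwas, cov, phenotype_variance=1.0, n=10_000)
        # single SNP: R_l^2 = R_g^2, the correction cancels identically
        assert exact.zscore == pytest.approx(approx.zscore, abs=1e-12)
        assert exact.exact_factor_applied

    def test_small_effects_make_correction_negligible(self, rng):
        model, gwas, cov = random_instance(rng, p=3)
        small = {
            v: GwasRecord(v, "A", "G", beta=r.zscore * 0.01, se=0.01, zscore=r.zscore)
            for v, r in gwas.items()
        }
        approx = compute_zscore(model, small, cov).zscore
        exact = compute_zscore_exact(model, small, cov, phenotype_variance=1.0, n=10_000).zscore
        assert abs(exact - approx) / abs(approx) < 0.01

    def test_factor_exceeds_one_when_gene_explains_more_than_snp(self):
        # two SNPs pushing the same direction: R_g^2 > each R_l^2
        model = model_for({"rs1": 1.0, "rs2": 1.0})
        gwas = {
            v: GwasRecord(v, "A", "G", beta=0.1, se=0.02, zscore=5.0) for v in ("rs1", "rs2")
        }
        cov = SnpCovariance("G", ["rs1", "rs2"], np.eye(2))
        approx = compute_zscore(model, gwas, cov).zscore
        exact = compute_zscore_exact(model, gwas, cov, phenotype_variance=1.0, n=2000).zscore
        assert abs(exact) > abs(approx)

    def test_inconsistent_inputs_raise(self):
        model = model_for({"rs1": 1.0})
        gwas = {"rs1": GwasRecord("rs1", "A", "G", beta=2.0, se=0.1, zscore=20.0)}
        cov = SnpCovariance("G", ["rs1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="variance explained"):
            compute_zscore_exact(model, gwas, cov, phenotype_variance=1.0, n=100)


class TestEffectSize:
    def test_single_unit_weight_returns_snp_beta(self):
        model = model_for({"rs1": 1.0})
        gwas = {"rs1": GwasRecord("rs1", "A", "G", beta=0.37, se=0.1, zscore=3.7)}
        cov = SnpCovariance("G", ["rs1"], np.array([[0.8]]))
        assert effect_size(model, gwas, cov) == pytest.approx(0.37, abs=1e-12)

    def test_doubling_weights_halves_effect(self, rng):
        model, gwas, cov = random_instance(rng)
        base = effect_size(model, gwas, cov)
        doubled = model_for({v: 2 * w.weight for v, w in model.weights.items()})
        assert effect_size(doubled, gwas, cov) == pytest.approx(base / 2, rel=1e-10)

    def test_recovers_mediated_effect_from_simulation(self):
        """Y = gamma * T_g + noise: the summary effect estimate recovers gamma."""
        rng = np.random.default_rng(9)
        n = 5000
        x = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        dosages = pd.DataFrame(x, columns=["rs1", "rs2"])
        w = {"rs1": 0.8, "rs2": -0.5}
        t = x @ np.array(list(w.values()))
        gamma = 0.2
        y = gamma * t + rng.normal(size=n)
        variants = pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "chrom": "1", "pos": [1, 2],
             "effect_allele": "A", "other_allele": "G"}
        )
        records = records_index(gwas_scan(dosages, y, variants))
        model = model_for(w)
        cov = compute_covariance(dosages, model)
        estimate = effect_size(model, records, cov)
        se_gamma = association(t, y).se
        assert abs(estimate - gamma) < 3 * se_gamma


def test_bonferroni_threshold():
    assert bonferroni_threshold(200) == pytest.approx(0.05 / 200)
    with pytest.raises(ValueError):
        bonferroni_threshold(0)
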