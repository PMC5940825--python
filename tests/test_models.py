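"""Model storage, training filters, elastic-net fitting, FDR retention."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sumxcan.fdr import qvalues
from sumxcan.models import (
    ModelFormatError,
    ModelRejection,
    ModelWeight,
    PredictionModel,
    TrainingData,
    filter_models_by_qvalue,
    filter_training_variants,
    read_model_db,
    residualize,
    select_cis_snps,
    train_elastic_net,
    write_model_db,
)
from sumxcan.simulate import SimScenario, simulate_gene_models, simulate_genotypes


def make_model(gene="G1", snps=("rs1", "rs2", "rs3"), r2=0.4, p=1e-4):
    weights = {
        vid: ModelWeight(weight=0.1 * (i + 1), effect_allele="A", other_allele="G")
        for i, vid in enumerate(snps)
    }
    return PredictionModel(gene_id=gene, gene_name=gene, weights=weights, perf_r2=r2, perf_pvalue=p)


class TestModelDb:
    def test_round_trip_is_identity(self, tmp_path):
        models = [make_model("G1"), make_model("G2", snps=("rs9",), r2=0.1, p=0.02)]
        path = tmp_path / "models.db"
        write_model_db(models, path)
        loaded = read_model_db(path)
        assert len(loaded) == 2
        for original, back in zip(models, loaded):
            assert back.gene_id == original.gene_id
            assert back.weights == original.weights
            assert back.perf_r2 == original.perf_r2
            assert back.perf_pvalue == original.perf_pvalue
            assert back.n_snps_in_model == original.n_snps_in_model

    def test_orphan_weight_rows_are_a_format_error(self, tmp_path):
        import sqlite3

        path = tmp_path / "models.db"
        write_model_db([make_model("G1")], path)
        conn = sqlite3.connect(path)
        conn.execute("INSERT INTO weights VALUES ('GHOST','rs1','rs1','G','A',0.5)")
        conn.commit()
        conn.close()
        with pytest.raises(ModelFormatError, match="GHOST"):
            read_model_db(path)

    def test_missing_table_or_column_named_in_error(self, tmp_path):
        import sqlite3

        path = tmp_path / "bad.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE weights (gene TEXT)")  # truncated schema
        conn.commit()
        conn.close()
        with pytest.raises(ModelFormatError, match="rsid"):
            read_model_db(path)

        path2 = tmp_path / "bad2.db"
        conn = sqlite3.connect(path2)
        conn.execute(
            "CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT,"
            " ref_allele TEXT, eff_allele TEXT, weight REAL)"
        )
        conn.commit()
        conn.close()
        with pytest.raises(ModelFormatError, match="extra"):
            read_model_db(path2)

    def test_empty_db_yields_empty_collection(self, tmp_path):
        path = tmp_path / "empty.db"
        write_model_db([], path)
        assert read_model_db(path) == []


class TestCisWindow:
    gene = {"gene_id": "G", "chrom": "1", "tss": 2_000_000, "tes": 2_010_000}

    @pytest.mark.parametrize(
        "chrom,pos,included",
        [
            ("1", 1_000_000, True),   # exactly tss - 1 Mb: boundary inclusive
            ("1", 999_999, False),
            ("1", 3_010_000, True),   # exactly tes + 1 Mb
            ("1", 3_010_001, False),
            ("2", 2_000_000, False),  # other chromosome
        ],
    )
    def test_window_boundaries(self, chrom, pos, included):
        variants = pd.DataFrame(
            {"variant_id": ["v"], "chrom": [chrom], "pos": [pos]}
        )
        got = select_cis_snps(self.gene, variants)
        assert (got == ["v"]) is included


class TestVariantFilters:
    def test_maf_and_strand_filters(self):
        n = 1000
        dosages = pd.DataFrame(
            {
                "rare": [1.0] * 5 + [0.0] * (n - 5),          # freq 0.0025
                "flip_rare": [2.0] * (n - 5) + [1.0] * 5,      # freq 0.9975
                "common": [1.0] * n,
                "ambiguous": [0.0, 1.0] * (n // 2),
            }
        )
        variants = pd.DataFrame(
            {
                "variant_id": ["rare", "flip_rare", "common", "ambiguous"],
                "chrom": "1",
                "pos": [1, 2, 3, 4],
                "effect_allele": ["A", "A", "A", "A"],
                "other_allele": ["G", "G", "G", "T"],
            }
        )
        kept_dosages, kept_variants = filter_training_variants(dosages, variants)
        assert list(kept_dosages.columns) == ["common"]
        assert kept_variants["variant_id"].tolist() == ["common"]


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.normal(size=30)
        res = residualize(y, pd.DataFrame(index=range(30)))
        assert np.allclose(res, y - y.mean())

    def test_perfect_linear_dependence_gives_zero_residuals(self, rng):
        c = rng.normal(size=40)
        y = 3.0 * c + 2.0
        res = residualize(y, pd.DataFrame({"c": c}))
        assert np.max(np.abs(res)) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        C = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        res = residualize(y, pd.DataFrame(C, columns=list("abc")))
        X = np.column_stack([np.ones(n), C])
        expected = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res, expected, atol=1e-10)
        assert np.max(np.abs(X.T @ res)) < 1e-8  # orthogonal to covariates

    def test_collinear_covariates_named(self, rng):
        c = rng.normal(size=20)
        covs = pd.DataFrame({"a": c, "b": 2 * c})
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=20), covs)


def training_fixture(seed=7, **overrides):
    scenario = SimScenario(
        seed=seed,
        n_individuals=overrides.pop("n_individuals", 300),
        n_genes=overrides.pop("n_genes", 5),
        snps_per_gene=overrides.pop("snps_per_gene", 50),
        n_causal_snps=overrides.pop("n_causal_snps", 1),
        h2_expr=overrides.pop("h2_expr", 0.8),
        architecture="null",
        **overrides,
    )
    dosages, variants, genes = simulate_genotypes(scenario)
    truth, _, expression, _ = simulate_gene_models(scenario, dosages, variants)
    training = TrainingData(
        dosages=dosages, variants=variants, expression=expression,
        covariates=None, genes=genes,
    )
    return scenario, training, truth


class TestElasticNet:
    def test_strong_causal_snp_recovered_with_sign(self):
        _, training, truth = training_fixture(h2_expr=0.9)
        gene = training.expression.columns[0]
        model = train_elastic_net(training, gene, seed=0)
        assert isinstance(model, PredictionModel)
        (causal, w_true), = truth[gene].items()
        assert causal in model.weights
        assert np.sign(model.weights[causal].weight) == np.sign(w_true)
        assert model.perf_pvalue < 1e-6

    def test_noiseless_expression_is_nearly_perfectly_predicted(self):
        _, training, _ = training_fixture(h2_expr=1.0)
        gene = training.expression.columns[0]
        model = train_elastic_net(training, gene, seed=0)
        assert isinstance(model, PredictionModel)
        assert model.perf_r2 > 0.99

    def test_pure_noise_yields_rejection_or_unremarkable_performance(self):
        _, training, _ = training_fixture(h2_expr=0.0, n_genes=8, n_individuals=200)
        for gene in training.expression.columns:
            model = train_elastic_net(training, gene, seed=0)
            if isinstance(model, PredictionModel):
                assert model.perf_pvalue > 1e-4

    def test_training_is_reproducible_for_fixed_seed(self):
        _, training, _ = training_fixture()
        gene = training.expression.columns[1]
        m1 = train_elastic_net(training, gene, seed=3)
        m2 = train_elastic_net(training, gene, seed=3)
        assert type(m1) is type(m2)
        if isinstance(m1, PredictionModel):
            assert m1.weights == m2.weights
            assert m1.perf_r2 == m2.perf_r2
            assert m1.perf_pvalue == m2.perf_pvalue


class TestQvalueRetention:
    def test_extreme_pvalues(self):
        models = [make_model("G1", p=1e-10), make_model("G2", p=0.9)]
        kept = filter_models_by_qvalue(models)
        assert [m.gene_id for m in kept] == ["G1"]

    def test_all_null_pvalues_retain_nothing(self):
        models = [make_model(f"G{i}", p=1.0) for i in range(5)]
        assert filter_models_by_qvalue(models) == []

    def test_empty_input(self):
        assert filter_models_by_qvalue([]) == []

    def test_mixture_retains_about_the_alternatives(self, rng):
        """900 uniform nulls + 100 alternatives at p=1e-6: ~100 retained."""
        pvals = np.concatenate([rng.uniform(size=900), np.full(100, 1e-6)])
        models = [make_model(f"G{i}", p=p) for i, p in enumerate(pvals)]
        kept = filter_models_by_qvalue(models)
        assert 100 <= len(kept) <= 115
        # every true alternative is retained (their BH-bound q is ~1e-5)
        alt_ids = {f"G{i}" for i in range(900, 1000)}
        assert alt_ids <= {m.gene_id for m in kept}

    def test_qvalues_bounded_by_benjamini_hochberg(self, rng):
        """Storey q-values never exceed the BH adjustment (pi0 <= 1)."""
        from statsmodels.stats.multitest import multipletests

        pvals = rng.uniform(size=200)
        q = qvalues(pvals)
        _, bh, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.all(q <= bh + 1e-12)
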