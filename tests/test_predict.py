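"""Unit tests for effect back-solving, scoring, metrics and fold assignment."""

import numpy as np
import pytest

from multiblup.genotype_io import GenotypeMatrix, SnpRecord, normalize
from multiblup.kinship import Region, compute_gsm
from multiblup.predict import (
    Metrics,
    cross_validate,
    evaluate,
    fit_prediction_model,
    genetic_score,
    grouped_kfold,
    predict_phenotype,
    predict_via_kinship,
    snp_effects_from_fit,
)
from multiblup.reml import GenotypeBlock, RemlOptions, VarianceModel, reml_fit
from multiblup.simulate import SimScenario, assign_regions, simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="module")
def trained():
    g = simulate_genotypes(300, 120, seed=31)
    x = normalize(g)
    regions = assign_regions(g.snps, 2)
    sim = simulate_phenotype(
        x, regions, SimScenario(n_regions=2, weights=[1, 1], h2_total=0.6,
                                n_causal_per_region="all", seed=32)
    )
    blocks = [GenotypeBlock(x.columns(r.snp_ids), list(r.snp_ids), r.name)
              for r in regions]
    model = VarianceModel([(b.name, b) for b in blocks])
    fit = reml_fit(sim.y, np.ones((x.n, 1)), model, RemlOptions(loglik_tol=1e-8))
    return g, x, regions, sim, blocks, model, fit


class TestSnpEffects:
    def test_effects_reproduce_algebraic_identity(self, rng):
        """X beta equals sigma2 K V^-1 (y - F b) computed by dense algebra."""
        n, p = 30, 5
        x_mat = rng.standard_normal((n, p))
        x_mat = (x_mat - x_mat.mean(0)) / x_mat.std(0)
        g_part = x_mat @ rng.standard_normal(p)
        y = g_part * 0.3 + rng.standard_normal(n)
        block = GenotypeBlock(x_mat, [f"s{j}" for j in range(p)], "r")
        model = VarianceModel([("r", block)])
        F = np.ones((n, 1))
        fit = reml_fit(y, F, model, RemlOptions(loglik_tol=1e-10))
        xg = normalize_from_block(x_mat)
        pm = snp_effects_from_fit(fit, model, xg)
        K = block.to_gsm().matrix
        V = fit.sigma2[0] * K + fit.sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        b = fit.fixed_coefs
        expected = fit.sigma2[0] * K @ Vi @ (y - F @ b)
        assert x_mat @ pm.regions[0].beta == pytest.approx(expected, abs=1e-10)

    def test_training_predictions_match_ghat_route(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        pm = snp_effects_from_fit(fit, model, x)
        via_effects = genetic_score(pm, g)
        via_ghat = sum(fit.ghat.values())
        assert via_effects == pytest.approx(via_ghat, abs=1e-8)

    def test_zero_variance_components_give_zero_effects(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        import copy

        silent = copy.deepcopy(fit)
        silent.sigma2 = np.zeros_like(fit.sigma2)
        pm = snp_effects_from_fit(silent, model, x)
        assert all(np.all(r.beta == 0) for r in pm.regions)
        pred = predict_phenotype(pm, g)
        assert np.ptp(pred) == 0.0  # fixed part only

    def test_gsm_component_rejected(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        k = compute_gsm(x, regions[0])
        bad = VarianceModel([("region_1", k), ("region_2", blocks[1])])
        with pytest.raises(ValueError, match="predict_via_kinship"):
            snp_effects_from_fit(fit, bad, x)


def normalize_from_block(mat):
    """Wrap an already-normalized matrix for effect extraction."""
    from multiblup.genotype_io import NormalizedGenotypes

    p = mat.shape[1]
    ids = [f"s{j}" for j in range(p)]
    return NormalizedGenotypes(
        matrix=mat, freqs=np.full(p, 0.5), snp_ids=ids,
        snps=[SnpRecord(i, 1, j + 1, "A", "G") for j, i in enumerate(ids)],
    )


class TestPredictPhenotype:
    def test_identical_individual_gets_training_score(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        pm = snp_effects_from_fit(fit, model, x)
        sub = g.subset(sample_idx=[7])
        score = genetic_score(pm, sub)[0]
        train_score = sum(fit.ghat.values())[7]
        assert score == pytest.approx(train_score, abs=1e-8)

    def test_allele_flip_resolved_by_sign(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        pm = snp_effects_from_fit(fit, model, x)
        flipped = GenotypeMatrix(
            samples=g.samples,
            snps=[SnpRecord(s.snp_id, s.chromosome, s.position_bp,
                            s.allele2, s.allele1) for s in g.snps],
            calls=np.where(g.calls == -1, -1, 2 - g.calls),
        )
        assert predict_phenotype(pm, flipped) == pytest.approx(
            predict_phenotype(pm, g), abs=1e-10
        )

    def test_absent_snp_reported(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        pm = snp_effects_from_fit(fit, model, x)
        with pytest.raises(KeyError, match="absent"):
            predict_phenotype(pm, g.subset(snp_idx=np.arange(5)))

    def test_allele_mismatch_rejected(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        pm = snp_effects_from_fit(fit, model, x)
        bad = GenotypeMatrix(
            samples=g.samples,
            snps=[SnpRecord(s.snp_id, s.chromosome, s.position_bp, "X", "Y")
                  for s in g.snps],
            calls=g.calls,
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_phenotype(pm, bad)


class TestKinshipRoute:
    def test_interpolates_training_values(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        k_full = compute_gsm(x, "all")
        # single full-rank component fit
        fit1 = reml_fit(sim.y, np.ones((x.n, 1)),
                        VarianceModel([("all", k_full)]),
                        RemlOptions(loglik_tol=1e-8))
        idx = np.arange(10)
        pred = predict_via_kinship(
            fit1,
            {"all": k_full.matrix[idx, :]},
            {"all": k_full},
        )
        expected = fit1.ghat["all"][idx] + fit1.fixed_coefs[0]
        assert pred == pytest.approx(expected, abs=1e-5)

    def test_route_equivalence_full_rank(self):
        g = simulate_genotypes(120, 200, seed=41)
        x = normalize(g)
        rng = np.random.default_rng(42)
        y = x.matrix @ rng.standard_normal(200) * 0.08 + rng.standard_normal(120)
        train, test = np.arange(90), np.arange(90, 120)
        g_tr = g.subset(sample_idx=train)
        x_tr = normalize(g_tr)
        block = GenotypeBlock(x_tr.matrix, x_tr.snp_ids, "all")
        model = VarianceModel([("all", block)])
        fit = reml_fit(y[train], np.ones((90, 1)), model,
                       RemlOptions(loglik_tol=1e-8))
        pm = snp_effects_from_fit(fit, model, x_tr)
        via_effects = predict_phenotype(pm, g.subset(sample_idx=test))

        # test rows on the training normalized scale
        calls = g.calls[np.ix_(test, np.arange(g.p))].astype(float)
        z = (calls - 2 * x_tr.freqs) / np.sqrt(2 * x_tr.freqs * (1 - x_tr.freqs))
        k_ts = z @ x_tr.matrix.T / g.p
        via_kinship = predict_via_kinship(
            fit, {"all": k_ts}, {"all": block.to_gsm()}
        )
        assert via_effects == pytest.approx(via_kinship, abs=1e-6)

    def test_zero_cross_kinship_gives_fixed_part(self, trained):
        g, x, regions, sim, blocks, model, fit = trained
        k_full = compute_gsm(x, "all")
        fit1 = reml_fit(sim.y, np.ones((x.n, 1)),
                        VarianceModel([("all", k_full)]))
        pred = predict_via_kinship(
            fit1, {"all": np.zeros((4, x.n))}, {"all": k_full}
        )
        assert pred == pytest.approx(np.full(4, fit1.fixed_coefs[0]))


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(20)
        m = evaluate(y, y)
        assert (m.correlation, m.mse, m.median_abs_error) == (
            pytest.approx(1.0), 0.0, 0.0)

    def test_separated_classes_auc_one(self):
        pred = np.array([3.0, 2.5, 0.1, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert evaluate(pred, labels.astype(float), labels).auc == 1.0

    def test_random_labels_auc_half(self, rng):
        pred = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        m = evaluate(pred, labels.astype(float), labels)
        assert m.auc == pytest.approx(0.5, abs=0.05)

    def test_constant_prediction_correlation_undefined(self, rng):
        m = evaluate(np.ones(10), rng.standard_normal(10))
        assert m.correlation is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(3), np.ones(4))


class TestGroupedKfold:
    def test_singleton_groups(self):
        folds = grouped_kfold(10, np.arange(10), k=10, seed=1)
        assert sorted(np.bincount(folds)) == [1] * 10

    def test_cagemates_never_split(self):
        groups = np.repeat(np.arange(25), 2)  # cages of two
        for seed in range(5):
            folds = grouped_kfold(50, groups, k=5, seed=seed)
            for cage in range(25):
                members = folds[groups == cage]
                assert len(set(members)) == 1

    def test_plain_folds_balanced(self):
        folds = grouped_kfold(100, None, k=10, seed=3)
        assert np.bincount(folds).tolist() == [10] * 10

    def test_more_folds_than_groups_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(10, np.repeat([0, 1], 5), k=3)


@pytest.fixture(scope="module")
def small():
    g = simulate_genotypes(240, 150, seed=51)
    x = normalize(g)
    regions = assign_regions(g.snps, 3)
    sim = simulate_phenotype(
        x, regions, SimScenario(n_regions=3, weights=[0, 0, 1],
                                h2_total=0.6, seed=52)
    )
    return g, sim, regions


class TestCrossValidate:

    def test_blup_equals_single_region_multiblup(self, small):
        g, sim, regions = small
        one = [Region("all", g.snp_ids)]
        a = cross_validate(g, sim.y, method="blup", k=3, seed=7)
        b = cross_validate(g, sim.y, method="multiblup", regions=one, k=3, seed=7)
        assert a.equals(b)

    def test_deterministic(self, small):
        g, sim, regions = small
        a = cross_validate(g, sim.y, method="multiblup", regions=regions,
                           k=3, seed=11)
        b = cross_validate(g, sim.y, method="multiblup", regions=regions,
                           k=3, seed=11)
        assert a.equals(b)

    def test_single_split_mode(self, small):
        g, sim, regions = small
        df = cross_validate(g, sim.y, method="blup", seed=3,
                            split_ratio=(5, 1))
        assert len(df) == 2  # one fold + mean row
        assert df.iloc[0]["n_test"] == pytest.approx(40)
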