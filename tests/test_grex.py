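"""Prediction-model training: baseline, symmetric and asymmetric variants."""

import warnings

import numpy as np
import pytest

from celltwas import (
    ElasticNetSpec,
    TrainingGeneData,
    build_celltype_design,
    evaluate_prediction,
    predict_grex,
    train_celltype_model,
    train_celltype_model_asymmetric,
    train_tissue_model,
)
from celltwas._penalized import fit_partially_penalized


def _simulate_gene(rng, n=300, p=50, b1_snp=7, b2_snp=13, b0=1.0,
                   b1=1.0, b2=1.0, homogeneous=False):
    X = rng.binomial(2, rng.uniform(0.05, 0.5, p), size=(n, p)).astype(float)
    pi = np.clip(rng.beta(2, 3, n), 1e-3, 1 - 1e-3)
    eff1 = np.zeros(p)
    eff2 = np.zeros(p)
    eff1[b1_snp] = b1
    eff2[b1_snp if homogeneous else b2_snp] = b2
    u = b0 + X @ eff1 + rng.standard_normal(n)
    v = X @ eff2 + rng.standard_normal(n)
    y = pi * u + (1 - pi) * v
    return TrainingGeneData(y=y, X=X, pi_hat=pi)


class TestTissueModel:
    def test_noise_outcome_selects_no_snps(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = rng.binomial(2, 0.3, size=(300, 50)).astype(float)
            y = rng.standard_normal(300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = train_tissue_model(TrainingGeneData(y=y, X=X),
                                       ElasticNetSpec(seed=seed))
            hits += int(np.all(m.b == 0))
        assert hits >= 7  # pure-noise predictors are nulled out almost always

    def test_single_causal_snp_recovered_with_shrunken_weight(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.3, size=(300, 50)).astype(float)
        y = 1.0 * X[:, 7] + rng.standard_normal(300)
        m = train_tissue_model(TrainingGeneData(y=y, X=X), ElasticNetSpec(seed=0))
        assert m.b[7] > 0
        assert 0.5 < m.b[7] < 1.2
        assert not m.untrainable

    def test_infinite_penalty_gives_empty_model(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(100, 10)).astype(float)
        y = X[:, 0] + rng.standard_normal(100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train_tissue_model(TrainingGeneData(y=y, X=X),
                                   ElasticNetSpec(lambda_=1e6))
        assert np.all(m.b == 0)
        assert m.untrainable

    def test_constant_expression_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(ValueError, match="constant"):
            train_tissue_model(TrainingGeneData(y=np.ones(50), X=X),
                               ElasticNetSpec())


class TestCellTypeDesign:
    def test_half_proportions_zero_out_interaction_block(self):
        X = np.array([[1.0, 2.0], [0.0, 1.0]])
        c, P, blocks = build_celltype_design(X, None, np.array([0.5, 0.5]))
        assert np.all(c == 0)
        assert np.all(P[:, blocks["interaction"]] == 0)

    def test_interaction_entry_is_centered_proportion_times_dosage(self):
        c, P, blocks = build_celltype_design(np.array([[2.0]]), None, np.array([0.9]))
        assert P[0, blocks["interaction"]][0] == pytest.approx(0.4 * 2.0)

    def test_complementary_proportions_flip_centered_blocks_only(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, (20, 4)).astype(float)
        pi = rng.uniform(0.1, 0.9, 20)
        c1, P1, bl = build_celltype_design(X, None, pi)
        c2, P2, _ = build_celltype_design(X, None, 1 - pi)
        np.testing.assert_allclose(c2, -c1)
        np.testing.assert_allclose(P2[:, bl["snp"]], P1[:, bl["snp"]])
        np.testing.assert_allclose(P2[:, bl["interaction"]], -P1[:, bl["interaction"]])


class TestSymmetricModel:
    def test_zero_penalty_matches_ols_on_augmented_design(self, heterogeneous_training):
        data, _ = heterogeneous_training
        c, P, _ = build_celltype_design(data.X, None, data.pi_hat)
        A = np.hstack([np.ones((len(data.y), 1)), c, P])
        beta_ols, *_ = np.linalg.lstsq(A, data.y, rcond=None)
        fit = fit_partially_penalized(data.y, P, c, lambda_=0.0)
        got = np.concatenate([fit.coef_unpen, fit.coef_pen])
        np.testing.assert_allclose(got, beta_ols, atol=1e-6)

    def test_label_swap_symmetry(self, heterogeneous_training):
        data, _ = heterogeneous_training
        flipped = TrainingGeneData(y=data.y, X=data.X, pi_hat=1 - data.pi_hat)
        spec = ElasticNetSpec(seed=3)
        m1 = train_celltype_model(data, spec, seed=11)
        m2 = train_celltype_model(flipped, spec, seed=11)
        np.testing.assert_allclose(m1.b_u, m2.b_v, atol=1e-8)
        np.testing.assert_allclose(m1.b_v, m2.b_u, atol=1e-8)
        assert m1.a_u == pytest.approx(m2.a_v, abs=1e-8)
        rng = np.random.default_rng(5)
        Xn = rng.binomial(2, 0.3, (100, data.X.shape[1])).astype(float)
        pin = rng.beta(2, 3, 100)
        t1 = predict_grex(m1, Xn, pi_new=pin).tissue
        t2 = predict_grex(m2, Xn, pi_new=1 - pin).tissue
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_heterogeneous_effects_detected_with_correct_signs(self, heterogeneous_training):
        data, truth = heterogeneous_training
        m = train_celltype_model(data, ElasticNetSpec(seed=0), seed=1)
        assert m.model_type == "cell_type_specific"
        assert m.b_u[truth["p1"]] > 0
        assert m.b_v[truth["p2"]] > 0

    def test_homogeneous_effects_usually_yield_nonspecific_models(self):
        n_nonspecific = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            data = _simulate_gene(rng, homogeneous=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = train_celltype_model(data, ElasticNetSpec(seed=seed), seed=seed)
            n_nonspecific += int(m.model_type == "nonspecific")
        assert n_nonspecific >= 0.7 * reps

    def test_half_proportions_collapse_to_tissue_model(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, (200, 20)).astype(float)
        y = X[:, 3] + rng.standard_normal(200)
        data = TrainingGeneData(y=y, X=X, pi_hat=np.full(200, 0.5))
        spec = ElasticNetSpec(seed=0)
        m = train_celltype_model(data, spec)
        t = train_tissue_model(data, spec)
        assert m.model_type == "nonspecific"
        np.testing.assert_allclose(m.b_u, m.b_v)
        np.testing.assert_allclose(m.b_u, t.b, atol=1e-8)


class TestAsymmetricModel:
    def test_order_dependence_on_heterogeneous_fixture(self, heterogeneous_training):
        data, _ = heterogeneous_training
        flipped = TrainingGeneData(y=data.y, X=data.X, pi_hat=1 - data.pi_hat)
        spec = ElasticNetSpec(seed=3)
        m1 = train_celltype_model_asymmetric(data, spec)
        m2 = train_celltype_model_asymmetric(flipped, spec)
        # swapping component order does NOT merely relabel the weights
        assert not (np.allclose(m1.b_u, m2.b_v, atol=1e-8)
                    and np.allclose(m1.b_v, m2.b_u, atol=1e-8))

    def test_homogeneous_fixture_gives_similar_weights(self):
        rng = np.random.default_rng(8)
        data = _simulate_gene(rng, homogeneous=True)
        m = train_celltype_model_asymmetric(data, ElasticNetSpec(seed=0))
        assert np.max(np.abs(m.b_u - m.b_v)) < 0.3

    def test_infinite_penalty_gives_empty_model(self):
        rng = np.random.default_rng(1)
        data = _simulate_gene(rng, n=100, p=10, b2_snp=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = train_celltype_model_asymmetric(data, ElasticNetSpec(lambda_=1e6))
        assert np.all(m.b_u == 0) and np.all(m.b_v == 0)


class TestPredictGrex:
    def test_weighted_mixture_arithmetic(self, heterogeneous_training):
        from celltwas import CellTypePredictionModel

        m = CellTypePredictionModel(
            gene_id="g", snp_ids=["s"], b_u=np.array([0.5]), b_v=np.array([-0.5]),
            a_u=0.0, a_v=0.0, c=np.zeros(0), model_type="cell_type_specific")
        pred = predict_grex(m, np.array([[2.0]]), pi_new=np.array([0.4]))
        assert pred.y_u[0] == pytest.approx(1.0)
        assert pred.y_v[0] == pytest.approx(-1.0)
        assert pred.tissue[0] == pytest.approx(0.4 * 1.0 + 0.6 * -1.0)

    def test_zero_weights_predict_zero(self):
        from celltwas import CellTypePredictionModel

        m = CellTypePredictionModel(
            gene_id="g", snp_ids=["a", "b"], b_u=np.zeros(2), b_v=np.zeros(2),
            a_u=0.0, a_v=0.0, c=np.zeros(0), model_type="nonspecific")
        pred = predict_grex(m, np.ones((5, 2)))
        assert np.all(pred.y_u == 0) and np.all(pred.y_v == 0)

    def test_nonspecific_model_predicts_identical_cell_types(self, heterogeneous_training):
        data, _ = heterogeneous_training
        spec = ElasticNetSpec(seed=0)
        m = train_tissue_model(data, spec)
        pred = predict_grex(m, data.X)
        np.testing.assert_array_equal(pred.y_u, pred.y_v)


class TestEvaluatePrediction:
    def test_identical_predictions_give_wilcoxon_p_one(self):
        from celltwas import CellTypePredictionModel

        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, (50, 2)).astype(float)
        pi = rng.uniform(0.2, 0.8, 50)
        m = CellTypePredictionModel(
            gene_id="g", snp_ids=["a", "b"], b_u=np.array([1.0, 0.0]),
            b_v=np.array([1.0, 0.0]), a_u=0, a_v=0, c=np.zeros(0),
            model_type="nonspecific")
        y = (X @ np.array([1.0, 0.0]))[:, None]
        rs, flags, comp = evaluate_prediction({"a": [m], "b": [m]}, y, X, pi)
        assert comp[("a", "b")] == 1.0
        assert rs["a"][0] == pytest.approx(1.0)  # perfect prediction

    def test_celltype_model_beats_baseline_on_heterogeneous_genes(self):
        rng = np.random.default_rng(77)
        n_genes = 20
        Xte = rng.binomial(2, rng.uniform(0.05, 0.5, 50), size=(400, 50)).astype(float)
        pite = np.clip(rng.beta(2, 3, 400), 1e-3, 1 - 1e-3)
        ys = []
        cell_models, tissue_models = [], []
        for g in range(n_genes):
            p1, p2 = rng.choice(50, size=2, replace=False)
            Xtr = rng.binomial(2, rng.uniform(0.05, 0.5, 50), size=(300, 50)).astype(float)
            pitr = np.clip(rng.beta(2, 3, 300), 1e-3, 1 - 1e-3)
            e1 = np.zeros(50); e1[p1] = 1.0
            e2 = np.zeros(50); e2[p2] = 1.0
            utr = 1 + Xtr @ e1 + rng.standard_normal(300)
            vtr = Xtr @ e2 + rng.standard_normal(300)
            data = TrainingGeneData(y=pitr * utr + (1 - pitr) * vtr, X=Xtr, pi_hat=pitr)
            spec = ElasticNetSpec(seed=g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell_models.append(train_celltype_model(data, spec, seed=g))
                tissue_models.append(train_tissue_model(data, spec))
            ute = 1 + Xte @ e1 + rng.standard_normal(400)
            vte = Xte @ e2 + rng.standard_normal(400)
            ys.append(pite * ute + (1 - pite) * vte)
        y_true = np.column_stack(ys)
        rs, _, _ = evaluate_prediction(
            {"celltype": cell_models, "baseline": tissue_models}, y_true, Xte, pite)
        assert np.median(rs["celltype"]) > np.median(rs["baseline"])
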