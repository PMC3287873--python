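"""Feature selection from the consensus network, AUC mechanics, risk models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bndissect.bayesnet import Dag, NodeSpec
from bndissect.errors import DataError
from bndissect.prediction import (
    FeatureSet,
    PredictionReport,
    evaluate,
    rank_auc,
    select_features,
    train_predictor,
)


class TestRankAuc:
    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            y = (rng.random(200) < 0.3).astype(int)
            s = rng.standard_normal(200) + y
            assert rank_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = (rng.random(300) < 0.4).astype(int)
        s = rng.standard_normal(300) + 0.5 * y
        assert rank_auc(s, y) == pytest.approx(rank_auc(np.exp(2 * s) + 5, y))

    def test_constant_score_gives_half(self):
        y = np.array([0, 1, 0, 1])
        assert rank_auc(np.zeros(4), y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            rank_auc(np.arange(4.0), np.ones(4))


class TestSelectFeatures:
    SPECS = [
        NodeSpec("geneA", "gene"), NodeSpec("geneB", "gene"), NodeSpec("geneC", "gene"),
        NodeSpec("Q1", "trait"), NodeSpec("Q2", "trait"),
        NodeSpec("affected", "disease"), NodeSpec("age", "environment"),
    ]
    NAMES = tuple(s.name for s in SPECS)

    def test_only_trait_connected_genes_are_qtls(self):
        dag = Dag(
            self.NAMES,
            edges=[("geneA", "Q1"), ("geneB", "Q2"), ("geneC", "affected")],
        )
        fs = select_features(dag, self.SPECS, include_env=False)
        # geneC points only at the disease node: not a QTL
        assert fs.qtl_genes == ("geneA", "geneB")

    def test_feature_class_toggles(self):
        dag = Dag(self.NAMES, edges=[("geneA", "Q1")])
        genes_only = select_features(dag, self.SPECS, include_env=False)
        assert genes_only.all_features == ("geneA",)
        full = select_features(dag, self.SPECS, include_traits=True, include_env=True)
        assert set(full.environment) == {"age", "sex", "smoking"}
        assert set(full.traits) == {"Q1", "Q2", "Q4"}

    def test_env_only_when_no_qtl_edges(self):
        dag = Dag(self.NAMES)
        fs = select_features(dag, self.SPECS, include_env=True)
        assert fs.qtl_genes == () and set(fs.environment) == {"age", "sex", "smoking"}

    def test_empty_feature_set_rejected(self):
        dag = Dag(self.NAMES)
        with pytest.raises(DataError):
            select_features(dag, self.SPECS, include_env=False)


class TestTrainPredictor:
    def test_separable_toy_reaches_full_training_auc(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        X = pd.DataFrame({"s": y + 0.01 * rng.standard_normal(200)})
        est = train_predictor(X, y)
        assert rank_auc(est.decision_function(X.to_numpy()), y) == 1.0

    def test_permutation_null_auc_near_half(self, rng):
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 5)))
        aucs = []
        for k in range(30):
            y = np.zeros(n, dtype=int)
            y[rng.permutation(n)[: n // 3]] = 1
            est = train_predictor(X.iloc[: n // 2], y[: n // 2], seed=k)
            aucs.append(rank_auc(est.decision_function(X.iloc[n // 2 :].to_numpy()), y[n // 2 :]))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_deterministic_given_seed(self, rng):
        y = (rng.random(150) < 0.4).astype(int)
        X = pd.DataFrame(rng.standard_normal((150, 3)))
        a = train_predictor(X, y, seed=3).decision_function(X.to_numpy())
        b = train_predictor(X, y, seed=3).decision_function(X.to_numpy())
        np.testing.assert_array_equal(a, b)

    def test_single_class_labels_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 2)))
        with pytest.raises(DataError):
            train_predictor(X, np.zeros(50))

    def test_lasso_logistic_model_available(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        X = pd.DataFrame(rng.standard_normal((200, 4)))
        X["0"] = X.iloc[:, 0] + y
        est = train_predictor(X, y, model="lasso_logistic")
        assert rank_auc(est.decision_function(X.to_numpy()), y) > 0.7


class _OracleScore:
    """Predictor whose decision score is a fixed column of the input."""

    def __init__(self, col):
        self.col = col

    def decision_function(self, X):
        return np.asarray(X)[:, self.col]


class TestEvaluate:
    def _fs(self):
        return FeatureSet(qtl_genes=("g",))

    def test_report_rows_and_mean(self, rng):
        sets = []
        for _ in range(10):
            y = (rng.random(100) < 0.3).astype(int)
            sets.append((pd.DataFrame({"g": rng.standard_normal(100) + y}), y))
        rep = evaluate(_OracleScore(0), sets, self._fs())
        assert len(rep.per_replicate) == 10
        assert rep.mean_auc == pytest.approx(rep.per_replicate.mean())

    def test_sd_matches_two_pass_computation(self, rng):
        sets = []
        for _ in range(8):
            y = (rng.random(80) < 0.4).astype(int)
            sets.append((pd.DataFrame({"g": rng.standard_normal(80) + 0.5 * y}), y))
        rep = evaluate(_OracleScore(0), sets, self._fs())
        vals = rep.per_replicate.to_numpy()
        mean = vals.sum() / len(vals)
        sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
        assert rep.sd_auc == pytest.approx(sd, abs=1e-12)

    def test_single_class_replicate_skipped(self, rng):
        good = (pd.DataFrame({"g": rng.standard_normal(50)}), (rng.random(50) < 0.5).astype(int))
        bad = (pd.DataFrame({"g": rng.standard_normal(50)}), np.zeros(50, dtype=int))
        rep = evaluate(_OracleScore(0), [good, bad], self._fs())
        assert rep.skipped == [1] and len(rep.per_replicate) == 1

    def test_liability_oracle_beats_fitted_model(self, tiny_replicates):
        # the latent liability is the Bayes-optimal score on this data
        rs = tiny_replicates
        from bndissect.gene_scores import score_all_genes
        from bndissect.prediction import build_feature_frame

        scores = score_all_genes(rs.genotypes, rs.variants, "nonsynonymous")
        fs = FeatureSet(
            environment=("age", "sex", "smoking"),
            qtl_genes=tuple(rs.truth.causal_genes["Q1"]),
        )
        X_train = build_feature_frame(rs.phenotypes[0], scores, fs)
        y_train = rs.phenotypes[0]["affected"].to_numpy()
        est = train_predictor(X_train, y_train)
        fitted, oracle = [], []
        for ph in rs.phenotypes[1:]:
            X = build_feature_frame(ph, scores, fs)
            y = ph["affected"].to_numpy()
            fitted.append(rank_auc(est.decision_function(X.to_numpy()), y))
            oracle.append(rank_auc(ph["liability"].to_numpy(), y))
        assert np.mean(oracle) > np.mean(fitted)
        assert np.mean(oracle) > 0.95


class TestFeatureSetInvariants:
    @given(st.sampled_from([(True, True), (True, False), (False, True)]))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_classes_disjoint(self, flags):
        env, traits = flags
        fs = FeatureSet(
            environment=("age",) if env else (),
            qtl_genes=("g1",),
            traits=("Q1",) if traits else (),
        )
        names = fs.all_features
        assert len(names) == len(set(names))
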