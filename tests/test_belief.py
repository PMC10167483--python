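"""Belief models: algebra, likelihood, fitting, features, classifiers."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln

from mechassembly.belief import (
    BeliefModel,
    FeatureConfig,
    belief_multisource,
    belief_simple,
    belief_with_refinements,
    encode_features,
    feature_matrix,
    neg_log_likelihood,
    statement_correct,
    train_and_evaluate,
)
from mechassembly.corpus_stats import sample_discrete_power_law


class TestBeliefAlgebra:
    def test_hand_computed_single_source(self):
        # 1 - (0.2 + 0.4^1 * 0.8) = 0.48
        assert belief_simple(1, 0.2, 0.4) == pytest.approx(0.48)

    def test_zero_random_error_limit(self):
        for n in (1, 5, 100):
            assert belief_simple(n, 0.2, 0.0) == pytest.approx(0.8)

    def test_asymptote(self):
        assert belief_simple(500, 0.05, 0.9) == pytest.approx(0.95, abs=1e-6)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            belief_simple(0, 0.1, 0.1)

    def test_binomial_hand_product(self):
        b = belief_multisource({"A": 2, "B": 1},
                               {"A": {"e_rand": 0.5}, "B": {"e_rand": 0.1}},
                               model="binomial")
        assert b == pytest.approx(1 - 0.25 * 0.1)

    def test_beta_binomial_uniform_single_mention(self):
        # Beta(1, 2)/Beta(1, 1) = 1/2
        b = belief_multisource({"A": 1}, {"A": {"alpha": 1.0, "beta": 1.0}},
                               model="beta_binomial")
        assert b == pytest.approx(0.5)

    def test_single_source_reduces_to_simple(self):
        params = {"A": {"e_syst": 0.13, "e_rand": 0.27}}
        for n in (1, 3, 10):
            assert belief_multisource({"A": n}, params, "rs") == \
                pytest.approx(belief_simple(n, 0.13, 0.27))

    def test_zero_count_source_is_noop(self):
        params = {"A": {"e_syst": 0.1, "e_rand": 0.3},
                  "B": {"e_syst": 0.9, "e_rand": 0.9}}
        with_b = belief_multisource({"A": 2, "B": 0}, params, "rs")
        without = belief_multisource({"A": 2}, params, "rs")
        assert with_b == pytest.approx(without)

    def test_unknown_source_error_names_source(self):
        with pytest.raises(KeyError, match="mystery"):
            belief_multisource({"mystery": 1}, {}, "rs")

    def test_unknown_source_uses_default(self):
        b = belief_multisource({"db": 1}, {},
                               default_params={"e_syst": 0.01,
                                               "e_rand": 0.05})
        assert b == pytest.approx(belief_simple(1, 0.01, 0.05))


class TestBeliefProperties:
    """Random-draw invariants shared by all three models."""

    @pytest.mark.parametrize("model", ["rs", "binomial", "beta_binomial"])
    def test_monotone_bounded_and_noop(self, model):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            # parameter ranges keep the belief increments representable in
            # floating point (e_rand^n underflows for tiny rates / huge n)
            if model == "beta_binomial":
                params = {"A": {"alpha": 10 ** rng.uniform(-1, 1),
                                "beta": 10 ** rng.uniform(-1, 1)},
                          "B": {"alpha": 10 ** rng.uniform(-1, 1),
                                "beta": 10 ** rng.uniform(-1, 1)}}
            else:
                params = {"A": {"e_syst": rng.uniform(0, 0.9),
                                "e_rand": rng.uniform(0.2, 0.95)},
                          "B": {"e_syst": rng.uniform(0, 0.9),
                                "e_rand": rng.uniform(0.2, 0.95)}}
            n = int(rng.integers(1, 10))
            b1 = belief_multisource({"A": n}, params, model)
            b2 = belief_multisource({"A": n + 1}, params, model)
            assert 0.0 <= b1 < 1.0
            assert b2 > b1 or b1 > 1 - 1e-12  # strictly increasing
            both = belief_multisource({"A": n, "B": 0}, params, model)
            assert both == pytest.approx(b1)

    def test_rs_asymptote_multisource(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            params = {s: {"e_syst": rng.uniform(0.01, 0.5),
                          "e_rand": rng.uniform(0.1, 0.9)}
                      for s in ("A", "B")}
            limit = 1 - params["A"]["e_syst"] * params["B"]["e_syst"]
            b = belief_multisource({"A": 400, "B": 400}, params, "rs")
            assert b == pytest.approx(limit, abs=1e-6)

    def test_binomial_is_rs_with_zero_systematic(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            er = {s: rng.uniform(0.05, 0.95) for s in ("A", "B")}
            counts = {"A": int(rng.integers(0, 8)),
                      "B": int(rng.integers(0, 8))}
            if sum(counts.values()) == 0:
                continue
            b_bin = belief_multisource(
                counts, {s: {"e_rand": e} for s, e in er.items()},
                "binomial")
            b_rs = belief_multisource(
                counts, {s: {"e_syst": 0.0, "e_rand": e}
                         for s, e in er.items()}, "rs")
            assert b_bin == pytest.approx(b_rs, abs=1e-12)


class TestStatementCorrect:
    def test_any_correct(self):
        assert statement_correct(["incorrect", "correct"])

    def test_all_incorrect(self):
        assert not statement_correct(["incorrect", "incorrect"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            statement_correct([])


class TestLikelihood:
    def test_single_statement_half(self):
        counts = np.array([[1.0]])
        # params giving B = 0.5: binomial with e_rand = 0.5
        nll = neg_log_likelihood(np.array([0.5]), counts, np.array([1.0]),
                                 model="binomial")
        assert nll == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_model_zero(self):
        counts = np.array([[1.0]])
        nll = neg_log_likelihood(np.array([0.0]), counts, np.array([1.0]),
                                 model="binomial", epsilon=0.0)
        assert nll == pytest.approx(0.0)

    def test_matches_per_item_sum_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, size=(10, 2)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        labels = rng.integers(0, 2, size=10).astype(float)
        theta = np.array([0.1, 0.2, 0.3, 0.4])  # e_syst x2, e_rand x2
        total = neg_log_likelihood(theta, counts, labels, "rs")
        acc = 0.0
        for i in range(10):
            b = belief_multisource(
                {"A": int(counts[i, 0]), "B": int(counts[i, 1])},
                {"A": {"e_syst": 0.1, "e_rand": 0.3},
                 "B": {"e_syst": 0.2, "e_rand": 0.4}}, "rs")
            b = min(max(b, 1e-6), 1 - 1e-6)
            acc -= labels[i] * np.log(b) + (1 - labels[i]) * np.log(1 - b)
        assert total == pytest.approx(acc, rel=1e-9)


def _simulate_curated(n, e_syst, e_rand, seed):
    """Direct model-based curation sample: power-law counts, Bernoulli
    correctness under the two-parameter model."""
    rng = np.random.default_rng(seed)
    counts = sample_discrete_power_law(n, 2.38, rng, xmax=50)
    syst = rng.random(n) < e_syst
    n_correct = rng.binomial(counts, 1 - e_rand)
    labels = (~syst) & (n_correct > 0)
    return counts.astype(float)[:, None], labels.astype(float)


class TestFitting:
    def test_mcmc_recovers_reference_parameters(self):
        counts, labels = _simulate_curated(2000, 0.1, 0.35, seed=101)
        model = BeliefModel(counts, labels, sources=("reader_a",),
                            model="rs")
        res = model.fit(method="mcmc", seed=101)
        assert res.params["reader_a"]["e_syst"] == pytest.approx(0.1,
                                                                 abs=0.05)
        assert res.params["reader_a"]["e_rand"] == pytest.approx(0.35,
                                                                 abs=0.05)
        assert res.param_sd["reader_a"]["e_syst"] > 0

    def test_mle_matches_mcmc_mode(self):
        counts, labels = _simulate_curated(2000, 0.1, 0.35, seed=11)
        model = BeliefModel(counts, labels, sources=("s",), model="rs")
        mle = model.fit_mle()
        mcmc = model.fit(method="mcmc", seed=11)
        for p in ("e_syst", "e_rand"):
            assert mle.params["s"][p] == pytest.approx(mcmc.params["s"][p],
                                                       abs=0.02)

    def test_error_free_data_boundary_estimate(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 6, size=300).astype(float)[:, None]
        labels = np.ones(300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BeliefModel(counts, labels, sources=("s",),
                                model="binomial")
            res = model.fit_mle()
        assert res.params["s"]["e_rand"] < 0.01

    def test_degenerate_data_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            BeliefModel(np.ones((5, 1)), np.ones(5), model="rs")

    def test_two_parameter_models_beat_binomial_on_systematic_data(self):
        """Data generated with nonzero systematic error: both two-parameter
        models reach lower -log likelihood than the binomial."""
        counts, labels = _simulate_curated(2000, 0.15, 0.3, seed=21)
        nlls = {}
        for m in ("binomial", "rs", "beta_binomial"):
            nlls[m] = BeliefModel(counts, labels, sources=("s",),
                                  model=m).fit_mle().nll
        assert nlls["rs"] < nlls["binomial"]
        assert nlls["beta_binomial"] < nlls["binomial"]

    def test_summary_mentions_model_and_params(self):
        counts, labels = _simulate_curated(200, 0.1, 0.35, seed=5)
        res = BeliefModel(counts, labels, sources=("s",),
                          model="rs").fit_mle()
        text = res.summary()
        assert "rs" in text and "e_syst" in text and "e_rand" in text


class TestRefinementBeliefs:
    def test_isolated_equals_direct(self, small_corpus):
        config, corpus, _ = small_corpus
        beliefs = belief_with_refinements(corpus, config.source_params, "rs")
        for key in corpus.statements:
            if corpus.refinement_graph.in_degree(key) == 0:
                direct = belief_multisource(
                    corpus.evidence_counts(key).direct,
                    config.source_params, "rs")
                assert beliefs[key] == pytest.approx(direct)

    def test_refined_statement_belief_not_lower(self, small_corpus):
        config, corpus, _ = small_corpus
        beliefs = belief_with_refinements(corpus, config.source_params, "rs")
        for key in corpus.statements:
            direct = belief_multisource(corpus.evidence_counts(key).direct,
                                        config.source_params, "rs")
            assert beliefs[key] >= direct - 1e-12

    def test_chain_belief_non_increasing_toward_specific(self, chain_fixture):
        stmts, onto = chain_fixture
        from mechassembly.assembly import AssembledCorpus, \
            build_refinement_graph
        corpus = AssembledCorpus(stmts, build_refinement_graph(stmts, onto),
                                 onto)
        params = {"reader_a": {"e_syst": 0.1, "e_rand": 0.35}}
        beliefs = belief_with_refinements(corpus, params, "rs")
        # walk one maximal chain from most generic to most specific
        import networkx as nx
        path = nx.dag_longest_path(corpus.refinement_graph)
        chain_beliefs = [beliefs[k] for k in path]  # specific -> generic
        assert chain_beliefs == sorted(chain_beliefs)


class TestFeatures:
    def _counts_corpus(self):
        from mechassembly.assembly import AssembledCorpus
        from mechassembly.statements import Evidence, Statement
        import networkx as nx
        from conftest import make_agent
        evs = [
            Evidence(source_api="reader_a", pmid="1", text=" ".join(["t"] * 10)),
            Evidence(source_api="reader_a", pmid="2", text=" ".join(["t"] * 12)),
            Evidence(source_api="reader_b", pmid="2", text=" ".join(["t"] * 8)),
        ]
        s = Statement("Activation", [make_agent("A"), make_agent("B")],
                      evidence=evs)
        from mechassembly.statements import matches_key
        stmts = {matches_key(s): s}
        g = nx.DiGraph()
        g.add_nodes_from(stmts)
        return AssembledCorpus(stmts, g), next(iter(stmts))

    def test_constructed_vector(self):
        corpus, key = self._counts_corpus()
        config = FeatureConfig(sources=("reader_a", "reader_b"),
                               stmt_types=("Activation",))
        feats = encode_features(key, corpus, config)
        assert feats["n_reader_a"] == 2 and feats["n_reader_b"] == 1
        assert feats["n_pmids"] == 2
        assert feats["mean_text_len"] == pytest.approx(10.0)
        assert feats["keyword_freq"] == 0.0
        assert feats["type_Activation"] == 1.0

    def test_keyword_frequency(self):
        corpus, key = self._counts_corpus()
        stmt = corpus.statements[key]
        stmt.evidence.append(
            type(stmt.evidence[0])(source_api="reader_b", pmid="3",
                                   text="binds the promoter region"))
        config = FeatureConfig(sources=("reader_a", "reader_b"))
        feats = encode_features(key, corpus, config)
        assert feats["keyword_freq"] == pytest.approx(0.25)

    def test_extended_columns_are_separate(self, small_corpus):
        _, corpus, _ = small_corpus
        keys = list(corpus.statements)[:20]
        cfg_direct = FeatureConfig(sources=("reader_a",))
        cfg_ext = FeatureConfig(sources=("reader_a",), include_extended=True)
        direct = feature_matrix(corpus, keys, cfg_direct)
        ext = feature_matrix(corpus, keys, cfg_ext)
        assert "n_ext_reader_a" in ext.columns
        assert "n_ext_reader_a" not in direct.columns
        assert (ext["n_reader_a"] == direct["n_reader_a"]).all()


class TestClassifiers:
    def test_perfectly_separable_auprc_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.01, 200)])
        res = train_and_evaluate(X, y, "logistic", folds=5, seed=0)
        assert res["mean_auprc"] == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        n, p = 4000, 0.3
        y = (rng.random(n) < p).astype(int)
        X = rng.random((n, 3))  # uninformative, nonnegative for the log
        # transform
        res = train_and_evaluate(X, y, "logistic", folds=5, seed=1)
        assert res["mean_auprc"] == pytest.approx(p, abs=0.05)

    def test_rf_beats_prevalence_on_informative_counts(
            self, single_source_corpus):
        config, corpus, _ = single_source_corpus
        keys = list(corpus.statements)
        labels = np.array(
            [any(ev.annotations["correct"]
                 for ev in corpus.statements[k].evidence) for k in keys],
            dtype=int)
        X = feature_matrix(corpus, keys)
        res = train_and_evaluate(X, labels, "random_forest", folds=5,
                                 seed=0, n_estimators=200)
        prevalence = labels.mean()
        assert res["mean_auprc"] >= prevalence + 0.1
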