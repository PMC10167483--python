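"""Codependency scoring, multiple-testing corrections, explanations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mechassembly.codependency import (
    CodependencyModel,
    exclude_mito_pairs,
    explain_pairs,
    pairwise_z,
    ppi_belief_comparison,
    significant_pairs,
)
from mechassembly.ontology import OntologyGraph
from mechassembly.synthetic import (
    SimulationConfig,
    generate_dependency_matrices,
)


def _matrices_from_effects(effects1, effects2=None):
    m1 = pd.DataFrame(effects1)
    m2 = pd.DataFrame(effects2 if effects2 is not None else effects1)
    return m1, m2


class TestPairwiseZ:
    def test_zero_correlation_zero_combined(self):
        rng = np.random.default_rng(0)
        m1 = pd.DataFrame(rng.normal(size=(2, 2000)), index=["a", "b"])
        m2 = pd.DataFrame(rng.normal(size=(2, 2000)), index=["a", "b"])
        out = pairwise_z(m1, m2)
        assert abs(out.iloc[0]["z_comb"]) < 3

    def test_stouffer_identity_equal_z(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(2, 300))
        m = pd.DataFrame(base, index=["a", "b"])
        out = pairwise_z(m, m.copy())
        row = out.iloc[0]
        assert row["z1"] == pytest.approx(row["z2"])
        assert row["z_comb"] == pytest.approx(row["z1"] * math.sqrt(2))

    def test_planted_pair_z_magnitude(self):
        rng = np.random.default_rng(2)
        n = 500
        frames = []
        for _ in range(2):
            latent = rng.normal(size=n)
            a = np.sqrt(0.5) * latent + np.sqrt(0.5) * rng.normal(size=n)
            b = np.sqrt(0.5) * latent + np.sqrt(0.5) * rng.normal(size=n)
            frames.append(pd.DataFrame([a, b], index=["a", "b"]))
        out = pairwise_z(frames[0], frames[1])
        expected = 2 * math.atanh(0.5) * math.sqrt(n - 3) / math.sqrt(2)
        assert out.iloc[0]["z_comb"] == pytest.approx(expected, abs=3)

    def test_insufficient_overlap_skipped(self):
        m1 = pd.DataFrame([[1, 2, np.nan, np.nan],
                           [np.nan, np.nan, 3, 4],
                           [1, 2, 3, 4]], index=["a", "b", "c"],
                          dtype=float)
        out = pairwise_z(m1, m1.copy(), min_samples=2)
        pairs = {frozenset((r["gene_a"], r["gene_b"]))
                 for _, r in out.iterrows()}
        assert frozenset(("a", "b")) not in pairs

    def test_sign_preserved(self):
        rng = np.random.default_rng(3)
        n = 400
        latent = rng.normal(size=n)
        a = latent + 0.5 * rng.normal(size=n)
        b = -latent + 0.5 * rng.normal(size=n)
        m = pd.DataFrame([a, b], index=["a", "b"])
        out = pairwise_z(m, m.copy())
        assert out.iloc[0]["z_comb"] < 0


class TestMitoExclusion:
    def _scores(self):
        return pd.DataFrame({
            "gene_a": ["m1", "m1", "g1"], "gene_b": ["m2", "g1", "g2"],
            "z_comb": [5.0, 4.0, 3.0], "p": [1e-6, 1e-4, 1e-2]})

    def test_both_in_set_excluded(self):
        kept, excluded = exclude_mito_pairs(self._scores(), {"m1", "m2"})
        assert len(excluded) == 1
        assert excluded.iloc[0]["gene_a"] == "m1"
        assert (excluded["explanation"] == "excluded_mito").all()

    def test_one_in_set_retained(self):
        kept, _ = exclude_mito_pairs(self._scores(), {"m1", "m2"})
        assert {"g1"} < set(kept["gene_a"]) | set(kept["gene_b"])
        assert len(kept) == 2

    def test_empty_set_identity(self):
        scores = self._scores()
        kept, excluded = exclude_mito_pairs(scores, set())
        assert len(kept) == 3 and len(excluded) == 0


def _bruteforce_stepup(pvals, alpha, weights):
    """Generic step-up threshold scan: reject the largest k with
    p_(k) <= alpha * k / (m * c)."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= alpha * k / (m * weights):
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestSignificantPairs:
    def _frame(self, pvals):
        n = len(pvals)
        return pd.DataFrame({"gene_a": [f"a{i}" for i in range(n)],
                             "gene_b": [f"b{i}" for i in range(n)],
                             "p": pvals})

    def test_worked_four_pvalue_example(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        bh, _ = significant_pairs(self._frame(pvals), "bh", 0.05)
        bonf, _ = significant_pairs(self._frame(pvals), "bonferroni", 0.05)
        by, _ = significant_pairs(self._frame(pvals), "by", 0.05)
        assert int(bh["significant"].sum()) == 4
        assert int(bonf["significant"].sum()) == 1
        assert int(by["significant"].sum()) == 0

    def test_matches_bruteforce_scan_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(1, 50))
            pvals = rng.random(m) ** 2
            frame = self._frame(pvals)
            bh, _ = significant_pairs(frame, "bh", 0.05)
            assert (bh["significant"].to_numpy()
                    == _bruteforce_stepup(pvals, 0.05, 1.0)).all()
            c_m = sum(1.0 / i for i in range(1, m + 1))
            by, _ = significant_pairs(frame, "by", 0.05)
            assert (by["significant"].to_numpy()
                    == _bruteforce_stepup(pvals, 0.05, c_m)).all()
            bonf, _ = significant_pairs(frame, "bonferroni", 0.05)
            assert (bonf["significant"].to_numpy()
                    == (pvals <= 0.05 / m)).all()

    def test_unknown_method_config_error(self):
        with pytest.raises(ValueError):
            significant_pairs(self._frame([0.01]), "fdr_magic")

    def test_prior_restricts_and_reports_prior_only(self):
        rng = np.random.default_rng(7)
        pvals = rng.random(200) * 0.2
        frame = self._frame(pvals)
        prior = {(f"a{i}", f"b{i}") for i in range(0, 200, 4)}
        out, summary = significant_pairs(frame, "by", 0.05, prior)
        assert summary["n_tests_prior"] == 50
        assert summary["n_tests_prior"] <= summary["n_tests_total"]
        prior_only = out[out["significant"] & ~out["significant_no_prior"]]
        assert summary["n_significant_prior_only"] == len(prior_only)
        # every prior-only significant pair is non-significant in the
        # unrestricted run at the same alpha (consistency)
        assert not prior_only["significant_no_prior"].any()


class TestExplanations:
    def _ontology(self):
        onto = OntologyGraph()
        fam = onto.add_node("FPLX", "ROCK", "ROCK")
        g1 = onto.add_node("HGNC", "1", "ROCK1")
        g2 = onto.add_node("HGNC", "2", "ROCK2")
        onto.add_edge(g1, fam, "isa")
        onto.add_edge(g2, fam, "isa")
        onto.add_node("HGNC", "3", "MPRIP")
        return onto

    def _scores(self, pairs):
        return pd.DataFrame({"gene_a": [p[0] for p in pairs],
                             "gene_b": [p[1] for p in pairs],
                             "p": [0.01] * len(pairs)})

    def test_direct_edge_either_direction(self):
        scores = self._scores([("A", "B")])
        out = explain_pairs(scores, [("B", "A")])
        assert out.iloc[0]["explanation"] == "direct"

    def test_shared_family_parent(self):
        scores = self._scores([("ROCK1", "ROCK2")])
        out = explain_pairs(scores, [], self._ontology())
        assert out.iloc[0]["explanation"] == "family_complex"

    def test_parent_link_via_family_edge(self):
        # an edge between MPRIP and the ROCK family explains the
        # MPRIP-ROCK2 codependency through the parent
        scores = self._scores([("MPRIP", "ROCK2")])
        out = explain_pairs(scores, [("ROCK", "MPRIP")], self._ontology())
        assert out.iloc[0]["explanation"] == "parent_link"

    def test_unexplained_and_priority_order(self):
        onto = self._ontology()
        scores = self._scores([("ROCK1", "ROCK2"), ("X", "Y")])
        out = explain_pairs(scores, [("ROCK1", "ROCK2")], onto)
        # direct outranks family_complex for the same pair
        assert out.iloc[0]["explanation"] == "direct"
        assert out.iloc[1]["explanation"] == "unexplained"

    def test_multi_step_paths_never_count(self):
        scores = self._scores([("A", "C")])
        out = explain_pairs(scores, [("A", "B"), ("B", "C")])
        assert out.iloc[0]["explanation"] == "unexplained"


class TestPPIComparison:
    def _pairs(self, beliefs, in_ref_flags):
        n = len(beliefs)
        frame = pd.DataFrame({
            "gene_a": [f"a{i}" for i in range(n)],
            "gene_b": [f"b{i}" for i in range(n)],
            "belief": beliefs})
        ref = [(f"a{i}", f"b{i}") for i, f in enumerate(in_ref_flags) if f]
        return frame, ref

    def test_all_in_reference_fraction_one(self):
        frame, ref = self._pairs([0.2, 0.5, 0.9], [True, True, True])
        out = ppi_belief_comparison(frame, ref)
        nonempty = out["bins"][out["bins"]["n_total"] > 0]
        assert (nonempty["fraction_in_reference"] == 1.0).all()
        assert out["expected_uncurated_correct"] == 0.0

    def test_single_uncurated_expectation(self):
        frame, ref = self._pairs([0.9], [False])
        out = ppi_belief_comparison(frame, ref)
        assert out["expected_uncurated_correct"] == pytest.approx(0.9)
        assert out["yield_curve"]["expected_correct"].iloc[-1] == \
            pytest.approx(0.9)

    def test_calibrated_beliefs_estimate_planted_truth(self):
        """With calibrated beliefs and a reference holding a known half of
        the true pairs, the expected-uncurated-correct estimate lands
        within 10% of the planted number of true-but-uncurated pairs."""
        rng = np.random.default_rng(8)
        n_uncurated = 4000
        beliefs = rng.uniform(0.05, 0.95, n_uncurated)
        truth = rng.random(n_uncurated) < beliefs  # calibrated on the pool
        planted_uncurated_true = int(truth.sum())
        # the curated reference holds a separate set of known-true pairs
        # sized to cover half of all true pairs
        n_ref = planted_uncurated_true
        ref_beliefs = rng.uniform(0.5, 0.99, n_ref)
        all_beliefs = np.concatenate([beliefs, ref_beliefs]).tolist()
        in_ref = [False] * n_uncurated + [True] * n_ref
        frame, ref = self._pairs(all_beliefs, in_ref)
        out = ppi_belief_comparison(frame, ref)
        assert out["expected_uncurated_correct"] == pytest.approx(
            float(beliefs.sum()))
        assert out["expected_uncurated_correct"] == pytest.approx(
            planted_uncurated_true, rel=0.10)


class TestEndToEnd:
    def test_planted_pairs_recovered_and_dataset_order_invariant(self):
        config = SimulationConfig(seed=33)
        m1, m2, planted = generate_dependency_matrices(config)
        res = CodependencyModel(m1, m2).fit(method="bh", alpha=0.05)
        sig = {frozenset((r["gene_a"], r["gene_b"]))
               for _, r in res.significant.iterrows()}
        hits = sum(frozenset(p) in sig for p in planted)
        assert hits >= 0.9 * len(planted)
        # dataset order invariance of the combined z
        res_swapped = CodependencyModel(m2, m1).fit(method="bh", alpha=0.05)
        np.testing.assert_allclose(
            np.sort(res.scores["z_comb"].to_numpy()),
            np.sort(res_swapped.scores["z_comb"].to_numpy()), rtol=1e-10)

    def test_replicates_differ(self):
        config = SimulationConfig(seed=33)
        m1, m2, _ = generate_dependency_matrices(config)
        assert not np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_rho_zero_centered(self):
        config = SimulationConfig(seed=9, n_planted_pairs=0, n_genes=20,
                                  n_samples=300)
        m1, m2, planted = generate_dependency_matrices(config)
        assert planted == []
        scores = pairwise_z(m1, m2)
        assert abs(scores["r1"].mean()) < 0.05
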