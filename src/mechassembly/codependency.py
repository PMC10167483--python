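r"""Gene codependency detection and explanation with a network prior.

Genome-scale perturbation screens report, for each gene, an effect on
viability across hundreds of cell lines.  Genes whose effect profiles
correlate across cell lines ("codependencies") frequently act in the same
complex or pathway.  This module scores gene pairs across two replicate
screens, combines the evidence, controls the false discovery rate (with or
without restricting the tested hypotheses to pairs present in an assembled
mechanism network), and labels each significant pair with the most
specific available mechanistic explanation.

Scoring: the Pearson correlation r of a pair in each dataset is Fisher-
transformed into a signed z-score, z = atanh(r) * sqrt(n - 3), and the two
datasets are combined by Stouffer's method, z_comb = (z1 + z2)/sqrt(2),
from which a two-sided p-value follows.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .assembly import AssembledCorpus
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_z",
    "exclude_mito_pairs",
    "significant_pairs",
    "explain_pairs",
    "ppi_belief_comparison",
    "CodependencyModel",
    "CodependencyResults",
]

_METHOD_MAP = {"bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by"}

EXPLANATION_LABELS = ("direct", "family_complex", "parent_link",
                      "unexplained", "excluded_mito")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def pairwise_z(matrix1: pd.DataFrame, matrix2: pd.DataFrame,
               min_samples: int = 4) -> pd.DataFrame:
    """Per-pair correlations, signed z-scores and combined significance.

    Both matrices are genes x samples; only genes present in both are
    scored.  Correlations use pairwise-complete observations; pairs with
    fewer than ``min_samples`` common samples in either dataset are
    skipped (logged).  Returns a DataFrame with columns gene_a, gene_b,
    r1, z1, n1, r2, z2, n2, z_comb, p.
    """
    genes = sorted(set(matrix1.index) & set(matrix2.index))
    if len(genes) < 2:
        raise ValueError("need at least two genes shared by both matrices")
    rows = []
    n_skipped = 0
    stats_per_ds = []
    for mat in (matrix1, matrix2):
        sub = mat.loc[genes]
        arr = sub.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        # pairwise-complete correlation and overlap counts
        corr = sub.T.corr(min_periods=min_samples).to_numpy()
        n_common = finite.astype(float) @ finite.astype(float).T
        stats_per_ds.append((corr, n_common))
    for i, j in itertools.combinations(range(len(genes)), 2):
        zs, entry = [], {"gene_a": genes[i], "gene_b": genes[j]}
        ok = True
        for d, (corr, n_common) in enumerate(stats_per_ds, start=1):
            n = int(n_common[i, j])
            r = corr[i, j]
            if n < max(min_samples, 4) or not np.isfinite(r):
                ok = False
                break
            r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
            z = math.atanh(r) * math.sqrt(n - 3)
            entry[f"r{d}"], entry[f"z{d}"], entry[f"n{d}"] = r, z, n
            zs.append(z)
        if not ok:
            n_skipped += 1
            continue
        z_comb = sum(zs) / math.sqrt(len(zs))
        entry["z_comb"] = z_comb
        entry["p"] = 2.0 * sps.norm.sf(abs(z_comb))
        rows.append(entry)
    if n_skipped:
        logger.info("skipped %d pairs with insufficient sample overlap",
                    n_skipped)
    return pd.DataFrame(rows)


def exclude_mito_pairs(scores: pd.DataFrame, mito_gene_set: set[str],
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off pairs where BOTH genes are mitochondrial.

    Correlations among mitochondrial genes are a known screening artifact
    and are considered explained a priori; pairs with exactly one
    mitochondrial gene are retained for testing.  Returns
    (retained, excluded) frames; excluded rows are labeled
    ``excluded_mito``.
    """
    if scores.empty or not mito_gene_set:
        return scores, scores.iloc[0:0]
    both = (scores["gene_a"].isin(mito_gene_set)
            & scores["gene_b"].isin(mito_gene_set))
    excluded = scores[both].copy()
    excluded["explanation"] = "excluded_mito"
    return scores[~both].copy(), excluded


def significant_pairs(scores: pd.DataFrame, method: str = "by",
                      alpha: float = 0.05,
                      prior_pairs: Optional[set] = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Flag significant pairs under a multiple-testing correction.

    ``method`` is one of bonferroni / bh / by.  When ``prior_pairs`` is
    given (a set of unordered gene-symbol pairs from a mechanism network),
    only pairs in the prior are tested, shrinking the hypothesis family;
    the summary then also counts pairs significant *only* under the prior
    (i.e. not significant in the unrestricted run at the same alpha).
    """
    if method not in _METHOD_MAP:
        raise ValueError(f"unknown correction method {method!r}; choose "
                         f"from {sorted(_METHOD_MAP)}")
    scores = scores.copy()
    pvals = scores["p"].to_numpy()
    rejected_all, _, _, _ = multipletests(pvals, alpha=alpha,
                                          method=_METHOD_MAP[method])
    summary = {"method": method, "alpha": alpha,
               "n_tests_total": len(scores),
               "n_significant_total": int(rejected_all.sum())}
    if prior_pairs is None:
        scores["significant"] = rejected_all
        return scores, summary
    keys = [_pair_key(a, b) for a, b in zip(scores["gene_a"],
                                            scores["gene_b"])]
    prior = {_pair_key(*p) for p in prior_pairs}
    in_prior = np.array([k in prior for k in keys])
    rejected_prior = np.zeros(len(scores), dtype=bool)
    if in_prior.any():
        rej, _, _, _ = multipletests(pvals[in_prior], alpha=alpha,
                                     method=_METHOD_MAP[method])
        rejected_prior[np.flatnonzero(in_prior)] = rej
    scores["in_prior"] = in_prior
    scores["significant"] = rejected_prior
    scores["significant_no_prior"] = rejected_all
    summary.update({
        "n_tests_prior": int(in_prior.sum()),
        "n_significant_prior": int(rejected_prior.sum()),
        "n_significant_prior_only": int(
            (rejected_prior & ~rejected_all).sum()),
    })
    return scores, summary


def _parents(gene: str, onto: Optional[OntologyGraph]) -> set[str]:
    if onto is None:
        return set()
    node = onto.node_by_name(gene)
    if node is None:
        return set()
    return {onto.name_of(k) for k in onto.ancestor_closure(node)}


def explain_pairs(scores: pd.DataFrame, network_edges: Iterable[tuple],
                  onto: Optional[OntologyGraph] = None) -> pd.DataFrame:
    """Label each pair with its most specific mechanistic explanation.

    Priority order (exclusive, most to least specific):

    - ``direct``: a network edge connects the two genes (either direction);
    - ``family_complex``: the genes share an isa/partof parent in the
      ontology (same family or complex);
    - ``parent_link``: an edge connects a gene or one of its parents to
      the other gene or one of its parents, with at least one endpoint
      being a parent rather than the gene itself;
    - ``unexplained`` otherwise.  Multi-step network paths never count.
    """
    edge_set = set()
    for u, v in network_edges:
        edge_set.add(_pair_key(u, v))
    out = scores.copy()
    labels = []
    parent_cache: dict[str, set[str]] = {}
    for a, b in zip(out["gene_a"], out["gene_b"]):
        for g in (a, b):
            if g not in parent_cache:
                parent_cache[g] = _parents(g, onto)
        pa, pb = parent_cache[a], parent_cache[b]
        if _pair_key(a, b) in edge_set:
            labels.append("direct")
        elif pa & pb:
            labels.append("family_complex")
        else:
            found = False
            for x in {a} | pa:
                for y in {b} | pb:
                    if (x, y) == (a, b):
                        continue
                    if _pair_key(x, y) in edge_set and (x in pa or y in pb):
                        found = True
                        break
                if found:
                    break
            labels.append("parent_link" if found else "unexplained")
    out["explanation"] = labels
    return out


def ppi_belief_comparison(pairs: pd.DataFrame,
                          reference_edges: Iterable[tuple],
                          bin_width: float = 0.1) -> dict:
    """Compare belief-scored interaction pairs against a curated reference.

    ``pairs`` needs columns gene_a, gene_b, belief (one row per unique
    undirected pair, e.g. from Complex-type Statements).  Pairs are binned
    by belief (width 0.1); each bin reports how many fall inside/outside
    the reference and the in-reference fraction.  For pairs *not* in the
    reference ("uncurated") the expected number of correct-but-uncurated
    interactions is the sum of their beliefs, and a curation-yield curve
    gives the cumulative expected correct count were pairs reviewed in
    descending belief order.
    """
    ref = {_pair_key(u, v) for u, v in reference_edges}
    pairs = pairs.copy()
    pairs["in_reference"] = [
        _pair_key(a, b) in ref
        for a, b in zip(pairs["gene_a"], pairs["gene_b"])]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    bin_idx = np.clip(np.digitize(pairs["belief"], edges) - 1, 0,
                      len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        n = int(mask.sum())
        n_in = int(pairs.loc[mask, "in_reference"].sum())
        rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                     "n_total": n, "n_in_reference": n_in,
                     "n_not_in_reference": n - n_in,
                     "fraction_in_reference": n_in / n if n else np.nan})
    uncurated = pairs[~pairs["in_reference"]]
    expected_correct = float(uncurated["belief"].sum())
    order = uncurated.sort_values("belief", ascending=False)
    yield_curve = pd.DataFrame({
        "n_reviewed": np.arange(1, len(order) + 1),
        "expected_correct": order["belief"].cumsum().to_numpy(),
    })
    return {"bins": pd.DataFrame(rows),
            "expected_uncurated_correct": expected_correct,
            "yield_curve": yield_curve,
            "n_pairs": len(pairs)}


# ---------------------------------------------------------------------------
# Model/Results wrapper
# ---------------------------------------------------------------------------

class CodependencyModel:
    """Codependency analysis over two replicate gene-effect matrices.

    Wraps the scoring/exclusion/correction/explanation steps behind a
    fit() returning a results object, statsmodels-style.
    """

    def __init__(self, matrix1: pd.DataFrame, matrix2: pd.DataFrame,
                 mito_genes: Optional[set[str]] = None,
                 network_edges: Optional[Iterable[tuple]] = None,
                 ontology: Optional[OntologyGraph] = None,
                 min_samples: int = 4):
        self.matrix1 = matrix1
        self.matrix2 = matrix2
        self.mito_genes = set(mito_genes or ())
        self.network_edges = list(network_edges or ())
        self.ontology = ontology
        self.min_samples = min_samples

    def fit(self, method: str = "by", alpha: float = 0.05,
            use_prior: bool = False) -> "CodependencyResults":
        scores = pairwise_z(self.matrix1, self.matrix2, self.min_samples)
        scores, excluded = exclude_mito_pairs(scores, self.mito_genes)
        prior = None
        if use_prior:
            prior = {_pair_key(u, v) for u, v in self.network_edges}
        scores, summary = significant_pairs(scores, method, alpha, prior)
        if self.network_edges or self.ontology is not None:
            scores = explain_pairs(scores, self.network_edges, self.ontology)
        return CodependencyResults(scores=scores, excluded_mito=excluded,
                                   corrections=summary, alpha=alpha,
                                   method=method)


@dataclass
class CodependencyResults:
    scores: pd.DataFrame
    excluded_mito: pd.DataFrame
    corrections: dict
    alpha: float
    method: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.scores[self.scores["significant"]]

    def summary(self) -> str:
        lines = [
            "Codependency analysis",
            f"  pairs scored: {len(self.scores)} "
            f"(+{len(self.excluded_mito)} excluded mitochondrial pairs)",
            f"  correction: {self.method} at alpha={self.alpha}",
            f"  significant: {int(self.scores['significant'].sum())}",
        ]
        if "explanation" in self.scores.columns:
            sig = self.significant
            counts = sig["explanation"].value_counts().to_dict()
            lines.append(f"  explanations among significant: {counts}")
        return "\n".join(lines)
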