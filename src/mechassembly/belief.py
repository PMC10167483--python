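r"""Reliability (belief) models for assembled Statements.

The belief of a Statement is the estimated probability that it was
correctly extracted, given its per-source mention counts.  Three parametric
models are implemented, all of the form

    B(T) = 1 - prod_k f_k(N_k)

where N_k is the number of mentions from source k and f_k is the
probability that all of source k's mentions are jointly incorrect:

- two-parameter random/systematic error model ("rs" model, the default):
  f_k(N) = e_syst + e_rand^N (1 - e_syst)  for N >= 1 and 1 for N = 0.
  e_syst is the probability that the source extracts the mechanism wrongly
  in a way repeated across all of its mentions (e.g. a systematically
  misgrounded entity); e_rand is the per-mention independent error rate.
  A useful heuristic consequence: the error rate of 1-mention Statements
  is e_syst + (1 - e_syst) e_rand, and of high-mention Statements e_syst,
  so both parameters can be read off empirical precision curves.

- binomial: f_k(N) = e_rand^N, the e_syst = 0 special case; every mention
  is an independent Bernoulli trial.

- beta-binomial: the per-mention success probability is itself drawn from
  a Beta(alpha, beta), giving f_k(N) = Beta(alpha, N + beta)/Beta(alpha, beta).

Parameters are fitted to curated statement-level correct/incorrect labels
by maximizing the Bernoulli likelihood of B(T), either with an
affine-invariant ensemble MCMC sampler (emcee; uniform priors) or with a
deterministic bounded L-BFGS maximum-likelihood path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln

from .assembly import AssembledCorpus
from .statements import CurationRecord, Statement, resolve_curations

logger = logging.getLogger(__name__)

__all__ = [
    "belief_simple",
    "belief_multisource",
    "belief_with_refinements",
    "statement_correct",
    "neg_log_likelihood",
    "BeliefModel",
    "BeliefResults",
    "encode_features",
    "feature_matrix",
    "train_and_evaluate",
    "DEFAULT_DB_PARAMS",
]

MODELS = ("rs", "binomial", "beta_binomial")

#: Default error profile for curated-database sources when no fit is
#: available: databases are treated as high-reliability sources.
DEFAULT_DB_PARAMS = {"e_syst": 0.01, "e_rand": 0.05}


def belief_simple(n: int, e_syst: float, e_rand: float) -> float:
    """Single-source two-parameter belief, B = 1 - (e_syst + e_rand^n (1 - e_syst)).

    Lies in [0, 1 - e_syst) and increases strictly in n while e_rand < 1,
    approaching 1 - e_syst asymptotically.
    """
    if n < 1:
        raise ValueError("n must be >= 1; use belief_multisource for "
                         "statements with zero counts from a source")
    return 1.0 - (e_syst + e_rand ** n * (1.0 - e_syst))


def _source_factor(n: np.ndarray, model: str, p1: np.ndarray,
                   p2: Optional[np.ndarray]) -> np.ndarray:
    """Joint-error factor f(N) per source; f(0) = 1 in every model."""
    n = np.asarray(n, dtype=float)
    if model == "binomial":
        return p1 ** n
    if model == "rs":
        active = np.minimum(1.0, n)  # 0 when the source contributes nothing
        return p1 * active + p2 ** n * (1.0 - p1 * active)
    if model == "beta_binomial":
        return np.exp(betaln(p1, n + p2) - betaln(p1, p2))
    raise ValueError(f"unknown belief model {model!r}")


def belief_multisource(counts: Mapping[str, int],
                       params: Mapping[str, Mapping[str, float]],
                       model: str = "rs",
                       default_params: Optional[Mapping[str, float]] = None,
                       ) -> float:
    """Belief from per-source mention counts, B = 1 - prod_k f_k(N_k).

    ``params`` maps each source to its parameter dict ({"e_syst", "e_rand"}
    for the rs model, {"e_rand"} for binomial, {"alpha", "beta"} for
    beta-binomial).  Sources with zero counts contribute a factor of 1.
    An unknown source with a positive count uses ``default_params`` if
    given, otherwise raises naming the source.
    """
    log_factor = 0.0
    for source, n in counts.items():
        if n == 0:
            continue
        p = params.get(source, default_params)
        if p is None:
            raise KeyError(f"no belief parameters for source {source!r} "
                           "and no default source profile configured")
        if model == "binomial":
            f = _source_factor(n, model, np.float64(p["e_rand"]), None)
        elif model == "rs":
            f = _source_factor(n, model, np.float64(p["e_syst"]),
                               np.float64(p["e_rand"]))
        else:
            f = _source_factor(n, model, np.float64(p["alpha"]),
                               np.float64(p["beta"]))
        log_factor += np.log(np.maximum(f, 1e-300))
    return float(1.0 - np.exp(log_factor))


def belief_with_refinements(corpus: AssembledCorpus,
                            params: Mapping[str, Mapping[str, float]],
                            model: str = "rs",
                            default_params: Optional[Mapping[str, float]] =
                            DEFAULT_DB_PARAMS,
                            ) -> dict[str, float]:
    """Per-statement beliefs computed on refinement-extended evidence counts.

    Evidence flows from specific Statements to the generic ones they
    refine, so the belief of the most specific Statements depends only on
    their direct support, while generic Statements accumulate support from
    every refining variant.
    """
    out = {}
    for key in corpus.statements:
        counts = corpus.evidence_counts(key).extended
        out[key] = belief_multisource(counts, params, model, default_params)
    return out


def statement_correct(labels: Iterable[str]) -> bool:
    """Statement-level correctness from per-evidence labels.

    A Statement is correct if supported by at least one correctly
    extracted mention; with incomplete curation, all-curated-incorrect
    implies overall incorrectness.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no curation labels supplied")
    return any(lab == "correct" for lab in labels)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def _beliefs_from_matrix(counts: np.ndarray, theta: np.ndarray,
                         model: str) -> np.ndarray:
    """Vectorized B(T) for a (n_statements, n_sources) count matrix."""
    n_sources = counts.shape[1]
    if model == "binomial":
        p1, p2 = theta[:n_sources], None
    else:
        p1, p2 = theta[:n_sources], theta[n_sources:]
    log_f = np.zeros(counts.shape[0])
    for k in range(n_sources):
        f = _source_factor(counts[:, k], model, p1[k],
                           None if p2 is None else p2[k])
        log_f += np.log(np.maximum(f, 1e-300))
    return 1.0 - np.exp(log_f)


def neg_log_likelihood(theta: np.ndarray, counts: np.ndarray,
                       labels: np.ndarray, model: str = "rs",
                       epsilon: float = 1e-6) -> float:
    """Statement-level Bernoulli negative log-likelihood.

    -sum_i [y_i log B_i + (1 - y_i) log(1 - B_i)], with beliefs clamped
    into [epsilon, 1 - epsilon] so that boundary parameter values with
    contradicting labels stay finite (clamping is logged at debug level).
    """
    b = _beliefs_from_matrix(counts, np.asarray(theta, dtype=float), model)
    clipped = np.clip(b, epsilon, 1.0 - epsilon)
    if np.any(clipped != b):
        logger.debug("beliefs clamped to [%g, %g] in likelihood", epsilon,
                     1 - epsilon)
    y = np.asarray(labels, dtype=float)
    # piecewise to avoid 0 * log(0) at the (unclamped) boundary
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.where(y > 0, y * np.log(clipped), 0.0)
        neg = np.where(y < 1, (1 - y) * np.log1p(-clipped), 0.0)
    return float(-np.sum(pos + neg))


@dataclass
class BeliefResults:
    """Fitted belief-model parameters with uncertainty and diagnostics."""

    model: str
    sources: tuple[str, ...]
    params: dict[str, dict[str, float]]
    nll: float
    method: str
    param_sd: Optional[dict[str, dict[str, float]]] = None
    samples: Optional[np.ndarray] = None  # flattened posterior draws
    n_obs: int = 0

    def belief(self, counts: Mapping[str, int],
               default_params: Optional[Mapping[str, float]] = None) -> float:
        return belief_multisource(counts, self.params, self.model,
                                  default_params)

    def params_table(self) -> pd.DataFrame:
        rows = []
        for src in self.sources:
            for name, value in self.params[src].items():
                sd = (self.param_sd or {}).get(src, {}).get(name, np.nan)
                rows.append({"source": src, "parameter": name,
                             "estimate": value, "sd": sd})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Belief model results ({self.model}, fit by {self.method})",
            f"  observations: {self.n_obs}",
            f"  -log likelihood at estimate: {self.nll:.4f}",
            self.params_table().to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {"model": self.model, "params": self.params, "nll": self.nll,
                "method": self.method}


_PARAM_NAMES = {
    "rs": ("e_syst", "e_rand"),
    "binomial": ("e_rand",),
    "beta_binomial": ("alpha", "beta"),
}

# alpha/beta sample on a log10 scale with a log-uniform prior on [1e-2, 1e2];
# error rates use a uniform prior on [0, 1].
_LOG_BOUNDS = (-2.0, 2.0)


class BeliefModel:
    """Parametric Statement-reliability model, fitted to curated labels.

    Parameters
    ----------
    counts :
        (n_statements, n_sources) array of per-source mention counts, or a
        DataFrame whose columns name the sources.
    labels :
        Boolean (or 0/1) statement-level correctness labels.
    model :
        "rs" (two-parameter random+systematic, default), "binomial" or
        "beta_binomial".
    """

    def __init__(self, counts, labels, sources: Optional[Sequence[str]] = None,
                 model: str = "rs", epsilon: float = 1e-6):
        if model not in MODELS:
            raise ValueError(f"unknown belief model {model!r}")
        if isinstance(counts, pd.DataFrame):
            sources = tuple(counts.columns)
            counts = counts.to_numpy()
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        self.labels = np.asarray(labels, dtype=float)
        if self.counts.shape[0] != self.labels.shape[0]:
            raise ValueError("counts and labels differ in length")
        self.sources = (tuple(sources) if sources is not None else
                        tuple(f"source_{k}"
                              for k in range(self.counts.shape[1])))
        self.model = model
        self.epsilon = epsilon
        if self.labels.min() == self.labels.max():
            warnings.warn(
                "degenerate curation data (all labels identical); parameter "
                "estimates will sit on the boundary", stacklevel=2)

    @classmethod
    def from_curations(cls, corpus: AssembledCorpus,
                       curations: Iterable[CurationRecord],
                       sources: Optional[Sequence[str]] = None,
                       model: str = "rs", scope: str = "direct",
                       ) -> "BeliefModel":
        """Build the design matrix from an assembled corpus and curations.

        Statement labels follow the at-least-one-correct rule over the
        (conflict-resolved) evidence labels; counts are the corpus's
        direct or refinement-extended per-source counts.
        """
        resolved = resolve_curations(curations)
        by_stmt: dict[str, list[str]] = {}
        for (stmt_key, _), label in resolved.items():
            by_stmt.setdefault(stmt_key, []).append(label)
        keys = [k for k in by_stmt if k in corpus.statements]
        if sources is None:
            seen: set[str] = set()
            for k in keys:
                seen.update(getattr(corpus.evidence_counts(k), scope))
            sources = tuple(sorted(seen))
        counts = np.zeros((len(keys), len(sources)))
        labels = np.zeros(len(keys))
        for i, k in enumerate(keys):
            src_counts = getattr(corpus.evidence_counts(k), scope)
            for j, s in enumerate(sources):
                counts[i, j] = src_counts.get(s, 0)
            labels[i] = statement_correct(by_stmt[k])
        return cls(counts, labels, sources=sources, model=model)

    # -- parameter vector layout -------------------------------------------

    @property
    def n_params(self) -> int:
        return len(_PARAM_NAMES[self.model]) * len(self.sources)

    def _theta_natural(self, theta: np.ndarray) -> np.ndarray:
        """Map the sampling-scale vector to natural parameters."""
        if self.model == "beta_binomial":
            return 10.0 ** np.asarray(theta, dtype=float)
        return np.asarray(theta, dtype=float)

    def _in_support(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        if self.model == "beta_binomial":
            return bool(np.all((theta >= _LOG_BOUNDS[0])
                               & (theta <= _LOG_BOUNDS[1])))
        return bool(np.all((theta >= 0.0) & (theta <= 1.0)))

    def nll(self, theta: np.ndarray) -> float:
        return neg_log_likelihood(self._theta_natural(theta), self.counts,
                                  self.labels, self.model, self.epsilon)

    def log_prob(self, theta: np.ndarray) -> float:
        """Log posterior under uniform (or log-uniform) priors."""
        if not self._in_support(theta):
            return -np.inf
        return -self.nll(theta)

    def _pack_params(self, theta_nat: np.ndarray) -> dict:
        names = _PARAM_NAMES[self.model]
        out = {}
        for i, src in enumerate(self.sources):
            out[src] = {name: float(theta_nat[j * len(self.sources) + i])
                        for j, name in enumerate(names)}
        return out

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "mcmc", seed: Optional[int] = None,
            nwalkers: int = 100, nburn: int = 100, nsteps: int = 100,
            ) -> BeliefResults:
        """Fit parameters; ``method`` is "mcmc" (default) or "mle".

        MCMC runs an affine-invariant ensemble sampler (100 walkers, 100
        burn-in steps, 100 sampling steps by default) over the prior
        support; the point estimate is the maximum-posterior sample, and
        parameter uncertainty is the posterior standard deviation.  The
        deterministic "mle" path runs bounded L-BFGS from multiple starts
        and reports no sampling uncertainty.
        """
        if method == "mle":
            return self.fit_mle(seed=seed)
        import emcee

        rng = np.random.default_rng(seed)
        ndim = self.n_params
        lo, hi = ((_LOG_BOUNDS if self.model == "beta_binomial"
                   else (0.0, 1.0)))
        p0 = rng.uniform(lo, hi, size=(nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, self.log_prob)
        # pin the sampler's internal randomness to the same seed
        sampler._random = np.random.RandomState(
            None if seed is None else seed % (2 ** 31))
        state = sampler.run_mcmc(p0, nburn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, nsteps, progress=False)
        chain = sampler.get_chain(flat=True)
        log_probs = sampler.get_log_prob(flat=True)
        best = chain[int(np.argmax(log_probs))]
        nat_chain = self._theta_natural(chain)
        theta_nat = self._theta_natural(best)
        sd = nat_chain.std(axis=0)
        return BeliefResults(
            model=self.model, sources=self.sources,
            params=self._pack_params(theta_nat),
            param_sd=self._pack_params(sd),
            nll=self.nll(best), method="mcmc", samples=nat_chain,
            n_obs=len(self.labels))

    def fit_mle(self, seed: Optional[int] = None,
                n_starts: int = 8) -> BeliefResults:
        """Deterministic maximum likelihood via bounded L-BFGS multi-start."""
        rng = np.random.default_rng(0 if seed is None else seed)
        lo, hi = ((_LOG_BOUNDS if self.model == "beta_binomial"
                   else (0.0, 1.0)))
        bounds = [(lo, hi)] * self.n_params
        best_res = None
        starts = [np.full(self.n_params, (lo + hi) / 2.0)]
        starts += [rng.uniform(lo, hi, self.n_params)
                   for _ in range(n_starts - 1)]
        for x0 in starts:
            res = minimize(self.nll, x0, method="L-BFGS-B", bounds=bounds)
            if best_res is None or res.fun < best_res.fun:
                best_res = res
        theta_nat = self._theta_natural(best_res.x)
        return BeliefResults(
            model=self.model, sources=self.sources,
            params=self._pack_params(theta_nat), nll=float(best_res.fun),
            method="mle", n_obs=len(self.labels))


# ---------------------------------------------------------------------------
# Feature encoding and machine-learned reliability models
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    sources: tuple[str, ...] = ()
    include_extended: bool = False
    stmt_types: tuple[str, ...] = ()
    keyword: str = "promoter"


def encode_features(stmt_key: str, corpus: AssembledCorpus,
                    config: FeatureConfig) -> dict[str, float]:
    """Deterministic feature vector for one Statement.

    Columns: per-source direct mention counts; per-source refinement-
    extended counts (separate columns, only when enabled — they never
    overwrite the direct ones); unique supporting publications; one-hot
    statement type; mean evidence text length in whitespace tokens; and
    the frequency of the "promoter" keyword across mention texts (a known
    marker of promoter-binding sentences mis-extracted as interactions).
    """
    stmt = corpus.statements[stmt_key]
    sec = corpus.evidence_counts(stmt_key)
    feats: dict[str, float] = {}
    for src in config.sources:
        feats[f"n_{src}"] = float(sec.direct.get(src, 0))
    if config.include_extended:
        for src in config.sources:
            feats[f"n_ext_{src}"] = float(sec.extended.get(src, 0))
    feats["n_pmids"] = float(sec.direct_pmids)
    if config.include_extended:
        feats["n_pmids_ext"] = float(sec.extended_pmids)
    for typ in config.stmt_types:
        feats[f"type_{typ}"] = float(stmt.stmt_type == typ)
    texts = [ev.text for ev in stmt.evidence if ev.text]
    if texts:
        feats["mean_text_len"] = float(np.mean([len(t.split())
                                                for t in texts]))
        feats["keyword_freq"] = float(
            sum(config.keyword in t for t in texts) / len(texts))
    else:
        feats["mean_text_len"] = 0.0
        feats["keyword_freq"] = 0.0
    return feats


def feature_matrix(corpus: AssembledCorpus,
                   keys: Optional[Sequence[str]] = None,
                   config: Optional[FeatureConfig] = None) -> pd.DataFrame:
    """Feature DataFrame (fixed column order) for a set of Statements."""
    keys = list(keys if keys is not None else corpus.statements)
    if config is None:
        sources = sorted({src for k in keys
                          for src in corpus.evidence_counts(k).direct})
        types = sorted({corpus.statements[k].stmt_type for k in keys})
        config = FeatureConfig(sources=tuple(sources),
                               stmt_types=tuple(types))
    rows = [encode_features(k, corpus, config) for k in keys]
    return pd.DataFrame(rows, index=keys)


def _make_classifier(model_spec: str, seed: Optional[int], **overrides):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import FunctionTransformer, StandardScaler
    from sklearn.svm import SVC

    if model_spec == "logistic":
        # log-transformed mention counts
        return make_pipeline(
            FunctionTransformer(np.log1p),
            LogisticRegression(max_iter=1000, random_state=seed))
    if model_spec == "knn":
        return KNeighborsClassifier(**overrides)
    if model_spec == "svc":
        return make_pipeline(StandardScaler(),
                             SVC(probability=True, random_state=seed,
                                 **overrides))
    if model_spec == "random_forest":
        params = {"n_estimators": 2000, "max_depth": 13}
        params.update(overrides)
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model_spec {model_spec!r}")


def train_and_evaluate(features, labels, model_spec: str = "random_forest",
                       folds: int = 10, seed: Optional[int] = None,
                       calibrate: bool = False, **overrides) -> dict:
    """Stratified k-fold cross-validated AUPRC for a reliability classifier.

    Returns mean AUPRC and per-fold values; folds whose training or test
    split is single-class are skipped with a warning.  With ``calibrate``
    the classifier is wrapped in isotonic probability calibration (useful
    when the predicted probabilities, not just the ranking, are consumed
    downstream as belief scores).
    """
    from sklearn.metrics import average_precision_score
    from sklearn.model_selection import StratifiedKFold

    X = (features.to_numpy() if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurpcs = []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            warnings.warn("skipping single-class fold", stacklevel=2)
            continue
        clf = _make_classifier(model_spec, seed, **overrides)
        if calibrate:
            from sklearn.calibration import CalibratedClassifierCV
            clf = CalibratedClassifierCV(clf, method="isotonic", cv=3)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        aurpcs.append(float(average_precision_score(y[test_idx], scores)))
    return {"model": model_spec,
            "mean_auprc": float(np.mean(aurpcs)) if aurpcs else np.nan,
            "fold_auprc": aurpcs}
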