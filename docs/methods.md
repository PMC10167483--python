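# Methods

## The assembly problem

Mechanistic findings about molecular biology — "MAP2K1 phosphorylates
MAPK1 on T185", "TP53 binds MDM2" — are scattered across the literature
and across curated pathway databases, described at inconsistent levels of
detail and with inconsistent entity identifiers.  Machine reading systems
can extract such assertions at scale, but their output is redundant
(many sentences describe the same mechanism), fragmentary (the same
mechanism appears with and without sites, with gene-level and
family-level participants), and noisy (a substantial fraction of
extractions are wrong).  `mechassembly` implements the full loop that
turns such raw extractions into a usable knowledge base: normalization
and filtering, deduplication, organization into a refinement hierarchy,
probabilistic reliability ("belief") scoring, and two downstream
analyses (comparison against a curated interaction reference, and
explanation of gene codependencies with the assembled network as a
prior).

## Statements, equivalence, refinement

A Statement is a typed assertion with role-ordered Agent slots; Agents
carry multi-namespace groundings plus molecular state (modifications,
mutations, activity, bound partners, location).  Duplicates are detected
with a canonical *equivalence key* covering the statement type, each
agent's canonical grounding (chosen under a configurable namespace
priority, default FPLX > HGNC > UP > CHEBI > GO > MESH, name fallback)
and full state, and remaining arguments such as residue and position.
The key is an explicit canonical string rather than a language hash so
it is stable across runs and platforms.  Complex membership is
unordered; an absent agent slot (the unknown enzyme in "CREB1 is
phosphorylated") is an explicit token in the key.

Statement `a` *refines* statement `b` when both have the same type,
every element of `a` equals or specializes the corresponding element of
`b`, at least one strictly specializes, and no element goes the other
way.  Entity specialization follows the ontology's directed `isa` and
`partof` edges (both by default, configurable); states specialize by
carrying strictly more information (an extra modification, an explicit
site, an extra bound partner).  Activity and location have no internal
hierarchy here: they compare by equality or presence-vs-absence.  Bound
conditions recurse one level through the entity hierarchy (bound-to-gene
refines bound-to-family); this is an interpretation where the underlying
procedure is silent.

The refinement graph is built from a candidate index keyed by
(type, slot, canonical-or-ancestor id), so only statements with
compatible entities in every slot are compared; unordered (Complex)
statements are compared within their type group via backtracking member
matching.  The construction is checked against a brute-force all-pairs
oracle in the tests.  *Extended evidence* E'(T) is the union of a
statement's own evidence with the extended evidence of everything
refining it, deduplicated by the evidence identity key
(source, publication, text, record id) — identical sentences read by
different systems stay distinct, matching multi-reader accounting.

## Reliability models

For a statement with N_k mentions from source k, all models take the
form B = 1 − ∏_k f_k(N_k), with f_k(0) = 1:

| model | f_k(N) | parameters (per source) |
|---|---|---|
| two-parameter ("rs", default) | e_syst + e_rand^N (1 − e_syst) | e_syst, e_rand ∈ [0,1] |
| binomial | e_rand^N | e_rand |
| beta-binomial | B(α, N+β)/B(α, β) | α, β > 0 |

`e_syst` is the probability the source extracts the mechanism wrongly in
a way repeated across all its mentions (e.g. a systematically
misgrounded synonym); `e_rand` is the independent per-mention error
rate.  Useful consequences: one-mention statements have error rate
e_syst + (1 − e_syst) e_rand, high-mention statements plateau at e_syst,
so both parameters can be read off empirical precision curves.  The
binomial model is the e_syst = 0 special case; the beta-binomial model
draws the per-mention success probability from a Beta distribution.
Unknown sources fall back to a configurable default profile
(e_syst = 0.01, e_rand = 0.05), treating curated databases as
high-reliability sources.

Fitting maximizes the statement-level Bernoulli likelihood of B against
curated correct/incorrect labels (a statement is correct when at least
one mention supports it correctly; all-curated-incorrect implies
incorrect).  Beliefs are clamped into [ε, 1−ε] (ε = 10⁻⁶, configurable)
so boundary parameters with contradicting labels stay finite.  Two
fitting paths are provided: an affine-invariant ensemble MCMC sampler
(emcee; 100 walkers, 100 burn-in + 100 sampling steps by default;
uniform priors on error rates, log-uniform on [10⁻², 10²] for α and β;
point estimate = maximum-posterior sample, uncertainty = posterior
standard deviation), and a deterministic bounded L-BFGS multi-start
maximum-likelihood path for reproducibility without sampling noise.
Whether likelihoods should be statement-level or mention-level is
genuinely open; this package is statement-level throughout.

With ~2,000 curated statements under a power-law count distribution the
sampling standard error of the estimates is about 0.03; recovery claims
in the tests are stated accordingly (a ±0.05 window is ~1.7σ per seed).

Machine-learned reliability models (logistic regression on
log-transformed counts, k-NN, SVC, random forest with 2,000 trees and
depth 13) consume a deterministic feature vector: per-source direct
mention counts, optional refinement-extended counts in separate columns,
unique supporting publications, one-hot statement type, mean mention
length in whitespace tokens, and the frequency of the token "promoter"
(a marker of promoter-binding sentences mis-read as interactions).
Evaluation is stratified 10-fold cross-validated AUPRC.

## Power-law machinery

Mention counts are fit with the exact discrete power-law MLE — the
maximizer of the Hurwitz-zeta likelihood, initialized at the closed form
α ≈ 1 + n [Σ ln(x_i/(x_min − ½))]⁻¹, which is itself biased at small
x_min — with a standard error from the observed Fisher information.  A
second estimate comes from linear regression of the log complement-CDF
(exponent = 1 − slope); all observed points enter the regression and its
r² is reported as-is, so this estimate is noticeably noisier in the
tail than the MLE (spread ~0.07 at n = 10⁵).  Vuong-style normalized
log-likelihood-ratio tests compare the power law against a geometric
(discrete exponential) alternative and a discrete positive lognormal
normalized over the observed support.  x_min defaults to 1, with an
optional Kolmogorov–Smirnov scan.

## Codependency analysis

Gene pairs are scored across two replicate perturbation screens:
pairwise-complete Pearson correlation in each dataset, Fisher-transformed
into a signed z-score z = atanh(r)·√(n−3) (the standard variance-
stabilizing choice; the sign of r is preserved), combined across
datasets by Stouffer's method z = (z₁+z₂)/√2, with a two-sided normal
p-value.  Pairs with fewer than 4 common samples are skipped.  Pairs
where *both* genes are mitochondrial are excluded before testing (a
known screening artifact, considered explained a priori); pairs with one
mitochondrial gene are retained — this is the narrower reading of an
ambiguous exclusion rule, and it is configurable.  Multiple-testing
control offers Bonferroni, Benjamini–Hochberg and Benjamini–Yekutieli
(via statsmodels), optionally restricting the hypothesis family to pairs
present in an assembled network; the summary reports pairs significant
only under the prior.  Significant pairs are labeled with the most
specific available explanation, in priority order: `direct` (an edge
between the genes, either direction), `family_complex` (a shared
isa/partof parent), `parent_link` (an edge touching a gene's parent),
else `unexplained`; multi-step paths never count, since edge chains need
not compose causally.

For reference-interaction comparison, Complex-type pairs are binned by
belief (width 0.1); the expected number of correct-but-uncurated
interactions is the sum of beliefs over pairs absent from the reference,
which is unbiased exactly when beliefs are calibrated on that uncurated
pool; a curation-yield curve orders uncurated pairs by descending
belief.

## What the synthetic generator emulates — and what it does not

The generator draws a set of true mechanisms over a toy gene/family
ontology (default 20 families × 3 members, two namespaces with xref
aliases), gives each mechanism a discrete power-law mention count
(default exponent 2.38, the corpus-scale value), and assigns mentions to
sources (default five, with distinct error profiles; the reference
source is e_syst = 0.10, e_rand = 0.35, the condition used in the
recovery experiments).  Systematic errors are a per-(mechanism, source)
coin flip that corrupts all of that source's mentions identically into a
fixed variant statement.  Random errors are per-mention: the mention
stays attached to the mechanism's own statement but mis-supports it, so
the per-statement correctness law is exactly the two-parameter model.
Mentions are independently degraded in specificity (site dropped with
probability 0.3, entity generalized to its family with probability 0.2)
so that generic and specific variants coexist and the refinement graph
is nontrivial.  Texts are token-count placeholders with a "promoter"
keyword planted at different rates in correct and incorrect mentions.
Everything is deterministic given the config seed.

Real corpora differ in ways the generator does not emulate: real reader
errors are correlated across systems; entity ambiguity is contextual
rather than tabular; mention counts, statement types and site usage are
not independent; and real curation is incomplete and biased toward
high-mention statements.  Passing tests therefore demonstrate the
correctness and internal consistency of the machinery, not reader-level
performance on literature.

Two deliberate consequences of the degradation mechanism are worth
knowing.  First, splitting a mechanism's mentions across specificity
variants thins per-statement counts, and pooled generic statements mix
mechanisms, so belief-model parameters fitted on a heavily degraded
corpus drift from the generating values; recovery experiments run with
degradation off.  Second, systematic-error variants always carry
single-source profiles, so single-source statements are empirically
worse than a per-source independence model predicts — the same
source-overlap effect seen in real multi-reader corpora.  Fitting
absorbs most of this (measured worst belief-bin calibration error
~0.04 at ~5,500 statements); raw random-forest vote probabilities are
mid-range compressed and are *not* bin-calibrated within ±0.05 — use
the `calibrate=True` isotonic wrapper when probabilities rather than
rankings are consumed.

## Numerical choices and degenerate inputs

- Equivalence keys and all generator output are deterministic;
  simulation output is byte-identical across runs at a fixed seed.
- Belief factors are computed in log space and floored at 10⁻³⁰⁰;
  likelihood clamping ε = 10⁻⁶.
- MCMC walkers initialize uniformly over the prior support; the emcee
  sampler's internal randomness is pinned to the same seed.
- All-equal mention counts make the power-law exponent undefined and
  raise; a constant per-source count vector makes a correlation
  undefined and reports NaN.
- Curation conflicts between curators resolve to "correct" if any
  curator said correct (consistent with the statement-level rule) and
  are logged.
- Sites absent from the site map are treated as valid (permissive
  default, logged); mapped sites overwrite residue/position; invalid
  sites remove the statement.
- Degenerate (single-class) curation data triggers a warning and
  boundary estimates; single-class cross-validation folds are skipped
  with a warning.

## Known limitations

- Activity types and cellular locations refine only by
  presence/absence, not through their own ontologies.
- The multi-source belief model assumes independence between sources;
  fitting all five synthetic sources jointly (10 parameters) is weakly
  identified at a few thousand curated statements.
- The grounding-override table is the only disambiguation mechanism; a
  context-based predictor can be plugged in by subclassing
  `GroundingMap`.
- The site map is a hand-authorable verdict table, not a reference-
  sequence validator.
- Problem sizes in the test suite (corpora of a few thousand unique
  statements, 10⁵ power-law samples, 40-gene dependency matrices) were
  chosen so the full suite exercises every claim at desk scale.
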