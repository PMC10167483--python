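# mechassembly

Assembly and reliability modeling of mechanistic knowledge extracted
from the biomedical literature and curated databases.

Machine reading systems and pathway databases both produce *Statements*
— typed assertions like `Phosphorylation(MAP2K1, MAPK1, T185)` or
`Complex(TP53, MDM2)` — but raw multi-source output is redundant,
fragmentary and noisy.  `mechassembly` is for computational biologists
and biocurators who want to turn that output into a non-redundant,
reliability-scored knowledge base:

- **normalize** entity groundings through an ontology graph
  (xref/isa/partof edges), apply override tables, map modification
  sites, and filter hypotheses, ungrounded or non-gene participants;
- **deduplicate** Statements by canonical equivalence keys and merge
  their supporting evidence;
- **organize** the unique Statements into a refinement hierarchy — a
  directed acyclic graph pointing from more specific to less specific
  assertions (gene vs. family, with vs. without a site) — and pool
  evidence along it;
- **score** each Statement with a belief model: the probability that it
  was correctly extracted given its per-source mention counts,

  `B(T) = 1 − ∏_k [ e_syst,k + e_rand,k^{N_k} (1 − e_syst,k) ]`,

  where `N_k` is the mention count from source *k*, `e_syst` its
  systematic and `e_rand` its per-mention random error rate (binomial
  and beta-binomial variants included; parameters fitted to curated
  labels by ensemble MCMC or deterministic maximum likelihood, and
  machine-learned classifiers available alongside);
- **analyze**: corpus statistics (power-law mention distributions,
  multi-source overlap, empirical precision), comparison of
  belief-scored interactions against a curated reference with an
  expected-curation-yield curve, and detection/explanation of gene
  codependencies across paired perturbation screens (Fisher z +
  Stouffer combination, FDR control with an optional network prior,
  direct / family-complex / parent-link explanations).

A synthetic-data module simulates the whole study design — true
mechanisms over a toy ontology, per-source systematic/random errors,
power-law mention counts, specificity degradation, planted codependent
gene pairs — so every stage is testable offline.

## Worked example

```python
from mechassembly import (SimulationConfig, simulate_corpus,
                          AssembledCorpus, BeliefModel)
from mechassembly.synthetic import ground_truth_curations
from mechassembly.statements import render_english

config = SimulationConfig(seed=1, n_mechanisms=500)
raw, truth = simulate_corpus(config)
print(f"raw mentions: {len(raw)}")

corpus = AssembledCorpus.assemble(raw, truth["ontology"])
print(f"unique statements: {len(corpus)}")
print(f"top-level (most specific): {len(corpus.top_level_keys())}")

key = max(corpus.statements,
          key=lambda k: len(corpus.statements[k].evidence))
stmt = corpus.statements[key]
print(f"best-supported: '{render_english(stmt)}' "
      f"with {len(stmt.evidence)} mentions")

curations = ground_truth_curations(corpus)
model = BeliefModel.from_curations(corpus, curations, model="rs")
results = model.fit(method="mcmc", seed=1)
print(results.summary())
print(f"belief of a 3-mention reader_a statement: "
      f"{results.belief({'reader_a': 3}):.3f}")
```

prints

```
raw mentions: 958
unique statements: 687
top-level (most specific): 538
best-supported: 'G1_2 inhibits G5_0' with 18 mentions
Belief model results (rs, fit by mcmc)
  observations: 687
  -log likelihood at estimate: 427.5302
  source parameter  estimate     sd
reader_a    e_syst    0.1751 0.1096
reader_a    e_rand    0.2872 0.1174
reader_b    e_syst    0.1985 0.1254
reader_b    e_rand    0.4173 0.1266
reader_c    e_syst    0.1953 0.1196
reader_c    e_rand    0.3262 0.1159
reader_d    e_syst    0.3453 0.0911
reader_d    e_rand    0.1380 0.0997
reader_e    e_syst    0.3329 0.0974
reader_e    e_rand    0.0653 0.1043
belief of a 3-mention reader_a statement: 0.805
```

958 raw per-mention extractions collapse to 687 unique Statements, of
which 538 are not refined by anything more specific.  The fitted
`e_syst`/`e_rand` columns are each source's systematic and per-mention
random error rates with posterior standard deviations (with only ~700
curated statements split over five sources the per-source posteriors
are wide).  A statement with three mentions from `reader_a` gets belief
0.805: three independent mentions make random error unlikely, leaving
mostly the source's systematic error.

There is also a thin CLI over the same library —
`mechassembly synth | assemble | stats | belief fit/score/eval | codep`
— operating on plain-text formats (Statement JSON, ontology TSV,
gene-effect CSV).

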