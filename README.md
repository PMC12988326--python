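# defensomics

A tested, reusable pipeline for surveying the antiviral **defensome** of
prokaryotic genomes, with an emphasis on the archaeal/bacterial comparison:

* a REBASE-style **restriction–modification (RM) system caller** that matches
  proteins to a reference catalogue by best-hit homology (identity ≥ 0.65,
  both-sided coverage ≥ 0.8), then applies gene-neighborhood architecture
  rules (±5 genes around each restriction nuclease) to type systems as
  I / II / III / IV / IIG;
* a **defensome aggregation layer** that merges RM calls with external
  defense-caller tables (Padloc-like CSV dialect), discards non-defense rows
  (DMS, VSPR), and builds per-genome system-count tables;
* the survey's **statistical battery**: Wilson score intervals, Firth
  bias-reduced logistic regression with phylum-vs-overall-mean contrasts and
  Benjamini–Hochberg FDR, completeness-adjusted prevalence extrapolation,
  Spearman/OLS/variance-partitioning genome-size analyses, OGT binning with
  Kruskal–Wallis + Dunn tests, negative-binomial GLMs and zero-truncated
  hurdle NB models with Nagelkerke pseudo-R²;
* a **synthetic-cohort generator** that plants RM operons at controlled
  sequence identity, emulates tool-output tables (including decoy rows), and
  simulates cohort metadata with known logistic/negative-binomial structure —
  so every stage can be scored against recorded ground truth.

## The model in brief

RM typing follows component architecture: Type I requires R, M and S
subunits in one neighborhood; Types II and III require R and M; Types IV and
IIG are single modules. Candidate components are best hits against the
catalogue (lowest e-value, then highest score, then smallest reference id),
purged of proteins claimed by non-RM systems from external callers. Anchors
(nucleases/modules) are scanned left-to-right and greedily consume their
nearest eligible components, so calls are disjoint and deterministic.

Prevalence of a system with `k` carriers among `n` genomes gets a Wilson
95% interval; phylum effects are modelled as `presence ~ phylum` under the
Jeffreys-penalized likelihood ℓ(β) + ½·log det I(β) (finite estimates under
separation) and contrasted against the unweighted grand mean on the logit
scale. Incompleteness bias is corrected by `presence ~ completeness +
domain` logistic fits evaluated at completeness = 1. Count responses use
NB2 regression, `Var = μ + μ²/θ`, with temperature effects reported as
percent change per 10 °C, `100·(e^{10β} − 1)`; zero-deflated responses use a
hurdle: logistic zero part plus zero-truncated NB on the positives.

## Worked example

```bash
defensomics run-all --seed 4 --out survey_out
```

simulates 60 genomes (30 archaeal, 30 bacterial) with planted RM operons at
identity 0.75, runs detection, aggregation and statistics, and writes plain
tables under `survey_out/`. On this run the log reports, per genome, lines
like

```
detect G0000: 17 genes, 5 assigned, 2 RM calls
...
aggregate: 79 calls -> cohort of 60 genomes
```

and `rm_calls.tsv` begins

```
genome_id  rm_type  anchor_gene_id  component_gene_ids
G0000      I        G0000|c1|5      G0000|c1|5;G0000|c1|6;G0000|c1|7
G0000      II      G0000|c1|14     G0000|c1|14;G0000|c1|15
```

— one row per called RM system with its anchor nuclease and consumed
components. `stats_report.json` carries the cohort-level summaries. On this
seed the archaeal OGT model reports `"percent_change_per_10C": 43.4`
(simulated truth: +35.7% per 10 °C, i.e. a coefficient of `ln(1.357)/10`
per °C; a 300-genome cohort estimates it with that much sampling spread —
the acceptance script repeats the fit at n = 5000, where it lands on
35.6), and the Kruskal–Wallis test across temperature bins is strongly
significant (`"ogt_kruskal_p": 7.3e-22`).

Every stage is also callable as a library function (`defensomics.homology`,
`defensomics.rm_detection`, `defensomics.aggregate`,
`defensomics.prevalence`, `defensomics.abundance`,
`defensomics.synthetic`).

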