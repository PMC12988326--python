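# Methods

## Scope and design

`defensomics` reconstructs a defensome survey as a pipeline of five stages —
homology assignment, RM-system calling, defensome aggregation, prevalence
statistics, abundance statistics — plus a synthetic-data layer that
generates every input with recorded ground truth. Real cohorts (GFF3 +
protein FASTA per genome, a reference FASTA of RM components, tabular
search output, Padloc-like call tables, a metadata TSV) plug into the same
stages; the simulator exists so the pipeline's behaviour can be *scored*,
not only run.

## Homology assignment

Queries are matched to catalogue entries either from a 12(+2)-column
BLAST-tab/MMseqs2 file or from internally computed global alignments
(BLOSUM62, affine gaps open 11 / extend 1, via Biopython's
`PairwiseAligner`). Identity is matches over alignment columns between the
first and last aligned pair (terminal gaps excluded), which approximates a
local search tool's identity on these global stand-ins; coverage is the
aligned span over each sequence's length. A hit survives at identity ≥ 0.65
and **both-sided** coverage ≥ 0.8 (the both-sided reading of a coverage
mode that constrains query and target alike). Per query, the best hit wins
by lowest e-value; the internal aligner produces no e-value (it would need
database-size calibration the pipeline never uses), so ranking falls back
to score, then to the lexicographically smallest reference id — making
assignment invariant to input order. Inside the pipeline a score-only pass
ranks all references per gene and only the winner is traced back; the
selected best hit is identical to tracing every pair.

## RM-system calling

Assignments claimed by an external *non-RM system* call are removed first.
Two row categories never disqualify: RM-named rows (the caller replaces
them) and DMS/VSPR rows — DMS labels individual DNA-modification proteins
(often RM methyltransferases themselves) and VSPR rows are not defense
systems, so neither constitutes membership in a competing system. Without
this reading, a modification-protein row landing on a true methyltransferase
would veto its own RM system.

Every assigned restriction nuclease (role R) or single-gene module (Types
IV/IIG) anchors a window of five genes upstream and five downstream on its
contig, truncated at contig ends; contigs are treated as linear (MAG
contigs are fragments; circularity is unknowable). Rules: Type I = type I R
with type I M *and* S in the window; Types II/III = matching R + M; Types
IV/IIG = the module alone. Components count only when their assigned type
matches the anchor's — a deliberate resolution of what happens when one
neighborhood satisfies several type rules. Anchors are processed
left-to-right and greedily consume the nearest eligible component (ties go
upstream), so component sets of distinct calls are disjoint and the caller
is deterministic; a module inside another anchor's window still forms its
own single-gene call, since modules are defined "alone". Per-genome RM
count = number of calls.

## Aggregation

DMS and VSPR rows are discarded from defensome counts (case-insensitive).
For genomes routed through the internal RM caller (by default the archaeal
half of a cohort), tool RM rows — recognized by an editable name-prefix
list, since tool dialects differ — are replaced by internal calls; all
non-RM rows pass through untouched. Cohort summaries count every occurrence
for abundance and count each system once per genome for prevalence. The
core defensome is the union of the top-k (default 20) most prevalent
systems per domain, ranked by prevalence with ties broken by total
occurrence count, then name. "Defenseless beyond the core" counts genomes
whose every called system is RM or CRISPR-Cas (or that have no calls).

## Prevalence statistics

* **Wilson intervals** via `statsmodels.proportion_confint`.
* **Firth bias-reduced logistic regression**: Newton iteration on the
  modified score `Xᵀ(y − p + h∘(½ − p))` with step-halving on the penalized
  log-likelihood; convergence at score norm < 1e-8 (or when the objective
  stalls at machine resolution with score norm < 1e-4), max 100 iterations;
  standard errors from the Fisher information at the optimum. Implemented in
  house — the estimator has no pre-installed Python implementation.
* **Phylum contrasts**: a cell-means Firth fit of `presence ~ phylum`
  (phyla with fewer than 10 genomes excluded); each phylum's logit-scale
  marginal mean is contrasted against the *unweighted* mean of phylum means
  (the conventional estimated-marginal-means behaviour; weighting is a
  genuinely open choice and unweighted was fixed here), tested by Wald z
  and adjusted by Benjamini–Hochberg within the model. Pooling the FDR
  across systems instead is exposed by adjusting the concatenated p-vector.
* **Completeness adjustment**: ordinary logistic `presence ~ completeness +
  domain`, predictions at completeness = 1, Wald intervals built on the
  logit scale and mapped through the inverse logit. Perfect separation
  raises an error directing the caller to the Firth routine; a cohort with
  constant completeness degenerates cleanly to per-domain prevalence.

## Abundance statistics

Counts are modelled as NB2 (`Var = μ + μ²/θ`, log link) by joint MLE of β
and θ (statsmodels' discrete NegativeBinomial; θ = 1/α), with a BFGS
restart on non-convergence. Temperature effects are reported as percent
change per 10 °C, `100·(e^{10β} − 1)`. Zero-deflated responses use a hurdle
model: logistic fit of the positive indicator plus a zero-truncated NB part
fitted on the positives only (each NB term divided by 1 − P(0); statsmodels'
truncated NB MLE), validated in tests against a direct Nelder-Mead
maximization of an independently written truncated likelihood. Explanatory
power is Nagelkerke's pseudo-R² (Cox–Snell scaled by its maximum) against
the intercept-only NB fit. Genome-size structure uses Spearman correlation
(mid-rank ties), OLS with a Wilcoxon rank-sum test on between-domain
residuals, and a two-block variance partition on **adjusted** R²
(`unique_a = R²ab − R²b`, etc.); components sum to one by construction and
small negative components are reported as-is, not clamped. OGT bins are
half-open — mesophilic below 50 °C, thermophilic [50, 80), hyperthermophilic
≥ 80 °C — resolving the ambiguity at exactly 50 °C in favour of
thermophilic; values below 25 °C fall in the mesophilic bin. Group
differences use tie-corrected Kruskal–Wallis plus Dunn's pairwise z with
Bonferroni (Dunn is implemented in house; no pre-installed package provides
it).

## Synthetic data

**Sequence level.** The reference catalogue covers all nine valid
(type, role) combinations — I-R/M/S, II-R/M, III-R/M, IV-module,
IIG-module — with uniform-random 20-letter sequences (lengths Poisson
around 150 residues). Planted operon components are catalogue copies
mutated to an exact positional identity (default 0.75, safely above the
0.65 threshold; the mutation count is rounded, so realized identity is
within 1/len of the target). Operons are contiguous by default with a knob
to intersperse up to two decoy genes; operon blocks are separated by at
least window+1 decoys so neighborhoods of distinct systems never overlap.
Genomes alternate between the two domains (two phyla each) and draw
size/OGT metadata from the cohort-level defaults. Incompleteness is
modelled as independent per-gene dropout — gene-level rather than
contig-level loss, matching the per-gene granularity of all downstream
rules (a modelling assumption; real assembly loss is spatially
correlated). Emulated tool tables contain one row per planted non-RM
system, DMS/VSPR decoy rows, and a deliberately weak RM channel (each RM
system reported with probability 0.5) so the merge policy is exercised.
One RNG stream per genome derives from (master seed, genome index), so
cohorts reproduce under any generation order.

**Cohort level.** Metadata emulates the survey's setting: archaeal genomes
log-normal around 1.8 Mb, bacterial around 3.8 Mb; archaeal completeness
lower on average (Beta-distributed on (0.5, 1]); archaeal OGT a
mesophile/thermophile/hyperthermophile mixture, bacterial OGT mostly
mesophilic. Total defense counts are drawn NB(μ, θ) with
log μ = intercept + β_OGT·OGT + β_logsize·log(size) + phylum offset; the
default β_OGT = ln(1.357)/10 encodes a +35.7% change per 10 °C and θ = 2 a
realistic overdispersion. Per-system presence is Bernoulli with
logit p = intercept + β_completeness·completeness + β_domain·[Bacteria].
Counts and presence are sampled from their respective *marginal* models —
the two substrates of the abundance and prevalence analyses — so the strict
additivity between per-system counts and totals holds on the aggregation
path (where it is tested), not in the direct cohort draw. All generating
coefficients are recorded in the simulation plan.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: nucleotide-level realism and codon usage,
HMM profile scores, CRISPR array structure, spatially correlated assembly
loss, phylogenetic autocorrelation between genomes, and real REBASE
sequence diversity (decoys are uniform-random, so the homology stage faces
a much easier discrimination problem than against real paralogs).

## Problem sizes and numerical choices

Validation cohorts are sized for a desk machine: 200 genomes for RM
recovery, n = 5000 per replicate for the count- and presence-model recovery
studies (30–100 replicates), 10 000 draws for interval coverage. NB θ is
reported from the MLE of α with a floor of 1e-8 on α; the hurdle count part
requires at least one zero and one positive count and refuses degenerate
inputs with directed errors. The end-to-end CLI is bit-reproducible for a
fixed config and seed (timestamps live only in logs), and every output
table ships with a sidecar JSON of the configuration used.

## Known limitations

Orphan methyltransferases (M without R) are out of scope by design, as are
recognition-sequence prediction and distinguishing RM enzymes from other
catalogue classes beyond the role labels. The single-best-hit policy
discards secondary matches that a profile-based method would keep. The
Firth contrast machinery assumes independent genomes; lineage structure
within a phylum is not corrected for.
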