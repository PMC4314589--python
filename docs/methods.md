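# Methods

## Overview

`cofunet` builds *cofunctional* gene networks: weighted graphs in which
an edge between two genes asserts they likely act in the same pathway
or biological process. The construction is a supervised benchmarking
scheme. Heterogeneous raw evidence of cofunctionality — literature
cocitation (CC), coexpression (CX), shared protein domains (DC), gene
neighborhood (GN), phylogenetic profiling (PG), and two classes of
protein–protein interaction data (HT, LC) — is calibrated against a
gold standard of annotation-sharing gene pairs, placed on a common
log-likelihood scale, and merged by a weighted sum that discounts
correlated evidence. The resulting network supports two
guilt-by-association tools: prioritizing new members of a pathway and
inferring functions for a gene from its neighbors.

## Gold standard

Positive pairs are pairs of genes that co-occur in at least one
eligible annotation term. Eligibility filters:

* GO biological-process terms restricted to experimental evidence codes
  (default whitelist `IDA`, `IGI`, `IMP`). The whitelist applies only to
  terms that declare evidence codes; pathway-database terms (EcoCyc /
  MetaCyc style) carry none and pass through.
* An explicit exclusion list of term ids, defaulting to the five
  largest transcription-regulation GO-BP terms (`GO:0006351`,
  `GO:0045892`, `GO:0006355`, `GO:0000160`, `GO:0045893`): with them the
  gold standard would be dominated by global transcription and the
  learned scores biased toward it. A generic `--max-term-size` style
  cutoff is deliberately not the default — the exclusion is a curated
  choice, not a size rule.
* Superpathway-flagged terms removed (a superpathway links genes of
  different constituent pathways, which would create between-pathway
  positives).

Negatives are **every remaining pair of annotated genes**:
`|neg| = C(n, 2) − |pos|` over the union universe of genes appearing in
at least one post-filter term. The negative set is quadratic, so it is
never materialized: the `GoldStandard` object answers membership and
count queries lazily (a `materialize=True` escape hatch exists for
small problems). Terms removed by filtering are treated as nonexistent
for both positives and negatives.

## Log-likelihood scoring (LLS)

For an evidence stratum E the score is

```
LLS = ln [ (P(L|E) / P(∼L|E)) / (P(L) / P(∼L)) ]
```

with P(L|E), P(∼L|E) the frequencies of gold positives and negatives
among pairs carrying the evidence and P(L), P(∼L) the gold-standard
base rates. LLS = 0 means the stratum is exactly as enriched as
background; positive values mean informative evidence.

Strata are formed by sorting an evidence set's gold-overlapping links
along the raw-score axis and cutting **equal-gold-count bins** (default
100 gold pairs per bin; the strongest bin absorbs the remainder).
Equal-count binning is robust to arbitrarily skewed raw-score
distributions, which equal-width bins are not. Each bin's counts get a
Haldane–Anscombe pseudocount (c = 0.5, configurable) so pure bins keep
finite scores. Every link then maps to its bin's LLS
(piecewise-constant); raw scores outside the modeled range clamp to the
nearest end bin and the clamps are counted and logged. An optional
isotonic (monotone non-decreasing, gold-count-weighted) smoothing of
the bin sequence is available behind a flag for callers who want a
monotone raw-score → LLS map.

**Evidence inclusion rule.** An evidence set is retained for
integration iff its maximum bin LLS is positive *and* the Spearman
correlation between bin rank and bin positive-fraction is positive with
permutation p < 0.05 (exhaustive permutation up to 6 bins, seeded
Monte Carlo with 2000 draws above). This operationalizes "keep only
data sets whose scores correlate with cofunctionality" — e.g. the
selection of informative coexpression series — as an explicit,
configurable test. Evidence with fewer than 10 gold positives of
overlap returns a `BenchmarkFailure` value (excluded, not an
exception).

## Weighted-sum integration (WS)

For one pair with per-evidence LLS values, let S0 ≥ S1 ≥ … ≥ Sn after
dropping values below the cutoff T:

```
WS = S0 + Σ_{i=1..n} Si / (D · i)
```

D ≥ 1 discounts secondary evidence (D = 1 is a plain sum — naïve-Bayes
style; D → ∞ keeps only the best single evidence). Choices made where
the formula leaves room:

* **T filters summands before ranking** — a sub-threshold value neither
  contributes nor shifts the ranks of surviving values.
* Ties in LLS are broken by evidence-code lexicographic order, so
  integration is deterministic.
* D < 1 is rejected at construction (it would weight secondary evidence
  above the primary).
* The same machinery merges link sets *within* a data type (many
  coexpression series → one CX network; Archaea + Bacteria profile
  networks → one PG network; the two GN variants → one GN network),
  each merge with its own (D, T).
* Two input networks sharing an evidence code with overlapping pairs
  are refused: that situation means a within-type merge was skipped.

`tune_ws` selects (D, T) on a grid by a seeded split of the gold
positives: half is held out, and each candidate parameter pair is
scored by the trapezoid area under the integrated network's cumulative
accuracy-vs-coverage curve with "accurate" meaning membership in the
held-out half. Ties keep the first grid entry.

## Evidence scorers

* **CC** — upper-tail hypergeometric probability of the observed number
  of co-mentioning articles (N articles total, m with gene a, n with
  gene b, k with both: p = P(X ≥ k)); raw score −log10 p.
* **CX** — Pearson correlation across the samples of one series; a
  series must have more than 8 samples, and a pair needs ≥ 9 shared
  non-missing samples and nonzero variance to be scored.
* **DC** — weighted mutual information over shared domains, concretely
  Σ −log2(f_d) over the shared domains (rarity in bits, f_d = carriers
  / proteome size): rarer shared domains indicate more specific
  pathways. The proteome size is a fixed constant of the table, not the
  number of annotated entries.
* **PG** — mutual information between two genes' similarity profiles
  across genomes after equal-frequency discretization (default k = 4
  bins; boundary values join the upper bin so heavily tied
  presence/absence profiles still split). Computed per taxonomic domain
  (Archaea-only and Bacteria-only columns) when a partition is given,
  producing two link sets merged downstream by WS. Profile values are
  taken as given; the recommended provenance is self-hit-normalized
  −log10 E-values from a sequence search, but any non-negative
  similarity works.
* **GN** — two complementary scores. Distance-based: negated median
  intergenic distance (bp) between the orthologs over co-present
  genomes, with different-replicon occurrences charged a cap (default
  10⁶ bp). Probability-based: per genome the orthologs are neighbors
  iff within W gene slots (default W = 1) on one replicon, with null
  probability q = min(1, 2W/(n_slots − 1)); the score is −log10 of the
  exact Poisson-binomial upper tail of the observed neighbor-genome
  count (reduces to a plain binomial tail when all genomes have equal
  q). Both require co-presence in ≥ 3 genomes by default.
* **HT / LC** — binary interaction sets score 1 per link and are kept
  separate per source, so each source is benchmarked to its own
  single-bin LLS before WS merging.

All scorers return "no score" (`None`) rather than a default when a
pair cannot be evaluated, and all are invariant under a consistent
relabeling of genes.

## Assessment

`phenotypes_from_scores` thresholds a genes × conditions growth-score
matrix at −4 (strictly below; a score of exactly −4 is not a defect).

The **cumulative accuracy-vs-coverage curve** sorts links by descending
weight (ties by pair order) and, per successive bin of links (default
1000), reports accuracy = % of *evaluable* cumulated pairs (both
endpoints phenotype-annotated) sharing ≥ 1 phenotype, against coverage
= % of the coding genome in the cumulated node set. Restricting the
denominator to evaluable pairs keeps the measure independent of the
phenotype panel's gene coverage; a prefix with no evaluable pair
reports a missing accuracy rather than 0.

**Leave-one-out AUC**: each member of a phenotype gene set is held out
and every candidate scored by the summed edge weight to the remaining
members (0 if unconnected); the held-out member's Mann–Whitney AUC with
midrank ties is averaged over members. The candidate universe defaults
to all network genes; the remaining members are excluded from the
negatives since they are known positives of the same phenotype (both
configurable). Paired AUC lists from two networks are compared with the
two-sided Wilcoxon signed-rank test, zero differences dropped; networks
of unequal size should be truncated to a common top-k first
(`truncate_network`).

## Prediction tools

*Find new members*: query connectivity is summarized by the LOO AUC
over the query genes found in the network (missing queries are
reported, not silently dropped); candidates are ranked by summed edge
LLS to the query genes, ties broken by number of supporting query
edges, then gene id. *Infer functions*: candidate terms (annotation
evidence whitelist default `IDA, IMP, IGI, IPI, IEP, TAS`) score the
summed edge LLS from the gene to its term-annotated neighbors; ties
prefer the smaller (more specific) term, then term id; top 30 returned.
A hypergeometric-enrichment scorer is available behind the same
contract for users who prefer a size-corrected statistic.

## Synthetic data

The generators produce every input class in the package's own file
formats, from one integer seed; per-stage generators are derived by
hashing the stage name so adding a stage never perturbs another's
draws. Outputs are byte-reproducible.

* `annotation_fixture(n_genes, target_pairs)` builds disjoint clique
  terms greedily (largest C(k,2) ≤ remainder) so sharing pairs sum
  *exactly* to the target, falling back to overlapping 2-gene terms
  when fresh genes run out; leftover genes get singleton terms. The
  genome-scale instance (1835 genes, 10,804 pairs → cliques of 147, 12,
  4, 2 plus 1670 singletons) reproduces the bookkeeping identity
  |neg| = C(1835, 2) − 10,804 = 1,671,891.
* `evidence_fixture` scores a seeded sample of each gold class from a
  named distribution (default positives Normal(2, 1), negatives
  Normal(0, 1)); negatives are rejection-sampled so the quadratic class
  is never materialized.
* `phenotype_fixture` plants module-structured growth defects:
  conditions are assigned to modules round-robin; module genes score
  below the −4 threshold with probability `defect_rate_in` (default
  0.9), others with `defect_rate_out` (default 0.02); defective scores
  are −4.5 − |draw| so thresholding is exact.
* `expression_fixture` and `network_fixture` plant latent-factor
  coexpression and dense high-LLS modules respectively.

**What the generator does not emulate**: the heavy tails and ascertainment
bias of real literature co-mention counts, microarray normalization
artifacts, phylogenetic non-independence of genomes, and operon-level
correlation between evidence types. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted structure,
not field performance on real compendia.

## Problem sizes and test-regime design

The structure-recovery checks use 20 planted modules of 5 genes over
150 genes (200 gold positives, 10,975 negatives) and per-evidence
coverage 0.4 with 2,000 gold-overlapping pairs per evidence set. These
sizes are chosen so that a *single* evidence network is measurably
incomplete: with ~40% of within-module edges per data type, held-out
members are sometimes unreachable from their module, leaving
single-evidence LOO retrieval clearly off ceiling. That is the regime
the integration method exists for — with large dense modules or
near-complete evidence, every network saturates at AUC ≈ 1 and the
integrated-vs-single comparison degenerates to noise. Under these
conditions the weighted-sum network beats both single-evidence networks
in ≥ 80% of 20 seeded replicates (observed: 20/20), and
`scripts/acceptance.py` recomputes the same quantities end to end.

## Known limitations

* Raw-score → LLS mapping is piecewise-constant between bin boundaries;
  isotonic smoothing is optional, continuous density-ratio estimation is
  out of scope.
* No per-evidence D in the weighted sum; no full naïve-Bayes product
  integration (a D = 1 sum is the closest built-in analogue).
* Gene identifiers are opaque strings; no alias resolution.
* The WMI formula, the profile-MI discretization, and the GN parameters
  are stated defaults behind stable contracts, not claims about any
  particular upstream implementation.
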