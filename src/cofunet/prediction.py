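"""Network-assisted hypothesis generation.

Two guilt-by-association tools over a scored network:

* ``find_new_members`` — given query genes known to share a pathway or
  phenotype, first quantify how well the network "knows" the set
  (leave-one-out connectivity AUC among the queries), then rank every
  non-query gene by the sum of its edge weights to the query genes.
* ``infer_functions`` — given one gene, score candidate biological-
  process terms by the summed edge weight from the gene to its
  neighbors annotated with each term, restricted to annotations backed
  by reliable GO evidence codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from cofunet.core_io import AnnotationTable, ScoredNetwork
from cofunet.gold_standard import filter_terms
from cofunet import assessment

logger = logging.getLogger("cofunet.prediction")

#: GO evidence codes accepted by default for function inference:
#: direct assay, mutant phenotype, genetic interaction, physical
#: interaction, expression pattern, traceable author statement.
DEFAULT_FUNCTION_EVIDENCE = frozenset({"IDA", "IMP", "IGI", "IPI", "IEP", "TAS"})


@dataclass
class RankedCandidate:
    gene: str
    score: float  # summed edge LLS to the query genes
    support: dict[str, float] = field(default_factory=dict)  # query gene -> LLS
    evidence_codes: frozenset[str] = frozenset()


@dataclass
class CandidateRanking:
    """Result of a new-member search: ranked candidates plus query diagnostics."""

    candidates: list[RankedCandidate]
    connectivity_auc: float
    query_found: list[str]
    query_missing: list[str]

    def summary(self) -> str:
        return (
            f"{len(self.query_found)} of "
            f"{len(self.query_found) + len(self.query_missing)} query genes found in "
            f"the network; connectivity AUC = {self.connectivity_auc:.3f}"
        )


def find_new_members(
    net: ScoredNetwork,
    query: set[str],
    top_k: int = 100,
) -> CandidateRanking:
    """Prioritize candidate new members of the pathway the query genes share.

    Query connectivity is summarized by the leave-one-out AUC over the
    query set; candidates (non-query genes with at least one edge to a
    query gene) are ranked by summed edge LLS to the query genes, ties
    broken by the number of supporting query edges, then by gene id.
    """
    net_genes = net.genes()
    found = sorted(query & net_genes)
    missing = sorted(query - net_genes)
    if len(found) < 2:
        raise ValueError(
            f"only {len(found)} query gene(s) found in the network; need at least 2"
        )
    if missing:
        logger.warning("%d of %d query genes not found in the network", len(missing), len(query))

    auc = assessment.loo_auc(net, set(found))

    support: dict[str, dict[str, float]] = {}
    for q in found:
        for neighbor, w in net.neighbors(q).items():
            if neighbor in query:
                continue
            support.setdefault(neighbor, {})[q] = w

    candidates = []
    for gene, per_query in support.items():
        codes: set[str] = set()
        for q in per_query:
            pair = (gene, q) if gene < q else (q, gene)
            codes |= net.provenance.get(pair, frozenset())
        candidates.append(
            RankedCandidate(
                gene=gene,
                score=sum(per_query.values()),
                support=per_query,
                evidence_codes=frozenset(codes),
            )
        )
    candidates.sort(key=lambda c: (-c.score, -len(c.support), c.gene))
    return CandidateRanking(
        candidates=candidates[:top_k],
        connectivity_auc=auc,
        query_found=found,
        query_missing=missing,
    )


@dataclass
class TermPrediction:
    term_id: str
    score: float
    term_size: int
    neighbors: dict[str, float] = field(default_factory=dict)  # neighbor -> LLS


@dataclass
class FunctionPrediction:
    gene: str
    terms: list[TermPrediction]
    evidence_filter: frozenset[str]


def infer_functions(
    net: ScoredNetwork,
    gene: str,
    annotations: AnnotationTable,
    evidence_whitelist: frozenset[str] = DEFAULT_FUNCTION_EVIDENCE,
    top_k: int = 30,
    method: str = "lls_sum",
) -> FunctionPrediction:
    """Infer candidate functions for one gene from its network neighbors.

    With the default ``lls_sum`` method each term scores the summed edge
    LLS from the gene to its neighbors annotated with the term; the
    alternative ``hypergeometric`` method scores -log10 of the
    enrichment p of the term among the gene's neighbors.  Terms are
    ranked by score, ties broken by smaller term size (more specific
    first), then term id.  A gene with no annotated neighbor yields an
    empty prediction.
    """
    if gene not in net.genes():
        raise ValueError(f"gene {gene!r} is not in the network")
    table = filter_terms(annotations, evidence_whitelist=evidence_whitelist)
    neighbors = net.neighbors(gene)

    predictions: list[TermPrediction] = []
    n_universe = len(net.genes())
    for term_id, members in table.terms.items():
        annotated_neighbors = {v: w for v, w in neighbors.items() if v in members}
        if not annotated_neighbors:
            continue
        if method == "lls_sum":
            score = sum(annotated_neighbors.values())
        elif method == "hypergeometric":
            k = len(annotated_neighbors)
            m = len(members - {gene})
            p = float(stats.hypergeom.sf(k - 1, n_universe - 1, m, len(neighbors)))
            import math

            score = -math.log10(max(p, 1e-300))
        else:
            raise ValueError(f"unknown scoring method {method!r}")
        predictions.append(
            TermPrediction(
                term_id=term_id,
                score=score,
                term_size=len(members),
                neighbors=annotated_neighbors,
            )
        )
    predictions.sort(key=lambda t: (-t.score, t.term_size, t.term_id))
    return FunctionPrediction(
        gene=gene,
        terms=predictions[:top_k],
        evidence_filter=evidence_whitelist,
    )
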