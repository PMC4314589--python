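"""Gold-standard positive and negative cofunctional gene pairs.

Positives are pairs of genes sharing at least one curated annotation
(GO biological-process terms restricted to experimental evidence codes,
plus pathway-database terms with superpathways excluded).  Negatives are
every remaining pair of annotated genes, so positives and negatives
together tile C(n, 2) over the annotated-gene universe.  The negative
set is quadratic in the gene count and is therefore represented lazily:
membership tests and counts, never a materialized set, unless asked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

from cofunet.core_io import AnnotationTable, GenePair

logger = logging.getLogger("cofunet.gold_standard")

#: GO evidence codes accepted for gold-standard biological-process terms:
#: direct assay, genetic interaction, mutant phenotype.
DEFAULT_EVIDENCE_WHITELIST = frozenset({"IDA", "IGI", "IMP"})

#: The five largest transcription-related GO-BP terms, excluded so the
#: gold standard is not dominated by global transcription regulation.
DEFAULT_EXCLUDED_TERMS = frozenset(
    {"GO:0006351", "GO:0045892", "GO:0006355", "GO:0000160", "GO:0045893"}
)


@dataclass(frozen=True)
class GoldStandard:
    """Positive pairs, the annotated-gene universe, and implicit negatives."""

    positives: frozenset[GenePair]
    annotated_genes: frozenset[str]

    def __post_init__(self) -> None:
        for a, b in self.positives:
            if a not in self.annotated_genes or b not in self.annotated_genes:
                raise ValueError(f"positive pair ({a}, {b}) has an unannotated endpoint")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_negatives(self) -> int:
        return comb(len(self.annotated_genes), 2) - len(self.positives)

    @property
    def prior_odds(self) -> float:
        """P(L)/P(~L) = |positives| / |negatives|."""
        return self.n_positives / self.n_negatives

    def is_positive(self, pair: GenePair) -> bool:
        return pair in self.positives

    def is_negative(self, pair: GenePair) -> bool:
        a, b = pair
        return (
            a in self.annotated_genes
            and b in self.annotated_genes
            and pair not in self.positives
        )

    def label(self, pair: GenePair) -> bool | None:
        """True positive / False negative / None not in the gold universe."""
        if pair in self.positives:
            return True
        if self.is_negative(pair):
            return False
        return None


def filter_terms(
    table: AnnotationTable,
    evidence_whitelist: frozenset[str] | None = DEFAULT_EVIDENCE_WHITELIST,
    excluded_term_ids: frozenset[str] = frozenset(),
    exclude_superpathways: bool = False,
) -> AnnotationTable:
    """Restrict an annotation table to gold-standard-eligible terms.

    The evidence whitelist applies to terms that declare evidence codes
    (a term passes if any of its codes is whitelisted); terms with no
    declared codes (typically pathway-database terms) are unaffected.
    Terms named in ``excluded_term_ids`` are removed; ids absent from
    the table only produce a warning.  Superpathway-flagged terms are
    removed when ``exclude_superpathways`` is set.
    """
    missing = excluded_term_ids - set(table.terms)
    if missing:
        logger.warning("excluded term ids absent from table: %s", sorted(missing))
    out = AnnotationTable()
    for term_id, members in table.terms.items():
        info = table.info[term_id]
        if term_id in excluded_term_ids:
            continue
        if exclude_superpathways and info.superpathway:
            continue
        if (
            evidence_whitelist is not None
            and info.evidence_codes
            and not (info.evidence_codes & evidence_whitelist)
        ):
            continue
        out.add_term(term_id, set(members), info)
    return out


def positives_from_annotation(table: AnnotationTable) -> set[GenePair]:
    """All distinct pairs of genes co-member in at least one term."""
    pairs: set[GenePair] = set()
    for members in table.terms.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pairs.add((a, b))
    return pairs


@dataclass(frozen=True)
class MergeResult:
    union: frozenset[GenePair]
    overlap_count: int
    pct_overlap_of_b: int  # 100 * |A ∩ B| / |B|, nearest integer


def merge_positive_sets(a: set[GenePair], b: set[GenePair]) -> MergeResult:
    """Union two positive-pair sets and report their overlap statistics."""
    overlap = a & b
    pct = round(100 * len(overlap) / len(b)) if b else 0
    return MergeResult(
        union=frozenset(a | b),
        overlap_count=len(overlap),
        pct_overlap_of_b=pct,
    )


def negatives_from_annotation(
    annotated_genes: set[str],
    positives: set[GenePair],
    materialize: bool = False,
) -> set[GenePair] | int:
    """Pairs of annotated genes sharing no annotation.

    By default returns only the count C(n, 2) - |positives|; with
    ``materialize=True`` the full (quadratic) pair set is built.
    """
    for a, b in positives:
        if a not in annotated_genes or b not in annotated_genes:
            raise ValueError(f"positive pair ({a}, {b}) has an unannotated endpoint")
    n_neg = comb(len(annotated_genes), 2) - len(positives)
    if not materialize:
        return n_neg
    ordered = sorted(annotated_genes)
    out: set[GenePair] = set()
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if (a, b) not in positives:
                out.add((a, b))
    assert len(out) == n_neg
    return out


def gold_standard_from_tables(
    go_table: AnnotationTable,
    pathway_table: AnnotationTable | None = None,
    evidence_whitelist: frozenset[str] | None = DEFAULT_EVIDENCE_WHITELIST,
    excluded_term_ids: frozenset[str] = DEFAULT_EXCLUDED_TERMS,
    exclude_superpathways: bool = True,
) -> GoldStandard:
    """Full gold-standard derivation from annotation tables.

    Filters each table, derives sharing pairs, merges them, and takes
    the annotated-gene universe as every gene appearing in at least one
    post-filter term (the union over sources).
    """
    go_f = filter_terms(
        go_table,
        evidence_whitelist=evidence_whitelist,
        excluded_term_ids=excluded_term_ids,
        exclude_superpathways=exclude_superpathways,
    )
    pos = positives_from_annotation(go_f)
    universe = go_f.genes()
    if pathway_table is not None:
        pw_f = filter_terms(
            pathway_table,
            evidence_whitelist=None,
            excluded_term_ids=excluded_term_ids,
            exclude_superpathways=exclude_superpathways,
        )
        merged = merge_positive_sets(pos, positives_from_annotation(pw_f))
        logger.info(
            "merged positive sets: union=%d overlap=%d (%d%% of pathway links)",
            len(merged.union),
            merged.overlap_count,
            merged.pct_overlap_of_b,
        )
        pos = set(merged.union)
        universe |= pw_f.genes()
    return GoldStandard(positives=frozenset(pos), annotated_genes=frozenset(universe))
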