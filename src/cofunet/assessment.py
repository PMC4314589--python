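"""Network assessment against knockout-phenotype data.

Two complementary views of predictive power:

* the cumulative accuracy-vs-coverage curve — links are sorted by edge
  score and, for each successive bin of links, the fraction of
  evaluable cumulated pairs that share at least one knockout phenotype
  (accuracy) is plotted against the fraction of the coding genome
  covered by the cumulated node set (coverage);
* per-phenotype leave-one-out ROC/AUC — each member of a phenotype gene
  set is held out in turn and ranked among candidate genes by the sum
  of its network edge weights to the remaining members; the
  Mann-Whitney AUC (midrank ties) summarizes retrieval, and paired
  AUC lists from two networks are compared with the two-sided Wilcoxon
  signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cofunet.core_io import GenePair, ScoredNetwork

logger = logging.getLogger("cofunet.assessment")

#: a gene is associated with a stress condition when its growth score is
#: strictly below this threshold
GROWTH_DEFECT_THRESHOLD = -4.0


@dataclass
class PhenotypeAssignment:
    """Gene -> stress-phenotype-set mapping derived from growth scores."""

    phenotypes: dict[str, frozenset[str]]
    threshold: float = GROWTH_DEFECT_THRESHOLD

    def __len__(self) -> int:
        return len(self.phenotypes)

    def genes(self) -> set[str]:
        return set(self.phenotypes)

    def shares_phenotype(self, pair: GenePair) -> bool | None:
        """True/False if both endpoints are phenotype-annotated, else None."""
        a, b = pair
        pa = self.phenotypes.get(a)
        pb = self.phenotypes.get(b)
        if pa is None or pb is None:
            return None
        return bool(pa & pb)

    def members_of(self, condition: str) -> set[str]:
        return {g for g, conds in self.phenotypes.items() if condition in conds}

    def conditions(self) -> set[str]:
        out: set[str] = set()
        for conds in self.phenotypes.values():
            out |= conds
        return out


def phenotypes_from_scores(
    matrix: pd.DataFrame, threshold: float = GROWTH_DEFECT_THRESHOLD
) -> PhenotypeAssignment:
    """Threshold a genes x conditions growth-score matrix.

    A gene is assigned a condition iff its score is strictly below the
    threshold; genes with no assigned condition are dropped.
    """
    phenotypes: dict[str, frozenset[str]] = {}
    values = matrix.to_numpy(dtype=float)
    conds = np.asarray(matrix.columns)
    for gene, row in zip(matrix.index, values):
        hit = conds[row < threshold]
        if len(hit):
            phenotypes[str(gene)] = frozenset(str(c) for c in hit)
    return PhenotypeAssignment(phenotypes=phenotypes, threshold=threshold)


@dataclass(frozen=True)
class AccuracyCoveragePoint:
    bin_index: int
    n_links: int  # cumulated links
    coverage: float  # % of coding genome covered by cumulated genes
    accuracy: float | None  # % of evaluable cumulated pairs sharing a phenotype


def accuracy_coverage_curve(
    net: ScoredNetwork,
    phenotypes: PhenotypeAssignment,
    bin_size: int = 1000,
    total_coding_genes: int | None = None,
) -> list[AccuracyCoveragePoint]:
    """Cumulative accuracy vs genome coverage over score-sorted link bins.

    Links are sorted by descending edge weight (ties by pair order).
    After each successive bin of ``bin_size`` links, accuracy is the
    percentage of evaluable cumulated pairs (both endpoints phenotype-
    annotated) sharing at least one phenotype, and coverage is the
    percentage of ``total_coding_genes`` appearing in the cumulated
    pairs.  A prefix with no evaluable pair yields a point with missing
    accuracy.
    """
    if len(net) == 0:
        raise ValueError("cannot assess an empty network")
    return _curve_from_predicates(
        net,
        evaluable=lambda p: phenotypes.shares_phenotype(p) is not None,
        shares=lambda p: bool(phenotypes.shares_phenotype(p)),
        bin_size=bin_size,
        total_genes=total_coding_genes or len(net.genes()),
    )


def _curve_from_predicates(
    net: ScoredNetwork,
    evaluable: Callable[[GenePair], bool],
    shares: Callable[[GenePair], bool],
    bin_size: int,
    total_genes: int,
) -> list[AccuracyCoveragePoint]:
    points: list[AccuracyCoveragePoint] = []
    genes: set[str] = set()
    n_eval = 0
    n_share = 0
    links = net.sorted_links()
    for idx in range(0, len(links), bin_size):
        for pair, _ in links[idx : idx + bin_size]:
            genes.update(pair)
            if evaluable(pair):
                n_eval += 1
                if shares(pair):
                    n_share += 1
        points.append(
            AccuracyCoveragePoint(
                bin_index=len(points),
                n_links=min(idx + bin_size, len(links)),
                coverage=100.0 * len(genes) / total_genes,
                accuracy=(100.0 * n_share / n_eval) if n_eval else None,
            )
        )
    return points


def _curve_area_from_predicates(
    net: ScoredNetwork,
    evaluable: Callable[[GenePair], bool],
    shares: Callable[[GenePair], bool],
    bin_size: int,
    total_genes: int,
) -> float:
    """Trapezoid area under the accuracy-vs-coverage curve (used for
    parameter tuning); points with missing accuracy are skipped."""
    pts = [
        (p.coverage, p.accuracy)
        for p in _curve_from_predicates(net, evaluable, shares, bin_size, total_genes)
        if p.accuracy is not None
    ]
    if len(pts) == 0:
        return float("-inf")
    if len(pts) == 1:
        return pts[0][0] * pts[0][1]
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


def loo_auc(
    net: ScoredNetwork,
    members: set[str],
    universe: set[str] | None = None,
    exclude_members_from_negatives: bool = True,
) -> float:
    """Leave-one-out AUC of guilt-by-association retrieval for one gene set.

    Each member is held out in turn; every candidate gene is scored by
    the sum of its edge weights to the remaining members (0 when
    unconnected) and the held-out member's ROC position among the
    candidates gives a Mann-Whitney AUC with midrank tie handling; the
    mean over held-out members is returned.  The candidate universe
    defaults to all network genes (plus any ``universe`` additions);
    the remaining members are excluded from the negatives since they
    are known positives of the same phenotype.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 member genes for leave-one-out analysis")
    net_genes = net.genes()
    missing = members - net_genes
    if missing:
        logger.warning("%d member gene(s) not in the network; scored as unconnected", len(missing))
    cand_universe = set(net_genes)
    if universe:
        cand_universe |= universe
    cand_universe |= members

    adj = net.adjacency()
    aucs = []
    for held_out in sorted(members):
        rest = members - {held_out}
        # connection score of every candidate to the remaining members
        scores: dict[str, float] = {}
        for m in rest:
            for neighbor, w in adj.get(m, {}).items():
                scores[neighbor] = scores.get(neighbor, 0.0) + w
        negatives = cand_universe - {held_out}
        if exclude_members_from_negatives:
            negatives -= rest
        pos_score = scores.get(held_out, 0.0)
        neg_scores = np.array([scores.get(g, 0.0) for g in negatives])
        if len(neg_scores) == 0:
            continue
        auc = (np.sum(pos_score > neg_scores) + 0.5 * np.sum(pos_score == neg_scores)) / len(
            neg_scores
        )
        aucs.append(auc)
    return float(np.mean(aucs))


def loo_auc_per_phenotype(
    net: ScoredNetwork,
    phenotypes: PhenotypeAssignment,
    min_members: int = 2,
) -> dict[str, float]:
    """LOO AUC for every stress condition with enough member genes."""
    out: dict[str, float] = {}
    for cond in sorted(phenotypes.conditions()):
        members = phenotypes.members_of(cond)
        if len(members) >= min_members:
            out[cond] = loo_auc(net, members)
    return out


def compare_auc_sets(
    aucs_a: Sequence[float], aucs_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-phenotype AUCs.

    Zero differences are dropped (classic Wilcoxon convention).  When
    every difference is zero the test is undefined; (0.0, 1.0) is
    returned with a warning.
    """
    if len(aucs_a) != len(aucs_b):
        raise ValueError("AUC lists must be paired (equal length)")
    diffs = np.asarray(aucs_a, dtype=float) - np.asarray(aucs_b, dtype=float)
    if np.all(diffs == 0):
        logger.warning("all paired AUC differences are zero; p = 1")
        return 0.0, 1.0
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def truncate_network(net: ScoredNetwork, top_k: int) -> ScoredNetwork:
    """Top-k links by weight (ties by pair order) — used to size-match
    networks before comparison, since link count affects every measure."""
    out = ScoredNetwork()
    for pair, w in net.sorted_links()[:top_k]:
        out.add(pair, w, net.provenance.get(pair, frozenset()))
    return out
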