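"""Raw cofunctionality scores for the seven evidence data types.

Each scorer turns one standard input table into a raw pair score that
feeds the LLS benchmarking stage unchanged:

* CC — literature cocitation: upper-tail hypergeometric probability of
  observing at least the seen number of co-mentioning articles, reported
  as -log10 p.
* CX — coexpression: Pearson correlation across the samples of one
  expression series.
* DC — domain co-occurrence: weighted mutual information where each
  shared protein domain contributes its rarity in bits, -log2(f_d).
* PG — phylogenetic profiling: mutual information between two genes'
  similarity profiles across genomes, computed separately for Archaea
  and Bacteria columns when a taxonomic partition is requested.
* GN — gene neighborhood: a distance-based score (negated median
  intergenic distance of the two orthologs across genomes) and a
  probability-based score (upper tail of the chance of seeing the
  observed number of genomes where the orthologs are adjacent).
* HT / LC — protein-protein interaction link sets: binary evidence, all
  links score 1, kept per source so each source is benchmarked to its
  own single-bin LLS.

Scorers return None ("no score") when a pair cannot be evaluated; they
never silently emit a default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cofunet.core_io import EvidenceLinkSet, gene_pair

logger = logging.getLogger("cofunet.evidence_scorers")


# ---------------------------------------------------------------------------
# CC — cocitation
# ---------------------------------------------------------------------------


@dataclass
class ArticleGeneIndex:
    """Article -> mentioned-gene-set index over a literature corpus."""

    articles: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_articles(self) -> int:
        return len(self.articles)

    def article_count(self, gene: str) -> int:
        return sum(1 for genes in self.articles.values() if gene in genes)

    def cocount(self, a: str, b: str) -> int:
        return sum(1 for genes in self.articles.values() if a in genes and b in genes)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.articles.values():
            out |= genes
        return out

    @classmethod
    def from_tsv(cls, path) -> "ArticleGeneIndex":
        """Read a two-column TSV: article-id, gene."""
        idx = cls()
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                article, _, gene = line.partition("\t")
                idx.articles.setdefault(article, set()).add(gene)
        return idx


def cocitation_pvalue(idx: ArticleGeneIndex, a: str, b: str) -> float | None:
    """Hypergeometric upper-tail p of the observed cocitation count.

    With N articles total, m mentioning gene a, n mentioning gene b and
    k mentioning both, returns P(X >= k) for X ~ Hypergeom(N, m, n).
    None when either gene is absent from the index.
    """
    m = idx.article_count(a)
    n = idx.article_count(b)
    if m == 0 or n == 0:
        return None
    k = idx.cocount(a, b)
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, idx.n_articles, m, n))


def cocitation_score(idx: ArticleGeneIndex, a: str, b: str) -> float | None:
    """-log10 of the cocitation p-value (higher = stronger evidence)."""
    p = cocitation_pvalue(idx, a, b)
    if p is None:
        return None
    return -math.log10(max(p, np.finfo(float).tiny))


def cocitation_linkset(idx: ArticleGeneIndex, min_cocount: int = 1) -> EvidenceLinkSet:
    """Score every gene pair co-mentioned in at least ``min_cocount`` articles."""
    ev = EvidenceLinkSet(evidence_code="CC", higher_is_better=True)
    pair_counts: dict[tuple[str, str], int] = {}
    for genes in idx.articles.values():
        ordered = sorted(genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    for (a, b), k in pair_counts.items():
        if k < min_cocount:
            continue
        score = cocitation_score(idx, a, b)
        if score is not None:
            ev.add(a, b, score)
    return ev


# ---------------------------------------------------------------------------
# CX — coexpression
# ---------------------------------------------------------------------------

#: a series must have more than 8 samples to be scored
MIN_SHARED_SAMPLES = 9


def coexpression_pcc(matrix: pd.DataFrame, a: str, b: str) -> float | None:
    """Pearson correlation of two genes across an expression series.

    Only samples where both genes have values count; fewer than
    MIN_SHARED_SAMPLES shared samples, or a zero-variance gene, give no
    score.
    """
    if a not in matrix.index or b not in matrix.index:
        return None
    x = matrix.loc[a].to_numpy(dtype=float)
    y = matrix.loc[b].to_numpy(dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < MIN_SHARED_SAMPLES:
        return None
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def coexpression_linkset(
    matrix: pd.DataFrame, series_id: str = "CX", min_abs_r: float = 0.0
) -> EvidenceLinkSet:
    """All-vs-all Pearson correlations for one expression series."""
    if matrix.shape[1] < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"series {series_id!r} has {matrix.shape[1]} samples; more than 8 required"
        )
    ev = EvidenceLinkSet(evidence_code=series_id, higher_is_better=True)
    genes = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            x, y = values[i], values[j]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < MIN_SHARED_SAMPLES:
                continue
            xm, ym = x[mask], y[mask]
            if np.ptp(xm) == 0 or np.ptp(ym) == 0:
                continue
            r = float(stats.pearsonr(xm, ym).statistic)
            if abs(r) >= min_abs_r:
                ev.add(genes[i], genes[j], r)
    return ev


# ---------------------------------------------------------------------------
# DC — domain co-occurrence
# ---------------------------------------------------------------------------


@dataclass
class DomainTable:
    """Protein/gene -> domain-set table over a proteome of known size."""

    domains: dict[str, set[str]] = field(default_factory=dict)
    proteome_size: int = 0

    def __post_init__(self) -> None:
        if self.proteome_size == 0:
            self.proteome_size = len(self.domains)
        if self.proteome_size < len(self.domains):
            raise ValueError("proteome size smaller than the number of annotated proteins")

    def domain_frequency(self, domain: str) -> float:
        carriers = sum(1 for ds in self.domains.values() if domain in ds)
        return carriers / self.proteome_size

    @classmethod
    def from_tsv(cls, path, proteome_size: int = 0) -> "DomainTable":
        """Read a two-column TSV: protein/gene, domain-id."""
        domains: dict[str, set[str]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                protein, _, domain = line.partition("\t")
                domains.setdefault(protein, set()).add(domain)
        return cls(domains=domains, proteome_size=proteome_size)


def domain_wmi(table: DomainTable, a: str, b: str) -> float | None:
    """Weighted mutual information of shared domains, in rarity bits.

    Each domain shared by the two proteins contributes -log2(f_d) where
    f_d is its proteome frequency: rarer shared domains weigh more, on
    the assumption that rare domains mark specific pathways.  Zero when
    nothing is shared; None when either protein is not in the table.
    """
    if a not in table.domains or b not in table.domains:
        return None
    shared = table.domains[a] & table.domains[b]
    return sum(-math.log2(table.domain_frequency(d)) for d in shared)


def domain_linkset(table: DomainTable) -> EvidenceLinkSet:
    """Score every pair of proteins sharing at least one domain."""
    ev = EvidenceLinkSet(evidence_code="DC", higher_is_better=True)
    by_domain: dict[str, list[str]] = {}
    for protein, ds in table.domains.items():
        for d in ds:
            by_domain.setdefault(d, []).append(protein)
    candidate_pairs: set[tuple[str, str]] = set()
    for carriers in by_domain.values():
        ordered = sorted(carriers)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                candidate_pairs.add((a, b))
    for a, b in candidate_pairs:
        score = domain_wmi(table, a, b)
        if score:
            ev.add(a, b, score)
    return ev


# ---------------------------------------------------------------------------
# PG — phylogenetic profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileMatrix:
    """Genes x genomes similarity-score matrix with per-genome taxonomy.

    Values are similarity scores of the best ortholog hit in each genome
    (recommended provenance: -log10 E-value normalized to [0, 1] by the
    self-hit; any non-negative similarity works).  ``genome_domains``
    labels each genome column Archaea or Bacteria for the partitioned
    two-network variant.
    """

    values: pd.DataFrame
    genome_domains: dict[str, str] = field(default_factory=dict)

    def columns_for_domain(self, domain: str) -> list[str]:
        return [g for g in self.values.columns if self.genome_domains.get(g) == domain]


def _equal_frequency_bins(x: np.ndarray, k: int) -> np.ndarray:
    """Discretize into k equal-frequency bins; constant input -> one bin."""
    if np.ptp(x) == 0:
        return np.zeros(len(x), dtype=int)
    quantiles = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
    # side="right": a value equal to a boundary joins the upper bin, so
    # heavily tied (e.g. presence/absence) profiles still split
    return np.searchsorted(quantiles, x, side="right").astype(int)


def phyloprofile_mi(
    profiles: ProfileMatrix | pd.DataFrame,
    a: str,
    b: str,
    bins: int = 4,
    columns: Sequence[str] | None = None,
) -> float | None:
    """Mutual information (bits) between two phylogenetic profiles.

    Each profile is discretized into ``bins`` equal-frequency bins over
    the genome axis; MI is computed from the joint histogram.  Constant
    profiles carry no coinheritance signal and score 0 (with a warning).
    None when either gene is not profiled.
    """
    values = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    if a not in values.index or b not in values.index:
        return None
    x = values.loc[a]
    y = values.loc[b]
    if columns is not None:
        x, y = x[list(columns)], y[list(columns)]
    x = x.to_numpy(dtype=float)
    y = y.to_numpy(dtype=float)
    if len(x) == 0:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate (constant) profile for pair (%s, %s); MI = 0", a, b)
        return 0.0
    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    joint = np.zeros((bins, bins))
    for i, j in zip(bx, by):
        joint[i, j] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log2(joint[i, j] / (px[i] * py[j]))
    return max(mi, 0.0)


def profile_linksets(
    profiles: ProfileMatrix,
    bins: int = 4,
    partition_by_domain: bool = True,
    min_mi: float = 0.0,
) -> list[EvidenceLinkSet]:
    """MI link sets from a profile matrix.

    With ``partition_by_domain`` one link set per taxonomic domain
    (Archaea-only and Bacteria-only columns) is produced, to be merged
    by weighted-sum integration downstream; otherwise a single link set
    over all genomes.
    """
    groups: list[tuple[str, Sequence[str] | None]]
    if partition_by_domain and profiles.genome_domains:
        groups = [
            (f"PG-{dom}", profiles.columns_for_domain(dom))
            for dom in sorted(set(profiles.genome_domains.values()))
        ]
        groups = [(code, cols) for code, cols in groups if cols]
    else:
        groups = [("PG", None)]
    out: list[EvidenceLinkSet] = []
    genes = list(profiles.values.index)
    for code, cols in groups:
        ev = EvidenceLinkSet(evidence_code=code, higher_is_better=True)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                mi = phyloprofile_mi(profiles, genes[i], genes[j], bins=bins, columns=cols)
                if mi is not None and mi > min_mi:
                    ev.add(genes[i], genes[j], mi)
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# GN — gene neighborhood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    replicon: str
    slot: int  # ordinal position along the replicon
    start: int  # bp
    end: int  # bp


@dataclass
class GenomeContext:
    """Ordered gene positions per genome with ortholog mapping.

    ``loci[genome][reference_gene]`` is the locus of that gene's
    ortholog in the genome (at most one slot per genome per gene);
    ``slots[genome][replicon]`` is the slot count of the replicon.
    """

    loci: dict[str, dict[str, GeneLocus]] = field(default_factory=dict)
    slots: dict[str, dict[str, int]] = field(default_factory=dict)

    def co_present_genomes(self, a: str, b: str) -> list[str]:
        return [g for g, m in self.loci.items() if a in m and b in m]

    @classmethod
    def from_tsv(cls, path) -> "GenomeContext":
        """Read a TSV: genome, replicon, position, start-bp, end-bp, reference-ortholog."""
        ctx = cls()
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                genome, replicon, pos, start, end, ref = line.split("\t")[:6]
                locus = GeneLocus(replicon, int(pos), int(start), int(end))
                ctx.loci.setdefault(genome, {})
                ctx.slots.setdefault(genome, {})
                ctx.slots[genome][replicon] = max(ctx.slots[genome].get(replicon, 0), int(pos) + 1)
                if ref and ref != "-":
                    ctx.loci[genome][ref] = locus
        return ctx


DIFFERENT_REPLICON_CAP = 1_000_000  # bp charged when orthologs sit on different replicons


def gn_distance_score(
    ctx: GenomeContext,
    a: str,
    b: str,
    min_genomes: int = 3,
    cap: float = DIFFERENT_REPLICON_CAP,
) -> float | None:
    """Distance-based gene-neighborhood score.

    Negated median intergenic distance (bp) between the two genes'
    orthologs over genomes where both are present; different-replicon
    occurrences are charged the cap distance.  Higher (less negative)
    means consistently closer, hence stronger operon-like coupling.
    None when co-present in fewer than ``min_genomes`` genomes.
    """
    genomes = ctx.co_present_genomes(a, b)
    if len(genomes) < min_genomes:
        return None
    distances = []
    for g in genomes:
        la, lb = ctx.loci[g][a], ctx.loci[g][b]
        if la.replicon != lb.replicon:
            distances.append(cap)
        else:
            gap = max(la.start, lb.start) - min(la.end, lb.end)
            distances.append(max(gap, 0))
    return -float(np.median(distances))


def gn_probability_score(
    ctx: GenomeContext,
    a: str,
    b: str,
    window: int = 1,
    min_genomes: int = 3,
) -> float | None:
    """Probability-based gene-neighborhood score.

    In each co-present genome the orthologs are "neighbors" iff they lie
    on the same replicon within ``window`` gene slots.  The chance of
    that under a random arrangement is q = min(1, 2*window/(n_slots-1)).
    The score is -log10 of the exact upper-tail probability of seeing at
    least the observed number of neighbor genomes (Poisson-binomial over
    the per-genome q values; plain binomial when all q are equal).
    """
    genomes = ctx.co_present_genomes(a, b)
    if len(genomes) < min_genomes:
        return None
    qs = []
    hits = 0
    for g in genomes:
        la, lb = ctx.loci[g][a], ctx.loci[g][b]
        n_slots = ctx.slots[g].get(la.replicon, 0)
        q = min(1.0, 2 * window / (n_slots - 1)) if n_slots > 1 else 1.0
        qs.append(q)
        if la.replicon == lb.replicon and abs(la.slot - lb.slot) <= window:
            hits += 1
    p = _poisson_binomial_upper_tail(qs, hits)
    return -math.log10(max(p, np.finfo(float).tiny))


def _poisson_binomial_upper_tail(qs: Sequence[float], k: int) -> float:
    """P(X >= k) for X a sum of independent Bernoulli(q_i), by DP."""
    pmf = np.zeros(len(qs) + 1)
    pmf[0] = 1.0
    for q in qs:
        pmf[1:] = pmf[1:] * (1 - q) + pmf[:-1] * q
        pmf[0] *= 1 - q
    return float(pmf[k:].sum())


def gn_linksets(
    ctx: GenomeContext,
    genes: Iterable[str],
    window: int = 1,
    min_genomes: int = 3,
    cap: float = DIFFERENT_REPLICON_CAP,
) -> list[EvidenceLinkSet]:
    """Both gene-neighborhood link sets (distance- and probability-based)
    over all pairs of the given reference genes; merged downstream by
    weighted-sum integration."""
    dist = EvidenceLinkSet(evidence_code="GN-dist", higher_is_better=True)
    prob = EvidenceLinkSet(evidence_code="GN-prob", higher_is_better=True)
    ordered = sorted(set(genes))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            d = gn_distance_score(ctx, a, b, min_genomes=min_genomes, cap=cap)
            if d is not None:
                dist.add(a, b, d)
            p = gn_probability_score(ctx, a, b, window=window, min_genomes=min_genomes)
            if p is not None:
                prob.add(a, b, p)
    return [dist, prob]


# ---------------------------------------------------------------------------
# HT / LC — protein-protein interactions
# ---------------------------------------------------------------------------


def ppi_to_linkset(
    edges: Iterable[tuple[str, str]],
    label: str,
    source: str | None = None,
) -> EvidenceLinkSet:
    """Turn one source's binary PPI edge list into single-score evidence.

    Every interaction scores 1 (the whole set is one evidence stratum,
    benchmarked to a single-bin LLS).  Self-interactions are dropped
    with a logged count.  Keep sources separate: each gets its own link
    set and its own benchmark before weighted-sum merging.
    """
    code = f"{label}:{source}" if source else label
    ev = EvidenceLinkSet(evidence_code=code, higher_is_better=True)
    skipped_self = 0
    for a, b in edges:
        if a == b:
            skipped_self += 1
            continue
        ev.add(a, b, 1.0)
    if skipped_self:
        logger.warning("%s: dropped %d self-interactions", code, skipped_self)
    return ev
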