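"""Log-likelihood scoring of raw evidence against the gold standard.

The LLS of an evidence stratum is

    LLS = ln[ (P(L|E) / P(~L|E)) / (P(L) / P(~L)) ]

where P(L|E) and P(~L|E) are the frequencies of gold-standard positives
and negatives among pairs carrying the evidence, and P(L), P(~L) the
frequencies over all gold-standard pairs.  An LLS of 0 means the
evidence stratum is no more enriched for cofunctional pairs than
background; positive values mean enrichment.

Raw evidence scores are binned along the score axis into bins holding an
equal number of gold-overlapping pairs (robust to skewed score
distributions), each bin receives its own LLS, and every link in the
evidence set is then mapped to the LLS of its bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cofunet.core_io import EvidenceLinkSet, ScoredNetwork
from cofunet.gold_standard import GoldStandard

logger = logging.getLogger("cofunet.lls_scoring")

#: Haldane–Anscombe pseudocount keeping bin LLS finite in pure bins
DEFAULT_PSEUDOCOUNT = 0.5


def lls_from_counts(
    pos_in_bin: float,
    neg_in_bin: float,
    pos_total: float,
    neg_total: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """LLS for one evidence stratum from raw positive/negative counts.

    Returns ln[((pos_in_bin + c) / (neg_in_bin + c)) / (pos_total / neg_total)].
    With c = 0 a bin empty of both classes has no defined score and a
    ValueError instructs the caller to use a nonzero pseudocount.
    """
    if pos_total <= 0 or neg_total <= 0:
        raise ValueError("gold-standard totals must be positive")
    if pos_in_bin < 0 or neg_in_bin < 0:
        raise ValueError("bin counts must be non-negative")
    p = pos_in_bin + pseudocount
    n = neg_in_bin + pseudocount
    if p == 0 or n == 0:
        raise ValueError(
            "bin with zero positives or negatives and pseudocount 0 has an "
            "undefined LLS; use a nonzero pseudocount"
        )
    return math.log((p / n) / (pos_total / neg_total))


@dataclass
class LLSBin:
    lo: float  # lowest raw score in the bin
    hi: float  # highest raw score in the bin
    pos: int
    neg: int
    lls: float


@dataclass
class BinnedLLSModel:
    """Piecewise-constant raw-score -> LLS mapping learned from the gold standard.

    ``bins`` are ordered from weakest to strongest evidence under the
    declared orientation.  ``passes`` records the evidence-inclusion
    rule: the maximum bin LLS is positive and bin strength correlates
    positively (Spearman, permutation p < alpha) with the bin positive
    fraction.
    """

    bins: list[LLSBin]
    pos_total: int
    neg_total: int
    pseudocount: float
    higher_is_better: bool
    passes: bool = True
    trend_rho: float = float("nan")
    trend_p: float = float("nan")
    n_clamped: int = field(default=0, repr=False)

    @property
    def max_lls(self) -> float:
        return max(b.lls for b in self.bins)

    def lls_for_score(self, score: float) -> float:
        """LLS of the bin containing ``score``; scores outside every bin
        (out of the modeled range, or in a gap between bins) clamp to the
        nearest bin, and the clamp is counted."""
        for b in self.bins:
            if b.lo <= score <= b.hi:
                return b.lls
        self.n_clamped += 1
        nearest = min(self.bins, key=lambda b: min(abs(score - b.lo), abs(score - b.hi)))
        return nearest.lls

    def smoothed(self) -> "BinnedLLSModel":
        """Monotone (isotonic) smoothing of the bin LLS sequence.

        Returns a copy whose bin LLS values are non-decreasing from
        weakest to strongest evidence, fitted by isotonic regression
        weighted by the gold count per bin.
        """
        from sklearn.isotonic import IsotonicRegression

        x = np.arange(len(self.bins))
        y = np.array([b.lls for b in self.bins])
        w = np.array([b.pos + b.neg for b in self.bins], dtype=float)
        iso = IsotonicRegression(increasing=True)
        y_fit = iso.fit_transform(x, y, sample_weight=w)
        new_bins = [
            LLSBin(b.lo, b.hi, b.pos, b.neg, float(v)) for b, v in zip(self.bins, y_fit)
        ]
        return BinnedLLSModel(
            bins=new_bins,
            pos_total=self.pos_total,
            neg_total=self.neg_total,
            pseudocount=self.pseudocount,
            higher_is_better=self.higher_is_better,
            passes=self.passes,
            trend_rho=self.trend_rho,
            trend_p=self.trend_p,
        )


@dataclass(frozen=True)
class BenchmarkFailure:
    """Evidence could not be benchmarked and is excluded from integration."""

    evidence_code: str
    reason: str


def _trend_test(
    pos_frac: np.ndarray, rng_seed: int = 0, n_perm: int = 2000
) -> tuple[float, float]:
    """Spearman correlation of bin rank vs bin positive fraction, with a
    permutation p-value (exhaustive for few bins, seeded Monte Carlo
    otherwise)."""
    k = len(pos_frac)
    if k < 2 or np.allclose(pos_frac, pos_frac[0]):
        return 0.0, 1.0
    ranks = np.arange(k, dtype=float)
    rho = float(stats.spearmanr(ranks, pos_frac).statistic)
    import itertools

    if k <= 6:  # exhaustive permutation
        perms = itertools.permutations(pos_frac)
        stats_all = [float(stats.spearmanr(ranks, np.array(p)).statistic) for p in perms]
        p_val = sum(1 for s in stats_all if s >= rho - 1e-12) / len(stats_all)
    else:
        rng = np.random.default_rng(rng_seed)
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(pos_frac)
            if float(stats.spearmanr(ranks, perm).statistic) >= rho - 1e-12:
                count += 1
        p_val = count / (n_perm + 1)
    return rho, p_val


def benchmark_linkset(
    ev: EvidenceLinkSet,
    gold: GoldStandard,
    gold_per_bin: int = 100,
    min_gold_positives: int = 10,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    trend_alpha: float = 0.05,
) -> BinnedLLSModel | BenchmarkFailure:
    """Benchmark one evidence link set against the gold standard.

    Gold-overlapping links (both endpoints annotated) are sorted by raw
    score from weakest to strongest evidence and partitioned into bins
    of ``gold_per_bin`` gold pairs each (the strongest-evidence bin
    absorbs the remainder).  Each bin's LLS is computed from its
    positive/negative counts.  Too little gold overlap yields a
    BenchmarkFailure result rather than an exception.
    """
    labeled: list[tuple[float, bool]] = []  # (raw score, is_positive)
    for pair, score in ev.links.items():
        lab = gold.label(pair)
        if lab is not None:
            labeled.append((score, lab))
    n_pos_overlap = sum(1 for _, lab in labeled if lab)
    if n_pos_overlap < min_gold_positives:
        return BenchmarkFailure(
            evidence_code=ev.evidence_code,
            reason=(
                f"only {n_pos_overlap} gold positives overlap the evidence "
                f"(minimum {min_gold_positives})"
            ),
        )

    # weakest evidence first so bins are ordered by increasing strength
    labeled.sort(key=lambda t: t[0], reverse=not ev.higher_is_better)

    bins: list[LLSBin] = []
    chunk: list[tuple[float, bool]] = []
    n_remaining = len(labeled)
    for item in labeled:
        chunk.append(item)
        n_remaining -= 1
        if len(chunk) >= gold_per_bin and n_remaining >= gold_per_bin:
            bins.append(_make_bin(chunk, gold, pseudocount))
            chunk = []
    if chunk:
        bins.append(_make_bin(chunk, gold, pseudocount))

    pos_frac = np.array([b.pos / (b.pos + b.neg) for b in bins])
    rho, p_val = _trend_test(pos_frac)
    model = BinnedLLSModel(
        bins=bins,
        pos_total=gold.n_positives,
        neg_total=gold.n_negatives,
        pseudocount=pseudocount,
        higher_is_better=ev.higher_is_better,
        passes=(max(b.lls for b in bins) > 0) and (rho > 0) and (p_val < trend_alpha),
        trend_rho=rho,
        trend_p=p_val,
    )
    return model


def _make_bin(
    chunk: list[tuple[float, bool]], gold: GoldStandard, pseudocount: float
) -> LLSBin:
    scores = [s for s, _ in chunk]
    pos = sum(1 for _, lab in chunk if lab)
    neg = len(chunk) - pos
    return LLSBin(
        lo=min(scores),
        hi=max(scores),
        pos=pos,
        neg=neg,
        lls=lls_from_counts(pos, neg, gold.n_positives, gold.n_negatives, pseudocount),
    )


def apply_lls(
    ev: EvidenceLinkSet,
    model: BinnedLLSModel,
    threshold: float = float("-inf"),
    isotonic: bool = False,
) -> ScoredNetwork:
    """Map every evidence link to its bin's LLS, dropping links below
    ``threshold``.  Raw scores outside the modeled range clamp to the
    nearest end bin (clamp count logged)."""
    if ev.higher_is_better != model.higher_is_better:
        raise ValueError("evidence orientation does not match the model's")
    m = model.smoothed() if isotonic else model
    m.n_clamped = 0
    net = ScoredNetwork()
    for pair, score in ev.links.items():
        lls = m.lls_for_score(score)
        if lls < threshold:
            continue
        net.add(pair, lls, {ev.evidence_code})
    if m.n_clamped:
        logger.warning(
            "%s: %d raw scores outside the modeled range were clamped",
            ev.evidence_code,
            m.n_clamped,
        )
    return net


def write_model(model: BinnedLLSModel, path) -> None:
    """Emit the model as TSV: bin lower bound, upper bound, pos, neg, LLS."""
    with open(path, "w") as fh:
        fh.write("# lls model; bins ordered weakest to strongest evidence\n")
        fh.write("lo\thi\tpos\tneg\tlls\n")
        for b in model.bins:
            fh.write(f"{b.lo!r}\t{b.hi!r}\t{b.pos}\t{b.neg}\t{b.lls!r}\n")
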