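"""Weighted-sum (WS) integration of LLS-scored evidence networks.

For one gene pair with LLS values from several evidence networks, let
S0 be the best value and S1 >= S2 >= ... the remainder (rank index i
from 1).  Then

    WS = S0 + sum_i  Si / (D * i),      over all values S >= T

where D >= 1 is a weight factor discounting correlated secondary
evidence (D = 1 recovers a plain sum; D -> infinity keeps only the
single best evidence) and T is the minimum LLS a value must reach to be
integrated at all.  The same machinery merges link sets within one data
type (e.g. many coexpression series into one coexpression network) and
across data types into the final integrated network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cofunet.core_io import GenePair, ScoredNetwork
from cofunet.gold_standard import GoldStandard

logger = logging.getLogger("cofunet.integration")


@dataclass(frozen=True)
class WSParams:
    """Weighted-sum free parameters: weight factor D and LLS cutoff T."""

    D: float = 1.0
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError(
                f"D must be >= 1 (got {self.D}); D < 1 would weight secondary "
                "evidence above the primary one"
            )


def weighted_sum(scores: Iterable[float], params: WSParams) -> float | None:
    """WS of one pair's evidence LLS values; None when no value reaches T.

    T filters individual summands before ranking, so a below-threshold
    value neither contributes nor shifts the rank of the others.
    """
    surviving = sorted((s for s in scores if s >= params.T), reverse=True)
    if not surviving:
        return None
    total = surviving[0]
    for i, s in enumerate(surviving[1:], start=1):
        total += s / (params.D * i)
    return total


def integrate_networks(
    nets: Sequence[ScoredNetwork],
    params: WSParams = WSParams(),
) -> ScoredNetwork:
    """Integrate evidence networks into one WS-scored network.

    Each input network contributes at most one LLS per pair; a pair
    absent from a network simply contributes nothing.  Provenance is the
    union of the evidence codes of the contributing (>= T) values.  Two
    input networks carrying the same evidence code must not overlap in
    pairs: such inputs need a within-data-type merge first.
    """
    if not nets:
        raise ValueError("need at least one network to integrate")
    _check_duplicate_codes(nets)

    stacks: dict[GenePair, list[tuple[float, frozenset[str]]]] = {}
    for net in nets:
        for pair, w in net.links.items():
            stacks.setdefault(pair, []).append((w, net.provenance.get(pair, frozenset())))

    out = ScoredNetwork()
    for pair, contribs in stacks.items():
        # ties in LLS broken by evidence-code order for a deterministic stack
        contribs.sort(key=lambda t: (-t[0], tuple(sorted(t[1]))))
        surviving = [(w, codes) for w, codes in contribs if w >= params.T]
        if not surviving:
            continue
        ws = weighted_sum([w for w, _ in surviving], params)
        assert ws is not None
        codes: frozenset[str] = frozenset().union(*(c for _, c in surviving))
        out.add(pair, ws, codes)
    return out


def _check_duplicate_codes(nets: Sequence[ScoredNetwork]) -> None:
    for i, net_a in enumerate(nets):
        codes_a = {c for codes in net_a.provenance.values() for c in codes}
        for net_b in nets[i + 1 :]:
            codes_b = {c for codes in net_b.provenance.values() for c in codes}
            shared = codes_a & codes_b
            if shared and set(net_a.links) & set(net_b.links):
                raise ValueError(
                    f"evidence code(s) {sorted(shared)} appear in two input "
                    "networks with overlapping pairs; merge those networks "
                    "within the data type before integration"
                )


def tune_ws(
    nets: Sequence[ScoredNetwork],
    gold: GoldStandard,
    d_grid: Sequence[float],
    t_grid: Sequence[float],
    seed: int = 0,
) -> WSParams:
    """Select (D, T) on a grid by held-out gold-standard ranking quality.

    The gold positives are split in half (seeded); for each candidate
    (D, T) the integrated network is scored by the area under its
    cumulative accuracy-vs-coverage curve where "accurate" means the
    pair belongs to the held-out positive half and "evaluable" means
    both endpoints are annotated.  Degenerate single-value grids are
    returned as-is with a warning.
    """
    if not d_grid or not t_grid:
        raise ValueError("parameter grids must be nonempty")
    if len(d_grid) == 1 and len(t_grid) == 1:
        logger.warning("degenerate (D, T) grid; returning its only candidate")
        return WSParams(D=d_grid[0], T=t_grid[0])

    rng = np.random.default_rng(seed)
    positives = sorted(gold.positives)
    rng.shuffle(positives)
    held_out = frozenset(positives[len(positives) // 2 :])
    logger.info("tune_ws: %d of %d positives held out (seed %d)", len(held_out), len(positives), seed)

    from cofunet.assessment import _curve_area_from_predicates

    annotated = gold.annotated_genes
    best: tuple[float, WSParams] | None = None
    for d in d_grid:
        for t in t_grid:
            params = WSParams(D=d, T=t)
            net = integrate_networks(nets, params)
            if len(net) == 0:
                area = float("-inf")
            else:
                area = _curve_area_from_predicates(
                    net,
                    evaluable=lambda p: p[0] in annotated and p[1] in annotated,
                    shares=lambda p: p in held_out,
                    bin_size=max(1, len(net) // 20),
                    total_genes=len(annotated),
                )
            # strict > keeps the first grid entry on ties (deterministic)
            if best is None or area > best[0]:
                best = (area, params)
    assert best is not None
    return best[1]
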