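"""Domain types and file I/O shared by every pipeline stage.

Gene identifiers are opaque strings (b-numbers or symbols); no alias
resolution is attempted.  Every unordered gene pair is stored exactly
once, as a lexicographically sorted 2-tuple, because cofunctional links
are symmetric and direction never carries meaning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("cofunet.core_io")

GenePair = tuple[str, str]

#: header comment written at the top of every network edge file
NETWORK_HEADER = "# cofunet network; edge weights are log-likelihood scores in natural-log units"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def gene_pair(a: str, b: str) -> GenePair:
    """Return the canonical (sorted) representation of an unordered pair.

    Raises ValueError for self-pairs: a link from a gene to itself is
    meaningless in a cofunctional network.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class EvidenceLinkSet:
    """Raw-scored gene pairs from one evidence source.

    ``higher_is_better`` declares the orientation of the raw score axis
    (True for e.g. -log10 p-values or correlations, False for ranks or
    distances where smaller means stronger evidence).
    """

    evidence_code: str
    links: dict[GenePair, float] = field(default_factory=dict)
    higher_is_better: bool = True

    def __len__(self) -> int:
        return len(self.links)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.links:
            out.add(a)
            out.add(b)
        return out

    def add(self, a: str, b: str, score: float) -> None:
        """Insert a link, collapsing duplicates by keeping the better score."""
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for ({a}, {b}): {score}")
        pair = gene_pair(a, b)
        if pair in self.links:
            old = self.links[pair]
            better = max(old, score) if self.higher_is_better else min(old, score)
            self.links[pair] = better
        else:
            self.links[pair] = score


@dataclass
class ScoredNetwork:
    """LLS-weighted unordered gene pairs with per-pair evidence provenance."""

    links: dict[GenePair, float] = field(default_factory=dict)
    provenance: dict[GenePair, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.links)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.links:
            out.add(a)
            out.add(b)
        return out

    def add(self, pair: GenePair, weight: float, codes: Iterable[str]) -> None:
        if not math.isfinite(weight):
            raise ValueError(f"non-finite weight for {pair}: {weight}")
        self.links[pair] = weight
        self.provenance[pair] = frozenset(codes)

    def sorted_links(self) -> list[tuple[GenePair, float]]:
        """Links by descending weight; ties broken by pair lexicographic order."""
        return sorted(self.links.items(), key=lambda kv: (-kv[1], kv[0]))

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Gene -> {neighbor -> weight} map, built once and cached until
        the link set changes size."""
        cached = getattr(self, "_adjacency", None)
        if cached is not None and cached[0] == len(self.links):
            return cached[1]
        adj: dict[str, dict[str, float]] = {}
        for (a, b), w in self.links.items():
            adj.setdefault(a, {})[b] = w
            adj.setdefault(b, {})[a] = w
        self._adjacency = (len(self.links), adj)
        return adj

    def neighbors(self, gene: str) -> dict[str, float]:
        """Map neighbor -> edge weight for one gene."""
        return dict(self.adjacency().get(gene, {}))


@dataclass
class TermInfo:
    """Per-term metadata carried alongside the member set."""

    source: str = "other"  # GO-BP | EcoCyc | MetaCyc | other
    evidence_codes: frozenset[str] = frozenset()
    superpathway: bool = False


@dataclass
class AnnotationTable:
    """Term -> member-gene-set table with per-term source/evidence metadata."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    info: dict[str, TermInfo] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out

    def add_term(self, term_id: str, members: Iterable[str], info: TermInfo | None = None) -> None:
        if term_id in self.terms:
            raise ParseError(f"duplicate term id: {term_id}")
        self.terms[term_id] = set(members)
        self.info[term_id] = info or TermInfo()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(
    path: str | Path,
    evidence_code: str = "NA",
    higher_is_better: bool = True,
) -> EvidenceLinkSet:
    """Read a 3-column TSV (geneA, geneB, score) into an EvidenceLinkSet.

    Pairs are canonicalized; self-pairs are skipped with a logged count;
    duplicate pairs collapse to the better score under the declared
    orientation.  An optional single header line (non-numeric third
    column) is tolerated.
    """
    ev = EvidenceLinkSet(evidence_code=evidence_code, higher_is_better=higher_is_better)
    skipped_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}")
            a, b, score_s = fields[0], fields[1], fields[2]
            try:
                score = float(score_s)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric score {score_s!r}") from None
            if a == b:
                skipped_self += 1
                continue
            ev.add(a, b, score)
    if skipped_self:
        logger.warning("%s: skipped %d self-pair rows", path, skipped_self)
    return ev


def read_gene_sets(path: str | Path) -> AnnotationTable:
    """Read a GMT-style gene-set file.

    Column 1 is the term id, column 2 a description that may carry
    ``key=value`` metadata pairs separated by ``;`` (recognised keys:
    ``source``, ``evidence`` with comma-separated GO evidence codes,
    ``superpathway``), remaining columns are member genes.  Terms with
    zero members are dropped with a warning; duplicate term ids are an
    error.
    """
    table = AnnotationTable()
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                if len(fields) == 2:
                    # term with zero member genes
                    dropped += 1
                    logger.warning("%s:%d: term %r has no member genes; dropped", path, lineno, fields[0])
                    continue
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}")
            term_id, desc = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            if not members:
                dropped += 1
                logger.warning("%s:%d: term %r has no member genes; dropped", path, lineno, term_id)
                continue
            info = _parse_term_desc(desc)
            if term_id in table.terms:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            table.add_term(term_id, members, info)
    if dropped:
        logger.warning("%s: dropped %d empty terms", path, dropped)
    return table


def _parse_term_desc(desc: str) -> TermInfo:
    source = "other"
    evidence: frozenset[str] = frozenset()
    superpathway = False
    for chunk in desc.split(";"):
        if "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key == "source":
            source = value
        elif key == "evidence":
            evidence = frozenset(c.strip() for c in value.split(",") if c.strip())
        elif key == "superpathway":
            superpathway = value.lower() in {"1", "true", "yes"}
    return TermInfo(source=source, evidence_codes=evidence, superpathway=superpathway)


def write_gene_sets(table: AnnotationTable, path: str | Path) -> None:
    """Write an AnnotationTable in the GMT dialect read_gene_sets parses."""
    with open(path, "w") as fh:
        for term_id in sorted(table.terms):
            info = table.info[term_id]
            meta = [f"source={info.source}"]
            if info.evidence_codes:
                meta.append("evidence=" + ",".join(sorted(info.evidence_codes)))
            if info.superpathway:
                meta.append("superpathway=true")
            members = "\t".join(sorted(table.terms[term_id]))
            fh.write(f"{term_id}\t{';'.join(meta)}\t{members}\n")


def write_network(net: ScoredNetwork, path: str | Path) -> None:
    """Write a ScoredNetwork as TSV: geneA, geneB, LLS, evidence codes.

    Rows are sorted by descending LLS, ties by pair lexicographic order,
    so repeated writes of the same network are byte-identical.  Weights
    are emitted at full double precision (repr round-trip).
    """
    with open(path, "w") as fh:
        fh.write(NETWORK_HEADER + "\n")
        for (a, b), w in net.sorted_links():
            codes = ",".join(sorted(net.provenance.get((a, b), frozenset())))
            fh.write(f"{a}\t{b}\t{w!r}\t{codes}\n")


def read_network(path: str | Path) -> ScoredNetwork:
    """Read a network edge file written by write_network."""
    net = ScoredNetwork()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
            codes = frozenset(c for c in fields[3].split(",") if c) if len(fields) > 3 else frozenset()
            net.add(gene_pair(a, b), w, codes)
    return net


def read_matrix(path: str | Path):
    """Read a TSV matrix: first column row ids, header row of column ids."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a plain ``key=value`` configuration file (``#`` comments)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.strip()
    return cfg


def setup_logging(verbose: bool = False) -> None:
    """Configure stderr logging for the CLI."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
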