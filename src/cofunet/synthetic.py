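"""Synthetic inputs with controlled statistical structure.

Every input class the pipeline consumes — annotation tables, raw
evidence link sets, expression matrices, knockout-phenotype matrices,
planted-module networks — can be generated here, seeded and
bit-reproducible, in the exact external file formats of
:mod:`cofunet.core_io`, so every stage (including the CLI) is testable
without any external resource.

One integer seed drives a root generator; per-stage sub-generators are
derived by hashing the stage name, so adding a stage never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import comb, isqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cofunet.core_io import (
    AnnotationTable,
    EvidenceLinkSet,
    GenePair,
    ScoredNetwork,
    TermInfo,
    gene_pair,
)
from cofunet.gold_standard import GoldStandard


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the
    root seed and the stage name (stable across runs and platforms)."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


#: (distribution name, parameters): normal(mu, sigma), exponential(scale),
#: uniform(lo, hi)
DistSpec = tuple[str, tuple[float, ...]]


def sample_dist(rng: np.random.Generator, dist: DistSpec, size: int) -> np.ndarray:
    name, params = dist
    if name == "normal":
        return rng.normal(params[0], params[1], size)
    if name == "exponential":
        return rng.exponential(params[0], size)
    if name == "uniform":
        return rng.uniform(params[0], params[1], size)
    raise ValueError(f"unknown distribution {name!r}")


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------


def annotation_fixture(
    n_genes: int,
    target_positive_pairs: int,
    gene_prefix: str = "g",
    source: str = "GO-BP",
    evidence: str = "IDA",
) -> AnnotationTable:
    """Annotation table with an exact target count of sharing pairs.

    Builds disjoint clique terms greedily (largest C(k, 2) <= remainder
    first) so the within-term pair counts sum exactly to the target;
    when fresh genes run out, overlapping 2-gene terms supply the last
    pairs.  All n_genes end up annotated — leftover genes get singleton
    terms — so the annotated-gene universe is exactly the gene roster.
    """
    if target_positive_pairs > comb(n_genes, 2):
        raise ValueError(
            f"target of {target_positive_pairs} pairs infeasible over {n_genes} genes "
            f"(max {comb(n_genes, 2)})"
        )
    width = len(str(n_genes - 1))
    genes = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    fresh = list(genes)
    table = AnnotationTable()
    info = TermInfo(source=source, evidence_codes=frozenset({evidence}))
    pairs: set[GenePair] = set()
    remaining = target_positive_pairs
    term_no = 0

    while remaining > 0:
        # largest clique the remainder and the fresh-gene pool both allow
        k = min(len(fresh), isqrt(8 * remaining + 1) // 2 + 1)
        while k >= 2 and comb(k, 2) > remaining:
            k -= 1
        if k >= 2:
            members = fresh[:k]
            del fresh[:k]
            table.add_term(f"T{term_no:04d}", members, info)
            term_no += 1
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(gene_pair(a, b))
            remaining -= comb(k, 2)
        else:
            # no 2 fresh genes left: overlapping 2-cliques over used genes
            used = [g for g in genes if g not in fresh]
            placed = False
            for i, a in enumerate(used):
                for b in list(used[i + 1 :]) + fresh:
                    if gene_pair(a, b) not in pairs:
                        table.add_term(f"T{term_no:04d}", [a, b], info)
                        term_no += 1
                        pairs.add(gene_pair(a, b))
                        if b in fresh:
                            fresh.remove(b)
                        remaining -= 1
                        placed = True
                        break
                if placed:
                    break
            if not placed:  # pragma: no cover - guarded by the feasibility check
                raise ValueError("could not place remaining pairs")

    for g in fresh:
        table.add_term(f"S{g}", [g], info)
    return table


def module_annotation(
    module_sizes: Sequence[int],
    n_genes: int,
    gene_prefix: str = "g",
    source: str = "GO-BP",
    evidence: str = "IDA",
) -> tuple[AnnotationTable, list[set[str]]]:
    """Disjoint clique terms of the given sizes (the planted modules),
    plus singleton terms so every gene is annotated.  Returns the table
    and the module gene sets."""
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed the gene count")
    width = len(str(n_genes - 1))
    genes = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    table = AnnotationTable()
    info = TermInfo(source=source, evidence_codes=frozenset({evidence}))
    modules: list[set[str]] = []
    cursor = 0
    for t, size in enumerate(module_sizes):
        members = genes[cursor : cursor + size]
        cursor += size
        table.add_term(f"M{t:03d}", members, info)
        modules.append(set(members))
    for g in genes[cursor:]:
        table.add_term(f"S{g}", [g], info)
    return table, modules


# ---------------------------------------------------------------------------
# evidence fixtures
# ---------------------------------------------------------------------------


def evidence_fixture(
    gold: GoldStandard,
    pos_dist: DistSpec = ("normal", (2.0, 1.0)),
    neg_dist: DistSpec = ("normal", (0.0, 1.0)),
    coverage: float = 1.0,
    rng: np.random.Generator | None = None,
    evidence_code: str = "SYN",
    max_negatives: int | None = None,
) -> EvidenceLinkSet:
    """Raw evidence whose scores separate gold positives from negatives.

    A seeded sample of ``coverage`` of each gold class receives a raw
    score drawn from its class distribution; the negative class can be
    capped (``max_negatives``) since it is quadratic in the gene count.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    ev = EvidenceLinkSet(evidence_code=evidence_code, higher_is_better=True)
    if coverage == 0:
        return ev

    positives = sorted(gold.positives)
    n_pos = round(coverage * len(positives))
    chosen_idx = rng.choice(len(positives), size=n_pos, replace=False)
    pos_scores = sample_dist(rng, pos_dist, n_pos)
    for idx, score in zip(chosen_idx, pos_scores):
        a, b = positives[idx]
        ev.add(a, b, float(score))

    n_neg_target = round(coverage * gold.n_negatives)
    if max_negatives is not None:
        n_neg_target = min(n_neg_target, max_negatives)
    genes = sorted(gold.annotated_genes)
    chosen_neg: set[GenePair] = set()
    # rejection sampling keeps the negative class lazy (never materialized)
    while len(chosen_neg) < n_neg_target:
        need = n_neg_target - len(chosen_neg)
        ii = rng.integers(0, len(genes), size=2 * need + 8)
        jj = rng.integers(0, len(genes), size=2 * need + 8)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            pair = gene_pair(genes[i], genes[j])
            if pair in gold.positives or pair in chosen_neg or pair in ev.links:
                continue
            chosen_neg.add(pair)
            if len(chosen_neg) == n_neg_target:
                break
    neg_scores = sample_dist(rng, neg_dist, len(chosen_neg))
    for pair, score in zip(sorted(chosen_neg), neg_scores):
        ev.add(pair[0], pair[1], float(score))
    return ev


def expression_fixture(
    modules: Sequence[set[str]],
    all_genes: Sequence[str],
    n_samples: int = 20,
    within_corr: float = 0.8,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expression matrix in which module genes share a latent profile.

    Each module has a latent sample profile; a member's expression is
    within_corr * latent + noise.  Non-module genes are pure noise, so
    within-module Pearson correlations are high and between-module ones
    are centred on zero.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    data = rng.normal(0.0, noise_sd, size=(len(all_genes), n_samples))
    index = {g: i for i, g in enumerate(all_genes)}
    for module in modules:
        latent = rng.normal(0.0, 1.0, size=n_samples)
        for g in module:
            if g in index:
                data[index[g]] = within_corr * latent + np.sqrt(
                    max(1 - within_corr**2, 0.0)
                ) * rng.normal(0.0, noise_sd, size=n_samples)
    return pd.DataFrame(data, index=list(all_genes), columns=[f"s{i:03d}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# phenotype and network fixtures
# ---------------------------------------------------------------------------


def phenotype_fixture(
    modules: Sequence[set[str]],
    n_conditions: int,
    defect_rate_in: float = 0.9,
    defect_rate_out: float = 0.05,
    all_genes: Sequence[str] | None = None,
    defect_dist: DistSpec = ("exponential", (2.0,)),
    healthy_dist: DistSpec = ("normal", (0.0, 1.0)),
    threshold: float = -4.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Growth-score matrix with planted gene modules.

    Conditions are assigned to modules round-robin.  A gene in the
    condition's module receives a defective score (strictly below the
    threshold: threshold - 0.5 - |defect draw|) with probability
    ``defect_rate_in``; any other gene with probability
    ``defect_rate_out``; remaining cells draw healthy scores clipped
    above the threshold.
    """
    if not (0 <= defect_rate_in <= 1 and 0 <= defect_rate_out <= 1):
        raise ValueError("defect rates must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    genes = list(all_genes) if all_genes is not None else sorted(set().union(*modules)) if modules else []
    conditions = [f"c{i:03d}" for i in range(n_conditions)]
    scores = np.empty((len(genes), n_conditions))
    gene_to_module = {}
    for m, module in enumerate(modules):
        for g in module:
            gene_to_module.setdefault(g, set()).add(m)
    for j, _cond in enumerate(conditions):
        mod_idx = j % len(modules) if modules else -1
        for i, g in enumerate(genes):
            in_module = mod_idx in gene_to_module.get(g, ())
            rate = defect_rate_in if in_module else defect_rate_out
            if rng.random() < rate:
                scores[i, j] = threshold - 0.5 - abs(sample_dist(rng, defect_dist, 1)[0])
            else:
                healthy = sample_dist(rng, healthy_dist, 1)[0]
                scores[i, j] = max(healthy, threshold + 0.1)
    return pd.DataFrame(scores, index=genes, columns=conditions)


def network_fixture(
    modules: Sequence[set[str]],
    all_genes: Sequence[str],
    p_within: float = 0.8,
    p_between: float = 0.005,
    lls_within: DistSpec = ("uniform", (2.0, 5.0)),
    lls_between: DistSpec = ("uniform", (0.1, 1.0)),
    rng: np.random.Generator | None = None,
    evidence_code: str = "SYN",
) -> ScoredNetwork:
    """Scored network with dense high-LLS planted modules over a sparse
    low-LLS background."""
    rng = rng if rng is not None else np.random.default_rng(0)
    gene_to_module: dict[str, int] = {}
    for m, module in enumerate(modules):
        for g in module:
            gene_to_module[g] = m
    net = ScoredNetwork()
    ordered = sorted(all_genes)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            same = a in gene_to_module and gene_to_module.get(a) == gene_to_module.get(b)
            p, dist = (p_within, lls_within) if same else (p_between, lls_between)
            if rng.random() < p:
                net.add(gene_pair(a, b), float(sample_dist(rng, dist, 1)[0]), {evidence_code})
    return net


# ---------------------------------------------------------------------------
# end-to-end simulation spec
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Study conditions for an end-to-end simulated input collection.

    Defaults are desk-scale stand-ins for the real inputs: a few hundred
    genes with clique-structured annotations, evidence whose positive
    and negative raw scores are drawn from Normal(2, 1) and Normal(0, 1)
    respectively at partial coverage, and a knockout matrix whose
    conditions hit the planted modules.
    """

    seed: int = 0
    n_genes: int = 200
    module_sizes: tuple[int, ...] = (12, 10, 10, 8, 8, 6, 6)
    evidence_codes: tuple[str, ...] = ("CC", "CX", "DC", "GN", "HT", "LC", "PG")
    pos_dist: DistSpec = ("normal", (2.0, 1.0))
    neg_dist: DistSpec = ("normal", (0.0, 1.0))
    coverage: float = 0.5
    max_negatives_per_evidence: int = 5000
    n_conditions: int = 21
    defect_rate_in: float = 0.9
    defect_rate_out: float = 0.02


def simulate_inputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write every input class to ``out_dir`` in the standard formats.

    Produces an annotation GMT, one raw-evidence edge TSV per evidence
    code, an expression matrix TSV, and a knockout growth-score matrix
    TSV.  Identical spec + seed give byte-identical files.
    """
    from cofunet.core_io import write_gene_sets, write_matrix
    from cofunet.gold_standard import gold_standard_from_tables, positives_from_annotation

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, modules = module_annotation(spec.module_sizes, spec.n_genes)
    gold = GoldStandard(
        positives=frozenset(positives_from_annotation(table)),
        annotated_genes=frozenset(table.genes()),
    )
    paths: dict[str, Path] = {}

    paths["annotations"] = out_dir / "annotations.gmt"
    write_gene_sets(table, paths["annotations"])

    for code in spec.evidence_codes:
        ev = evidence_fixture(
            gold,
            pos_dist=spec.pos_dist,
            neg_dist=spec.neg_dist,
            coverage=spec.coverage,
            rng=derive_rng(spec.seed, f"evidence:{code}"),
            evidence_code=code,
            max_negatives=spec.max_negatives_per_evidence,
        )
        path = out_dir / f"evidence_{code}.tsv"
        with open(path, "w") as fh:
            for (a, b), score in sorted(ev.links.items()):
                fh.write(f"{a}\t{b}\t{score!r}\n")
        paths[f"evidence_{code}"] = path

    genes = sorted(gold.annotated_genes)
    expr = expression_fixture(modules, genes, rng=derive_rng(spec.seed, "expression"))
    paths["expression"] = out_dir / "expression.tsv"
    write_matrix(expr, paths["expression"])

    pheno = phenotype_fixture(
        modules,
        spec.n_conditions,
        defect_rate_in=spec.defect_rate_in,
        defect_rate_out=spec.defect_rate_out,
        all_genes=genes,
        rng=derive_rng(spec.seed, "phenotype"),
    )
    paths["phenotypes"] = out_dir / "phenotypes.tsv"
    write_matrix(pheno, paths["phenotypes"])
    return paths
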