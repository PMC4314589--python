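"""Per-data-type raw scorers: closed forms, oracles, invariances."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from cofunet.evidence_scorers import (
    ArticleGeneIndex,
    DomainTable,
    GeneLocus,
    GenomeContext,
    ProfileMatrix,
    _poisson_binomial_upper_tail,
    cocitation_pvalue,
    cocitation_score,
    coexpression_pcc,
    domain_wmi,
    gn_distance_score,
    gn_probability_score,
    phyloprofile_mi,
    ppi_to_linkset,
)


def _index(n_articles, m, n, k):
    """Index with N articles; gene a in the first m, gene b in k of those
    plus (n - k) others."""
    idx = ArticleGeneIndex()
    for i in range(n_articles):
        idx.articles[f"pmc{i}"] = set()
    for i in range(m):
        idx.articles[f"pmc{i}"].add("a")
    for i in range(k):
        idx.articles[f"pmc{i}"].add("b")
    for i in range(m, m + n - k):
        idx.articles[f"pmc{i}"].add("b")
    return idx


class TestCocitation:
    @pytest.mark.parametrize(
        "N, m, n, k, expected",
        [
            (10, 2, 2, 2, 1 / 45),  # C(2,2)C(8,0)/C(10,2)
            (10, 2, 2, 0, 1.0),  # P(X >= 0)
            (10, 2, 2, 1, 17 / 45),  # tail sum
        ],
    )
    def test_closed_form_values(self, N, m, n, k, expected):
        idx = _index(N, m, n, k)
        assert cocitation_pvalue(idx, "a", "b") == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """For N <= 12, the upper-tail p equals the fraction of all
        C(N, n) placements of gene b's articles whose overlap with gene
        a's articles is at least the observed overlap."""
        for N, m, n, k in [(8, 3, 4, 2), (10, 5, 3, 1), (12, 6, 6, 3), (7, 2, 5, 2)]:
            idx = _index(N, m, n, k)
            a_set = set(range(m))
            hits = sum(
                1
                for b_set in itertools.combinations(range(N), n)
                if len(a_set & set(b_set)) >= k
            )
            assert cocitation_pvalue(idx, "a", "b") == pytest.approx(
                hits / comb(N, n), abs=1e-12
            )

    def test_unindexed_gene_gives_no_score(self):
        idx = _index(5, 2, 2, 1)
        assert cocitation_pvalue(idx, "a", "ghost") is None

    def test_score_is_negative_log10(self):
        idx = _index(10, 2, 2, 2)
        assert cocitation_score(idx, "a", "b") == pytest.approx(-math.log10(1 / 45))


class TestCoexpression:
    def _matrix(self, rows):
        return pd.DataFrame(rows).T  # dict of gene -> samples

    def test_identical_rows_correlate_perfectly(self):
        x = list(range(9))
        mat = pd.DataFrame([x, x], index=["a", "b"], columns=[f"s{i}" for i in range(9)])
        assert coexpression_pcc(mat, "a", "b") == pytest.approx(1.0)

    def test_negated_row_anticorrelates(self):
        x = np.arange(9.0)
        mat = pd.DataFrame([x, -x], index=["a", "b"])
        assert coexpression_pcc(mat, "a", "b") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.arange(1.0, 10.0)
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8, 90.0])
        mat = pd.DataFrame([x, y], index=["a", "b"])
        r = coexpression_pcc(mat, "a", "b")
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(float(expected), abs=1e-12)

    def test_too_few_shared_samples_unscored(self):
        x = np.arange(9.0)
        y = x.copy()
        y[0] = np.nan  # 8 shared samples < 9
        mat = pd.DataFrame([x, y], index=["a", "b"])
        assert coexpression_pcc(mat, "a", "b") is None

    def test_zero_variance_unscored(self):
        mat = pd.DataFrame([np.arange(9.0), np.ones(9)], index=["a", "b"])
        assert coexpression_pcc(mat, "a", "b") is None


class TestDomainWMI:
    def _table(self):
        return DomainTable(
            domains={
                "p1": {"d1", "d2"},
                "p2": {"d1", "d2"},
                "p3": {"d3"},
                "p4": {"d3"},
                "p5": {"d3", "d4"},
                "p6": {"d3", "d4"},
                "p7": {"d4"},
                "p8": {"d4"},
            },
            proteome_size=8,
        )

    def test_no_shared_domain_scores_zero(self):
        assert domain_wmi(self._table(), "p1", "p3") == 0.0

    def test_rarity_bits_of_one_shared_domain(self):
        # d1 carried by 2 of 8 proteins: -log2(0.25) = 2 bits; d2 likewise
        table = DomainTable(
            domains={"p1": {"d1"}, "p2": {"d1"}, "p3": set(), "p4": set(),
                     "p5": set(), "p6": set(), "p7": set(), "p8": set()},
            proteome_size=8,
        )
        assert domain_wmi(table, "p1", "p2") == pytest.approx(2.0)

    def test_each_shared_domain_adds_its_rarity(self):
        # sharing a second domain with frequency 0.5 adds exactly 1 bit
        t1 = DomainTable(domains={"p1": {"d"}, "p2": {"d"}, "p3": set(), "p4": set()},
                         proteome_size=4)
        base = domain_wmi(t1, "p1", "p2")
        t2 = DomainTable(
            domains={"p1": {"d", "e"}, "p2": {"d", "e"}, "p3": set(), "p4": set()},
            proteome_size=4,
        )
        assert domain_wmi(t2, "p1", "p2") == pytest.approx(base + 1.0)

    def test_deleting_noncarrier_annotation_never_lowers_score(self):
        table = self._table()
        before = domain_wmi(table, "p1", "p2")
        del table.domains["p3"]  # p3 carries neither d1 nor d2; P unchanged
        assert domain_wmi(table, "p1", "p2") >= before


class TestPhyloProfileMI:
    def test_identical_balanced_binary_profiles_give_one_bit(self):
        x = [0.0] * 5 + [1.0] * 5
        mat = pd.DataFrame([x, x], index=["a", "b"], columns=[f"G{i}" for i in range(10)])
        assert phyloprofile_mi(mat, "a", "b", bins=2) == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(2, 10_000)), index=["a", "b"])
        assert phyloprofile_mi(mat, "a", "b", bins=4) < 0.01

    def test_symmetric_in_arguments(self, rng):
        mat = pd.DataFrame(rng.normal(size=(2, 50)), index=["a", "b"])
        assert phyloprofile_mi(mat, "a", "b") == pytest.approx(phyloprofile_mi(mat, "b", "a"))

    def test_invariant_under_monotone_transform(self, rng):
        """Equal-frequency binning makes MI invariant under strictly
        monotone rescaling of either profile."""
        x = rng.normal(size=60)
        y = x + rng.normal(scale=0.5, size=60)
        mat1 = pd.DataFrame([x, y], index=["a", "b"])
        mat2 = pd.DataFrame([np.exp(x), y], index=["a", "b"])
        assert phyloprofile_mi(mat1, "a", "b") == pytest.approx(phyloprofile_mi(mat2, "a", "b"))

    def test_constant_profile_scores_zero_with_warning(self, caplog):
        mat = pd.DataFrame([[1.0] * 10, list(range(10))], index=["a", "b"])
        assert phyloprofile_mi(mat, "a", "b") == 0.0
        assert "degenerate" in caplog.text

    def test_domain_partition_scores_each_column_group(self):
        x = [0.0] * 5 + [1.0] * 5
        cols = [f"G{i}" for i in range(10)]
        profiles = ProfileMatrix(
            values=pd.DataFrame([x, x], index=["a", "b"], columns=cols),
            genome_domains={c: ("Archaea" if i < 4 else "Bacteria") for i, c in enumerate(cols)},
        )
        arch = phyloprofile_mi(profiles, "a", "b", bins=2, columns=profiles.columns_for_domain("Archaea"))
        bact = phyloprofile_mi(profiles, "a", "b", bins=2, columns=profiles.columns_for_domain("Bacteria"))
        assert arch == 0.0  # Archaea columns are all-zero (constant)
        assert bact > 0.0


def _context(entries):
    """entries: genome -> {gene: (replicon, slot, start, end)}, slots per replicon inferred."""
    ctx = GenomeContext()
    for genome, genes in entries.items():
        ctx.loci[genome] = {
            g: GeneLocus(rep, slot, start, end) for g, (rep, slot, start, end) in genes.items()
        }
        ctx.slots[genome] = {}
        for rep, slot, *_ in genes.values():
            ctx.slots[genome][rep] = max(ctx.slots[genome].get(rep, 0), slot + 1)
    return ctx


class TestGeneNeighborhood:
    def test_constant_adjacency_distance(self):
        ctx = _context(
            {
                f"G{i}": {"a": ("chr", 0, 0, 100), "b": ("chr", 1, 150, 250)}
                for i in range(3)
            }
        )
        assert gn_distance_score(ctx, "a", "b") == -50.0

    def test_median_with_different_replicon_cap(self):
        ctx = _context(
            {
                "G0": {"a": ("chr", 0, 0, 100), "b": ("chr", 1, 200, 300)},
                "G1": {"a": ("chr", 0, 0, 100), "b": ("chr", 1, 300, 400)},
                "G2": {"a": ("chr", 0, 0, 100), "b": ("plasmid", 0, 0, 100)},
            }
        )
        # distances {100, 200, cap}; median 200
        assert gn_distance_score(ctx, "a", "b") == -200.0

    def test_never_copresent_gives_no_score(self):
        ctx = _context({"G0": {"a": ("chr", 0, 0, 100)}, "G1": {"b": ("chr", 0, 0, 100)}})
        assert gn_distance_score(ctx, "a", "b") is None
        assert gn_probability_score(ctx, "a", "b") is None

    def test_probability_score_binomial_tail(self):
        """Two genomes of 5 slots (q = 2*1/(5-1) = 0.5 each), orthologs
        adjacent in both: P(X >= 2) = 0.25, score = -log10 0.25."""
        ctx = _context(
            {
                "G0": {"a": ("chr", 0, 0, 90), "b": ("chr", 1, 100, 190)},
                "G1": {"a": ("chr", 2, 200, 290), "b": ("chr", 3, 300, 390)},
            }
        )
        for g in ("G0", "G1"):
            ctx.slots[g]["chr"] = 5
        score = gn_probability_score(ctx, "a", "b", window=1, min_genomes=2)
        assert score == pytest.approx(-math.log10(0.25), abs=1e-12)

    def test_no_neighbor_genomes_score_zero(self):
        ctx = _context(
            {
                f"G{i}": {"a": ("chr", 0, 0, 90), "b": ("chr", 4, 400, 490)}
                for i in range(3)
            }
        )
        for g in ctx.slots:
            ctx.slots[g]["chr"] = 100
        assert gn_probability_score(ctx, "a", "b", window=1) == pytest.approx(0.0, abs=1e-9)

    def test_poisson_binomial_matches_enumeration(self, rng):
        """DP upper tail equals brute-force enumeration over all 2^G
        neighbor/non-neighbor outcomes."""
        for _ in range(20):
            qs = rng.uniform(0.05, 0.95, size=6)
            k = int(rng.integers(0, 7))
            brute = 0.0
            for outcome in itertools.product([0, 1], repeat=6):
                if sum(outcome) >= k:
                    p = 1.0
                    for q, o in zip(qs, outcome):
                        p *= q if o else 1 - q
                    brute += p
            assert _poisson_binomial_upper_tail(qs, k) == pytest.approx(brute, abs=1e-12)

    def test_tail_monotone_in_hit_count(self):
        qs = [0.3] * 5
        tails = [_poisson_binomial_upper_tail(qs, k) for k in range(6)]
        assert tails == sorted(tails, reverse=True)


class TestPPI:
    def test_unique_interactions_score_one(self):
        ev = ppi_to_linkset([("a", "b"), ("c", "d"), ("e", "f")], "LC", source="intact")
        assert len(ev) == 3
        assert set(ev.links.values()) == {1.0}
        assert ev.evidence_code == "LC:intact"

    def test_duplicate_edge_in_two_sources_stays_in_both(self):
        s1 = ppi_to_linkset([("a", "b")], "HT", source="apms")
        s2 = ppi_to_linkset([("a", "b")], "HT", source="y2h")
        assert ("a", "b") in s1.links and ("a", "b") in s2.links
        assert s1.evidence_code != s2.evidence_code

    def test_self_interaction_dropped(self, caplog):
        ev = ppi_to_linkset([("a", "a"), ("a", "b")], "LC")
        assert len(ev) == 1
        assert "self-interaction" in caplog.text


class TestLabelInvariance:
    """Scrambling gene labels consistently across inputs leaves every raw
    score identical."""

    def test_cocitation_and_wmi_and_mi_label_invariant(self, rng):
        relabel = {"a": "zz9", "b": "qq3"}

        idx1 = _index(10, 4, 3, 2)
        idx2 = ArticleGeneIndex(
            articles={
                art: {relabel.get(g, g) for g in genes} for art, genes in idx1.articles.items()
            }
        )
        assert cocitation_pvalue(idx1, "a", "b") == cocitation_pvalue(idx2, "zz9", "qq3")

        t1 = DomainTable(domains={"a": {"d1"}, "b": {"d1"}, "c": {"d2"}}, proteome_size=5)
        t2 = DomainTable(
            domains={relabel.get(p, p): ds for p, ds in t1.domains.items()}, proteome_size=5
        )
        assert domain_wmi(t1, "a", "b") == domain_wmi(t2, "zz9", "qq3")

        vals = rng.normal(size=(2, 40))
        m1 = pd.DataFrame(vals, index=["a", "b"])
        m2 = pd.DataFrame(vals, index=["zz9", "qq3"])
        assert phyloprofile_mi(m1, "a", "b") == phyloprofile_mi(m2, "zz9", "qq3")
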