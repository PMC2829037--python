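"""Domain coverage, family construction, pair selection and chaining."""

import numpy as np
import pytest

from _oracles import best_chain_size_oracle
from linspec.annotation_io import SequenceRecord
from linspec.paralog_segdup import (
    CollinearChain,
    DomainAnnotation,
    GenePair,
    build_families,
    chain_collinear_pairs,
    cluster_novel_domains,
    fraction_in_blocks,
    select_similar_pairs,
    uncovered_regions,
    _best_chain,
)


class TestUncoveredRegions:
    def test_interval_complement_with_min_length(self):
        regions = uncovered_regions(200, [DomainAnnotation("p", 50, 100, "D1")])
        assert regions == [(101, 200)]  # [1,49] dropped: 49 < 75

    def test_no_domains_whole_protein(self):
        assert uncovered_regions(100, []) == [(1, 100)]

    def test_random_layouts_match_position_mask(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            plen = int(rng.integers(100, 400))
            domains = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(1, plen))
                e = int(rng.integers(s, min(plen, s + 120) + 1))
                domains.append(DomainAnnotation("p", s, e, "D"))
            mask = np.zeros(plen + 1, dtype=bool)
            for d in domains:
                mask[d.start : d.end + 1] = True
            runs, start = [], None
            for pos in range(1, plen + 1):
                if not mask[pos] and start is None:
                    start = pos
                if mask[pos] and start is not None:
                    runs.append((start, pos - 1))
                    start = None
            if start is not None:
                runs.append((start, plen))
            expected = [r for r in runs if r[1] - r[0] + 1 >= 75]
            assert uncovered_regions(plen, domains) == expected


def _protein(rng, n):
    return "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n)])


class TestNovelDomains:
    def test_identical_regions_cluster(self):
        rng = np.random.default_rng(41)
        seq = _protein(rng, 80)
        regions = [SequenceRecord("r1", seq), SequenceRecord("r2", seq)]
        mapping = cluster_novel_domains(regions)
        assert mapping["r1"] == mapping["r2"]

    def test_unrelated_regions_do_not_cluster(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            regions = [
                SequenceRecord("r1", _protein(rng, 80)),
                SequenceRecord("r2", _protein(rng, 80)),
            ]
            assert cluster_novel_domains(regions) == {}

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(43)
        a = _protein(rng, 100)
        # B shares its first 80 aa with A and its last 80 with C; A and C
        # share nothing
        b = a[:80] + _protein(rng, 80)
        c = b[80:] + _protein(rng, 20)
        regions = [
            SequenceRecord("A", a),
            SequenceRecord("B", b),
            SequenceRecord("C", c),
        ]
        mapping = cluster_novel_domains(regions)
        assert len({mapping["A"], mapping["B"], mapping["C"]}) == 1


class TestFamilies:
    def test_shared_domain_linkage(self):
        domains = [
            DomainAnnotation("P1", 1, 50, "D1"),
            DomainAnnotation("P2", 1, 50, "D1"),
            DomainAnnotation("P2", 60, 120, "D2"),
            DomainAnnotation("P3", 1, 50, "D2"),
        ]
        families, fraction = build_families(["P1", "P2", "P3"], domains)
        assert len(families) == 1
        assert families[0].members == frozenset({"P1", "P2", "P3"})
        assert fraction == 1.0

    def test_identical_composition_mode_splits(self):
        domains = [
            DomainAnnotation("P1", 1, 50, "D1"),
            DomainAnnotation("P2", 1, 50, "D1"),
            DomainAnnotation("P2", 60, 120, "D2"),
            DomainAnnotation("P3", 1, 50, "D2"),
        ]
        families, _ = build_families(["P1", "P2", "P3"], domains, mode="identical")
        assert families == []  # all compositions distinct

    def test_domainless_proteins_unclassified(self):
        families, fraction = build_families(["P1", "P2"], [])
        assert families == [] and fraction == 0.0

    def test_planted_two_member_families(self):
        domains = []
        proteins = []
        for i in range(10):
            for j in (1, 2):
                pid = f"F{i}P{j}"
                proteins.append(pid)
                domains.append(DomainAnnotation(pid, 1, 80, f"D{i}"))
        families, fraction = build_families(proteins, domains)
        assert len(families) == 10 and fraction == 1.0

    def test_order_invariance(self):
        domains = [
            DomainAnnotation("P1", 1, 50, "D1"),
            DomainAnnotation("P2", 1, 50, "D1"),
        ]
        f1, _ = build_families(["P1", "P2"], domains)
        f2, _ = build_families(["P2", "P1"], domains)
        assert [f.members for f in f1] == [f.members for f in f2]


class TestSimilarPairs:
    def test_truncation_and_dedup(self):
        rng = np.random.default_rng(51)
        base = _protein(rng, 150)
        proteins = {f"g{i}": SequenceRecord(f"g{i}", base) for i in range(8)}
        pairs = select_similar_pairs(proteins, max_hits_per_query=5)
        # 8 identical proteins: per query <= 5 subjects; all unordered pairs
        per_gene = {}
        for a, b, _ in pairs:
            per_gene[a] = per_gene.get(a, 0) + 1
            per_gene[b] = per_gene.get(b, 0) + 1
        assert all(n <= 10 for n in per_gene.values())
        assert len(pairs) == len({frozenset((a, b)) for a, b, _ in pairs})

    def test_unrelated_proteins_no_pairs(self):
        rng = np.random.default_rng(52)
        proteins = {
            f"g{i}": SequenceRecord(f"g{i}", _protein(rng, 100)) for i in range(4)
        }
        assert select_similar_pairs(proteins) == []


def _pair(x, y, name=None):
    name = name or f"p{x}"
    return GenePair(name, name + "b", "c1", "c2", x, y)


class TestChaining:
    def test_perfect_diagonal_single_chain(self):
        pairs = [_pair(i * 10_000, i * 10_000) for i in range(5)]
        chains = chain_collinear_pairs(pairs, max_gap=100_000, min_pairs=4)
        assert len(chains) == 1 and chains[0].score == 5

    def test_large_gap_breaks_chain(self):
        xs = [0, 10_000, 20_000, 30_000, 190_000]
        pairs = [_pair(x, x) for x in xs]
        chains = chain_collinear_pairs(pairs, max_gap=100_000, min_pairs=4)
        assert len(chains) == 1 and chains[0].score == 4

    def test_self_diagonal_excluded(self):
        pairs = [GenePair("g1", "g1", "c1", "c1", 5.0, 5.0)]
        assert chain_collinear_pairs(pairs, min_pairs=1) == []

    def test_dp_matches_subset_enumeration(self):
        rng = np.random.default_rng(61)
        for trial in range(120):
            n = int(rng.integers(1, 9))
            max_gap = float(rng.choice([30, 60, 1000]))
            points = [
                (float(rng.integers(0, 200)), float(rng.integers(0, 200)))
                for _ in range(n)
            ]
            pairs = [
                GenePair(f"a{i}", f"b{i}", "c1", "c2", x, y)
                for i, (x, y) in enumerate(points)
            ]
            ordered = sorted(pairs, key=lambda p: (p.pos_a, p.pos_b))
            dp = len(_best_chain(ordered, max_gap))
            assert dp == best_chain_size_oracle(points, max_gap)

    def test_score_monotone_in_max_gap(self):
        rng = np.random.default_rng(62)
        points = [(float(x), float(x + rng.integers(-5, 6))) for x in range(0, 500, 40)]
        pairs = [
            GenePair(f"a{i}", f"b{i}", "c1", "c2", x, y)
            for i, (x, y) in enumerate(points)
        ]
        sizes = []
        for gap in (20, 50, 100, 1000):
            ordered = sorted(pairs, key=lambda p: (p.pos_a, p.pos_b))
            sizes.append(len(_best_chain(ordered, gap)))
        assert sizes == sorted(sizes)


class TestBlockFractions:
    def test_no_chains_everything_outside(self):
        positions = {"g1": ("c1", 100.0), "g2": ("c1", 200.0)}
        labels = {"g1": "A", "g2": "A"}
        pct, _ = fraction_in_blocks(positions, labels, [])
        assert pct == {"A": 100.0}

    def test_boundary_is_inclusive(self):
        chain = CollinearChain(
            pairs=[
                GenePair("a1", "b1", "c1", "c2", 100.0, 500.0),
                GenePair("a2", "b2", "c1", "c2", 300.0, 700.0),
            ],
            score=2,
        )
        positions = {"edge": ("c1", 300.0), "out": ("c1", 301.0)}
        labels = {"edge": "A", "out": "A"}
        pct, _ = fraction_in_blocks(positions, labels, [chain])
        assert pct == {"A": 50.0}

    def test_planted_block_genes_inside(self):
        pairs = [
            GenePair(f"L{i}", f"R{i}", "c1", "c1", 1000.0 * i, 50_000.0 + 1000.0 * i)
            for i in range(10)
        ]
        chains = chain_collinear_pairs(pairs, max_gap=100_000, min_pairs=4)
        positions = {}
        labels = {}
        for i in range(10):
            positions[f"L{i}"] = ("c1", 1000.0 * i)
            positions[f"R{i}"] = ("c1", 50_000.0 + 1000.0 * i)
            labels[f"L{i}"] = labels[f"R{i}"] = "dup"
        positions["far"] = ("c1", 900_000.0)
        labels["far"] = "dup"
        pct, _ = fraction_in_blocks(positions, labels, chains)
        assert pct["dup"] == pytest.approx(round(100 * 1 / 21, 1))
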