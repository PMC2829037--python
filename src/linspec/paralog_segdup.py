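"""Paralogous families and segmental duplication.

Family construction follows the curated-plus-novel-domain scheme: peptide
regions not covered by curated domain annotations are clustered by pairwise
homology (>45% identity over >=75 aa, E < 1e-3; single linkage) into novel
domains, and proteins sharing at least one domain id (curated or novel) are
linked into families by connected components.

Segmental duplications are detected by selecting similar protein pairs
(all-vs-all search, E < 1e-10, at most 5 subjects per query) and chaining
collinear pairs on the genomic dot-plot by dynamic programming (unit score
per pair; a chain breaks when the gap on either axis exceeds 100 kb;
chains shorter than ``min_pairs`` are discarded), emulating a DAGChainer-
style run with self-comparisons allowed and the trivial self-diagonal
excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .annotation_io import SequenceRecord
from .genic_features import compare_sets
from .homology_search import ScoringScheme, evalue_from_score, local_align
from .lineage_classifier import round_half_up

__all__ = [
    "DomainAnnotation",
    "ParalogFamily",
    "GenePair",
    "CollinearChain",
    "uncovered_regions",
    "cluster_novel_domains",
    "build_families",
    "select_similar_pairs",
    "chain_collinear_pairs",
    "fraction_in_blocks",
]


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    start: int  # aa, 1-based inclusive
    end: int
    domain_id: str
    source: str = "curated"  # curated | novel

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain interval [{self.start},{self.end}]")


@dataclass
class ParalogFamily:
    family_id: str
    members: frozenset[str]
    domain_composition: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a family needs >= 2 members")


@dataclass(frozen=True)
class GenePair:
    """Unordered similar-gene pair with genomic midpoints."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    pos_a: float
    pos_b: float
    evalue: float = 0.0


@dataclass
class CollinearChain:
    pairs: list[GenePair]
    score: int
    chrom_a: str = ""
    chrom_b: str = ""
    block_a: tuple[float, float] = (0.0, 0.0)
    block_b: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pairs:
            self.chrom_a = self.pairs[0].chrom_a
            self.chrom_b = self.pairs[0].chrom_b
            xs = [p.pos_a for p in self.pairs]
            ys = [p.pos_b for p in self.pairs]
            self.block_a = (min(xs), max(xs))
            self.block_b = (min(ys), max(ys))


# ---------------------------------------------------------------------------
# Novel domains


def uncovered_regions(
    protein_length: int,
    domains: list[DomainAnnotation],
    min_len: int = 75,
) -> list[tuple[int, int]]:
    """Maximal intervals not covered by any curated domain, each >= min_len."""
    for d in domains:
        if d.end > protein_length:
            raise ValueError(
                f"domain [{d.start},{d.end}] outside protein length {protein_length}"
            )
    covered = sorted((d.start, d.end) for d in domains)
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    prev_end = 0
    for s, e in merged + [[protein_length + 1, protein_length + 1]]:
        if s - prev_end - 1 >= min_len:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    return gaps


def cluster_novel_domains(
    regions: list[SequenceRecord],
    scheme: ScoringScheme | None = None,
    min_identity: float = 0.45,
    min_aln_len: int = 75,
    e_cutoff: float = 1e-3,
) -> dict[str, str]:
    """Single-linkage clustering of uncovered regions into novel domains.

    An edge joins two regions when their local alignment has identity
    > ``min_identity`` over >= ``min_aln_len`` aligned columns with
    E < ``e_cutoff`` (all-vs-all). Singletons receive no domain id.
    Returns region id -> novel domain id.
    """
    scheme = scheme or ScoringScheme()
    n_total = sum(len(r) for r in regions) or 1
    parent = {r.id: r.id for r in regions}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(regions, 2):
        score, ident, alen = local_align(a, b, scheme)
        if alen < min_aln_len or ident <= min_identity:
            continue
        if evalue_from_score(score, len(a), n_total, scheme) < e_cutoff:
            parent[find(a.id)] = find(b.id)

    clusters: dict[str, list[str]] = {}
    for r in regions:
        clusters.setdefault(find(r.id), []).append(r.id)
    assignment: dict[str, str] = {}
    novel_idx = 0
    for root in sorted(clusters):
        members = clusters[root]
        if len(members) < 2:
            continue
        novel_idx += 1
        for rid in members:
            assignment[rid] = f"NOVEL{novel_idx:04d}"
    return assignment


def build_families(
    protein_ids: list[str],
    domains: list[DomainAnnotation],
    mode: str = "linkage",
) -> tuple[list[ParalogFamily], float]:
    """Group proteins into paralogous families by domain composition.

    ``linkage`` (default): connected components of the shared-domain graph.
    ``identical``: proteins grouped by identical domain-id sets.
    Returns the families and the fraction of proteins classified.
    """
    by_protein: dict[str, set[str]] = {p: set() for p in protein_ids}
    for d in domains:
        if d.protein_id in by_protein:
            by_protein[d.protein_id].add(d.domain_id)

    families: list[ParalogFamily] = []
    if mode == "identical":
        groups: dict[frozenset, list[str]] = {}
        for p, doms in by_protein.items():
            if doms:
                groups.setdefault(frozenset(doms), []).append(p)
        members_lists = [m for m in groups.values() if len(m) >= 2]
    elif mode == "linkage":
        by_domain: dict[str, list[str]] = {}
        for p, doms in by_protein.items():
            for d in doms:
                by_domain.setdefault(d, []).append(p)
        parent = {p: p for p in protein_ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for members in by_domain.values():
            for other in members[1:]:
                parent[find(other)] = find(members[0])
        comps: dict[str, list[str]] = {}
        for p, doms in by_protein.items():
            if doms:
                comps.setdefault(find(p), []).append(p)
        members_lists = [m for m in comps.values() if len(m) >= 2]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for i, members in enumerate(sorted(members_lists, key=min), start=1):
        composition = frozenset().union(*(by_protein[p] for p in members))
        families.append(
            ParalogFamily(f"FAM{i:05d}", frozenset(members), composition)
        )
    classified = sum(len(f.members) for f in families)
    fraction = classified / len(protein_ids) if protein_ids else 0.0
    return families, fraction


# ---------------------------------------------------------------------------
# Similar pairs and collinear chaining


def select_similar_pairs(
    proteins: dict[str, SequenceRecord],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-10,
    max_hits_per_query: int = 5,
) -> list[tuple[str, str, float]]:
    """All-vs-all similar pairs: per query keep <= 5 best non-self subjects
    at E < cutoff; pairs deduplicated unordered (best E retained)."""
    scheme = scheme or ScoringScheme()
    n_total = sum(len(r) for r in proteins.values()) or 1
    per_query: dict[str, list[tuple[float, str]]] = {q: [] for q in proteins}
    ids = sorted(proteins)
    for qi, si in itertools.combinations(ids, 2):
        score, _, alen = local_align(proteins[qi], proteins[si], scheme)
        if alen == 0:
            continue
        for a, b in ((qi, si), (si, qi)):
            E = evalue_from_score(score, len(proteins[a]), n_total, scheme)
            if E < e_cutoff:
                per_query[a].append((E, b))
    pairs: dict[frozenset, float] = {}
    for q, hits in per_query.items():
        for E, s in sorted(hits)[:max_hits_per_query]:
            key = frozenset((q, s))
            if key not in pairs or E < pairs[key]:
                pairs[key] = E
    return sorted(
        (min(k), max(k), e) for k, e in pairs.items()
    )


def chain_collinear_pairs(
    pairs: list[GenePair],
    max_gap: float = 100_000,
    min_pairs: int = 4,
) -> list[CollinearChain]:
    """Maximum-score collinear chains on the pair dot-plot.

    Unit score per pair; positions must strictly increase on both axes
    within a chain and consecutive gaps on either axis must not exceed
    ``max_gap``. Chains are extracted greedily best-first without pair
    reuse; chains with fewer than ``min_pairs`` pairs are discarded.
    The trivial self-diagonal (a gene paired with itself) is excluded.
    """
    chains: list[CollinearChain] = []
    by_chrom: dict[tuple[str, str], list[GenePair]] = {}
    for p in pairs:
        if p.gene_a == p.gene_b:
            continue  # self-diagonal
        by_chrom.setdefault((p.chrom_a, p.chrom_b), []).append(p)

    for group in by_chrom.values():
        remaining = sorted(group, key=lambda p: (p.pos_a, p.pos_b))
        while True:
            best = _best_chain(remaining, max_gap)
            if len(best) < min_pairs:
                break
            chains.append(CollinearChain(pairs=best, score=len(best)))
            used = set(id(p) for p in best)
            remaining = [p for p in remaining if id(p) not in used]
    chains.sort(key=lambda c: (-c.score, c.chrom_a, c.block_a))
    return chains


def _best_chain(pairs: list[GenePair], max_gap: float) -> list[GenePair]:
    """DP for the single maximum-cardinality collinear chain."""
    n = len(pairs)
    if n == 0:
        return []
    best_len = [1] * n
    back = [-1] * n
    for i in range(n):
        pi = pairs[i]
        for j in range(i):
            pj = pairs[j]
            if (
                pj.pos_a < pi.pos_a
                and pj.pos_b < pi.pos_b
                and pi.pos_a - pj.pos_a <= max_gap
                and pi.pos_b - pj.pos_b <= max_gap
                and best_len[j] + 1 > best_len[i]
            ):
                best_len[i] = best_len[j] + 1
                back[i] = j
    i = max(range(n), key=lambda k: best_len[k])
    chain = []
    while i != -1:
        chain.append(pairs[i])
        i = back[i]
    return chain[::-1]


def fraction_in_blocks(
    gene_positions: dict[str, tuple[str, float]],
    labels: dict[str, str],
    chains: list[CollinearChain],
) -> tuple[dict[str, float], dict[tuple[str, str], tuple[float, float]]]:
    """Per-label fraction of genes inside duplicated blocks + pairwise chi2.

    A gene is "in a block" iff its midpoint lies within a chain's block
    interval (inclusive ends) on the matching chromosome, on either axis.
    Returns ({label: pct_outside_blocks}, {(label_a, label_b): (chi2, p)});
    percentages rounded half-up to one decimal.
    """
    def in_block(chrom: str, pos: float) -> bool:
        for c in chains:
            if chrom == c.chrom_a and c.block_a[0] <= pos <= c.block_a[1]:
                return True
            if chrom == c.chrom_b and c.block_b[0] <= pos <= c.block_b[1]:
                return True
        return False

    counts: dict[str, list[int]] = {}
    for gid, (chrom, pos) in gene_positions.items():
        label = labels.get(gid)
        if label is None:
            continue
        inside = in_block(chrom, pos)
        counts.setdefault(label, [0, 0])[0 if inside else 1] += 1

    pct_outside = {
        lab: round_half_up(100 * out / (ins + out))
        for lab, (ins, out) in counts.items()
    }
    tests = {}
    for a, b in itertools.combinations(sorted(counts), 2):
        tests[(a, b)] = compare_sets(counts[a], counts[b], "chi_square_proportion")
    return pct_outside, tests
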