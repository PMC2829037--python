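"""Co-expression neighbourhoods and GO term enrichment.

Co-expression is defined against an empirical null: the threshold r* is the
99th percentile of Pearson correlation coefficients over randomly sampled
gene pairs from the compendium, so that ~1% of random pairs exceed it.
Genes correlated with a focal gene above r* (strict, signed r) form its
co-expression neighbourhood. GO term enrichment within a neighbourhood is a
one-sided Fisher exact test per term with Storey q-values (pi0 estimated on
a lambda grid with a cubic-smoother extrapolation; Benjamini-Hochberg as a
fallback for short p-value lists). Five manually curated functional groups
can be tested for over-representation among lineage-specific genes versus
background at a stated FDR.

GO annotations with evidence codes IEP, IEA or RCA (expression-derived or
purely computational) are excluded before any enrichment computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GoAnnotationTable",
    "EnrichmentRecord",
    "EXCLUDED_EVIDENCE_CODES",
    "pearson_cc",
    "estimate_null_threshold",
    "coexpressed_genes",
    "fisher_term_enrichment",
    "estimate_pi0",
    "estimate_qvalues",
    "group_overrepresentation",
]

EXCLUDED_EVIDENCE_CODES = frozenset({"IEP", "IEA", "RCA"})


@dataclass
class ExpressionMatrix:
    """Genes x experiments expression values; NaN marks missing."""

    values: pd.DataFrame  # index: gene ids, columns: experiment ids

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("an expression matrix needs >= 2 experiments")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class GoAnnotationTable:
    """(gene, GO id, GO term, evidence code) records, expression-evidence
    codes filtered out on construction."""

    records: pd.DataFrame  # columns: gene_id, go_id, go_term, evidence_code

    def __post_init__(self) -> None:
        keep = ~self.records["evidence_code"].isin(EXCLUDED_EVIDENCE_CODES)
        self.records = self.records.loc[keep].reset_index(drop=True)

    def genes_for_term(self, go_id: str) -> set[str]:
        mask = self.records["go_id"] == go_id
        return set(self.records.loc[mask, "gene_id"])

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.records["go_id"].unique())

    @classmethod
    def from_tsv(cls, path) -> "GoAnnotationTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentRecord:
    subject_id: str  # focal gene or group id
    go_id: str
    table: tuple[int, int, int, int]  # (in&ann, in&not, out&ann, out&not)
    p_value: float
    q_value: float = math.nan


# ---------------------------------------------------------------------------
# Correlation and the null threshold


def pearson_cc(x, y) -> float:
    """Pearson r over pairwise-complete observations; NaN when undefined
    (fewer than 3 complete pairs or zero variance on either side)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def estimate_null_threshold(
    matrix: ExpressionMatrix,
    n_pairs: int = 1_000_000,
    percentile: float = 99.0,
    seed: int = 0,
) -> float:
    """r* = the given percentile of r over sampled random gene pairs.

    Signed (not absolute) r; pairs are sampled uniformly with a seeded
    generator, so the estimate is deterministic given the seed.
    """
    if n_pairs < 1000:
        raise ValueError("n_pairs must be >= 1000 for a stable percentile")
    rng = np.random.default_rng(seed)
    data = matrix.values.to_numpy(dtype=float)
    valid = (~np.isnan(data)).sum(axis=1) >= 3
    data = data[valid]
    n_genes = data.shape[0]
    if n_genes < 10:
        raise ValueError("too few genes with >= 3 observations")

    i = rng.integers(0, n_genes, size=n_pairs)
    j = rng.integers(0, n_genes, size=n_pairs)
    distinct = i != j
    i, j = i[distinct], j[distinct]

    if np.isnan(data).any():
        rs = np.fromiter(
            (pearson_cc(data[a], data[b]) for a, b in zip(i, j)),
            dtype=float,
            count=i.size,
        )
    else:
        centered = data - data.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            rs = (centered[i] * centered[j]).sum(axis=1) / (norms[i] * norms[j])
    rs = rs[~np.isnan(rs)]
    if rs.size == 0:
        raise ValueError("no defined correlations among sampled pairs")
    return float(np.percentile(rs, percentile))


def coexpressed_genes(
    focal_gene: str, matrix: ExpressionMatrix, r_star: float
) -> set[str]:
    """All genes with r(focal, g) strictly above r*."""
    if focal_gene not in matrix.values.index:
        raise KeyError(f"gene {focal_gene!r} not in the expression matrix")
    x = matrix.profile(focal_gene)
    out = set()
    for gid in matrix.gene_ids:
        if gid == focal_gene:
            continue
        r = pearson_cc(x, matrix.profile(gid))
        if not math.isnan(r) and r > r_star:
            out.add(gid)
    return out


# ---------------------------------------------------------------------------
# Enrichment


def _fisher_one_sided(table: tuple[int, int, int, int]) -> float:
    a, b, c, d = table
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def fisher_term_enrichment(
    gene_set: set[str],
    go: GoAnnotationTable,
    universe: set[str],
    subject_id: str = "",
) -> list[EnrichmentRecord]:
    """One-sided (over-representation) Fisher exact test per GO term.

    Only terms annotating >= 1 universe gene are tested; q-values are
    attached across the tested terms.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not gene_set:
        return []
    records = []
    for go_id in go.term_ids:
        annotated = go.genes_for_term(go_id) & universe
        if not annotated:
            continue
        a = len(gene_set & annotated)
        b = len(gene_set) - a
        c = len(annotated) - a
        d = len(universe) - len(gene_set) - c
        table = (a, b, c, d)
        records.append(
            EnrichmentRecord(subject_id, go_id, table, _fisher_one_sided(table))
        )
    qs = estimate_qvalues([r.p_value for r in records])
    for r, q in zip(records, qs):
        r.q_value = q
    return records


def estimate_pi0(p_values) -> float:
    """Proportion of true nulls, by the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is evaluated on the grid
    0.05..0.95 (step 0.05), a cubic smoother is fitted and extrapolated to
    lambda -> 1; the result is clipped to (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    coeffs = np.polyfit(lam, pi0_lam, 3)
    return min(max(float(np.polyval(coeffs, 1.0)), 1e-8), 1.0)


def estimate_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) by fitting a
    cubic smoother to pi0(lambda) and extrapolating to lambda -> 1, clipped
    to (0, 1]. For fewer than 100 p-values the smoother is unstable and the
    Benjamini-Hochberg procedure (pi0 = 1) is used instead.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        # the smoother is unstable on short lists; fall back to BH (pi0=1)
        pi0 = 1.0 if p.size < 100 else estimate_pi0(p)
    order = np.argsort(p)
    n = p.size
    ranked = p[order] * pi0 * n / np.arange(1, n + 1)
    # step-up: enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (configuration fallback)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def group_overrepresentation(
    lineage_set: set[str],
    background_set: set[str],
    gene_groups: dict[str, str],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of curated functional groups among lineage genes.

    One 2x2 Fisher test per group: (lineage vs background) x (in-group vs
    not). Returns a frame with counts, p, q and a significance flag at the
    requested FDR (BH over the handful of groups).
    """
    groups = sorted(set(gene_groups.values()))
    if not groups:
        raise ValueError("no functional groups supplied")
    rows = []
    for grp in groups:
        members = {g for g, v in gene_groups.items() if v == grp}
        a = len(lineage_set & members)
        b = len(lineage_set) - a
        c = len(background_set & members)
        d = len(background_set) - c
        rows.append(
            {
                "group": grp,
                "lineage_in": a,
                "lineage_out": b,
                "background_in": c,
                "background_out": d,
                "p_value": _fisher_one_sided((a, b, c, d)),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = estimate_qvalues(df["p_value"])
    df["significant"] = df["q_value"] < fdr
    return df
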