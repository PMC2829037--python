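"""Per-gene genic metrics and set-level statistical comparisons.

For each gene (representative model) the module computes exon count, exon /
intron / gene / CDS / protein lengths, GC content of gene, exons, introns and
CDS, GC at the three codon positions, and a single-exon flag. Set-level
summaries report mean, sample SD (n-1) and median per feature; sets are
compared with Welch's unequal-variance t-test or a 2x2 chi-square test on
proportions (no continuity correction).

N bases are excluded from both numerator and denominator of GC fractions;
a GC value over zero informative bases is reported as missing (NaN), not 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    SequenceRecord,
    extract_gene_regions,
    select_representative_model,
)

__all__ = [
    "GeneFeatureVector",
    "compute_feature_vector",
    "summarize_features",
    "compare_sets",
    "gc_content",
]

_FEATURES = (
    "exon_count",
    "gene_length",
    "cds_length",
    "protein_length",
    "mean_exon_length",
    "mean_intron_length",
    "gc_gene",
    "gc_exon",
    "gc_intron",
    "gc_cds",
    "gc_pos1",
    "gc_pos2",
    "gc_pos3",
)


def gc_content(seq: str) -> float:
    """G+C fraction over non-N positions; NaN if no informative base."""
    informative = sum(1 for c in seq if c in "ACGTacgt")
    if informative == 0:
        return math.nan
    gc = sum(1 for c in seq if c in "GCgc")
    return gc / informative


@dataclass
class GeneFeatureVector:
    gene_id: str
    exon_count: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    gene_length: int
    cds_length: int
    protein_length: int
    gc_gene: float
    gc_exon: float
    gc_intron: float
    gc_cds: float
    gc_pos1: float
    gc_pos2: float
    gc_pos3: float

    @property
    def is_single_exon(self) -> bool:
        return self.exon_count == 1

    @property
    def mean_exon_length(self) -> float:
        return float(np.mean(self.exon_lengths))

    @property
    def mean_intron_length(self) -> float:
        return float(np.mean(self.intron_lengths)) if self.intron_lengths else math.nan


def compute_feature_vector(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    regions: dict[str, SequenceRecord] | None = None,
) -> GeneFeatureVector:
    """Genic metrics for one gene's representative model."""
    if regions is None:
        regions = extract_gene_regions(gene, annotation)
    model = select_representative_model(gene)
    exon_seqs = [r.seq for k, r in regions.items() if k.startswith("exon_")]
    intron_seqs = [r.seq for k, r in regions.items() if k.startswith("intron_")]
    cds = regions["cds"].seq
    frame = cds[: len(cds) - len(cds) % 3]
    pos = [frame[i::3] for i in range(3)]
    return GeneFeatureVector(
        gene_id=gene.id,
        exon_count=len(model.exons),
        exon_lengths=[len(s) for s in exon_seqs],
        intron_lengths=[len(s) for s in intron_seqs],
        gene_length=len(regions["gene"].seq),
        cds_length=len(cds),
        protein_length=len(regions["protein"].seq),
        gc_gene=gc_content(regions["gene"].seq),
        gc_exon=gc_content("".join(exon_seqs)),
        gc_intron=gc_content("".join(intron_seqs)) if intron_seqs else math.nan,
        gc_cds=gc_content(cds),
        gc_pos1=gc_content(pos[0]) if len(frame) >= 3 else math.nan,
        gc_pos2=gc_content(pos[1]) if len(frame) >= 3 else math.nan,
        gc_pos3=gc_content(pos[2]) if len(frame) >= 3 else math.nan,
    )


def summarize_features(
    vectors_by_label: dict[str, list[GeneFeatureVector]],
    pooled_exons: bool = True,
) -> pd.DataFrame:
    """Mean / sample SD / median per set x feature.

    ``pooled_exons=True`` pools exon and intron lengths over all features in
    the set (each exon one observation); False averages within genes first.
    Missing values are excluded per cell; an SD over a single observation is
    reported as missing.
    """
    rows = []
    for label, vectors in vectors_by_label.items():
        if not vectors:
            raise ValueError(f"label {label!r} has no genes")
        columns: dict[str, list[float]] = {f: [] for f in _FEATURES}
        columns["exon_length"] = []
        columns["intron_length"] = []
        for v in vectors:
            for f in _FEATURES:
                if f in ("mean_exon_length", "mean_intron_length"):
                    continue
                columns[f].append(getattr(v, f))
            if pooled_exons:
                columns["exon_length"].extend(v.exon_lengths)
                columns["intron_length"].extend(v.intron_lengths)
            else:
                columns["exon_length"].append(v.mean_exon_length)
                if v.intron_lengths:
                    columns["intron_length"].append(v.mean_intron_length)
        for feature, values in columns.items():
            if feature in ("mean_exon_length", "mean_intron_length"):
                continue
            arr = np.asarray(values, dtype=float)
            arr = arr[~np.isnan(arr)]
            rows.append(
                {
                    "label": label,
                    "feature": feature,
                    "n": arr.size,
                    "mean": float(arr.mean()) if arr.size else math.nan,
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
                    "median": float(np.median(arr)) if arr.size else math.nan,
                }
            )
    return pd.DataFrame(rows)


def compare_sets(
    a, b, kind: str = "welch_t"
) -> tuple[float, float]:
    """Two-set comparison: Welch t-test on values or chi-square on a 2x2.

    ``welch_t``: ``a`` and ``b`` are value sequences (>= 2 each);
    ``chi_square_proportion``: ``a`` and ``b`` are (successes, failures)
    count pairs; chi-square without continuity correction, two-sided.
    """
    if kind == "welch_t":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            raise ValueError("Welch t-test requires >= 2 values per side")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if kind == "chi_square_proportion":
        table = np.array([list(a), list(b)], dtype=float)
        if (table < 0).any():
            raise ValueError("counts must be non-negative")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("chi-square table has a zero row/column")
        if (table == table[0]).all():
            return 0.0, 1.0
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown comparison kind {kind!r}")
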