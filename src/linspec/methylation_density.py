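"""Cytosine methylation density in gene-relative regions.

Density is the number of 5-methylcytosine calls per 100 bp of a region.
Each gene contributes three regions based on its representative model:
the 500 bp upstream flank, the coding region (genomic span from the first
to the last CDS base; a spliced mode excluding introns from the denominator
is available), and the 500 bp downstream flank. Flanks are transcriptional
(strand-aware) and truncated at chromosome ends, with the density computed
over the truncated length. Calls on both strands are pooled; the CG / CHG /
CHH sequence context is carried through and reportable per class.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    select_representative_model,
)
from .genic_features import compare_sets

__all__ = [
    "MethylationCallSet",
    "region_density",
    "gene_density_profile",
    "compare_methylation",
    "methylation_context",
]

CONTEXTS = ("CG", "CHG", "CHH")
REGIONS = ("upstream", "coding", "downstream")


def methylation_context(chrom_seq: str, pos: int, strand: str) -> str | None:
    """CG / CHG / CHH context of a cytosine at 1-based ``pos``.

    On the minus strand the context is read off the reverse complement.
    Returns None when the base at ``pos`` is not a cytosine on the given
    strand or the context runs off the chromosome end.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        window = chrom_seq[pos - 1 : pos + 2]
    else:
        raw = chrom_seq[max(0, pos - 3) : pos][::-1]
        window = "".join(comp.get(c, "N") for c in raw)
    if not window or window[0] != "C":
        return None
    if len(window) < 2:
        return None
    if window[1] == "G":
        return "CG"
    if len(window) < 3 or window[1] not in "ACT":
        return None
    if window[2] == "G":
        return "CHG"
    if window[2] in "ACT":
        return "CHH"
    return None


@dataclass
class MethylationCallSet:
    """Methylcytosine calls (chrom, 1-based pos, strand, context)."""

    records: pd.DataFrame  # columns: chrom, position, strand, context

    def __post_init__(self) -> None:
        bad = set(self.records["context"]) - set(CONTEXTS)
        if bad:
            raise ValueError(f"unknown methylation contexts: {sorted(bad)}")
        self._positions = {
            chrom: sorted(sub["position"])
            for chrom, sub in self.records.groupby("chrom")
        }

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self._positions.get(interval.chrom, [])
        return bisect_right(pos, interval.end) - bisect_left(pos, interval.start)

    @classmethod
    def from_tsv(cls, path) -> "MethylationCallSet":
        df = pd.read_csv(
            path,
            sep="\t",
            names=["chrom", "position", "strand", "context"],
            dtype={"chrom": str, "position": int, "strand": str, "context": str},
            comment="#",
        )
        return cls(df)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, header=False)


def region_density(calls: MethylationCallSet, interval: GenomicInterval) -> float:
    """Methylcytosines per 100 bp in a genomic interval (both strands)."""
    return 100.0 * calls.count_in(interval) / interval.length


def gene_regions_for_methylation(
    gene: GeneModel, annotation: GenomeAnnotation, flank: int = 500
) -> dict[str, GenomicInterval | None]:
    """Upstream / coding / downstream intervals of the representative model."""
    model = select_representative_model(gene)
    chrom_len = len(annotation.sequences[model.chrom])
    span = model.cds_span
    minus = model.strand == "-"
    if minus:
        up = (model.end + 1, min(chrom_len, model.end + flank))
        down = (max(1, model.start - flank), model.start - 1)
    else:
        up = (max(1, model.start - flank), model.start - 1)
        down = (model.end + 1, min(chrom_len, model.end + flank))

    def iv(bounds) -> GenomicInterval | None:
        lo, hi = bounds
        if hi < lo:
            return None
        return GenomicInterval(model.chrom, lo, hi, model.strand)

    return {"upstream": iv(up), "coding": span, "downstream": iv(down)}


def gene_density_profile(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    calls: MethylationCallSet,
    flank: int = 500,
    spliced_coding: bool = False,
) -> tuple[float, float, float]:
    """(upstream, coding, downstream) densities for one gene.

    ``spliced_coding=True`` counts calls within CDS exons only and divides
    by the spliced CDS length instead of the genomic span.
    """
    regions = gene_regions_for_methylation(gene, annotation, flank)

    def dens(iv: GenomicInterval | None) -> float:
        return region_density(calls, iv) if iv is not None else 0.0

    if spliced_coding:
        model = select_representative_model(gene)
        n = sum(calls.count_in(iv) for iv in model.cds)
        coding = 100.0 * n / model.cds_length if model.cds_length else 0.0
    else:
        coding = dens(regions["coding"])
    return dens(regions["upstream"]), coding, dens(regions["downstream"])


def compare_methylation(
    profiles_by_label: dict[str, list[tuple[float, float, float]]],
) -> pd.DataFrame:
    """Per-region group means and pairwise Welch t-tests between labels."""
    import itertools

    rows = []
    for ri, region in enumerate(REGIONS):
        for label, profiles in profiles_by_label.items():
            vals = [p[ri] for p in profiles]
            rows.append(
                {
                    "region": region,
                    "label": label,
                    "comparison": None,
                    "mean_density": sum(vals) / len(vals),
                    "p_value": None,
                }
            )
        for a, b in itertools.combinations(sorted(profiles_by_label), 2):
            va = [p[ri] for p in profiles_by_label[a]]
            vb = [p[ri] for p in profiles_by_label[b]]
            _, p = compare_sets(va, vb, "welch_t")
            rows.append(
                {
                    "region": region,
                    "label": None,
                    "comparison": f"{a} vs {b}",
                    "mean_density": None,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
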