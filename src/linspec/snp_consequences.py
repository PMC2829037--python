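"""SNP filtering, codon mapping and synonymous/non-synonymous classification.

Accession SNP tables are first reduced to biallelic sites: per site the
distinct non-N bases across the reference and all accession calls are
counted and only sites with exactly two are kept (sites with more are
excluded as multi-allelic; sites monomorphic after N removal are dropped
and counted separately). Kept SNPs falling in the spliced CDS of a gene's
representative model are assigned codon coordinates (splice first, then
index codons); the alternate base is complemented for minus-strand genes.
A SNP is synonymous when the mutated codon translates to the same amino
acid as the reference codon (stop-to-stop included), non-synonymous
otherwise. Per-gene densities are counts per 100 bp of spliced CDS, and
set-level non-synonymous:synonymous ratios are ratios of mean per-gene
densities (a total-count mode is also available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .annotation_io import GeneModel, GenomeAnnotation, select_representative_model

__all__ = [
    "SnpRecord",
    "CodingSnpCall",
    "filter_biallelic",
    "locate_in_cds",
    "classify_consequence",
    "classify_gene_snps",
    "per_gene_densities",
    "set_level_ratio",
    "read_snp_table",
    "write_snp_table",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    position: int  # 1-based
    reference_base: str
    accession_calls: tuple[tuple[str, str], ...]  # (accession id, base)

    def __post_init__(self) -> None:
        if self.reference_base not in "ACGT":
            raise ValueError(f"invalid reference base {self.reference_base!r}")
        if not self.accession_calls:
            raise ValueError("a SNP needs >= 1 accession call")

    @property
    def alleles(self) -> set[str]:
        """Distinct non-N bases across reference + accessions."""
        bases = {b for _, b in self.accession_calls if b != "N"}
        bases.add(self.reference_base)
        return bases

    @property
    def alternate_base(self) -> str | None:
        alt = self.alleles - {self.reference_base}
        return next(iter(alt)) if len(alt) == 1 else None


@dataclass(frozen=True)
class CodingSnpCall:
    gene_id: str
    codon_index: int  # 1-based within the spliced CDS
    position_in_codon: int  # 1..3
    reference_codon: str
    alternate_base: str  # on the coding strand
    verdict: str  # synonymous | nonsynonymous


def filter_biallelic(snps: list[SnpRecord]) -> tuple[list[SnpRecord], int, int]:
    """Keep biallelic SNPs; returns (kept, n_multiallelic, n_monomorphic)."""
    kept, multi, mono = [], 0, 0
    for snp in snps:
        n = len(snp.alleles)
        if n == 2:
            kept.append(snp)
        elif n > 2:
            multi += 1
        else:
            mono += 1
    return kept, multi, mono


def _spliced_offset(model, chrom: str, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS (coding
    strand orientation), or None when outside the CDS."""
    if chrom != model.chrom:
        return None
    offset = 0
    for iv in model.cds:
        if iv.start <= pos <= iv.end:
            fwd = offset + (pos - iv.start)
            if model.strand == "+":
                return fwd
            return model.cds_length - 1 - fwd
        offset += iv.length
    return None


def locate_in_cds(
    snp: SnpRecord, gene: GeneModel, annotation: GenomeAnnotation
) -> tuple[int, int, str] | None:
    """(codon_index, position_in_codon, reference_codon) for a coding SNP.

    None when the SNP is outside the spliced CDS; positions in a trailing
    partial codon (CDS length not divisible by 3) also return None with a
    warning.
    """
    model = select_representative_model(gene)
    off = _spliced_offset(model, snp.chrom, snp.position)
    if off is None:
        return None
    if off >= model.cds_length - model.cds_length % 3:
        warnings.warn(
            f"gene {gene.id}: SNP at {snp.chrom}:{snp.position} falls in a "
            "trailing partial codon",
            stacklevel=2,
        )
        return None
    chrom_seq = annotation.sequences[model.chrom].seq
    parts = [chrom_seq[iv.start - 1 : iv.end] for iv in model.cds]
    cds_seq = "".join(parts)
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    codon_index = off // 3 + 1
    position_in_codon = off % 3 + 1
    codon = cds_seq[(codon_index - 1) * 3 : codon_index * 3]
    return codon_index, position_in_codon, codon


def classify_consequence(
    reference_codon: str, position_in_codon: int, alternate_base: str
) -> str | None:
    """``synonymous`` / ``nonsynonymous`` verdict for a single-base change.

    Stop-to-amino-acid (and the reverse) changes are non-synonymous;
    stop-to-stop is synonymous. A reference codon containing N is
    unclassifiable (None).
    """
    reference_codon = reference_codon.upper()
    alternate_base = alternate_base.upper()
    if "N" in reference_codon or alternate_base == "N":
        return None
    if not (1 <= position_in_codon <= 3):
        raise ValueError("position_in_codon must be 1..3")
    if reference_codon[position_in_codon - 1] == alternate_base:
        raise ValueError("alternate base equals the reference base")
    mutated = (
        reference_codon[: position_in_codon - 1]
        + alternate_base
        + reference_codon[position_in_codon:]
    )
    table = standard_dna_table
    ref_aa = "*" if reference_codon in table.stop_codons else table.forward_table[reference_codon]
    alt_aa = "*" if mutated in table.stop_codons else table.forward_table[mutated]
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def classify_gene_snps(
    gene: GeneModel,
    snps: list[SnpRecord],
    annotation: GenomeAnnotation,
    check_reference: bool = True,
) -> list[CodingSnpCall]:
    """Map biallelic SNPs into a gene's CDS and classify each one."""
    model = select_representative_model(gene)
    calls = []
    chrom_seq = annotation.sequences[model.chrom].seq
    for snp in snps:
        located = locate_in_cds(snp, gene, annotation)
        if located is None:
            continue
        if check_reference and chrom_seq[snp.position - 1] != snp.reference_base:
            raise ValueError(
                f"SNP at {snp.chrom}:{snp.position}: reference base "
                f"{snp.reference_base} conflicts with the genome sequence "
                f"{chrom_seq[snp.position - 1]}"
            )
        alt = snp.alternate_base
        if alt is None:
            continue
        if model.strand == "-":
            alt = _COMPLEMENT[alt]
        codon_index, pos_in_codon, codon = located
        verdict = classify_consequence(codon, pos_in_codon, alt)
        if verdict is None:
            continue
        calls.append(
            CodingSnpCall(gene.id, codon_index, pos_in_codon, codon, alt, verdict)
        )
    return calls


def per_gene_densities(
    gene: GeneModel, calls: list[CodingSnpCall]
) -> tuple[float, float, float]:
    """(total, non-synonymous, synonymous) SNPs per 100 bp of spliced CDS."""
    model = select_representative_model(gene)
    if model.cds_length == 0:
        raise ValueError(f"gene {gene.id} has a zero-length CDS")
    mine = [c for c in calls if c.gene_id == gene.id]
    nonsyn = sum(1 for c in mine if c.verdict == "nonsynonymous")
    syn = len(mine) - nonsyn
    scale = 100.0 / model.cds_length
    return len(mine) * scale, nonsyn * scale, syn * scale


def set_level_ratio(
    densities: list[tuple[float, float, float]],
    mode: str = "density_mean",
    counts: list[tuple[int, int]] | None = None,
) -> dict:
    """Non-synonymous : synonymous ratio for a gene set.

    ``density_mean`` (default): ratio of the mean per-gene non-synonymous
    density to the mean per-gene synonymous density, on unrounded means.
    ``total_counts``: ratio of summed counts (requires ``counts`` as
    (nonsyn, syn) per gene). Also reports mean densities and the number of
    genes with more non-synonymous than synonymous SNPs. A zero synonymous
    denominator yields an infinite ratio with a flag.
    """
    if not densities:
        raise ValueError("empty gene set")
    n = len(densities)
    mean_total = sum(d[0] for d in densities) / n
    mean_nonsyn = sum(d[1] for d in densities) / n
    mean_syn = sum(d[2] for d in densities) / n
    if mode == "density_mean":
        num, den = mean_nonsyn, mean_syn
    elif mode == "total_counts":
        if counts is None:
            raise ValueError("total_counts mode requires counts")
        num = sum(c[0] for c in counts)
        den = sum(c[1] for c in counts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    infinite = den == 0
    return {
        "ratio": math.inf if infinite else num / den,
        "infinite": infinite,
        "mean_snp_density": mean_total,
        "mean_nonsyn_density": mean_nonsyn,
        "mean_syn_density": mean_syn,
        "n_genes": n,
        "n_genes_more_nonsyn": sum(1 for d in densities if d[1] > d[2]),
    }


# ---------------------------------------------------------------------------
# Tabular I/O (chrom, pos, ref, one column per accession)


def read_snp_table(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    accessions = [c for c in df.columns if c not in ("chrom", "position", "ref")]
    out = []
    for d in df.to_dict("records"):
        out.append(
            SnpRecord(
                chrom=d["chrom"],
                position=int(d["position"]),
                reference_base=d["ref"],
                accession_calls=tuple((a, d[a]) for a in accessions),
            )
        )
    return out


def write_snp_table(snps: list[SnpRecord], path) -> None:
    if not snps:
        raise ValueError("no SNPs to write")
    accessions = [a for a, _ in snps[0].accession_calls]
    rows = []
    for s in snps:
        row = {"chrom": s.chrom, "position": s.position, "ref": s.reference_base}
        row.update(dict(s.accession_calls))
        rows.append(row)
    pd.DataFrame(rows, columns=["chrom", "position", "ref"] + accessions).to_csv(
        path, sep="\t", index=False
    )
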