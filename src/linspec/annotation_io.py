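"""Genome annotation I/O and per-gene region extraction.

Reads GFF3 (gene/mRNA/exon/CDS hierarchy) together with the genome FASTA,
validates the feature hierarchy, selects representative transcript models and
derives per-gene region sequences: gene span, exons, introns, spliced CDS,
translated protein and 500 bp flanks.

Coordinates are GFF3-style throughout: 1-based, inclusive on both ends.
"upstream"/"downstream" are transcriptional, i.e. on the minus strand the
upstream flank lies at higher genomic coordinates and every extracted
sequence is reverse-complemented to read 5'->3' on the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "TranscriptModel",
    "GeneModel",
    "GenomeAnnotation",
    "AnnotationParseError",
    "AnnotationValidationError",
    "read_genome_annotation",
    "write_genome_annotation",
    "filter_te_and_pseudogenes",
    "select_representative_model",
    "extract_gene_regions",
]

BIOTYPES = ("protein_coding", "transposable_element", "pseudogene")


class AnnotationParseError(ValueError):
    """Malformed GFF3 content; the message names the offending line."""


class AnnotationValidationError(ValueError):
    """Structurally parseable annotation that violates an invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval on a chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SequenceRecord:
    """Named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    is_representative: bool = False
    has_transcript_support: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationValidationError(
                    f"overlapping exons in transcript {self.id}"
                )
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise AnnotationValidationError(
                    f"CDS {c.chrom}:{c.start}-{c.end} of transcript {self.id} "
                    "not contained in any exon"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def cds_span(self) -> GenomicInterval | None:
        """Genomic span from first to last CDS base (introns included)."""
        if not self.cds:
            return None
        return GenomicInterval(
            self.chrom, self.cds[0].start, self.cds[-1].end, self.strand
        )


@dataclass
class GeneModel:
    id: str
    isoforms: list[TranscriptModel]
    biotype: str = "protein_coding"
    known_function: bool = False

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise AnnotationValidationError(f"gene {self.id} has no isoforms")
        if self.biotype not in BIOTYPES:
            raise AnnotationValidationError(
                f"gene {self.id}: unknown biotype {self.biotype!r}"
            )

    @property
    def chrom(self) -> str:
        return self.isoforms[0].chrom

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.isoforms)

    @property
    def end(self) -> int:
        return max(t.end for t in self.isoforms)

    @property
    def has_transcript_support(self) -> bool:
        return any(t.has_transcript_support for t in self.isoforms)


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel]
    sequences: dict[str, SequenceRecord]

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            for iso in gene.isoforms:
                for iv in iso.exons + iso.cds:
                    chrom = self.sequences.get(iv.chrom)
                    if chrom is None:
                        raise AnnotationValidationError(
                            f"gene {gene.id}: unknown chromosome {iv.chrom}"
                        )
                    if iv.end > len(chrom):
                        raise AnnotationValidationError(
                            f"gene {gene.id}: interval {iv.chrom}:{iv.start}-"
                            f"{iv.end} outside chromosome (length {len(chrom)})"
                        )

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GFF3 parsing


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_GENE_TYPES = {
    "gene": "protein_coding",
    "transposable_element_gene": "transposable_element",
    "pseudogene": "pseudogene",
}


def read_genome_annotation(gff3_path, fasta_path) -> GenomeAnnotation:
    """Load a GFF3 gene/mRNA/exon/CDS hierarchy plus its genome FASTA.

    Raises :class:`AnnotationParseError` (naming the line) for malformed
    parent links and :class:`AnnotationValidationError` for intervals
    outside their chromosome or CDS outside exons.
    """
    sequences = {
        rec.id: SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    genes_raw: dict[str, dict] = {}
    mrnas_raw: dict[str, dict] = {}
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 tab-separated columns"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            attributes = _parse_attributes(attrs)
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except (ValueError, AnnotationValidationError) as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            if ftype in _GENE_TYPES:
                gid = attributes.get("ID")
                if gid is None:
                    raise AnnotationParseError(f"line {lineno}: gene without ID")
                genes_raw[gid] = {
                    "interval": iv,
                    "biotype": attributes.get("biotype", _GENE_TYPES[ftype]),
                    "known_function": attributes.get("known_function", "0") == "1",
                    "mrnas": [],
                }
            elif ftype == "mRNA":
                tid, parent = attributes.get("ID"), attributes.get("Parent")
                if tid is None or parent is None:
                    raise AnnotationParseError(
                        f"line {lineno}: mRNA requires ID and Parent"
                    )
                if parent not in genes_raw:
                    raise AnnotationParseError(
                        f"line {lineno}: mRNA {tid} references unknown gene {parent}"
                    )
                mrnas_raw[tid] = {
                    "interval": iv,
                    "gene": parent,
                    "exons": [],
                    "cds": [],
                    "representative": attributes.get("representative", "0") == "1",
                    "transcript_support": attributes.get("transcript_support", "0")
                    == "1",
                }
                genes_raw[parent]["mrnas"].append(tid)
            elif ftype in ("exon", "CDS"):
                parent = attributes.get("Parent")
                if parent is None or parent not in mrnas_raw:
                    raise AnnotationParseError(
                        f"line {lineno}: {ftype} references unknown mRNA "
                        f"{parent!r}"
                    )
                mrnas_raw[parent]["exons" if ftype == "exon" else "cds"].append(iv)

    genes: dict[str, GeneModel] = {}
    for gid, g in genes_raw.items():
        isoforms = []
        for tid in g["mrnas"]:
            m = mrnas_raw[tid]
            isoforms.append(
                TranscriptModel(
                    id=tid,
                    exons=m["exons"],
                    cds=m["cds"],
                    is_representative=m["representative"],
                    has_transcript_support=m["transcript_support"],
                )
            )
        genes[gid] = GeneModel(
            id=gid,
            isoforms=isoforms,
            biotype=g["biotype"],
            known_function=g["known_function"],
        )
    return GenomeAnnotation(genes=genes, sequences=sequences)


def write_genome_annotation(annotation: GenomeAnnotation, gff3_path, fasta_path):
    """Serialize an annotation back to GFF3 + FASTA (round-trip safe)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation.genes.values():
            ftype = {
                "protein_coding": "gene",
                "transposable_element": "transposable_element_gene",
                "pseudogene": "pseudogene",
            }[gene.biotype]
            attrs = f"ID={gene.id};biotype={gene.biotype}"
            if gene.known_function:
                attrs += ";known_function=1"
            fh.write(
                f"{gene.chrom}\tlinspec\t{ftype}\t{gene.start}\t{gene.end}"
                f"\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for iso in gene.isoforms:
                attrs = f"ID={iso.id};Parent={gene.id}"
                if iso.is_representative:
                    attrs += ";representative=1"
                if iso.has_transcript_support:
                    attrs += ";transcript_support=1"
                fh.write(
                    f"{iso.chrom}\tlinspec\tmRNA\t{iso.start}\t{iso.end}"
                    f"\t.\t{iso.strand}\t.\t{attrs}\n"
                )
                for iv in iso.exons:
                    fh.write(
                        f"{iv.chrom}\tlinspec\texon\t{iv.start}\t{iv.end}"
                        f"\t.\t{iv.strand}\t.\tParent={iso.id}\n"
                    )
                for iv in iso.cds:
                    fh.write(
                        f"{iv.chrom}\tlinspec\tCDS\t{iv.start}\t{iv.end}"
                        f"\t.\t{iv.strand}\t0\tParent={iso.id}\n"
                    )
    with open(fasta_path, "w") as fh:
        for rec in annotation.sequences.values():
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Gene-set filtering and representative selection


def filter_te_and_pseudogenes(
    annotation: GenomeAnnotation, extra_te_ids: set[str] | None = None
) -> tuple[GenomeAnnotation, int]:
    """Drop pseudogenes, TE genes and any gene named in ``extra_te_ids``.

    Returns the filtered annotation and the number of genes removed.
    Ids in ``extra_te_ids`` absent from the annotation produce a warning.
    """
    extra_te_ids = set(extra_te_ids or ())
    missing = extra_te_ids - set(annotation.genes)
    if missing:
        warnings.warn(
            f"{len(missing)} TE ids not present in the annotation", stacklevel=2
        )
    kept = {
        gid: g
        for gid, g in annotation.genes.items()
        if g.biotype == "protein_coding" and gid not in extra_te_ids
    }
    removed = len(annotation.genes) - len(kept)
    return GenomeAnnotation(genes=kept, sequences=annotation.sequences), removed


def select_representative_model(gene: GeneModel) -> TranscriptModel:
    """Single isoform used for all per-gene statistics.

    Priority: annotation flag, then longest total CDS, then lexicographically
    smallest isoform id. Deterministic.
    """
    flagged = [t for t in gene.isoforms if t.is_representative]
    if flagged:
        return min(flagged, key=lambda t: t.id)
    if all(t.cds_length == 0 for t in gene.isoforms):
        raise AnnotationValidationError(f"gene {gene.id} has no coding isoform")
    return min(gene.isoforms, key=lambda t: (-t.cds_length, t.id))


# ---------------------------------------------------------------------------
# Region extraction


def _slice(seq: str, start: int, end: int) -> str:
    # 1-based inclusive -> python slice
    return seq[start - 1 : end]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds_seq: str, gene_id: str = "?") -> str:
    """Translate a spliced CDS; trailing stop dropped.

    A CDS length not divisible by 3 is flagged with a warning and the
    longest in-frame prefix is translated; internal stops are flagged.
    """
    if len(cds_seq) % 3 != 0:
        warnings.warn(
            f"gene {gene_id}: CDS length {len(cds_seq)} not divisible by 3; "
            "translating longest in-frame prefix",
            stacklevel=2,
        )
        cds_seq = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
    protein = str(Seq(cds_seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(f"gene {gene_id}: internal stop codon", stacklevel=2)
    return protein


def extract_gene_regions(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    flank: int = 500,
) -> dict[str, SequenceRecord]:
    """Per-gene region sequences, all 5'->3' on the coding strand.

    Keys: ``gene``, ``exon_<k>``/``intron_<k>`` (numbered in transcription
    order), ``cds`` (spliced), ``protein``, ``upstream``, ``downstream``.
    Flanks are truncated at chromosome ends; a gene at the chromosome edge
    may have an empty flank.
    """
    model = select_representative_model(gene)
    chrom_seq = annotation.sequences[model.chrom].seq
    minus = model.strand == "-"

    def oriented(s: str) -> str:
        return reverse_complement(s) if minus else s

    regions: dict[str, SequenceRecord] = {}
    gene_seq = _slice(chrom_seq, model.start, model.end)
    regions["gene"] = SequenceRecord(f"{gene.id}:gene", oriented(gene_seq))

    exons = list(model.exons)
    introns = [
        GenomicInterval(model.chrom, a.end + 1, b.start - 1, model.strand)
        for a, b in zip(exons, exons[1:])
        if b.start - a.end > 1
    ]
    exon_order = exons[::-1] if minus else exons
    intron_order = introns[::-1] if minus else introns
    for k, iv in enumerate(exon_order, start=1):
        regions[f"exon_{k}"] = SequenceRecord(
            f"{gene.id}:exon_{k}", oriented(_slice(chrom_seq, iv.start, iv.end))
        )
    for k, iv in enumerate(intron_order, start=1):
        regions[f"intron_{k}"] = SequenceRecord(
            f"{gene.id}:intron_{k}", oriented(_slice(chrom_seq, iv.start, iv.end))
        )

    cds_parts = [_slice(chrom_seq, iv.start, iv.end) for iv in model.cds]
    cds_seq = "".join(cds_parts)
    cds_seq = oriented(cds_seq) if not minus else reverse_complement(cds_seq)
    regions["cds"] = SequenceRecord(f"{gene.id}:cds", cds_seq)
    regions["protein"] = SequenceRecord(
        f"{gene.id}:protein", translate_cds(cds_seq, gene.id) if cds_seq else ""
    )

    chrom_len = len(chrom_seq)
    if minus:
        up = (model.end + 1, min(chrom_len, model.end + flank))
        down = (max(1, model.start - flank), model.start - 1)
    else:
        up = (max(1, model.start - flank), model.start - 1)
        down = (model.end + 1, min(chrom_len, model.end + flank))
    up_seq = _slice(chrom_seq, up[0], up[1]) if up[1] >= up[0] else ""
    down_seq = _slice(chrom_seq, down[0], down[1]) if down[1] >= down[0] else ""
    regions["upstream"] = SequenceRecord(f"{gene.id}:upstream", oriented(up_seq))
    regions["downstream"] = SequenceRecord(f"{gene.id}:downstream", oriented(down_seq))
    return regions
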