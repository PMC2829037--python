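"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the data a lineage-specificity study
consumes: a focal genome annotation whose genes carry planted conservation
labels (EC / CLADE_SPECIFIC / SPECIES_SPECIFIC), homolog databases at two
divergence tiers (within-clade transcript assemblies and outside-clade
genomic sequences), a protein knowledgebase with clade taxonomy, an
expression compendium with latent co-expression modules and coherent GO
annotations, a methylome with label- and region-dependent methylation
rates, accession SNP tables with a tunable non-synonymous bias, and
per-isoform localization predictions with label-dependent compartment
probabilities.

Planted EC genes have homologs in both clade and outgroup databases;
clade-planted genes only in clade databases; species-planted genes are
random sequences present nowhere else. Divergence parameters are
per-residue amino-acid substitution probabilities: a homolog is created by
mutating the focal protein and back-translating it with random codons,
which fixes the protein-level identity the searches see. All draws come
from a single seeded integer-state generator, so outputs are byte-identical
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    select_representative_model,
)
from .coexpression_go import ExpressionMatrix, GoAnnotationTable
from .homology_search import SequenceDatabase
from .lineage_classifier import CLADE_SPECIFIC, EC, SPECIES_SPECIFIC
from .localization_assign import COMPARTMENTS, IsoformLocalizationPrediction
from .methylation_density import MethylationCallSet, methylation_context
from .snp_consequences import SnpRecord, classify_consequence

__all__ = [
    "SimulationSpec",
    "LineageSimulation",
    "simulate_lineage_genomes",
    "simulate_expression_compendium",
    "simulate_methylome",
    "simulate_accession_snps",
    "simulate_localization_predictions",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

def _build_codon_table() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table

    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    table["*"] = list(standard_dna_table.stop_codons)
    return table


_CODONS = _build_codon_table()


@dataclass
class SimulationSpec:
    """All tunable study conditions for the synthetic data.

    Divergences are amino-acid substitution probabilities per residue; the
    outgroup tier must exceed the clade tier to plant a detectability gap.
    """

    # lineage genome
    n_ec: int = 70
    n_clade: int = 20
    n_species: int = 10
    n_clade_relatives: int = 3
    n_outgroups: int = 3
    divergence_clade: float = 0.20
    divergence_outgroup: float = 0.45
    protein_length_range: tuple[int, int] = (80, 200)
    exon_count_range: tuple[int, int] = (1, 4)
    intron_length_range: tuple[int, int] = (60, 200)
    intergenic_length_range: tuple[int, int] = (600, 1000)
    alt_isoform_fraction: float = 0.2
    n_decoys_per_db: int = 5
    # stage-3 knowledgebase planting (0 = exercise via tests only)
    kb_nonclade_of_clade: int = 0
    kb_nonclade_of_species: int = 0
    kb_clade_of_species: int = 0
    kb_divergence: float = 0.20
    n_kb_decoys: int = 10
    # gene attributes, roughly mirroring real annotation proportions
    p_known_function: dict = field(
        default_factory=lambda: {EC: 0.79, CLADE_SPECIFIC: 0.24, SPECIES_SPECIFIC: 0.06}
    )
    p_transcript_support: dict = field(
        default_factory=lambda: {EC: 0.96, CLADE_SPECIFIC: 0.77, SPECIES_SPECIFIC: 0.53}
    )
    # expression compendium
    n_experiments: int = 50
    n_expression_genes: int = 500  # compendium size incl. background genes
    n_modules: int = 5
    module_size: int = 10
    module_loading: float = 0.9
    expression_noise_sd: float = 1.0
    go_terms_per_module: int = 1
    go_background_annotations: int = 50
    go_excluded_fraction: float = 0.2
    # methylation: per-bp methylcytosine probability by label and region
    methylation_rates: dict = field(
        default_factory=lambda: {
            EC: {"upstream": 0.005, "coding": 0.01, "downstream": 0.005},
            CLADE_SPECIFIC: {"upstream": 0.01, "coding": 0.02, "downstream": 0.01},
            SPECIES_SPECIFIC: {"upstream": 0.01, "coding": 0.02, "downstream": 0.01},
        }
    )
    # accession SNPs
    n_snps: int = 1000
    target_nonsyn_syn_ratio: float = 1.0
    n_accessions: int = 20
    multiallelic_fraction: float = 0.05
    n_call_fraction: float = 0.1
    # localization
    localization_probs: dict = field(
        default_factory=lambda: {
            EC: (0.15, 0.12, 0.20, 0.53),
            CLADE_SPECIFIC: (0.04, 0.08, 0.45, 0.43),
            SPECIES_SPECIFIC: (0.05, 0.17, 0.20, 0.58),
        }
    )
    rc_probs: tuple = (0.35, 0.25, 0.2, 0.12, 0.08)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_clade < self.divergence_outgroup <= 1:
            if not (self.divergence_clade == self.divergence_outgroup == 0):
                raise ValueError(
                    "outgroup divergence must exceed clade divergence"
                )


@dataclass
class LineageSimulation:
    annotation: GenomeAnnotation
    truth: dict[str, str]
    outside_dbs: list[SequenceDatabase]
    clade_dbs: list[SequenceDatabase]
    knowledgebase: SequenceDatabase
    proteins: dict[str, SequenceRecord]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = _NT) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + _random_seq(rng, n - 1, _AA)


def _back_translate(rng: np.random.Generator, protein: str, stop: bool = True) -> str:
    parts = [ _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    if stop:
        parts.append(_CODONS["*"][rng.integers(0, 3)])
    return "".join(parts)


def _mutate_protein(rng: np.random.Generator, protein: str, d: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < d:
            choices = _AA.replace(aa, "")
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# Genomes and homolog databases


def simulate_lineage_genomes(
    spec: SimulationSpec, seed: int = 0
) -> LineageSimulation:
    """Focal annotation + homolog databases with planted 3-way truth labels."""
    rng = np.random.default_rng(seed)
    labels = (
        [EC] * spec.n_ec
        + [CLADE_SPECIFIC] * spec.n_clade
        + [SPECIES_SPECIFIC] * spec.n_species
    )
    n_genes = len(labels)

    chrom_parts: list[str] = []
    cursor = 0
    genes: dict[str, GeneModel] = {}
    truth: dict[str, str] = {}
    proteins: dict[str, SequenceRecord] = {}
    chrom = "chr1"

    for idx, label in enumerate(labels):
        gid = f"G{idx + 1:04d}"
        plen = int(rng.integers(*spec.protein_length_range))
        protein = _random_protein(rng, plen)
        cds_nt = _back_translate(rng, protein)
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        # split the CDS into n_exons contiguous pieces (each >= 10 nt)
        if n_exons > 1:
            cuts = sorted(
                rng.choice(
                    np.arange(10, len(cds_nt) - 10), size=n_exons - 1, replace=False
                )
            )
        else:
            cuts = []
        pieces = np.split(np.array(list(cds_nt)), cuts)
        exon_seqs = ["".join(p) for p in pieces]
        intron_seqs = [
            _random_seq(rng, int(rng.integers(*spec.intron_length_range)))
            for _ in range(n_exons - 1)
        ]
        tx_parts = []
        for k, ex in enumerate(exon_seqs):
            tx_parts.append(ex)
            if k < len(intron_seqs):
                tx_parts.append(intron_seqs[k])
        gene_seq = "".join(tx_parts)
        strand = "+" if rng.random() < 0.5 else "-"

        gap = int(rng.integers(*spec.intergenic_length_range))
        chrom_parts.append(_random_seq(rng, gap))
        cursor += gap
        gene_start = cursor + 1  # 1-based
        placed = gene_seq if strand == "+" else _revcomp(gene_seq)
        chrom_parts.append(placed)
        cursor += len(gene_seq)

        # exon intervals in transcription order, then to genomic order
        exon_ivs = []
        off = 0
        for k, ex in enumerate(exon_seqs):
            if strand == "+":
                s = gene_start + off
                exon_ivs.append(GenomicInterval(chrom, s, s + len(ex) - 1, strand))
            else:
                e = gene_start + len(gene_seq) - 1 - off
                exon_ivs.append(GenomicInterval(chrom, e - len(ex) + 1, e, strand))
            off += len(ex)
            if k < len(intron_seqs):
                off += len(intron_seqs[k])
        exon_ivs.sort(key=lambda iv: iv.start)

        isoforms = [
            TranscriptModel(
                id=f"{gid}.1",
                exons=exon_ivs,
                cds=list(exon_ivs),
                is_representative=True,
                has_transcript_support=bool(
                    rng.random() < spec.p_transcript_support[label]
                ),
            )
        ]
        if rng.random() < spec.alt_isoform_fraction:
            isoforms.append(
                TranscriptModel(
                    id=f"{gid}.2",
                    exons=exon_ivs,
                    cds=list(exon_ivs),
                    is_representative=False,
                )
            )
        genes[gid] = GeneModel(
            id=gid,
            isoforms=isoforms,
            biotype="protein_coding",
            known_function=bool(rng.random() < spec.p_known_function[label]),
        )
        truth[gid] = label
        proteins[gid] = SequenceRecord(gid, protein)

    chrom_parts.append(_random_seq(rng, int(rng.integers(*spec.intergenic_length_range))))
    annotation = GenomeAnnotation(
        genes=genes,
        sequences={chrom: SequenceRecord(chrom, "".join(chrom_parts))},
    )

    ec_ids = [g for g, l in truth.items() if l == EC]
    clade_ids = [g for g, l in truth.items() if l == CLADE_SPECIFIC]
    species_ids = [g for g, l in truth.items() if l == SPECIES_SPECIFIC]

    def homolog_nt(gid: str, divergence: float, genomic: bool) -> str:
        mutated = _mutate_protein(rng, proteins[gid].seq, divergence)
        nt = _back_translate(rng, mutated)
        if genomic:
            nt = _random_seq(rng, 100) + nt + _random_seq(rng, 100)
        return nt

    outside_dbs = []
    for j in range(spec.n_outgroups):
        records = [
            SequenceRecord(f"OUT{j + 1}_{gid}", homolog_nt(gid, spec.divergence_outgroup, True))
            for gid in ec_ids
        ]
        records += [
            SequenceRecord(f"OUT{j + 1}_decoy{d}", _random_seq(rng, 600))
            for d in range(spec.n_decoys_per_db)
        ]
        outside_dbs.append(
            SequenceDatabase(f"outgroup{j + 1}", records, "outside_clade_genomic")
        )

    clade_dbs = []
    for k in range(spec.n_clade_relatives):
        records = [
            SequenceRecord(f"CL{k + 1}_{gid}", homolog_nt(gid, spec.divergence_clade, False))
            for gid in ec_ids + clade_ids
        ]
        records += [
            SequenceRecord(f"CL{k + 1}_decoy{d}", _random_seq(rng, 600))
            for d in range(spec.n_decoys_per_db)
        ]
        clade_dbs.append(
            SequenceDatabase(f"clade{k + 1}", records, "clade_transcript")
        )

    kb_records, kb_taxonomy = [], {}

    def kb_entry(gid: str, taxon: str, tag: str) -> None:
        rec_id = f"KB_{tag}_{gid}"
        kb_records.append(
            SequenceRecord(rec_id, _mutate_protein(rng, proteins[gid].seq, spec.kb_divergence))
        )
        kb_taxonomy[rec_id] = taxon

    for gid in clade_ids[: spec.kb_nonclade_of_clade]:
        kb_entry(gid, "outgroup", "nc")
    for gid in species_ids[: spec.kb_nonclade_of_species]:
        kb_entry(gid, "outgroup", "nc")
    offset = spec.kb_nonclade_of_species
    for gid in species_ids[offset : offset + spec.kb_clade_of_species]:
        kb_entry(gid, "clade", "cl")
    for d in range(spec.n_kb_decoys):
        rec_id = f"KB_decoy{d}"
        kb_records.append(SequenceRecord(rec_id, _random_protein(rng, 150)))
        kb_taxonomy[rec_id] = "outgroup"
    kb = SequenceDatabase("uniprot_like", kb_records, "knowledgebase", kb_taxonomy)

    return LineageSimulation(
        annotation=annotation,
        truth=truth,
        outside_dbs=outside_dbs,
        clade_dbs=clade_dbs,
        knowledgebase=kb,
        proteins=proteins,
    )


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# Expression + GO


def simulate_expression_compendium(
    spec: SimulationSpec,
    gene_ids: list[str],
    seed: int = 0,
) -> tuple[ExpressionMatrix, GoAnnotationTable, dict[str, list[str]]]:
    """Compendium with latent modules + a module-coherent GO table.

    Returns (matrix, GO table, module id -> member genes). Module members
    load on a shared latent factor; everything else is independent noise.
    The GO table contains one coherent term per module, random background
    annotations, and a fraction of records carrying excluded evidence codes
    (IEP/IEA/RCA) so the evidence filter is exercised. The compendium is
    padded with unannotated background genes up to ``n_expression_genes``
    so that planted modules stay a small fraction of all pairs, as they
    would be in a genome-wide compendium.
    """
    rng = np.random.default_rng(seed)
    m = spec.n_experiments
    gene_ids = list(gene_ids)
    n_pad = max(0, spec.n_expression_genes - len(gene_ids))
    gene_ids += [f"BG{i + 1:05d}" for i in range(n_pad)]
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    data = rng.normal(0.0, spec.expression_noise_sd, size=(n, m))

    modules: dict[str, list[str]] = {}
    order = rng.permutation(n)
    idx = 0
    for mod in range(spec.n_modules):
        members = [gene_ids[i] for i in order[idx : idx + spec.module_size]]
        idx += spec.module_size
        factor = rng.normal(0.0, 1.0, size=m)
        for gid in members:
            noise = rng.normal(0.0, spec.expression_noise_sd, size=m)
            lam = spec.module_loading
            data[index[gid]] = lam * factor + np.sqrt(max(0.0, 1 - lam**2)) * noise
        modules[f"MOD{mod + 1}"] = members

    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=gene_ids, columns=[f"exp{i + 1}" for i in range(m)])
    )

    good_codes = ["IDA", "IMP", "TAS", "ISS"]
    bad_codes = sorted({"IEP", "IEA", "RCA"})
    rows = []
    for mod, members in modules.items():
        for t in range(spec.go_terms_per_module):
            go_id = f"GO:{1000 + 10 * int(mod[3:]) + t:07d}"
            for gid in members:
                rows.append(
                    {
                        "gene_id": gid,
                        "go_id": go_id,
                        "go_term": f"planted function {mod}",
                        "evidence_code": good_codes[rng.integers(0, len(good_codes))],
                    }
                )
    for _ in range(spec.go_background_annotations):
        gid = gene_ids[rng.integers(0, n)]
        excluded = rng.random() < spec.go_excluded_fraction
        rows.append(
            {
                "gene_id": gid,
                "go_id": f"GO:{2000 + int(rng.integers(0, 20)):07d}",
                "go_term": "background term",
                "evidence_code": (
                    bad_codes[rng.integers(0, 3)]
                    if excluded
                    else good_codes[rng.integers(0, len(good_codes))]
                ),
            }
        )
    go = GoAnnotationTable(pd.DataFrame(rows))
    return matrix, go, modules


# ---------------------------------------------------------------------------
# Methylome


def simulate_methylome(
    spec: SimulationSpec,
    annotation: GenomeAnnotation,
    truth: dict[str, str],
    seed: int = 0,
    flank: int = 500,
) -> MethylationCallSet:
    """Bernoulli methylcytosine calls at label/region-dependent per-bp rates.

    Every cytosine (C on + strand, G read as C on - strand) within a gene's
    upstream / coding-span / downstream region is called methylated with
    the configured probability; context comes from the local sequence.
    """
    from .methylation_density import gene_regions_for_methylation

    rng = np.random.default_rng(seed)
    rows = []
    for gid, gene in annotation.genes.items():
        label = truth[gid]
        rates = spec.methylation_rates[label]
        regions = gene_regions_for_methylation(gene, annotation, flank)
        chrom_seq = annotation.sequences[gene.chrom].seq
        for region_name, iv in regions.items():
            if iv is None:
                continue
            rate = rates[region_name]
            if rate <= 0:
                continue
            for pos in range(iv.start, iv.end + 1):
                base = chrom_seq[pos - 1]
                if base == "C":
                    strand = "+"
                elif base == "G":
                    strand = "-"
                else:
                    continue
                if rng.random() >= rate:
                    continue
                context = methylation_context(chrom_seq, pos, strand)
                if context is None:
                    continue
                rows.append(
                    {
                        "chrom": iv.chrom,
                        "position": pos,
                        "strand": strand,
                        "context": context,
                    }
                )
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "context"])
    df = df.drop_duplicates(subset=["chrom", "position", "strand"])
    return MethylationCallSet(df.sort_values(["chrom", "position"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Accession SNPs


def _genomic_position_of_offset(model, offset: int) -> int:
    """Inverse of spliced-CDS offset -> genomic 1-based position."""
    if model.strand == "-":
        offset = model.cds_length - 1 - offset
    for iv in model.cds:
        if offset < iv.length:
            return iv.start + offset
        offset -= iv.length
    raise IndexError("offset outside the spliced CDS")


def simulate_accession_snps(
    spec: SimulationSpec,
    annotation: GenomeAnnotation,
    seed: int = 0,
) -> list[SnpRecord]:
    """Biallelic SNPs planted in CDS with a target non-synonymous bias.

    The desired consequence class of each SNP is drawn Bernoulli with odds
    equal to the target non-synonymous:synonymous ratio; a CDS position and
    alternate base achieving that class are found by rejection sampling
    against the codon table. Multi-allelic sites and N calls are injected
    at the configured fractions.
    """
    rng = np.random.default_rng(seed)
    gene_list = list(annotation.genes.values())
    models = {g.id: select_representative_model(g) for g in gene_list}
    target = spec.target_nonsyn_syn_ratio
    p_nonsyn = target / (1.0 + target)
    accessions = [f"acc{i + 1:02d}" for i in range(spec.n_accessions)]

    used_positions: set[tuple[str, int]] = set()
    snps: list[SnpRecord] = []
    while len(snps) < spec.n_snps:
        # fix the desired consequence class first, then rejection-sample
        # sites until one achieves it (redrawing the class on failure would
        # bias toward the easier-to-achieve non-synonymous class)
        want = "nonsynonymous" if rng.random() < p_nonsyn else "synonymous"
        found = None
        for _ in range(1000):
            gene = gene_list[rng.integers(0, len(gene_list))]
            model = models[gene.id]
            usable = model.cds_length - model.cds_length % 3
            if usable < 3:
                continue
            offset = int(rng.integers(0, usable))
            pos = _genomic_position_of_offset(model, offset)
            if (model.chrom, pos) in used_positions:
                continue
            chrom_seq = annotation.sequences[model.chrom].seq
            ref = chrom_seq[pos - 1]
            if ref not in "ACGT":
                continue
            # reference codon on the coding strand
            codon_index, pos_in_codon = offset // 3, offset % 3 + 1
            spliced = "".join(
                chrom_seq[iv.start - 1 : iv.end] for iv in model.cds
            )
            if model.strand == "-":
                spliced = _revcomp(spliced)
            codon = spliced[codon_index * 3 : codon_index * 3 + 3]
            coding_ref = codon[pos_in_codon - 1]
            alts = [b for b in "ACGT" if b != coding_ref]
            rng.shuffle(alts)
            for alt in alts:
                if classify_consequence(codon, pos_in_codon, alt) == want:
                    found = (model, pos, ref, alt)
                    break
            if found:
                break
        if found is None:
            raise RuntimeError(
                "target non-synonymous:synonymous ratio unreachable on this CDS set"
            )
        model, pos, ref, chosen = found
        genomic_alt = chosen if model.strand == "+" else _revcomp(chosen)

        calls = []
        n_alt = int(rng.integers(1, spec.n_accessions))
        alt_carriers = set(rng.choice(spec.n_accessions, size=n_alt, replace=False))
        for i, acc in enumerate(accessions):
            if rng.random() < spec.n_call_fraction:
                calls.append((acc, "N"))
            elif i in alt_carriers:
                calls.append((acc, genomic_alt))
            else:
                calls.append((acc, ref))
        if not any(b == genomic_alt for _, b in calls):
            calls[0] = (accessions[0], genomic_alt)
        if rng.random() < spec.multiallelic_fraction:
            third = [b for b in "ACGT" if b not in (ref, genomic_alt)]
            calls[-1] = (accessions[-1], third[rng.integers(0, len(third))])
        used_positions.add((model.chrom, pos))
        snps.append(
            SnpRecord(
                chrom=model.chrom,
                position=pos,
                reference_base=ref,
                accession_calls=tuple(calls),
            )
        )
    snps.sort(key=lambda s: (s.chrom, s.position))
    return snps


# ---------------------------------------------------------------------------
# Localization predictions


def simulate_localization_predictions(
    spec: SimulationSpec,
    annotation: GenomeAnnotation,
    truth: dict[str, str],
    seed: int = 0,
    n_tie_genes: int = 0,
) -> list[IsoformLocalizationPrediction]:
    """Per-isoform compartment draws with label-dependent probabilities.

    ``n_tie_genes`` multi-isoform genes are forced into an equal-RC tie
    between two distinct targeting compartments, exercising the Uncertain
    assignment rule.
    """
    rng = np.random.default_rng(seed)
    preds: list[IsoformLocalizationPrediction] = []
    tie_candidates = [
        g for g in annotation.genes.values() if len(g.isoforms) >= 2
    ]
    tie_ids = {g.id for g in tie_candidates[:n_tie_genes]}
    rc_values = np.arange(1, 6)
    for gid, gene in annotation.genes.items():
        probs = spec.localization_probs[truth[gid]]
        if gid in tie_ids:
            rc = int(rng.choice(rc_values, p=spec.rc_probs))
            comp_pair = rng.choice(len(COMPARTMENTS) - 1, size=2, replace=False)
            for iso, ci in zip(gene.isoforms[:2], comp_pair):
                preds.append(
                    IsoformLocalizationPrediction(iso.id, gid, COMPARTMENTS[ci], rc)
                )
            continue
        for iso in gene.isoforms:
            comp = COMPARTMENTS[rng.choice(len(COMPARTMENTS), p=probs)]
            rc = int(rng.choice(rc_values, p=spec.rc_probs))
            preds.append(IsoformLocalizationPrediction(iso.id, gid, comp, rc))
    return preds
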