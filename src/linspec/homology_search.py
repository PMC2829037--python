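"""Desk-scale homology search backend.

Emulates the protein-vs-genome (TBLASTN-like) and protein-vs-protein
(BLASTP-like) searches used by the staged lineage classifier: six-frame
translation, optimal Smith-Waterman local alignment with affine gaps
(via Bio.Align.PairwiseAligner), and Karlin-Altschul E-values

    E = K * m * n * exp(-lambda * S)

with m the query length and n the (translated) database length. The backend
is pluggable: tabular hit files (BLAST outfmt-6-like) can be ingested in
place of the built-in search so external search output can drive the
classifier at genome scale.

Alignments in translated frames never cross a stop codon: each frame is
split at ``*`` and segments are aligned independently, mimicking HSP
behaviour. Per (query, subject, frame) only the best-scoring alignment is
kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .annotation_io import SequenceRecord

__all__ = [
    "ScoringScheme",
    "SequenceDatabase",
    "SearchHit",
    "translate_six_frames",
    "local_align",
    "evalue_from_score",
    "search_protein_vs_nucleotide",
    "search_protein_vs_protein",
    "read_tabular_hits",
    "write_tabular_hits",
]

TAXON_GROUPS = (
    "outside_clade_genomic",
    "outside_clade_transcript",
    "clade_transcript",
    "knowledgebase",
)


@dataclass
class ScoringScheme:
    """Alignment scoring + Karlin-Altschul statistics.

    Defaults are the published gapped BLOSUM62 values (gap open 11,
    extend 1, K = 0.041, lambda = 0.267 nats per score unit).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    K: float = 0.041
    lam: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self):
        return self._matrix

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self._matrix
        # BLAST convention: a gap of length k costs open + k * extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    @property
    def max_match_score(self) -> float:
        """Largest diagonal entry; bounds the score per aligned residue."""
        import numpy as np

        return float(np.max(np.diag(self._matrix)))


@dataclass
class SequenceDatabase:
    """A FASTA-backed subject database tagged by taxon group."""

    name: str
    records: list[SequenceRecord]
    taxon_group: str
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"database {self.name}: unknown taxon group {self.taxon_group!r}"
            )
        self._frames: dict[str, list[tuple[int, str]]] | None = None

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def translated_frames(self) -> dict[str, list[tuple[int, str]]]:
        """Six-frame translations per record, computed once per database."""
        if self._frames is None:
            self._frames = {}
            for rec in self.records:
                frames = []
                for frame_rec in translate_six_frames(rec):
                    frame = int(frame_rec.id.rsplit("frame", 1)[1])
                    frames.append((frame, frame_rec.seq))
                self._frames[rec.id] = frames
        return self._frames


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity_fraction: float
    aligned_length: int
    frame: int = 0  # 0 = protein subject; +-1..3 = translated frame

    def __post_init__(self) -> None:
        if self.evalue < 0 or not (0.0 <= self.identity_fraction <= 1.0):
            raise ValueError("invalid hit statistics")


# ---------------------------------------------------------------------------
# Translation


def translate_six_frames(nt: SequenceRecord) -> list[SequenceRecord]:
    """All six translation frames; stops as ``*``, N-containing codons as X.

    Frames +1..+3 read the forward strand with offsets 0..2; -1..-3 read
    the reverse complement likewise. Sequences shorter than 3 nt yield
    empty translations.
    """
    fwd = nt.seq.upper()
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for strand_seq, sign in ((fwd, 1), (rev, -1)):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            frames.append(SequenceRecord(f"{nt.id}|frame{sign * (offset + 1)}", aa))
    return frames


# ---------------------------------------------------------------------------
# Alignment and E-values


def local_align(
    q: SequenceRecord | str,
    s: SequenceRecord | str,
    scheme: ScoringScheme | None = None,
) -> tuple[float, float, int]:
    """Optimal local alignment: (raw score, identity fraction, aligned length).

    Affine gaps (open + k*extend for a length-k gap); identity fraction is
    identities over alignment columns (gap columns included), the BLAST
    tabular convention. Empty input or no positive-scoring alignment
    returns (0, 0.0, 0).
    """
    scheme = scheme or ScoringScheme()
    qs = q.seq if isinstance(q, SequenceRecord) else q
    ss = s.seq if isinstance(s, SequenceRecord) else s
    if not qs or not ss:
        return 0.0, 0.0, 0
    aligner = scheme.make_aligner()
    score = aligner.score(qs, ss)
    if score <= 0:
        return 0.0, 0.0, 0
    alignment = next(iter(aligner.align(qs, ss)))
    counts = alignment.counts()
    aligned_length = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / aligned_length if aligned_length else 0.0
    return float(score), identity, aligned_length


def evalue_from_score(
    S: float, m: int, n: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    scheme = scheme or ScoringScheme()
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lam * S)


# ---------------------------------------------------------------------------
# Database search


def _finish(hits: list[SearchHit]) -> list[SearchHit]:
    return sorted(hits, key=lambda h: (h.evalue, -h.score, h.subject_id))


def _min_significant_score(
    e_cutoff: float, m: int, n: int, scheme: ScoringScheme
) -> float:
    """Smallest raw score whose E-value clears the cutoff."""
    if e_cutoff == math.inf:
        return 0.0
    if e_cutoff <= 0:
        return math.inf  # no finite score can clear a zero cutoff
    return math.log(scheme.K * m * n / e_cutoff) / scheme.lam


def _best_segment_score(
    aligner, query_seq: str, subject_aa: str, min_useful: float, max_diag: float
) -> tuple[float, str]:
    """Best score of query against the stop-free segments of a frame.

    Segments whose length bound ``max_diag * len`` cannot reach
    ``min_useful`` are skipped — they can never yield a reportable hit.
    Returns (score, best segment).
    """
    best, best_seg = 0.0, ""
    for segment in subject_aa.split("*"):
        if not segment or max_diag * min(len(segment), len(query_seq)) <= min_useful:
            continue
        score = aligner.score(query_seq, segment)
        if score > best:
            best, best_seg = score, segment
    return best, best_seg


def _identity_stats(aligner, query_seq: str, subject_seq: str) -> tuple[float, int]:
    alignment = next(iter(aligner.align(query_seq, subject_seq)))
    counts = alignment.counts()
    alen = counts.gaps + counts.identities + counts.mismatches
    return (counts.identities / alen if alen else 0.0), alen


def search_protein_vs_nucleotide(
    query: SequenceRecord,
    db: SequenceDatabase,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
) -> list[SearchHit]:
    """TBLASTN-like search of a protein query against a nucleotide database.

    Each subject is translated in six frames; the best alignment per
    (subject, frame) with E < ``e_cutoff`` is reported, sorted by E-value.
    The database length in the E-value formula is the translated length
    (total nucleotides / 3).
    """
    scheme = scheme or ScoringScheme()
    n_db = max(1, db.total_length // 3)
    min_score = _min_significant_score(e_cutoff, max(1, len(query)), n_db, scheme)
    aligner = scheme.make_aligner()
    max_diag = scheme.max_match_score
    hits = []
    for rec in db.records:
        for frame, aa in db.translated_frames()[rec.id]:
            score, seg = _best_segment_score(
                aligner, query.seq, aa, min_score, max_diag
            )
            if score <= min_score:
                continue
            E = evalue_from_score(score, len(query), n_db, scheme)
            if E < e_cutoff:
                ident, alen = _identity_stats(aligner, query.seq, seg)
                hits.append(SearchHit(query.id, rec.id, score, E, ident, alen, frame))
    return _finish(hits)


def search_protein_vs_protein(
    query: SequenceRecord,
    db: SequenceDatabase,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
) -> list[SearchHit]:
    """BLASTP-like search of a protein query against a protein database."""
    scheme = scheme or ScoringScheme()
    n_db = max(1, db.total_length)
    min_score = _min_significant_score(e_cutoff, max(1, len(query)), n_db, scheme)
    aligner = scheme.make_aligner()
    max_diag = scheme.max_match_score
    hits = []
    for rec in db.records:
        if not rec.seq or max_diag * min(len(rec), len(query)) <= min_score:
            continue
        score = aligner.score(query.seq, rec.seq)
        if score <= min_score:
            continue
        E = evalue_from_score(score, len(query), n_db, scheme)
        if E < e_cutoff:
            ident, alen = _identity_stats(aligner, query.seq, rec.seq)
            hits.append(SearchHit(query.id, rec.id, score, E, ident, alen, 0))
    return _finish(hits)


def find_first_hit(
    query: SequenceRecord,
    db: SequenceDatabase,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-5,
    exclude_subject=None,
) -> SearchHit | None:
    """Existence check: the first subject with E < cutoff, or None.

    Equivalent to ``bool(search_*(...))`` but returns as soon as any
    subject passes, which is what the staged classifier needs.
    """
    scheme = scheme or ScoringScheme()
    protein_db = db.taxon_group == "knowledgebase"
    n_db = max(1, db.total_length if protein_db else db.total_length // 3)
    min_score = _min_significant_score(e_cutoff, max(1, len(query)), n_db, scheme)
    aligner = scheme.make_aligner()
    max_diag = scheme.max_match_score
    for rec in db.records:
        if exclude_subject is not None and exclude_subject(rec.id):
            continue
        candidates: list[tuple[int, str]]
        if protein_db:
            candidates = [(0, rec.seq)]
        else:
            candidates = db.translated_frames()[rec.id]
        for frame, aa in candidates:
            score, seg = _best_segment_score(aligner, query.seq, aa, min_score, max_diag)
            if score <= min_score:
                continue
            E = evalue_from_score(score, len(query), n_db, scheme)
            if E < e_cutoff:
                ident, alen = _identity_stats(aligner, query.seq, seg)
                return SearchHit(query.id, rec.id, score, E, ident, alen, frame)
    return None


# ---------------------------------------------------------------------------
# Tabular (outfmt-6-like) interchange, for substituting real search output

_COLUMNS = (
    "query_id subject_id identity_pct aligned_length mismatches gap_opens "
    "q_start q_end s_start s_end evalue score"
).split()


def write_tabular_hits(hits: list[SearchHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity_fraction:.2f}"
                f"\t{h.aligned_length}\t0\t0\t0\t0\t0\t0\t{h.evalue:.3g}"
                f"\t{h.score:.1f}\n"
            )


def read_tabular_hits(path) -> list[SearchHit]:
    """Ingest 12-column BLAST-outfmt-6-like hits as SearchHit records."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 columns")
            hits.append(
                SearchHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_fraction=float(fields[2]) / 100.0,
                    aligned_length=int(fields[3]),
                    evalue=float(fields[10]),
                    score=float(fields[11]),
                )
            )
    return _finish(hits)
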