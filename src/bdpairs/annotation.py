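"""Coordinate model for genome annotations.

Reads a GFF3 gene -> transcript hierarchy into validated records with
1-based inclusive coordinates, derives transcription start sites (TSSs)
and gene spans, and loads genome sequence for promoter analyses.

The TSS of a stranded interval is its 5'-most coordinate: ``start`` on
the forward strand, ``end`` on the reverse strand.  Gene spans are the
union of all member transcripts (the "gene cluster" boundaries used by
gene-level pair searches).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

#: Feature types accepted as transcripts (configurable per call).
DEFAULT_TRANSCRIPT_TYPES = frozenset(
    {
        "mRNA",
        "transcript",
        "ncRNA",
        "lnc_RNA",
        "lincRNA",
        "tRNA",
        "rRNA",
        "snRNA",
        "snoRNA",
        "miRNA",
        "pre_miRNA",
        "pseudogenic_transcript",
    }
)

#: Feature types accepted as genes.
DEFAULT_GENE_TYPES = frozenset({"gene", "pseudogene", "transposable_element_gene"})

#: Gene feature types that imply a biotype when no attribute states one.
_FEATURETYPE_BIOTYPE = {
    "pseudogene": "pseudogene",
    "transposable_element_gene": "transposable_element",
    "pseudogenic_transcript": "pseudogene",
}

_VALID_STORE = set("ACGTN")
_IUPAC_AMBIGUITY = set("RYSWKMBDHV")


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single transcript: a stranded genomic interval with a parent gene.

    Coordinates are 1-based inclusive (GFF3 convention).  ``cds_start``,
    when present, is the genomic position of the first coding base in
    transcript orientation (the A of the start ATG).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"transcript {self.transcript_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.gene_id:
            raise AnnotationError(f"transcript {self.transcript_id}: empty gene_id")

    @property
    def tss(self) -> int:
        return self.start if self.strand == FORWARD else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == FORWARD else self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene: the coordinate union of its member transcripts."""

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    biotype: str = "protein_coding"

    @property
    def start(self) -> int:  # interval-protocol alias
        return self.span_start

    @property
    def end(self) -> int:
        return self.span_end

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == FORWARD else self.span_end

    @property
    def three_prime(self) -> int:
        return self.span_end if self.strand == FORWARD else self.span_start


def tss_of(record: TranscriptRecord | GeneRecord) -> int:
    """5'-most coordinate of a transcript or gene on its strand."""
    return record.tss


@dataclass
class GenomeAnnotation:
    """Validated annotation: transcripts, genes, and per-chromosome order.

    ``transcripts_by_chrom`` / ``genes_by_chrom`` hold records sorted by
    (start, end, id) — the physical 5'-to-3' chromosome order that the
    pair searches sweep.
    """

    transcripts: dict[str, TranscriptRecord]
    genes: dict[str, GeneRecord]
    transcripts_by_chrom: dict[str, list[TranscriptRecord]] = field(default_factory=dict)
    genes_by_chrom: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self.transcripts_by_chrom = {}
        self.genes_by_chrom = {}
        for t in self.transcripts.values():
            self.transcripts_by_chrom.setdefault(t.chrom, []).append(t)
        for g in self.genes.values():
            self.genes_by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self.transcripts_by_chrom.values():
            lst.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        for lst in self.genes_by_chrom.values():
            lst.sort(key=lambda g: (g.span_start, g.span_end, g.gene_id))

    def validate(self) -> None:
        for t in self.transcripts.values():
            g = self.genes.get(t.gene_id)
            if g is None:
                raise AnnotationError(
                    f"orphan transcript {t.transcript_id}: gene {t.gene_id} not found"
                )
            if g.chrom != t.chrom:
                raise AnnotationError(
                    f"transcript {t.transcript_id} disagrees with gene {g.gene_id} on chrom"
                )
            if not (g.span_start <= t.start and t.end <= g.span_end):
                raise AnnotationError(
                    f"gene {g.gene_id} span does not cover transcript {t.transcript_id}"
                )

    @property
    def chroms(self) -> list[str]:
        out = set(self.genes_by_chrom) | set(self.transcripts_by_chrom)
        return sorted(out)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptRecord]:
        return sorted(
            (t for t in self.transcripts.values() if t.gene_id == gene_id),
            key=lambda t: t.transcript_id,
        )

    def first_transcript(self, gene_id: str) -> TranscriptRecord:
        """Deterministic representative transcript (smallest transcript_id)."""
        ts = self.transcripts_of_gene(gene_id)
        if not ts:
            raise AnnotationError(f"gene {gene_id} has no transcripts")
        return ts[0]


def records_to_annotation(
    transcripts: list[TranscriptRecord],
    gene_biotypes: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Build a GenomeAnnotation from transcript records alone.

    Gene spans are the min/max of member transcript coordinates; gene
    biotypes default to the biotype shared by the member transcripts.
    """
    gene_biotypes = gene_biotypes or {}
    tdict: dict[str, TranscriptRecord] = {}
    for t in transcripts:
        if t.transcript_id in tdict:
            raise AnnotationError(f"duplicate transcript ID {t.transcript_id}")
        tdict[t.transcript_id] = t
    genes: dict[str, GeneRecord] = {}
    for t in tdict.values():
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = GeneRecord(
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                span_start=t.start,
                span_end=t.end,
                biotype=gene_biotypes.get(t.gene_id, t.biotype),
            )
        else:
            if g.chrom != t.chrom:
                raise AnnotationError(
                    f"gene {t.gene_id}: member transcripts disagree on chrom"
                )
            if g.strand != t.strand:
                # tolerated annotation error; gene strand stays that of the
                # first transcript, the pair searches' same-gene filter
                # prevents such transcripts pairing with each other
                logger.warning(
                    "gene %s has transcripts on both strands", t.gene_id
                )
            genes[t.gene_id] = replace(
                g,
                span_start=min(g.span_start, t.start),
                span_end=max(g.span_end, t.end),
            )
    return GenomeAnnotation(transcripts=tdict, genes=genes)


def _biotype_from_attributes(attrs, featuretype: str) -> str:
    for key in ("biotype", "gene_biotype", "type"):
        if key in attrs:
            return attrs[key][0]
    return _FEATURETYPE_BIOTYPE.get(featuretype, "protein_coding")


def parse_annotation(
    gff3_stream,
    transcript_types: frozenset[str] = DEFAULT_TRANSCRIPT_TYPES,
    gene_types: frozenset[str] = DEFAULT_GENE_TYPES,
    biotype_overrides: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 stream (or string/path) into a GenomeAnnotation.

    Genes must precede nothing in particular — the hierarchy is resolved
    after reading the whole file.  Gene spans are recomputed as the union
    of member transcripts so that multi-transcript genes get "gene
    cluster" boundaries even when the gene line understates them.

    ``biotype_overrides`` maps gene or transcript IDs to replacement
    biotypes (the two-column TSV interface).
    """
    if isinstance(gff3_stream, str) and "\n" in gff3_stream:
        handle = io.StringIO(gff3_stream)
    elif isinstance(gff3_stream, str):
        handle = open(gff3_stream)
    else:
        handle = gff3_stream
    overrides = biotype_overrides or {}

    gene_lines: dict[str, tuple] = {}
    raw_transcripts: list[tuple] = []  # (lineno, feature)
    cds_bounds: dict[str, tuple[int, int]] = {}  # transcript -> (min start, max end)

    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            break  # embedded FASTA section
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # column/attribute syntax errors
            raise AnnotationError(f"line {lineno}: cannot parse GFF3 line ({exc})") from exc
        if feat.end < feat.start:
            raise AnnotationError(f"line {lineno}: end {feat.end} < start {feat.start}")
        if feat.featuretype in gene_types:
            gid = feat.attributes.get("ID", [None])[0]
            if gid is None:
                raise AnnotationError(f"line {lineno}: gene feature without ID")
            if gid in gene_lines:
                raise AnnotationError(f"line {lineno}: duplicate gene ID {gid}")
            gene_lines[gid] = (lineno, feat)
        elif feat.featuretype in transcript_types:
            raw_transcripts.append((lineno, feat))
        elif feat.featuretype == "CDS":
            parent = feat.attributes.get("Parent", [None])[0]
            if parent is not None:
                lo, hi = cds_bounds.get(parent, (feat.start, feat.end))
                cds_bounds[parent] = (min(lo, feat.start), max(hi, feat.end))
        # other feature types (exon, UTR, chromosome...) are ignored

    transcripts: list[TranscriptRecord] = []
    seen_tids: set[str] = set()
    for lineno, feat in raw_transcripts:
        tid = feat.attributes.get("ID", [None])[0]
        if tid is None:
            raise AnnotationError(f"line {lineno}: transcript feature without ID")
        if tid in seen_tids:
            raise AnnotationError(f"line {lineno}: duplicate transcript ID {tid}")
        seen_tids.add(tid)
        parent = feat.attributes.get("Parent", [None])[0]
        if parent is None:
            raise AnnotationError(f"line {lineno}: transcript {tid} has no Parent")
        if parent not in gene_lines:
            raise AnnotationError(
                f"line {lineno}: orphan transcript {tid} (Parent {parent} absent)"
            )
        _, gfeat = gene_lines[parent]
        biotype = overrides.get(
            tid, _biotype_from_attributes(feat.attributes, feat.featuretype)
        )
        cds_start = None
        if tid in cds_bounds:
            lo, hi = cds_bounds[tid]
            cds_start = lo if feat.strand == FORWARD else hi
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=parent,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                biotype=biotype,
                cds_start=cds_start,
            )
        )

    gene_biotypes = {
        gid: overrides.get(
            gid, _biotype_from_attributes(feat.attributes, feat.featuretype)
        )
        for gid, (_, feat) in gene_lines.items()
    }
    return records_to_annotation(transcripts, gene_biotypes=gene_biotypes)


def write_gff3(annotation: GenomeAnnotation, handle=None) -> str:
    """Serialize an annotation back to GFF3 (round-trips with parse_annotation)."""
    out = handle or io.StringIO()
    out.write("##gff-version 3\n")
    for chrom in annotation.chroms:
        for g in annotation.genes_by_chrom.get(chrom, []):
            out.write(
                f"{g.chrom}\tbdpairs\tgene\t{g.span_start}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for t in annotation.transcripts_of_gene(g.gene_id):
                out.write(
                    f"{t.chrom}\tbdpairs\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={t.gene_id};biotype={t.biotype}\n"
                )
                if t.cds_start is not None:
                    cs, ce = (
                        (t.cds_start, t.end)
                        if t.strand == FORWARD
                        else (t.start, t.cds_start)
                    )
                    out.write(
                        f"{t.chrom}\tbdpairs\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t0\t"
                        f"ID=cds:{t.transcript_id};Parent={t.transcript_id}\n"
                    )
    if handle is None:
        return out.getvalue()
    return ""


class SequenceStore:
    """Uppercase genome sequences keyed by chromosome name.

    Subscripting returns the whole sequence; :meth:`fetch` slices with
    1-based inclusive coordinates.  IUPAC ambiguity codes other than N
    are stored as N; non-IUPAC characters are rejected.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            self._seqs[name] = self._clean(name, seq)

    @staticmethod
    def _clean(name: str, seq: str) -> str:
        seq = seq.upper()
        bad = set(seq) - _VALID_STORE
        if bad - _IUPAC_AMBIGUITY:
            raise AnnotationError(
                f"sequence {name}: non-IUPAC character(s) {sorted(bad - _IUPAC_AMBIGUITY)}"
            )
        if bad:
            seq = "".join(c if c in _VALID_STORE else "N" for c in seq)
        return seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice; errors if out of bounds."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom} absent from sequence store")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise AnnotationError(
                f"fetch {chrom}:{start}-{end} outside sequence of length {len(seq)}"
            )
        return seq[start - 1 : end]


def load_sequences(fasta_stream) -> SequenceStore:
    """Load FASTA (stream, path, or text) into a SequenceStore."""
    from Bio import SeqIO

    if isinstance(fasta_stream, str) and fasta_stream.lstrip().startswith(">"):
        handle = io.StringIO(fasta_stream)
    elif isinstance(fasta_stream, str):
        handle = open(fasta_stream)
    else:
        handle = fasta_stream
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seqs:
            raise AnnotationError(f"duplicate FASTA record name {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return SequenceStore(seqs)


def check_sequence_coverage(
    annotation: GenomeAnnotation, sequences: SequenceStore
) -> list[str]:
    """Chromosomes annotated but absent/too short in the FASTA.

    Pair searches need only coordinates, so such chromosomes are kept for
    searching and merely excluded from sequence analyses (warning logged).
    """
    missing = []
    for chrom in annotation.chroms:
        feats = annotation.transcripts_by_chrom.get(chrom, [])
        max_end = max((t.end for t in feats), default=0)
        if chrom not in sequences or sequences.length(chrom) < max_end:
            missing.append(chrom)
    if missing:
        logger.warning(
            "chromosomes excluded from sequence analyses (absent/short in FASTA): %s",
            ", ".join(missing),
        )
    return missing
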