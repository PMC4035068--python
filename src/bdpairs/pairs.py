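"""Detection of bidirectional, convergent, and co-directional pairs.

Two search models are provided.  The gene-level model (after Trinklein's
human genome screen) collapses each gene to the union span of its
transcripts and pairs only nearest neighbours in chromosome order.  The
transcript-level model instead scans every transcript against every
opposite-strand transcript nearby, so a gene whose long transcript
overlaps its neighbour can still form a pair through a shorter
alternative transcript — the case the gene-level model misses.

All four pair geometries reduce to the same interval arithmetic: with
the left member's interval ending at L and the right member's starting
at R (non-overlapping, so L < R), the two anchors are the facing edges
and the intergenic gap is the R - L - 1 bases strictly between them.
"Less than 1.0 kb" between anchors therefore means gap in [1, 999].
What differs per mode is which strands may occupy the left/right slots:

==========================  ============  ============
mode                        left strand   right strand
==========================  ============  ============
bidirectional (head/head)   -             +
convergent (tail/tail)      +             -
codirectional_forward       +             +
codirectional_reverse       -             -
==========================  ============  ============
"""

from __future__ import annotations

import hashlib
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .annotation import FORWARD, REVERSE, GeneRecord, GenomeAnnotation

MODES = (
    "bidirectional",
    "convergent",
    "codirectional_forward",
    "codirectional_reverse",
)
LEVELS = ("gene", "transcript")

#: (left strand, right strand) required by each mode.
_MODE_STRANDS = {
    "bidirectional": (REVERSE, FORWARD),
    "convergent": (FORWARD, REVERSE),
    "codirectional_forward": (FORWARD, FORWARD),
    "codirectional_reverse": (REVERSE, REVERSE),
}

CATEGORIES = ("coding_coding", "coding_pseudogene", "coding_transposable_element", "other")


class PairSearchError(ValueError):
    pass


@dataclass(frozen=True)
class PairRecord:
    """One called pair, members given in coordinate order (left, right)."""

    pair_id: str
    mode: str
    level: str
    chrom: str
    left_id: str
    right_id: str
    left_anchor: int
    right_anchor: int
    gap_start: int
    gap_end: int
    category: str = "other"
    n_intervening: int = 0

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start + 1

    @property
    def member_ids(self) -> tuple[str, str]:
        return (self.left_id, self.right_id)


@dataclass
class PairSet:
    pairs: list[PairRecord]
    level: str
    mode: str
    max_gap: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def member_ids(self) -> list[str]:
        """All member slots in pair order (each pair contributes two)."""
        out = []
        for p in self.pairs:
            out.extend(p.member_ids)
        return out

    def gene_ids(self, annotation: GenomeAnnotation) -> set[str]:
        """Distinct parent genes of all members."""
        out = set()
        for m in self.member_ids():
            out.add(_parent_gene(m, self.level, annotation))
        return out

    def to_records(self) -> list[dict]:
        return [
            {
                "pair_id": p.pair_id,
                "mode": p.mode,
                "level": p.level,
                "chrom": p.chrom,
                "left_id": p.left_id,
                "right_id": p.right_id,
                "left_anchor": p.left_anchor,
                "right_anchor": p.right_anchor,
                "gap_start": p.gap_start,
                "gap_end": p.gap_end,
                "gap_length": p.gap_length,
                "category": p.category,
                "n_intervening": p.n_intervening,
            }
            for p in self.pairs
        ]


@dataclass(frozen=True)
class AccountingSummary:
    """Member bookkeeping for a PairSet (the "unique vs redundant" table).

    A member occupying more than one pair slot is redundant in every slot
    beyond its first, so unique = 2 x pairs - redundant always holds.
    """

    n_pairs: int
    total_member_slots: int
    unique_members: int
    redundant_members: int
    translated_unique_genes: int
    new_unique_genes_vs_baseline: int | None = None


def _parent_gene(member_id: str, level: str, annotation: GenomeAnnotation) -> str:
    if level == "gene":
        if member_id not in annotation.genes:
            raise PairSearchError(f"gene {member_id} absent from annotation")
        return member_id
    if member_id not in annotation.transcripts:
        raise PairSearchError(f"transcript {member_id} absent from annotation")
    return annotation.transcripts[member_id].gene_id


def _pair_id(chrom: str, la: int, ra: int, lid: str, rid: str) -> str:
    key = f"{chrom}|{la}|{ra}|{lid}|{rid}".encode()
    return "bp" + hashlib.sha1(key).hexdigest()[:12]


def _record_id(rec) -> str:
    return rec.gene_id if isinstance(rec, GeneRecord) else rec.transcript_id


def _make_pair(mode: str, level: str, left, right, n_intervening: int = 0) -> PairRecord:
    la, ra = left.end, right.start
    lid, rid = _record_id(left), _record_id(right)
    return PairRecord(
        pair_id=_pair_id(left.chrom, la, ra, lid, rid),
        mode=mode,
        level=level,
        chrom=left.chrom,
        left_id=lid,
        right_id=rid,
        left_anchor=la,
        right_anchor=ra,
        gap_start=la + 1,
        gap_end=ra - 1,
        n_intervening=n_intervening,
    )


def _sort_pairs(pairs: list[PairRecord]) -> list[PairRecord]:
    pairs.sort(
        key=lambda p: (p.chrom, p.left_anchor, p.right_anchor, p.left_id, p.right_id)
    )
    return pairs


def _no_intervening_gene(genes, starts, prefix_max_end, left, right) -> bool:
    """True when no third gene's span intersects the open interval between
    left.span_end and right.span_start (the nearest-neighbour condition;
    symmetric under coordinate mirroring, unlike raw sort adjacency)."""
    cut = bisect_left(starts, right.span_start)
    max_end = prefix_max_end[cut - 1] if cut else 0
    # left itself contributes exactly left.span_end, which never exceeds it
    return max_end <= left.span_end


def _gene_level_scan(annotation: GenomeAnnotation, mode: str, max_gap: int) -> list[PairRecord]:
    """Nearest-neighbour scan over gene spans, one mode."""
    ls, rs = _MODE_STRANDS[mode]
    out: list[PairRecord] = []
    for chrom, genes in annotation.genes_by_chrom.items():
        starts = [g.span_start for g in genes]
        prefix_max_end = []
        m = 0
        for g in genes:
            m = max(m, g.span_end)
            prefix_max_end.append(m)
        for i, left in enumerate(genes):
            if left.strand != ls:
                continue
            lo = bisect_left(starts, left.span_end + 2)
            hi = bisect_right(starts, left.span_end + 1 + max_gap)
            for right in genes[lo:hi]:
                if right.strand != rs:
                    continue
                if _no_intervening_gene(genes, starts, prefix_max_end, left, right):
                    out.append(_make_pair(mode, "gene", left, right))
    return _sort_pairs(out)


def _count_intervening(tss_sorted: list[int], lo: int, hi: int) -> int:
    """TSSs strictly inside (lo, hi)."""
    return bisect_left(tss_sorted, hi) - bisect_right(tss_sorted, lo)


def _transcript_level_scan(
    annotation: GenomeAnnotation, mode: str, max_gap: int
) -> list[PairRecord]:
    """All-pairs scan over transcripts via a window sweep on start positions."""
    ls, rs = _MODE_STRANDS[mode]
    out: list[PairRecord] = []
    for chrom, transcripts in annotation.transcripts_by_chrom.items():
        rights = [t for t in transcripts if t.strand == rs]
        starts = [t.start for t in rights]
        tss_sorted = sorted(t.tss for t in transcripts)
        for left in transcripts:
            if left.strand != ls:
                continue
            # right members with start in [left.end + 2, left.end + 1 + max_gap]
            lo = bisect_left(starts, left.end + 2)
            hi = bisect_right(starts, left.end + 1 + max_gap)
            for right in rights[lo:hi]:
                if right.gene_id == left.gene_id:
                    continue
                if mode in ("codirectional_forward", "codirectional_reverse") and (
                    right.transcript_id == left.transcript_id
                ):
                    continue
                n_int = _count_intervening(tss_sorted, left.end, right.start)
                out.append(_make_pair(mode, "transcript", left, right, n_int))
    return _sort_pairs(out)


def find_pairs(
    annotation: GenomeAnnotation,
    mode: str,
    level: str = "transcript",
    max_gap: int = 999,
) -> PairSet:
    """Run one search mode at one level.  See module docstring for geometry."""
    if mode not in MODES:
        raise PairSearchError(f"unknown mode {mode!r}")
    if level not in LEVELS:
        raise PairSearchError(f"unknown level {level!r}")
    if level == "gene":
        pairs = _gene_level_scan(annotation, mode, max_gap)
    else:
        pairs = _transcript_level_scan(annotation, mode, max_gap)
    return PairSet(pairs=pairs, level=level, mode=mode, max_gap=max_gap)


def find_gene_level_bd_pairs(annotation: GenomeAnnotation, max_gap: int = 999) -> PairSet:
    """Gene-level head-to-head search (Trinklein model): nearest-neighbour
    gene spans on opposite strands with < 1 kb between their 5' ends."""
    return find_pairs(annotation, "bidirectional", "gene", max_gap)


def find_transcript_level_bd_pairs(
    annotation: GenomeAnnotation, max_gap: int = 999
) -> PairSet:
    """Transcript-level head-to-head search (modified model): every divergent
    transcript pair from different genes with TSS gap in [1, max_gap]."""
    return find_pairs(annotation, "bidirectional", "transcript", max_gap)


def find_convergent_pairs(
    annotation: GenomeAnnotation, level: str = "gene", max_gap: int = 999
) -> PairSet:
    """Tail-to-tail pairs: 3' ends facing across a gap in [1, max_gap]."""
    return find_pairs(annotation, "convergent", level, max_gap)


def find_codirectional_pairs(
    annotation: GenomeAnnotation,
    level: str = "gene",
    strand: str = FORWARD,
    max_gap: int = 999,
) -> PairSet:
    """Same-strand pairs: upstream 3' end within max_gap of downstream 5' end."""
    mode = "codirectional_forward" if strand in (FORWARD, "forward") else "codirectional_reverse"
    return find_pairs(annotation, mode, level, max_gap)


def brute_force_pairs(
    annotation: GenomeAnnotation, mode: str, level: str, max_gap: int = 999
) -> PairSet:
    """O(n^2) oracle: test every candidate pair against the predicates directly.

    Intended for small inputs; the sweep implementations must agree with
    this on every annotation.
    """
    if mode not in MODES:
        raise PairSearchError(f"unknown mode {mode!r}")
    ls, rs = _MODE_STRANDS[mode]
    out: list[PairRecord] = []
    if level == "gene":
        for chrom, genes in annotation.genes_by_chrom.items():
            for left in genes:
                for right in genes:
                    if left.gene_id == right.gene_id:
                        continue
                    if left.strand != ls or right.strand != rs:
                        continue
                    gap = right.span_start - left.span_end - 1
                    if not (1 <= gap <= max_gap):
                        continue
                    # nearest neighbours: no third gene span may intersect
                    # the open interval between the two spans
                    blocked = any(
                        g.gene_id not in (left.gene_id, right.gene_id)
                        and g.span_start < right.span_start
                        and g.span_end > left.span_end
                        for g in genes
                    )
                    if not blocked:
                        out.append(_make_pair(mode, "gene", left, right))
    else:
        for chrom, transcripts in annotation.transcripts_by_chrom.items():
            tss_sorted = sorted(t.tss for t in transcripts)
            for left in transcripts:
                for right in transcripts:
                    if left.transcript_id == right.transcript_id:
                        continue
                    if left.strand != ls or right.strand != rs:
                        continue
                    if left.gene_id == right.gene_id:
                        continue
                    gap = right.start - left.end - 1
                    if not (1 <= gap <= max_gap):
                        continue
                    n_int = _count_intervening(tss_sorted, left.end, right.start)
                    out.append(_make_pair(mode, "transcript", left, right, n_int))
    # opposite-strand modes cannot emit duplicates; codirectional all-pairs can
    seen = set()
    deduped = []
    for p in _sort_pairs(out):
        key = (p.left_id, p.right_id, p.mode)
        if key not in seen:
            seen.add(key)
            deduped.append(p)
    return PairSet(pairs=deduped, level=level, mode=mode, max_gap=max_gap)


def accounting_summary(
    pairset: PairSet,
    annotation: GenomeAnnotation,
    baseline_pairset: PairSet | None = None,
) -> AccountingSummary:
    """Member bookkeeping: slots, unique, redundant, parent genes, and the
    gene gain over a baseline pair set (e.g., transcript-level vs gene-level)."""
    slots = pairset.member_ids()
    unique = sorted(set(slots))
    for m in unique:
        _parent_gene(m, pairset.level, annotation)  # raises if unresolvable
    genes = {_parent_gene(m, pairset.level, annotation) for m in unique}
    new_genes: int | None = None
    if baseline_pairset is not None:
        base_genes = baseline_pairset.gene_ids(annotation)
        new_genes = len(genes - base_genes)
    return AccountingSummary(
        n_pairs=len(pairset),
        total_member_slots=len(slots),
        unique_members=len(unique),
        redundant_members=len(slots) - len(unique),
        translated_unique_genes=len(genes),
        new_unique_genes_vs_baseline=new_genes,
    )


def _normalize_biotype(biotype: str) -> str:
    b = biotype.lower()
    if "pseudogene" in b or b == "pseudogenic_transcript":
        return "pseudogene"
    if "transposable" in b or "transposon" in b:
        return "transposable_element"
    if b in ("protein_coding", "mrna", "coding"):
        return "protein_coding"
    return b


def classify_pair_category(pair: PairRecord, annotation: GenomeAnnotation) -> str:
    """Categorize a pair by member biotypes: both coding; coding + pseudogene;
    coding + transposable element; anything else -> other."""
    biotypes = []
    for m in pair.member_ids:
        if pair.level == "gene":
            rec = annotation.genes.get(m)
        else:
            rec = annotation.transcripts.get(m)
        if rec is None:
            raise PairSearchError(f"member {m} absent from annotation")
        biotypes.append(_normalize_biotype(rec.biotype))
    a, b = biotypes
    if a == "protein_coding" and b == "protein_coding":
        return "coding_coding"
    for special, label in (
        ("pseudogene", "coding_pseudogene"),
        ("transposable_element", "coding_transposable_element"),
    ):
        if {a, b} == {"protein_coding", special}:
            return label
    return "other"


def categorize_pairset(pairset: PairSet, annotation: GenomeAnnotation) -> PairSet:
    """Return a PairSet with the category field filled in for every pair."""
    from dataclasses import replace

    pairs = [
        replace(p, category=classify_pair_category(p, annotation)) for p in pairset.pairs
    ]
    return PairSet(pairs=pairs, level=pairset.level, mode=pairset.mode, max_gap=pairset.max_gap)
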