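"""Characterization of bidirectional promoters (BD PROs).

A BD PRO is the intergenic segment strictly between the two facing TSSs
of a head-to-head pair.  This module extracts those segments, scans the
four strict TATA-box motifs (TTATTT, TATAAAT, TATTAAT, TATATAA) in the
-10..-50 window upstream of each TSS, computes pooled GC content,
samples a length-matched random-promoter (RD PRO) background from
randomly chosen genes, builds length/chromosome distributions, and
applies the 50-bp rule that collapses near-duplicate promoters arising
from alternative transcripts of the same gene pair.

Window geometry.  Positions are measured into the promoter from each
edge.  The right edge abuts the forward-strand TSS, so its -10..-50
region is the segment 10-50 bp inward from the right edge, scanned on
the forward strand.  The left edge abuts the reverse-strand TSS; by
symmetry its window is scanned on the reverse complement.  A motif
counts as a hit when it *starts* within the window, i.e. when its first
base (read 5'->3' on the scanned strand) lies 10-50 bp from the TSS-side
edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotation import (
    FORWARD,
    REVERSE,
    GenomeAnnotation,
    SequenceStore,
)
from .pairs import PairSet

TATA_MOTIFS = ("TTATTT", "TATAAAT", "TATTAAT", "TATATAA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PromoterError(ValueError):
    pass


@dataclass(frozen=True)
class PromoterRegion:
    """The gap interval of one head-to-head pair, with forward-strand sequence.

    ``left_transcript_id`` is the reverse-strand member whose TSS sits just
    left of ``start``; ``right_transcript_id`` the forward-strand member
    whose TSS sits just right of ``end``.  ``gene_pair_key`` is the
    unordered parent-gene pair, used by the de-duplication rule.
    """

    pair_id: str
    chrom: str
    start: int
    end: int
    left_transcript_id: str
    right_transcript_id: str
    sequence: str
    gene_pair_key: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PromoterError(f"promoter {self.pair_id}: end < start")
        if len(self.sequence) != self.length:
            raise PromoterError(
                f"promoter {self.pair_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TataScanResult:
    pair_id: str
    left_hit: bool
    right_hit: bool
    hit_motifs: tuple = ()  # (end, motif, distance-from-edge of motif start)

    @property
    def classification(self) -> str:
        if self.left_hit and self.right_hit:
            return "both_ends"
        if self.left_hit or self.right_hit:
            return "one_end"
        return "none"


@dataclass(frozen=True)
class CompositionReport:
    """Pooled sequence statistics for a promoter set (one table row)."""

    set_label: str
    n_regions: int
    pooled_gc_percent: float
    mean_gc_percent: float  # unweighted mean of per-region GC
    pct_tata_both_ends: float
    pct_tata_one_end: float  # exactly one end
    pct_tata_any_end: float  # at least one end
    mean_length: float


@dataclass(frozen=True)
class RdProSummary:
    """Random-promoter background: mean over replicates of pooled GC and
    one-end TATA frequency, for length-matched upstream regions."""

    n_genes_per_replicate: int
    n_replicates: int
    region_length: int
    per_replicate_gc: tuple[float, ...]
    per_replicate_tata_pct: tuple[float, ...]
    seed: int

    @property
    def mean_gc(self) -> float:
        return float(np.mean(self.per_replicate_gc))

    @property
    def pct_tata_one_end(self) -> float:
        return float(np.mean(self.per_replicate_tata_pct))


@dataclass
class LengthHistogram:
    """Counts of promoter lengths in [k*bin_width, (k+1)*bin_width) bins."""

    bin_width: int
    bin_counts: dict[int, int]  # bin lower edge -> count

    @property
    def n(self) -> int:
        return sum(self.bin_counts.values())

    def pct_per_bin(self) -> dict[int, float]:
        n = self.n
        return {edge: 100.0 * c / n for edge, c in sorted(self.bin_counts.items())}

    def pct_range(self, a: int, b: int) -> float:
        """Percentage of promoters with length in [a, b) (a, b on bin edges)."""
        if a % self.bin_width or b % self.bin_width:
            raise PromoterError("range endpoints must lie on bin edges")
        total = sum(
            c for edge, c in self.bin_counts.items() if a <= edge < b
        )
        return 100.0 * total / self.n


def extract_promoters(
    pairset: PairSet,
    sequences: SequenceStore,
    annotation: GenomeAnnotation | None = None,
) -> list[PromoterRegion]:
    """One PromoterRegion per head-to-head pair, covering exactly its gap.

    ``annotation`` (optional) supplies parent gene ids for the
    de-duplication key; at gene level the member ids are used directly.
    """
    if pairset.mode != "bidirectional":
        raise PromoterError("promoters are defined only for bidirectional pair sets")
    regions = []
    for p in pairset:
        if p.chrom not in sequences:
            raise PromoterError(f"chromosome {p.chrom} absent from FASTA")
        if p.gap_end > sequences.length(p.chrom):
            raise PromoterError(
                f"pair {p.pair_id}: gap {p.gap_start}-{p.gap_end} exceeds "
                f"{p.chrom} length {sequences.length(p.chrom)}"
            )
        if annotation is not None and pairset.level == "transcript":
            key = tuple(
                sorted(
                    (
                        annotation.transcripts[p.left_id].gene_id,
                        annotation.transcripts[p.right_id].gene_id,
                    )
                )
            )
        else:
            key = tuple(sorted((p.left_id, p.right_id)))
        regions.append(
            PromoterRegion(
                pair_id=p.pair_id,
                chrom=p.chrom,
                start=p.gap_start,
                end=p.gap_end,
                left_transcript_id=p.left_id,
                right_transcript_id=p.right_id,
                sequence=sequences.fetch(p.chrom, p.gap_start, p.gap_end),
                gene_pair_key=key,
            )
        )
    return regions


def _window_hits(seq: str, window_near: int, window_far: int, motifs) -> list[tuple[str, int]]:
    """Motif occurrences starting 10-50 bp (near-far) from the right edge of seq.

    Returns (motif, distance) where distance is the motif start's distance
    from the right edge (1 = last base).  The window truncates at the left
    boundary of short sequences automatically.
    """
    L = len(seq)
    hits = []
    for motif in motifs:
        p = seq.find(motif)
        while p != -1:
            dist = L - p  # 1-based distance of motif start from right edge
            if window_near <= dist <= window_far:
                hits.append((motif, dist))
            p = seq.find(motif, p + 1)
    return hits


def scan_tata(
    promoter: PromoterRegion,
    window_near: int = 10,
    window_far: int = 50,
    motifs=TATA_MOTIFS,
) -> TataScanResult:
    """Scan both TSS-proximal windows of a BD PRO for strict TATA motifs.

    Right end: forward strand, window measured from the right edge.
    Left end: reverse complement, window measured from the left edge
    (equivalently the right edge of the reverse-complemented sequence).
    """
    seq = promoter.sequence
    right = _window_hits(seq, window_near, window_far, motifs)
    left = _window_hits(revcomp(seq), window_near, window_far, motifs)
    hit_motifs = tuple(
        [("left", m, d) for m, d in sorted(left)] + [("right", m, d) for m, d in sorted(right)]
    )
    return TataScanResult(
        pair_id=promoter.pair_id,
        left_hit=bool(left),
        right_hit=bool(right),
        hit_motifs=hit_motifs,
    )


def gc_percent(seq: str) -> float:
    """GC over non-N bases, as a percentage.  NaN for all-N/empty input."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def composition_report(
    regions: list[PromoterRegion],
    scan_results: list[TataScanResult],
    label: str = "BD PRO",
) -> CompositionReport:
    """Pooled GC and TATA frequencies over a promoter set.

    GC is pooled over all bases of all regions (N excluded from numerator
    and denominator); the unweighted per-region mean is also reported.
    """
    if not regions:
        raise PromoterError("empty region set")
    if len(regions) != len(scan_results):
        raise PromoterError("scan_results not aligned to regions")
    pooled = "".join(r.sequence for r in regions)
    per_region = [gc_percent(r.sequence) for r in regions]
    finite = [g for g in per_region if not math.isnan(g)]
    n = len(regions)
    n_both = sum(1 for s in scan_results if s.classification == "both_ends")
    n_one = sum(1 for s in scan_results if s.classification == "one_end")
    return CompositionReport(
        set_label=label,
        n_regions=n,
        pooled_gc_percent=gc_percent(pooled),
        mean_gc_percent=float(np.mean(finite)) if finite else float("nan"),
        pct_tata_both_ends=100.0 * n_both / n,
        pct_tata_one_end=100.0 * n_one / n,
        pct_tata_any_end=100.0 * (n_both + n_one) / n,
        mean_length=float(np.mean([r.length for r in regions])),
    )


def _upstream_region(
    gene, anchor: int, strand: str, region_length: int, chrom_len: int
) -> tuple[int, int]:
    """1-based inclusive interval of the region_length bp upstream of anchor,
    truncated at chromosome edges.  Returns (0, -1) if empty."""
    if strand == FORWARD:
        start, end = anchor - region_length, anchor - 1
    else:
        start, end = anchor + 1, anchor + region_length
    start = max(1, start)
    end = min(chrom_len, end)
    return (start, end) if start <= end else (0, -1)


def sample_rd_pros(
    annotation: GenomeAnnotation,
    sequences: SequenceStore,
    n_genes: int = 1000,
    region_length: int = 440,
    n_replicates: int = 20,
    seed: int = 0,
    window_near: int = 10,
    window_far: int = 50,
    motifs=TATA_MOTIFS,
) -> RdProSummary:
    """Sample the random-promoter (RD PRO) background.

    Per replicate, draw ``n_genes`` genes uniformly without replacement
    (with replacement, logged, if the genome has fewer) and take the
    ``region_length`` bp immediately upstream (strand-aware) of each
    gene's anchor — the start-codon position when a CDS is annotated,
    else the TSS of the gene's first transcript.  Each replicate yields
    one pooled GC value and one one-end TATA percentage (a single
    TSS-proximal window scanned in gene orientation); the summary is the
    mean over replicates.

    Defaults match a 1000-gene, 20-replicate background with regions
    length-matched to the observed mean BD PRO length (440 bp in maize).
    """
    if region_length < 1:
        raise PromoterError("region_length must be >= 1")
    eligible = [
        g
        for chrom in annotation.genes_by_chrom
        if chrom in sequences
        for g in annotation.genes_by_chrom[chrom]
    ]
    eligible.sort(key=lambda g: g.gene_id)
    if not eligible:
        raise PromoterError("no genes on sequence-bearing chromosomes")
    rng = np.random.default_rng(seed)
    replace_draw = len(eligible) < n_genes
    if replace_draw:
        import logging

        logging.getLogger(__name__).warning(
            "only %d genes available for %d draws; sampling with replacement",
            len(eligible),
            n_genes,
        )
    gcs: list[float] = []
    tatas: list[float] = []
    for _ in range(n_replicates):
        idx = rng.choice(len(eligible), size=n_genes, replace=replace_draw)
        g_count = c_count = at_count = 0
        n_scanned = n_hit = 0
        for i in idx:
            g = eligible[int(i)]
            t = annotation.first_transcript(g.gene_id)
            anchor = t.cds_start if t.cds_start is not None else t.tss
            start, end = _upstream_region(
                g, anchor, g.strand, region_length, sequences.length(g.chrom)
            )
            if start == 0:
                continue
            seq = sequences.fetch(g.chrom, start, end)
            if g.strand == REVERSE:
                seq = revcomp(seq)  # gene orientation: anchor at the right edge
            g_count += seq.count("G")
            c_count += seq.count("C")
            at_count += seq.count("A") + seq.count("T")
            n_scanned += 1
            if _window_hits(seq, window_near, window_far, motifs):
                n_hit += 1
        denom = g_count + c_count + at_count
        gcs.append(100.0 * (g_count + c_count) / denom if denom else float("nan"))
        tatas.append(100.0 * n_hit / n_scanned if n_scanned else float("nan"))
    return RdProSummary(
        n_genes_per_replicate=n_genes,
        n_replicates=n_replicates,
        region_length=region_length,
        per_replicate_gc=tuple(gcs),
        per_replicate_tata_pct=tuple(tatas),
        seed=seed,
    )


def length_histogram(regions: list[PromoterRegion], bin_width: int = 100) -> LengthHistogram:
    """Histogram of promoter lengths in fixed-width bins starting at 0."""
    if not regions:
        raise PromoterError("empty region set")
    counts: dict[int, int] = {}
    for r in regions:
        edge = (r.length // bin_width) * bin_width
        counts[edge] = counts.get(edge, 0) + 1
    return LengthHistogram(bin_width=bin_width, bin_counts=counts)


def deduplicate_promoters(
    regions: list[PromoterRegion], min_extra: int = 50
) -> list[PromoterRegion]:
    """Collapse alternative-transcript promoters of the same gene pair.

    Within each unordered gene-pair group, promoters are sorted by length;
    the shortest is kept, and each longer one is kept only if it exceeds
    the last kept length by at least ``min_extra`` bp.  Singleton groups
    pass through.
    """
    groups: dict[tuple[str, str], list[PromoterRegion]] = {}
    for r in regions:
        groups.setdefault(r.gene_pair_key, []).append(r)
    kept: list[PromoterRegion] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: (r.length, r.pair_id))
        last = None
        for r in members:
            if last is None or r.length - last >= min_extra:
                kept.append(r)
                last = r.length
    kept.sort(key=lambda r: (r.chrom, r.start, r.end, r.pair_id))
    return kept


def summarize_by_chromosome(pairset: PairSet, top_k: int = 3):
    """Per-chromosome pair counts and percentages, plus the top-k share.

    Returns (DataFrame with chrom/count/percent, top-k aggregate percent).
    """
    import pandas as pd

    counts: dict[str, int] = {}
    for p in pairset:
        counts[p.chrom] = counts.get(p.chrom, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["chrom", "count", "percent"]), 0.0
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["chrom", "count"],
    )
    total = df["count"].sum()
    df["percent"] = 100.0 * df["count"] / total
    top_pct = float(df["percent"].head(top_k).sum())
    return df, top_pct
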