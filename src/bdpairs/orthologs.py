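"""Structural conservation of head-to-head pairs via BLASTp orthologs.

Consumes standard 12-column tabular BLAST output (outfmt 6), builds a
deterministic best-hit map per query transcript (e-value, then bitscore,
then subject id), and counts how many source pairs have both orthologs
arranged head-to-head on one target chromosome within each TSS-distance
threshold.  Distances are the absolute difference of the two subject
TSS coordinates; thresholds are cumulative, so counts are non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .annotation import REVERSE, GenomeAnnotation
from .pairs import PairSet

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_THRESHOLDS = (500, 1000, 2000, 5000)

_COLUMNS = (
    "query_id subject_id percent_identity alignment_length mismatches "
    "gap_opens q_start q_end s_start s_end evalue bitscore"
).split()


class OrthologError(ValueError):
    pass


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class OrthologMapping:
    subject_id: str
    evalue: float
    bitscore: float


@dataclass
class OrthologMap:
    """Best-hit subject per query transcript, after e-value filtering."""

    mapping: dict[str, OrthologMapping]
    max_evalue: float = DEFAULT_MAX_EVALUE

    def __contains__(self, query_id: str) -> bool:
        return query_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def subject_of(self, query_id: str) -> str:
        return self.mapping[query_id].subject_id

    def mapped_queries(self) -> set[str]:
        return set(self.mapping)


@dataclass
class ConservationTable:
    """Counts of conserved head-to-head arrangements per TSS-distance threshold."""

    total_mapped: int
    n_source_pairs: int
    n_pairs_both_mapped: int
    thresholds: tuple[int, ...]
    counts: dict[int, int]  # threshold -> cumulative count

    def as_row(self) -> dict:
        row = {"total_mapped": self.total_mapped}
        row.update({f"within_{t}bp": self.counts[t] for t in self.thresholds})
        return row


@dataclass
class OverlapCounts:
    """Exclusive Venn-region counts of mapped source ids across species."""

    species: tuple[str, ...]
    totals: dict[str, int]  # per-species mapped totals
    regions: dict[str, int]  # e.g. "A∩B" -> ids mapped in exactly {A, B}

    def intersection_all(self) -> int:
        return self.regions.get("∩".join(self.species), 0)


def read_blast_tabular(stream, max_evalue: float = DEFAULT_MAX_EVALUE) -> list[BlastHit]:
    """Parse outfmt-6 lines, keeping hits with evalue < max_evalue in file order.

    ``stream`` may be an open handle, a path, or the tabular text itself.
    Lines starting with '#' are comments.
    """
    import io

    if isinstance(stream, str):
        if "\t" in stream or "\n" in stream:
            handle = io.StringIO(stream)
        else:
            handle = open(stream)
    else:
        handle = stream
    hits: list[BlastHit] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise OrthologError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hit = BlastHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise OrthologError(f"line {lineno}: unparseable numeric field ({exc})") from exc
        if hit.evalue < max_evalue:
            hits.append(hit)
    return hits


def best_hit_map(
    hits: list[BlastHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    exclude_self: bool = False,
) -> OrthologMap:
    """One best subject per query: smallest e-value, then largest bitscore,
    then lexicographically smallest subject id.  ``exclude_self`` drops
    query==subject hits (for within-species searches)."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        if exclude_self and h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return OrthologMap(
        mapping={
            q: OrthologMapping(subject_id=h.subject_id, evalue=h.evalue, bitscore=h.bitscore)
            for q, h in best.items()
        },
        max_evalue=max_evalue,
    )


def count_conserved_pairs(
    source_pairset: PairSet,
    ortholog_map: OrthologMap,
    target_annotation: GenomeAnnotation,
    thresholds=DEFAULT_THRESHOLDS,
) -> ConservationTable:
    """Count source pairs whose two orthologs are head-to-head in the target.

    A pair is conserved at threshold t when both members map, the two
    subject transcripts lie on the same target chromosome on opposite
    strands in divergent orientation (reverse-strand TSS left of
    forward-strand TSS), and their TSS distance is <= t.  Counts are
    cumulative across thresholds.
    """
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(set(thresholds)) or not thresholds:
        raise OrthologError("thresholds must be strictly increasing and non-empty")
    members = set(source_pairset.member_ids())
    total_mapped = sum(1 for m in members if m in ortholog_map)
    counts = {t: 0 for t in thresholds}
    n_both = 0
    missing: list[str] = []
    for p in source_pairset:
        if p.left_id not in ortholog_map or p.right_id not in ortholog_map:
            continue
        n_both += 1
        s1 = ortholog_map.subject_of(p.left_id)
        s2 = ortholog_map.subject_of(p.right_id)
        if s1 == s2:
            continue  # both members collapse onto one subject: not a pair
        t1 = target_annotation.transcripts.get(s1)
        t2 = target_annotation.transcripts.get(s2)
        if t1 is None or t2 is None:
            missing.extend(s for s, t in ((s1, t1), (s2, t2)) if t is None)
            continue
        if t1.chrom != t2.chrom or t1.strand == t2.strand:
            continue
        rev, fwd = (t1, t2) if t1.strand == REVERSE else (t2, t1)
        if rev.tss >= fwd.tss:
            continue  # convergent/overlapping, not head-to-head
        dist = abs(fwd.tss - rev.tss)
        for t in thresholds:
            if dist <= t:
                counts[t] += 1
    if missing:
        raise OrthologError(
            "subject transcripts absent from target annotation: "
            + ", ".join(sorted(set(missing)))
        )
    return ConservationTable(
        total_mapped=total_mapped,
        n_source_pairs=len(source_pairset),
        n_pairs_both_mapped=n_both,
        thresholds=thresholds,
        counts=counts,
    )


def shared_ortholog_counts(maps: dict[str, OrthologMap]) -> OverlapCounts:
    """Venn-region counts of source transcripts mapped in each species subset.

    Region keys join species names with '∩'; each region counts source ids
    mapped in exactly that subset of species (exclusive regions, so they
    sum to the size of the union).
    """
    if not 2 <= len(maps) <= 4:
        raise OrthologError("expected 2-4 species maps")
    species = tuple(sorted(maps))
    mapped = {sp: maps[sp].mapped_queries() for sp in species}
    totals = {sp: len(mapped[sp]) for sp in species}
    regions: dict[str, int] = {}
    universe = set().union(*mapped.values())
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            inside = set(universe)
            for sp in combo:
                inside &= mapped[sp]
            for sp in species:
                if sp not in combo:
                    inside -= mapped[sp]
            regions["∩".join(combo)] = len(inside)
    return OverlapCounts(species=species, totals=totals, regions=regions)
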