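"""Synthetic genomes with planted, fully known pair structure.

The generator lays out gene "cassettes" left-to-right along each
chromosome: head-to-head, tail-to-tail, and co-directional two-gene
cassettes at chosen intergenic gaps; multi-transcript cassettes in which
a gene's long transcript overlaps its divergent neighbour while a short
alternative transcript still forms a transcript-level pair (invisible to
the gene-level search); and isolated decoy genes.  Cassettes are
separated by >= 1000 bp of spacer so no unplanned pair can satisfy a
sub-kilobase gap rule, and a post-generation audit re-runs the searches
to assert that the emitted annotation yields exactly the planted truth.

Promoter sequences are drawn from a configurable base composition;
strict TATA motifs can be planted at chosen offsets inside either
TSS-proximal scan window, and window segments are resampled until the
scan classification equals the plan (so accidental motifs never corrupt
the truth table).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    FORWARD,
    REVERSE,
    GenomeAnnotation,
    TranscriptRecord,
    records_to_annotation,
)
from .pairs import MODES, PairSet, find_pairs
from .promoters import PromoterRegion, revcomp, scan_tata

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticDatasetSpec:
    """Parameters of one synthetic genome.

    ``gap_lengths`` is either an explicit list (cycled over cassettes) or
    a (lo, hi) range sampled uniformly; planted gaps should stay within
    [1, 999] unless exclusion behaviour is itself under test.
    ``tata_plan`` maps the ordinal of a planted head-to-head promoter
    (plain cassettes first, then multi-transcript cassettes) to a list of
    (end, motif, offset) plants, where ``end`` is "left"/"right" and
    ``offset`` the motif start's distance from that end's TSS-side edge.
    """

    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_bd_pairs: int = 5
    n_convergent: int = 0
    n_codirectional_f: int = 0
    n_codirectional_r: int = 0
    gap_lengths: tuple | list = (100, 900)
    n_multi_transcript_cases: int = 0
    n_decoy_genes: int = 0
    base_composition: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    tata_plan: dict = field(default_factory=dict)
    gene_length_range: tuple[int, int] = (300, 800)
    spacer_range: tuple[int, int] = (1001, 2000)
    seed: int = 0


@dataclass(frozen=True)
class PlantedPair:
    mode: str
    gene_visible: bool  # findable by the gene-level search
    left_transcript: str
    right_transcript: str
    left_gene: str
    right_gene: str
    chrom: str
    gap_start: int
    gap_end: int

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start + 1


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset: what every search must find."""

    pairs: list[PlantedPair]
    tata_classes: dict[tuple[str, str], str]  # (left_t, right_t) -> classification

    def expected(self, mode: str, level: str, max_gap: int = 999) -> set[tuple[str, str, int]]:
        """(left gene, right gene, gap length) triples findable at a level.

        Pairs planted with gaps beyond ``max_gap`` (to test exclusion) are
        not expected to be found.
        """
        out = set()
        for p in self.pairs:
            if p.mode != mode or p.gap_length > max_gap:
                continue
            if level == "gene" and not p.gene_visible:
                continue
            out.add((p.left_gene, p.right_gene, p.gap_length))
        return out


def _sample_bases(rng: np.random.Generator, n: int, composition: dict) -> np.ndarray:
    probs = np.array([composition.get(b, 0.0) for b in "ACGT"], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise SimulationError("base_composition must sum to 1 over A/C/G/T")
    return _BASES[rng.choice(4, size=n, p=probs)]


def _gap_iter(spec: SyntheticDatasetSpec, rng: np.random.Generator):
    """A (lo, hi) tuple is a uniform range; a list is cycled verbatim."""
    gaps = spec.gap_lengths
    if isinstance(gaps, tuple) and len(gaps) == 2:
        lo, hi = gaps
        while True:
            yield int(rng.integers(lo, hi + 1))
    else:
        i = 0
        seq = list(gaps)
        while True:
            yield int(seq[i % len(seq)])
            i += 1


def _plant_promoter_sequence(
    chrom_seq: np.ndarray,
    gap_start: int,
    gap_end: int,
    plants: list[tuple[str, str, int]],
    rng: np.random.Generator,
    composition: dict,
    max_tries: int = 200,
) -> str:
    """Write a promoter sequence whose TATA scan matches the plan exactly.

    Planted motifs are written at their offsets; random segments are
    resampled until no accidental in-window motif alters the planned
    left/right hit pattern.
    """
    L = gap_end - gap_start + 1
    want_left = any(end == "left" for end, _, _ in plants)
    want_right = any(end == "right" for end, _, _ in plants)
    for _ in range(max_tries):
        seg = _sample_bases(rng, L, composition)
        for end, motif, offset in plants:
            m = len(motif)
            if end == "right":
                # motif start `offset` bp from the right edge, forward strand
                p0 = L - offset  # 0-based
                if p0 < 0 or p0 + m > L:
                    raise SimulationError(
                        f"cannot plant {motif} at right offset {offset} in {L}-bp promoter"
                    )
                seg[p0 : p0 + m] = list(motif)
            else:
                # left end: reverse-complement strand; motif start `offset`
                # bp from the left edge means revcomp(motif) occupies
                # forward positions offset-m+1 .. offset (1-based)
                p0 = offset - m  # 0-based start of revcomp(motif)
                if p0 < 0 or offset > L:
                    raise SimulationError(
                        f"cannot plant {motif} at left offset {offset} in {L}-bp promoter"
                    )
                seg[p0:offset] = list(revcomp(motif))
        seq = "".join(seg)
        probe = PromoterRegion(
            pair_id="probe",
            chrom="probe",
            start=gap_start,
            end=gap_end,
            left_transcript_id="",
            right_transcript_id="",
            sequence=seq,
        )
        res = scan_tata(probe)
        if res.left_hit == want_left and res.right_hit == want_right:
            chrom_seq[gap_start - 1 : gap_end] = seg
            return seq
    raise SimulationError("could not realize planned TATA pattern (composition too motif-rich?)")


def generate_synthetic_dataset(
    spec: SyntheticDatasetSpec, seed: int | None = None
) -> tuple[str, str, TruthTable]:
    """Generate (FASTA text, GFF3 text, TruthTable) for a dataset spec.

    Deterministic for a fixed seed (``seed`` overrides ``spec.seed``).
    Raises if the planted cassettes cannot be packed into the requested
    chromosome length, stating the length required.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gaps = _gap_iter(spec, rng)
    glen = lambda: int(rng.integers(*spec.gene_length_range))
    spacer = lambda: int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))

    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    cursors = {c: 1 for c in chroms}
    transcripts: list[TranscriptRecord] = []
    planted: list[PlantedPair] = []
    bd_promoters: list[tuple[str, int, int, tuple[str, str]]] = []  # chrom, gap, members
    counter = 0

    def next_chrom() -> str:
        return chroms[counter % len(chroms)]

    def place_two_gene_cassette(mode: str) -> None:
        nonlocal counter
        counter += 1
        chrom = next_chrom()
        s = cursors[chrom] + spacer()
        l1, l2 = glen(), glen()
        g = next(gaps)
        left_strand = {"bidirectional": REVERSE, "convergent": FORWARD,
                       "codirectional_forward": FORWARD, "codirectional_reverse": REVERSE}[mode]
        right_strand = {"bidirectional": FORWARD, "convergent": REVERSE,
                        "codirectional_forward": FORWARD, "codirectional_reverse": REVERSE}[mode]
        tag = {"bidirectional": "bd", "convergent": "cv",
               "codirectional_forward": "cf", "codirectional_reverse": "cr"}[mode]
        ga, gb = f"{tag}{counter:04d}a", f"{tag}{counter:04d}b"
        left = TranscriptRecord(f"{ga}.t1", ga, chrom, left_strand, s, s + l1 - 1)
        r0 = s + l1 + g
        right = TranscriptRecord(f"{gb}.t1", gb, chrom, right_strand, r0, r0 + l2 - 1)
        transcripts.extend([left, right])
        planted.append(
            PlantedPair(
                mode=mode,
                gene_visible=True,
                left_transcript=left.transcript_id,
                right_transcript=right.transcript_id,
                left_gene=ga,
                right_gene=gb,
                chrom=chrom,
                gap_start=left.end + 1,
                gap_end=right.start - 1,
            )
        )
        if mode == "bidirectional":
            bd_promoters.append(
                (chrom, left.end + 1, right.start - 1, (left.transcript_id, right.transcript_id))
            )
        cursors[chrom] = right.end

    def place_fig1b_cassette() -> None:
        """Reverse-strand gene with two transcripts sharing a 3' end; the
        long one overlaps the forward neighbour, the short one pairs."""
        nonlocal counter
        counter += 1
        chrom = next_chrom()
        s = cursors[chrom] + spacer()
        short_len = glen()
        g = next(gaps)
        ga, gb = f"mt{counter:04d}a", f"mt{counter:04d}b"
        b = s + short_len - 1  # short transcript TSS (reverse strand)
        d = b + g + 1  # neighbour start
        e = d + 399  # neighbour end
        c = d + 150  # long transcript reaches into the neighbour
        t_short = TranscriptRecord(f"{ga}.t2", ga, chrom, REVERSE, s, b)
        t_long = TranscriptRecord(f"{ga}.t1", ga, chrom, REVERSE, s, c)
        t_right = TranscriptRecord(f"{gb}.t1", gb, chrom, FORWARD, d, e)
        transcripts.extend([t_long, t_short, t_right])
        planted.append(
            PlantedPair(
                mode="bidirectional",
                gene_visible=False,
                left_transcript=t_short.transcript_id,
                right_transcript=t_right.transcript_id,
                left_gene=ga,
                right_gene=gb,
                chrom=chrom,
                gap_start=b + 1,
                gap_end=d - 1,
            )
        )
        bd_promoters.append((chrom, b + 1, d - 1, (t_short.transcript_id, t_right.transcript_id)))
        cursors[chrom] = e

    def place_decoy() -> None:
        nonlocal counter
        counter += 1
        chrom = next_chrom()
        s = cursors[chrom] + spacer()
        strand = FORWARD if counter % 2 else REVERSE
        gid = f"dc{counter:04d}"
        t = TranscriptRecord(f"{gid}.t1", gid, chrom, strand, s, s + glen() - 1)
        transcripts.append(t)
        cursors[chrom] = t.end

    for _ in range(spec.n_bd_pairs):
        place_two_gene_cassette("bidirectional")
    for _ in range(spec.n_convergent):
        place_two_gene_cassette("convergent")
    for _ in range(spec.n_codirectional_f):
        place_two_gene_cassette("codirectional_forward")
    for _ in range(spec.n_codirectional_r):
        place_two_gene_cassette("codirectional_reverse")
    for _ in range(spec.n_multi_transcript_cases):
        place_fig1b_cassette()
    for _ in range(spec.n_decoy_genes):
        place_decoy()

    needed = max(cursors.values()) + 100
    if needed > spec.chrom_length:
        raise SimulationError(
            f"infeasible packing: cassettes need >= {needed} bp per chromosome, "
            f"chrom_length is {spec.chrom_length}"
        )

    # sequence: random background, then promoter plants with audit
    chrom_arrays = {
        c: _sample_bases(rng, spec.chrom_length, spec.base_composition) for c in chroms
    }
    tata_classes: dict[tuple[str, str], str] = {}
    for ordinal, (chrom, gs, ge, members) in enumerate(bd_promoters):
        plants = list(spec.tata_plan.get(ordinal, []))
        _plant_promoter_sequence(
            chrom_arrays[chrom], gs, ge, plants, rng, spec.base_composition
        )
        ends = {end for end, _, _ in plants}
        tata_classes[members] = (
            "both_ends" if ends == {"left", "right"} else "one_end" if ends else "none"
        )

    fasta = io.StringIO()
    for c in chroms:
        fasta.write(f">{c}\n")
        seq = "".join(chrom_arrays[c])
        for i in range(0, len(seq), 80):
            fasta.write(seq[i : i + 80] + "\n")

    annotation = records_to_annotation(transcripts)
    from .annotation import write_gff3

    gff3_text = write_gff3(annotation)
    truth = TruthTable(pairs=planted, tata_classes=tata_classes)
    _audit(annotation, truth)
    return fasta.getvalue(), gff3_text, truth


def _audit(annotation: GenomeAnnotation, truth: TruthTable) -> None:
    """Assert the searches recover exactly the planted truth (no accidental pairs)."""
    for mode in MODES:
        for level in ("gene", "transcript"):
            found = find_pairs(annotation, mode, level)
            got = set()
            for p in found:
                if level == "gene":
                    lg, rg = p.left_id, p.right_id
                else:
                    lg = annotation.transcripts[p.left_id].gene_id
                    rg = annotation.transcripts[p.right_id].gene_id
                got.add((lg, rg, p.gap_length))
            want = truth.expected(mode, level)
            if got != want:
                raise SimulationError(
                    f"audit failure for {mode}/{level}: planted {sorted(want)} "
                    f"but searches found {sorted(got)}"
                )


@dataclass
class OrthologFixtureTruth:
    """Planted ortholog map and conserved-pair distances."""

    ortholog_map: dict[str, str]  # source transcript -> target transcript
    conserved_distances: dict[tuple[str, str], int]  # (left, right) -> TSS distance
    n_source_pairs: int

    def expected_count(self, threshold: int) -> int:
        return sum(1 for d in self.conserved_distances.values() if d <= threshold)


def generate_ortholog_fixture(
    source_pairset: PairSet,
    conserved_fraction: float,
    distance_plan=(400,),
    seed: int = 0,
    n_decoy_hits: int = 5,
) -> tuple[GenomeAnnotation, str, OrthologFixtureTruth]:
    """Build a target annotation + BLAST table realizing a known ortholog map.

    The first round(fraction * n) source pairs map to divergent target
    pairs at the planned TSS distances (cycled); the rest map to subjects
    scattered over other chromosomes or the same strand.  The BLAST
    table encodes the true map at e-value 1e-30 with weaker secondary
    hits below threshold and decoy hits above it.
    """
    if not 0.0 <= conserved_fraction <= 1.0:
        raise SimulationError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = list(source_pairset)
    n = len(pairs)
    k = round(conserved_fraction * n)
    distances = [int(distance_plan[i % len(distance_plan)]) for i in range(k)]

    target_transcripts: list[TranscriptRecord] = []
    blast_lines: list[str] = []
    omap: dict[str, str] = {}
    conserved: dict[tuple[str, str], int] = {}
    cursor = {"t_chr1": 1, "t_chr2": 1, "t_chr3": 1}
    body = 300

    def add_hit(q: str, s: str, evalue: float, bitscore: float) -> None:
        blast_lines.append(
            f"{q}\t{s}\t85.00\t200\t30\t0\t1\t200\t1\t200\t{evalue:.1e}\t{bitscore:.1f}"
        )

    for i, p in enumerate(pairs):
        sa, sb = f"t{i:04d}a.1", f"t{i:04d}b.1"
        if i < k:
            d = distances[i]
            x = cursor["t_chr1"] + 2000
            rev = TranscriptRecord(sa, f"tg{i:04d}a", "t_chr1", REVERSE, x, x + body - 1)
            fwd_start = rev.end + d  # TSS distance = fwd.start - rev.end
            fwd = TranscriptRecord(sb, f"tg{i:04d}b", "t_chr1", FORWARD, fwd_start, fwd_start + body - 1)
            target_transcripts.extend([rev, fwd])
            cursor["t_chr1"] = fwd.end
            conserved[(p.left_id, p.right_id)] = d
        else:
            # scattered: different chromosomes (even) or same strand far apart (odd)
            if i % 2 == 0:
                x2 = cursor["t_chr2"] + 2000
                x3 = cursor["t_chr3"] + 2000
                ta = TranscriptRecord(sa, f"tg{i:04d}a", "t_chr2", REVERSE, x2, x2 + body - 1)
                tb = TranscriptRecord(sb, f"tg{i:04d}b", "t_chr3", FORWARD, x3, x3 + body - 1)
                cursor["t_chr2"] = ta.end
                cursor["t_chr3"] = tb.end
            else:
                x = cursor["t_chr2"] + 2000
                ta = TranscriptRecord(sa, f"tg{i:04d}a", "t_chr2", FORWARD, x, x + body - 1)
                tb = TranscriptRecord(
                    sb, f"tg{i:04d}b", "t_chr2", FORWARD, x + body + 9999, x + 2 * body + 9998
                )
                cursor["t_chr2"] = tb.end
            target_transcripts.extend([ta, tb])
        omap[p.left_id] = sa
        omap[p.right_id] = sb
        add_hit(p.left_id, sa, 1e-30, 210.0)
        add_hit(p.right_id, sb, 1e-30, 210.0)
        # weaker secondary hit that passes the filter but loses best-hit selection
        add_hit(p.left_id, sb, 1e-12, 90.0)

    members = sorted({m for p in pairs for m in p.member_ids})
    for j in range(min(n_decoy_hits, len(members))):
        add_hit(members[j], f"decoy{j:03d}", 1e-5, 40.0)  # above threshold: dropped

    target_annotation = records_to_annotation(target_transcripts)
    truth = OrthologFixtureTruth(
        ortholog_map=omap, conserved_distances=conserved, n_source_pairs=n
    )
    return target_annotation, "\n".join(blast_lines) + "\n", truth


def random_annotation(
    n_genes: int,
    seed: int,
    n_chromosomes: int = 2,
    genome_span: int = 50_000,
    max_transcripts: int = 3,
) -> GenomeAnnotation:
    """An arbitrary (messy, overlap-permitting) annotation for property tests.

    Unlike the planted generator, this makes no effort to avoid accidental
    pairs — it exists to feed the sweep-vs-brute-force oracle comparison.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptRecord] = []
    for i in range(n_genes):
        chrom = f"rc{int(rng.integers(1, n_chromosomes + 1))}"
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        anchor = int(rng.integers(1, genome_span))
        gid = f"rg{i:04d}"
        for j in range(int(rng.integers(1, max_transcripts + 1))):
            start = max(1, anchor + int(rng.integers(-300, 301)))
            end = start + int(rng.integers(50, 1500))
            transcripts.append(
                TranscriptRecord(f"{gid}.t{j + 1}", gid, chrom, strand, start, end)
            )
    return records_to_annotation(transcripts)
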