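import pytest

from bdpairs.annotation import TranscriptRecord, records_to_annotation


def make_annotation(*specs, biotypes=None):
    """Build an annotation from (tid, gid, chrom, strand, start, end) tuples."""
    records = [TranscriptRecord(*s) for s in specs]
    return records_to_annotation(records, gene_biotypes=biotypes or {})


@pytest.fixture
def divergent_toy():
    """Reverse gene 1-500 (5' end 500) facing forward gene 1136-2000 (5' end
    1136): a single head-to-head pair with a 635-bp intergenic gap."""
    return make_annotation(
        ("gA.t1", "gA", "chr1", "-", 1, 500),
        ("gB.t1", "gB", "chr1", "+", 1136, 2000),
    )


@pytest.fixture
def fig1b_toy():
    """Gene 1 (reverse) with a long transcript overlapping gene 2 (forward)
    and a short alternative transcript whose TSS faces gene 2 across 499 bp.
    The gene-level search sees overlapping spans and finds nothing; the
    transcript-level search finds the short-transcript pair."""
    return make_annotation(
        ("g1.t1", "g1", "chr1", "-", 200, 3000),
        ("g1.t3", "g1", "chr1", "-", 200, 1400),
        ("g2.t1", "g2", "chr1", "+", 1900, 2600),
    )
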