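"""Promoter extraction, TATA windows, GC, background sampling, de-duplication."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdpairs.annotation import SequenceStore, load_sequences
from bdpairs.promoters import (
    PromoterError,
    PromoterRegion,
    TataScanResult,
    composition_report,
    deduplicate_promoters,
    extract_promoters,
    gc_percent,
    length_histogram,
    revcomp,
    sample_rd_pros,
    scan_tata,
    summarize_by_chromosome,
)
from bdpairs.pairs import find_gene_level_bd_pairs, find_transcript_level_bd_pairs
from bdpairs.simulate import SyntheticDatasetSpec, generate_synthetic_dataset

from conftest import make_annotation


def region(seq, pair_id="p1", start=1, key=("gX", "gY")):
    return PromoterRegion(
        pair_id=pair_id,
        chrom="chr1",
        start=start,
        end=start + len(seq) - 1,
        left_transcript_id="l",
        right_transcript_id="r",
        sequence=seq,
        gene_pair_key=key,
    )


class TestExtract:
    def test_gap_slicing_contract(self, divergent_toy):
        seq = "A" * 500 + "G" * 635 + "T" * 865
        store = SequenceStore({"chr1": seq})
        ps = find_gene_level_bd_pairs(divergent_toy)
        regions = extract_promoters(ps, store, divergent_toy)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.length) == (501, 1135, 635)
        assert r.sequence == "G" * 635
        assert r.gene_pair_key == ("gA", "gB")

    def test_one_bp_gap(self):
        ann = make_annotation(
            ("gA.t1", "gA", "chr1", "-", 1, 500),
            ("gB.t1", "gB", "chr1", "+", 502, 900),
        )
        store = SequenceStore({"chr1": "C" * 1000})
        regions = extract_promoters(find_gene_level_bd_pairs(ann), store)
        assert regions[0].length == 1

    def test_missing_chromosome_errors(self, divergent_toy):
        store = SequenceStore({"chrX": "ACGT"})
        with pytest.raises(PromoterError, match="absent"):
            extract_promoters(find_gene_level_bd_pairs(divergent_toy), store)

    def test_gap_beyond_chromosome_errors(self, divergent_toy):
        store = SequenceStore({"chr1": "A" * 800})
        with pytest.raises(PromoterError, match="exceeds"):
            extract_promoters(find_gene_level_bd_pairs(divergent_toy), store)


def plant(base, motif, *, last_base_from_right=None, start_from_left=None):
    """Place a motif in an all-`base` 100-bp sequence."""
    seq = list(base * 100)
    if last_base_from_right is not None:
        end = 100 - last_base_from_right  # 0-based index past motif end
        seq[end - len(motif) : end] = list(motif)
    else:
        seq[start_from_left : start_from_left + len(motif)] = list(motif)
    return "".join(seq)


class TestTataScan:
    def test_right_window_hit(self):
        # TATAAAT with its last base 15 bp from the right edge: motif start
        # is 21 bp from the edge, inside the -10..-50 window
        res = scan_tata(region(plant("C", "TATAAAT", last_base_from_right=15)))
        assert (res.left_hit, res.right_hit) == (False, True)
        assert res.classification == "one_end"

    def test_left_window_hit_via_reverse_complement(self):
        # ATTAATA on the forward strand 20 bp from the left edge reads
        # TATTAAT on the reverse strand facing the left TSS
        res = scan_tata(region(plant("C", "ATTAATA", start_from_left=20)))
        assert (res.left_hit, res.right_hit) == (True, False)

    def test_no_motif_none(self):
        assert scan_tata(region("C" * 100)).classification == "none"

    def test_both_ends(self):
        seq = plant("C", "TATAAAT", last_base_from_right=15)
        seq = seq[:20] + "ATTAATA" + seq[27:]
        res = scan_tata(region(seq))
        assert res.classification == "both_ends"

    @pytest.mark.parametrize("last_from_right", [0, 1, 2])
    def test_motif_too_close_to_edge_misses(self, last_from_right):
        # start distance = last_from_right + 6 < 10: outside the window
        res = scan_tata(region(plant("C", "TATAAAT", last_base_from_right=last_from_right)))
        assert res.classification == "none"

    def test_motif_beyond_window_misses(self):
        # start 60 bp from the right edge: outside -10..-50
        seq = plant("C", "TATAAAT", last_base_from_right=54)
        assert scan_tata(region(seq)).classification == "none"

    def test_short_promoter_window_truncates(self):
        # 20-bp promoter: windows truncate, motif start 14 bp from right edge
        seq = "C" * 6 + "TATAAAT" + "C" * 7
        res = scan_tata(region(seq))
        assert res.right_hit

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_revcomp_swaps_end_labels(self, seq):
        fwd = scan_tata(region(seq))
        rev = scan_tata(region(revcomp(seq)))
        assert (fwd.left_hit, fwd.right_hit) == (rev.right_hit, rev.left_hit)


class TestComposition:
    def test_pooled_gc_simple(self):
        regions = [region("GCGC", "a"), region("ATAT", "b")]
        scans = [scan_tata(r) for r in regions]
        rep = composition_report(regions, scans)
        assert rep.pooled_gc_percent == pytest.approx(50.0)

    def test_single_region_gc(self):
        r = region("ATGCATGC")
        rep = composition_report([r], [scan_tata(r)])
        assert rep.pooled_gc_percent == pytest.approx(50.0)

    def test_tata_percentages(self):
        regions = [region("C" * 100, f"p{i}") for i in range(10)]
        scans = [TataScanResult(f"p{i}", False, False) for i in range(10)]
        scans[0] = TataScanResult("p0", True, True)
        scans[1] = TataScanResult("p1", True, False)
        scans[2] = TataScanResult("p2", False, True)
        rep = composition_report(regions, scans)
        assert rep.pct_tata_both_ends == pytest.approx(10.0)
        assert rep.pct_tata_one_end == pytest.approx(20.0)
        assert rep.pct_tata_any_end == pytest.approx(30.0)

    def test_empty_set_errors(self):
        with pytest.raises(PromoterError, match="empty"):
            composition_report([], [])

    def test_n_bases_excluded(self):
        r = region("GGNN")
        rep = composition_report([r], [scan_tata(r)])
        assert rep.pooled_gc_percent == pytest.approx(100.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=60), min_size=1, max_size=8))
    def test_pooled_gc_is_length_weighted_mean(self, seqs):
        regions = [region(s, f"p{i}") for i, s in enumerate(seqs)]
        scans = [scan_tata(r) for r in regions]
        rep = composition_report(regions, scans)
        weighted = sum(gc_percent(s) * len(s) for s in seqs) / sum(len(s) for s in seqs)
        assert rep.pooled_gc_percent == pytest.approx(weighted)


class TestRdPros:
    def _uniform_dataset(self, seed=5):
        spec = SyntheticDatasetSpec(
            n_bd_pairs=0, n_decoy_genes=40, chrom_length=120_000, seed=seed
        )
        fasta, gff3, _ = generate_synthetic_dataset(spec)
        from bdpairs.annotation import parse_annotation

        return parse_annotation(gff3), load_sequences(fasta)

    def test_all_g_genome_gives_100(self):
        ann = make_annotation(("g.t1", "g", "chr1", "+", 500, 900))
        store = SequenceStore({"chr1": "G" * 1000})
        rd = sample_rd_pros(ann, store, n_genes=5, region_length=100, n_replicates=3, seed=1)
        assert rd.mean_gc == pytest.approx(100.0)

    def test_uniform_genome_gc_near_50(self):
        # upstream regions of 300 bp lie wholly inside the i.i.d. uniform
        # spacers, so pooled GC is binomial over the distinct sampled bases
        ann, store = self._uniform_dataset()
        rd = sample_rd_pros(ann, store, n_genes=40, region_length=300, n_replicates=20, seed=9)
        se = 100 * math.sqrt(0.25 / (40 * 300))
        assert abs(rd.mean_gc - 50.0) < 3 * se

    def test_seed_determinism(self):
        ann, store = self._uniform_dataset()
        a = sample_rd_pros(ann, store, n_genes=20, region_length=200, n_replicates=4, seed=42)
        b = sample_rd_pros(ann, store, n_genes=20, region_length=200, n_replicates=4, seed=42)
        assert a == b

    def test_upstream_region_is_strand_aware(self):
        # reverse gene: upstream lies at higher coordinates
        ann = make_annotation(("g.t1", "g", "chr1", "-", 101, 200))
        store = SequenceStore({"chr1": "A" * 200 + "G" * 50 + "A" * 50})
        rd = sample_rd_pros(ann, store, n_genes=1, region_length=50, n_replicates=1, seed=0)
        assert rd.mean_gc == pytest.approx(100.0)

    def test_bad_region_length_errors(self):
        ann = make_annotation(("g.t1", "g", "chr1", "+", 500, 900))
        with pytest.raises(PromoterError):
            sample_rd_pros(ann, SequenceStore({"chr1": "A" * 1000}), region_length=0)


class TestHistogram:
    def test_range_percentage(self):
        regions = [region("A" * n, f"p{n}") for n in (150, 250, 350)]
        hist = length_histogram(regions)
        assert hist.pct_range(100, 300) == pytest.approx(66.7, abs=0.05)

    def test_single_bin(self):
        regions = [region("A" * 50, f"p{i}") for i in range(4)]
        hist = length_histogram(regions)
        assert hist.bin_counts == {0: 4}

    def test_two_bins_even_split(self):
        regions = [region("A" * 100, "a"), region("A" * 999, "b")]
        hist = length_histogram(regions)
        assert hist.bin_counts == {100: 1, 900: 1}
        assert hist.pct_per_bin() == {100: 50.0, 900: 50.0}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=999), min_size=1, max_size=40))
    def test_counts_conserve_n(self, lengths):
        regions = [region("A" * n, f"p{i}") for i, n in enumerate(lengths)]
        hist = length_histogram(regions)
        assert hist.n == len(lengths)
        assert sum(hist.pct_per_bin().values()) == pytest.approx(100.0)


class TestDeduplication:
    def _group(self, lengths, key=("g1", "g2")):
        return [region("A" * n, f"p{i}", key=key) for i, n in enumerate(lengths)]

    def test_insufficiently_longer_dropped(self):
        kept = deduplicate_promoters(self._group([200, 230, 300]))
        assert sorted(r.length for r in kept) == [200, 300]

    def test_each_step_at_least_50_all_kept(self):
        kept = deduplicate_promoters(self._group([200, 250, 300]))
        assert sorted(r.length for r in kept) == [200, 250, 300]

    def test_singleton_passes(self):
        kept = deduplicate_promoters(self._group([123]))
        assert len(kept) == 1

    def test_groups_independent(self):
        regions = self._group([200, 230], key=("g1", "g2")) + self._group(
            [400, 430], key=("g3", "g4")
        )
        kept = deduplicate_promoters(regions)
        assert sorted(r.length for r in kept) == [200, 400]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=999), min_size=1, max_size=20))
    def test_kept_lengths_spaced_by_min_extra(self, lengths):
        kept = deduplicate_promoters(self._group(lengths))
        ks = sorted(r.length for r in kept)
        assert ks[0] == min(lengths)
        assert all(b - a >= 50 for a, b in zip(ks, ks[1:]))


class TestChromosomeSummary:
    def test_simple_share(self):
        ann = make_annotation(
            *[
                (f"g{i}.t1", f"g{i}", "chr1", "-", 1 + 3000 * i, 500 + 3000 * i)
                for i in range(4)
            ],
            *[
                (f"h{i}.t1", f"h{i}", "chr1", "+", 700 + 3000 * i, 1500 + 3000 * i)
                for i in range(4)
            ],
            ("k.t1", "k", "chr2", "-", 1, 500),
            ("k2.t1", "k2", "chr2", "+", 700, 1500),
        )
        ps = find_transcript_level_bd_pairs(ann)
        df, top = summarize_by_chromosome(ps, top_k=1)
        row = df.set_index("chrom")
        assert row.loc["chr1", "count"] == 4
        assert row.loc["chr1", "percent"] == pytest.approx(80.0)
        assert top == pytest.approx(80.0)

    def test_empty_set(self):
        ps = find_transcript_level_bd_pairs(make_annotation(("g.t1", "g", "chr1", "+", 1, 9)))
        df, top = summarize_by_chromosome(ps)
        assert df.empty and top == 0.0

    def test_top_k_aggregate(self):
        counts = {"chr1": 2, "chr2": 1, "chr3": 1, "chr4": 1}
        specs = []
        i = 0
        for chrom, n in counts.items():
            for _ in range(n):
                base = 1 + 5000 * i
                specs.append((f"g{i}.t1", f"g{i}", chrom, "-", base, base + 400))
                specs.append((f"h{i}.t1", f"h{i}", chrom, "+", base + 600, base + 1200))
                i += 1
        ps = find_transcript_level_bd_pairs(make_annotation(*specs))
        _, top = summarize_by_chromosome(ps, top_k=3)
        assert top == pytest.approx(80.0)
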