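"""Tabular report writers: pair lists, accounting, composition, conservation.

Column names and order are fixed so downstream parsing is stable;
percentages are written to one decimal place.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .orthologs import ConservationTable, OverlapCounts
from .pairs import AccountingSummary, PairSet
from .promoters import CompositionReport, LengthHistogram, PromoterRegion, RdProSummary

PAIR_COLUMNS = [
    "pair_id",
    "mode",
    "level",
    "chrom",
    "left_id",
    "right_id",
    "left_anchor",
    "right_anchor",
    "gap_start",
    "gap_end",
    "gap_length",
    "category",
    "n_intervening",
]

ACCOUNTING_COLUMNS = [
    "label",
    "n_pairs",
    "total_member_slots",
    "unique_members",
    "redundant_members",
    "translated_unique_genes",
    "new_unique_genes_vs_baseline",
]


def pairs_to_dataframe(pairset: PairSet) -> pd.DataFrame:
    return pd.DataFrame(pairset.to_records(), columns=PAIR_COLUMNS)


def write_pairs_tsv(pairset: PairSet, path) -> None:
    pairs_to_dataframe(pairset).to_csv(path, sep="\t", index=False)


def write_gap_bed(pairset: PairSet, path) -> None:
    """Gap intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for p in pairset:
            fh.write(f"{p.chrom}\t{p.gap_start - 1}\t{p.gap_end}\t{p.pair_id}\n")


def accounting_to_dataframe(summary: AccountingSummary, label: str = "run") -> pd.DataFrame:
    row = {"label": label, **asdict(summary)}
    row["new_unique_genes_vs_baseline"] = (
        "" if row["new_unique_genes_vs_baseline"] is None else row["new_unique_genes_vs_baseline"]
    )
    return pd.DataFrame([row], columns=ACCOUNTING_COLUMNS)


def write_accounting_tsv(summary: AccountingSummary, path, label: str = "run") -> None:
    accounting_to_dataframe(summary, label).to_csv(path, sep="\t", index=False)


def write_summary_json(summaries: dict, path) -> None:
    """Arbitrary labelled summaries (dataclasses or dicts) as one JSON object."""

    def enc(obj):
        try:
            return asdict(obj)
        except TypeError:
            return str(obj)

    with open(path, "w") as fh:
        json.dump(summaries, fh, indent=2, default=enc)
        fh.write("\n")


def composition_to_dataframe(
    bd: CompositionReport, rd: RdProSummary | None = None
) -> pd.DataFrame:
    rows = [
        {
            "set": bd.set_label,
            "n": bd.n_regions,
            "gc_percent": round(bd.pooled_gc_percent, 1),
            "mean_gc_percent": round(bd.mean_gc_percent, 1),
            "pct_tata_both_ends": round(bd.pct_tata_both_ends, 1),
            "pct_tata_one_end": round(bd.pct_tata_one_end, 1),
            "pct_tata_any_end": round(bd.pct_tata_any_end, 1),
            "mean_length": round(bd.mean_length, 1),
        }
    ]
    if rd is not None:
        rows.append(
            {
                "set": "RD PRO",
                "n": rd.n_genes_per_replicate * rd.n_replicates,
                "gc_percent": round(rd.mean_gc, 1),
                "mean_gc_percent": "",
                "pct_tata_both_ends": "",
                "pct_tata_one_end": round(rd.pct_tata_one_end, 1),
                "pct_tata_any_end": "",
                "mean_length": rd.region_length,
            }
        )
    return pd.DataFrame(rows)


def write_composition_tsv(bd: CompositionReport, path, rd: RdProSummary | None = None) -> None:
    composition_to_dataframe(bd, rd).to_csv(path, sep="\t", index=False)


def write_histogram_tsv(hist: LengthHistogram, path) -> None:
    rows = [
        {
            "bin_start": edge,
            "bin_end": edge + hist.bin_width,
            "count": count,
            "percent": round(pct, 1),
        }
        for (edge, count), pct in zip(
            sorted(hist.bin_counts.items()), hist.pct_per_bin().values()
        )
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def conservation_to_dataframe(tables: dict[str, ConservationTable]) -> pd.DataFrame:
    rows = []
    for species, tab in tables.items():
        rows.append({"species": species, **tab.as_row()})
    return pd.DataFrame(rows)


def write_conservation_tsv(tables: dict[str, ConservationTable], path) -> None:
    conservation_to_dataframe(tables).to_csv(path, sep="\t", index=False)


def write_overlap_json(overlap: OverlapCounts, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"species": list(overlap.species), "totals": overlap.totals, "regions": overlap.regions},
            fh,
            indent=2,
            ensure_ascii=False,
        )
        fh.write("\n")


def write_promoter_fasta(regions: list[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.pair_id} {r.chrom}:{r.start}-{r.end}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def write_promoter_bed(regions: list[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.pair_id}\n")
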