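"""Upstream-AUG detection and assembly of the per-gene feature table.

uAUG counting is a frame-agnostic scan of the raw 5'UTR string for the
literal triplet ``ATG``: every occurrence counts, whether or not it opens a
complete upstream ORF, and a triplet spanning the 5'UTR/CDS boundary does
not (the scan is confined to the 5'UTR).  Genes split into two classes
only — ``uAUG`` (at least one hit) and ``uAUG_less`` — so genes with an
empty or missing 5'UTR are uAUG-less by definition.
"""

from __future__ import annotations

import warnings
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .genome_io import GeneModel
from .promoter_tata import PromoterCall

__all__ = [
    "UAUGScan",
    "count_uaug",
    "build_regions",
    "build_feature_table",
    "uaug_prevalence_by_class",
    "UAUG_CLASSES",
]

UAUG_CLASSES = ("uAUG", "uAUG_less")
_VALID_BASES = frozenset("ACGTN")


class UAUGScan(NamedTuple):
    count: int
    positions: tuple[int, ...]


def count_uaug(utr5: str) -> UAUGScan:
    """Count ATG triplets in a 5'UTR sequence.

    Frame-agnostic: every 0-based index ``i <= len-3`` with
    ``utr5[i:i+3] == "ATG"`` counts, positions returned ascending.  An
    empty sequence yields zero.  Triplets containing ``N`` never match
    (literal comparison).  Non-nucleotide characters raise.
    """
    seq = utr5.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in 5'UTR: {sorted(bad)}")
    positions: list[int] = []
    i = seq.find("ATG")
    while i != -1:
        positions.append(i)
        i = seq.find("ATG", i + 1)
    return UAUGScan(len(positions), tuple(positions))


def build_regions(
    utr5: Mapping[str, str] | None = None,
    utr3: Mapping[str, str] | None = None,
    cds: Mapping[str, str] | None = None,
    promoter: Mapping[str, str] | None = None,
) -> dict[str, dict[str, str]]:
    """Merge per-region sequence maps into one gene -> region mapping."""
    regions: dict[str, dict[str, str]] = {}
    for name, mapping in (("utr5", utr5), ("utr3", utr3), ("cds", cds), ("promoter", promoter)):
        if mapping is None:
            continue
        for gid, seq in mapping.items():
            regions.setdefault(gid, {})[name] = seq.upper()
    return regions


def build_feature_table(
    genes: Sequence[GeneModel],
    regions: Mapping[str, Mapping[str, str]],
    promoter_calls: Sequence[PromoterCall] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble one feature row per (deduplicated) gene.

    Lengths come from the region sequences where available (the CDS length
    falls back to the spliced annotation length for genes without a CDS
    sequence); a missing 5'UTR yields length 0 and class uAUG-less.  Genes
    with no region entry at all are reported as unjoined and omitted.
    Returns ``(table, unjoined_ids)``.
    """
    call_by_gene = {c.gene_id: c.tata_class for c in promoter_calls} if promoter_calls else {}
    rows: list[dict] = []
    unjoined: list[str] = []
    seen: set[str] = set()
    for g in genes:
        if g.symbol in seen:
            raise ValueError(f"duplicate symbol {g.symbol!r}: deduplicate before building features")
        seen.add(g.symbol)
        reg = regions.get(g.symbol)
        if reg is None:
            unjoined.append(g.symbol)
            continue
        utr5 = reg.get("utr5", "")
        utr3 = reg.get("utr3", "")
        cds = reg.get("cds")
        scan = count_uaug(utr5)
        rows.append(
            {
                "gene": g.symbol,
                "uaug_count": scan.count,
                "uaug_class": "uAUG" if scan.count >= 1 else "uAUG_less",
                "utr5_length": len(utr5),
                "utr3_length": len(utr3),
                "cds_length": len(cds) if cds is not None else g.cds_length,
                "cds_frame_ok": (len(cds) % 3 == 0) if cds is not None else (g.cds_length % 3 == 0),
                "gene_length": g.gene_length,
                "exon_count": g.exon_count,
                "tata_class": call_by_gene.get(g.symbol),
            }
        )
    if unjoined:
        warnings.warn(f"{len(unjoined)} gene(s) absent from region sequences (e.g. {unjoined[:3]})")
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "uaug_count",
            "uaug_class",
            "utr5_length",
            "utr3_length",
            "cds_length",
            "cds_frame_ok",
            "gene_length",
            "exon_count",
            "tata_class",
        ],
    )
    return table, unjoined


def uaug_prevalence_by_class(
    table: pd.DataFrame, stratifier: str = "tata_class"
) -> pd.DataFrame:
    """Contingency table of uAUG prevalence across strata of a column.

    Rows are strata, columns the uAUG/uAUG-less counts plus the row
    percentage of uAUG genes.  Empty strata (and rows with a null
    stratifier value) are dropped with a warning; fewer than two remaining
    strata is an error since there is nothing to compare.
    """
    if stratifier not in table.columns:
        raise KeyError(f"no column {stratifier!r} in feature table")
    sub = table[table[stratifier].notna()]
    dropped = len(table) - len(sub)
    if dropped:
        warnings.warn(f"{dropped} gene(s) without {stratifier!r} value excluded from prevalence table")
    counts = (
        sub.groupby([stratifier, "uaug_class"], observed=True).size().unstack(fill_value=0)
    )
    for cls in UAUG_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[list(UAUG_CLASSES)]
    counts = counts[counts.sum(axis=1) > 0]
    if len(counts) < 2:
        raise ValueError("need at least two non-empty strata to compare uAUG prevalence")
    counts["n"] = counts.sum(axis=1)
    counts["pct_uaug"] = 100.0 * counts["uAUG"] / counts["n"]
    return counts
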