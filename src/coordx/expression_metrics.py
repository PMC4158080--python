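"""Expression-derived quantities: translation efficiency, ribosomal
density, nascent-transcription (Gro-seq) rate, and tissue-atlas summaries.

Definitions:

* translation efficiency  TE = footprint reads / total mRNA reads
  (undefined — gene excluded — when the mRNA count is zero);
* ribosomal density = TE / CDS length, the per-nucleotide translational
  load of each mRNA, independent of transcript abundance;
* Gro-seq rate = reads mapped beyond TSS+1 kb divided by (gene length -
  1 kb) in kb; the first kilobase is excluded to avoid the read pileup
  from promoter-proximal polymerase pausing; rates below 5 reads/kb are
  flagged as background;
* tissue summaries over an expression atlas: mean and max across all
  tissues, and breadth = number of tissues at or above a background
  threshold (default 200 expression units).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GroseqRate",
    "TissueSummary",
    "translation_efficiency",
    "ribosomal_density",
    "groseq_rate",
    "tissue_summary",
    "split_by_expression",
    "build_expression_table",
    "read_count_table",
    "read_tissue_matrix",
    "GROSEQ_BACKGROUND",
    "TISSUE_THRESHOLD",
]

GROSEQ_BACKGROUND = 5.0  # reads/kb
TISSUE_THRESHOLD = 200.0  # expression units


class GroseqRate(NamedTuple):
    rate: float  # reads/kb beyond the first kilobase
    background: bool


class TissueSummary(NamedTuple):
    mean: float
    max: float
    breadth: int
    below_background: bool


def translation_efficiency(footprint_reads: float, mrna_reads: float) -> float | None:
    """TE = footprint/mRNA; ``None`` (gene excluded) when mRNA reads are 0."""
    if footprint_reads < 0 or mrna_reads < 0:
        raise ValueError("read counts must be non-negative")
    if mrna_reads == 0:
        return None
    return footprint_reads / mrna_reads


def ribosomal_density(te: float, cds_length: float) -> float | None:
    """TE per coding nucleotide (TE / CDS length); ``None`` for CDS length 0."""
    if cds_length == 0:
        warnings.warn("zero CDS length: ribosomal density undefined, gene excluded")
        return None
    if cds_length < 0:
        raise ValueError("CDS length must be non-negative")
    return te / cds_length


def groseq_rate(
    reads_beyond_1kb: float, gene_length: float, background_threshold: float = GROSEQ_BACKGROUND
) -> GroseqRate | None:
    """Nascent-transcription rate in reads/kb, first kilobase excluded.

    Genes spanning <= 1 kb have no post-pausing territory and are excluded
    (``None`` with a warning).  The background flag marks rates strictly
    below the threshold.
    """
    if reads_beyond_1kb < 0:
        raise ValueError("read count must be non-negative")
    if gene_length <= 1000:
        warnings.warn(f"gene length {gene_length} <= 1 kb: Gro-seq rate undefined, gene excluded")
        return None
    rate = reads_beyond_1kb / ((gene_length - 1000.0) / 1000.0)
    return GroseqRate(rate, rate < background_threshold)


def tissue_summary(
    expr_vector: Iterable[float], threshold: float = TISSUE_THRESHOLD
) -> TissueSummary:
    """Mean/max over all tissues and expression breadth (tissues >= threshold).

    The mean is taken over every tissue, expressed or not; genes whose mean
    falls below the threshold are flagged below-background (they are
    excluded from expression-level comparisons downstream, not dropped
    here).  The breadth boundary is inclusive.
    """
    v = np.asarray(list(expr_vector), dtype=float)
    if v.size == 0:
        raise ValueError("empty tissue-expression vector")
    mean = float(v.mean())
    return TissueSummary(mean, float(v.max()), int((v >= threshold).sum()), mean < threshold)


def split_by_expression(
    values: Mapping[str, float] | pd.Series, top_fraction: float = 0.25
) -> tuple[set[str], set[str]]:
    """Partition genes into top-``top_fraction`` and bottom sets by value.

    The cut is the empirical linear-interpolation quantile at
    ``1 - top_fraction``; every gene at or above the cut goes to the top
    set, so ties at the boundary all land in top.  Deterministic, and the
    two sets always partition the input.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 genes for a quantile split")
    cut = float(np.quantile(s.to_numpy(), 1.0 - top_fraction, method="linear"))
    top = set(s.index[s >= cut])
    bottom = set(s.index) - top
    return top, bottom


def read_count_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a tab-separated count table with a header row; validates columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_tissue_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x tissues expression matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene'")
    return df.set_index("gene")


def build_expression_table(
    features: pd.DataFrame,
    ribo: pd.DataFrame | None = None,
    groseq: pd.DataFrame | None = None,
    tissues: pd.DataFrame | None = None,
    background_threshold: float = GROSEQ_BACKGROUND,
    tissue_threshold: float = TISSUE_THRESHOLD,
) -> pd.DataFrame:
    """Join all expression metrics onto the feature table, one row per gene.

    Each layer is optional; genes missing from a layer get NA for that
    layer's columns.  Exclusions (zero mRNA reads, zero CDS, short genes
    for Gro-seq, below-background tissue means) are recorded in the
    ``exclusion_reason`` column rather than dropped, so every analysis can
    apply its own universe.
    """
    out = features.set_index("gene").copy()
    reasons: dict[str, list[str]] = {g: [] for g in out.index}

    if ribo is not None:
        r = ribo.set_index("gene")
        out["footprint_reads"] = r["footprint_reads"].reindex(out.index)
        out["mrna_reads"] = r["mrna_reads"].reindex(out.index)
        te = np.where(out["mrna_reads"] > 0, out["footprint_reads"] / out["mrna_reads"], np.nan)
        out["te"] = te
        for g in out.index[(out["mrna_reads"] == 0)]:
            reasons[g].append("zero_mrna_reads")
        dens = np.where(out["cds_length"] > 0, out["te"] / out["cds_length"], np.nan)
        out["ribo_density"] = dens
        for g in out.index[(out["cds_length"] == 0) & out["te"].notna()]:
            reasons[g].append("zero_cds_length")

    if groseq is not None:
        gq = groseq.set_index("gene")
        reads = gq["reads_beyond_1kb"].reindex(out.index)
        span = out["gene_length"].astype(float)
        ok = span > 1000
        rate = np.where(ok & reads.notna(), reads / ((span - 1000.0) / 1000.0), np.nan)
        out["groseq_rate"] = rate
        out["groseq_background"] = pd.array(
            np.where(np.isnan(rate), pd.NA, rate < background_threshold), dtype="boolean"
        )
        for g in out.index[(~ok) & reads.notna()]:
            reasons[g].append("gene_shorter_than_1kb")
        for g in out.index[pd.Series(rate, index=out.index) < background_threshold]:
            reasons[g].append("groseq_background")

    if tissues is not None:
        t = tissues.reindex(out.index)
        out["tissue_mean"] = t.mean(axis=1)
        out["tissue_max"] = t.max(axis=1)
        breadth = (t >= tissue_threshold).sum(axis=1)
        out["tissue_breadth"] = breadth.where(t.notna().any(axis=1))
        below = out["tissue_mean"] < tissue_threshold
        for g in out.index[below.fillna(False)]:
            reasons[g].append("tissue_below_background")

    out["exclusion_reason"] = [";".join(reasons[g]) for g in out.index]
    return out.reset_index()
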