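"""Gene-model annotation and sequence I/O.

Coordinates follow the UCSC genePred convention throughout: 0-based,
half-open ``[start, end)`` intervals on the forward genomic strand.  The
annotation dialect is refFlat-style tab-separated text with a mandatory
header row (columns ``geneName, name, chrom, strand, txStart, txEnd,
cdsStart, cdsEnd, exonCount, exonStarts, exonEnds``; exon coordinate lists
are comma-separated, a UCSC-style trailing comma is accepted and emitted).

The promoter window handed to the TATA-box scanner covers positions -40 to
-15 relative to the annotated transcription start site, both endpoints
included, i.e. 26 nt, read 5'->3' on the gene's strand.  On the + strand
the TSS is ``tx_start`` and position -k is genomic index ``tx_start - k``;
on the - strand the TSS base is ``tx_end - 1`` and position -k is genomic
index ``tx_end - 1 + k``, so the window is the reverse complement of the
slice ``[tx_end + 14, tx_end + 40)``.

Sequences are uppercased on read; soft-masking is discarded.  ``N`` is kept
and never matches a motif base downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "GenePredError",
    "RecordError",
    "GENEPRED_COLUMNS",
    "read_genepred",
    "write_genepred",
    "extract_promoter_window",
    "dedupe_by_symbol",
    "structural_lengths",
    "read_fasta",
    "write_fasta",
    "load_genome_fasta",
    "check_cds_frame",
]

GENEPRED_COLUMNS = (
    "geneName",
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)

# promoter window: -40..-15 inclusive relative to the TSS
PROMOTER_UPSTREAM = 40
PROMOTER_DOWNSTREAM = 15
PROMOTER_WINDOW_LENGTH = PROMOTER_UPSTREAM - PROMOTER_DOWNSTREAM + 1  # 26 nt

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenePredError(ValueError):
    """A gene record violates the genePred coordinate invariants."""


class RecordError(NamedTuple):
    """A rejected annotation line: where it was and why."""

    line_number: int
    accession: str
    message: str


@dataclass(frozen=True)
class GeneModel:
    """One transcript record in genePred coordinates.

    Invariants (checked on construction): ``tx_start < tx_end``,
    ``tx_start <= cds_start <= cds_end <= tx_end``, exon lists sorted,
    non-overlapping and of length ``exon_count``, and the CDS bounds fall
    inside the exon union (when the CDS is non-empty).
    """

    accession: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_count: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenePredError(f"{self.accession}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise GenePredError(
                f"{self.accession}: inverted transcript coordinates "
                f"({self.tx_start} >= {self.tx_end})"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise GenePredError(f"{self.accession}: CDS bounds outside transcript bounds")
        if len(self.exon_starts) != self.exon_count or len(self.exon_ends) != self.exon_count:
            raise GenePredError(
                f"{self.accession}: exonCount {self.exon_count} does not match "
                f"coordinate lists ({len(self.exon_starts)}/{len(self.exon_ends)})"
            )
        if self.exon_count < 1:
            raise GenePredError(f"{self.accession}: exon_count must be positive")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise GenePredError(f"{self.accession}: empty or inverted exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise GenePredError(f"{self.accession}: exons unsorted or overlapping")
            prev_end = e
        if self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end:
            raise GenePredError(f"{self.accession}: exons outside transcript bounds")
        if self.cds_start < self.cds_end:
            if not (self._in_exons(self.cds_start) and self._in_exons(self.cds_end - 1)):
                raise GenePredError(f"{self.accession}: CDS bounds outside exon union")

    def _in_exons(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in zip(self.exon_starts, self.exon_ends))

    @property
    def gene_length(self) -> int:
        """Genomic span: ``tx_end - tx_start`` (nt)."""
        return self.tx_end - self.tx_start

    @property
    def cds_length(self) -> int:
        """Spliced (exonic) CDS length in nt; 0 for non-coding records."""
        total = 0
        for s, e in zip(self.exon_starts, self.exon_ends):
            total += max(0, min(e, self.cds_end) - max(s, self.cds_start))
        return total

    @property
    def tss(self) -> int:
        """Genomic index of the transcription start base (0-based)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def _parse_coord_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x != "")


class GenePredRead(NamedTuple):
    genes: list[GeneModel]
    errors: list[RecordError]


def read_genepred(path: str | Path) -> GenePredRead:
    """Read a refFlat-dialect annotation table.

    Returns the valid records plus a list of :class:`RecordError` for every
    malformed line (wrong column count, non-numeric coordinates, inverted
    coordinates, exon-count mismatches...), each tagged with its 1-based
    line number.  The header row is required and validated.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    errors: list[RecordError] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != GENEPRED_COLUMNS:
            expected = "\t".join(GENEPRED_COLUMNS)
            raise GenePredError(f"{path}: missing or malformed header row (expected {expected!r})")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(GENEPRED_COLUMNS):
                errors.append(RecordError(line_no, fields[1] if len(fields) > 1 else "?",
                                          f"expected {len(GENEPRED_COLUMNS)} columns, got {len(fields)}"))
                continue
            try:
                gene = GeneModel(
                    symbol=fields[0],
                    accession=fields[1],
                    chrom=fields[2],
                    strand=fields[3],
                    tx_start=int(fields[4]),
                    tx_end=int(fields[5]),
                    cds_start=int(fields[6]),
                    cds_end=int(fields[7]),
                    exon_count=int(fields[8]),
                    exon_starts=_parse_coord_list(fields[9]),
                    exon_ends=_parse_coord_list(fields[10]),
                )
            except (ValueError, GenePredError) as exc:
                errors.append(RecordError(line_no, fields[1], str(exc)))
                continue
            genes.append(gene)
    return GenePredRead(genes, errors)


def write_genepred(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write records in the canonical dialect (round-trips byte-identically)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GENEPRED_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    (
                        g.symbol,
                        g.accession,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.cds_start),
                        str(g.cds_end),
                        str(g.exon_count),
                        ",".join(map(str, g.exon_starts)) + ",",
                        ",".join(map(str, g.exon_ends)) + ",",
                    )
                )
                + "\n"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoter_window(gene: GeneModel, genome: Mapping[str, object]) -> str | None:
    """Extract the 26-nt core-promoter window (-40..-15 relative to the TSS).

    ``genome`` maps chromosome name to a string-like sequence (plain str,
    ``Bio.Seq.Seq`` or any sliceable with string conversion).  The window is
    returned 5'->3' on the gene's strand (reverse-complemented for -).
    Returns ``None`` with a warning when the window runs off either end of
    the contig, or when the chromosome is absent.
    """
    if gene.chrom not in genome:
        warnings.warn(f"{gene.accession}: chromosome {gene.chrom!r} not in genome; gene excluded")
        return None
    contig = genome[gene.chrom]
    n = len(contig)
    if gene.strand == "+":
        start = gene.tx_start - PROMOTER_UPSTREAM
        end = gene.tx_start - PROMOTER_DOWNSTREAM + 1
    else:
        start = gene.tx_end - 1 + PROMOTER_DOWNSTREAM
        end = gene.tx_end - 1 + PROMOTER_UPSTREAM + 1
    if start < 0 or end > n:
        warnings.warn(
            f"{gene.accession}: promoter window [{start}, {end}) outside contig "
            f"{gene.chrom!r} (length {n}); gene excluded"
        )
        return None
    window = str(contig[start:end]).upper()
    if gene.strand == "-":
        window = reverse_complement(window)
    return window


def dedupe_by_symbol(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse transcripts to one record per gene symbol.

    The retained transcript is the one with the longest spliced CDS; ties
    are broken by lexicographically smaller accession.  Output order follows
    the first occurrence of each symbol, so a duplicate-free input is
    returned unchanged.  Idempotent, and the retained set is independent of
    input order.
    """
    best: dict[str, GeneModel] = {}
    order: list[str] = []
    for g in genes:
        if g.symbol not in best:
            best[g.symbol] = g
            order.append(g.symbol)
            continue
        cur = best[g.symbol]
        key_new = (g.cds_length, _neg_accession(g.accession))
        key_cur = (cur.cds_length, _neg_accession(cur.accession))
        if key_new > key_cur:
            best[g.symbol] = g
    return [best[s] for s in order]


class _neg_accession(str):
    """Ordering helper: larger means lexicographically *smaller* accession."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def structural_lengths(gene: GeneModel) -> dict[str, int]:
    """Gene length (txEnd - txStart) and exon count for one record."""
    return {"gene_length": gene.gene_length, "exon_count": gene.exon_count}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


# a genome FASTA and a per-region FASTA are read identically at desk scale
load_genome_fasta = read_fasta


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences in input order, wrapped at ``width`` columns."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if len(seq) == 0:
                fh.write("\n")


def check_cds_frame(cds_seqs: Mapping[str, str]) -> list[str]:
    """Return ids whose CDS length is not a multiple of 3 (annotation reality;
    flagged, not rejected)."""
    bad = [gid for gid, seq in cds_seqs.items() if len(seq) % 3 != 0]
    if bad:
        warnings.warn(f"{len(bad)} CDS sequence(s) not divisible by 3 (e.g. {bad[:3]})")
    return bad
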