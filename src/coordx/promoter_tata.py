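"""Core-promoter TATA-box classification by degenerate-motif scanning.

Each gene's 26-nt window upstream of the TSS (positions -40..-15) is
scanned with the IUPAC pattern ``TATAWAG`` (W = A or T).  Every length-7
sub-window is scored by its mismatch count against the pattern; the minimum
over all offsets determines the promoter class:

* ``canonical``    — a perfect match exists (0 mismatches),
* ``one_mismatch`` — best match has exactly 1 mismatch,
* ``tata_less``    — every sub-window has >= 2 mismatches.

Scanning is sense-strand only (the TATA-box is orientation-dependent; the
window is already strand-oriented upstream).  ``N`` in the sequence never
matches any pattern base.  Ties between equally good offsets resolve to the
smallest offset, i.e. the most upstream hit — this affects the reported
position only, never the class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "IUPAC",
    "MotifSpec",
    "PromoterCall",
    "TATA_CLASSES",
    "mismatch_count",
    "scan_promoter",
    "classify_cohort",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

TATA_CLASSES = ("canonical", "one_mismatch", "tata_less")


@dataclass(frozen=True)
class MotifSpec:
    """Degenerate motif with a mismatch budget.

    The default is the TATA-box consensus ``TATAWAG`` with at most one
    mismatch: 0 mismatches is a canonical box, 1 a one-mismatch box,
    anything beyond the budget is TATA-less.
    """

    pattern: str = "TATAWAG"
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class PromoterCall:
    """Promoter classification for one gene.

    ``best_offset``/``best_mismatches`` refer to the best-scoring sub-window
    and are ``None`` only for TATA-less calls where no offset is meaningful
    (the minimum mismatch count is still recorded in ``min_mismatches``).
    """

    gene_id: str
    tata_class: str
    best_offset: int | None
    best_mismatches: int | None
    min_mismatches: int

    @property
    def is_tata(self) -> bool:
        """TATA in the combined sense: canonical or one-mismatch box."""
        return self.tata_class in ("canonical", "one_mismatch")


def mismatch_count(window: str, motif: MotifSpec | str = MotifSpec()) -> int:
    """Count mismatches of ``window`` against an equal-length IUPAC pattern.

    A position mismatches when the window base is not in the pattern
    character's allowed set; ``N`` in the window never matches (even against
    pattern ``N``).
    """
    pattern = motif.pattern if isinstance(motif, MotifSpec) else MotifSpec(pattern=motif).pattern
    if len(window) != len(pattern):
        raise ValueError(f"window length {len(window)} != pattern length {len(pattern)}")
    window = window.upper()
    mm = 0
    for base, code in zip(window, pattern):
        if base == "N" or base not in IUPAC[code]:
            mm += 1
    return mm


def scan_promoter(
    window: str, motif: MotifSpec = MotifSpec(), gene_id: str = ""
) -> PromoterCall:
    """Scan every sub-window of ``window`` and classify the promoter.

    The scan is confined to the given window (a 26-nt region yields offsets
    0..19 for a 7-nt pattern).  The minimum mismatch count over all offsets
    decides the class; among equal minima the smallest (most upstream)
    offset is reported.
    """
    window = window.upper()
    k = len(motif.pattern)
    if len(window) < k:
        raise ValueError(f"window ({len(window)} nt) shorter than pattern ({k} nt)")
    best_mm = k + 1
    best_off = 0
    for off in range(len(window) - k + 1):
        mm = mismatch_count(window[off : off + k], motif)
        if mm < best_mm:
            best_mm, best_off = mm, off
            if mm == 0:
                break
    if best_mm == 0:
        cls = "canonical"
    elif best_mm <= motif.max_mismatch:
        cls = "one_mismatch"
    else:
        cls = "tata_less"
    if cls == "tata_less":
        return PromoterCall(gene_id, cls, None, None, best_mm)
    return PromoterCall(gene_id, cls, best_off, best_mm, best_mm)


def classify_cohort(
    windows: Mapping[str, str], motif: MotifSpec = MotifSpec()
) -> tuple[list[PromoterCall], pd.DataFrame]:
    """Classify every gene's promoter window and tabulate class frequencies.

    Windows with more than 50% ``N`` are excluded with a warning.  Returns
    the per-gene calls and a frequency table (count and proportion per
    class; proportions sum to 1 over the classified genes).
    """
    if not windows:
        raise ValueError("empty window map: nothing to classify")
    calls: list[PromoterCall] = []
    excluded: list[str] = []
    for gid, window in windows.items():
        w = window.upper()
        if w.count("N") * 2 > len(w):
            excluded.append(gid)
            continue
        calls.append(scan_promoter(w, motif, gene_id=gid))
    if excluded:
        warnings.warn(f"{len(excluded)} window(s) with >50% N excluded (e.g. {excluded[:3]})")
    if not calls:
        raise ValueError("no classifiable windows (all excluded)")
    counts = {cls: 0 for cls in TATA_CLASSES}
    for c in calls:
        counts[c.tata_class] += 1
    n = len(calls)
    freq = pd.DataFrame(
        {
            "tata_class": list(TATA_CLASSES),
            "count": [counts[c] for c in TATA_CLASSES],
            "proportion": [counts[c] / n for c in TATA_CLASSES],
        }
    )
    return calls, freq


def calls_to_frame(calls: Sequence[PromoterCall]) -> pd.DataFrame:
    """Tabulate promoter calls (gene, class, offset, mismatches)."""
    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in calls],
            "tata_class": [c.tata_class for c in calls],
            "best_offset": [c.best_offset for c in calls],
            "best_mismatches": [c.best_mismatches for c in calls],
            "min_mismatches": [c.min_mismatches for c in calls],
        }
    )
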