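"""Translocation breakpoint flanks and RAG recombination-signal-sequence scanning.

RAG recombinase targets a recombination signal sequence (RSS): a conserved
heptamer (canonically CACAGTG) separated from a nonamer (ACAAAAACC) by a
12 or 23 bp spacer.  Illegitimate RAG activity at oncogene loci often
leaves only partial signals, so the scanner distinguishes full RSSs from
heptamer-only matches near a breakpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotate import motif_scan, reverse_complement

__all__ = [
    "Breakpoint",
    "RssHit",
    "extract_flank",
    "rss_scan",
    "classify_breakpoint",
    "HEPTAMER",
    "NONAMER",
]

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Breakpoint:
    name: str
    chrom: str
    position: int            # 1-based
    orientation: str = "+"   # which derivative side is retained; '-' = revcomp flanks

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("breakpoint position must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass(frozen=True)
class RssHit:
    start: int               # 0-based, leftmost heptamer base on forward coords
    strand: str
    heptamer_mismatches: int
    nonamer_mismatches: int | None
    spacer: int | None       # realised spacer length, None for heptamer-only
    spacer_class: int | None # 12 or 23
    classification: str      # 'full-RSS' | 'heptamer-only'


@dataclass
class Flank:
    sequence: str
    truncated: bool = False


def extract_flank(sequence: str, position: int, side: str, length: int,
                  orientation: str = "+") -> Flank:
    """Extract ``length`` bp up- or downstream of a 1-based breakpoint position.

    The downstream flank starts at position+1; the upstream flank ends at
    position-1 (the breakpoint base itself belongs to neither).  A flank
    running past a contig end is truncated and flagged.  Orientation '-'
    reverse-complements the result.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    if length < 0:
        raise ValueError("length must be non-negative")
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if side == "downstream":
        start, end = position, position + length  # 0-based slice
    else:
        start, end = position - 1 - length, position - 1
    truncated = start < 0 or end > len(sequence)
    seq = sequence[max(start, 0):min(end, len(sequence))]
    if orientation == "-":
        seq = reverse_complement(seq)
    return Flank(seq, truncated)


def _full_rss_at(seq: str, hept_start: int, strand: str, nonamer: str,
                 spacer_classes, spacer_slack: int, max_mm_nona: int):
    """Best nonamer placement for a heptamer hit; None if no spacer works."""
    hl, nl = len(HEPTAMER), len(nonamer)
    if strand == "-":
        seq = reverse_complement(seq)
        hept_start = len(seq) - hept_start - hl
    best = None
    for cls in spacer_classes:
        for spacer in range(cls - spacer_slack, cls + spacer_slack + 1):
            ns = hept_start + hl + spacer
            if ns < 0 or ns + nl > len(seq):
                continue
            window = seq[ns:ns + nl]
            mm = sum(1 for a, b in zip(window, nonamer) if a != b)
            if mm <= max_mm_nona and (best is None or mm < best[0]):
                best = (mm, spacer, cls)
    return best


def rss_scan(
    sequence: str,
    heptamer: str = HEPTAMER,
    nonamer: str = NONAMER,
    spacer_classes: tuple[int, ...] = (12, 23),
    spacer_slack: int = 1,
    max_mismatch_heptamer: int = 0,
    max_mismatch_nonamer: int = 1,
) -> list[RssHit]:
    """Scan both strands for RSS motifs.

    Every heptamer placement within the mismatch budget is reported; for
    each, the nonamer is sought downstream of the heptamer (in the
    element's reading direction) at offsets consistent with each spacer
    class +/- slack on the same strand.  Hits with a nonamer are classified
    full-RSS, otherwise heptamer-only.
    """
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    if len(sequence) < len(heptamer):
        raise ValueError("sequence shorter than heptamer")

    hits: list[RssHit] = []
    for hit in motif_scan(sequence, heptamer, max_mismatch_heptamer, both_strands=True):
        strands = ("+", "-") if hit.strand == "both" else (hit.strand,)
        for strand in strands:
            found = _full_rss_at(sequence, hit.start, strand, nonamer,
                                 spacer_classes, spacer_slack, max_mismatch_nonamer)
            if found:
                mm, spacer, cls = found
                hits.append(RssHit(hit.start, strand, hit.mismatches, mm,
                                   spacer, cls, "full-RSS"))
            else:
                hits.append(RssHit(hit.start, strand, hit.mismatches, None,
                                   None, None, "heptamer-only"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class BreakpointCall:
    name: str
    category: str            # 'full-RSS-proximal' | 'heptamer-only-proximal' | 'no-RSS'
    nearest_distance: float  # bp from breakpoint to nearest qualifying hit; inf if none


def classify_breakpoint(
    hits: list[RssHit],
    breakpoint_offset: int,
    window: int = 50,
    name: str = "",
    heptamer_len: int = len(HEPTAMER),
) -> BreakpointCall:
    """Categorise a breakpoint by the RSS hits within ``window`` bp.

    ``breakpoint_offset`` is the junction's 0-based coordinate in the same
    sequence the hits were scanned on.  Hit-to-breakpoint distance is the
    gap between the heptamer interval and the junction (0 if the junction
    falls inside the heptamer).  Full RSSs take precedence over
    heptamer-only hits.
    """

    def distance(h: RssHit) -> int:
        lo, hi = h.start, h.start + heptamer_len - 1
        if lo <= breakpoint_offset <= hi:
            return 0
        return lo - breakpoint_offset if breakpoint_offset < lo else breakpoint_offset - hi

    best_full = best_hept = math.inf
    for h in hits:
        d = distance(h)
        if d > window:
            continue
        if h.classification == "full-RSS":
            best_full = min(best_full, d)
        else:
            best_hept = min(best_hept, d)
    if best_full < math.inf:
        return BreakpointCall(name, "full-RSS-proximal", best_full)
    if best_hept < math.inf:
        return BreakpointCall(name, "heptamer-only-proximal", best_hept)
    return BreakpointCall(name, "no-RSS", math.inf)
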