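"""Peak-to-gene assignment, Hi-C contact linking, consensus-motif scanning."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TssRecord",
    "assign_peaks_to_tss",
    "hic_link",
    "motif_scan",
    "reverse_complement",
    "MotifHit",
    "HicLink",
]

# IUPAC nucleotide codes -> set of matching bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chromosome must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"interval must satisfy start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site; position is 1-based (annotation convention)."""

    gene: str
    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("TSS position must be >= 1")


def _tss_peak_distance(tss: TssRecord, peak: GenomicInterval) -> int:
    """Distance from a TSS point to a peak interval; 0 when inside."""
    pos0 = tss.position - 1
    if peak.start <= pos0 < peak.end:
        return 0
    if pos0 < peak.start:
        return peak.start - pos0
    return pos0 - (peak.end - 1)


def assign_peaks_to_tss(
    peaks: list[GenomicInterval],
    tss_table: list[TssRecord],
    window: int = 1000,
) -> pd.DataFrame:
    """All gene-peak pairs where the TSS lies within ``window`` bp of the peak.

    Distance is to the nearest peak edge (0 inside), window inclusive, TSS
    strand ignored.  Returns a table with columns gene/peak/chrom/distance;
    empty inputs give an empty table.
    """
    rows = []
    for tss in tss_table:
        for i, peak in enumerate(peaks):
            if peak.chrom != tss.chrom:
                continue
            d = _tss_peak_distance(tss, peak)
            if d <= window:
                rows.append({"gene": tss.gene, "peak": peak.name or f"peak_{i}",
                             "chrom": tss.chrom, "distance": d})
    return pd.DataFrame(rows, columns=["gene", "peak", "chrom", "distance"])


@dataclass
class HicLink:
    linked: bool
    max_contact: float
    bins_a: tuple[int, ...]
    bins_b: tuple[int, ...]
    no_data: bool = False


def hic_link(
    contacts: pd.DataFrame,
    interval_a: GenomicInterval,
    interval_b: GenomicInterval,
    resolution: int,
    threshold: float,
) -> HicLink:
    """Link two intervals if any bin pair between them reaches ``threshold``.

    ``contacts`` has columns bin_i/bin_j/value and is symmetrised on ingest.
    Bins are floor(position/resolution) over each interval's 0-based span;
    interval pairs sharing a bin are linked by convention (distance 0).
    Intervals outside the matrix extent are flagged no-data.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lut: dict[tuple[int, int], float] = {}
    for bi, bj, v in contacts[["bin_i", "bin_j", "value"]].itertuples(index=False):
        if v < 0:
            raise ValueError("contact values must be non-negative")
        key = (int(bi), int(bj))
        lut[key] = max(lut.get(key, 0.0), float(v))
        lut[key[::-1]] = lut[key]

    def bins(iv: GenomicInterval) -> tuple[int, ...]:
        return tuple(range(iv.start // resolution, (iv.end - 1) // resolution + 1))

    ba, bb = bins(interval_a), bins(interval_b)
    extent = max((max(k) for k in lut), default=-1)
    if min(ba) > extent and min(bb) > extent:
        return HicLink(False, math.nan, ba, bb, no_data=True)

    shared = set(ba) & set(bb)
    values = [lut.get((i, j), 0.0) for i in ba for j in bb]
    max_v = max(values) if values else 0.0
    linked = bool(shared) or max_v >= threshold
    return HicLink(linked, max_v, ba, bb)


@dataclass(frozen=True)
class MotifHit:
    start: int          # 0-based leftmost position on the forward sequence
    strand: str         # '+', '-' or 'both' (palindrome)
    mismatches: int


def _mismatch_profile(seq: str, consensus: str) -> np.ndarray:
    """Mismatch count of ``consensus`` at every start of ``seq`` (IUPAC-aware).

    A base in the sequence outside ACGT (e.g. the masking 'N') matches only
    a consensus code that covers all four bases.
    """
    m, ls = len(consensus), len(seq)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n_win = ls - m + 1
    mismatches = np.zeros(n_win, dtype=np.int32)
    for j, code in enumerate(consensus):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC[code]:
            allowed[ord(b)] = True
        if code == "N":
            allowed[ord("N")] = True
        mismatches += ~allowed[arr[j:j + n_win]]
    return mismatches


def motif_scan(
    sequence: str,
    consensus: str,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All placements of an IUPAC consensus within a Hamming-distance budget.

    Reverse-complement hits are reported at their forward-strand leftmost
    coordinate with strand '-'; a palindrome hitting both strands at the
    same position is collapsed to a single record with strand 'both'.
    """
    consensus = consensus.upper()
    for ch in consensus:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
    if len(consensus) > len(sequence):
        raise ValueError("consensus longer than sequence")

    fwd = _mismatch_profile(sequence, consensus)
    hits: dict[int, MotifHit] = {
        int(i): MotifHit(int(i), "+", int(fwd[i]))
        for i in np.nonzero(fwd <= max_mismatches)[0]
    }
    if both_strands:
        rev = _mismatch_profile(sequence, reverse_complement(consensus))
        for i in np.nonzero(rev <= max_mismatches)[0]:
            i = int(i)
            if i in hits:
                hits[i] = MotifHit(i, "both", min(hits[i].mismatches, int(rev[i])))
            else:
                hits[i] = MotifHit(i, "-", int(rev[i]))
    return [hits[i] for i in sorted(hits)]
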