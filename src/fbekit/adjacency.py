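"""Adjacent-element pair detection within CLIP peaks and summary counts.

A peak "has adjacent FBEs" when it contains at least one canonical 9-nt
FBE plus a second element (canonical, compact, or FBEa*-like) such that
the spacing between the two, measured from element starts and accounting
for the 5'-most element's length, lies within a 1-20 nt window.  The gap
convention operates on the core elements; a flank-inclusive utility
serves the alternative convention that extends elements 5' through the
affinity-relevant upstream bases (e.g. the *gld-1* FBEa/FBEa* pair is
5 nt apart by core elements, 3 nt by flanked elements).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from fbekit.motif import ElementMatch, scan_all

REGIONS = ("three_prime_utr", "five_prime_utr", "cds", "other")
CATEGORIES = ("lower", "higher", "unchanged")

DEFAULT_MIN_GAP = 1
DEFAULT_MAX_GAP = 20


@dataclass(frozen=True)
class PeakRecord:
    """One CLIP peak: sequence, annotation and occupancy heights (FPKM)."""

    peak_id: str
    gene_id: str
    region: str
    sequence: str
    height_wt: float
    height_mut: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peak {self.peak_id!r}: empty sequence")
        if self.region not in REGIONS:
            raise ValueError(
                f"peak {self.peak_id!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.height_wt < 0:
            raise ValueError(
                f"peak {self.peak_id!r}: negative height_wt {self.height_wt}"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(
                f"peak {self.peak_id!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class AdjacentPair:
    """A qualifying element pair, oriented 5'->3', with its core gap."""

    peak_id: str
    upstream: ElementMatch
    downstream: ElementMatch
    gap: int


@dataclass
class ScanSummary:
    """Peak/gene/region-level tallies of the adjacent-element scan."""

    n_peaks_scanned: int
    n_peaks_with_pairs: int
    n_distinct_genes: int
    n_by_region: dict[str, int]
    pairs: list[AdjacentPair] = field(default_factory=list)


def gap_of(upstream_start: int, upstream_len: int, downstream_start: int) -> int:
    """Nucleotides between two elements, from 0-based starts.

    gap = downstream_start - upstream_start - upstream_len.  May be <= 0
    for abutting or overlapping elements; callers filter.
    """
    if downstream_start < upstream_start:
        raise ValueError("downstream_start must be >= upstream_start")
    return downstream_start - upstream_start - upstream_len


def flank_inclusive_gap(
    upstream_start: int,
    upstream_len: int,
    downstream_start: int,
    *,
    flank_5p: int = 2,
) -> int:
    """Gap under the flank-inclusive element convention.

    Extending both elements 5' by ``flank_5p`` bases (default 2, the
    upstream CA of the affinity-enhancing flank) shifts each start left
    and lengthens the upstream element, so the gap shrinks by
    ``flank_5p`` relative to the core convention.
    """
    return gap_of(
        upstream_start - flank_5p,
        upstream_len + flank_5p,
        downstream_start - flank_5p,
    )


def find_pairs(
    matches: Sequence[ElementMatch],
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[AdjacentPair]:
    """Qualifying adjacent pairs among one sequence's element matches.

    A pair qualifies when at least one member is the canonical FBE9 and
    the core-element gap lies in [min_gap, max_gap].  Orientation does
    not matter for qualification (the second element may be upstream or
    downstream of the canonical one); each unordered pair is emitted
    once, oriented by start.  Overlapping or abutting matches (gap <= 0)
    never qualify because min_gap >= 1.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1 (overlaps never qualify)")
    ordered = sorted(matches, key=lambda m: (m.start, m.pattern_name))
    pairs: list[AdjacentPair] = []
    for a, b in combinations(ordered, 2):
        up, down = (a, b) if a.start <= b.start else (b, a)
        if up.pattern_name != "FBE9" and down.pattern_name != "FBE9":
            continue
        gap = gap_of(up.start, up.length, down.start)
        if min_gap <= gap <= max_gap:
            pairs.append(AdjacentPair(up.sequence_id, up, down, gap))
    return pairs


def scan_peak(
    peak: PeakRecord,
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[PeakRecord, list[AdjacentPair]]:
    """Scan one peak's sequence for qualifying adjacent element pairs."""
    matches = scan_all(peak.sequence, sequence_id=peak.peak_id)
    return peak, find_pairs(matches, min_gap, max_gap)


def summarize(
    scanned: Iterable[tuple[PeakRecord, list[AdjacentPair]]],
) -> ScanSummary:
    """Aggregate scanned peaks to peak-, gene- and region-level counts.

    A peak counts once regardless of how many qualifying pairs it holds;
    distinct genes are counted by gene_id among peaks with pairs.
    """
    scanned = list(scanned)
    seen: set[str] = set()
    for peak, _ in scanned:
        if peak.peak_id in seen:
            raise ValueError(f"duplicate peak_id {peak.peak_id!r}")
        seen.add(peak.peak_id)

    with_pairs = [(p, prs) for p, prs in scanned if prs]
    region_counts = Counter(p.region for p, _ in with_pairs)
    all_pairs = [pair for _, prs in with_pairs for pair in prs]
    return ScanSummary(
        n_peaks_scanned=len(scanned),
        n_peaks_with_pairs=len(with_pairs),
        n_distinct_genes=len({p.gene_id for p, _ in with_pairs}),
        n_by_region={r: region_counts.get(r, 0) for r in REGIONS},
        pairs=all_pairs,
    )
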