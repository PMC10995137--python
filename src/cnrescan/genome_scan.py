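"""Exhaustive both-strand genome scanning for cNRE-like occurrences.

The scan slides the 32-nt consensus over every position of the target (both
strands), counts mismatches by Hamming distance, and applies the hexad
retention rule: a hit is kept when it covers consensus positions 3-29 and
carries at most one mismatch inside each hexad; mismatches in the spacers
are unrestricted.  Edge windows that hang off the sequence are reported
with a truncated covered range and can never pass the rule unless positions
3-29 are covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .motif import TripartiteMotif
from .seqcore import NucSequence, hamming, revcomp_str

#: minimum overlap with the target for a truncated edge window to be reported
MIN_EDGE_OVERLAP = 6

#: full-length hits with this many or more mismatches are called divergent
#: (4/32 = 12.5%, i.e. more than a 12% mismatch level)
DIVERGENCE_THRESHOLD = 4

#: largest per-hit mismatch count retained by default
DEFAULT_MAX_MISMATCHES = 11


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence, ungapped, in plus-strand coordinates
    (1-based inclusive).  ``oriented_sequence`` reads in motif orientation;
    ``covered_query_range`` is the 1-based inclusive consensus interval the
    hit covers (smaller than (1, 32) only for truncated edge windows)."""

    target_id: str
    start: int
    end: int
    strand: str
    oriented_sequence: str
    total_mismatches: int
    hexad_mismatches: tuple[int, int, int] | None = None
    covered_query_range: tuple[int, int] = (1, 32)
    passes_filter: bool | None = None
    locus_label: str | None = None
    locus_distance: int | None = None

    @property
    def is_full_length(self) -> bool:
        return self.covered_query_range == (1, 32)


@dataclass(frozen=True)
class GeneLocus:
    target_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    name: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"locus {self.name}: end < start")


def scan_sequence(
    target: NucSequence,
    motif: TripartiteMotif,
    max_total_mismatches: int = DEFAULT_MAX_MISMATCHES,
    include_truncated: bool = True,
) -> list[MotifHit]:
    """Report every window on either strand whose mismatch count does not
    exceed ``max_total_mismatches``, exactly once, with plus-strand
    coordinates.  Hits come back with the hexad filter verdict filled."""
    m = len(motif.consensus)
    L = len(target)
    if L < MIN_EDGE_OVERLAP:
        return []
    cons = motif.consensus.codes()
    cons_rc = np.array([_rc_code(c) for c in cons[::-1]], dtype=cons.dtype)
    codes = target.codes()
    hits: list[MotifHit] = []

    if L >= m:
        win = sliding_window_view(codes, m)
        amb = win == 4  # N in the target never matches
        mm_plus = ((win != cons[None, :]) | amb).sum(axis=1)
        mm_minus = ((win != cons_rc[None, :]) | amb).sum(axis=1)
        for strand, mm in (("+", mm_plus), ("-", mm_minus)):
            for off in np.nonzero(mm <= max_total_mismatches)[0]:
                hits.append(_make_hit(target, motif, int(off), strand, int(mm[off])))

    if include_truncated:
        edge_offsets = [o for o in range(-(m - MIN_EDGE_OVERLAP), 0)]
        edge_offsets += [o for o in range(max(L - m + 1, 0), L - MIN_EDGE_OVERLAP + 1)]
        if L < m:  # short targets: every placement is truncated
            edge_offsets = list(range(-(m - MIN_EDGE_OVERLAP), L - MIN_EDGE_OVERLAP + 1))
        for off in sorted(set(edge_offsets)):
            for strand in "+-":
                hit = _make_truncated_hit(target, motif, off, strand)
                if hit.total_mismatches <= max_total_mismatches:
                    hits.append(hit)

    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return [hexad_filter(h, motif) for h in hits]


def _rc_code(c: int) -> int:
    return 3 - c if c < 4 else 4


def _make_hit(
    target: NucSequence, motif: TripartiteMotif, off: int, strand: str, mm: int
) -> MotifHit:
    m = len(motif.consensus)
    frag = target.bases[off : off + m]
    oriented = frag if strand == "+" else revcomp_str(frag)
    return MotifHit(
        target_id=target.id,
        start=off + 1,
        end=off + m,
        strand=strand,
        oriented_sequence=oriented,
        total_mismatches=mm,
    )


def _make_truncated_hit(
    target: NucSequence, motif: TripartiteMotif, off: int, strand: str
) -> MotifHit:
    m = len(motif.consensus)
    L = len(target)
    lo, hi = max(off, 0), min(off + m, L)  # covered target slice, 0-based
    frag = target.bases[lo:hi]
    clip_left, clip_right = lo - off, off + m - hi
    if strand == "+":
        covered = (clip_left + 1, m - clip_right)
        oriented = frag
    else:
        covered = (clip_right + 1, m - clip_left)
        oriented = revcomp_str(frag)
    ref = motif.bases[covered[0] - 1 : covered[1]]
    return MotifHit(
        target_id=target.id,
        start=lo + 1,
        end=hi,
        strand=strand,
        oriented_sequence=oriented,
        total_mismatches=hamming(oriented, ref),
        covered_query_range=covered,
    )


def hexad_filter(hit: MotifHit, motif: TripartiteMotif) -> MotifHit:
    """Fill per-hexad mismatch counts and the retention verdict: the hit
    must cover consensus positions 3-29 with at most 1 mismatch per hexad."""
    c0, c1 = hit.covered_query_range
    lo_needed, hi_needed = motif.hexads[0].start, motif.hexads[-1].end
    if c0 > lo_needed or c1 < hi_needed:
        return replace(hit, hexad_mismatches=None, passes_filter=False)
    # oriented_sequence starts at consensus position c0
    per_hexad = tuple(
        hamming(
            hit.oriented_sequence[h.start - c0 : h.end - c0 + 1],
            motif.bases[h.slice()],
        )
        for h in motif.hexads
    )
    return replace(
        hit,
        hexad_mismatches=per_hexad,
        passes_filter=all(x <= 1 for x in per_hexad),
    )


def classify_conservation(hit: MotifHit) -> str:
    """'divergent' for 4 or more mismatches over the full 32-bp stretch
    (a mismatch level above 12%), else 'conserved'."""
    if not hit.is_full_length:
        raise ValueError("conservation class is undefined for truncated hits")
    return "divergent" if hit.total_mismatches >= DIVERGENCE_THRESHOLD else "conserved"


def reduce_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlap reduction for counting occurrences in tandem
    arrays: repeatedly keep the hit with the fewest mismatches (ties to the
    leftmost), discarding everything that overlaps it."""
    chosen: list[MotifHit] = []
    pool = sorted(hits, key=lambda h: (h.total_mismatches, h.start, h.end))
    while pool:
        best = pool.pop(0)
        chosen.append(best)
        pool = [h for h in pool if h.end < best.start or h.start > best.end]
    return sorted(chosen, key=lambda h: h.start)


@dataclass(frozen=True)
class FlankSegment:
    sequence: NucSequence
    start: int  # 1-based inclusive on the target
    end: int
    side: str  # 'upstream' | 'downstream'
    clipped: bool


def extract_flanks(
    target: NucSequence, hit: MotifHit, near: int = 5000, far: int = 6000
) -> tuple[FlankSegment, FlankSegment]:
    """Extract the [far, near) window upstream and (near, far] window
    downstream of a hit (e.g. the 5-6 kb flanks used for transposable-
    element profiling), clipping at sequence bounds with a flag."""
    if not (far > near >= 0):
        raise ValueError("need far > near >= 0")
    if hit.start < 1 or hit.end > len(target):
        raise ValueError("hit outside target bounds")
    up_lo, up_hi = hit.start - far, hit.start - near - 1  # 1-based inclusive
    dn_lo, dn_hi = hit.end + near + 1, hit.end + far
    segs = []
    for side, lo, hi in (("upstream", up_lo, up_hi), ("downstream", dn_lo, dn_hi)):
        clo, chi = max(lo, 1), min(hi, len(target))
        clipped = (clo, chi) != (lo, hi)
        bases = target.bases[clo - 1 : chi] if chi >= clo else ""
        segs.append(
            FlankSegment(
                NucSequence(f"{target.id}_{side}_{clo}_{chi}", bases),
                clo, chi, side, clipped,
            )
        )
    return segs[0], segs[1]


def colocalize(hits: list[MotifHit], loci: list[GeneLocus]) -> list[MotifHit]:
    """Annotate each hit with its relation to the nearest gene locus on the
    same scaffold: 5'-flanking, 3'-flanking or intragenic, plus the distance
    to the nearest locus edge.  Hits on scaffolds without a locus get label
    ``different_scaffold``."""
    out = []
    for hit in hits:
        same = [l for l in loci if l.target_id == hit.target_id]
        if not same:
            out.append(replace(hit, locus_label="different_scaffold"))
            continue
        nearest = min(same, key=lambda l: _edge_distance(hit, l))
        dist = _edge_distance(hit, nearest)
        if hit.end < nearest.start:
            label = "5_flanking" if nearest.strand != "-" else "3_flanking"
        elif hit.start > nearest.end:
            label = "3_flanking" if nearest.strand != "-" else "5_flanking"
        else:
            label = "intragenic"
        out.append(replace(hit, locus_label=f"{nearest.name}:{label}", locus_distance=dist))
    return out


def _edge_distance(hit: MotifHit, locus: GeneLocus) -> int:
    if hit.end < locus.start:
        return locus.start - hit.end
    if hit.start > locus.end:
        return hit.start - locus.end
    return 0


def read_bed_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from BED (0-based half-open, converted to 1-based
    inclusive internally)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        GeneLocus(r.chrom, int(r.start) + 1, int(r.end), str(r.strand), str(r.name))
        for r in df.itertuples()
    ]


def write_bed_loci(loci: list[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.target_id}\t{l.start - 1}\t{l.end}\t{l.name}\t0\t{l.strand}\n")


HIT_COLUMNS = [
    "target_id", "start", "end", "strand", "sequence", "total_mismatches",
    "hexA_mm", "hexB_mm", "hexC_mm", "pass", "locus_label",
]


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Hit table with columns mirroring the published per-hit layout."""
    rows = []
    for h in hits:
        ha, hb, hc = h.hexad_mismatches if h.hexad_mismatches else (None, None, None)
        rows.append(
            dict(
                target_id=h.target_id, start=h.start, end=h.end, strand=h.strand,
                sequence=h.oriented_sequence, total_mismatches=h.total_mismatches,
                hexA_mm=ha, hexB_mm=hb, hexC_mm=hc, pass_=h.passes_filter,
                locus_label=h.locus_label,
            )
        )
    df = pd.DataFrame(rows, columns=[c if c != "pass" else "pass_" for c in HIT_COLUMNS])
    return df.rename(columns={"pass_": "pass"})
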