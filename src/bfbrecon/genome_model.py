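"""Coordinate, segment and junction model for breakage-fusion-bridge events.

A BFB candidate event lives on a small local genome region that SV
breakpoints partition into an ordered, gap-free run of segments
``s_1 .. s_n`` (the *reference path*).  Junctions connect one end of two
segments; their end-orientation combination determines the rearrangement
class (deletion, duplication, fold-back inversion, translocation, or virus
integration).  Coordinates are 0-based half-open internally; VCF I/O
converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

HEAD = "head"  # lower-coordinate (5' on the reference forward strand) end
TAIL = "tail"  # higher-coordinate end

#: junction classes: intra-contig, inter-contig, and human-virus
DEL_HT = "DEL-ht"
DUP_TH = "DUP-th"
FBI_HH = "FBI-hh"
FBI_TT = "FBI-tt"
TRX_TYPES = ("TRX-ht", "TRX-th", "TRX-hh", "TRX-tt")
VIT = "VIT"

FBI_TYPES = (FBI_HH, FBI_TT)

#: default snap tolerance (bp) when mapping junction endpoints to segment
#: boundaries; absorbs breakpoint jitter between callers/protocols.
DEFAULT_SNAP_TOLERANCE = 50


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True, order=True)
class Breakpoint:
    """One junction endpoint: a contig position plus the segment end it cuts."""

    contig: str
    pos: int
    end: str  # HEAD or TAIL

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise InputError(f"negative breakpoint position {self.pos}")
        if self.end not in (HEAD, TAIL):
            raise InputError(f"breakpoint end must be head/tail, got {self.end!r}")


@dataclass(frozen=True)
class SegmentRef:
    """A reference segment s_i of a layout.

    ``observed_cn`` is the (possibly real-valued) copy number c(s_i) measured
    from depth; integerization happens only inside the ILP.
    """

    contig: str
    start: int
    end: int
    index: int  # 1-based position in its layout
    observed_cn: float = 0.0
    origin: str = "human"  # "human" or "virus"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"segment {self.contig}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceLayout:
    """Gap-free ordered tiling s_1..s_n of one contig's candidate window."""

    contig: str
    start: int
    end: int
    segments: list[SegmentRef] = field(default_factory=list)
    origin: str = "human"

    def __post_init__(self) -> None:
        prev_end = self.start
        for i, seg in enumerate(self.segments, start=1):
            if seg.index != i:
                raise InputError(f"segment indices must be consecutive 1..n, got {seg.index} at {i}")
            if seg.start != prev_end:
                raise InputError(
                    f"layout {self.contig} has a gap/overlap at {seg.start} (expected {prev_end})"
                )
            prev_end = seg.end
        if self.segments and prev_end != self.end:
            raise InputError(f"layout {self.contig} does not tile its region (ends at {prev_end})")

    @property
    def n(self) -> int:
        return len(self.segments)

    def observed_cns(self) -> list[float]:
        return [s.observed_cn for s in self.segments]

    def boundaries(self) -> list[int]:
        """Internal boundary positions (n - 1 of them)."""
        return [s.end for s in self.segments[:-1]]

    def segment_at(self, pos: int) -> SegmentRef:
        for seg in self.segments:
            if seg.start <= pos < seg.end:
                return seg
        if pos == self.end:  # right-closed convenience for tail breakpoints
            return self.segments[-1]
        raise InputError(f"position {self.contig}:{pos} outside layout {self.start}-{self.end}")

    def with_cns(self, cns: Sequence[float]) -> "ReferenceLayout":
        if len(cns) != self.n:
            raise InputError("CN vector length does not match segment count")
        segs = [replace(s, observed_cn=float(c)) for s, c in zip(self.segments, cns)]
        return ReferenceLayout(self.contig, self.start, self.end, segs, origin=self.origin)


@dataclass
class Junction:
    """One SV/FBI/VIT junction between two breakpoints.

    ``seg_a``/``seg_b`` are resolved 1-based segment indices (set by
    :func:`resolve_junction`).  For fold-backs, a *perfect* junction has
    both breakpoints at the same boundary; an *imperfect* one spans distinct
    segments and loses the intervening DNA on the return arm.
    """

    bp_a: Breakpoint
    bp_b: Breakpoint
    jtype: str = ""
    support: int = 1
    observed_cn: float | None = None
    seg_a: int | None = None
    seg_b: int | None = None
    virtual: bool = False

    def __post_init__(self) -> None:
        # canonical endpoint order: sorted by (contig, pos, end)
        if (self.bp_b.contig, self.bp_b.pos, self.bp_b.end) < (
            self.bp_a.contig,
            self.bp_a.pos,
            self.bp_a.end,
        ):
            self.bp_a, self.bp_b = self.bp_b, self.bp_a
            self.seg_a, self.seg_b = self.seg_b, self.seg_a

    @property
    def is_fbi(self) -> bool:
        return self.jtype in FBI_TYPES

    @property
    def is_perfect_fbi(self) -> bool:
        return self.is_fbi and self.bp_a.pos == self.bp_b.pos

    def key(self) -> tuple:
        return (
            self.jtype,
            self.bp_a.contig,
            self.bp_a.pos,
            self.bp_a.end,
            self.bp_b.contig,
            self.bp_b.pos,
            self.bp_b.end,
        )


@dataclass
class LinkageEvidence:
    """Oriented segment adjacencies observed in linked/long reads.

    Each adjacency is ``((segment_index, orient), (segment_index, orient))``
    with orient ``+1`` for the forward segment and ``-1`` for its reverse
    complement, read along the molecule.
    """

    adjacencies: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    protocol: str = "generic"
    support: int = 1


def classify_junction(
    bp_a: Breakpoint,
    bp_b: Breakpoint,
    virus_contigs: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Classify a junction by its two breakpoint end orientations.

    Intra-contig junctions map onto DEL-ht / DUP-th / FBI-hh / FBI-tt;
    inter-contig onto TRX-{ht,th,hh,tt}; a junction with exactly one endpoint
    on a virus contig is a virus integration (VIT).  Symmetric in its
    arguments.
    """
    if (bp_a.contig, bp_a.pos, bp_a.end) == (bp_b.contig, bp_b.pos, bp_b.end):
        raise InputError("degenerate self-junction: both breakpoints identical")
    # canonical order by (contig, pos, end) so ties at one position are
    # resolved the same way regardless of argument order
    if (bp_b.contig, bp_b.pos, bp_b.end) < (bp_a.contig, bp_a.pos, bp_a.end):
        bp_a, bp_b = bp_b, bp_a
    a_virus = bp_a.contig in virus_contigs
    b_virus = bp_b.contig in virus_contigs
    if a_virus != b_virus:
        return VIT
    if bp_a.contig != bp_b.contig:
        code = ("h" if bp_a.end == HEAD else "t") + ("h" if bp_b.end == HEAD else "t")
        return f"TRX-{code}"
    if bp_a.end == HEAD and bp_b.end == HEAD:
        return FBI_HH
    if bp_a.end == TAIL and bp_b.end == TAIL:
        return FBI_TT
    if bp_a.end == TAIL and bp_b.end == HEAD:
        return DEL_HT
    return DUP_TH


def classify_or_foldback(
    bp_a: Breakpoint,
    bp_b: Breakpoint,
    virus_contigs: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Like :func:`classify_junction`, but identical breakpoints denote a
    perfect fold-back (the two sister-chromatid copies fuse at one point)."""
    if (bp_a.contig, bp_a.pos, bp_a.end) == (bp_b.contig, bp_b.pos, bp_b.end):
        return FBI_HH if bp_a.end == HEAD else FBI_TT
    return classify_junction(bp_a, bp_b, virus_contigs)


def build_segmentation(
    contig: str,
    start: int,
    end: int,
    breakpoints: Iterable[Breakpoint],
    snap_tolerance: int = DEFAULT_SNAP_TOLERANCE,
    origin: str = "human",
) -> ReferenceLayout:
    """Partition ``[start, end)`` into segments at the breakpoint positions.

    Positions within ``snap_tolerance`` of an already-accepted boundary are
    snapped onto it rather than creating a sliver segment.  k distinct
    internal cut positions give k + 1 segments.
    """
    if start >= end:
        raise InputError(f"empty region {contig}:{start}-{end}")
    positions: list[int] = []
    for bp in breakpoints:
        if bp.contig != contig:
            raise InputError(f"breakpoint on {bp.contig} passed to segmentation of {contig}")
        if not (start <= bp.pos <= end):
            raise InputError(f"breakpoint {bp.contig}:{bp.pos} outside region {start}-{end}")
        positions.append(bp.pos)
    cuts: list[int] = []
    for pos in sorted(set(positions)):
        if pos <= start or pos >= end:
            continue
        if cuts and pos - cuts[-1] <= snap_tolerance:
            continue
        if pos - start <= snap_tolerance or end - pos <= snap_tolerance:
            continue
        cuts.append(pos)
    bounds = [start] + cuts + [end]
    segments = [
        SegmentRef(contig, a, b, index=i + 1, origin=origin)
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]
    return ReferenceLayout(contig, start, end, segments, origin=origin)


def depth_to_copy_number(
    depth: float,
    genome_depth: float,
    purity: float = 1.0,
    tumor_ploidy: float = 2.0,
    normal_ploidy: float = 2.0,
) -> float:
    """Convert a read depth to an observed copy number.

    The expected depth of a single haplotype copy is
    ``D_h = D_g / (rho * P_t + (1 - rho) * P_n)``; the observed CN is then
    ``C = D / D_h``.  Linear in depth.
    """
    if genome_depth <= 0:
        raise InputError("genome_depth must be positive")
    denom = purity * tumor_ploidy + (1.0 - purity) * normal_ploidy
    if denom <= 0:
        raise InputError("purity/ploidy combination gives non-positive haplotype depth")
    d_h = genome_depth / denom
    return depth / d_h


def resolve_junction(junction: Junction, layouts: dict[str, ReferenceLayout]) -> Junction:
    """Resolve junction endpoints onto segment indices of the given layouts.

    A HEAD breakpoint maps to the segment starting at (or just after) its
    position; a TAIL breakpoint to the segment ending at it.
    """

    def seg_index(bp: Breakpoint) -> int:
        layout = layouts.get(bp.contig)
        if layout is None:
            raise InputError(f"junction endpoint on unknown contig {bp.contig}")
        if bp.end == HEAD:
            # segment whose start is nearest bp.pos
            best = min(layout.segments, key=lambda s: abs(s.start - bp.pos))
        else:
            best = min(layout.segments, key=lambda s: abs(s.end - bp.pos))
        return best.index

    junction.seg_a = seg_index(junction.bp_a)
    junction.seg_b = seg_index(junction.bp_b)
    return junction


def fbi_fold_assignment(junction: Junction) -> tuple[str, int, int]:
    """Canonicalize a (possibly imperfect) fold-back onto a single fold index.

    Returns ``(side, canonical_index, far_index)`` where side is ``"head"``
    for FBI-hh (fold before segment i) or ``"tail"`` for FBI-tt (fold after
    segment i).  For an imperfect fold (s_i, s̄_j) the canonical index is the
    endpoint on the longer retained arm: the lower segment index for FBI-hh,
    the higher for FBI-tt; ``far_index`` records j for post-hoc revision.
    """
    if not junction.is_fbi:
        raise InputError(f"not a fold-back junction: {junction.jtype}")
    if junction.seg_a is None or junction.seg_b is None:
        raise InputError("junction not resolved to segment indices")
    lo, hi = sorted((junction.seg_a, junction.seg_b))
    if junction.jtype == FBI_HH:
        return (HEAD, lo, hi)
    return (TAIL, hi, lo)
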