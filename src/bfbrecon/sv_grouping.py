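"""Grouping of SV junctions into candidate complex events.

SVs caused by one catastrophic event cluster in genomic space: a
breadth-first search links junctions whose nearest breakpoints lie within
``max_gap`` on the same contig, and the transitive closure partitions the
input into groups.  Groups containing at least ``min_fbi`` fold-back
inversions (default two, i.e. "more than one") are BFB candidates; each
candidate gets per-contig windows covering its breakpoints, and groups
spanning more than ``max_span`` are flagged and skipped.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .genome_model import FBI_TYPES, InputError, Junction

DEFAULT_MAX_GAP = 1_000_000
DEFAULT_MIN_FBI = 2
DEFAULT_MAX_SPAN = 10_000_000
DEFAULT_FLANK = 10_000


@dataclass
class SvGroup:
    junctions: list[Junction] = field(default_factory=list)
    group_id: int = 0
    flagged: bool = False

    @property
    def fbi_count(self) -> int:
        return sum(1 for j in self.junctions if j.jtype in FBI_TYPES)

    def breakpoints(self):
        for j in self.junctions:
            yield j.bp_a
            yield j.bp_b

    def span(self) -> dict[str, tuple[int, int]]:
        """Minimal per-contig window covering every member breakpoint."""
        out: dict[str, tuple[int, int]] = {}
        for bp in self.breakpoints():
            lo, hi = out.get(bp.contig, (bp.pos, bp.pos))
            out[bp.contig] = (min(lo, bp.pos), max(hi, bp.pos))
        return out


def _near(j1: Junction, j2: Junction, max_gap: int) -> bool:
    for a in (j1.bp_a, j1.bp_b):
        for b in (j2.bp_a, j2.bp_b):
            if a.contig == b.contig and abs(a.pos - b.pos) <= max_gap:
                return True
    return False


def cluster_svs(junctions: list[Junction], max_gap: int = DEFAULT_MAX_GAP) -> list[SvGroup]:
    """Partition junctions into proximity groups by BFS transitive closure.

    Input order does not matter: junctions are canonically sorted first and
    group ids follow (contig, min breakpoint position).
    """
    if max_gap <= 0:
        raise InputError("max_gap must be positive")
    items = sorted(junctions, key=lambda j: j.key())
    unvisited = set(range(len(items)))
    groups: list[SvGroup] = []
    while unvisited:
        seed = min(unvisited)
        comp = [seed]
        unvisited.discard(seed)
        queue = deque([seed])
        while queue:
            u = queue.popleft()
            for v in sorted(unvisited):
                if _near(items[u], items[v], max_gap):
                    unvisited.discard(v)
                    comp.append(v)
                    queue.append(v)
        groups.append(SvGroup(junctions=[items[i] for i in sorted(comp)]))
    groups.sort(key=lambda g: min((bp.contig, bp.pos) for bp in g.breakpoints()))
    for gid, g in enumerate(groups):
        g.group_id = gid
    return groups


def select_candidates(groups: list[SvGroup], min_fbi: int = DEFAULT_MIN_FBI) -> list[SvGroup]:
    """Keep groups with at least ``min_fbi`` fold-back inversions."""
    if min_fbi < 1:
        raise InputError("min_fbi must be >= 1")
    return [g for g in groups if g.fbi_count >= min_fbi]


def candidate_window(
    group: SvGroup,
    max_span: int = DEFAULT_MAX_SPAN,
    flank: int = DEFAULT_FLANK,
) -> dict[str, tuple[int, int]] | None:
    """Per-contig windows (min/max breakpoint +- flank, floored at 0).

    Returns None (and flags the group) when any contig's raw span exceeds
    ``max_span``.
    """
    if not group.junctions:
        raise InputError("empty group")
    windows: dict[str, tuple[int, int]] = {}
    for contig, (lo, hi) in group.span().items():
        if hi - lo > max_span:
            group.flagged = True
            return None
        windows[contig] = (max(0, lo - flank), hi + flank)
    return windows
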