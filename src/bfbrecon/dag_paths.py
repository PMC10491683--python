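"""BFB DAG construction, palindromic path composition and post-processing.

The solved entity configuration becomes a DAG (vertices: entities with
positive CN; edges: parent -> child, i.e. shared endpoint with strictly
longer span).  Entities are inserted into a growing path following a
topological order (decreasing length), each insertion preserving the BFB
invariant that the path is either the plain reference run or ends in a
palindromic suffix.  Post-processing then restores imperfect fold-backs,
applies deletion/duplication/insertion edits, concatenates per-chromosome
paths across translocations (BFB-to-TRX) or fuses chromosomes into a
virtual contig first (TRX-to-BFB, used for virus integration), and finally
recovers a minimal fusion-breakage cycle history by peeling.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .entity_solver import LOOP, MONO, CnConfiguration, Entity, loop, mono
from .genome_model import (
    HEAD,
    TAIL,
    Breakpoint,
    InputError,
    Junction,
    ReferenceLayout,
    SegmentRef,
    classify_or_foldback,
)

#: paths longer than this use greedy (approximate) history peeling
HISTORY_BFS_LIMIT = 64


class CompositionError(RuntimeError):
    """No valid insertion position for an entity under the BFB invariant."""

    def __init__(self, message: str, entity: Entity | None = None) -> None:
        super().__init__(message)
        self.entity = entity


class OrientedSegment(NamedTuple):
    """One oriented segment occurrence on a local genomic map."""

    contig: str
    index: int
    forward: bool

    def flip(self) -> "OrientedSegment":
        return OrientedSegment(self.contig, self.index, not self.forward)

    def __str__(self) -> str:
        return f"{'+' if self.forward else '-'}{self.contig}:{self.index}"


Path = tuple[OrientedSegment, ...]


def fwd(contig: str, index: int) -> OrientedSegment:
    return OrientedSegment(contig, index, True)


def rev(contig: str, index: int) -> OrientedSegment:
    return OrientedSegment(contig, index, False)


def rc_path(path: Sequence[OrientedSegment]) -> Path:
    return tuple(s.flip() for s in reversed(path))


def reference_path(contig: str, n: int) -> Path:
    return tuple(fwd(contig, i) for i in range(1, n + 1))


def is_reference_adjacent(x: OrientedSegment, y: OrientedSegment) -> bool:
    if x.contig != y.contig:
        return False
    if x.forward and y.forward:
        return y.index == x.index + 1
    if not x.forward and not y.forward:
        return y.index == x.index - 1
    return False


def fold_at(x: OrientedSegment, y: OrientedSegment) -> tuple[str, int] | None:
    """Return (side, index) if x|y is a perfect fold adjacency, else None."""
    if x.contig == y.contig and x.index == y.index and x.forward != y.forward:
        return (TAIL, x.index) if x.forward else (HEAD, x.index)
    return None


def has_bfb_suffix(path: Sequence[OrientedSegment]) -> bool:
    """BFB invariant: plain forward reference run, or a palindromic suffix
    (an even-length suffix equal to its own reverse complement)."""
    if all(s.forward for s in path) and all(
        is_reference_adjacent(x, y) for x, y in zip(path, path[1:])
    ):
        return True
    m = len(path)
    for length in range(2, m + 1, 2):
        suf = tuple(path[m - length:])
        if suf == rc_path(suf):
            return True
    return False


def segment_multiplicities(path: Sequence[OrientedSegment]) -> Counter:
    """Occurrences per (contig, index), counting both orientations."""
    return Counter((s.contig, s.index) for s in path)


@dataclass
class BfbPath:
    """A local genomic map: ordered oriented segments plus staged history."""

    segments: list[OrientedSegment] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    extra_alleles: int = 0  # additional unrearranged reference copies
    virtual_junctions: list = field(default_factory=list)
    cycle_count: int | None = None
    cycle_count_exact: bool = True

    @property
    def path(self) -> Path:
        return tuple(self.segments)

    def multiplicities(self, layout: ReferenceLayout | None = None) -> Counter:
        counts = segment_multiplicities(self.segments)
        if self.extra_alleles and layout is not None:
            for seg in layout.segments:
                counts[(layout.contig, seg.index)] += self.extra_alleles
        return counts

    def cn_vector(self, layout: ReferenceLayout) -> list[int]:
        counts = self.multiplicities(layout)
        return [counts.get((layout.contig, s.index), 0) for s in layout.segments]

    def render(self) -> str:
        """Human-readable map, e.g. ``H1 H2 H3 -H3 -H2 H2 H3``."""
        labels = []
        contigs = {s.contig for s in self.segments}
        for s in self.segments:
            tag = f"{s.contig}:{s.index}" if len(contigs) > 1 else f"H{s.index}"
            labels.append(tag if s.forward else f"-{tag}")
        return " ".join(labels)

    def to_record(self) -> dict:
        return {
            "schema": 1,
            "segments": [
                {"contig": s.contig, "index": s.index, "orient": "+" if s.forward else "-"}
                for s in self.segments
            ],
            "extra_alleles": self.extra_alleles,
            "history": self.history,
            "cycle_count": self.cycle_count,
            "cycle_count_exact": self.cycle_count_exact,
            "rendered": self.render(),
        }


# --------------------------------------------------------------------------
# DAG over entities
# --------------------------------------------------------------------------

def is_child(e1: Entity, e2: Entity) -> bool:
    """e1 is a child of e2 iff they share an endpoint and e1 is strictly
    shorter; a loop is additionally the child of the equal-extent mono-chain
    (the loop nests onto the chain it mirrors)."""
    if not (e1.a == e2.a or e1.b == e2.b):
        return False
    if (e1.b - e1.a) < (e2.b - e2.a):
        return True
    return (e1.a, e1.b) == (e2.a, e2.b) and e1.kind == LOOP and e2.kind == MONO


def build_dag(config: CnConfiguration) -> nx.DiGraph:
    """DAG over positive-CN entities; edges parent -> child.

    Every non-root vertex must be reachable from the root chain m(1, n);
    an orphan indicates a violated solver constraint.
    """
    cns = config.entity_cns()
    root = mono(1, config.n)
    if cns.get(root, 0) < 1:
        raise InputError("configuration lacks the root chain m(1,n)")
    g = nx.DiGraph()
    for e, cn in cns.items():
        g.add_node(e, cn=cn)
    for p, c in itertools.permutations(cns, 2):
        if is_child(c, p):
            g.add_edge(p, c)
    for v in g.nodes:
        if v != root and g.in_degree(v) == 0:
            raise InputError(f"orphan entity {v} has no parent in the DAG")
    return g


def canonical_order(entities: Iterable[Entity]) -> list[Entity]:
    """Decreasing length, then start index, mono-chains before loops."""
    return sorted(entities, key=lambda e: (-e.length, e.a, 0 if e.kind == MONO else 1))


def topological_orders(dag: nx.DiGraph, limit: int = 1):
    """Yield up to ``limit`` topological orders, the canonical one first.

    Any decreasing-length order is topological (edges always point from
    longer to shorter entities), so the canonical sort is always valid.
    """
    first = canonical_order(dag.nodes)
    yield first
    count = 1
    if count >= limit:
        return
    for order in nx.all_topological_sorts(dag):
        order = list(order)
        if order == first:
            continue
        yield order
        count += 1
        if count >= limit:
            return


# --------------------------------------------------------------------------
# path composition
# --------------------------------------------------------------------------

def _allowed_folds(config: CnConfiguration) -> set[tuple[str, int]]:
    return {(f.side, f.index) for f in config.folds}


def _valid_adjacency(x: OrientedSegment, y: OrientedSegment,
                     allowed: set[tuple[str, int]]) -> bool:
    if is_reference_adjacent(x, y):
        return True
    f = fold_at(x, y)
    return f is not None and f in allowed


def _try_insert(path: list[OrientedSegment], pos: int, block: Sequence[OrientedSegment],
                allowed: set[tuple[str, int]]) -> list[OrientedSegment] | None:
    """Insert block after index pos (pos == -1 prepends); validate the two
    boundary adjacencies and the BFB suffix invariant."""
    new = path[:pos + 1] + list(block) + path[pos + 1:]
    if pos >= 0 and not _valid_adjacency(new[pos], new[pos + 1], allowed):
        return None
    right = pos + 1 + len(block)
    if right < len(new) and not _valid_adjacency(new[right - 1], new[right], allowed):
        return None
    if not has_bfb_suffix(new):
        return None
    return new


def _chain_block(contig: str, a: int, b: int, forward: bool) -> list[OrientedSegment]:
    if forward:
        return [fwd(contig, i) for i in range(a, b + 1)]
    return [rev(contig, i) for i in range(b, a - 1, -1)]


def compose_path(
    config: CnConfiguration,
    order: Sequence[Entity] | None = None,
    contig: str | None = None,
    node_budget: int = 200_000,
) -> BfbPath:
    """Compose a BFB path realizing the configuration.

    Entities are placed one copy at a time in decreasing length (a
    topological order of the BFB DAG, canonical by default; equal-length
    entities and chain attachment sides are searched with backtracking).  A
    loop ``l(a,b)`` is spliced in as ``s̄_b..s̄_a s_a..s_b`` after a forward
    ``s_b`` (realizing the tail fold at b and the head fold at a) or as its
    mirror after a reverse ``s̄_a``; a mono-chain attaches through the fold
    at one of its detected endpoints.  Rightmost valid positions are
    preferred; every insertion must keep the palindromic-suffix invariant,
    and the final path must realize every detected fold.
    """
    contig = contig or config.contig or "chr"
    allowed = _allowed_folds(config)
    dag = build_dag(config)  # validates root presence and parent structure
    n = config.n
    root = mono(1, n)

    heads = {i for s, i in allowed if s == HEAD}
    tails = {i for s, i in allowed if s == TAIL}
    copies: list[tuple[Entity, tuple[str | None, ...]]] = []
    base_order = list(order) if order is not None else canonical_order(dag.nodes)
    for entity in base_order:
        if entity.kind == LOOP:
            for _ in range(config.loop_cns.get((entity.a, entity.b), 0)):
                copies.append((entity, (None,)))
        else:
            uh, ut = config.chain_sides.get((entity.a, entity.b), (0, 0))
            sides = tuple(
                s for s, ok in ((HEAD, entity.a in heads), (TAIL, entity.b in tails)) if ok
            )
            for _ in range(uh + ut):
                copies.append((entity, sides or (TAIL,)))

    result = BfbPath()
    result.history.append({"stage": 1, "op": "root", "entity": str(root)})
    result.extra_alleles = max(config.root_cn - 1, 0)
    start = _chain_block(contig, 1, n, forward=True)

    budget = [node_budget]
    events: list[dict] = []
    final = _compose_dfs(start, copies, 0, contig, allowed, budget, events, n)
    if final is None:
        hint = "budget exhausted" if budget[0] <= 0 else "no valid arrangement"
        raise CompositionError(
            f"composition failure ({hint}) for entities "
            f"{[str(e) for e, _ in copies]}",
            copies[0][0] if copies else None,
        )
    result.history.extend(events)
    result.segments = final
    return result


def _compose_dfs(path, copies, k, contig, allowed, budget, events, n_ref):
    """Place copies[k:] by depth-first search.

    Copies are tried in canonical (decreasing-length) order first, but any
    remaining copy may be chosen next: incomparable entities of different
    lengths sometimes must interleave (any such sequence is still consistent
    with a topological order of the DAG, since insertion positions for a
    child only exist once an ancestor is in place).  A complete arrangement
    is accepted only if it realizes every detected fold and is generable by
    the fusion-breakage process (peelable).
    """
    if k == len(copies):
        if _realized_folds(path) < allowed:
            return None
        try:
            derive_history(path, n_reference=n_ref)
        except CompositionError:
            return None
        return path
    if budget[0] <= 0:
        return None
    # candidate next copies: any not-yet-placed copy, canonical order first
    tried: set = set()
    for idx in range(k, len(copies)):
        entity, sides = copies[idx]
        key = (entity, sides)
        if key in tried:
            continue
        tried.add(key)
        reordered = copies[:k] + [copies[idx]] + copies[k:idx] + copies[idx + 1:]
        for side in sides:
            for pos, block in _insertion_candidates(path, entity, side, contig):
                budget[0] -= 1
                if budget[0] <= 0:
                    return None
                new = _try_insert(path, pos, block, allowed)
                if new is None:
                    continue
                events.append({"stage": 1, "op": "insert", "entity": str(entity),
                               "side": side, "position": pos})
                done = _compose_dfs(new, reordered, k + 1, contig, allowed, budget,
                                    events, n_ref)
                if done is not None:
                    return done
                events.pop()
    return None


def _realized_folds(path) -> set[tuple[str, int]]:
    return {f for f in (fold_at(x, y) for x, y in zip(path, path[1:])) if f is not None}


def _insertion_candidates(path, entity: Entity, side: str | None, contig: str):
    """Candidate (position, block) insertions, rightmost first."""
    a, b = entity.a, entity.b
    if entity.kind == LOOP:
        r_block = _chain_block(contig, a, b, False) + _chain_block(contig, a, b, True)
        f_block = _chain_block(contig, a, b, True) + _chain_block(contig, a, b, False)
        for pos in range(len(path) - 1, -1, -1):
            s = path[pos]
            if s.contig != contig:
                continue
            if s.forward and s.index == b:
                yield pos, r_block
            if not s.forward and s.index == a:
                yield pos, f_block
    elif side == TAIL:
        block = _chain_block(contig, a, b, False)
        for pos in range(len(path) - 1, -1, -1):
            s = path[pos]
            if s.contig == contig and s.forward and s.index == b:
                yield pos, block
    else:  # HEAD attachment
        block = _chain_block(contig, a, b, True)
        for pos in range(len(path) - 1, -1, -1):
            s = path[pos]
            if s.contig == contig and not s.forward and s.index == a:
                yield pos, block


# --------------------------------------------------------------------------
# post-processing: imperfect folds, intra-chromosomal edits, translocation
# --------------------------------------------------------------------------

def restore_imperfect_folds(bfb: BfbPath, fold_map: Sequence, layouts=None) -> BfbPath:
    """Rewrite perfect fold adjacencies back to their imperfect originals.

    An imperfect FBI (s_i, s̄_j) was solved as a perfect fold at the
    retained-arm index i; here ``s_i|s̄_i`` (tail side) becomes ``s_i|s̄_j``
    by dropping the segments between i and j on the return arm, and
    symmetrically ``s̄_i|s_i`` (head side) becomes ``s̄_j|s_i``.  Each fold
    record revises as many adjacency copies as its observed junction CN
    supports (default one), leftmost first; the remainder stays perfect.
    """
    path = list(bfb.segments)
    for f in fold_map:
        if not getattr(f, "imperfect", False):
            continue
        i, j = f.index, f.far_index
        copies = max(1, int(round(f.observed_cn))) if f.observed_cn else 1
        revised = 0
        for _ in range(copies):
            pos = _find_perfect_fold(path, f.side, i)
            if pos is None:
                break
            if f.side == TAIL:
                # ... s_i | s̄_i s̄_{i-1} .. s̄_j ... -> drop s̄_i .. s̄_{j+1}
                span = i - j
                expected = [rev(path[pos].contig, k) for k in range(i, j, -1)]
                if path[pos + 1: pos + 1 + span] != expected:
                    break
                del path[pos + 1: pos + 1 + span]
            else:
                # ... s̄_j .. s̄_i | s_i ... -> drop s̄_{j-1} .. s̄_i
                span = j - i
                expected = [rev(path[pos].contig, k) for k in range(j - 1, i - 1, -1)]
                if path[pos + 1 - span: pos + 1] != expected:
                    break
                del path[pos + 1 - span: pos + 1]
            revised += 1
            bfb.history.append(
                {"stage": 1, "op": "imperfect_fold", "side": f.side,
                 "index": i, "far_index": j}
            )
        if revised == 0:
            raise CompositionError(
                f"imperfect fold ({f.side} {i}->{j}) has no matching perfect "
                f"adjacency in the composed path"
            )
    bfb.segments = path
    return bfb


def _find_perfect_fold(path: list[OrientedSegment], side: str, i: int) -> int | None:
    for pos in range(len(path) - 1):
        f = fold_at(path[pos], path[pos + 1])
        if f == (side, i):
            return pos
    return None


@dataclass
class IntraEdit:
    """A stage-2 intra-chromosomal edit applied onto the composed path.

    kind: ``del`` removes segments (lo+1 .. hi-1) in one spanned copy;
    ``dup`` tandem-duplicates segments (lo .. hi); ``ins`` splices
    ``donor`` between an adjacent oriented pair.
    """

    kind: str
    contig: str = ""
    lo: int = 0
    hi: int = 0
    donor: list[OrientedSegment] = field(default_factory=list)
    after: OrientedSegment | None = None  # for insertions
    before: OrientedSegment | None = None
    copies: int = 1
    occurrence: str = "leftmost"


def apply_intra_edits(bfb: BfbPath, edits: Sequence[IntraEdit]) -> BfbPath:
    """Apply DEL/DUP/INS edits; each edit modifies ``copies`` occurrences
    (leftmost by default).  Edits may not span fold adjacencies (the spanned
    run must be reference-contiguous in the path)."""
    path = list(bfb.segments)
    for edit in edits:
        for _ in range(edit.copies):
            if edit.kind == "del":
                run = [fwd(edit.contig, k) for k in range(edit.lo, edit.hi + 1)]
                pos = _find_run(path, run, edit.occurrence)
                if pos is None:
                    raise CompositionError(
                        f"deletion {edit.contig}:{edit.lo}-{edit.hi} spans no "
                        f"reference-contiguous run (would cross a fold)"
                    )
                path[pos: pos + len(run)] = [run[0], run[-1]]
            elif edit.kind == "dup":
                run = [fwd(edit.contig, k) for k in range(edit.lo, edit.hi + 1)]
                pos = _find_run(path, run, edit.occurrence)
                if pos is None:
                    raise CompositionError(
                        f"duplication {edit.contig}:{edit.lo}-{edit.hi} spans no "
                        f"reference-contiguous run (would cross a fold)"
                    )
                path[pos: pos + len(run)] = run + run
            elif edit.kind == "ins":
                pos = _find_adjacency(path, edit.after, edit.before, edit.occurrence)
                if pos is None:
                    raise CompositionError(
                        f"insertion target adjacency {edit.after}|{edit.before} not found"
                    )
                path[pos + 1: pos + 1] = list(edit.donor)
            else:
                raise InputError(f"unknown edit kind {edit.kind!r}")
            bfb.history.append({"stage": 2, "op": edit.kind, "detail": str(edit)})
    bfb.segments = path
    return bfb


def _find_run(path, run, occurrence="leftmost"):
    rng = range(len(path) - len(run) + 1)
    if occurrence == "rightmost":
        rng = reversed(rng)
    for pos in rng:
        if path[pos: pos + len(run)] == run:
            return pos
    return None


def _find_adjacency(path, after, before, occurrence="leftmost"):
    rng = range(len(path) - 1)
    if occurrence == "rightmost":
        rng = reversed(rng)
    for pos in rng:
        if path[pos] == after and path[pos + 1] == before:
            return pos
    return None


def _terminal_exposure(path: Sequence[OrientedSegment], end: str) -> tuple[str, int, str]:
    """(contig, segment index, exposed segment end) at a path terminus."""
    s = path[-1] if end == "right" else path[0]
    if end == "right":
        return (s.contig, s.index, TAIL if s.forward else HEAD)
    return (s.contig, s.index, HEAD if s.forward else TAIL)


def concat_translocations(paths: Sequence[BfbPath], trx_junctions: Sequence[Junction]) -> BfbPath:
    """Concatenate per-contig BFB paths through translocation junctions
    (BFB-to-TRX mode).

    Each junction must join a terminus of the growing path to a terminus of
    one remaining per-contig path, flipping blocks (reverse complement) as
    the junction's end combination dictates; every input path stays a
    contiguous block of the result.
    """
    if not paths:
        raise InputError("no paths to concatenate")
    merged = list(paths[0].segments)
    history = list(paths[0].history)
    remaining = {id(p): p for p in paths[1:]}
    pending = list(trx_junctions)
    extra = paths[0].extra_alleles

    def endpoints(jn: Junction):
        return (
            (jn.bp_a.contig, jn.seg_a, jn.bp_a.end),
            (jn.bp_b.contig, jn.seg_b, jn.bp_b.end),
        )

    while pending:
        progressed = False
        for jn in list(pending):
            ja, jb = endpoints(jn)
            for key, other in list(remaining.items()):
                blocks = [tuple(other.segments), rc_path(other.segments)]
                for mflip in (False, True):
                    cur = rc_path(merged) if mflip else tuple(merged)
                    for blk in blocks:
                        # join cur's right end to blk's left end
                        if (_terminal_exposure(cur, "right") == ja
                                and _terminal_exposure(blk, "left") == jb) or (
                                _terminal_exposure(cur, "right") == jb
                                and _terminal_exposure(blk, "left") == ja):
                            merged = list(cur) + list(blk)
                            history.append(
                                {"stage": 2, "op": "trx_concat", "junction": jn.key()}
                            )
                            history.extend(other.history)
                            extra += other.extra_alleles
                            del remaining[key]
                            pending.remove(jn)
                            progressed = True
                            break
                    if progressed:
                        break
                if progressed:
                    break
            if progressed:
                break
        if not progressed:
            raise CompositionError(
                "translocation endpoints are interior to the per-contig paths; "
                "consider TRX-to-BFB mode"
            )
    out = BfbPath(segments=merged, history=history, extra_alleles=extra)
    return out


def build_virtual_contig(
    layouts: dict[str, ReferenceLayout],
    junctions: Sequence[Junction],
    name: str = "virtual",
) -> tuple[ReferenceLayout, list[tuple[str, int, bool]]]:
    """Fuse layouts along a simple chain of TRX/VIT junctions (TRX-to-BFB).

    Returns the fused layout plus a provenance list mapping each fused
    segment index (1-based) to ``(source contig, source index, forward)``.
    The host block runs up to the junction breakpoint; the joined block
    continues from its breakpoint onward, reverse-complemented when the
    junction's end combination requires it.
    """
    if not junctions:
        if len(layouts) != 1:
            raise InputError("virtual contig without junctions needs exactly one layout")
        layout = next(iter(layouts.values()))
        prov = [(layout.contig, s.index, True) for s in layout.segments]
        return layout, prov

    # chain: oriented blocks of (contig, segment range, orientation)
    used: set[str] = set()
    jn = junctions[0]
    a = (jn.bp_a.contig, jn.seg_a, jn.bp_a.end)
    b = (jn.bp_b.contig, jn.seg_b, jn.bp_b.end)

    def block(contig: str, idx: int, end: str, role: str) -> list[tuple[str, int, bool]]:
        """role 'head' = block ends at this breakpoint; 'tail' = starts."""
        layout = layouts[contig]
        if role == "left":  # keep the part whose exposed end is this breakpoint
            if end == TAIL:
                return [(contig, s.index, True) for s in layout.segments if s.index <= idx]
            return [(contig, s.index, False) for s in layout.segments if s.index >= idx][::-1]
        if end == HEAD:
            return [(contig, s.index, True) for s in layout.segments if s.index >= idx]
        return [(contig, s.index, False) for s in layout.segments if s.index <= idx][::-1]

    prov = block(*a, "left") + block(*b, "right")
    used = {a[0], b[0]}
    for jn in junctions[1:]:
        ja = (jn.bp_a.contig, jn.seg_a, jn.bp_a.end)
        jb = (jn.bp_b.contig, jn.seg_b, jn.bp_b.end)
        if ja[0] in used and jb[0] in used:
            raise InputError("junction chain is not a simple path across layouts")
        if jb[0] in used:
            ja, jb = jb, ja
        # attach jb's block at the end of the provenance chain
        last = prov[-1]
        if last[0] != ja[0]:
            raise InputError("junction chain is not a simple path across layouts")
        prov = prov + block(*jb, "right")
        used.add(jb[0])

    segments: list[SegmentRef] = []
    pos = 0
    for i, (contig, idx, forward) in enumerate(prov, start=1):
        src = layouts[contig].segments[idx - 1]
        segments.append(
            SegmentRef(name, pos, pos + src.length, index=i,
                       observed_cn=src.observed_cn, origin=src.origin)
        )
        pos += src.length
    fused = ReferenceLayout(name, 0, pos, segments, origin="fused")
    return fused, prov


def map_virtual_path(bfb: BfbPath, prov: list[tuple[str, int, bool]]) -> BfbPath:
    """Translate a path over a virtual contig back to source coordinates."""
    out = []
    for s in bfb.segments:
        contig, idx, forward = prov[s.index - 1]
        out.append(OrientedSegment(contig, idx, forward == s.forward))
    bfb.segments = out
    return bfb


# --------------------------------------------------------------------------
# history derivation (fusion-breakage peeling)
# --------------------------------------------------------------------------

def _peels(path: Path):
    """All single-cycle undo moves: P = Z + rc(Y) with Y a suffix of Z."""
    m = len(path)
    for w in range(1, m // 2 + 1):
        z = path[:m - w]
        if path[m - w:] == rc_path(z[len(z) - w:]):
            yield z


def derive_history(
    path: Sequence[OrientedSegment],
    n_reference: int | None = None,
    max_cycles: int = 32,
) -> tuple[int, list[dict], bool]:
    """Minimal number of fusion-breakage cycles generating the path.

    Breadth-first search over peel moves (undoing ``P = Z | rc(Y)`` with Y a
    suffix of Z) guarantees minimality for paths of <= 64 oriented segments;
    longer paths fall back to greedy longest-peel and are flagged
    approximate.  A terminal state that is a *proper* prefix of the
    reference adds one truncation cycle.  Returns
    ``(cycle_count, events, exact)``.
    """
    start = tuple(path)
    if not start:
        raise InputError("empty path")
    contig = start[0].contig
    if n_reference is None:
        n_reference = max(s.index for s in start)

    def terminal_cost(p: Path) -> int | None:
        if not all(s.forward for s in p):
            return None
        idxs = [s.index for s in p]
        if idxs[0] != 1 or idxs != list(range(1, len(p) + 1)):
            return None
        return 0 if len(p) == n_reference else 1

    exact = len(start) <= HISTORY_BFS_LIMIT
    if exact:
        seen = {start: None}
        queue = deque([(start, 0)])
        while queue:
            state, depth = queue.popleft()
            cost = terminal_cost(state)
            if cost is not None:
                events = _peel_events(start, state, seen)
                return depth + cost, events, True
            if depth >= max_cycles:
                continue
            for z in _peels(state):
                if z not in seen:
                    seen[z] = state
                    queue.append((z, depth + 1))
        raise CompositionError(f"path on {contig} is not BFB-consistent (no peel sequence)")
    # greedy longest peel
    state, cycles, events = start, 0, []
    while terminal_cost(state) is None:
        zs = sorted(_peels(state), key=len)
        if not zs:
            raise CompositionError(f"path on {contig} is not BFB-consistent (greedy)")
        nxt = zs[0]
        events.append({"op": "fusion", "kept": len(state) - len(nxt)})
        state, cycles = nxt, cycles + 1
        if cycles > max_cycles:
            raise CompositionError("history peeling exceeded the cycle cap")
    return cycles + terminal_cost(state), events, False


def _peel_events(start: Path, terminal: Path, parents: dict) -> list[dict]:
    chain = [terminal]
    node = terminal
    while parents.get(node) is not None:
        node = parents[node]
        chain.append(node)
    chain.reverse()  # start .. terminal
    events = []
    for longer, shorter in zip(chain, chain[1:]):
        fuse_seg = shorter[-1]
        events.append(
            {
                "op": "fusion",
                "fold_index": fuse_seg.index,
                "fold_side": TAIL if fuse_seg.forward else HEAD,
                "appended": len(longer) - len(shorter),
            }
        )
    events.reverse()  # chronological: first cycle first
    return events


def realized_junctions(
    path: Sequence[OrientedSegment],
    layouts: dict[str, ReferenceLayout],
    virus_contigs: frozenset[str] | set[str] = frozenset(),
) -> list[Junction]:
    """Extract the typed junction list realized by a path's adjacencies.

    Every consecutive pair that is not a reference adjacency exposes two
    breakpoints (tail of a forward segment / head of a reverse one on the
    left; the mirror on the right) and is classified like a called SV.
    """
    out: list[Junction] = []
    for x, y in zip(path, path[1:]):
        if is_reference_adjacent(x, y):
            continue
        seg_x = layouts[x.contig].segments[x.index - 1]
        seg_y = layouts[y.contig].segments[y.index - 1]
        bp_x = Breakpoint(x.contig, seg_x.end if x.forward else seg_x.start,
                          TAIL if x.forward else HEAD)
        bp_y = Breakpoint(y.contig, seg_y.start if y.forward else seg_y.end,
                          HEAD if y.forward else TAIL)
        jtype = classify_or_foldback(bp_x, bp_y, virus_contigs)
        # seg indices passed through the constructor so the canonical
        # breakpoint ordering swaps them consistently
        out.append(Junction(bp_x, bp_y, jtype=jtype, seg_a=x.index, seg_b=y.index))
    return out
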