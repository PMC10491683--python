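"""Fusion-breakage simulator: ground-truth BFB paths and noisy observables.

Each cycle concatenates the current path with its reverse complement and
cuts off a random number of trailing segments, exactly the generative
process the reconstruction inverts.  On top of the core path the simulator
overlays minor duplications, imperfect fold-backs, insertions,
translocations and virus integration (the six benchmark archetypes), and
derives the observables a caller would produce: a segment copy-number
profile, a typed junction list with optional dropout, and sliding-window
read-linkage evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dag_paths import (
    BfbPath,
    OrientedSegment,
    Path,
    fold_at,
    fwd,
    is_reference_adjacent,
    rc_path,
    realized_junctions,
    reference_path,
    rev,
)
from .genome_model import (
    HEAD,
    TAIL,
    Breakpoint,
    InputError,
    Junction,
    LinkageEvidence,
    ReferenceLayout,
    SegmentRef,
    classify_junction,
)

DEFAULT_SEGMENT_BP = 10_000


@dataclass
class NoiseSpec:
    """Observation noise emulating depth/purity effects."""

    cn_jitter_sd: float = 0.0
    junction_dropout: float = 0.0
    linkage_window: int = 0  # 0 = no linkage evidence emitted


@dataclass
class SimulationConfig:
    n_segments: tuple[int, int] = (6, 15)
    n_cycles: tuple[int, int] = (2, 7)
    minor_dup_prob: float = 0.30
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    batch_size: int = 410
    total_cn_range: tuple[int, int] = (13, 105)
    max_segment_cn_range: tuple[int, int] = (3, 11)


def make_layout(contig: str, n: int, segment_bp: int = DEFAULT_SEGMENT_BP,
                start: int = 0, origin: str = "human") -> ReferenceLayout:
    segs = [
        SegmentRef(contig, start + i * segment_bp, start + (i + 1) * segment_bp,
                   index=i + 1, origin=origin)
        for i in range(n)
    ]
    return ReferenceLayout(contig, start, start + n * segment_bp, segs, origin=origin)


def simulate_history(
    n_segments: int,
    n_cycles: int,
    rng: np.random.Generator,
    contig: str = "chr",
) -> BfbPath:
    """Run ``n_cycles`` fusion-breakage cycles on an n-segment reference.

    The appended (reverse-complemented) copy is truncated uniformly to
    between 1 and len(last arm) segments, so every cycle leaves an
    observable fold; the palindromic-suffix invariant holds throughout.
    """
    if n_segments < 1:
        raise InputError("need at least one segment")
    path = list(reference_path(contig, n_segments))
    history = [{"stage": 1, "op": "root", "entity": f"m(1,{n_segments})"}]
    arm_len = n_segments
    for _ in range(n_cycles):
        keep = int(rng.integers(1, arm_len + 1))
        appended = list(rc_path(path))[:keep]
        fuse = path[-1]
        history.append(
            {
                "stage": 1,
                "op": "fusion",
                "fold_index": fuse.index,
                "fold_side": TAIL if fuse.forward else HEAD,
                "appended": keep,
            }
        )
        path = path + appended
        arm_len = keep
    return BfbPath(segments=path, history=history, cycle_count=n_cycles)


def fusion_path(contig: str, n_segments: int, fusion_indices: list[int],
                final_keep: int | None = None) -> BfbPath:
    """Deterministic fusion-breakage path with prescribed fold indices.

    ``fusion_indices[k]`` is the segment whose fold the (k+1)-th cycle
    creates; cuts are chosen so the next cycle fuses at the requested
    segment.  The first fusion must be at the current path end (segment
    ``n_segments`` for the first cycle)."""
    path = list(reference_path(contig, n_segments))
    history = [{"stage": 1, "op": "root", "entity": f"m(1,{n_segments})"}]
    for k, idx in enumerate(fusion_indices):
        last = path[-1]
        if last.index != idx:
            raise InputError(
                f"cycle {k + 1}: path ends at segment {last.index}, cannot fuse at {idx}"
            )
        if k + 1 < len(fusion_indices):
            nxt = fusion_indices[k + 1]
            appended = []
            for s in rc_path(path):
                appended.append(s)
                if s.index == nxt:
                    break
            else:
                raise InputError(f"cannot reach fusion segment {nxt} after fusing at {idx}")
        else:
            arm = _last_arm_len(path)
            keep = final_keep if final_keep is not None else max(arm // 2, 1)
            appended = list(rc_path(path))[:keep]
        history.append(
            {
                "stage": 1,
                "op": "fusion",
                "fold_index": idx,
                "fold_side": TAIL if last.forward else HEAD,
                "appended": len(appended),
            }
        )
        path = path + appended
    return BfbPath(segments=path, history=history, cycle_count=len(fusion_indices))


def _last_arm_len(path: list[OrientedSegment]) -> int:
    n = 1
    for x, y in zip(reversed(path[:-1]), reversed(path[1:])):
        if is_reference_adjacent(x, y):
            n += 1
        else:
            break
    return n


def add_minor_duplications(
    bfb: BfbPath,
    prob: float,
    rng: np.random.Generator,
    max_len: int = 2,
) -> BfbPath:
    """With probability ``prob``, tandem-duplicate one short (1-2 segment)
    forward run in place, recording the DUP junction in the history."""
    if not (0.0 <= prob <= 1.0):
        raise InputError("probability must be in [0, 1]")
    if rng.random() >= prob:
        return bfb
    path = list(bfb.segments)
    runs = []
    for pos in range(len(path)):
        for length in range(1, max_len + 1):
            run = path[pos: pos + length]
            if len(run) < length:
                continue
            if all(s.forward for s in run) and all(
                is_reference_adjacent(x, y) for x, y in zip(run, run[1:])
            ):
                runs.append((pos, length))
    if not runs:
        return bfb
    pos, length = runs[int(rng.integers(0, len(runs)))]
    run = path[pos: pos + length]
    path[pos: pos + length] = run + run
    bfb.segments = path
    bfb.history.append(
        {"stage": 2, "op": "dup", "contig": run[0].contig,
         "lo": run[0].index, "hi": run[-1].index}
    )
    return bfb


def apply_imperfect_folds(bfb: BfbPath, count: int, rng: np.random.Generator) -> BfbPath:
    """Convert up to ``count`` perfect fold adjacencies into imperfect ones
    by dropping 1+ segments on the return arm (mirrors the revision rule)."""
    path = list(bfb.segments)
    applied = 0
    order = list(range(len(path) - 1))
    rng.shuffle(order)
    for pos in order:
        if applied >= count:
            break
        if pos >= len(path) - 1:
            continue
        f = fold_at(path[pos], path[pos + 1])
        if f is None:
            continue
        side, i = f
        if side == TAIL:
            # drop s̄_i .. s̄_{j+1} after the fold, j < i
            arm = 0
            k = pos + 1
            while k < len(path) and not path[k].forward and (
                k == pos + 1 or path[k].index == path[k - 1].index - 1
            ):
                arm += 1
                k += 1
            if arm < 2:
                continue
            drop = int(rng.integers(1, arm))
            del path[pos + 1: pos + 1 + drop]
        else:
            arm = 0
            k = pos
            while k >= 0 and not path[k].forward and (
                k == pos or path[k].index == path[k + 1].index + 1
            ):
                arm += 1
                k -= 1
            if arm < 2:
                continue
            drop = int(rng.integers(1, arm))
            del path[pos + 1 - drop: pos + 1]
        applied += 1
        bfb.history.append({"stage": 1, "op": "imperfect_fold", "side": side, "index": i})
    bfb.segments = path
    return bfb


COMPLEX_TEMPLATES = (
    "perfect", "imperfect-folds", "insertion", "translocation", "dup+ins", "virus",
)


def apply_complex_template(
    template: str,
    rng: np.random.Generator,
    n_segments: int = 6,
    fusion_indices: list[int] | None = None,
    layouts: dict[str, ReferenceLayout] | None = None,
):
    """Build one of the six benchmark archetypes.

    Returns ``(bfb_path, layouts)`` where layouts covers every contig the
    truth path touches (virus contigs have origin 'virus').
    """
    if template not in COMPLEX_TEMPLATES:
        raise InputError(f"unknown template {template!r}")
    if fusion_indices is None:
        fusion_indices = [n_segments, 2, 4, 3] if n_segments >= 6 else [n_segments, 1]
    if layouts is None:
        layouts = {"chrA": make_layout("chrA", n_segments)}
    host = next(iter(layouts))
    if not fusion_indices:
        bfb = BfbPath(segments=list(reference_path(host, n_segments)),
                      history=[{"stage": 1, "op": "root", "entity": f"m(1,{n_segments})"}],
                      cycle_count=0)
        return bfb, layouts

    if template == "virus":
        vlay = make_layout("virus", 3, segment_bp=1_000, origin="virus")
        layouts = {**layouts, "virus": vlay}
        # fuse host prefix with the virus contig, then run cycles on it
        host_lay = layouts[host]
        join = max(2, n_segments // 2)
        fused_n = join + vlay.n
        bfb = simulate_history(fused_n, max(len(fusion_indices), 2), rng, contig="fused")
        prov = [(host, i + 1, True) for i in range(join)] + [
            ("virus", i + 1, True) for i in range(vlay.n)
        ]
        mapped = [
            OrientedSegment(*prov[s.index - 1][:2], prov[s.index - 1][2] == s.forward)
            for s in bfb.segments
        ]
        bfb.segments = mapped
        return bfb, layouts

    if template == "translocation":
        other = make_layout("chrB", max(3, n_segments // 2))
        layouts = {**layouts, "chrB": other}
        bfb_a = fusion_path(host, n_segments, fusion_indices)
        cycles_b = [other.n] if other.n >= 1 else []
        bfb_b = fusion_path("chrB", other.n, cycles_b, final_keep=1)
        # join A's right terminus to B's left terminus (TRX junction)
        merged = list(bfb_a.segments) + list(bfb_b.segments)
        bfb = BfbPath(segments=merged,
                      history=bfb_a.history + bfb_b.history
                      + [{"stage": 2, "op": "trx_concat"}],
                      cycle_count=(bfb_a.cycle_count or 0) + (bfb_b.cycle_count or 0))
        return bfb, layouts

    bfb = fusion_path(host, n_segments, fusion_indices)
    if template == "imperfect-folds":
        bfb = apply_imperfect_folds(bfb, 2, rng)
    elif template == "insertion":
        donor = make_layout("chrC", 2)
        layouts = {**layouts, "chrC": donor}
        _insert_donor(bfb, donor, rng)
    elif template == "dup+ins":
        bfb = add_minor_duplications(bfb, 1.0, rng)
        donor = make_layout("chrC", 2)
        layouts = {**layouts, "chrC": donor}
        _insert_donor(bfb, donor, rng)
    return bfb, layouts


def _insert_donor(bfb: BfbPath, donor: ReferenceLayout, rng: np.random.Generator) -> None:
    path = list(bfb.segments)
    # insert at a reference adjacency so the truth folds stay detectable
    sites = [p for p in range(len(path) - 1)
             if is_reference_adjacent(path[p], path[p + 1])]
    pos = sites[int(rng.integers(0, len(sites)))]
    block = [fwd(donor.contig, s.index) for s in donor.segments]
    path[pos + 1: pos + 1] = block
    bfb.segments = path
    bfb.history.append({"stage": 2, "op": "ins", "contig": donor.contig, "position": pos})


def derive_observables(
    bfb: BfbPath,
    layouts: dict[str, ReferenceLayout],
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[float]], list[Junction], LinkageEvidence | None]:
    """Derive (CN profile per contig, junction list, linkage) from a path.

    With noise off this is the exact inverse of the solver's inputs:
    CNs are path multiplicities, junctions the realized non-reference
    adjacencies.  Jitter perturbs CNs (rounded Gaussian, clipped at 0);
    dropout removes junctions independently; linkage windows slide over the
    truth path emitting oriented adjacencies.
    """
    noise = noise or NoiseSpec()
    rng = rng if rng is not None else np.random.default_rng(0)
    counts = bfb.multiplicities()
    profile: dict[str, list[float]] = {}
    virus = {c for c, lay in layouts.items() if lay.origin == "virus"}
    for contig, layout in layouts.items():
        cns = [float(counts.get((contig, s.index), 0)) for s in layout.segments]
        if noise.cn_jitter_sd > 0:
            cns = [max(0.0, round(c + rng.normal(0.0, noise.cn_jitter_sd))) for c in cns]
        profile[contig] = cns
    junctions: list[Junction] = []
    seen: set[tuple] = set()
    for jn in realized_junctions(bfb.segments, layouts, virus_contigs=virus):
        if jn.key() in seen:
            continue
        seen.add(jn.key())
        if noise.junction_dropout > 0 and rng.random() < noise.junction_dropout:
            continue
        junctions.append(jn)
    linkage = None
    if noise.linkage_window >= 2:
        adjacencies = []
        seen_adj = set()
        path = bfb.segments
        for start in range(0, max(len(path) - 1, 0)):
            window = path[start: start + noise.linkage_window]
            for x, y in zip(window, window[1:]):
                key = ((x.index, 1 if x.forward else -1), (y.index, 1 if y.forward else -1))
                if x.contig == y.contig and key not in seen_adj:
                    seen_adj.add(key)
                    adjacencies.append(key)
        linkage = LinkageEvidence(adjacencies=adjacencies, protocol="simulated")
    return profile, junctions, linkage


@dataclass
class BatchEntry:
    seed: int
    n_segments: int
    n_cycles: int
    fbi_count: int
    total_cn: int
    max_cn: int
    path: list[str]


def simulate_batch(config: SimulationConfig) -> list[BatchEntry]:
    """Simulate a batch of BFB paths whose manifests fall in the configured
    ranges (segments, FBIs, total and largest segment CN); deterministic
    under the config seed."""
    rng = np.random.default_rng(config.seed)
    out: list[BatchEntry] = []
    attempts = 0
    max_attempts = max(200, config.batch_size * 200)
    while len(out) < config.batch_size and attempts < max_attempts:
        attempts += 1
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = np.random.default_rng(sub_seed)
        n = int(sub.integers(config.n_segments[0], config.n_segments[1] + 1))
        k = int(sub.integers(config.n_cycles[0], config.n_cycles[1] + 1))
        bfb = simulate_history(n, k, sub)
        bfb = add_minor_duplications(bfb, config.minor_dup_prob, sub)
        counts = bfb.multiplicities()
        cns = [counts.get(("chr", i), 0) for i in range(1, n + 1)]
        folds = {
            fold_at(x, y)
            for x, y in zip(bfb.segments, bfb.segments[1:])
            if fold_at(x, y) is not None
        }
        entry = BatchEntry(
            seed=sub_seed,
            n_segments=n,
            n_cycles=k,
            fbi_count=len(folds),
            total_cn=sum(cns),
            max_cn=max(cns),
            path=[str(s) for s in bfb.segments],
        )
        if not (config.n_cycles[0] <= entry.fbi_count <= config.n_cycles[1]):
            continue
        if not (config.total_cn_range[0] <= entry.total_cn <= config.total_cn_range[1]):
            continue
        if not (config.max_segment_cn_range[0] <= entry.max_cn <= config.max_segment_cn_range[1]):
            continue
        out.append(entry)
    if len(out) < config.batch_size:
        raise RuntimeError("batch rejection sampling exhausted its attempt budget")
    return out
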