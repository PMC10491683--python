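"""Copy-number fitting over BFB mono-chains and loops by integer programming.

A BFB path decomposes into *entities*: mono-chains ``m(a,b)`` (a run of
consecutive segments, forward or reverse-complemented) and *loops* ``l(a,b)``
(a mono-chain concatenated with its own reverse complement).  A mono-chain
copy contributes 1 to the copy number of every segment it spans, a loop copy
contributes 2.  Given observed segment CNs and the set of detected fold-back
inversions, an integer linear program picks entity copy numbers minimizing
the total disparity between estimated and observed CNs, subject to:

* every non-root entity has a parent entity (shared endpoint, strictly
  longer) in the result, so the support forms a BFB DAG;
* every detected fold-back must be usable: at least one entity realizes a
  fold at that segment end;
* entities may only place folds at detected (or virtual) fold ends: a loop
  ``l(a,b)`` realizes a head-side fold at ``a`` and a tail-side fold at
  ``b``; a non-root mono-chain attaches at one of its endpoints through a
  fold, so each chain copy carries a head- or tail-attachment label.

Optional fold-junction CN bands (with the mono-chain pair-average terms) are
added when observed junction CNs are available; optional linkage and
multi-subclone coupling constraints refine the fit.  The MILP is solved
exactly (zero gap) with HiGHS via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .genome_model import HEAD, TAIL, InputError

MONO = "mono_chain"
LOOP = "loop"

# objective layering: residuals dominate, then total entity count (Occam),
# then a slight preference for longer entities as tie-break.
_W_RESIDUAL = 1.0e6
_W_COUNT = 1.0e2
_W_LENGTH = 5.0e-3

#: default penalty (in residual units) charged per virtual fold-back added
DEFAULT_VIRTUAL_PENALTY = 2
#: default maximum number of virtual fold-backs to hypothesize
DEFAULT_VIRTUAL_BUDGET = 3


class SolverError(RuntimeError):
    pass


class InfeasibleError(SolverError):
    """The program admits no integral solution (prompts virtual-FBI search)."""


@dataclass(frozen=True, order=True)
class Entity:
    """A mono-chain or loop over segments ``a..b`` (1-based, a <= b)."""

    kind: str
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.kind not in (MONO, LOOP):
            raise InputError(f"unknown entity kind {self.kind!r}")
        if not (1 <= self.a <= self.b):
            raise InputError(f"invalid entity bounds ({self.a}, {self.b})")

    @property
    def length(self) -> int:
        return self.b - self.a + 1

    def __str__(self) -> str:  # m(2,4) / l(3,3)
        return f"{'m' if self.kind == MONO else 'l'}({self.a},{self.b})"


def mono(a: int, b: int) -> Entity:
    return Entity(MONO, a, b)


def loop(a: int, b: int) -> Entity:
    return Entity(LOOP, a, b)


@dataclass(frozen=True)
class FoldBack:
    """A detected (or hypothesized) fold-back at one segment end.

    ``side`` is HEAD for an FBI-hh fold before segment ``index`` and TAIL for
    an FBI-tt fold after it.  ``far_index`` is set for imperfect folds
    (s_i, s̄_j): the path is composed with the fold treated as perfect at
    ``index`` and revised afterwards.
    """

    side: str
    index: int
    observed_cn: float | None = None
    far_index: int | None = None
    virtual: bool = False
    source: str = "sv"  # sv | linkage | virtual

    @property
    def imperfect(self) -> bool:
        return self.far_index is not None and self.far_index != self.index


@dataclass
class EntityCatalog:
    """All n(n+1)/2 mono-chains and n(n+1)/2 loops for an n-segment layout,
    with the index sets used by the CN-fit formulas."""

    n: int
    mono_chains: list[Entity] = field(default_factory=list)
    loops: list[Entity] = field(default_factory=list)

    @property
    def entities(self) -> list[Entity]:
        return self.mono_chains + self.loops

    def M(self, i: int) -> list[Entity]:
        """Mono-chains containing segment i."""
        return [e for e in self.mono_chains if e.a <= i <= e.b]

    def L(self, i: int) -> list[Entity]:
        """Loops containing segment i."""
        return [e for e in self.loops if e.a <= i <= e.b]

    def L_ii(self, i: int) -> list[Entity]:
        """Loops realizing the fold junction at segment i (a = i or b = i)."""
        return [e for e in self.loops if e.a == i or e.b == i]

    def P(self, i: int) -> list[tuple[Entity, Entity]]:
        """Mono-chain pairs joined by the fold junction at i: shared endpoint
        equal to i on the same side, strictly different lengths (longer
        first)."""
        pairs = []
        for e1, e2 in itertools.combinations(self.mono_chains, 2):
            if e1.length == e2.length:
                continue
            lo, hi = (e2, e1) if e1.length > e2.length else (e1, e2)
            if (hi.a == lo.a == i) or (hi.b == lo.b == i):
                pairs.append((hi, lo))
        return pairs


def enumerate_entities(n: int) -> EntityCatalog:
    """Enumerate every mono-chain and loop for an n-segment reference path."""
    if n < 1:
        raise InputError(f"segment count must be >= 1, got {n}")
    chains = [mono(a, b) for a in range(1, n + 1) for b in range(a, n + 1)]
    loops = [loop(a, b) for a in range(1, n + 1) for b in range(a, n + 1)]
    return EntityCatalog(n=n, mono_chains=chains, loops=loops)


@dataclass
class SolverOptions:
    time_limit: float = 60.0
    max_entity_cn: int | None = None
    max_root_cn: int | None = None  # 1 = single-allele mode
    enforce_fold_usage: bool = True
    virtual_penalty: float = DEFAULT_VIRTUAL_PENALTY
    virtual_budget: int = DEFAULT_VIRTUAL_BUDGET


@dataclass
class CnConfiguration:
    """Solved entity CN configuration for one layout."""

    n: int
    contig: str | None = None
    root_cn: int = 1
    #: attached copies per mono-chain: (head-fold copies, tail-fold copies)
    chain_sides: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    loop_cns: dict[tuple[int, int], int] = field(default_factory=dict)
    folds: list[FoldBack] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    junction_residuals: dict[int, float] = field(default_factory=dict)
    objective: float = 0.0
    status: str = "optimal"
    raw_x: object = None  # solver solution vector (for no-good cuts)

    def chain_cn(self, a: int, b: int) -> int:
        uh, ut = self.chain_sides.get((a, b), (0, 0))
        base = self.root_cn if (a, b) == (1, self.n) else 0
        return base + uh + ut

    def entity_cns(self) -> dict[Entity, int]:
        out: dict[Entity, int] = {}
        for (a, b) in sorted(set(self.chain_sides) | {(1, self.n)}):
            cn = self.chain_cn(a, b)
            if cn > 0:
                out[mono(a, b)] = cn
        for (a, b), cn in sorted(self.loop_cns.items()):
            if cn > 0:
                out[loop(a, b)] = cn
        return out

    def estimated_segment_cns(self) -> list[int]:
        """Eq.-(2)-style aggregate: chains contribute cn, loops 2*cn."""
        est = [0] * self.n
        for e, cn in self.entity_cns().items():
            w = 1 if e.kind == MONO else 2
            for i in range(e.a, e.b + 1):
                est[i - 1] += w * cn
        return est


class _Lp:
    """Tiny incremental MILP builder over scipy.optimize.milp."""

    def __init__(self) -> None:
        self.obj: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[tuple[dict[int, float], float, float]] = []

    def var(self, obj: float = 0.0, lb: float = 0.0, ub: float = math.inf,
            integer: bool = True) -> int:
        self.obj.append(obj)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integrality.append(1 if integer else 0)
        return len(self.obj) - 1

    def row(self, coeffs: dict[int, float], lo: float, hi: float) -> None:
        self.rows.append((coeffs, lo, hi))

    def solve(self, time_limit: float) -> tuple[np.ndarray, float, str]:
        ncol = len(self.obj)
        if not self.rows:
            self.row({0: 0.0}, -math.inf, math.inf)
        data, indices, indptr = [], [], [0]
        lo_v, hi_v = [], []
        for coeffs, lo, hi in self.rows:
            for j, c in coeffs.items():
                data.append(c)
                indices.append(j)
            indptr.append(len(data))
            lo_v.append(lo)
            hi_v.append(hi)
        a = csr_matrix((data, indices, indptr), shape=(len(self.rows), ncol))
        res = milp(
            c=np.asarray(self.obj),
            constraints=LinearConstraint(a, lo_v, hi_v),
            integrality=np.asarray(self.integrality),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
            options={"time_limit": time_limit, "mip_rel_gap": 0.0},
        )
        if res.status == 2:
            raise InfeasibleError("CN program infeasible")
        if res.status not in (0, 3) or res.x is None:
            raise SolverError(f"MILP failed: status {res.status} ({res.message})")
        status = "optimal" if res.status == 0 else "time_limit_incumbent"
        return np.asarray(res.x), float(res.fun), status


@dataclass
class CnProgram:
    """Assembled MILP plus the variable bookkeeping needed to read it back."""

    catalog: EntityCatalog
    observed: list[float]
    folds: list[FoldBack]
    options: SolverOptions
    contig: str | None = None
    lp: _Lp = field(default_factory=_Lp)
    v_root: int = -1
    v_head: dict[tuple[int, int], int] = field(default_factory=dict)
    v_tail: dict[tuple[int, int], int] = field(default_factory=dict)
    v_loop: dict[tuple[int, int], int] = field(default_factory=dict)
    v_eps: list[int] = field(default_factory=list)
    v_xi: dict[int, int] = field(default_factory=dict)
    y_entity: dict[Entity, int] = field(default_factory=dict)
    big_m: float = 0.0
    unsatisfiable_linkage: list = field(default_factory=list)

    # ----- helpers over variable structure -------------------------------
    def chain_cn_coeffs(self, a: int, b: int) -> dict[int, float]:
        coeffs: dict[int, float] = {}
        if (a, b) == (1, self.catalog.n):
            coeffs[self.v_root] = 1.0
        if (a, b) in self.v_head:
            coeffs[self.v_head[(a, b)]] = 1.0
        if (a, b) in self.v_tail:
            coeffs[self.v_tail[(a, b)]] = coeffs.get(self.v_tail[(a, b)], 0.0) + 1.0
        return coeffs

    def entity_cn_coeffs(self, e: Entity) -> dict[int, float]:
        if e.kind == MONO:
            return self.chain_cn_coeffs(e.a, e.b)
        if (e.a, e.b) in self.v_loop:
            return {self.v_loop[(e.a, e.b)]: 1.0}
        return {}


def _fold_sets(folds: list[FoldBack]) -> tuple[set[int], set[int]]:
    heads = {f.index for f in folds if f.side == HEAD}
    tails = {f.index for f in folds if f.side == TAIL}
    return heads, tails


def assemble_program(
    catalog: EntityCatalog,
    observed_cns: list[float],
    folds: list[FoldBack],
    options: SolverOptions | None = None,
    contig: str | None = None,
) -> CnProgram:
    """Build the CN-fit MILP for one layout.

    ``observed_cns`` are the per-segment observed copy numbers; ``folds`` the
    detected/virtual fold-backs (imperfect folds already canonicalized onto
    their retained-arm index).
    """
    options = options or SolverOptions()
    n = catalog.n
    if len(observed_cns) != n:
        raise InputError("observed CN vector length does not match catalog")
    for f in folds:
        if not (1 <= f.index <= n):
            raise InputError(f"fold-back at segment {f.index} outside layout 1..{n}")
    prog = CnProgram(catalog, list(map(float, observed_cns)), list(folds), options, contig)
    lp = prog.lp
    heads, tails = _fold_sets(folds)
    if options.max_entity_cn is not None:
        max_cn = options.max_entity_cn
    else:
        # a CN-optimal configuration never needs an entity above the largest
        # observed segment CN (its span alone would overshoot everywhere)
        max_cn = int(math.ceil(max(observed_cns, default=1.0))) + 1
    total = sum(observed_cns)
    prog.big_m = max(total, 2 * max(observed_cns, default=0.0)) + 1

    def lenpen(e: Entity) -> float:
        return _W_COUNT + _W_LENGTH * (n - e.length)

    # --- variables -------------------------------------------------------
    root_ub = options.max_root_cn if options.max_root_cn is not None else max_cn
    prog.v_root = lp.var(obj=lenpen(mono(1, n)), lb=1, ub=root_ub)
    for a in range(1, n + 1):
        for b in range(a, n + 1):
            e = mono(a, b)
            if a in heads:
                prog.v_head[(a, b)] = lp.var(obj=lenpen(e), ub=max_cn)
            if b in tails:
                prog.v_tail[(a, b)] = lp.var(obj=lenpen(e), ub=max_cn)
            if a in heads and b in tails:
                prog.v_loop[(a, b)] = lp.var(obj=lenpen(loop(a, b)), ub=max_cn)
    prog.v_eps = [lp.var(obj=_W_RESIDUAL, integer=False) for _ in range(n)]

    # --- segment CN bands (estimated - observed within +-eps) ------------
    for i in range(1, n + 1):
        est: dict[int, float] = {}
        for a in range(1, i + 1):
            for b in range(i, n + 1):
                for j, c in prog.chain_cn_coeffs(a, b).items():
                    est[j] = est.get(j, 0.0) + c
                if (a, b) in prog.v_loop:
                    est[prog.v_loop[(a, b)]] = est.get(prog.v_loop[(a, b)], 0.0) + 2.0
        eps = prog.v_eps[i - 1]
        obs = prog.observed[i - 1]
        lp.row({**est, eps: 1.0}, obs, math.inf)     # est + eps >= obs
        lp.row({**est, eps: -1.0}, -math.inf, obs)   # est - eps <= obs

    # --- fold usage: each detected fold must be realized at least once ----
    if options.enforce_fold_usage:
        for side, idx in sorted({(f.side, f.index) for f in folds}):
            coeffs: dict[int, float] = {}
            if side == HEAD:
                for (a, b), j in prog.v_loop.items():
                    if a == idx:
                        coeffs[j] = 1.0
                for (a, b), j in prog.v_head.items():
                    if a == idx:
                        coeffs[j] = 1.0
            else:
                for (a, b), j in prog.v_loop.items():
                    if b == idx:
                        coeffs[j] = 1.0
                for (a, b), j in prog.v_tail.items():
                    if b == idx:
                        coeffs[j] = 1.0
            if not coeffs:
                raise InfeasibleError(f"no entity can realize the {side} fold at segment {idx}")
            lp.row(coeffs, 1.0, math.inf)

    # --- support indicators + parent existence ---------------------------
    attachable: list[Entity] = []
    for (a, b) in sorted(set(prog.v_head) | set(prog.v_tail)):
        attachable.append(mono(a, b))
    for (a, b) in sorted(prog.v_loop):
        attachable.append(loop(a, b))
    for e in attachable:
        # small cost keeps y tight (y = 1 iff the entity is in the support)
        y = prog.lp.var(ub=1, obj=1.0e-2)
        prog.y_entity[e] = y
        cn = prog.entity_cn_coeffs(e)
        if e.kind == MONO and (e.a, e.b) == (1, n):
            # additional copies of the full-span chain attach to the root
            # baseline copy, which always exists: parent rule satisfied.
            cn = {k: v for k, v in cn.items() if k != prog.v_root}
            lp.row({**cn, y: -prog.big_m}, -math.inf, 0.0)
            continue
        lp.row({**cn, y: -prog.big_m}, -math.inf, 0.0)  # c_e <= M * y_e
        parents: dict[int, float] = {}
        for p in catalog.entities:
            longer = (p.a == e.a or p.b == e.b) and p.length > e.length
            # a loop is also parented by the equal-extent mono-chain
            same_extent = (e.kind == LOOP and p.kind == MONO
                           and (p.a, p.b) == (e.a, e.b))
            if longer or same_extent:
                for j, c in prog.entity_cn_coeffs(p).items():
                    parents[j] = parents.get(j, 0.0) + c
        if parents:
            lp.row({**parents, y: -1.0}, 0.0, math.inf)  # sum parents >= y_e
        else:
            lp.row({y: 1.0}, 0.0, 0.0)  # no possible parent: entity unusable

    # --- optional fold-junction CN bands (pair averages + loops) ----------
    fold_cn: dict[int, float] = {}
    for f in folds:
        if f.observed_cn is not None:
            fold_cn[f.index] = fold_cn.get(f.index, 0.0) + float(f.observed_cn)
    for i, obs_j in sorted(fold_cn.items()):
        xi = lp.var(obj=_W_RESIDUAL, integer=False)
        prog.v_xi[i] = xi
        agg: dict[int, float] = {}
        for e in catalog.L_ii(i):
            for j, c in prog.entity_cn_coeffs(e).items():
                agg[j] = agg.get(j, 0.0) + c
        for hi, lo in catalog.P(i):
            cn_hi = prog.entity_cn_coeffs(hi)
            cn_lo = prog.entity_cn_coeffs(lo)
            if not cn_hi or not cn_lo:
                continue

            def _support_ind(e: Entity) -> int | None:
                if e.kind == MONO and (e.a, e.b) == (1, n):
                    return None  # root: always in support
                return prog.y_entity.get(e)

            y_hi, y_lo = _support_ind(hi), _support_ind(lo)
            z = lp.var(ub=1)
            known = [y for y in (y_hi, y_lo) if y is not None]
            for y in known:
                lp.row({z: 1.0, y: -1.0}, -math.inf, 0.0)  # z <= y
            # z = 1 whenever both chains are in the support (None = root,
            # always supported): z >= sum(y) - (#known - 1)
            lp.row({z: 1.0, **{y: -1.0 for y in known}}, 1 - len(known), math.inf)
            w = lp.var(integer=False)
            half = {j: 0.5 * c for j, c in {**cn_hi}.items()}
            for j, c in cn_lo.items():
                half[j] = half.get(j, 0.0) + 0.5 * c
            lp.row({w: 1.0, **{j: -c for j, c in half.items()}}, -math.inf, 0.0)
            lp.row({w: 1.0, z: -prog.big_m}, -math.inf, 0.0)
            lp.row({w: 1.0, **{j: -c for j, c in half.items()}, z: -prog.big_m},
                   -prog.big_m, math.inf)  # w >= half - M(1-z)
            agg[w] = agg.get(w, 0.0) + 1.0
        lp.row({**agg, xi: 1.0}, obs_j, math.inf)
        lp.row({**agg, xi: -1.0}, -math.inf, obs_j)

    return prog


def add_linkage_constraints(prog: CnProgram, linkage) -> CnProgram:
    """Require that observed oriented adjacencies are realized by the result.

    Fold-type adjacencies must be realized by at least one supported entity;
    reference adjacencies are vacuous (the root realizes them); anything else
    is flagged unsatisfiable and dropped with a warning counter.
    """
    n = prog.catalog.n
    for adj in linkage.adjacencies:
        (i, oi), (j, oj) = adj
        if not (1 <= i <= n and 1 <= j <= n):
            raise InputError(f"linkage adjacency references unknown segment: {adj}")
        if (oi, oj) == (1, 1) and j == i + 1 or (oi, oj) == (-1, -1) and j == i - 1:
            continue  # reference adjacency, satisfied by the root
        coeffs: dict[int, float] = {}
        if i == j and (oi, oj) == (1, -1):  # s_i | s̄_i : tail fold at i
            for (a, b), v in prog.v_loop.items():
                if b == i:
                    coeffs[v] = 1.0
            for (a, b), v in prog.v_tail.items():
                if b == i:
                    coeffs[v] = 1.0
        elif i == j and (oi, oj) == (-1, 1):  # s̄_i | s_i : head fold at i
            for (a, b), v in prog.v_loop.items():
                if a == i:
                    coeffs[v] = 1.0
            for (a, b), v in prog.v_head.items():
                if a == i:
                    coeffs[v] = 1.0
        if coeffs:
            prog.lp.row(coeffs, 1.0, math.inf)
        else:
            prog.unsatisfiable_linkage.append(adj)
    return prog


def solve_configuration(prog: CnProgram) -> CnConfiguration:
    """Solve the assembled program and read back the entity CN configuration."""
    x, _fun, status = prog.lp.solve(prog.options.time_limit)

    def iv(j: int) -> int:
        return int(round(x[j]))

    cfg = CnConfiguration(n=prog.catalog.n, contig=prog.contig, status=status)
    cfg.root_cn = iv(prog.v_root)
    for (a, b) in sorted(set(prog.v_head) | set(prog.v_tail)):
        uh = iv(prog.v_head[(a, b)]) if (a, b) in prog.v_head else 0
        ut = iv(prog.v_tail[(a, b)]) if (a, b) in prog.v_tail else 0
        if uh or ut:
            cfg.chain_sides[(a, b)] = (uh, ut)
    for (a, b), j in sorted(prog.v_loop.items()):
        if iv(j):
            cfg.loop_cns[(a, b)] = iv(j)
    cfg.folds = list(prog.folds)
    cfg.residuals = [float(x[j]) for j in prog.v_eps]
    cfg.junction_residuals = {i: float(x[j]) for i, j in prog.v_xi.items()}
    cfg.objective = sum(cfg.residuals) + sum(cfg.junction_residuals.values())
    cfg.raw_x = x
    return cfg


def exclude_solution(prog: CnProgram, raw_x) -> None:
    """No-good cut: forbid the exact entity CN vector of a prior solution.

    Used when a CN-optimal configuration turns out not to be composable into
    a valid BFB path: the next solve returns the next-best configuration.
    Each entity variable gets deviation indicators (above/below its previous
    value); at least one must deviate.
    """
    lp = prog.lp
    entity_vars = ([prog.v_root] + sorted(prog.v_head.values())
                   + sorted(prog.v_tail.values()) + sorted(prog.v_loop.values()))
    m = prog.big_m + 2
    ds = []
    for v in entity_vars:
        val = float(round(raw_x[v]))
        d_up = lp.var(ub=1)  # 1 -> x >= val + 1
        lp.row({v: 1.0, d_up: -m}, val + 1 - m, math.inf)
        ds.append(d_up)
        if val >= lp.lb[v] + 1:
            d_dn = lp.var(ub=1)  # 1 -> x <= val - 1
            lp.row({v: 1.0, d_dn: m}, -math.inf, val - 1 + m)
            ds.append(d_dn)
    lp.row({d: 1.0 for d in ds}, 1.0, math.inf)


def fit_cn_configuration(
    observed_cns: list[float],
    folds: list[FoldBack],
    options: SolverOptions | None = None,
    contig: str | None = None,
    linkage=None,
) -> CnConfiguration:
    """Convenience wrapper: enumerate, assemble, (link,) solve."""
    catalog = enumerate_entities(len(observed_cns))
    prog = assemble_program(catalog, observed_cns, folds, options, contig)
    if linkage is not None:
        add_linkage_constraints(prog, linkage)
    return solve_configuration(prog)


def joint_solve_subclones(
    profiles: list[list[float]],
    folds_per_clone: list[list[FoldBack]],
    coupling_weight: float = 1.0,
    couple_pairs: list[tuple[int, int]] | None = None,
    options: SolverOptions | None = None,
) -> list[CnConfiguration]:
    """Jointly fit several subclone profiles sharing one layout.

    Each clone gets its own copy of the CN program; the joint objective adds
    ``coupling_weight`` (in residual units) per unit of absolute CN
    difference for each entity between the designated clone pairs, favouring
    shared entities across subclones.
    """
    options = options or SolverOptions()
    if not profiles:
        return []
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise InputError("all subclone profiles must share one layout")
    if len(folds_per_clone) != len(profiles):
        raise InputError("need one fold list per subclone profile")
    if couple_pairs is None:
        couple_pairs = [(u, u + 1) for u in range(len(profiles) - 1)]

    catalog = enumerate_entities(n)
    progs = [
        assemble_program(catalog, prof, fl, options)
        for prof, fl in zip(profiles, folds_per_clone)
    ]
    # merge into one LP with per-clone column offsets
    joint = _Lp()
    offsets: list[int] = []
    for prog in progs:
        off = len(joint.obj)
        offsets.append(off)
        joint.obj.extend(prog.lp.obj)
        joint.lb.extend(prog.lp.lb)
        joint.ub.extend(prog.lp.ub)
        joint.integrality.extend(prog.lp.integrality)
        for coeffs, lo, hi in prog.lp.rows:
            joint.rows.append(({j + off: c for j, c in coeffs.items()}, lo, hi))
    if coupling_weight > 0:
        for u, v in couple_pairs:
            for e in catalog.entities:
                cu = {j + offsets[u]: c for j, c in progs[u].entity_cn_coeffs(e).items()}
                cv = {j + offsets[v]: c for j, c in progs[v].entity_cn_coeffs(e).items()}
                if not cu and not cv:
                    continue
                d = joint.var(obj=coupling_weight * _W_RESIDUAL, integer=False)
                diff = dict(cu)
                for j, c in cv.items():
                    diff[j] = diff.get(j, 0.0) - c
                joint.row({**diff, d: 1.0}, 0.0, math.inf)    # d >= cv - cu
                joint.row({**diff, d: -1.0}, -math.inf, 0.0)  # d >= cu - cv
    x, _fun, status = joint.solve(options.time_limit)

    configs = []
    for prog, off in zip(progs, offsets):
        sub = np.asarray(x[off:off + len(prog.lp.obj)])

        def iv(j: int) -> int:
            return int(round(sub[j]))

        cfg = CnConfiguration(n=n, status=status)
        cfg.root_cn = iv(prog.v_root)
        for (a, b) in sorted(set(prog.v_head) | set(prog.v_tail)):
            uh = iv(prog.v_head[(a, b)]) if (a, b) in prog.v_head else 0
            ut = iv(prog.v_tail[(a, b)]) if (a, b) in prog.v_tail else 0
            if uh or ut:
                cfg.chain_sides[(a, b)] = (uh, ut)
        for (a, b), j in sorted(prog.v_loop.items()):
            if iv(j):
                cfg.loop_cns[(a, b)] = iv(j)
        cfg.folds = list(prog.folds)
        cfg.residuals = [float(sub[j]) for j in prog.v_eps]
        cfg.junction_residuals = {i: float(sub[j]) for i, j in prog.v_xi.items()}
        cfg.objective = sum(cfg.residuals) + sum(cfg.junction_residuals.values())
        configs.append(cfg)
    return configs


def virtual_fold_candidates(observed_cns: list[float], existing: list[FoldBack]) -> list[FoldBack]:
    """Candidate virtual fold-backs at CN steps, largest step first.

    A CN rise entering segment i suggests a head-side fold at i (a loop
    starting there); a CN drop after segment i suggests a tail-side fold at
    i.  Ends already carrying a fold are skipped.
    """
    n = len(observed_cns)
    have = {(f.side, f.index) for f in existing}
    cands: list[tuple[float, FoldBack]] = []
    for i in range(1, n + 1):
        left = observed_cns[i - 2] if i > 1 else None
        right = observed_cns[i] if i < n else None
        cur = observed_cns[i - 1]
        rise = cur - left if left is not None else cur
        drop = cur - right if right is not None else cur
        if rise > 0 and (HEAD, i) not in have:
            cands.append((rise, FoldBack(HEAD, i, virtual=True, source="virtual")))
        if drop > 0 and (TAIL, i) not in have:
            cands.append((drop, FoldBack(TAIL, i, virtual=True, source="virtual")))
    cands.sort(key=lambda t: (-t[0], t[1].index, t[1].side))
    return [f for _step, f in cands]


def augment_virtual_fbis(
    observed_cns: list[float],
    folds: list[FoldBack],
    options: SolverOptions | None = None,
    contig: str | None = None,
) -> tuple[CnConfiguration, list[FoldBack]]:
    """Greedily add virtual fold-backs until the fit stops improving.

    Each added virtual fold costs ``options.virtual_penalty`` residual units;
    a candidate is kept only if it lowers the penalized objective.  Returns
    the best configuration and the virtual folds adopted (also flagged inside
    the configuration's fold list).
    """
    options = options or SolverOptions()

    def try_solve(fold_set: list[FoldBack]) -> CnConfiguration | None:
        try:
            return fit_cn_configuration(observed_cns, fold_set, options, contig)
        except InfeasibleError:
            return None

    base = try_solve(folds)
    best = base
    best_folds = list(folds)
    best_score = math.inf if base is None else base.objective
    adopted: list[FoldBack] = []
    candidates = virtual_fold_candidates(observed_cns, folds)
    for cand in candidates:
        if len(adopted) >= options.virtual_budget:
            break
        trial_folds = best_folds + [cand]
        cfg = try_solve(trial_folds)
        if cfg is None:
            continue
        score = cfg.objective + options.virtual_penalty * (len(adopted) + 1)
        if score < best_score:
            best, best_folds, best_score = cfg, trial_folds, score
            adopted.append(cand)
    if best is None:
        raise InfeasibleError(
            "unresolved: CN program infeasible and virtual fold-back search exhausted"
        )
    return best, adopted
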