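import itertools

import networkx as nx
import pytest

from bfbrecon.dag_paths import (
    BfbPath,
    CompositionError,
    IntraEdit,
    apply_intra_edits,
    build_dag,
    build_virtual_contig,
    compose_path,
    concat_translocations,
    derive_history,
    fwd,
    has_bfb_suffix,
    is_child,
    map_virtual_path,
    rc_path,
    realized_junctions,
    reference_path,
    restore_imperfect_folds,
    rev,
    topological_orders,
)
from bfbrecon.entity_solver import CnConfiguration, FoldBack, loop, mono
from bfbrecon.genome_model import (
    HEAD,
    TAIL,
    Breakpoint,
    InputError,
    Junction,
)
from bfbrecon.simulator import make_layout


def config(n, root=1, chains=None, loops=None, folds=(), contig="chr"):
    return CnConfiguration(
        n=n,
        contig=contig,
        root_cn=root,
        chain_sides=dict(chains or {}),
        loop_cns=dict(loops or {}),
        folds=[FoldBack(s, i) for s, i in folds],
    )


class TestIsChild:
    def test_shared_endpoint_shorter_is_child(self):
        assert is_child(mono(3, 6), mono(1, 6))

    def test_no_shared_endpoint(self):
        assert not is_child(mono(2, 4), mono(1, 6))

    def test_equal_length_not_child(self):
        assert not is_child(mono(1, 6), mono(1, 6))

    def test_kind_agnostic(self):
        assert is_child(loop(2, 3), mono(1, 3))
        assert is_child(mono(3, 3), loop(2, 3))


class TestBuildDag:
    def test_root_plus_loop(self):
        dag = build_dag(config(3, loops={(2, 3): 1}, folds=[(HEAD, 2), (TAIL, 3)]))
        assert set(dag.edges) == {(mono(1, 3), loop(2, 3))}

    def test_single_segment_loop(self):
        dag = build_dag(config(1, loops={(1, 1): 2}, folds=[(HEAD, 1), (TAIL, 1)]))
        assert set(dag.edges) == {(mono(1, 1), loop(1, 1))}

    def test_nested_loops(self):
        cfg = config(3, loops={(2, 3): 1, (3, 3): 1},
                     folds=[(HEAD, 2), (HEAD, 3), (TAIL, 3)])
        dag = build_dag(cfg)
        assert set(dag.edges) == {
            (mono(1, 3), loop(2, 3)),
            (mono(1, 3), loop(3, 3)),
            (loop(2, 3), loop(3, 3)),
        }

    def test_missing_root_rejected(self):
        with pytest.raises(InputError):
            build_dag(CnConfiguration(n=3, root_cn=0))


class TestTopologicalOrders:
    def test_chain_dag_single_order(self):
        dag = build_dag(config(3, loops={(2, 3): 1}, folds=[(HEAD, 2), (TAIL, 3)]))
        orders = list(topological_orders(dag, limit=10))
        assert len(orders) == 1

    def test_incomparable_equal_loops_two_orders(self):
        cfg = config(4, loops={(1, 2): 1, (3, 4): 1},
                     folds=[(HEAD, 1), (TAIL, 2), (HEAD, 3), (TAIL, 4)])
        dag = build_dag(cfg)
        orders = list(topological_orders(dag, limit=10))
        # brute-force linear extension count
        expected = sum(
            1
            for perm in itertools.permutations(dag.nodes)
            if all(perm.index(u) < perm.index(v) for u, v in dag.edges)
        )
        assert len(orders) == expected == 2

    def test_limit_one_yields_canonical(self):
        cfg = config(4, loops={(1, 2): 1, (3, 4): 1},
                     folds=[(HEAD, 1), (TAIL, 2), (HEAD, 3), (TAIL, 4)])
        dag = build_dag(cfg)
        (order,) = topological_orders(dag, limit=1)
        assert order[0] == mono(1, 4)
        lengths = [e.length for e in order]
        assert lengths == sorted(lengths, reverse=True)


class TestComposePath:
    def test_root_plus_loop_canonical_path(self):
        cfg = config(3, loops={(2, 3): 1}, folds=[(HEAD, 2), (TAIL, 3)])
        bfb = compose_path(cfg)
        assert bfb.segments == [
            fwd("chr", 1), fwd("chr", 2), fwd("chr", 3),
            rev("chr", 3), rev("chr", 2), fwd("chr", 2), fwd("chr", 3),
        ]

    def test_single_segment_double_loop(self):
        cfg = config(1, loops={(1, 1): 2}, folds=[(HEAD, 1), (TAIL, 1)])
        bfb = compose_path(cfg)
        assert bfb.segments == [
            fwd("chr", 1), rev("chr", 1), fwd("chr", 1), rev("chr", 1), fwd("chr", 1)
        ]

    def test_root_alone_is_reference(self):
        bfb = compose_path(config(4))
        assert bfb.segments == list(reference_path("chr", 4))

    def test_segment_multiplicities_match_aggregates(self):
        cfg = config(3, chains={(2, 3): (0, 1)}, loops={(2, 3): 1},
                     folds=[(HEAD, 2), (TAIL, 3)])
        bfb = compose_path(cfg)
        counts = bfb.multiplicities()
        assert [counts[("chr", i)] for i in (1, 2, 3)] == cfg.estimated_segment_cns()

    def test_suffix_invariant_on_result(self):
        cfg = config(3, loops={(2, 3): 1}, folds=[(HEAD, 2), (TAIL, 3)])
        assert has_bfb_suffix(compose_path(cfg).segments)

    def test_unrealizable_fold_set_fails(self):
        # head-only fold at 1 on a single segment cannot be composed
        cfg = config(1, chains={(1, 1): (1, 0)}, folds=[(HEAD, 1)])
        with pytest.raises(CompositionError):
            compose_path(cfg)


class TestRestoreImperfectFolds:
    def test_tail_fold_revision_drops_return_arm(self):
        # ...H4 H5 | -H5 -H4 -H3... with imperfect (5, 3̄): drop -H5 -H4
        path = [fwd("c", i) for i in (1, 2, 3, 4, 5)] + [rev("c", i) for i in (5, 4, 3)]
        bfb = BfbPath(segments=path)
        out = restore_imperfect_folds(bfb, [FoldBack(TAIL, 5, far_index=3)])
        assert out.segments == [fwd("c", i) for i in (1, 2, 3, 4, 5)] + [rev("c", 3)]

    def test_head_fold_revision(self):
        # ...-H4 -H3 -H2 H2...  with imperfect (2 <- 4): drop -H3 -H2
        path = ([fwd("c", i) for i in (1, 2, 3, 4)]
                + [rev("c", i) for i in (4, 3, 2)] + [fwd("c", 2)])
        out = restore_imperfect_folds(BfbPath(segments=path),
                                      [FoldBack(HEAD, 2, far_index=4)])
        assert out.segments == [fwd("c", i) for i in (1, 2, 3, 4)] + [rev("c", 4), fwd("c", 2)]

    def test_empty_map_is_identity(self):
        path = [fwd("c", 1), rev("c", 1)]
        assert restore_imperfect_folds(BfbPath(segments=list(path)), []).segments == path

    def test_missing_adjacency_rejected(self):
        with pytest.raises(CompositionError):
            restore_imperfect_folds(
                BfbPath(segments=list(reference_path("c", 3))),
                [FoldBack(TAIL, 3, far_index=1)],
            )


class TestIntraEdits:
    def test_deletion_removes_spanned_run(self):
        bfb = BfbPath(segments=list(reference_path("c", 3)))
        out = apply_intra_edits(bfb, [IntraEdit("del", contig="c", lo=1, hi=3)])
        assert out.segments == [fwd("c", 1), fwd("c", 3)]

    def test_duplication_repeats_run(self):
        bfb = BfbPath(segments=list(reference_path("c", 3)))
        out = apply_intra_edits(bfb, [IntraEdit("dup", contig="c", lo=2, hi=3)])
        assert out.segments == [fwd("c", 1), fwd("c", 2), fwd("c", 3),
                                fwd("c", 2), fwd("c", 3)]

    def test_insertion_splices_donor(self):
        path = [fwd("c", 4), rev("c", 4), fwd("c", 2)]
        donor = [fwd("d", 1), fwd("d", 2)]
        out = apply_intra_edits(
            BfbPath(segments=list(path)),
            [IntraEdit("ins", donor=donor, after=rev("c", 4), before=fwd("c", 2))],
        )
        assert out.segments == [fwd("c", 4), rev("c", 4)] + donor + [fwd("c", 2)]

    def test_edit_crossing_fold_rejected(self):
        # deletion span interrupted by a fold: no contiguous forward run
        path = [fwd("c", 1), fwd("c", 2), rev("c", 2), fwd("c", 2), fwd("c", 3)]
        with pytest.raises(CompositionError):
            apply_intra_edits(
                BfbPath(segments=path), [IntraEdit("del", contig="c", lo=1, hi=3)]
            )


class TestConcatTranslocations:
    def _paths(self):
        a = BfbPath(segments=[fwd("A", 1), fwd("A", 2)])
        b = BfbPath(segments=[fwd("B", 1), fwd("B", 2)])
        return a, b

    def _junction(self, jtype, bp1, bp2, segs):
        jn = Junction(bp1, bp2, jtype=jtype)
        jn.seg_a, jn.seg_b = segs
        return jn

    def test_tail_head_appends_forward_block(self):
        a, b = self._paths()
        jn = Junction(Breakpoint("A", 200, TAIL), Breakpoint("B", 0, HEAD),
                      jtype="TRX-th", seg_a=2, seg_b=1)
        out = concat_translocations([a, b], [jn])
        assert out.segments == [fwd("A", 1), fwd("A", 2), fwd("B", 1), fwd("B", 2)]

    def test_tail_tail_reverse_complements_second_block(self):
        a, b = self._paths()
        jn = Junction(Breakpoint("A", 200, TAIL), Breakpoint("B", 200, TAIL),
                      jtype="TRX-tt", seg_a=2, seg_b=2)
        out = concat_translocations([a, b], [jn])
        assert out.segments == [fwd("A", 1), fwd("A", 2), rev("B", 2), rev("B", 1)]

    def test_three_contigs_chained(self):
        a, b = self._paths()
        c = BfbPath(segments=[fwd("C", 1)])
        j1 = Junction(Breakpoint("A", 200, TAIL), Breakpoint("B", 0, HEAD),
                      jtype="TRX-th", seg_a=2, seg_b=1)
        j2 = Junction(Breakpoint("B", 200, TAIL), Breakpoint("C", 0, HEAD),
                      jtype="TRX-th", seg_a=2, seg_b=1)
        out = concat_translocations([a, b, c], [j1, j2])
        assert out.segments == [fwd("A", 1), fwd("A", 2), fwd("B", 1), fwd("B", 2), fwd("C", 1)]
        # every input path is a contiguous block of the result
        text = " ".join(map(str, out.segments))
        for block in (a, b, c):
            assert " ".join(map(str, block.segments)) in text

    def test_interior_endpoints_fail_with_hint(self):
        a, b = self._paths()
        jn = Junction(Breakpoint("A", 100, TAIL), Breakpoint("B", 100, TAIL),
                      jtype="TRX-tt", seg_a=1, seg_b=1)
        with pytest.raises(CompositionError, match="TRX-to-BFB"):
            concat_translocations([a, b], [jn])


class TestVirtualContig:
    def test_host_virus_chain_splice(self):
        host = make_layout("H", 5)
        virus = make_layout("V", 3, segment_bp=1000, origin="virus")
        jn = Junction(Breakpoint("H", host.segments[1].end, TAIL),
                      Breakpoint("V", 0, HEAD), jtype="VIT", seg_a=2, seg_b=1)
        fused, prov = build_virtual_contig({"H": host, "V": virus}, [jn])
        assert prov == [("H", 1, True), ("H", 2, True),
                        ("V", 1, True), ("V", 2, True), ("V", 3, True)]
        assert fused.n == 5

    def test_single_layout_identity(self):
        host = make_layout("H", 3)
        fused, prov = build_virtual_contig({"H": host}, [])
        assert fused is host and prov == [("H", 1, True), ("H", 2, True), ("H", 3, True)]

    def test_tail_tail_junction_flips_joined_block(self):
        host = make_layout("H", 2)
        virus = make_layout("V", 2, segment_bp=1000, origin="virus")
        jn = Junction(Breakpoint("H", host.end, TAIL),
                      Breakpoint("V", virus.end, TAIL), jtype="VIT", seg_a=2, seg_b=2)
        fused, prov = build_virtual_contig({"H": host, "V": virus}, [jn])
        assert prov == [("H", 1, True), ("H", 2, True), ("V", 2, False), ("V", 1, False)]

    def test_mapping_path_back_to_sources(self):
        host = make_layout("H", 2)
        virus = make_layout("V", 2, segment_bp=1000, origin="virus")
        jn = Junction(Breakpoint("H", host.end, TAIL), Breakpoint("V", 0, HEAD),
                      jtype="VIT", seg_a=2, seg_b=1)
        fused, prov = build_virtual_contig({"H": host, "V": virus}, [jn])
        bfb = BfbPath(segments=[fwd(fused.contig, i) for i in (1, 2, 3, 4)])
        out = map_virtual_path(bfb, prov)
        assert out.segments == [fwd("H", 1), fwd("H", 2), fwd("V", 1), fwd("V", 2)]


class TestDeriveHistory:
    def test_forward_reverse_forward_two_cycles(self):
        core = [fwd("c", 1), rev("c", 1), fwd("c", 1)]
        assert derive_history(core, n_reference=1)[0] == 2

    def test_alternating_five_fragments_three_cycles(self):
        core = [fwd("c", 1), rev("c", 1), fwd("c", 1), rev("c", 1), fwd("c", 1)]
        assert derive_history(core, n_reference=1)[0] == 3

    def test_reference_path_zero_cycles(self):
        assert derive_history(list(reference_path("c", 5)), n_reference=5)[0] == 0

    def test_loop_insertion_two_cycles(self):
        path = [fwd("c", 1), fwd("c", 2), fwd("c", 3),
                rev("c", 3), rev("c", 2), fwd("c", 2), fwd("c", 3)]
        cycles, events, exact = derive_history(path, n_reference=3)
        assert cycles == 2 and exact

    def test_non_bfb_path_rejected(self):
        bad = [fwd("c", 1), fwd("c", 3)]  # skips segment 2: no peel exists
        with pytest.raises(CompositionError):
            derive_history(bad, n_reference=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_minimality_matches_forward_enumeration(self, seed):
        """BFS peeling equals exhaustive forward search on tiny paths."""
        import numpy as np

        from bfbrecon.simulator import simulate_history

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        k = int(rng.integers(0, 4))
        truth = simulate_history(n, k, rng)
        if len(truth.segments) > 10:
            return
        cycles, _, exact = derive_history(truth.segments, n_reference=n)
        assert exact and cycles <= k
        # forward oracle: breadth-first over fusion/cut choices
        start = reference_path("c", n)
        target = tuple(
            type(start[0])("c", s.index, s.forward) for s in truth.segments
        )
        frontier, depth = {start}, 0
        found = 0 if start == target else None
        while found is None and depth < 6:
            depth += 1
            nxt = set()
            for p in frontier:
                fused = p + rc_path(p)
                for keep in range(len(p) + 1, len(fused) + 1):
                    if len(fused[:keep]) <= 10:
                        nxt.add(fused[:keep])
            if target in nxt:
                found = depth
            frontier = nxt
        assert found == cycles


class TestRealizedJunctions:
    def test_fold_and_reference_adjacencies(self):
        lay = {"c": make_layout("c", 3)}
        path = [fwd("c", 1), fwd("c", 2), fwd("c", 3),
                rev("c", 3), rev("c", 2), fwd("c", 2), fwd("c", 3)]
        jns = realized_junctions(path, lay)
        assert [j.jtype for j in jns] == ["FBI-tt", "FBI-hh"]

    def test_deletion_junction(self):
        lay = {"c": make_layout("c", 3)}
        jns = realized_junctions([fwd("c", 1), fwd("c", 3)], lay)
        assert [j.jtype for j in jns] == ["DEL-ht"]

    def test_virus_junction(self):
        lays = {"c": make_layout("c", 2), "v": make_layout("v", 1, origin="virus")}
        jns = realized_junctions([fwd("c", 1), fwd("v", 1)], lays, virus_contigs={"v"})
        assert [j.jtype for j in jns] == ["VIT"]
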