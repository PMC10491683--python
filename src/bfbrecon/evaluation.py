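"""Benchmark metrics and the exhaustive fusion-breakage oracle.

CN accuracy is the fraction of segments whose inferred copy number matches
the truth exactly; total CN error sums the absolute per-segment
differences.  SV agreement uses precision/recall/F1 over canonicalized
junctions (type match plus both breakpoints within a tolerance; distinct
junctions by default, multiset mode optional).  The oracle enumerates every
fusion-breakage history on tiny instances and is used as an independent
check of the ILP + composition route.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .dag_paths import Path, fold_at, rc_path, reference_path
from .genome_model import InputError, Junction

DEFAULT_BP_TOLERANCE = 50

#: guard rails for the exhaustive oracle (combinatorial blow-up beyond)
ORACLE_MAX_SEGMENTS = 5
ORACLE_MAX_TOTAL_CN = 14


@dataclass
class EvaluationReport:
    cn_accuracy: float
    total_cn_error: int
    sv_precision: float
    sv_recall: float
    sv_f1: float
    fbi_recall: float
    cycle_count: int | None = None
    resolved: bool = False
    virtual_used: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cn_accuracy(pred: list[float], truth: list[float]) -> float:
    """Fraction of segments with correctly inferred (integer) CN."""
    if len(pred) != len(truth):
        raise InputError("segment count mismatch between prediction and truth")
    if not truth:
        raise InputError("empty CN vectors")
    hits = sum(1 for p, t in zip(pred, truth) if round(p) == round(t))
    return hits / len(truth)


def total_cn_error(pred: list[float], truth: list[float]) -> int:
    """Sum of absolute per-segment CN differences."""
    if len(pred) != len(truth):
        raise InputError("segment count mismatch between prediction and truth")
    return int(sum(abs(round(p) - round(t)) for p, t in zip(pred, truth)))


def _junction_key(jn: Junction) -> tuple:
    return jn.key()


def _match(a: Junction, b: Junction, tol: int) -> bool:
    if a.jtype != b.jtype:
        return False
    return (
        a.bp_a.contig == b.bp_a.contig
        and a.bp_b.contig == b.bp_b.contig
        and abs(a.bp_a.pos - b.bp_a.pos) <= tol
        and abs(a.bp_b.pos - b.bp_b.pos) <= tol
        and a.bp_a.end == b.bp_a.end
        and a.bp_b.end == b.bp_b.end
    )


def sv_metrics(
    pred: list[Junction],
    truth: list[Junction],
    tolerance: int = DEFAULT_BP_TOLERANCE,
    multiset: bool = False,
) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted junctions against the truth.

    By default junction lists are deduplicated (a junction used several
    times counts once); ``multiset=True`` requires matching multiplicities.
    Empty truth with empty prediction scores (1, 1, 1) by convention.
    """
    if not multiset:
        pred = _dedup(pred)
        truth = _dedup(truth)
    if not truth and not pred:
        return (1.0, 1.0, 1.0)
    remaining = list(truth)
    tp = 0
    for p in pred:
        for t in remaining:
            if _match(p, t, tolerance):
                remaining.remove(t)
                tp += 1
                break
    fp = len(pred) - tp
    fn = len(remaining)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1


def _dedup(junctions: list[Junction]) -> list[Junction]:
    seen: set[tuple] = set()
    out = []
    for jn in junctions:
        if jn.key() not in seen:
            seen.add(jn.key())
            out.append(jn)
    return out


def fbi_recall(pred: list[Junction], truth: list[Junction],
               tolerance: int = DEFAULT_BP_TOLERANCE) -> float:
    """Recall restricted to fold-back inversions (the real-data 'resolved'
    criterion: the inferred path includes all ground-truth FBIs)."""
    truth_fbi = [j for j in _dedup(truth) if j.is_fbi]
    pred_fbi = [j for j in _dedup(pred) if j.is_fbi]
    if not truth_fbi:
        return 1.0
    _, recall, _ = sv_metrics(pred_fbi, truth_fbi, tolerance)
    return recall


def evaluate(
    pred_cns: list[float],
    truth_cns: list[float],
    pred_junctions: list[Junction],
    truth_junctions: list[Junction],
    cycle_count: int | None = None,
    virtual_used: bool = False,
    mode: str = "simulation",
    tolerance: int = DEFAULT_BP_TOLERANCE,
) -> EvaluationReport:
    """Full report; 'resolved' follows the simulation criterion (all CNs and
    SVs exact) or, with mode='real', FBI recall = 1."""
    acc = cn_accuracy(pred_cns, truth_cns)
    err = total_cn_error(pred_cns, truth_cns)
    precision, recall, f1 = sv_metrics(pred_junctions, truth_junctions, tolerance)
    fbi = fbi_recall(pred_junctions, truth_junctions, tolerance)
    if mode == "real":
        resolved = fbi == 1.0
    else:
        resolved = acc == 1.0 and precision == 1.0 and recall == 1.0
    return EvaluationReport(
        cn_accuracy=acc,
        total_cn_error=err,
        sv_precision=precision,
        sv_recall=recall,
        sv_f1=f1,
        fbi_recall=fbi,
        cycle_count=cycle_count,
        resolved=resolved,
        virtual_used=virtual_used,
    )


# --------------------------------------------------------------------------
# exhaustive fusion-breakage oracle
# --------------------------------------------------------------------------

def _path_signature(path: Path, n: int) -> tuple[tuple[int, ...], frozenset]:
    counts = Counter(s.index for s in path)
    cn = tuple(counts.get(i, 0) for i in range(1, n + 1))
    folds = frozenset(
        f for f in (fold_at(x, y) for x, y in zip(path, path[1:])) if f is not None
    )
    return cn, folds


def enumerate_bfb_signatures(
    n: int,
    max_total_cn: int,
    max_cycles: int = 12,
) -> set[tuple[tuple[int, ...], frozenset, int]]:
    """All (CN vector, typed fold set, cycle count) reachable by the
    fusion-breakage process.  Breakage lands on the appended
    reverse-complement copy (the derivation's cut point ranges over the
    appended arm), so each cycle keeps the whole previous path plus at least
    one appended segment; cuts may still span several appended arms."""
    start = reference_path("chr", n)
    frontier = {start}
    seen = {start}
    signatures: set[tuple[tuple[int, ...], frozenset, int]] = set()
    cn, folds = _path_signature(start, n)
    signatures.add((cn, folds, 0))
    for cycle in range(1, max_cycles + 1):
        nxt = set()
        for path in frontier:
            fused = tuple(path) + rc_path(path)
            for keep in range(len(path) + 1, len(fused) + 1):
                cand = fused[:keep]
                if len(cand) > max_total_cn:
                    continue
                if cand in seen:
                    continue
                seen.add(cand)
                nxt.add(cand)
                cn, folds = _path_signature(cand, n)
                signatures.add((cn, folds, cycle))
        if not nxt:
            break
        frontier = nxt
    return signatures


def bfb_realizability_oracle(
    cn_vector: list[int],
    fold_set,
    max_cycles: int = 12,
) -> tuple[bool, int | None]:
    """Exhaustively decide whether a CN vector (and optional typed fold set
    {(side, index), ...}) is realized by some fusion-breakage path, and the
    minimal cycle count if so.  Guard rails: n <= 5 and total CN <= 14."""
    n = len(cn_vector)
    total = int(sum(cn_vector))
    if n > ORACLE_MAX_SEGMENTS or total > ORACLE_MAX_TOTAL_CN:
        raise InputError(
            f"oracle guard rails exceeded (n <= {ORACLE_MAX_SEGMENTS}, "
            f"total CN <= {ORACLE_MAX_TOTAL_CN})"
        )
    want_cn = tuple(int(c) for c in cn_vector)
    want_folds = None if fold_set is None else frozenset(fold_set)
    best: int | None = None
    for cn, folds, cycles in enumerate_bfb_signatures(n, total, max_cycles):
        if cn != want_cn:
            continue
        if want_folds is not None and folds != want_folds:
            continue
        best = cycles if best is None else min(best, cycles)
    return best is not None, best
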