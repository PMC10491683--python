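# bfbrecon

Reconstruction of complex **breakage-fusion-bridge (BFB)** rearrangements:
given the segment copy-number profile and the structural-variant junctions
around a candidate focal amplification, `bfbrecon` reconstructs the *local
genomic map* — the ordered, oriented sequence of reference segments the
rearranged locus is built from — together with a minimal fusion-breakage
cycle history.

BFB is a mutational process in cancer (and occasionally in germline and
evolutionary genomics): a chromosome lacking a telomere fuses with its
replicated sister, the dicentric bridge breaks at anaphase, and the cycle
repeats.  Each cycle leaves a **fold-back inversion (FBI)** — a junction
joining a segment to its own reverse complement — and drives stair-like
copy-number amplification.  Real events are rarely textbook-perfect: they
involve imperfect fold-backs (with DNA lost at the breakpoint),
deletions, duplications, insertions, translocations across chromosomes, and
oncovirus integration.  `bfbrecon` models all of these.

## The model

The reference locus is an ordered segment run `s_1 … s_n`.  Any BFB path is
built from two kinds of **entities**:

* a *mono-chain* `m(a,b) = s_a … s_b` (or its reverse complement),
* a *loop* `l(a,b) = s_a … s_b | s̄_b … s̄_a`, realizing a head-side fold at
  `a` and a tail-side fold at `b`.

A chain copy contributes 1 to the copy number of every segment it spans, a
loop copy 2.  Entity copy numbers `c_e(a,b)` are fit to the observed
segment CNs `c(s_i)` by an exact integer linear program

```
min Σ_i ε_i + Σ_i ξ_i
s.t.  -ε_i ≤ ( Σ_{m ∋ s_i} c_m + 2 Σ_{l ∋ s_i} c_l ) - c(s_i) ≤ ε_i
      every non-root entity has a parent (shared endpoint, longer) in the result
      every detected fold-back is realized by at least one entity
      c_m(1,n) ≥ 1,  all c_e integer ≥ 0
```

(with analogous `ξ` bands over fold-junction CNs when the caller provides
them, and optional read-linkage and multi-subclone coupling constraints).
The positive-CN entities form a DAG (edges parent → child); walking a
topological order, each entity is spliced into the growing path so that a
**palindromic suffix** is preserved after every insertion — the defining
invariant of BFB paths.  Post-processing revises imperfect fold-backs,
applies deletion/duplication/insertion edits, concatenates per-chromosome
paths across translocations (BFB-to-TRX) or fuses chromosomes into a
virtual contig before solving (TRX-to-BFB, used for virus integration), and
finally recovers a minimal cycle history by breadth-first *peeling*
(undoing `P = Z | rc(suffix of Z)` one cycle at a time).

A fusion-breakage **simulator** generates ground-truth paths and noisy
observables (CN jitter, junction dropout, linkage windows), and the
**evaluation** module implements CN accuracy, total CN error, SV
precision/recall/F1, FBI recall, and an exhaustive realizability oracle for
tiny instances.

## Worked example

```python
import numpy as np
from bfbrecon import simulate_history, derive_observables, resolve_event
from bfbrecon import evaluate_against_truth
from bfbrecon.simulator import make_layout

rng = np.random.default_rng(1)
truth = simulate_history(5, 3, rng, contig="chr")      # 3 BFB cycles, 5 segments
layouts = {"chr": make_layout("chr", 5)}
profile, junctions, _ = derive_observables(truth, layouts)

layouts = {"chr": layouts["chr"].with_cns(profile["chr"])}
result = resolve_event(layouts, junctions)
print(truth.render())
print(result.path.render())
print(result.cycle_counts, evaluate_against_truth(result, layouts, profile, junctions).to_dict())
```

prints

```
H1 H2 H3 H4 H5 -H5 -H4 -H3 H3 H4 -H4 -H3
H1 H2 H3 H4 H5 -H5 -H4 -H3 H3 H4 -H4 -H3
{'chr': 3} {'cn_accuracy': 1.0, 'total_cn_error': 0, 'sv_precision': 1.0,
 'sv_recall': 1.0, 'sv_f1': 1.0, 'fbi_recall': 1.0, 'cycle_count': 3,
 'resolved': True, 'virtual_used': False}
```

The reconstructed map equals the simulated truth: `-H3` denotes the reverse
complement of segment 3, the two `H3|-H3`/`-H3|H3` adjacencies are the
fold-back inversions of the second and third cycles, and `resolved` means
every segment CN and every junction of the truth is reproduced exactly.

## Command line

```
bfbrecon simulate --template virus --seed 3 --out sim/   # six benchmark archetypes
bfbrecon group    --sv sim/junctions.vcf                 # cluster SVs, pick BFB candidates
bfbrecon solve    --sv sim/junctions.vcf --cn sim/segments.tsv --out solved.json
bfbrecon evaluate --pred solved.json --truth sim/truth.json
```

`solve` accepts SVs as VCF breakends (BND bracket notation) or symbolic
DEL/DUP records, segment CNs (or depths plus purity/ploidy) as a TSV
tiling, and optional linked/long-read adjacency evidence; it exits 0 with a
path JSON on success and 3 with a structured reason when the event cannot
be resolved.

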