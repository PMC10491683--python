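# Methods

## Model

A candidate breakage-fusion-bridge (BFB) event lives on a local genome
window that the SV breakpoints partition into a gap-free, ordered run of
segments `s_1 … s_n` (the reference path).  The generative process starts
from the reference path and iterates cycles of *fusion* (the path is
concatenated with its own reverse complement) and *breakage* (a suffix of
the appended copy is cut off).  Every cycle therefore leaves a fold-back
adjacency — `s_i | s̄_i` (tail-side, FBI-tt) when the path ended forward at
`s_i`, or `s̄_i | s_i` (head-side, FBI-hh) when it ended reversed — and the
resulting path always carries an even-length *palindromic suffix* (a suffix
equal to its own reverse complement).  We treat that invariant as the
definition of BFB-consistency: a candidate map is accepted only if it can
be peeled back to the reference by undoing `P = Z | rc(suffix of Z)` moves.

### Entities and the copy-number fit

Any BFB path decomposes into *entities*: mono-chains `m(a,b)` (consecutive
segments, either orientation) and loops `l(a,b)` (a chain concatenated with
its reverse complement).  A chain copy adds 1 to the copy number (CN) of
each spanned segment, a loop copy 2; a loop realizes a head-side fold at
`a` and a tail-side fold at `b`, while a non-root chain attaches to the
growing path through a fold at one of its endpoints.  Fitting integer
entity CNs to the observed (real-valued) segment CNs is an exact MILP
(HiGHS via `scipy.optimize.milp`, zero MIP gap):

* **Disparity bands** per segment bound `|estimated − observed|` by a
  residual `ε_i`; the objective minimizes `Σ ε_i` (plus `Σ ξ_i` over
  fold-junction CN bands when the caller supplies junction CNs — most SV
  callers do not, so those bands are off by default; the pair-average terms
  of the junction bands are gated on entity-support indicators so zero-CN
  chains cannot contribute).
* **Root constraint**: the full chain `m(1,n)` has CN ≥ 1.  CN above 1
  represents additional unrearranged alleles unless fold-attached.
* **Parent existence**: every used entity must have a parent (an entity
  sharing an endpoint with strictly greater span; a loop is additionally
  the child of the equal-extent chain) in the result, so the support always
  forms a connected DAG rooted at `m(1,n)`.
* **Typed fold usage**: each detected fold-back must be realized by at
  least one used entity of the matching side, and entities may only place
  folds at detected (or virtual) fold ends.  The head/tail typing is our
  refinement of the single-index junction notation: without it, a
  reconstruction could satisfy the CN pattern while flipping a detected
  tail-side fold into a head-side one at a different genomic position.

Secondary objective layers (weights 10⁶ : 10² : small) implement Occam's
razor: among zero-residual fits, prefer fewer entity copies, then longer
entities, then deterministic HiGHS tie-breaking.  Imperfect fold-backs
`(s_i, s̄_j)` are canonicalized to the retained-arm index (lower for
head-side, higher for tail-side) before solving, and the observed CNs are
pre-adjusted by the copies the later revision will drop, so a noise-free
imperfect instance still fits at zero residual.  The same pre-adjustment
applies to deletion/duplication edits, which the MILP does not model.

### Composition and the solve–compose loop

Entities are spliced into the path one copy at a time, longest first (a
topological order of the entity DAG).  A loop is inserted after an
occurrence of `s_b` in reverse-then-forward form (or mirrored after `s̄_a`),
a chain attaches through the fold at its labelled endpoint; rightmost valid
positions are preferred and every insertion must keep the path either a
plain reference run or palindromic-suffixed.  Equal-length entities,
attachment sides and positions are searched depth-first with backtracking
(bounded at 2·10⁵ nodes); a finished arrangement is accepted only if it
realizes every detected fold and peels back to the reference.

A CN-optimal configuration is not always realizable as a path (the counts
can be right while no palindromic arrangement exists).  When composition
fails, the exact solution is excluded from the MILP with a no-good cut
(deviation indicators per entity variable) and the program re-solved — up
to 12 configurations by default.  If no composable configuration explains
the CNs, the *virtual fold-back* search begins: candidate folds sit at CN
steps (a rise entering `s_i` suggests a head-side fold at `i`, a drop after
it a tail-side fold), are tried largest step first, cost 2 residual units
each (budget 3), and are kept only while the penalized objective improves.
Adopted virtual folds are flagged in the output.

### Complex events

* **Imperfect fold-backs** are composed as perfect and then revised:
  `s_i | s̄_i` becomes `s_i | s̄_j` by dropping the return-arm segments
  between them (one adjacency per detected junction by default, leftmost).
* **Deletions / duplications / insertions** are stage-2 edits applied to
  the composed path at reference-contiguous runs (an edit spanning a fold
  is rejected); insertions are recognized from pairs of inter-contig
  junctions that flank a contiguous donor block on a contig without folds
  of its own.
* **Translocations** default to BFB-to-TRX: each chromosome's path is
  reconstructed independently and the paths are concatenated along the
  junction chain, reverse-complementing blocks as the end combination
  requires; each input path remains a contiguous block of the result.
* **Virus integration** forces TRX-to-BFB: the host and viral contigs are
  fused into a virtual contig along the integration junctions first, BFB
  is solved on the fusion, and the result is mapped back to source
  coordinates.  (Purely donor-style integrations — a viral block inserted
  into an ongoing host BFB — are handled as insertions instead.)

### History derivation

The minimal number of fusion-breakage cycles is found by breadth-first
search over peel moves, exact for paths of ≤ 64 oriented segments (all
realistic events are far below this; beyond it a greedy longest-peel
fallback is flagged approximate).  A terminal state that is a proper prefix
of the reference costs one additional truncation cycle.  Cycle counts are
reported per chromosome for the stage-1 (pre-edit) cores.

## Simulator

`simulate_history` runs the generative process directly; the kept length of
the appended copy is drawn uniformly from 1 to the previous arm length, so
every simulated cycle leaves an observable fold (a cycle whose entire
contribution is later excised is unobservable in principle and is not
generated).  On top of the core path the simulator overlays the six
benchmark archetypes (perfect, imperfect folds, insertion, translocation,
duplication+insertion, virus integration), minor duplications (probability
0.30, 1–2 segments — "minor" made concrete), and the observation model:
segment CNs are path multiplicities with optional rounded Gaussian jitter,
junctions drop out independently at a configurable rate (emulating low
depth/purity), and linkage evidence is emitted as oriented adjacencies
from sliding windows over the truth path (emulating linked/long reads).
Batch simulation rejects instances outside the configured manifest ranges
(segments 6–15, FBIs 2–7, total CN 13–105, largest CN 3–11 by default) and
is bit-reproducible under its seed.

What passing the synthetic suite does **not** show: the simulator emits
junctions at exact segment boundaries with perfect typing, does not model
read-level noise, mapping artifacts, caller-specific breakpoint jitter
beyond the snap tolerance, subclonal mixtures at the read level, or
germline CN background — resolution rates on real tumor data will be lower
and depend on the upstream caller.

## Parameter defaults

| parameter | default | meaning |
| --- | --- | --- |
| `max_gap` | 1 Mb | BFS clustering distance for SV grouping |
| `min_fbi` | 2 | fold-backs required for a BFB candidate ("more than one") |
| `max_span` | 10 Mb | candidate window cap; larger groups are flagged |
| `min_support` | 1 | supporting-read filter on input junctions |
| snap tolerance | 50 bp | breakpoint-to-boundary snapping |
| junction match tolerance | 50 bp | evaluation breakpoint matching |
| purity ρ, ploidies P_t / P_n | 1 / 2 / 2 | depth→CN conversion `C = D (ρP_t + (1−ρ)P_n) / D_g` |
| virtual penalty / budget | 2 residual units / 3 folds | virtual fold-back search |
| solver time limit | 60 s | per MILP; incumbents past it are flagged |
| subclone coupling weight | 1 residual unit per CN difference | joint subclone fit |

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based at the VCF
  boundary; the BND bracket table follows VCF 4.2 §5.4; INV records are
  promoted to a fold-back only when their span is ≤ 1 kb.
* Entity variables are bounded above by ⌈max observed CN⌉ + 1 (a larger
  copy number would overshoot every spanned segment), which keeps the MILP
  tight; big-M for indicator rows is `max(total CN, 2·max CN) + 1`.
* The canonical topological order sorts by length descending, start index
  ascending, chains before loops; the composed map is deterministic for a
  given input, and the CLI output is byte-identical across runs.
* Evaluation counts distinct junctions by default (multiset matching is an
  option); solver-vs-oracle equivalence uses distinct typed fold sets.
* Degenerate inputs: empty junction lists are an input error for `solve`;
  an empty truth with empty prediction scores precision = recall = 1 by
  convention; breakpoints within the snap tolerance of a window edge do not
  create sliver segments.

## Problem sizes used by the consistency batteries

Round-trip resolution runs 200 seeded instances at n ≤ 8, cycles ≤ 6.  The
solver-vs-oracle agreement uses the full two-sided cross of CN vectors ×
typed fold sets at n ≤ 3, total CN ≤ 6 (1544 points) plus the one-sided
check (every oracle-feasible signature must solve at zero residual) at
n ≤ 4, total CN ≤ 12 (253 signatures); the exhaustive oracle itself is
guard-railed at n ≤ 5, total CN ≤ 14.  History-minimality cross-checks run
on paths of ≤ 10 oriented segments against exhaustive forward enumeration.

## Known limitations

* The entity model assumes one rearranged allele plus optional intact
  copies; allele-specific (phased) reconstruction is out of scope.
* Fold-junction CN bands implement the pair-average formula literally;
  with three or more chains sharing an endpoint the formula counts every
  pair, which can overstate the estimated junction CN relative to the
  realized adjacencies.
* Enumerating *all* BFB trees of the DAG is not attempted; composition
  follows topological orders (with backtracking), which is a deliberate
  search-space reduction.
* The reported cycle count is the minimum of a generating history; the
  true historical count can be larger (cycles can cancel), and for paths
  over 64 oriented segments the count is a greedy upper bound.
* Virtual fold-backs are a heuristic recovery mechanism: they are
  hypotheses at CN steps, not evidence, and are always flagged.
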