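# Methods

## Problem and model

Given an RNA sequence q = (q_1, …, q_L) over {A, C, G, U}, the task is to
predict the set of base pairs {(i, j)} of its secondary structure, subject to
three constraints: only the six canonical ordered pair classes
(A,U), (U,A), (U,G), (G,U), (G,C), (C,G); at most one partner per base; and a
minimum pairing distance |i − j| ≥ 3. Pseudoknots — pairs (i, j), (k, l) with
i < k < j < l — are allowed throughout; nothing in the pipeline assumes a
nested (well-parenthesized) structure.

The model is purely data-driven: it scores every candidate pair with a
convolutional network and contains no thermodynamic energy terms.

### Input and target encoding

A sequence becomes an L × L × 8 one-hot relation map X. Channels 0–5 mark
which of the six canonical classes the ordered base combination (q_i, q_j)
belongs to, at cells where pairing is geometrically possible; channel 6 marks
the main diagonal (i = j), the slot used to express "unpaired"; channel 7
marks impossible cells (non-canonical combination, or 0 < |i − j| < 3 — the
distance rule dominates even for canonical combinations). The training
target is the binary L × L matrix T with t_ij = t_ji = 1 for each pair and
t_ii = 1 for unpaired bases, so every row sums to exactly 1.

The loss set V contains every cell except the channel-7 support. The
diagonal belongs to V: t_ii carries the unpaired signal, and the diagonal
channel exists precisely so the network can learn it. (Whether the original
formulation counted the diagonal in |V| is not decidable from its loss
description; including it is this package's explicit choice.)

### Network

Channels-last tensors flow through: two conv blocks (8→32, 32→32), M
residual blocks with distinct weights, then a single weight-shared residual
block applied N times like a recurrent model. After **every** shared pass a
shared readout (1×1 conv block plus a final 1×1 convolution with one output
channel) emits a score matrix Y_n. Each conv block is convolution →
batch-normalization → LeakyReLU (negative slope 0.01, configurable); spatial
size is preserved by same-padding, which makes the model fully convolutional:
one instance serves any L.

A residual block here is conv block → conv → batch-norm with an identity
skip added before the final activation — the conventional two-convolution
reading of a residual unit; it is stated explicitly so it is falsifiable.
Batch-norm statistics of the shared block and the readout are shared across
the N passes.

The loss is the average of the N intermediate masked mean-squared errors,

    l_n = (1/|V|) Σ_{(i,j)∈V} (y_ij^(n) − t_ij)²,   l = (1/N) Σ_n l_n,

which pushes the shared recurrence toward the right answer as early as
possible. The published architecture figure and its caption disagree on
which block is repeated M vs N times and where the loss attaches; this
implementation follows the running-text convention (M distinct blocks, N
shared passes, loss after each shared pass), which is the only one
consistent with the l = (1/N) Σ l_n formula.

The network is implemented directly in NumPy (`cnnfold.nn`): im2col + GEMM
convolutions, masked batch normalization, hand-written backward passes
verified against central finite differences, and Adam. Default dtype is
float32; float64 is available for gradient checking.

### Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| M | 2 | distinct residual blocks (10 in the "big" variant) |
| N | 2 | applications of the shared residual block |
| channels | 32 | feature width of every conv block except the readout output |
| kernel | 3 | spatial kernel of non-readout convolutions (not stated by the source text; 3 is the conventional residual-network choice, configurable) |
| learning rate | 0.005 | Adam |
| max batch | 16 | samples per mini-batch |
| solo threshold | 1000 nt | longer sequences train alone |
| min pairing distance | 3 | single named constant threaded through encoding, decoding, validation |
| decode k | 3 | per-row candidate cap for matching decoding (larger k stops helping) |
| mix threshold | 600 nt | L ≤ 600 routed to the higher-capacity short-sequence model |

With these defaults the M=2/N=2 model has ~69k parameters. (Published
parameter totals for the corresponding variants cannot be reconstructed
without the unstated kernel sizes and block internals and are treated as
non-binding.)

Model-variant presets mirror the published training recipes: (M=2, N=2,
30 epochs, all lengths), (M=2, N=2, 400 epochs, L < 600), and (M=10, N=2,
45 epochs, L < 600); mixed prediction dispatches at L ≤ 600.

### Mini-batching with variable lengths

Batches are padded to the longest member. Padded cells carry all-zero input
channels and are zeroed again at network entry, sit outside every sample's
V, and are excluded from batch-norm statistics via a spatial mask, so
gradients with respect to padding are exactly zero (asserted by a
perturbation test). Records are sorted by length before chunking to minimize
padding; whether the original batching bucketed by length is unstated, so
this is the package's own choice. Sequences over the solo threshold always
train alone.

## Decoding

**Argmax** (default): base i pairs with the column maximizing the masked row
i of Y (diagonal = unpaired). O(L²); ties break to the lowest column index
for cross-platform determinism. Row choices need not be symmetric, so the
result can contain conflicting pairings; conflicts are returned as
violations, never silently repaired.

**Blossom**: the symmetrized matrix (Y + Yᵀ)/2 is read as a weighted graph
on the bases, with self-loop weight y_ii for staying unpaired. Because
general matching implementations do not support self-loops, the graph is
doubled: each kept pair cell (i, j) contributes edges (u_i, u_j) and
(v_i, v_j) with weight y_ij, and each base an edge (u_i, v_i) with weight
2·y_ii. A maximum-weight (not necessarily perfect) matching is computed with
the Blossom algorithm (networkx) and pairs are read off the u-copy, which is
authoritative when a tie-broken matcher splits the copies inconsistently.
Per row only the k largest valid cells are kept (an edge survives if either
endpoint kept it, preserving symmetry); nonpositive edges are dropped, since
a maximum-weight matching never benefits from them — degenerate inputs
therefore decode to the all-unpaired structure. The output provably
satisfies every structural constraint, because edges exist only on valid
cells and a matching is partner-disjoint.

Scores are treated as pairing propensities on the scale of the binary
target, i.e. essentially in [0, 1]. In that regime the doubled-graph
construction is exact: for every score matrix the decoded structure attains
the exhaustive maximum of Σ_pairs 2·y_ij + Σ_unpaired 2·y_ii (verified
against full enumeration at small L). With negative diagonal entries the
construction would diverge from that objective — a matching can skip a
negative self-loop, a structure cannot skip its unpaired bases — which is
why the symmetrization and pruning choices are documented here rather than
claimed to be "what the original did" (its adjacency-interpretation footnote
is not part of the available text).

## Evaluation protocol

Per-sequence precision, recall and F1 over base-pair sets only — diagonal
"unpaired" marks never enter the counts. The shifted variant also credits a
predicted (i, j) when the reference holds (i±1, j) or (i, j±1) — never a
diagonal shift — matched greedily in 5′ order with each reference pair
creditable once, so tp ≤ min(|pred|, |ref|). (Whether the metric as used in
prior comparisons allows one reference pair to credit several predictions is
unstated; the one-credit rule is declared, not inferred.) Empty-set
conventions: both empty → P = R = F1 = 1; prediction empty, reference not →
P = F1 = 0; reference empty, prediction not → R = 0. Aggregation reports
plain means plus a length-weighted F1 with weights w_k = L_k / Σ_k L_k, and
a pseudoknot confusion table based on exact crossing detection.

## Synthetic data

The generator emulates the composition of curated structure corpora: stems
of 3–8 consecutive pairs placed by recursive interval splitting (guaranteeing
nestedness), loops of at least 3 unpaired bases between partners, pair bases
drawn uniformly from the six canonical classes, unpaired bases uniform over
A/C/G/U, and with probability 0.3 one extra stem rejection-sampled to cross
the nested skeleton (the pseudoknot rate of reference corpora is roughly a
third). Every record passes validation by construction.

What it does **not** emulate: thermodynamic stability, family-specific
topologies (tRNA cloverleafs, rRNA domains), sequence composition biases,
non-canonical pairs, or multi-structure ambiguity. Passing tests therefore
demonstrate that the machinery — encoding, optimization, decoding, metrics —
is correct and that the network has the capacity to memorize structured
targets; they say nothing about generalization to real RNA families, which
requires training on real corpora at full scale.

## Numerical choices and degenerate inputs

* Argmax ties → lowest column index; matching ties are resolved by reading
  the u-copy; generator and training are fully seeded (every public entry
  point takes a seed).
* Batch-norm eps 1e-5, momentum 0.1; He-normal weight init; Adam moments in
  float64 for reproducibility of long runs.
* Training aborts with diagnostics on a non-finite loss.
* Structures with multi-paired indices are representable (argmax output,
  permissive parsing) but rejected by target encoding and flagged by
  validation; files whose partner columns disagree are a parse error naming
  the offending lines.
* Ambiguity codes in input sequences are rejected by default; an opt-in
  keeps them as bases that cannot pair with anything (their off-diagonal
  cells go to the invalid channel).

## Problem sizes used by the test suite and acceptance script

Decoder-optimality enumeration uses L ≤ 10 (exhaustive over all pairings);
validity sweeps use 500 random matrices with L ∈ [20, 200]; the overfit
experiment trains the 32-channel M=2/N=2 model on 20 records of 30–60 nt for
at most 500 steps, stopping once the mean training-set F1 reaches 0.95.
These sizes exercise every code path of the full-scale method; the published
benchmark-corpus experiments (tens of thousands of sequences up to ~1800 nt)
are out of scope here.

## Known limitations

* CPU-only; a 3×3-conv forward pass is O(L²) in memory and compute per
  layer, so very long sequences (>~2000 nt) are slow to train.
* Matching decoding is cubic in L via the pure-Python Blossom
  implementation (~0.3 s at L = 200, seconds at L ≳ 1000).
* No sub-optimal/ensemble structure output; one structure per sequence.
* Base triplets, non-canonical pairs and tertiary contacts are out of scope
  by design.
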