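# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `paralign`, in the spirit of a methods appendix: what
the code computes, under which assumptions, and what a passing test does and
does not establish.

## 1. Pairwise alignment and distances

Global alignment uses the Gotoh three-state recursion for affine gaps. A
gap of length L costs `g_open + L·g_ext`, end gaps included — the simplest
consistent global model. Defaults are Clustal-family heritage: protein
`GONNET250 / g_open 10.0 / g_ext 0.1`; DNA `NUC.4.4 / 15.0 / 6.66`.

Determinism is part of the contract, because the distance phase must be
schedule-invariant. Two rules fix it:

* traceback tie-break: diagonal, then up (gap in the second sequence), then
  left; within a gap state, opening is preferred to extending on ties;
* each unordered pair is canonically ordered before aligning, so
  `d(a,b) = d(b,a)` holds exactly, not just approximately.

The distance is percent mismatch over gap-free aligned columns of the full
DP traceback (the "slow-accurate" convention); a pair with no gap-free
column gets d = 1. The raw DP score is kept alongside the distance on the
returned object, since both are legitimate "pair scores".

Unknown residues (X/N) absent from a source matrix grid are scored at the
matrix minimum: public data contains ambiguity codes, and a hard error in
the middle of an N²/2-pair run would be worse than a pessimistic score.

The DP inner loop is a numba kernel over a precomputed position-score
matrix. The same kernel serves residue-vs-residue and profile-vs-profile
alignment, which is also why the two-sequence progressive case reproduces
`nw_align` byte-for-byte. Memory is O(m·n) per pair (three DP planes plus
traceback), which is the accepted cost of exact affine DP.

## 2. Distance storage

The store abstracts a symmetric N×N matrix with a zero diagonal down to its
strict upper triangle, addressed by the canonical rank
`P(i,j) = i(2N−i−1)/2 + (j−i−1)`.

* **memory** backend: one flat float64 array.
* **disk** backend: one fixed-size file — 20-byte header (magic, version,
  N, cell width 8) followed by N(N−1)/2 little-endian float64 cells at
  offset `header + 8P`. Required capacity `header + 8·N(N−1)/2` bytes is
  checked at creation and stated in the error.

Unwritten cells hold NaN, a bit pattern outside [0, 1]; any read of one is
an "incomplete matrix" error naming the pair. This makes completion
checkable (`n_written == N(N−1)/2`) and rules out silently aligning against
zeros. The disk file reopens across processes with identical contents.

Disk-mode jobs can also spool every pair as its own two-record FASTA file
(`pair-%09d.fa`, 9-digit rank suffix, strictly increasing), generated
lazily so the full spool never needs to exist at once. The pipeline does
not spool by default — at desk scale the per-pair files buy nothing — but
the CLI exposes `--spool`.

## 3. Scheduling

Pair tasks are distributed under two policies:

* **insta** (dynamic): each worker holds exactly one task and receives the
  next unassigned task the moment it finishes — greedy list scheduling in
  canonical order, realized as event-driven idle detection (finishing
  workers announce themselves; ties go to the lowest worker index).
* **fixed_chunk** (static): tasks are pre-partitioned into consecutive
  chunks of `chunk_size` dealt round-robin before execution. Default
  `chunk_size = ceil(T / (5m))`. This is deliberately the *static*
  variant — it reproduces the imbalance pathology of chunked schedulers on
  heavy-tailed costs.

The simulator's default cost model is `cost(i,j) = len_i·len_j` scaled to
unit mean, i.e. the O(m·n) DP work. Simulated traces satisfy checkable
invariants (no overlap per worker, every task exactly once, makespan = max
finish, idle fraction = 1 − Σbusy/(m·makespan)).

Because insta is list scheduling, classical bounds apply and are tested:
makespan ≤ (2 − 1/m)·OPT, and makespan ≤ Σ/m + max cost ≤ fixed-chunk
makespan + max cost.

Real execution goes through a small executor contract (serial, or a thread
pool honoring the one-task-per-idle-worker protocol). Results always flow
back to the master, which alone writes the store keyed by (i, j) — so the
final matrix is bit-identical across policies, worker counts and backends.
A failed task is re-queued once, then the job fails naming the pair rank.

## 4. Guide tree

Saitou–Nei neighbor joining on the full matrix (dense O(N³), loaded from
the store in one bulk read; no fast-NJ heuristics — correctness-first at
desk-scale N). Deterministic tie-break: the minimal Q entry with the lowest
(i, j). Negative branch-length estimates are clamped to zero with the
deficit moved to the sibling so the pair distance is conserved.

Joins continue until two clusters remain and are fused with half the
remaining distance each (N−1 joins total); the tree is then re-rooted at
the midpoint of the longest leaf-to-leaf path (ties broken by leaf-name
order), giving a rooted binary tree regardless of where NJ happened to
stop. With checkpointing on, a Newick snapshot (`tree-%09d.nwk`) is written
after every join — the per-join reading of "record tree state at each
stage" — and the final snapshot is the returned rooted tree.

Sequence weights follow the branch-sharing scheme: a leaf's raw weight is
the sum over its root-path branches of `length / leaves below the branch`;
weights are floored at 1e−9 (a leaf at the end of an all-zero path must
still count) and normalized to max 1. An all-zero tree yields uniform
weights.

## 5. Progressive alignment

Profiles carry per-column weighted residue frequencies
(`f(a) = Σ_r w_r·[row r has a] / Σ_r w_r`, gap mass excluded, so columns
sum to ≤ 1). Merging profiles runs the same affine DP on the score matrix
`S₁₂ = F₁ S F₂ᵀ`; gaps inserted by earlier merges are permanent ("once a
gap, always a gap"). Merge order is the postorder of the rooted guide tree;
output rows are restored to input order.

**Deliberate simplification.** None of classic ClustalW's position-specific
gap-penalty heuristics (residue-specific opening costs, hydrophilic-run
discounts, short-gap deterrents) are applied: the gap model is plain
affine everywhere. This is the largest divergence from the Clustal lineage
and the main reason alignments of divergent families will differ from
ClustalW output. There is also no iterative refinement beyond the explicit
window realign operation.

SP score: sum over unordered row pairs of the pair's gapped-row score —
substitution scores on residue–residue columns, affine penalties on gap
runs re-derived from the pair's projected gap pattern, gap–gap columns
dropped (runs separated only by dropped columns merge). The weighted
variant multiplies each pair term by `w_i·w_j`; all-ones weights reproduce
the unweighted score exactly.

`realign_region(aln, c0, c1)` de-gaps the rows of the half-open column
window, re-runs the *entire* three-stage pipeline on the non-empty
fragments (fragment tree re-estimated from scratch — the self-contained
reading), re-inserts empty fragments as all-gap rows, and splices. Columns
outside the window are byte-identical to the input.

## 6. Synthetic data

The default protein family model emulates a large diverged superfamily:
10000s of relatives of one ancestor with a heavy-tailed length law.

* Lengths: log-normal truncated to [10, 11600] with target mean 440. The
  log-scale location is fitted (Brent root-finding on the closed-form
  truncated mean) so the *truncated* mean hits the target; `sigma_log`
  defaults to 0.7, chosen once as realistic for a superfamily whose
  maximum length runs ~26× its mean. With n = 10000 the empirical mean
  lands within ~1% of 440.
* Divergence: per-site substitution probability 0.2; indel events at rate
  0.05/site with geometric lengths (p = 0.3); sequences are then truncated
  or padded with random residues to their drawn lengths.
* Determinism: everything flows from one `numpy.random.default_rng(seed)`;
  identical seeds give identical FASTA bytes.

What this generator does **not** emulate: phylogenetic tree structure
among family members (all are siblings of one ancestor), rate heterogeneity
across sites, codon structure, or realistic amino-acid composition
(residues are uniform). Green tests on synthetic families therefore
establish pipeline correctness and invariants — not alignment accuracy on
real homologs, which only curated benchmarks could.

Task-cost generators (uniform, log-normal parameterized by mean and CV,
Pareto with finite mean) drive the scheduling experiments; the log-normal
with CV ≈ 2 is the stand-in for a pairwise workload over sequences of very
unequal lengths.

## 7. Known limitations

* No k-tuple fast distance mode: every distance is a full DP alignment.
* Plain affine gaps in the progressive stage (see §5).
* Dense NJ is O(N³) time and O(N²) memory even in disk mode — the disk
  backend removes the *distance-phase* memory wall, not the tree stage's.
* The thread-pool executor shares one process; true multi-machine
  transports are an interface (the executor contract), not a dependency.
* The `.aln` conservation line implements the standard strong/weak residue
  groups for protein and identity-only for DNA; no quality shading.
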