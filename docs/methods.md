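# Methods

## Scope and model

`seqfarm` implements the data-parallel wrapper pattern for scaling
black-box sequence-analysis tools: queries are independent work units, the
reference database is replicated (not fragmented) to every worker, and all
tool I/O is virtualized so the compute kernel never touches storage. The
package deliberately models the *observable contracts* of this pattern —
one backing-store read per run, logarithmic broadcast structure, prefetch
scheduling, exactly-once output — rather than machine-bound performance.
Wall-clock throughput, filesystem bandwidth, and TLB/page-size effects are
out of scope; where a hardware optimization exists in the design (large
pages for the preloaded database region), it is carried only as advisory
metadata (`page_hint`, default 2 MiB) so a privileged backend could honor
it.

## Database image and broadcast

The database is serialized into one contiguous byte payload
(length-prefixed id/residue records, little-endian 64-bit lengths, magic
header + version byte) with a record-offset index and a CRC-32 checksum.
`preload_image` reads the persisted payload with exactly one bulk `read()`
call, recorded in `load_stats.reads`; the small fixed-size file header read
is not counted as a payload access. Worker copies are reconstructed from
broadcast bytes and perform zero backing-store reads, which is what the
end-to-end one-reader assertion measures.

The broadcast plan is a binomial tree: the root is relabeled to virtual
rank 0, and in round `r` every virtual rank `v < 2^r` sends to `v + 2^r` if
it exists. This yields `ceil(log2 P)` rounds and exactly `P - 1` messages
for any `P`, verified exhaustively for `P` in 1..128. The reference
transport is round-synchronous and in-process; the `send(sender, receiver,
data) -> data` contract is the substitution point for an MPI-style backend.
Receivers verify the payload CRC against the root's, so a corrupting or
failing link is reported naming the edge.

## Dispatch protocol and scheduling

A worker may hold at most `1 + prefetch_depth` incomplete batches; pending
batches are dispatched in ascending batch id, and a request beyond capacity
is a protocol error. Assignments are final — a prefetched batch is never
reclaimed for rebalancing, since crash-level fault tolerance is outside
this design. Defaults: `batch_size` 16 queries and `prefetch_depth` 1 (one
batch in flight beyond the current one); the pattern itself fixes neither,
and one-deep prefetch is the smallest depth that fully hides a dispatch
latency no larger than the batch duration.

`simulate_schedule` is a discrete-event simulation of the same protocol
with explicit batch durations and a dispatch latency λ: every worker issues
an initial request at t = 0; with depth ≥ 1 a worker requests whenever its
held batches plus in-flight request are below capacity (in particular at
every batch start), with depth 0 only when it holds nothing; requests are
answered after λ. Determinism is pinned by two tie-breaks: simultaneous
request arrivals are served in ascending worker id, and completions are
processed before arrivals at equal times. Per-worker idle time is
`(last_finish - first_start) - total_compute`, rounded at 1e-9 to absorb
float noise. With λ = 0 and depth 0 the protocol reduces to greedy list
scheduling, so the classical `(2 - 1/W)` bound against the brute-force
optimal assignment applies and is tested over every `(n ≤ 8, W ≤ 3)` size
with seeded random and adversarially ordered durations (duration values are
continuous, so enumeration is over sizes, not values).

The execution backend runs workers as in-process threads behind the same
scheduler contract. This choice favors deterministic instrumentation (read
counters, open() interception, shared stores) and portability; record
*content* is deterministic, record *order* is not, and the output store's
reassembly defines the canonical order — which is why all equivalence
checks compare order-insensitively against a workers=1 oracle run.

## Kernels

Kernels exist to exercise the farm with exactly verifiable outputs, not to
reproduce production search tools. The aligner computes the best local
alignment score under identity scoring (match > 0, mismatch ≤ 0) with a
*linear* gap penalty — a deliberate divergence from affine-gap search tools
that keeps the brute-force oracle tractable. The DP is a two-row
numba-compiled scan returning the first maximum in row-major order; the
span start is recovered by re-running the DP on the reversed prefixes
ending at the best cell. Correctness is checked three ways: a pure-Python
DP oracle, exhaustive alignment enumeration at lengths ≤ 6 validating that
oracle, and an independent C implementation (biotite) in the test suite.
The profile scanner computes all ungapped window sums with a vectorized
sliding window; ties resolve to the leftmost offset, and a query shorter
than the model is a documented no-hit, not an error. Each kernel writes one
tab-separated record per query (`query_id, subject_id, score, q_start,
q_end, s_start, s_end, status`); a query on which the kernel raises becomes
a failure entry in the manifest and the rest of the batch proceeds.

## Output store

Records append to per-worker in-memory blocks. When a block's payload bytes
reach `flush_threshold x block_capacity` (defaults 0.9 and 4 MiB) the block
is handed to a single background flusher thread via a queue, so the append
path never blocks on storage — asserted by instrumentation counters
(appends observed while a flush is artificially delayed), not wall-clock
timing. The flusher optionally DEFLATE-compresses the framed payload and
writes it to `shard-(seq mod D)/block-<seq>.blk` (default D = 4), with a
little-endian header carrying magic, version, flags, seq, worker id, frame
and stored sizes, and the CRC-32 of the raw frame. CRC-32 is corruption
detection, not security. Whether blocks from different workers interleave
is left open by the pattern; here each worker fills private blocks, block
files are tagged with the worker id, and the canonical record order is
fixed at reassembly (sort by query id), which makes reassembled streams
provably independent of D, capacity, threshold, compression, and worker
count. `verify_run` re-reads every block and checks that result ids plus
failure ids cover the expected query ids exactly once.

## Workload generators

The generators reproduce the weak-scaling study conditions tying problem
size to core count: aligner — exactly 16 queries per core, all 200 aa;
profiler — 760 sequences per core ("approximately 760" is implemented as
exactly 760 so counts are deterministic), lengths uniform on 100–400 aa as
an explicit stand-in since no length law is part of the pattern; msa — 10
datasets per core, each 10 sequences derived from a random 200–400 aa
ancestor by 5% per-site substitution, emulating the within-dataset
relatedness of hit sets from a prior search. All content is seeded
(`numpy.random.default_rng`) and recorded in a YAML sidecar; identical
profile + seed reproduces byte-identical FASTA. Use distinct seeds for the
database and the workload: both draw from the same generator family, so a
shared seed yields overlapping residue streams and artificially perfect
alignments between generated queries and database records. Residues are
drawn uniformly from the 20 standard amino acids; the parser additionally accepts
`X`, upcases lowercase input with a warning, and rejects `*`.

What the synthetic data does *not* emulate: real database composition and
length distributions, sequence homology structure beyond the msa datasets,
alignment score statistics, and any hardware-bound timing. Passing tests
therefore demonstrate the correctness of scheduling, delivery, and storage
contracts under realistic shapes and sizes — not biological fidelity or
measured speedups.

## Problem sizes

The test suite and acceptance script use desk-scale instances chosen to
exercise every contract: a 64-query / 200 aa workload against a 50-record /
100 aa database for the 20-configuration serial-equivalence sweep (workers
1–8, batch size 1–16, depth 0–3), 30–100 record databases elsewhere, 200
random instances per kernel-oracle comparison, and exhaustive enumeration
where the space is finite (broadcast P ≤ 128, scheduling sizes n ≤ 8, W ≤
3). These sizes are the package's own test conditions; the contracts they
check are size-independent by construction.

## Known limitations

- No crash fault tolerance: a lost worker is not re-dispatched (failures
  are per-query only).
- The MPI/process backends are substitution points, not shipped code; the
  in-process transport and thread workers share one address space.
- Kernels are reference implementations: no E-values, substitution
  matrices, affine gaps, HMM scoring, or MSA construction.
- SQL output is a textual dump; no database connection management.
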