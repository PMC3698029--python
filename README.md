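# seqfarm

A portable task-farming framework for sequence-analysis workloads.

Large sequence-search jobs (protein similarity search, profile scanning,
multiple-alignment batches) parallelize naturally over queries, but scaling
them on shared storage is dominated by I/O: thousands of processes reading
the same reference database, and millions of small result writes. `seqfarm`
implements the wrapper pattern that makes such tools scale without touching
their compute core:

- **One-reader database broadcast.** The reference database is serialized
  into a single contiguous image, preloaded with one bulk read (counted and
  verifiable), and delivered to all `P` workers by a binomial-tree broadcast
  in `ceil(log2 P)` rounds using `P - 1` messages.
- **Prefetch-based dynamic load balancing.** A master dispatches query
  batches on demand; each worker may hold up to `1 + prefetch_depth`
  incomplete batches so dispatch latency overlaps computation. With batch
  durations `p_j` and `W` workers this is greedy list scheduling, whose
  makespan satisfies `C_greedy <= (2 - 1/W) * C_opt`; with durations `>=`
  the dispatch latency and prefetch enabled, workers never idle between
  their first assignment and end of work.
- **Virtual kernel I/O.** Compute kernels are black boxes behind a
  `ToolIO` session: queries and database are served from memory, and
  everything written is forwarded to the output store exactly once. The
  bundled kernels are a Smith–Waterman local aligner (identity scoring,
  linear gap penalty `g < 0`: `H_ij = max(0, H_{i-1,j-1} + s(a_i, b_j),
  H_{i-1,j} + g, H_{i,j-1} + g)`) and an ungapped position-weight-matrix
  scanner (`score(o) = sum_i w[i, q_{o+i}]`).
- **Two-stage buffered output.** Records accumulate in in-memory blocks; a
  background flusher writes blocks — optionally DEFLATE-compressed — to
  files sharded round-robin across directories when occupancy reaches a
  threshold, so appends never wait on storage. A manifest indexes every
  block for reassembly and exactly-once verification.
- **Weak-scaling workload generators** reproducing the standard study
  profiles: 16 queries/core at 200 aa (aligner), 760 sequences/core
  (profiler), 10 related-sequence datasets/core (msa), plus synthetic
  reference databases.
- **Output analysis**: raw hit records → a fixed 8-column tab-delimited
  table → a portable SQL dump.

## Worked example

```sh
seqfarm gendb --n 100 --length-law uniform:100:300 --seed 7 \
        --out nr_stand_in.fasta --image nr_stand_in.img
seqfarm genwork --tool aligner --cores 2 --seed 42 --out queries.fasta
```

```
wrote 100 records (22100 bytes) to nr_stand_in.fasta
wrote database image nr_stand_in.img (checksum 3660778486)
wrote 32 queries to queries.fasta (profile sidecar queries.fasta.workload.yaml)
```

32 queries is 16 per "core" for 2 cores; every query is 200 residues. With
a run configuration `run.yaml`:

```yaml
workers: 4
batch_size: 8
prefetch_depth: 1
queries: queries.fasta
database_image: nr_stand_in.img
tool: {name: aligner, params: {match: 2, mismatch: -1, gap: -2, min_score: 10}}
store: {root: store, shards: 4, block_capacity: 65536, compression: true}
```

```sh
seqfarm run --config run.yaml
seqfarm verify --manifest store/manifest.json --queries queries.fasta
seqfarm parse --manifest store/manifest.json --out hits.tsv
```

```
{"manifest": "store/manifest.json", "records": 32, "failures": 0, "blocks": 2}
PASS
wrote 32 rows to hits.tsv; 0 rejects
```

Every query produced exactly one record (`records: 32`), collected into 2
compressed blocks across the 4 shard directories; `verify` re-reads every
block, checks its CRC-32 against the manifest, and confirms each query id
appears exactly once. The table's first rows:

```
query_id  subject_id  score  q_start  q_end  s_start  s_end  status
q000000   db000064    10.0   107      117    115      124    hit
q000001   db000086    11.0   192      199    117      124    hit
```

Scores of 10–12 between 200-aa random queries and an unrelated random
database are the expected chance level for identity scoring; spans are
0-based half-open. `seqfarm tosql --in hits.tsv --out hits.sql` renders the
table as `CREATE TABLE` + `INSERT` statements loadable by any SQL engine.

Scheduling behaviour can be inspected without running kernels:

```sh
seqfarm simulate --durations 2,2,2,2 --workers 2 --depth 1 --latency 1
```

```
{"makespan": 5.0, "idle": [0.0, 0.0], "assignments": [[0, 2], [1, 3]]}
```

With prefetching the dispatch latency is fully hidden (makespan 5, zero
idle); the same schedule at `--depth 0` takes 6 time units.

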