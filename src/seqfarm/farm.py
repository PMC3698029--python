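"""Master-worker task farm with prefetch-based dynamic load balancing.

The master owns the batch queue; workers request batches on demand and may
hold up to ``1 + prefetch_depth`` incomplete batches so that dispatch
latency overlaps computation (latency hiding). Kernels see only a virtual
I/O session (:class:`ToolIO`): the database and batch queries are served
from memory and everything the kernel writes is forwarded to the output
store exactly once — the kernel never touches the filesystem.

Two execution surfaces share the dispatch protocol:

* :func:`run_farm` — the real thing: broadcast the database image, run the
  kernel over every batch on in-process worker threads, collect results into
  an output store, and return its manifest.
* :func:`simulate_schedule` — a discrete-event simulation of the same
  protocol with explicit batch durations and dispatch latency, used to test
  scheduling properties (greedy bound, latency hiding) deterministically.
"""

from __future__ import annotations

import heapq
import io
import logging
import threading
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .dbcast import (
    DatabaseImage,
    InProcessTransport,
    execute_broadcast,
    image_from_payload,
    plan_broadcast,
    preload_image,
)
from .errors import ConfigError, ProtocolError, StoreError, ValidationError
from .kernels import ToolSpec, tool_run_batch
from .outstore import OutputStore, RunManifest, finalize_store
from .seqio import SeqRecord, WorkBatch, make_batches, write_fasta

logger = logging.getLogger("seqfarm.farm")

#: Returned by the scheduler when no pending batches remain.
END_OF_WORK = object()


@dataclass(frozen=True)
class FarmConfig:
    workers: int = 1
    batch_size: int = 16
    prefetch_depth: int = 1
    seed: int = 0
    dispatch_latency: float = 0.0  # simulation mode only

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.prefetch_depth < 0:
            raise ConfigError("prefetch_depth must be >= 0")
        if self.dispatch_latency < 0:
            raise ConfigError("dispatch_latency must be >= 0")


class Scheduler:
    """Thread-safe batch dispatcher enforcing the prefetch capacity.

    Pending batches are dispatched in ascending batch_id; a worker may hold
    at most ``1 + prefetch_depth`` incomplete batches, and a request beyond
    that capacity is a protocol error.
    """

    def __init__(self, batches: Sequence[WorkBatch], prefetch_depth: int = 1):
        self._batches = list(batches)
        self._next = 0
        self._capacity = 1 + prefetch_depth
        self._held: dict[int, int] = {}
        self._lock = threading.Lock()

    def next_assignment(self, worker_id: int):
        with self._lock:
            if self._held.get(worker_id, 0) >= self._capacity:
                raise ProtocolError(
                    f"worker {worker_id} already holds {self._capacity} batches"
                )
            if self._next >= len(self._batches):
                return END_OF_WORK
            batch = self._batches[self._next]
            self._next += 1
            batch.assign(worker_id)
            self._held[worker_id] = self._held.get(worker_id, 0) + 1
            logger.info("assign worker=%d batch=%d", worker_id, batch.batch_id)
            return batch

    def complete(self, worker_id: int, batch: WorkBatch) -> None:
        with self._lock:
            batch.finish()
            self._held[worker_id] -= 1
            logger.info("complete worker=%d batch=%d", worker_id, batch.batch_id)


# ---------------------------------------------------------------------------
# Virtual I/O
# ---------------------------------------------------------------------------

class ToolIO:
    """Virtual I/O session isolating a kernel from the filesystem.

    The database and the batch's queries are served from memory; writes are
    buffered and forwarded to the output store (tagged with worker and batch
    id) exactly once when the session closes.
    """

    def __init__(
        self,
        dbimage: DatabaseImage,
        batch_records: Sequence[SeqRecord],
        store: OutputStore,
        worker_id: int,
        batch_id: int = 0,
    ):
        self._db = dbimage
        self._records = list(batch_records)
        self._store = store
        self.worker_id = worker_id
        self.batch_id = batch_id
        self._written: list[tuple[str, str]] = []
        self._failed: list[tuple[str, str]] = []
        self._closed = False

    def database(self) -> DatabaseImage:
        return self._db

    def query_stream(self) -> io.StringIO:
        buf = io.StringIO()
        write_fasta(self._records, buf)
        buf.seek(0)
        return buf

    def write(self, query_id: str, payload: str) -> None:
        if self._closed:
            raise StoreError("write after ToolIO close")
        self._written.append((query_id, payload))

    def write_failure(self, query_id: str, reason: str) -> None:
        if self._closed:
            raise StoreError("write after ToolIO close")
        self._failed.append((query_id, reason))

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        for query_id, payload in self._written:
            self._store.append_record(self.worker_id, query_id, payload)
        for query_id, reason in self._failed:
            self._store.append_failure(query_id, reason)


def open_tool_io(
    dbimage: DatabaseImage,
    batch_records: Sequence[SeqRecord],
    store: OutputStore,
    worker_id: int,
    batch_id: int = 0,
) -> ToolIO:
    return ToolIO(dbimage, batch_records, store, worker_id, batch_id)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_farm(
    config: FarmConfig,
    queries: Sequence[SeqRecord],
    db: DatabaseImage | str | Path,
    tool: ToolSpec,
    store: OutputStore,
) -> RunManifest:
    """Process every query with the kernel exactly once and return the
    store's manifest.

    ``db`` may be a :class:`DatabaseImage` or a path to a persisted image,
    in which case it is preloaded here with a single bulk read. The image is
    delivered to the ``workers`` via a binomial-tree broadcast (master is
    participant 0); the backing store is never read again. The resulting
    record set is independent of workers, batch_size, and prefetch_depth.
    """
    if not queries:
        raise ConfigError("empty query set")
    seen: set[str] = set()
    for q in queries:
        if q.id in seen:
            raise ValidationError(f"duplicate query id {q.id}")
        seen.add(q.id)

    image = db if isinstance(db, DatabaseImage) else preload_image(db)

    plan = plan_broadcast(config.workers + 1, root=0)
    receipts, delivered = execute_broadcast(
        plan, image.payload, InProcessTransport()
    )
    worker_images = {
        w: image_from_payload(delivered[w], image.page_hint)
        for w in range(1, config.workers + 1)
    }

    by_id = {q.id: q for q in queries}
    batches = make_batches(queries, config.batch_size)
    scheduler = Scheduler(batches, config.prefetch_depth)
    capacity = 1 + config.prefetch_depth
    failures: list[Exception] = []

    def worker_loop(worker_id: int) -> None:
        held: deque[WorkBatch] = deque()
        ended = False
        try:
            while True:
                while not ended and len(held) < capacity:
                    nxt = scheduler.next_assignment(worker_id)
                    if nxt is END_OF_WORK:
                        ended = True
                    else:
                        held.append(nxt)
                if not held:
                    return
                batch = held.popleft()
                session = open_tool_io(
                    worker_images[worker_id],
                    [by_id[q] for q in batch.query_ids],
                    store,
                    worker_id,
                    batch.batch_id,
                )
                try:
                    tool_run_batch(tool, session)
                finally:
                    session.close()
                scheduler.complete(worker_id, batch)
        except Exception as exc:  # surfaced after join
            failures.append(exc)

    threads = [
        threading.Thread(target=worker_loop, args=(w,), name=f"farm-worker-{w}")
        for w in range(1, config.workers + 1)
    ]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if failures:
        raise failures[0]

    manifest = finalize_store(store)
    manifest.stats.update(
        {
            "workers": config.workers,
            "batch_size": config.batch_size,
            "prefetch_depth": config.prefetch_depth,
            "db_reads": image.load_stats.reads,
            "broadcast_participants": plan.participants,
            "broadcast_rounds": len(plan.rounds),
            "broadcast_messages": plan.messages,
            "broadcast_receipts": len(receipts),
        }
    )
    logger.info("flush run=%s blocks=%d", manifest.run_id, manifest.totals["blocks"])
    return manifest


# ---------------------------------------------------------------------------
# Discrete-event simulation
# ---------------------------------------------------------------------------

@dataclass
class ScheduleResult:
    """Observable outcome of a simulated dispatch run."""

    assignments: list[list[int]]  # per-worker batch ids, in start order
    starts: dict[int, float]
    finishes: dict[int, float]
    makespan: float
    idle: list[float]  # per-worker idle between first start and last finish


def simulate_schedule(
    durations: Sequence[float],
    workers: int,
    prefetch_depth: int = 1,
    dispatch_latency: float = 0.0,
) -> ScheduleResult:
    """Discrete-event simulation of the prefetch dispatch protocol.

    Each worker issues an initial request at t=0. With depth >= 1 a new
    request is issued whenever the worker's held batches (computing +
    queued) plus its in-flight request are below capacity — in particular at
    every batch start; with depth 0 a request is issued only when the worker
    holds nothing. Requests are answered after ``dispatch_latency``;
    simultaneous arrivals are served in ascending worker id and pending
    batches dispatched in ascending batch id.
    """
    durations = list(durations)
    if any(d < 0 for d in durations):
        raise ValidationError("durations must be non-negative")
    if workers < 1:
        raise ConfigError("workers must be >= 1")
    if prefetch_depth < 0:
        raise ConfigError("prefetch_depth must be >= 0")
    if dispatch_latency < 0:
        raise ConfigError("dispatch_latency must be >= 0")

    n = len(durations)
    capacity = 1 + prefetch_depth
    pending = deque(range(n))
    queue_: list[deque[int]] = [deque() for _ in range(workers)]
    computing: list[int | None] = [None] * workers
    outstanding = [False] * workers
    ended = [False] * workers
    assignments: list[list[int]] = [[] for _ in range(workers)]
    starts: dict[int, float] = {}
    finishes: dict[int, float] = {}
    busy = [0.0] * workers
    first_start: list[float | None] = [None] * workers
    last_finish = [0.0] * workers

    _COMPLETE, _ARRIVE = 0, 1
    events: list[tuple[float, int, int]] = []

    def maybe_request(w: int, t: float) -> None:
        if ended[w] or outstanding[w]:
            return
        held = len(queue_[w]) + (1 if computing[w] is not None else 0)
        if prefetch_depth == 0:
            if held > 0:
                return
        elif held >= capacity:
            return
        outstanding[w] = True
        heapq.heappush(events, (t + dispatch_latency, _ARRIVE, w))

    def try_start(w: int, t: float) -> None:
        if computing[w] is not None or not queue_[w]:
            return
        b = queue_[w].popleft()
        computing[w] = b
        starts[b] = t
        if first_start[w] is None:
            first_start[w] = t
        busy[w] += durations[b]
        heapq.heappush(events, (t + durations[b], _COMPLETE, w))
        if prefetch_depth > 0:
            maybe_request(w, t)  # request at batch start hides latency

    for w in range(workers):
        maybe_request(w, 0.0)

    while events:
        t = events[0][0]
        batch_now: list[tuple[float, int, int]] = []
        while events and events[0][0] == t:
            batch_now.append(heapq.heappop(events))
        # completions first, then arrivals; each in ascending worker id
        for _, kind, w in sorted(batch_now, key=lambda e: (e[1], e[2])):
            if kind == _COMPLETE:
                b = computing[w]
                computing[w] = None
                finishes[b] = t
                last_finish[w] = t
                if prefetch_depth == 0:
                    maybe_request(w, t)
                try_start(w, t)
                maybe_request(w, t)
            else:
                outstanding[w] = False
                if pending:
                    b = pending.popleft()
                    queue_[w].append(b)
                    assignments[w].append(b)
                else:
                    ended[w] = True
                try_start(w, t)
                maybe_request(w, t)

    makespan = max(finishes.values(), default=0.0)
    idle = [
        (last_finish[w] - first_start[w]) - busy[w] if first_start[w] is not None else 0.0
        for w in range(workers)
    ]
    return ScheduleResult(
        assignments=assignments,
        starts=starts,
        finishes=finishes,
        makespan=makespan,
        idle=[max(0.0, round(x, 9)) for x in idle],
    )
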