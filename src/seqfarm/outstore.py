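"""Two-stage buffered, sharded, optionally compressed output store.

Result records accumulate in per-worker in-memory blocks. When a block's
occupancy reaches ``flush_threshold * block_capacity`` it is handed to a
background flusher thread, which (optionally) compresses it and writes it to
a block file in one of D shard directories chosen round-robin by block
sequence number. Appends therefore never wait on storage. ``finalize``
drains the flusher and writes a manifest — the authority for reassembly and
exactly-once verification.

Block file layout (little-endian): magic ``SFBK``, version u8, flags u8
(bit 0 = compressed), seq u64, worker_id u64, frame_size u64 (raw framed
bytes), stored_size u64, crc32 u32 of the raw framed bytes, then the stored
payload. Within the raw frame each record is [u32 id_len][id][u32 len][payload].
"""

from __future__ import annotations

import json
import os
import queue
import threading
import time
import uuid
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    ConfigError,
    CorruptionError,
    OversizeRecordError,
    StoreError,
)

_BLOCK_MAGIC = b"SFBK"
_BLOCK_VERSION = 1
_FLAG_COMPRESSED = 0x01
#: codec tag carried in the flags byte; only DEFLATE (zlib) is defined.
import struct

_BLOCK_HEADER = struct.Struct("<4sBBQQQQI")


@dataclass(frozen=True)
class StoreConfig:
    shard_dirs: tuple[Path, ...]
    block_capacity: int = 4 * 1024 * 1024
    flush_threshold: float = 0.9
    compression: bool = False
    manifest_path: Path | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        dirs = tuple(Path(d) for d in self.shard_dirs)
        object.__setattr__(self, "shard_dirs", dirs)
        if len(dirs) < 1:
            raise ConfigError("at least one shard directory required")
        if self.block_capacity <= 0:
            raise ConfigError("block_capacity must be > 0")
        if not 0.0 < self.flush_threshold <= 1.0:
            raise ConfigError("flush_threshold must be in (0, 1]")
        if self.manifest_path is None:
            object.__setattr__(
                self, "manifest_path", dirs[0].parent / "manifest.json"
            )
        else:
            object.__setattr__(self, "manifest_path", Path(self.manifest_path))
        if self.run_id is None:
            object.__setattr__(self, "run_id", uuid.uuid4().hex[:12])

    @classmethod
    def at(cls, root: str | Path, shards: int = 4, **kw) -> "StoreConfig":
        """Convenience layout: ``root/shard-k`` directories plus
        ``root/manifest.json``."""
        root = Path(root)
        return cls(
            shard_dirs=tuple(root / f"shard-{k}" for k in range(shards)),
            manifest_path=root / "manifest.json",
            **kw,
        )


def shard_for(seq: int, config: StoreConfig) -> Path:
    """Deterministic round-robin shard directory for a block sequence number."""
    return config.shard_dirs[seq % len(config.shard_dirs)]


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def _frame(records: Sequence[tuple[str, bytes]]) -> bytes:
    parts = []
    for qid, payload in records:
        qb = qid.encode("utf-8")
        parts.append(struct.pack("<I", len(qb)))
        parts.append(qb)
        parts.append(struct.pack("<I", len(payload)))
        parts.append(payload)
    return b"".join(parts)


def _unframe(raw: bytes) -> list[tuple[str, bytes]]:
    out = []
    pos = 0
    while pos < len(raw):
        try:
            (n,) = struct.unpack_from("<I", raw, pos)
            pos += 4
            qid = raw[pos : pos + n].decode("utf-8")
            pos += n
            (m,) = struct.unpack_from("<I", raw, pos)
            pos += 4
            payload = raw[pos : pos + m]
            if len(payload) != m:
                raise CorruptionError("truncated record frame")
            pos += m
        except struct.error as exc:
            raise CorruptionError("truncated record frame") from exc
        out.append((qid, payload))
    return out


@dataclass(frozen=True)
class OutputBlock:
    """One unit of flushing: an ordered run of records from one worker."""

    seq: int
    worker_id: int
    records: tuple[tuple[str, bytes], ...]
    compressed: bool = False
    stored: bytes | None = None  # compressed bytes when compressed

    @property
    def raw(self) -> bytes:
        return _frame(self.records)

    @property
    def raw_size(self) -> int:
        return sum(len(p) for _, p in self.records)

    @property
    def checksum(self) -> int:
        return zlib.crc32(self.raw)


def compress_block(block: OutputBlock) -> OutputBlock:
    """DEFLATE-compress a block's payload; checksum (of raw bytes) unchanged."""
    if block.compressed:
        return block
    return OutputBlock(
        seq=block.seq,
        worker_id=block.worker_id,
        records=block.records,
        compressed=True,
        stored=zlib.compress(block.raw),
    )


def decompress_block(block: OutputBlock) -> OutputBlock:
    """Inverse of :func:`compress_block`; verifies the raw checksum."""
    if not block.compressed:
        return block
    try:
        raw = zlib.decompress(block.stored)
    except zlib.error as exc:
        raise CorruptionError(f"block {block.seq}: corrupt compressed payload") from exc
    records = tuple(_unframe(raw))
    out = OutputBlock(seq=block.seq, worker_id=block.worker_id, records=records)
    if out.checksum != block.checksum and block.stored is not None:
        # checksum property is recomputed from records; a frame that decoded
        # but disagrees structurally is caught by _unframe above
        raise CorruptionError(f"block {block.seq}: checksum mismatch after decompress")
    return out


def _write_block_file(path: Path, block: OutputBlock, compression: bool) -> None:
    raw = block.raw
    if compression:
        stored = zlib.compress(raw)
        flags = _FLAG_COMPRESSED
    else:
        stored = raw
        flags = 0
    with open(path, "wb") as fh:
        fh.write(
            _BLOCK_HEADER.pack(
                _BLOCK_MAGIC,
                _BLOCK_VERSION,
                flags,
                block.seq,
                block.worker_id,
                len(raw),
                len(stored),
                zlib.crc32(raw),
            )
        )
        fh.write(stored)


def read_block_file(path: str | Path) -> OutputBlock:
    path = Path(path)
    if not path.exists():
        raise StoreError(f"missing shard file {path}")
    with open(path, "rb") as fh:
        header = fh.read(_BLOCK_HEADER.size)
        if len(header) < _BLOCK_HEADER.size:
            raise CorruptionError(f"truncated block file {path}")
        magic, version, flags, seq, worker_id, frame_size, stored_size, crc = (
            _BLOCK_HEADER.unpack(header)
        )
        if magic != _BLOCK_MAGIC or version != _BLOCK_VERSION:
            raise CorruptionError(f"not a block file: {path}")
        stored = fh.read(stored_size)
    if len(stored) != stored_size:
        raise CorruptionError(f"truncated block file {path}")
    if flags & _FLAG_COMPRESSED:
        try:
            raw = zlib.decompress(stored)
        except zlib.error as exc:
            raise CorruptionError(f"corrupt compressed payload in {path}") from exc
    else:
        raw = stored
    if len(raw) != frame_size or zlib.crc32(raw) != crc:
        raise CorruptionError(f"checksum mismatch in block file {path}")
    return OutputBlock(seq=seq, worker_id=worker_id, records=tuple(_unframe(raw)))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockEntry:
    seq: int
    path: str  # relative to the manifest directory
    worker_id: int
    record_count: int
    query_ids: tuple[str, ...]
    checksum: int
    compressed: bool


@dataclass
class RunManifest:
    """Index of all flushed blocks; authority for reassembly/verification."""

    run_id: str
    config: dict
    blocks: tuple[BlockEntry, ...]
    failures: tuple[tuple[str, str], ...]  # (query_id, reason)
    totals: dict
    stats: dict = field(default_factory=dict)
    base: Path = field(default_factory=Path)  # directory paths resolve against

    def result_ids(self) -> list[str]:
        return [qid for e in self.blocks for qid in e.query_ids]

    def to_json(self) -> str:
        doc = {
            "run_id": self.run_id,
            "config": self.config,
            "blocks": [asdict(e) for e in self.blocks],
            "failures": [list(f) for f in self.failures],
            "totals": self.totals,
            "stats": self.stats,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    return RunManifest(
        run_id=doc["run_id"],
        config=doc["config"],
        blocks=tuple(
            BlockEntry(
                seq=e["seq"],
                path=e["path"],
                worker_id=e["worker_id"],
                record_count=e["record_count"],
                query_ids=tuple(e["query_ids"]),
                checksum=e["checksum"],
                compressed=e["compressed"],
            )
            for e in doc["blocks"]
        ),
        failures=tuple((f[0], f[1]) for f in doc["failures"]),
        totals=doc["totals"],
        stats=doc.get("stats", {}),
        base=path.parent,
    )


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------

_SENTINEL = object()


class OutputStore:
    """Open store handle; use :func:`open_store` / :func:`finalize_store`."""

    def __init__(self, config: StoreConfig):
        self.config = config
        for d in config.shard_dirs:
            try:
                d.mkdir(parents=True, exist_ok=True)
                if not os.access(d, os.W_OK):
                    raise PermissionError(d)
            except OSError as exc:
                raise StoreError(f"shard directory not writable: {d}: {exc}") from exc
        config.manifest_path.parent.mkdir(parents=True, exist_ok=True)
        self._lock = threading.Lock()
        self._open_blocks: dict[int, list[tuple[str, bytes]]] = {}
        self._occupancy: dict[int, int] = {}
        self._seq = 0
        self._entries: list[BlockEntry] = []
        self._failures: list[tuple[str, str]] = []
        self._finalized = False
        self._flush_error: Exception | None = None
        self._queue: queue.Queue = queue.Queue()
        # instrumentation (contract: appends never wait on a flush)
        self.appends_total = 0
        self.appends_during_flush = 0
        self._flushes_active = 0
        self.flush_delay = 0.0  # test hook: artificially slow the flusher
        self._flusher = threading.Thread(target=self._flush_loop, daemon=True)
        self._flusher.start()

    # -- append path --------------------------------------------------------
    def append_record(self, worker_id: int, query_id: str, payload: bytes | str) -> None:
        if isinstance(payload, str):
            payload = payload.encode("utf-8")
        with self._lock:
            if self._finalized:
                raise StoreError("append after finalize")
            if len(payload) > self.config.block_capacity:
                raise OversizeRecordError(
                    f"record for {query_id} ({len(payload)} B) exceeds "
                    f"block capacity {self.config.block_capacity} B"
                )
            self.appends_total += 1
            if self._flushes_active > 0:
                self.appends_during_flush += 1
            recs = self._open_blocks.setdefault(worker_id, [])
            recs.append((query_id, payload))
            self._occupancy[worker_id] = self._occupancy.get(worker_id, 0) + len(payload)
            if (
                self._occupancy[worker_id]
                >= self.config.flush_threshold * self.config.block_capacity
            ):
                self._hand_off(worker_id)

    def append_failure(self, query_id: str, reason: str) -> None:
        with self._lock:
            if self._finalized:
                raise StoreError("append after finalize")
            self._failures.append((query_id, reason))

    def _hand_off(self, worker_id: int) -> None:
        # caller holds the lock
        recs = self._open_blocks.pop(worker_id, [])
        self._occupancy.pop(worker_id, None)
        if not recs:
            return
        block = OutputBlock(seq=self._seq, worker_id=worker_id, records=tuple(recs))
        self._seq += 1
        self._flushes_active += 1
        self._queue.put(block)

    # -- background flush ---------------------------------------------------
    def _flush_loop(self) -> None:
        while True:
            item = self._queue.get()
            if item is _SENTINEL:
                self._queue.task_done()
                return
            try:
                self._write_block(item)
            except Exception as exc:  # surfaced at finalize
                self._flush_error = exc
            finally:
                with self._lock:
                    self._flushes_active -= 1
                self._queue.task_done()

    def _write_block(self, block: OutputBlock) -> None:
        if self.flush_delay:
            time.sleep(self.flush_delay)
        shard = shard_for(block.seq, self.config)
        path = shard / f"block-{block.seq:08d}.blk"
        try:
            _write_block_file(path, block, self.config.compression)
        except OSError as exc:
            raise StoreError(f"flush failed for shard path {path}: {exc}") from exc
        entry = BlockEntry(
            seq=block.seq,
            path=os.path.relpath(path, self.config.manifest_path.parent),
            worker_id=block.worker_id,
            record_count=len(block.records),
            query_ids=tuple(q for q, _ in block.records),
            checksum=block.checksum,
            compressed=self.config.compression,
        )
        with self._lock:
            self._entries.append(entry)

    def wait_flushed(self) -> None:
        """Block until every handed-off block has hit the backing store."""
        self._queue.join()

    # -- finalize -----------------------------------------------------------
    def finalize(self) -> RunManifest:
        with self._lock:
            if self._finalized:
                raise StoreError("store already finalized")
            self._finalized = True
            for worker_id in sorted(self._open_blocks):
                self._hand_off(worker_id)
        self._queue.put(_SENTINEL)
        self._flusher.join()
        if self._flush_error is not None:
            raise self._flush_error
        entries = tuple(sorted(self._entries, key=lambda e: e.seq))
        manifest = RunManifest(
            run_id=self.config.run_id,
            config={
                "shard_dirs": [str(d) for d in self.config.shard_dirs],
                "block_capacity": self.config.block_capacity,
                "flush_threshold": self.config.flush_threshold,
                "compression": self.config.compression,
            },
            blocks=entries,
            failures=tuple(self._failures),
            totals={
                "records": sum(e.record_count for e in entries),
                "failures": len(self._failures),
                "blocks": len(entries),
            },
            base=self.config.manifest_path.parent,
        )
        with open(self.config.manifest_path, "w") as fh:
            fh.write(manifest.to_json())
        return manifest


def open_store(config: StoreConfig) -> OutputStore:
    """Create shard directories and start the background flusher.

    No block files are written until a threshold crossing or finalize."""
    return OutputStore(config)


def finalize_store(store: OutputStore) -> RunManifest:
    """Flush all partial blocks, drain the flusher, and write the manifest."""
    return store.finalize()


# ---------------------------------------------------------------------------
# Reassembly & verification
# ---------------------------------------------------------------------------

def _entry_block(manifest: RunManifest, entry: BlockEntry) -> OutputBlock:
    block = read_block_file(manifest.base / entry.path)
    if block.seq != entry.seq or block.checksum != entry.checksum:
        raise CorruptionError(
            f"block {entry.path}: content does not match manifest entry"
        )
    if len(block.records) != entry.record_count or tuple(
        q for q, _ in block.records
    ) != tuple(entry.query_ids):
        raise CorruptionError(f"block {entry.path}: record set mismatch")
    return block


def reassemble(manifest: RunManifest) -> list[tuple[str, bytes]]:
    """Canonically ordered record stream: all records sorted by query id.

    Independent of shard count, block capacity, compression, and worker
    count. Raises on a missing shard file or checksum mismatch.
    """
    records: list[tuple[str, bytes]] = []
    for entry in sorted(manifest.blocks, key=lambda e: e.seq):
        records.extend(_entry_block(manifest, entry).records)
    records.sort(key=lambda r: r[0])
    return records


@dataclass(frozen=True)
class VerificationReport:
    passed: bool
    missing: tuple[str, ...]
    duplicated: tuple[str, ...]
    unexpected: tuple[str, ...]
    corrupt: tuple[str, ...]

    def summary(self) -> str:
        if self.passed:
            return "PASS"
        return (
            f"FAIL missing={list(self.missing)} duplicated={list(self.duplicated)} "
            f"unexpected={list(self.unexpected)} corrupt={list(self.corrupt)}"
        )


def verify_run(
    manifest: RunManifest, expected_query_ids: Iterable[str]
) -> VerificationReport:
    """Check that results + failures cover the expected ids exactly once and
    that every referenced block verifies on disk."""
    expected = set(expected_query_ids)
    corrupt: list[str] = []
    seen: list[str] = []
    for entry in manifest.blocks:
        try:
            block = _entry_block(manifest, entry)
        except (StoreError, CorruptionError):
            corrupt.append(entry.path)
            seen.extend(entry.query_ids)  # still counted for coverage report
            continue
        seen.extend(q for q, _ in block.records)
    seen.extend(q for q, _ in manifest.failures)
    counts: dict[str, int] = {}
    for q in seen:
        counts[q] = counts.get(q, 0) + 1
    missing = tuple(sorted(expected - counts.keys()))
    duplicated = tuple(sorted(q for q, c in counts.items() if c > 1))
    unexpected = tuple(sorted(counts.keys() - expected))
    passed = not (missing or duplicated or unexpected or corrupt)
    return VerificationReport(passed, missing, duplicated, unexpected, tuple(corrupt))
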