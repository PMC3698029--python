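"""Reference "black box" compute kernels.

Two deterministic, oracle-verifiable kernels exercise the farm: a local
aligner (best Smith-Waterman score with identity match/mismatch scoring and a
linear gap penalty) and an ungapped position-weight-matrix scanner. They are
deliberately simple stand-ins for full search tools — no affine gaps,
substitution matrices, or alignment statistics — because the farming
machinery only needs a compute-heavy kernel with exact expected outputs.

Kernels interact with the run exclusively through a :class:`~seqfarm.farm.ToolIO`
session (virtual I/O); they never touch the filesystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ValidationError
from .seqio import ALPHABET, SeqRecord, parse_fasta

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_ENC = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    if arr.size and (arr >= 128).any():
        raise ValidationError("non-ASCII residue")
    idx = _ENC[arr]
    if (idx < 0).any():
        bad = sorted({residues[i] for i in np.nonzero(idx < 0)[0]})
        raise ValidationError(f"invalid residues {bad!r}")
    return idx.astype(np.int8)


@dataclass(frozen=True)
class ScoringScheme:
    """Identity scoring with a linear gap penalty."""

    match: int = 2
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValidationError("match score must be positive")
        if self.mismatch > 0:
            raise ValidationError("mismatch score must be <= 0")
        if self.gap >= 0:
            raise ValidationError("gap penalty must be negative")


@dataclass(frozen=True)
class Hit:
    """One search result; spans are 0-based half-open intervals."""

    query_id: str
    subject_id: str
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@njit(cache=True)
def _sw_end(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    """Best local score and its end cell (first maximum in row-major order)."""
    n, m = a.size, b.size
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur[0] = 0
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            t = prev[j] + gap
            if t > v:
                v = t
            t = cur[j - 1] + gap
            if t > v:
                v = t
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
                bi = i
                bj = j
        prev, cur = cur, prev
    return best, bi, bj


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


def sw_score(a: str, b: str, scheme: ScoringScheme) -> LocalAlignment:
    """Best local alignment score of ``a`` vs ``b`` with linear gaps.

    Returns score 0 with empty spans when either sequence is empty (the
    empty local alignment). The score is symmetric in (a, b). Span start is
    recovered by re-running the DP on the reversed prefixes ending at the
    best cell; ties resolve to the first maximum in row-major DP order.
    """
    ea, eb = _encode(a), _encode(b)
    if ea.size == 0 or eb.size == 0:
        return LocalAlignment(0, (0, 0), (0, 0))
    best, bi, bj = _sw_end(ea, eb, scheme.match, scheme.mismatch, scheme.gap)
    if best == 0:
        return LocalAlignment(0, (0, 0), (0, 0))
    rbest, ri, rj = _sw_end(
        ea[:bi][::-1].copy(), eb[:bj][::-1].copy(),
        scheme.match, scheme.mismatch, scheme.gap,
    )
    return LocalAlignment(int(best), (bi - int(ri), bi), (bj - int(rj), bj))


def sw_search(
    query: SeqRecord,
    dbimage,
    scheme: ScoringScheme,
    top_k: int = 1,
    min_score: int = 1,
) -> list[Hit]:
    """Rank database records against a query by local alignment score.

    Returns the ``top_k`` hits with score >= ``min_score``, sorted by
    (score desc, subject_id asc). Deterministic.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    if dbimage.record_count == 0:
        raise ValidationError("empty database image")
    hits = []
    for entry in dbimage.index:
        aln = sw_score(query.residues, dbimage.residues(entry), scheme)
        if aln.score >= min_score:
            hits.append(
                Hit(query.id, entry.id, float(aln.score), aln.query_span, aln.subject_span)
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits[:top_k]


# ---------------------------------------------------------------------------
# Profile scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileModel:
    """Position-specific score matrix over ``alphabet`` (L x |alphabet|)."""

    name: str
    alphabet: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] < 1 or w.shape[1] != len(self.alphabet):
            raise ValidationError(
                "weights must be L x |alphabet| with L >= 1 covering the alphabet"
            )
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])


def random_profile(name: str, length: int, seed: int = 0) -> ProfileModel:
    """Seeded random model (standard-normal weights) for tests and demos."""
    rng = np.random.default_rng(seed)
    return ProfileModel(name, ALPHABET, rng.normal(0.0, 1.0, size=(length, len(ALPHABET))))


def save_profile(model: ProfileModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{model.name}\t{model.length}\t{model.alphabet}\n")
        for row in model.weights:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def load_profile(path: str | Path) -> ProfileModel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 3:
            raise ValidationError(f"bad profile header in {path}")
        name, length, alphabet = header[0], int(header[1]), header[2]
        rows = [
            [float(x) for x in line.rstrip("\n").split("\t")]
            for line in fh
            if line.strip()
        ]
    if len(rows) != length:
        raise ValidationError(f"profile {path}: expected {length} rows, got {len(rows)}")
    return ProfileModel(name, alphabet, np.array(rows))


def profile_scan(
    query: SeqRecord, model: ProfileModel, threshold: float
) -> Hit | None:
    """Best ungapped window of the model along the query.

    score(o) = sum_i weights[i, query[o + i]]; a hit is returned iff the best
    window score >= threshold, the leftmost offset winning ties. A query
    shorter than the model yields no hit (documented rule, not an error).
    """
    L = model.length
    q = query.residues
    if len(q) < L:
        return None
    enc = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(model.alphabet):
        enc[ord(c)] = i
    arr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    idx = enc[arr]
    if (idx < 0).any():
        raise ValidationError("query contains residues outside the model alphabet")
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = model.weights[np.arange(L), windows].sum(axis=1)
    o = int(np.argmax(scores))  # first (leftmost) maximum
    best = float(scores[o])
    if best < threshold:
        return None
    return Hit(query.id, model.name, best, (o, o + L), (0, L))


# ---------------------------------------------------------------------------
# Kernel plug-in contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolSpec:
    """Kernel identifier plus parameters, as named in a run configuration."""

    name: str
    params: dict = field(default_factory=dict)


#: Registry of kernels: name -> factory(params, io) -> per-query callable
#: returning one serialized record line.
KERNELS: dict[str, Callable] = {}


def register_kernel(name: str):
    def deco(factory):
        KERNELS[name] = factory
        return factory

    return deco


def format_hit_line(hit: Hit) -> str:
    score = int(hit.score) if float(hit.score).is_integer() else hit.score
    return (
        f"{hit.query_id}\t{hit.subject_id}\t{score}\t"
        f"{hit.query_span[0]}\t{hit.query_span[1]}\t"
        f"{hit.subject_span[0]}\t{hit.subject_span[1]}\thit"
    )


def format_nohit_line(query_id: str) -> str:
    return f"{query_id}\t-\t0\t0\t0\t0\t0\tno-hit"


@register_kernel("aligner")
def _aligner_kernel(params: dict, io):
    scheme = ScoringScheme(
        match=params.get("match", 2),
        mismatch=params.get("mismatch", -1),
        gap=params.get("gap", -2),
    )
    min_score = params.get("min_score", 1)
    db = io.database()

    def per_query(rec: SeqRecord) -> str:
        hits = sw_search(rec, db, scheme, top_k=1, min_score=min_score)
        return format_hit_line(hits[0]) if hits else format_nohit_line(rec.id)

    return per_query


@register_kernel("profiler")
def _profiler_kernel(params: dict, io):
    model = params.get("model")
    if model is None:
        path = params.get("model_path")
        if path is None:
            raise ValidationError("profiler kernel needs 'model' or 'model_path'")
        model = load_profile(path)
    threshold = params.get("threshold", 0.0)

    def per_query(rec: SeqRecord) -> str:
        hit = profile_scan(rec, model, threshold)
        return format_hit_line(hit) if hit else format_nohit_line(rec.id)

    return per_query


def tool_run_batch(tool: ToolSpec, io) -> None:
    """Run a kernel over one batch through its virtual I/O session.

    Reads the batch queries (and database) only through ``io``; writes one
    record per query. A query on which the kernel raises is recorded as a
    failure entry and the rest of the batch proceeds.
    """
    if tool.name not in KERNELS:
        raise ValidationError(f"unknown kernel {tool.name!r}")
    per_query = KERNELS[tool.name](tool.params, io)
    for rec in parse_fasta(io.query_stream()):
        try:
            line = per_query(rec)
        except Exception as exc:  # per-query failure policy: record and continue
            io.write_failure(rec.id, f"{type(exc).__name__}: {exc}")
            continue
        io.write(rec.id, line)
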