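"""FASTA I/O, query batching, and synthetic workload generators.

The generators reproduce the weak-scaling study conditions used to exercise
wrapped sequence-analysis tools: an aligner workload of 16 queries per core,
each 200 amino acids long; a profile-scanner workload of 760 sequences per
core; and a multiple-sequence-alignment workload of 10 related-sequence
datasets per core. Sequence content is synthetic (seeded uniform draws over
the 20 standard amino acids); only the counts, lengths, and within-dataset
relatedness that the scheduling/IO machinery is sensitive to are emulated.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, FastaParseError, ProtocolError, ValidationError

#: The 20 standard amino acids, used for generated sequence content.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: 20 standard amino acids plus the ambiguity code X.
ALPHABET = AA20 + "X"
_ALLOWED = frozenset(ALPHABET)

#: Length distribution specs: ("fixed", L) or ("uniform", lo, hi) inclusive.
LengthLaw = tuple


@dataclass(frozen=True)
class SeqRecord:
    """One named amino-acid sequence.

    ``id`` must be a non-empty whitespace-free token; ``residues`` must be
    uppercase letters from :data:`ALPHABET`.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains invalid residues {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def parse_fasta(source: str | IO[str]) -> list[SeqRecord]:
    """Parse FASTA text into a list of :class:`SeqRecord`.

    Wrapped sequence lines are concatenated and blank lines ignored; input
    order is preserved. Lowercase residues are upcased with a single warning
    per stream. Raises :class:`FastaParseError` on a duplicate id (naming the
    id), on a residue outside the alphabet (naming the line number), or on a
    record with no sequence. ``*`` characters are rejected.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_parts: list[str] = []
    warned_lower = False

    def flush() -> None:
        nonlocal cur_id, cur_desc, cur_parts
        if cur_id is None:
            return
        if not cur_parts:
            raise FastaParseError(f"record {cur_id!r} has an empty sequence")
        records.append(SeqRecord(cur_id, "".join(cur_parts), cur_desc))
        cur_id, cur_desc, cur_parts = None, "", []

    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            head = line[1:].strip()
            if not head:
                raise FastaParseError(f"empty FASTA header at line {lineno}")
            parts = head.split(None, 1)
            rec_id = parts[0]
            if rec_id in seen:
                raise FastaParseError(f"duplicate id {rec_id}")
            seen.add(rec_id)
            cur_id = rec_id
            cur_desc = parts[1] if len(parts) > 1 else ""
        else:
            if cur_id is None:
                raise FastaParseError(
                    f"sequence data before first header at line {lineno}"
                )
            if any(c.islower() for c in line):
                if not warned_lower:
                    warnings.warn(
                        "lowercase residues upcased during FASTA parse",
                        stacklevel=2,
                    )
                    warned_lower = True
                line = line.upper()
            bad = set(line) - _ALLOWED
            if bad:
                raise FastaParseError(
                    f"invalid residue characters {sorted(bad)!r} at line {lineno}"
                )
            cur_parts.append(line)
    flush()
    return records


def write_fasta(
    records: Iterable[SeqRecord], sink: IO[str], wrap_width: int = 60
) -> int:
    """Write records as FASTA; returns the number of bytes written.

    Output re-parses (via :func:`parse_fasta`) to an identical collection;
    sequence lines are at most ``wrap_width`` residues.
    """
    if wrap_width < 1:
        raise ValidationError("wrap_width must be >= 1")
    from Bio.Seq import Seq
    from Bio.SeqIO.FastaIO import FastaWriter
    from Bio.SeqRecord import SeqRecord as _BioRecord

    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    buf = io.StringIO()
    FastaWriter(buf, wrap=wrap_width).write_file(bio)
    text = buf.getvalue()
    sink.write(text)
    return len(text.encode("utf-8"))


# ---------------------------------------------------------------------------
# Workload generation
# ---------------------------------------------------------------------------

_TOOL_KINDS = ("aligner", "profiler", "msa")

_DEFAULTS = {
    # per-core query multiplier and query length for the weak-scaling profiles
    "aligner": dict(queries_per_core=16, query_length=200),
    "profiler": dict(queries_per_core=760, length_law=("uniform", 100, 400)),
    "msa": dict(datasets_per_core=10, seqs_per_dataset=10),
}


@dataclass(frozen=True)
class WorkloadProfile:
    """Weak-scaling workload definition tying problem size to core count."""

    tool_kind: str
    cores: int
    queries_per_core: int = 16
    query_length: int = 200
    datasets_per_core: int = 10
    seqs_per_dataset: int = 10
    seed: int = 0
    #: length distribution for profiler queries; aligner uses query_length.
    length_law: LengthLaw = ("uniform", 100, 400)
    #: per-site substitution rate for msa dataset mutants.
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.tool_kind not in _TOOL_KINDS:
            raise ConfigError(f"unknown tool_kind {self.tool_kind!r}")
        for name in (
            "cores",
            "queries_per_core",
            "query_length",
            "datasets_per_core",
            "seqs_per_dataset",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")

    @classmethod
    def make(cls, tool_kind: str, cores: int, seed: int = 0, **overrides):
        """Build a profile with the per-tool defaults applied."""
        if tool_kind not in _TOOL_KINDS:
            raise ConfigError(f"unknown tool_kind {tool_kind!r}")
        kw = dict(_DEFAULTS[tool_kind])
        kw.update(overrides)
        return cls(tool_kind=tool_kind, cores=cores, seed=seed, **kw)


@dataclass(frozen=True)
class WorkloadBundle:
    """Generated workload: flat queries (aligner/profiler) or msa datasets."""

    profile: WorkloadProfile
    queries: tuple[SeqRecord, ...] = ()
    datasets: tuple[tuple[SeqRecord, ...], ...] = ()


def _random_residues(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AA20), size=length)
    return "".join(AA20[i] for i in idx)


def _draw_lengths(law: LengthLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    if not law or law[0] not in ("fixed", "uniform"):
        raise ConfigError(f"unknown length law {law!r}")
    if law[0] == "fixed":
        (_, length) = law
        if length < 1:
            raise ConfigError("fixed length must be >= 1")
        return np.full(n, int(length))
    (_, lo, hi) = law
    if not 1 <= lo <= hi:
        raise ConfigError(f"bad uniform length bounds {law!r}")
    return rng.integers(int(lo), int(hi) + 1, size=n)


def gen_workload(profile: WorkloadProfile) -> WorkloadBundle:
    """Generate the synthetic workload a profile describes.

    aligner: ``cores * queries_per_core`` queries, all ``query_length`` long.
    profiler: ``cores * queries_per_core`` queries with lengths drawn from
    ``profile.length_law``.  msa: ``cores * datasets_per_core`` datasets of
    ``seqs_per_dataset`` related sequences each (seeded point mutants of a
    per-dataset ancestor, emulating hit sets returned by a prior alignment
    search). Identical profile (including seed) yields an identical bundle.
    """
    rng = np.random.default_rng(profile.seed)
    if profile.tool_kind in ("aligner", "profiler"):
        n = profile.cores * profile.queries_per_core
        if profile.tool_kind == "aligner":
            lengths = np.full(n, profile.query_length)
        else:
            lengths = _draw_lengths(profile.length_law, n, rng)
        queries = tuple(
            SeqRecord(f"q{i:06d}", _random_residues(rng, int(lengths[i])))
            for i in range(n)
        )
        return WorkloadBundle(profile, queries=queries)

    datasets: list[tuple[SeqRecord, ...]] = []
    n_sets = profile.cores * profile.datasets_per_core
    for d in range(n_sets):
        anc_len = int(rng.integers(200, 401))
        ancestor = np.array(list(_random_residues(rng, anc_len)))
        members: list[SeqRecord] = []
        for s in range(profile.seqs_per_dataset):
            seq = ancestor.copy()
            mask = rng.random(anc_len) < profile.mutation_rate
            if mask.any():
                cur = np.array([AA20.index(c) for c in seq[mask]])
                shift = rng.integers(1, len(AA20), size=int(mask.sum()))
                seq[mask] = [AA20[(c + k) % len(AA20)] for c, k in zip(cur, shift)]
            members.append(SeqRecord(f"d{d:04d}_s{s:03d}", "".join(seq)))
        datasets.append(tuple(members))
    return WorkloadBundle(profile, datasets=tuple(datasets))


def gen_database(
    n_records: int, length_law: LengthLaw = ("uniform", 100, 400), seed: int = 0
) -> list[SeqRecord]:
    """Generate a synthetic reference database of unique-id sequences."""
    if n_records < 1:
        raise ValidationError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(length_law, n_records, rng)
    return [
        SeqRecord(f"db{i:06d}", _random_residues(rng, int(lengths[i])))
        for i in range(n_records)
    ]


# ---------------------------------------------------------------------------
# Work batches
# ---------------------------------------------------------------------------

_BATCH_STATES = ("pending", "assigned", "done")


@dataclass
class WorkBatch:
    """Unit of dispatch: an ordered set of query ids with assignment state."""

    batch_id: int
    query_ids: tuple[str, ...]
    state: str = "pending"
    assigned_worker: int | None = None

    def assign(self, worker_id: int) -> None:
        if self.state != "pending":
            raise ProtocolError(
                f"batch {self.batch_id} cannot be assigned from state {self.state}"
            )
        self.state = "assigned"
        self.assigned_worker = worker_id

    def finish(self) -> None:
        if self.state != "assigned":
            raise ProtocolError(
                f"batch {self.batch_id} cannot finish from state {self.state}"
            )
        self.state = "done"


def make_batches(
    records: Sequence[SeqRecord] | Sequence[str], batch_size: int
) -> list[WorkBatch]:
    """Partition query ids into consecutive batches of ``batch_size``.

    Order is preserved; all batches are full except possibly the last; the
    union of ids equals the input exactly once.
    """
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    ids = [r.id if isinstance(r, SeqRecord) else r for r in records]
    return [
        WorkBatch(b, tuple(ids[i : i + batch_size]))
        for b, i in enumerate(range(0, len(ids), batch_size))
    ]


# ---------------------------------------------------------------------------
# Workload persistence (FASTA + YAML sidecar)
# ---------------------------------------------------------------------------

def write_workload(bundle: WorkloadBundle, out: str | Path, wrap_width: int = 60) -> Path:
    """Persist a bundle: one FASTA (aligner/profiler) or a directory of
    per-dataset FASTA files (msa), plus a YAML sidecar recording the profile.

    Returns the sidecar path.
    """
    out = Path(out)
    profile_doc = asdict(bundle.profile)
    profile_doc["length_law"] = list(bundle.profile.length_law)
    if bundle.profile.tool_kind == "msa":
        out.mkdir(parents=True, exist_ok=True)
        for d, members in enumerate(bundle.datasets):
            with open(out / f"dataset_{d:04d}.fasta", "w") as fh:
                write_fasta(members, fh, wrap_width)
        sidecar = out / "workload.yaml"
    else:
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w") as fh:
            write_fasta(bundle.queries, fh, wrap_width)
        sidecar = out.with_name(out.name + ".workload.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"workload_profile": profile_doc}, fh, sort_keys=True)
    return sidecar
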