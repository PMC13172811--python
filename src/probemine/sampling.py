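"""Read streaming and uniform subsampling of FASTQ/FASTA files.

Large sequencing files are screened on a random subset of records: the
extraction ratio is an integer percentage in [1, 100], with a floor of
5,000 records for FASTQ files (small subsamples of read data are too
noisy to interpret; FASTA inputs, typically assembled sequences, have
no floor). FASTQ subsampling is double-pass — count records first, draw
sorted indices, then copy exactly those records — so files never need
to fit in memory; FASTA files are small enough to sample in memory.
"""

from __future__ import annotations

import gzip
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "SamplingPlan",
    "SeqFileError",
    "FASTQ_FLOOR",
    "detect_format",
    "open_text",
    "read_seq_file",
    "count_records",
    "plan_sample",
    "extract_sample",
]

#: Minimum FASTQ sample size enforced regardless of ratio.
FASTQ_FLOOR = 5000

_FASTQ_EXTS = (".fastq", ".fq")
_FASTA_EXTS = (".fasta", ".fa", ".fna")


class SeqFileError(ValueError):
    """A sequence file is malformed or inconsistent between passes."""


@dataclass(frozen=True)
class SeqRecord:
    """One read or sequence; quality is present for FASTQ only."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqFileError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise SeqFileError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


def detect_format(path: str | Path) -> str:
    """Infer ``"fastq"`` or ``"fasta"`` from the file extension."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix
    if suffix in _FASTQ_EXTS:
        return "fastq"
    if suffix in _FASTA_EXTS:
        return "fasta"
    raise SeqFileError(f"unrecognized sequence file extension: {Path(path).name}")


def _is_gzip(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(2) == b"\x1f\x8b"
    except OSError:
        return path.name.endswith(".gz")


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text, detecting gzip by magic bytes."""
    path = Path(path)
    if "r" in mode and _is_gzip(path):
        return gzip.open(path, mode)
    if "w" in mode and path.name.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq(handle: IO[str], path: str) -> Iterator[SeqRecord]:
    """Strict 4-line FASTQ records, with line numbers in errors."""
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise SeqFileError(
                f"{path}: line {lineno}: expected '@' FASTQ header, got {header[:30]!r}"
            )
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise SeqFileError(
                f"{path}: truncated FASTQ record starting at line {lineno} "
                "(file is not a multiple of 4 lines)"
            )
        lineno += 3
        if not plus.startswith("+"):
            raise SeqFileError(
                f"{path}: line {lineno - 1}: expected '+' separator, got {plus[:30]!r}"
            )
        yield SeqRecord(id=header[1:].split()[0] if header[1:] else "",
                        sequence=seq, quality=qual)


def read_seq_file(path: str | Path, fmt: str | None = None) -> Iterator[SeqRecord]:
    """Stream records from a FASTQ/FASTA file, plain or gzipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or detect_format(path)
    with open_text(path) as handle:
        if fmt == "fastq":
            yield from _parse_fastq(handle, str(path))
        elif fmt == "fasta":
            for rec in SeqIO.parse(handle, "fasta"):
                yield SeqRecord(id=rec.id, sequence=str(rec.seq))
        else:
            raise SeqFileError(f"unsupported format {fmt!r}")


def count_records(path: str | Path, fmt: str | None = None) -> int:
    """First pass: count records without holding them in memory."""
    path = Path(path)
    fmt = fmt or detect_format(path)
    if fmt == "fastq":
        with open_text(path) as handle:
            lines = sum(1 for _ in handle)
        if lines % 4:
            raise SeqFileError(
                f"{path}: FASTQ line count {lines} is not a multiple of 4"
            )
        return lines // 4
    return sum(1 for _ in read_seq_file(path, fmt))


@dataclass(frozen=True)
class SamplingPlan:
    """Which records of an N-record file to keep.

    ``target`` is ``min(N, max(ceil(N*ratio/100), floor))`` where the
    floor is 5,000 for FASTQ and 1 for FASTA; ``indices`` are drawn
    uniformly without replacement and kept sorted so extraction
    preserves original record order.
    """

    total: int
    ratio: int
    target: int
    indices: tuple[int, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.indices) != self.target:
            raise ValueError("plan indices do not match target count")


def plan_sample(total: int, ratio: int, fmt: str = "fastq",
                seed: int | None = None) -> SamplingPlan:
    """Plan a uniform without-replacement subsample.

    Parameters
    ----------
    total
        Record count from the first pass.
    ratio
        Integer extraction percentage in [1, 100].
    """
    if not (1 <= ratio <= 100):
        raise ValueError(f"extraction ratio must be an integer in [1, 100], got {ratio}")
    if total < 0:
        raise ValueError("record count must be >= 0")
    floor = FASTQ_FLOOR if fmt == "fastq" else 1
    target = min(total, max(math.ceil(total * ratio / 100), floor))
    if ratio == 100 or target == total:
        indices = tuple(range(total))
    else:
        rng = random.Random(seed)
        indices = tuple(sorted(rng.sample(range(total), target)))
    return SamplingPlan(total=total, ratio=ratio, target=target,
                        indices=indices, seed=seed)


def extract_sample(path: str | Path, plan: SamplingPlan,
                   out_path: str | Path) -> int:
    """Second pass: copy exactly the planned records to ``out_path``.

    FASTQ output is gzip-compressed when ``out_path`` ends in ``.gz``.
    Raises if the file's record count changed since the plan was made.
    Returns the number of records written.
    """
    path = Path(path)
    out_path = Path(out_path)
    fmt = detect_format(path)
    wanted = set(plan.indices)
    written = 0
    seen = 0
    with open_text(out_path, "wt") as out:
        if fmt == "fastq":
            # Copy raw 4-line blocks verbatim so sampled records are
            # byte-identical to the source.
            with open_text(path) as handle:
                idx = 0
                while True:
                    block = [handle.readline() for _ in range(4)]
                    if not block[0]:
                        break
                    if not block[3].endswith("\n") and block[3] == "":
                        raise SeqFileError(
                            f"{path}: truncated FASTQ record at index {idx}"
                        )
                    seen += 1
                    if idx in wanted:
                        out.writelines(block)
                        written += 1
                    idx += 1
        else:
            with open_text(path) as handle:
                for idx, rec in enumerate(SeqIO.parse(handle, "fasta")):
                    seen += 1
                    if idx in wanted:
                        out.write(f">{rec.description}\n{rec.seq}\n")
                        written += 1
    if seen != plan.total:
        raise SeqFileError(
            f"{path}: file changed between passes "
            f"(planned for {plan.total} records, found {seen})"
        )
    return written
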