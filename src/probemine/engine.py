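"""Screening orchestration: sampling, batching, parallel scoring, aggregation.

Each input file is subsampled (per the sampling module), split into
batches of records, and every batch is scored against the whole probe
panel. Batches may run across a process pool; workers receive the panel
once through the pool initializer. Because per-probe counts are merged
by elementwise addition, the results are identical for any worker count
or batch size — parallelism is an implementation detail, never a source
of nondeterminism.
"""

from __future__ import annotations

import logging
import os
import tempfile
import time
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .matching import MatchConfig, MatchRecord, score_read
from .probes import ProbePanel
from .sampling import (SeqRecord, count_records, detect_format, extract_sample,
                       plan_sample, read_seq_file)

__all__ = [
    "ScreenConfig",
    "FileSummary",
    "RunSummary",
    "screen_batch",
    "merge_counts",
    "run_screen",
]

log = logging.getLogger("probemine")


@dataclass(frozen=True)
class ScreenConfig:
    """Run-level parameters for a screen."""

    match: MatchConfig = field(default_factory=MatchConfig)
    extract_ratio: int = 100
    batch_size: int = 500
    jobs: int | None = None  # None: one worker per CPU, capped at batch count
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.jobs is not None and self.jobs < 1:
            raise ValueError("jobs must be >= 1")


@dataclass
class FileSummary:
    """Per-file screening result.

    ``total_selected`` is the sampled record count and is the denominator
    for every probe's percentage — reads excluded from a given probe for
    being shorter than it still count toward the denominator.
    """

    file: str
    total_selected: int
    counts: dict[str, int]
    excluded: dict[str, int]
    matches: list[MatchRecord] = field(default_factory=list)
    error: str | None = None

    def percentage(self, probe_name: str) -> float:
        if self.total_selected == 0:
            return 0.0
        return 100.0 * self.counts[probe_name] / self.total_selected


@dataclass
class RunSummary:
    """Whole-run result: one FileSummary per input file, in input order."""

    files: list[FileSummary]
    probe_names: list[str]
    config: ScreenConfig
    elapsed: float = 0.0


def screen_batch(records: Sequence[SeqRecord], panel: ProbePanel,
                 config: MatchConfig, file_tag: str = ""):
    """Score a batch of records against every probe in the panel.

    Returns ``(counts, excluded, matches)``: per-probe matched-record
    counts, per-probe excluded-record counts (read shorter than probe),
    and the individual MatchRecords. A record matched by k probes
    contributes one count to each of the k probes; a record matching a
    single probe on both strands still counts once.
    """
    counts = {p.name: 0 for p in panel}
    excluded = {p.name: 0 for p in panel}
    matches: list[MatchRecord] = []
    for rec in records:
        for probe in panel:
            outcome = score_read(rec, probe, config, file_tag=file_tag)
            if outcome.status == "match":
                counts[probe.name] += 1
                matches.append(outcome.record)
            elif outcome.status == "excluded":
                excluded[probe.name] += 1
    return counts, excluded, matches


def merge_counts(partials: Iterable[dict[str, int]]) -> dict[str, int]:
    """Elementwise sum of per-probe count dicts (associative, order-free)."""
    merged: dict[str, int] | None = None
    for part in partials:
        if merged is None:
            merged = dict(part)
        else:
            if set(part) != set(merged):
                raise ValueError("count dicts cover different probe sets")
            for k, v in part.items():
                merged[k] += v
    return merged if merged is not None else {}


def _batched(records: Iterable[SeqRecord], size: int) -> Iterator[list[SeqRecord]]:
    batch: list[SeqRecord] = []
    for rec in records:
        batch.append(rec)
        if len(batch) == size:
            yield batch
            batch = []
    if batch:
        yield batch


# Worker-side state, populated once per process by the pool initializer.
_WORKER_PANEL: ProbePanel | None = None
_WORKER_CONFIG: MatchConfig | None = None


def _init_worker(panel: ProbePanel, config: MatchConfig) -> None:
    global _WORKER_PANEL, _WORKER_CONFIG
    _WORKER_PANEL = panel
    _WORKER_CONFIG = config


def _score_batch_worker(args):
    records, file_tag = args
    return screen_batch(records, _WORKER_PANEL, _WORKER_CONFIG, file_tag=file_tag)


def _file_seed(seed: int | None, path: Path) -> int | None:
    """Stable per-file seed so results do not depend on file order."""
    if seed is None:
        return None
    return (seed * 2654435761 + zlib.crc32(path.name.encode())) % (2**31)


def _screen_records(records: Iterable[SeqRecord], panel: ProbePanel,
                    config: ScreenConfig, file_tag: str):
    batches = [(batch, file_tag)
               for batch in _batched(records, config.batch_size)]
    if not batches:
        zero = {p.name: 0 for p in panel}
        return dict(zero), dict(zero), [], 0

    jobs = config.jobs if config.jobs is not None else (os.cpu_count() or 1)
    jobs = min(jobs, len(batches))
    if jobs > 1:
        with ProcessPoolExecutor(max_workers=jobs, initializer=_init_worker,
                                 initargs=(panel, config.match)) as pool:
            results = list(pool.map(_score_batch_worker, batches))
    else:
        results = [screen_batch(b, panel, config.match, file_tag=t)
                   for b, t in batches]

    counts = merge_counts(r[0] for r in results)
    excluded = merge_counts(r[1] for r in results)
    matches = [m for r in results for m in r[2]]
    total = sum(len(b) for b, _ in batches)
    return counts, excluded, matches, total


def _screen_one_file(path: Path, panel: ProbePanel, config: ScreenConfig,
                     tmp_dir: Path) -> FileSummary:
    fmt = detect_format(path)
    total = count_records(path, fmt)
    plan = plan_sample(total, config.extract_ratio, fmt,
                       seed=_file_seed(config.seed, path))
    if plan.target == plan.total:
        records = read_seq_file(path, fmt)
    elif fmt == "fastq":
        # Double-pass extraction to a temporary gzip file, then stream it.
        sampled = tmp_dir / (path.name.removesuffix(".gz") + ".sampled.gz")
        extract_sample(path, plan, sampled)
        records = read_seq_file(sampled, fmt)
    else:
        # FASTA: in-memory selection.
        all_records = list(read_seq_file(path, fmt))
        records = [all_records[i] for i in plan.indices]

    counts, excluded, matches, selected = _screen_records(
        records, panel, config, file_tag=path.name)
    if selected != plan.target:
        raise RuntimeError(
            f"{path}: screened {selected} records but plan selected {plan.target}")
    return FileSummary(file=path.name, total_selected=selected,
                       counts=counts, excluded=excluded, matches=matches)


def run_screen(files: Sequence[str | Path], panel: ProbePanel,
               config: ScreenConfig) -> RunSummary:
    """Screen a list of files against a panel.

    Unreadable or malformed files are recorded as failed entries (zero
    counts plus an error note) and the run continues.
    """
    start = time.perf_counter()
    summaries: list[FileSummary] = []
    with tempfile.TemporaryDirectory(prefix="probemine_") as tmp:
        tmp_dir = Path(tmp)
        for raw in files:
            path = Path(raw)
            try:
                summaries.append(_screen_one_file(path, panel, config, tmp_dir))
            except Exception as exc:  # noqa: BLE001 - failures must not abort the run
                log.warning("skipping %s: %s", path, exc)
                zero = {p.name: 0 for p in panel}
                summaries.append(FileSummary(
                    file=path.name, total_selected=0, counts=dict(zero),
                    excluded=dict(zero), error=str(exc)))
    elapsed = time.perf_counter() - start
    return RunSummary(files=summaries, probe_names=panel.names,
                      config=config, elapsed=elapsed)
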