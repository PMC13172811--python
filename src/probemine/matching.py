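"""Fuzzy probe-vs-read scoring and match decisions.

The similarity metric is the *indel ratio*: ``100 * 2 * LCS(a, b) /
(|a| + |b|)``, equivalently ``100 * (1 - d / (|a| + |b|))`` where ``d``
is the insertion/deletion edit distance (a substitution costs one
deletion plus one insertion). The *partial ratio* of a probe against a
read is the maximum indel ratio over every contiguous substring of the
read, so a probe embedded anywhere in a longer read can still score 100.

A read matches a probe when the best score over both strands and all
IUPAC expansions is greater than or equal to the configured threshold
(inclusive). Reads shorter than the probe are excluded from matching
altogether. Scores are kept as exact reals; nothing is rounded before
the threshold comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from .probes import IUPAC_COMPLEMENT, Probe

__all__ = [
    "MatchConfig",
    "MatchRecord",
    "ScoreOutcome",
    "indel_ratio",
    "partial_ratio_score",
    "partial_ratio_bruteforce",
    "score_read",
]

_READ_RC_TABLE = str.maketrans(IUPAC_COMPLEMENT)


@dataclass(frozen=True)
class MatchConfig:
    """Screening parameters.

    threshold
        Match percentage in [0, 100]; a read is retained when its best
        score is >= threshold. 100 demands an exact substring occurrence
        of some expansion; 95 tolerates roughly one substitution in a
        20-mer (score 95.0) or one indel (score ~97.4).
    """

    threshold: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 100):
            raise ValueError(f"threshold must be in [0, 100], got {self.threshold}")


@dataclass(frozen=True)
class MatchRecord:
    """One qualifying (read, probe) hit."""

    read_id: str
    probe_name: str
    score: float
    strand: str  # "+" or "-"
    file_tag: str = ""
    sequence: str = ""  # matched read bases, kept for FASTA export


@dataclass(frozen=True)
class ScoreOutcome:
    """Result of scoring one read against one probe.

    status is one of ``"match"``, ``"no_match"``, ``"excluded"``
    (read shorter than the probe — no score is computed).
    """

    status: str
    score: float | None = None
    strand: str | None = None
    record: MatchRecord | None = None


@lru_cache(maxsize=65536)
def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr.setflags(write=False)
    return arr


def _read_reverse_complement(seq: str) -> str:
    # Lenient on purpose: raw reads may carry odd characters; anything
    # without a complement passes through and simply never matches.
    return seq.translate(_READ_RC_TABLE)[::-1]


def indel_ratio(a: str, b: str) -> float:
    """Indel similarity of two sequences, in [0, 100]."""
    if not a or not b:
        raise ValueError("indel_ratio requires non-empty sequences")
    return _kernels.indel_ratio_kernel(_encode(a), _encode(b))


def partial_ratio_score(probe_seq: str, read_seq: str) -> float:
    """Best indel ratio of the probe against any substring of the read.

    Requires ``|read_seq| >= |probe_seq|``; shorter reads must be
    excluded by the caller.
    """
    if not probe_seq or not read_seq:
        raise ValueError("partial_ratio_score requires non-empty sequences")
    if len(read_seq) < len(probe_seq):
        raise ValueError(
            f"read (length {len(read_seq)}) shorter than probe "
            f"(length {len(probe_seq)}); such reads are excluded upstream"
        )
    return _kernels.partial_ratio_kernel(_encode(probe_seq), _encode(read_seq))


def partial_ratio_bruteforce(probe_seq: str, read_seq: str) -> float:
    """Reference scorer: exhaustive enumeration of every read substring.

    Same contract as :func:`partial_ratio_score`; kept as the slow,
    obviously-correct implementation that the production scorer (and
    synthetic-fixture certification) are checked against.
    """
    if not probe_seq or not read_seq:
        raise ValueError("partial_ratio_bruteforce requires non-empty sequences")
    if len(read_seq) < len(probe_seq):
        raise ValueError("read shorter than probe")
    return _kernels.oracle_kernel(_encode(probe_seq), _encode(read_seq))


def score_read(read, probe: Probe, config: MatchConfig,
               file_tag: str = "") -> ScoreOutcome:
    """Score one read against one (possibly degenerate) probe.

    The score is the maximum over all probe expansions and both read
    orientations (the reverse strand compares expansions against the
    reverse complement of the read). Ties between strands report "+".

    Parameters
    ----------
    read
        Any object with ``id`` and ``sequence`` attributes.
    """
    seq = read.sequence.upper()
    if len(seq) < probe.length:
        return ScoreOutcome(status="excluded")

    fwd = _encode(seq)
    rev = _encode(_read_reverse_complement(seq))

    best = 0.0
    best_strand = "+"
    for strand, arr in (("+", fwd), ("-", rev)):
        for expansion in probe.expansions:
            s = _kernels.partial_ratio_kernel(_encode(expansion), arr)
            if s > best:
                best = s
                best_strand = strand
            if best == 100.0:
                # "+" is scanned first, so a later "-" hit at 100 is not a tie.
                break
        if best == 100.0:
            break

    if best >= config.threshold:
        record = MatchRecord(
            read_id=read.id,
            probe_name=probe.name,
            score=best,
            strand=best_strand,
            file_tag=file_tag,
            sequence=read.sequence,
        )
        return ScoreOutcome(status="match", score=best, strand=best_strand, record=record)
    return ScoreOutcome(status="no_match", score=best, strand=best_strand)
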