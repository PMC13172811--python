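"""Probe panels: FASTA ingestion, IUPAC expansion, reverse complement, ladders.

A *probe* is a short user-defined nucleotide sequence — typically a published
PCR primer or hybridization probe — screened against raw sequencing reads.
Probes may contain IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H, V, N);
a degenerate probe stands for every combinatorial expansion over {A,C,G,T},
all of which are matched independently during screening.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "Probe",
    "ProbePanel",
    "LadderSpec",
    "PanelFormatError",
    "ProbeValidationError",
    "ExpansionCapError",
    "expand_iupac",
    "reverse_complement",
    "parse_probe_fasta",
    "write_probe_fasta",
    "build_length_ladder",
]

# Alternatives listed in A < C < G < T order so expansions are deterministic.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)

#: Default refusal limit for combinatorial expansion of a single probe.
DEFAULT_EXPANSION_CAP = 4096


class PanelFormatError(ValueError):
    """The probe input is not structurally valid FASTA."""


class ProbeValidationError(ValueError):
    """A probe name or sequence violates the panel rules."""


class ExpansionCapError(ProbeValidationError):
    """A degenerate probe would expand into more sequences than allowed."""


def _validate_sequence(name: str, sequence: str) -> str:
    """Uppercase, normalize U->T and check the IUPAC alphabet.

    Raises :class:`ProbeValidationError` naming the offending position
    (0-based) and character.

    U (RNA-derived probes) is normalized to T, and inosine (I), which
    base-pairs indiscriminately in degenerate primers, to N.
    """
    if not sequence:
        raise ProbeValidationError(f"probe {name!r} has an empty sequence")
    seq = sequence.upper().replace("U", "T").replace("I", "N")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise ProbeValidationError(
                f"probe {name!r}: invalid character {ch!r} at position {pos}"
            )
    return seq


def degeneracy(sequence: str) -> int:
    """Number of unambiguous sequences a degenerate sequence stands for."""
    count = 1
    for ch in sequence:
        count *= len(IUPAC_CODES[ch])
    return count


def expand_iupac(sequence: str, cap: int | None = DEFAULT_EXPANSION_CAP) -> list[str]:
    """Expand a degenerate sequence into all unambiguous combinations.

    The order is deterministic: each position contributes its alternatives
    in A < C < G < T order, with the rightmost position varying fastest.

    Parameters
    ----------
    sequence
        Valid IUPAC nucleotide string (uppercase, no U).
    cap
        Refuse expansions larger than this; ``None`` disables the check.
        Degenerate primers are combinatorial — a 10-N probe alone would
        expand to ~10^6 sequences.
    """
    seq = _validate_sequence("<sequence>", sequence)
    n = degeneracy(seq)
    if cap is not None and n > cap:
        raise ExpansionCapError(
            f"sequence expands to {n} combinations, above the cap of {cap}; "
            "raise the cap explicitly to proceed"
        )
    return ["".join(combo) for combo in itertools.product(*(IUPAC_CODES[c] for c in seq))]


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide sequence."""
    seq = _validate_sequence("<sequence>", sequence)
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class Probe:
    """A named probe with its cached unambiguous expansions."""

    name: str
    sequence: str
    expansions: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_degenerate(self) -> bool:
        return len(self.expansions) > 1

    @classmethod
    def from_sequence(cls, name: str, sequence: str,
                      cap: int | None = DEFAULT_EXPANSION_CAP) -> "Probe":
        if not name:
            raise ProbeValidationError("probe name must be non-empty")
        seq = _validate_sequence(name, sequence)
        return cls(name=name, sequence=seq, expansions=tuple(expand_iupac(seq, cap=cap)))


@dataclass(frozen=True)
class ProbePanel:
    """An ordered, duplicate-free collection of probes."""

    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        if not self.probes:
            raise ProbeValidationError("probe panel is empty")
        seen: set[str] = set()
        for p in self.probes:
            if p.name in seen:
                raise ProbeValidationError(f"duplicate probe name {p.name!r}")
            seen.add(p.name)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def max_length(self) -> int:
        return max(p.length for p in self.probes)

    def __getitem__(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(name)


def parse_probe_fasta(text: str, cap: int | None = DEFAULT_EXPANSION_CAP) -> ProbePanel:
    """Parse a FASTA-formatted probe panel.

    Headers after ``>`` are taken verbatim (whitespace-trimmed) as probe
    names; multi-line sequences are concatenated. Sequences are uppercased
    and U is normalized to T, then expansions are computed and cached.
    """
    if not text or not text.strip():
        raise PanelFormatError("probe input is empty")
    lines = text.splitlines()
    first = next((ln for ln in lines if ln.strip()), "")
    if not first.lstrip().startswith(">"):
        raise PanelFormatError("probe input must start with a '>' FASTA header")

    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for ln in lines:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = stripped[1:].strip()
            if not name:
                raise ProbeValidationError("probe header with empty name")
            chunks = []
        else:
            chunks.append(stripped)
    if name is not None:
        records.append((name, "".join(chunks)))

    return ProbePanel(tuple(Probe.from_sequence(n, s, cap=cap) for n, s in records))


def write_probe_fasta(panel: ProbePanel) -> str:
    """Serialize a panel back to FASTA (one line per sequence)."""
    return "".join(f">{p.name}\n{p.sequence}\n" for p in panel)


@dataclass(frozen=True)
class LadderSpec:
    """Length ladder over a fixed unambiguous anchor sequence.

    Probes share the anchor's 5' end and grow by ``step`` bases toward the
    3' end — the construction used to study how probe length affects
    matched-read counts.
    """

    anchor: str
    min_len: int
    max_len: int
    step: int = 1

    def __post_init__(self) -> None:
        anchor = _validate_sequence("<anchor>", self.anchor)
        if degeneracy(anchor) != 1:
            raise ProbeValidationError("ladder anchor must be unambiguous (A/C/G/T only)")
        object.__setattr__(self, "anchor", anchor)
        if not (1 <= self.min_len <= self.max_len):
            raise ProbeValidationError("require 1 <= min_len <= max_len")
        if self.max_len > len(anchor):
            raise ProbeValidationError(
                f"max_len {self.max_len} exceeds anchor length {len(anchor)}"
            )
        if self.step < 1:
            raise ProbeValidationError("step must be >= 1")


def build_length_ladder(spec: LadderSpec) -> ProbePanel:
    """Build the anchored prefix ladder: one probe per length.

    Probe names encode the length (``"5bp"``, ``"6bp"``, ...); each probe is
    a prefix of every longer one.
    """
    probes = [
        Probe.from_sequence(f"{length}bp", spec.anchor[:length])
        for length in range(spec.min_len, spec.max_len + 1, spec.step)
    ]
    return ProbePanel(tuple(probes))
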