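"""Ground-truthed synthetic read fixtures.

Generates FASTQ/FASTA files whose content is fully known: a probe-free
background plus planted probe copies carrying controlled substitution /
insertion / deletion loads on either strand. Every background read is
certified by the exhaustive reference scorer to stay below the screening
threshold for every panel probe, and every planted read is certified to
score exactly what the planted copy scores in isolation — so screening
counts can be asserted exactly, not probabilistically.

These fixtures emulate short-read screening inputs only in the respects
that matter to the matcher (alphabet, read length, planted occurrences,
strand); they carry flat qualities and uniform base composition, none of
the error or coverage structure of real sequencing data.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import _kernels
from .matching import _encode
from .probes import Probe, ProbePanel, reverse_complement
from .sampling import open_text

__all__ = [
    "PlantSpec",
    "PlantedCopy",
    "FixtureManifest",
    "mutate_sequence",
    "generate_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """How many copies of a probe to plant, and how mutated."""

    probe: Probe
    copies: int
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if min(self.substitutions, self.insertions, self.deletions) < 0:
            raise ValueError("mutation counts must be >= 0")
        if self.substitutions + self.insertions + self.deletions > self.probe.length:
            raise ValueError("total mutation load exceeds probe length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.probe.expansions) != 1:
            raise ValueError("planting requires an unambiguous probe")


@dataclass(frozen=True)
class PlantedCopy:
    """Ground truth for one planted occurrence."""

    probe_name: str
    read_id: str
    read_index: int
    position: int
    strand: str
    planted_sequence: str  # the (possibly mutated) copy, probe orientation
    isolated_score: float  # reference score of the probe vs the copy alone
    substitutions: int
    insertions: int
    deletions: int


@dataclass
class FixtureManifest:
    """Losslessly serializable record of everything a fixture contains."""

    path: str
    fmt: str
    n_reads: int
    read_len: int
    threshold: float
    seed: int
    probe_names: list[str]
    plants: list[PlantedCopy] = field(default_factory=list)

    def expected_counts(self, threshold: float) -> dict[str, int]:
        """Per-probe matched-read counts a screen at ``threshold`` must find.

        Valid for thresholds >= the certification threshold the fixture
        was generated with (below it the background is not certified).
        """
        if threshold < self.threshold:
            raise ValueError(
                f"fixture certified at threshold {self.threshold}; "
                f"counts at {threshold} are not ground truth"
            )
        counts = {name: 0 for name in self.probe_names}
        for plant in self.plants:
            if plant.isolated_score >= threshold:
                counts[plant.probe_name] += 1
        return counts

    def save(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        payload = json.loads(Path(path).read_text())
        payload["plants"] = [PlantedCopy(**p) for p in payload["plants"]]
        return cls(**payload)


def mutate_sequence(seq: str, substitutions: int = 0, insertions: int = 0,
                    deletions: int = 0, seed: int | None = None,
                    rng: random.Random | None = None) -> str:
    """Apply exact mutation counts at distinct random positions.

    Substitutions always change the base; deletions remove bases;
    insertions add random bases at random gaps. The output length is
    ``len(seq) + insertions - deletions``.
    """
    if substitutions + deletions > len(seq):
        raise ValueError(
            f"cannot place {substitutions} substitutions and {deletions} "
            f"deletions in a {len(seq)}-base sequence"
        )
    rng = rng if rng is not None else random.Random(seed)
    positions = rng.sample(range(len(seq)), substitutions + deletions)
    sub_pos = set(positions[:substitutions])
    del_pos = set(positions[substitutions:])
    out: list[str] = []
    for i, base in enumerate(seq):
        if i in del_pos:
            continue
        if i in sub_pos:
            out.append(rng.choice([b for b in _BASES if b != base]))
        else:
            out.append(base)
    for _ in range(insertions):
        gap = rng.randrange(len(out) + 1)
        out.insert(gap, rng.choice(_BASES))
    return "".join(out)


def _reference_score(probe_seq: str, target: str) -> float:
    """Reference scorer without the read>=probe length restriction."""
    return float(_kernels.oracle_kernel(_encode(probe_seq), _encode(target)))


def _read_score(panel_probe: Probe, read_seq: str) -> float:
    """Best reference score of a probe vs a read, both strands."""
    best = 0.0
    for oriented in (read_seq, reverse_complement(read_seq)):
        for expansion in panel_probe.expansions:
            if len(oriented) < len(expansion):
                continue
            best = max(best, _reference_score(expansion, oriented))
            if best == 100.0:
                return best
    return best


def _random_read(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _certified_background(rng: random.Random, length: int, panel: ProbePanel,
                          threshold: float, max_attempts: int = 200) -> str:
    for _ in range(max_attempts):
        read = _random_read(rng, length)
        if all(_read_score(p, read) < threshold for p in panel):
            return read
    raise RuntimeError(
        f"could not draw a background read scoring below {threshold} against "
        f"the panel after {max_attempts} attempts; lower the read length, "
        "raise the threshold, or use a less promiscuous panel"
    )


def generate_fixture(n_reads: int, read_len: int, plant_specs: list[PlantSpec],
                     panel: ProbePanel, threshold: float, fmt: str,
                     seed: int, out_path: str | Path,
                     max_attempts: int = 200) -> FixtureManifest:
    """Write a certified fixture file and return its manifest.

    Background reads are rejection-sampled until the reference scorer
    puts them strictly below ``threshold`` for every panel probe on both
    strands. Planted copies are inserted at random positions of randomly
    chosen distinct reads (reverse-complemented for strand '-'); each
    planted read is redrawn until its score against its own probe equals
    the copy's isolated score and it stays below threshold for every
    other probe, so the manifest is exact ground truth.
    """
    total_copies = sum(s.copies for s in plant_specs)
    if total_copies > n_reads:
        raise ValueError("more planted copies than reads")
    for spec in plant_specs:
        if read_len < spec.probe.length + spec.insertions:
            raise ValueError(
                f"read length {read_len} too short for probe "
                f"{spec.probe.name!r} with {spec.insertions} insertions"
            )

    rng = random.Random(seed)
    out_path = Path(out_path)
    reads = [_certified_background(rng, read_len, panel, threshold, max_attempts)
             for _ in range(n_reads)]

    plant_indices = rng.sample(range(n_reads), total_copies)
    manifest = FixtureManifest(
        path=str(out_path), fmt=fmt, n_reads=n_reads, read_len=read_len,
        threshold=threshold, seed=seed, probe_names=panel.names)

    cursor = 0
    for spec in plant_specs:
        probe_seq = spec.probe.expansions[0]
        for _ in range(spec.copies):
            idx = plant_indices[cursor]
            cursor += 1
            copy = mutate_sequence(probe_seq, spec.substitutions,
                                   spec.insertions, spec.deletions, rng=rng)
            isolated = _reference_score(probe_seq, copy)
            inserted = copy if spec.strand == "+" else reverse_complement(copy)
            placed = False
            for _ in range(max_attempts):
                pos = rng.randrange(read_len - len(inserted) + 1)
                background = _certified_background(rng, read_len, panel,
                                                   threshold, max_attempts)
                candidate = background[:pos] + inserted + background[pos + len(inserted):]
                own = _read_score(spec.probe, candidate)
                others_clean = all(
                    _read_score(p, candidate) < threshold
                    for p in panel if p.name != spec.probe.name)
                if own == isolated and others_clean:
                    reads[idx] = candidate
                    manifest.plants.append(PlantedCopy(
                        probe_name=spec.probe.name, read_id=f"read_{idx}",
                        read_index=idx, position=pos, strand=spec.strand,
                        planted_sequence=copy, isolated_score=isolated,
                        substitutions=spec.substitutions,
                        insertions=spec.insertions, deletions=spec.deletions))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not plant a copy of {spec.probe.name!r} whose "
                    f"in-read score equals its isolated score {isolated:.2f}"
                )

    with open_text(out_path, "wt") as fh:
        for i, seq in enumerate(reads):
            if fmt == "fastq":
                fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            elif fmt == "fasta":
                fh.write(f">read_{i}\n{seq}\n")
            else:
                raise ValueError(f"unsupported fixture format {fmt!r}")
    return manifest
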