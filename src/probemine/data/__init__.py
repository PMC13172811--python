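"""Bundled probe panels and reference sequences.

The panels are published primer/probe sets commonly used for screening:
``hiv`` (33 probes targeting HIV-1 subtypes plus beta-actin controls),
``coronavirus`` (119 probes spanning SARS-CoV-2, SARS-CoV, alpha- and
universal coronavirus primers, other viruses, CRFK cell markers and
beta-actin), and ``kras`` (21 probes for KRAS codon 12/13 mutation
screening). ``LADDER_ANCHOR`` is the 105-bp region of the HIV-1
reference genome (NC_001802) around probe SK30, used to build the
5-105 bp probe length ladder.
"""

from importlib import resources

from ..probes import ProbePanel, parse_probe_fasta

__all__ = ["LADDER_ANCHOR", "available_panels", "load_panel"]

#: 105-bp anchor on the HIV-1 reference; prefix of length 17 is probe SK30.
LADDER_ANCHOR = (
    "GGTCTGAGGGATCTCTAGTTACCAGAGTCACACAACAGACGGGCACACACTACTTGAAGC"
    "ACTCAAGGCAAGCTTTATTGAGGCTTAAGCAGTGGGTTCCCTAGT"
)


def available_panels() -> list[str]:
    root = resources.files(__package__) / "panels"
    return sorted(p.name.removesuffix(".fasta")
                  for p in root.iterdir() if p.name.endswith(".fasta"))


def load_panel(name: str) -> ProbePanel:
    """Load a bundled panel by name (``hiv``, ``coronavirus``, ``kras``)."""
    path = resources.files(__package__) / "panels" / f"{name}.fasta"
    return parse_probe_fasta(path.read_text())
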