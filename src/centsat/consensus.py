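"""Circular repeat consensus monomers and their dimer representation.

A tandem-satellite monomer (e.g. the 156-bp *Zea* CentC unit, or the
~180-bp knob180 unit found on maize chromosome arms) is a circular
sequence: genomic copies are concatenated head-to-tail, so a short read can
start at any rotation and span the monomer junction.  Representing the
monomer as a dimer (two concatenated copies) lets an ordinary local aligner
recover a full-length alignment for any rotation — the "dimer trick".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import InvalidSpecError

# Zea CentC consensus monomer, 156 bp.
CENTC_MONOMER = (
    "TGGTTCCGGTGGCAAAAACTCGTGCTTTGTATGCACCCCGACACCCGTTTTCGGAATGGGTGACGTGCGG"
    "CAACGAAATTGCGCGAAACCACCCCAAACATGAGTTTTGGACCTAAAGTAGTGGATTGGGCATGTTCGTT"
    "GCGAAAAACGAAGAAA"
)

# knob180 consensus monomer, 180 bp (non-centromeric contrast satellite).
KNOB180_MONOMER = (
    "TGGGGTGAGGTGTATGAGCCTCTGGTCGATGATCAATGGCCACACAACCCCCATTTTTGTCGAAAATAGC"
    "CATGAACGACCATTTTCAATAATACCGAAGGCTAACACCTACGGATTTTTGACCAAGAAATGGTCTCCAC"
    "CAGAAATCCAAGAATGTGATCTATGGCAAGGAAACATATG"
)


@dataclass(frozen=True)
class RepeatConsensus:
    """A named circular monomer and its derived dimer.

    Parameters
    ----------
    name : str
        Repeat family name (e.g. ``"CentC"``).
    monomer : str
        Monomer sequence; treated as circular.
    """

    name: str
    monomer: str
    dimer: str = field(init=False)

    def __post_init__(self):
        if not self.monomer:
            raise InvalidSpecError("consensus monomer must be non-empty")
        mono = self.monomer.upper()
        if set(mono) - set("ACGTN"):
            raise InvalidSpecError(f"invalid bases in monomer for {self.name!r}")
        object.__setattr__(self, "monomer", mono)
        object.__setattr__(self, "dimer", mono + mono)

    def __len__(self) -> int:
        return len(self.monomer)

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "RepeatConsensus":
        """Load the first record of a FASTA file as a monomer."""
        record = next(SeqIO.parse(str(path), "fasta"), None)
        if record is None:
            raise InvalidSpecError(f"no sequences in {path}")
        return cls(name=name or record.id, monomer=str(record.seq))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n{self.monomer}\n")


ZEA_CENTC = RepeatConsensus("CentC", CENTC_MONOMER)
KNOB180 = RepeatConsensus("knob180", KNOB180_MONOMER)

BUILTIN_CONSENSI = {c.name: c for c in (ZEA_CENTC, KNOB180)}
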