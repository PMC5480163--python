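"""Synthetic genomes, satellite arrays, cenH3 domains, and ChIP/input reads.

The generator emulates the statistical structure the downstream analysis
assumes: chromosomes whose background sequence is i.i.d. uniform over
{A,C,G,T} (so non-repetitive regions are effectively unique at desk scale,
the analog of a MAPQ-filterable complex centromere), tandem satellite
arrays whose copies deviate independently from a shared circular monomer by
a per-base substitution rate (~4% reproduces the observed ~96% identity of
genomic satellite copies to their consensus), cenH3 domains that weight
ChIP read sampling by a fold-enrichment factor, and uniform input reads.

All randomness flows from a single :class:`numpy.random.Generator`; a given
spec + seed reproduces byte-identical FASTA/FASTQ output.

Coordinates are 0-based half-open.  Reads are sampled with replacement and
emitted grouped by chromosome in spec order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import decode, encode, revcomp
from .consensus import BUILTIN_CONSENSI
from .errors import InvalidSpecError
from .readprep import Read, write_fastq


@dataclass(frozen=True)
class SatelliteArray:
    """A planted tandem array: ``copies`` mutated monomer copies in a row."""

    chrom: str
    start: int
    monomer_name: str
    copies: int
    sub_rate: float
    strand: str = "+"

    def length(self, monomer_len: int) -> int:
        return self.copies * monomer_len


@dataclass
class GenomeSpec:
    """Blueprint for a synthetic genome with planted satellite arrays.

    ``monomers`` maps monomer names to sequences; names present in
    :data:`centsat.consensus.BUILTIN_CONSENSI` (CentC, knob180) may be used
    without listing them.
    """

    chromosomes: list[tuple[str, int]]
    arrays: list[SatelliteArray] = field(default_factory=list)
    monomers: dict[str, str] = field(default_factory=dict)
    rng_seed: int = 0

    def monomer(self, name: str) -> str:
        if name in self.monomers:
            return self.monomers[name].upper()
        if name in BUILTIN_CONSENSI:
            return BUILTIN_CONSENSI[name].monomer
        raise InvalidSpecError(f"unknown monomer {name!r}")

    def validate(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise InvalidSpecError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise InvalidSpecError(f"chromosome {name!r} has length {length}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for arr in self.arrays:
            if arr.chrom not in sizes:
                raise InvalidSpecError(f"array on unknown chromosome {arr.chrom!r}")
            if not 0.0 <= arr.sub_rate <= 1.0:
                raise InvalidSpecError("substitution rate must be in [0, 1]")
            if arr.copies <= 0:
                raise InvalidSpecError("array copy count must be positive")
            if arr.strand not in "+-":
                raise InvalidSpecError("array strand must be + or -")
            end = arr.start + arr.length(len(self.monomer(arr.monomer_name)))
            if arr.start < 0 or end > sizes[arr.chrom]:
                raise InvalidSpecError(
                    f"array {arr} exceeds chromosome bounds (end {end})"
                )
            by_chrom.setdefault(arr.chrom, []).append((arr.start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise InvalidSpecError(f"overlapping arrays on {chrom}")


@dataclass
class CenH3DomainSpec:
    """cenH3 domains and the relative ChIP sampling weight of their bases.

    ``fold_enrichment = 1`` reproduces input statistics exactly.
    """

    domains: list[tuple[str, int, int]]
    fold_enrichment: float = 20.0

    def validate(self, chrom_sizes: dict[str, int]) -> None:
        if self.fold_enrichment <= 0:
            raise InvalidSpecError("fold_enrichment must be positive")
        for chrom, start, end in self.domains:
            if chrom not in chrom_sizes:
                raise InvalidSpecError(f"domain on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= chrom_sizes[chrom]:
                raise InvalidSpecError(f"domain ({chrom},{start},{end}) out of bounds")


@dataclass
class TruthSet:
    """Everything the generator knows: the genome plus planted truth.

    ``array_intervals`` are BED-style (chrom, start, end, name) records;
    ``copy_identities`` hold one row per planted monomer copy with its exact
    identity to the (unmutated) monomer.
    """

    genome: dict[str, str]
    array_intervals: list[tuple[str, int, int, str]]
    copy_identities: list[dict]
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def mean_identity(self) -> float:
        if not self.copy_identities:
            raise InvalidSpecError("no planted copies")
        return float(np.mean([row["identity"] for row in self.copy_identities]))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_arrays_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, name in self.array_intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")

    def write_domains_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.domains:
                fh.write(f"{chrom}\t{start}\t{end}\tcenH3\n")

    def write_identities_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tarray_start\tmonomer\tcopy_index\tidentity\n")
            for row in self.copy_identities:
                fh.write(
                    f"{row['chrom']}\t{row['array_start']}\t{row['monomer']}\t"
                    f"{row['copy_index']}\t{row['identity']:.6f}\n"
                )


def mutate_copy(monomer: str, sub_rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``sub_rate``.

    A substituted base is replaced by one of the 3 alternative bases chosen
    uniformly, so a substitution never silently matches the original; length
    is preserved (no indels in the default model).
    """
    if not monomer:
        raise InvalidSpecError("monomer must be non-empty")
    if not 0.0 <= sub_rate <= 1.0:
        raise InvalidSpecError("sub_rate must be in [0, 1]")
    codes = encode(monomer)
    if (codes > 3).any():
        raise InvalidSpecError("monomer must contain only A,C,G,T")
    mask = rng.random(len(codes)) < sub_rate
    shift = rng.integers(1, 4, size=len(codes))
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return decode(out)


def identity_to(monomer: str, copy: str) -> float:
    """Fraction of positions identical between a monomer and one copy."""
    codes_a, codes_b = encode(monomer), encode(copy)
    return float((codes_a == codes_b).mean())


def build_genome(spec: GenomeSpec, rng: np.random.Generator | None = None) -> TruthSet:
    """Materialize a :class:`GenomeSpec` into a genome and its truth set.

    Background sequence is drawn i.i.d. uniform over {A,C,G,T}; array
    intervals are overwritten with concatenated :func:`mutate_copy` outputs
    (reverse-complemented as a block for minus-strand arrays).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    genome: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    identities: list[dict] = []
    for name, length in spec.chromosomes:
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        for arr in sorted(
            (a for a in spec.arrays if a.chrom == name), key=lambda a: a.start
        ):
            monomer = spec.monomer(arr.monomer_name)
            copies = []
            for i in range(arr.copies):
                copy = mutate_copy(monomer, arr.sub_rate, rng)
                identities.append(
                    {
                        "chrom": name,
                        "array_start": arr.start,
                        "monomer": arr.monomer_name,
                        "copy_index": i,
                        "identity": identity_to(monomer, copy),
                    }
                )
                copies.append(copy)
            block = "".join(copies)
            if arr.strand == "-":
                block = revcomp(block)
            end = arr.start + len(block)
            codes[arr.start : end] = encode(block)
            intervals.append((name, arr.start, end, arr.monomer_name))
        genome[name] = decode(codes)
    return TruthSet(genome=genome, array_intervals=intervals, copy_identities=identities)


def _apply_errors(
    codes: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_reads(
    genome: dict[str, str],
    domains: CenH3DomainSpec | None,
    n_reads: int,
    rng: np.random.Generator,
    read_len: int = 150,
    channel: str = "input",
    error_rate: float = 0.002,
    base_quality: int = 35,
    low_q_tail: tuple[float, int, int] | None = None,
) -> list[Read]:
    """Draw single-end reads from a genome, optionally cenH3-enriched.

    Read start positions are sampled with per-base weight
    ``fold_enrichment`` inside cenH3 domains for the ``chip`` channel and
    uniformly for ``input``; strand is uniform; sequencing errors are i.i.d.
    substitutions at ``error_rate``; base qualities are constant
    ``base_quality`` unless ``low_q_tail=(fraction, tail_len, tail_q)``
    marks a fraction of reads with a low-quality 3' tail.

    Read descriptions carry the truth origin as ``chrom:start:strand``.
    """
    if channel not in ("chip", "input"):
        raise InvalidSpecError(f"unknown channel {channel!r}")
    if n_reads < 0:
        raise InvalidSpecError("n_reads must be >= 0")
    chrom_sizes = {name: len(seq) for name, seq in genome.items()}
    if not chrom_sizes:
        raise InvalidSpecError("empty genome")
    if read_len > min(chrom_sizes.values()):
        raise InvalidSpecError("read_len exceeds shortest chromosome")
    if domains is not None:
        domains.validate(chrom_sizes)
    if n_reads == 0:
        return []

    fold = domains.fold_enrichment if (domains and channel == "chip") else 1.0
    weights: dict[str, np.ndarray] = {}
    for name, size in chrom_sizes.items():
        n_starts = size - read_len + 1
        w = np.ones(n_starts)
        if fold != 1.0:
            for chrom, start, end in domains.domains:
                if chrom == name:
                    w[start : min(end, n_starts)] = fold
        weights[name] = w

    totals = np.array([weights[name].sum() for name in chrom_sizes])
    per_chrom = rng.multinomial(n_reads, totals / totals.sum())

    reads: list[Read] = []
    i_read = 0
    for (name, seq), k in zip(genome.items(), per_chrom):
        if k == 0:
            continue
        w = weights[name]
        starts = rng.choice(len(w), size=k, replace=True, p=w / w.sum())
        strands = rng.integers(0, 2, size=k)  # 0 = '+', 1 = '-'
        enc_chrom = encode(seq)
        idx = starts[:, None] + np.arange(read_len)[None, :]
        mat = enc_chrom[idx]
        minus = strands == 1
        if minus.any():
            mat[minus] = (3 - mat[minus])[:, ::-1]
        mat = _apply_errors(mat, error_rate, rng)
        if low_q_tail is not None:
            frac, tail_len, tail_q = low_q_tail
            tails = rng.random(k) < frac
        for j in range(k):
            qual = [base_quality] * read_len
            if low_q_tail is not None and tails[j]:
                qual[-low_q_tail[1] :] = [low_q_tail[2]] * low_q_tail[1]
            strand = "-" if strands[j] else "+"
            reads.append(
                Read(
                    id=f"{channel}_{i_read:07d}",
                    seq=decode(mat[j]),
                    qual=tuple(qual),
                    desc=f"{name}:{starts[j]}:{strand}",
                )
            )
            i_read += 1
    return reads


def simulate_circular_reads(
    monomer: str,
    n_reads: int,
    rng: np.random.Generator,
    read_len: int = 100,
    sub_rate: float = 0.0,
    error_rate: float = 0.0,
    base_quality: int = 35,
) -> tuple[list[Read], list[str]]:
    """Reads drawn from independently mutated copies of a circular monomer.

    Each read takes a fresh :func:`mutate_copy` of the monomer, a uniform
    rotation (so reads span the junction), and a uniform strand.  Returns
    the reads and their true strands (useful for consensus-oriented k-mer
    counting without re-alignment).
    """
    if read_len <= 0:
        raise InvalidSpecError("read_len must be positive")
    reads: list[Read] = []
    strands: list[str] = []
    for i in range(n_reads):
        copy = mutate_copy(monomer, sub_rate, rng)
        doubled = copy + copy
        # tile enough copies for read_len > monomer_len
        while len(doubled) < len(copy) + read_len:
            doubled += copy
        offset = int(rng.integers(0, len(copy)))
        seq = doubled[offset : offset + read_len]
        strand = "-" if rng.integers(0, 2) else "+"
        if strand == "-":
            seq = revcomp(seq)
        codes = _apply_errors(encode(seq), error_rate, rng)
        reads.append(
            Read(
                id=f"sat_{i:07d}",
                seq=decode(codes),
                qual=tuple([base_quality] * read_len),
                desc=f"circular:{offset}:{strand}",
            )
        )
        strands.append(strand)
    return reads, strands


def read_truth_origin(read: Read) -> tuple[str, int, str]:
    """Parse the ``chrom:start:strand`` truth tag written by the simulator."""
    chrom, start, strand = read.desc.rsplit(":", 2)
    return chrom, int(start), strand


def reads_overlapping_intervals(
    reads: Sequence[Read],
    intervals: Iterable[tuple[str, int, int]],
    read_len: int,
    min_overlap: int = 125,
) -> int:
    """Count reads whose true origin overlaps any interval by >= min_overlap.

    This is the read-level truth against which alignment-based repeat
    fractions are judged.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    n = 0
    for read in reads:
        chrom, start, _ = read_truth_origin(read)
        for s, e in by_chrom.get(chrom, ()):
            if min(start + read_len, e) - max(start, s) >= min_overlap:
                n += 1
                break
    return n


def write_reads(path: str | Path, reads: Sequence[Read]) -> int:
    """Write simulated reads as FASTQ (Phred+33)."""
    return write_fastq(path, reads)
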