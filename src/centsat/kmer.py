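"""k-mer homogenization spectra for satellite reads.

From a fixed-size sample of satellite reads, trimmed to a common length,
count every distinct k-mer (50-mers by default).  A perfectly homogenized
satellite — every genomic copy identical to the consensus — concentrates
all the k-mer mass on the ``monomer_len`` distinct k-mers a circular
monomer can produce, each at the analytic copy number

    (read_len - k + 1) * n_reads / monomer_len

(e.g. 51 * 30000 / 156 = 9807.7 for 30,000 100-nt reads of a 156-bp
monomer).  Polymorphic copies spread the same total mass over many more
distinct k-mers at much lower copy numbers; the copy-number histogram is
therefore a direct homogenization readout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import revcomp
from .errors import InvalidSpecError, ShortfallError
from .readprep import Read


def expected_homogeneous_copy(
    read_len: int, n_reads: int, k: int, monomer_len: int
) -> float:
    """Mean copy number per distinct k-mer in the homogeneous limit.

    ``(read_len - k + 1)`` k-mers per read times ``n_reads`` reads, divided
    by the ``monomer_len`` distinct k-mer start positions of a circular
    monomer.
    """
    if k < 1 or read_len < k:
        raise InvalidSpecError("need read_len >= k >= 1")
    if monomer_len < 1:
        raise InvalidSpecError("monomer_len must be >= 1")
    if n_reads < 0:
        raise InvalidSpecError("n_reads must be >= 0")
    return (read_len - k + 1) * n_reads / monomer_len


def sample_satellite_reads(
    reads: Sequence[Read], n: int, rng: np.random.Generator
) -> list[Read]:
    """Uniform sample of ``n`` reads without replacement.

    Raises :class:`ShortfallError` (naming the deficit) when fewer than
    ``n`` reads are available; a pool of exactly ``n`` returns the pool
    itself (in sampled order).
    """
    if len(reads) < n:
        raise ShortfallError(needed=n, available=len(reads))
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


@dataclass
class KmerSpectrum:
    """Distinct k-mer counts from a read sample.

    ``counts`` maps each distinct k-mer to its copy number; k-mers
    containing N are skipped and tallied in ``n_skipped_n``.  When every
    read has length ``read_len`` (and no Ns), total mass conservation holds:
    ``sum(counts.values()) == n_reads * (read_len - k + 1)``.
    """

    k: int
    n_reads: int
    read_len: int | None
    counts: Counter = field(default_factory=Counter)
    n_skipped_n: int = 0
    n_too_short: int = 0

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def total_mass(self) -> int:
        return sum(self.counts.values())

    def mean_copy_number(self) -> float:
        if not self.counts:
            raise InvalidSpecError("empty spectrum")
        return self.total_mass / self.n_distinct

    def copy_numbers(self) -> np.ndarray:
        return np.array(sorted(self.counts.values()))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tcount\n")
            for kmer, count in sorted(self.counts.items()):
                fh.write(f"{kmer}\t{count}\n")


def count_kmers(
    reads: Sequence[Read],
    k: int = 50,
    orientation: str = "consensus",
    strands: Sequence[str] | None = None,
) -> KmerSpectrum:
    """Count every k-length substring of every read.

    orientation="consensus" (default) reverse-complements minus-strand
    reads before counting, so all k-mers live on the consensus strand;
    ``strands`` supplies the per-read strand calls ('+'/'-') from dimer
    alignment.  orientation="as-read" counts reads as sequenced.  Reads
    shorter than k are excluded and tallied.
    """
    if orientation not in ("consensus", "as-read"):
        raise InvalidSpecError(f"unknown orientation {orientation!r}")
    if orientation == "consensus" and strands is None:
        raise InvalidSpecError("consensus orientation requires per-read strands")
    if strands is not None and len(strands) != len(reads):
        raise InvalidSpecError("strands must be parallel to reads")
    lengths = {len(r) for r in reads}
    spectrum = KmerSpectrum(
        k=k,
        n_reads=len(reads),
        read_len=lengths.pop() if len(lengths) == 1 else None,
    )
    for i, read in enumerate(reads):
        seq = read.seq
        if orientation == "consensus" and strands[i] == "-":
            seq = revcomp(seq)
        if len(seq) < k:
            spectrum.n_too_short += 1
            continue
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if "N" in kmer:
                spectrum.n_skipped_n += 1
            else:
                spectrum.counts[kmer] += 1
    return spectrum


@dataclass(frozen=True)
class CopyNumberSummary:
    """Fractions of distinct k-mers below each copy-number threshold."""

    fractions_below: dict[int, float]
    max_copy_number: int
    n_distinct: int
    empty: bool = False


def copy_number_histogram(
    spectrum: KmerSpectrum, thresholds: Sequence[int] = (100, 2000)
) -> CopyNumberSummary:
    """Per-threshold fraction of distinct k-mers with copy number below it.

    A polymorphic satellite puts the vast majority of distinct k-mers below
    copy number 100; the homogeneous limit puts essentially none there.
    """
    if not spectrum.counts:
        return CopyNumberSummary(
            fractions_below={int(t): float("nan") for t in thresholds},
            max_copy_number=0,
            n_distinct=0,
            empty=True,
        )
    values = np.fromiter(spectrum.counts.values(), dtype=np.int64)
    return CopyNumberSummary(
        fractions_below={int(t): float((values < t).mean()) for t in thresholds},
        max_copy_number=int(values.max()),
        n_distinct=int(values.size),
    )
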