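"""Read preprocessing: 3' quality trimming, 3' adapter removal, fixed-length
trimming for k-mer work, and FASTQ (Phred+33) I/O.

The trimming rules mirror the common single-end Illumina pipeline: trim the
3' end while the terminal base quality is below a threshold, then remove the
best 3' adapter occurrence (allowing a mismatch fraction, down to a 1-base
suffix overlap) and discard reads that fall below a minimum length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class Read:
    """A single-end read: sequence plus per-base Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]
    desc: str = ""

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def prefix(self, n: int) -> "Read":
        return Read(self.id, self.seq[:n], self.qual[:n], self.desc)


def quality_trim(read: Read, threshold: int = 20) -> Read | None:
    """Trim the 3' end while the terminal base quality is below ``threshold``.

    Returns the (possibly shortened) read, or ``None`` if nothing survives.
    Retained base calls are never altered: the output is a prefix of the
    input.
    """
    end = len(read)
    while end > 0 and read.qual[end - 1] < threshold:
        end -= 1
    if end == 0:
        return None
    return read.prefix(end)


def _adapter_match(seq: str, adapter: str, max_err: float, min_overlap: int):
    """Best 3' adapter occurrence as (start, matches), or None.

    Candidates are every start position where the adapter (or a prefix of it
    overhanging the read end) aligns with mismatch fraction <= max_err; N
    counts as a mismatch.  Best = most matching bases, ties broken toward
    the smallest start (longest removed suffix).
    """
    best: tuple[int, int] | None = None
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - start)
        if overlap < min_overlap:
            break
        mism = 0
        for a, b in zip(seq[start : start + overlap], adapter[:overlap]):
            if a != b or a == "N":
                mism += 1
        if mism > int(max_err * overlap):
            continue
        matches = overlap - mism
        if best is None or matches > best[1]:
            best = (start, matches)
    return best


def adapter_trim(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    max_err: float = 0.05,
    min_overlap: int = 1,
    min_len: int = 100,
) -> Read | None:
    """Remove the best 3' adapter occurrence and everything 3' of it.

    Reads shorter than ``min_len`` after trimming (including untrimmed reads
    that were already short) are discarded (``None``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    hit = _adapter_match(read.seq, adapter, max_err, min_overlap)
    if hit is not None:
        read = read.prefix(hit[0])
    if len(read) < min_len:
        return None
    return read


def fixed_trim(read: Read, target_len: int = 100) -> Read | None:
    """Truncate to the first ``target_len`` bases; discard shorter reads."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if len(read) < target_len:
        return None
    return read.prefix(target_len)


@dataclass
class TrimStats:
    """Read-count bookkeeping across the preprocessing stages."""

    n_in: int = 0
    n_out: int = 0
    discarded: dict[str, int] = field(default_factory=dict)

    def discard(self, stage: str) -> None:
        self.discarded[stage] = self.discarded.get(stage, 0) + 1

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def conserved(self) -> bool:
        return self.n_in == self.n_out + self.n_discarded

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_in": self.n_in, "n_out": self.n_out, "discarded": self.discarded},
                fh,
                indent=2,
            )


def preprocess(
    reads: Iterable[Read],
    quality_threshold: int = 20,
    adapter: str = DEFAULT_ADAPTER,
    max_err: float = 0.05,
    min_overlap: int = 1,
    min_len: int = 100,
    kmer_trim: int | None = None,
) -> tuple[list[Read], TrimStats]:
    """Quality-trim then adapter-trim (pipeline order), optionally followed
    by fixed-length trimming for k-mer analysis.

    Returns the surviving reads and conservation statistics
    (``n_in == n_out + n_discarded``).
    """
    stats = TrimStats()
    out: list[Read] = []
    for read in reads:
        stats.n_in += 1
        r = quality_trim(read, threshold=quality_threshold)
        if r is None:
            stats.discard("quality_trim")
            continue
        r = adapter_trim(
            r, adapter=adapter, max_err=max_err, min_overlap=min_overlap, min_len=min_len
        )
        if r is None:
            stats.discard("adapter_trim")
            continue
        if kmer_trim is not None:
            r = fixed_trim(r, target_len=kmer_trim)
            if r is None:
                stats.discard("fixed_trim")
                continue
        out.append(r)
    stats.n_out = len(out)
    return out, stats


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate reads from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            id=rec.id,
            seq=str(rec.seq).upper(),
            qual=tuple(rec.letter_annotations["phred_quality"]),
            desc=rec.description[len(rec.id) :].strip(),
        )


def write_fastq(path: str | Path, reads: Iterable[Read]) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description=r.desc)
            rec.letter_annotations["phred_quality"] = list(r.qual)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
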