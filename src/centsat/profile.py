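"""Read mapping, binned ChIP/input enrichment, masking, and peak calling.

The mapper is a deliberately simple unique-placement aligner for synthetic
genomes: exact-seed lookup plus full-length mismatch verification, with a
read kept only when exactly one locus attains the best score — the
desk-scale analog of the MAPQ >= 20 uniqueness filter applied to real
short-read alignments (externally mapped SAM is ingested with that literal
filter).  Reads from homogeneous tandem arrays tie across copies and are
dropped, which is why satellite-resident centromeres leave no
unique-mapping enrichment signal.

Enrichment is the library-size-normalized per-bin ratio
``(chip_i / chip_total) / (input_i / input_total)`` over fixed-width bins
(20 kb default); bins with zero input and bins overlapping annotated
satellite positions are masked as unreliable.  A "complex centromere" is an
enrichment peak whose genomic span exceeds 500 kb; two peaks on one
chromosome count as a single complex centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from scipy import stats

from ._seq import encode, revcomp
from .consensus import RepeatConsensus
from .errors import EmptyInputError, InvalidSpecError, UndefinedComparisonError
from .readprep import Read

MASK_OK = 0
MASK_ZERO_INPUT = 1
MASK_SATELLITE = 2


@dataclass(frozen=True)
class AlignmentRecord:
    """A placed read; only ``unique`` records enter coverage."""

    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str
    unique: bool
    n_mismatches: int = 0


class UniqueMapper:
    """Seed-and-verify unique mapper for small synthetic genomes.

    An exact ``seed_len``-mer index over the forward genome generates
    candidate loci (seeds taken at the read's start, middle, and end, both
    strands); candidates are verified by full-length Hamming distance
    (substitution-only, matching the simulator's error model).  A read is
    ``unique`` iff exactly one locus attains the minimum mismatch count
    (and that count is <= ``max_mismatch``).  Reads whose candidate set
    exceeds ``max_candidates`` are declared non-unique outright: on an
    i.i.d. background only genuine repeats generate that many exact seed
    hits.
    """

    def __init__(
        self,
        genome: dict[str, str],
        seed_len: int = 20,
        max_mismatch: int = 8,
        max_candidates: int = 200,
    ):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise EmptyInputError("empty genome")
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self.max_candidates = max_candidates
        self.chrom_names = list(genome)
        self.chrom_sizes = {n: len(s) for n, s in genome.items()}
        self._enc = {n: encode(s) for n, s in genome.items()}
        self._offsets = {}
        off = 0
        for n in self.chrom_names:
            self._offsets[n] = off
            off += self.chrom_sizes[n]
        self._starts = np.array(
            [self._offsets[n] for n in self.chrom_names] + [off], dtype=np.int64
        )
        codes_list, pos_list = [], []
        k = seed_len
        for n in self.chrom_names:
            enc = self._enc[n].astype(np.int64)
            if len(enc) < k:
                continue
            valid = enc < 4
            ok = np.ones(len(enc) - k + 1, dtype=bool)
            kmers = np.zeros(len(enc) - k + 1, dtype=np.int64)
            for j in range(k):
                kmers = kmers * 4 + enc[j : j + len(kmers)]
                ok &= valid[j : j + len(kmers)]
            pos = np.flatnonzero(ok) + self._offsets[n]
            codes_list.append(kmers[ok])
            pos_list.append(pos)
        codes = np.concatenate(codes_list)
        pos = np.concatenate(pos_list)
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = pos[order]

    def _global_to_chrom(self, g: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._starts, g, side="right")) - 1
        name = self.chrom_names[i]
        return name, g - self._offsets[name]

    def _seed_candidates(self, enc_read: np.ndarray) -> np.ndarray:
        k, L = self.seed_len, len(enc_read)
        offsets = sorted({0, max(0, (L - k) // 2), max(0, L - k)})
        cands = []
        for off in offsets:
            seed = enc_read[off : off + k].astype(np.int64)
            if len(seed) < k or (seed > 3).any():
                continue
            code = 0
            for c in seed:
                code = code * 4 + int(c)
            lo = np.searchsorted(self._sorted_codes, code, side="left")
            hi = np.searchsorted(self._sorted_codes, code, side="right")
            if hi > lo:
                cands.append(self._sorted_pos[lo:hi] - off)
        if not cands:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(cands))

    def map_read(self, read: Read) -> AlignmentRecord | None:
        """Place one read; None if unplaced.  Non-unique placements are
        returned with ``unique=False`` (at an arbitrary best locus)."""
        L = len(read)
        best: list[tuple[int, str]] = []  # (global_start, strand) at best_mm
        best_mm = self.max_mismatch + 1
        overflow = False
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            enc_read = encode(seq)
            cands = self._seed_candidates(enc_read)
            if len(cands) > self.max_candidates:
                overflow = True
                cands = cands[: self.max_candidates]
            for g in cands:
                chrom, local = self._global_to_chrom(int(g))
                if local < 0 or local + L > self.chrom_sizes[chrom]:
                    continue
                ref = self._enc[chrom][local : local + L]
                mm = int(np.count_nonzero(ref != enc_read) + np.count_nonzero(ref > 3))
                if mm < best_mm:
                    best_mm = mm
                    best = [(int(g), strand)]
                elif mm == best_mm:
                    best.append((int(g), strand))
        if not best or best_mm > self.max_mismatch:
            return None
        unique = len(best) == 1 and not overflow
        g, strand = best[0]
        chrom, local = self._global_to_chrom(g)
        return AlignmentRecord(
            read_id=read.id,
            chrom=chrom,
            start=local,
            strand=strand,
            unique=unique,
            n_mismatches=best_mm,
        )


def map_reads(
    reads: Iterable[Read],
    genome: dict[str, str],
    seed_len: int = 20,
    max_mismatch: int = 8,
) -> list[AlignmentRecord]:
    """Map reads with the unique mapper; unplaced reads are dropped,
    non-unique ones retained with ``unique=False`` (excluded from coverage).
    """
    mapper = UniqueMapper(genome, seed_len=seed_len, max_mismatch=max_mismatch)
    out = []
    for read in reads:
        rec = mapper.map_read(read)
        if rec is not None:
            out.append(rec)
    return out


def read_alignments_sam(path: str | Path, min_mapq: int = 20) -> list[AlignmentRecord]:
    """Ingest externally mapped reads (SAM/BAM), applying the MAPQ filter
    literally: records with MAPQ >= ``min_mapq`` are unique, the rest are
    kept as non-unique."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    unique=rec.mapping_quality >= min_mapq,
                )
            )
    return out


@dataclass
class EnrichmentTrack:
    """Binned ChIP/input counts and normalized enrichment, with masking.

    Per chromosome: ``chip``/``input`` unique-read counts per bin,
    ``enrichment`` (NaN on masked bins), and ``mask`` codes (0 ok, 1 zero
    input, 2 satellite overlap).
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    chip: dict[str, np.ndarray]
    input: dict[str, np.ndarray]
    enrichment: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    chip_total: int = 0
    input_total: int = 0

    def n_bins(self, chrom: str) -> int:
        return len(self.chip[chrom])

    def bin_start(self, chrom: str, i: int) -> int:
        return i * self.bin_size

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, enr in self.enrichment.items():
                for i, v in enumerate(enr):
                    if np.isnan(v):
                        continue
                    start = i * self.bin_size
                    end = min(start + self.bin_size, self.chrom_sizes[chrom])
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.4f}\n")


def _bin_counts(
    records: Iterable[AlignmentRecord], chrom_sizes: dict[str, int], bin_size: int
) -> tuple[dict[str, np.ndarray], int]:
    counts = {
        chrom: np.zeros(-(-size // bin_size), dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    total = 0
    for rec in records:
        if not rec.unique:
            continue
        counts[rec.chrom][rec.start // bin_size] += 1
        total += 1
    return counts, total


def bin_enrichment(
    chip: Iterable[AlignmentRecord],
    input_: Iterable[AlignmentRecord],
    chrom_sizes: dict[str, int],
    bin_size: int = 20_000,
    satellite_mask: Sequence[tuple[str, int, int]] | None = None,
) -> EnrichmentTrack:
    """Library-size-normalized per-bin ChIP/input enrichment.

    Bins with zero input reads are masked ``zero_input``; bins overlapping
    ``satellite_mask`` intervals are flagged ``satellite`` (their apparent
    enrichment is unreliable where satellite positions are incompletely
    represented).  Only unique records are counted.
    """
    chip_counts, chip_total = _bin_counts(chip, chrom_sizes, bin_size)
    input_counts, input_total = _bin_counts(input_, chrom_sizes, bin_size)
    if chip_total == 0 or input_total == 0:
        raise EmptyInputError("zero retained reads in one channel")
    enrichment, mask = {}, {}
    for chrom in chrom_sizes:
        c, n = chip_counts[chrom], input_counts[chrom]
        m = np.full(len(c), MASK_OK, dtype=np.int8)
        m[n == 0] = MASK_ZERO_INPUT
        if satellite_mask:
            for s_chrom, s_start, s_end in (
                (iv[0], iv[1], iv[2]) for iv in satellite_mask
            ):
                if s_chrom != chrom:
                    continue
                first = s_start // bin_size
                last = (max(s_end - 1, s_start)) // bin_size
                m[first : last + 1] = MASK_SATELLITE
        e = np.full(len(c), np.nan)
        ok = m == MASK_OK
        with np.errstate(divide="ignore", invalid="ignore"):
            e[ok] = (c[ok] / chip_total) / (n[ok] / input_total)
        enrichment[chrom] = e
        mask[chrom] = m
    return EnrichmentTrack(
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        chip=chip_counts,
        input=input_counts,
        enrichment=enrichment,
        mask=mask,
        chip_total=chip_total,
        input_total=input_total,
    )


def annotate_reference_repeats(
    genome: dict[str, str],
    consensus: RepeatConsensus,
    word: int = 13,
    merge_gap: int | None = None,
) -> list[tuple[str, int, int]]:
    """Satellite positions in the reference: exact-word matches to the
    consensus dimer (both strands) merged into intervals.

    ``merge_gap`` defaults to the monomer length, so polymorphic copies in
    a tandem array merge into one interval; isolated spurious words shorter
    than the monomer are dropped.
    """
    if merge_gap is None:
        merge_gap = len(consensus)
    words = set()
    dimer = consensus.dimer
    for seq in (dimer, revcomp(dimer)):
        for i in range(len(seq) - word + 1):
            words.add(seq[i : i + word])
    out = []
    for chrom, seq in genome.items():
        hits = [
            i for i in range(len(seq) - word + 1) if seq[i : i + word] in words
        ]
        if not hits:
            continue
        start = hits[0]
        prev = hits[0]
        intervals = []
        for h in hits[1:]:
            if h - prev > merge_gap:
                intervals.append((start, prev + word))
                start = h
            prev = h
        intervals.append((start, prev + word))
        for s, e in intervals:
            if e - s >= len(consensus) // 2:
                out.append((chrom, s, e))
    return out


@dataclass(frozen=True)
class CentromerePeak:
    """A called CENH3 enrichment peak (genomic span includes tolerated gaps)."""

    chrom: str
    start: int
    end: int
    mean_enrichment: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ComplexCentromereCalls:
    """Called peaks plus the per-chromosome complex-centromere counts.

    Two or more peaks on one chromosome (heterozygosity can split a single
    centromere) count as one complex centromere.
    """

    peaks: list[CentromerePeak]
    per_chromosome: dict[str, int]

    @property
    def n_complex(self) -> int:
        return sum(self.per_chromosome.values())


def call_complex_centromeres(
    track: EnrichmentTrack,
    min_enrich: float = 2.0,
    min_len: int = 500_000,
    max_gap_bins: int = 2,
) -> ComplexCentromereCalls:
    """Call complex centromeres as enrichment peaks longer than ``min_len``.

    A peak is a maximal run of ok-bins with enrichment >= ``min_enrich``,
    tolerating up to ``max_gap_bins`` consecutive interior sub-threshold or
    masked bins; only runs whose genomic span exceeds ``min_len`` (strictly)
    are reported.
    """
    peaks: list[CentromerePeak] = []
    per_chrom: dict[str, int] = {}
    for chrom in track.chrom_sizes:
        enr = track.enrichment[chrom]
        above = np.zeros(len(enr), dtype=bool)
        valid = ~np.isnan(enr)
        above[valid] = enr[valid] >= min_enrich
        runs = []
        i = 0
        n = len(above)
        while i < n:
            if not above[i]:
                i += 1
                continue
            run_start = i
            last_above = i
            j = i + 1
            while j < n:
                if above[j]:
                    last_above = j
                    j += 1
                elif j - last_above <= max_gap_bins:
                    j += 1
                else:
                    break
            runs.append((run_start, last_above))
            i = last_above + 1
        n_peaks = 0
        for run_start, run_end in runs:
            start = run_start * track.bin_size
            end = min((run_end + 1) * track.bin_size, track.chrom_sizes[chrom])
            if end - start > min_len:
                seg = enr[run_start : run_end + 1]
                peaks.append(
                    CentromerePeak(
                        chrom=chrom,
                        start=start,
                        end=end,
                        mean_enrichment=float(np.nanmean(seg)),
                        n_bins=run_end - run_start + 1,
                    )
                )
                n_peaks += 1
        per_chrom[chrom] = min(1, n_peaks)
    return ComplexCentromereCalls(peaks=peaks, per_chromosome=per_chrom)


def correlate_abundance(
    complex_counts: Sequence[float], repeat_fractions: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) between per-sample
    complex-centromere counts and repeat fractions.

    Returns (rho, p-value).  A negative rho reproduces the satellite-
    abundance vs complex-centromere trade-off.
    """
    if len(complex_counts) != len(repeat_fractions):
        raise InvalidSpecError("paired samples required")
    if len(complex_counts) < 3:
        raise InvalidSpecError("need at least 3 paired samples")
    if len(set(complex_counts)) < 2 or len(set(repeat_fractions)) < 2:
        raise UndefinedComparisonError("constant input: correlation undefined")
    rho, p = stats.spearmanr(complex_counts, repeat_fractions)
    return float(rho), float(p)


def track_from_bedgraph(
    path: str | Path, chrom_sizes: dict[str, int], bin_size: int = 20_000
) -> EnrichmentTrack:
    """Rebuild an enrichment track from a bedGraph written by
    :meth:`EnrichmentTrack.to_bedgraph`.

    Bins absent from the file are masked (the writer omits masked bins);
    raw per-bin counts are not recoverable and are left at zero.
    """
    enrichment = {
        chrom: np.full(-(-size // bin_size), np.nan)
        for chrom, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, _end, value = line.split()[:4]
            if chrom not in enrichment:
                raise InvalidSpecError(f"bedGraph chromosome {chrom!r} not in genome")
            enrichment[chrom][int(start) // bin_size] = float(value)
    mask = {
        chrom: np.where(np.isnan(e), MASK_ZERO_INPUT, MASK_OK).astype(np.int8)
        for chrom, e in enrichment.items()
    }
    zeros = {
        chrom: np.zeros(len(e), dtype=np.int64) for chrom, e in enrichment.items()
    }
    return EnrichmentTrack(
        bin_size=bin_size,
        chrom_sizes=dict(chrom_sizes),
        chip=zeros,
        input={c: z.copy() for c, z in zeros.items()},
        enrichment=enrichment,
        mask=mask,
    )


def write_peaks_bed(path: str | Path, calls: ComplexCentromereCalls) -> None:
    with open(path, "w") as fh:
        for p in calls.peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tcomplex_centromere\t"
                f"{p.mean_enrichment:.3f}\n"
            )
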