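"""Unique mapping, binned enrichment, satellite masking, peak calling."""

import numpy as np
import pytest

from centsat import profile, sim
from centsat._seq import random_dna, revcomp
from centsat.consensus import ZEA_CENTC
from centsat.errors import EmptyInputError, InvalidSpecError, UndefinedComparisonError
from centsat.profile import (
    AlignmentRecord,
    EnrichmentTrack,
    MASK_OK,
    MASK_SATELLITE,
    MASK_ZERO_INPUT,
    annotate_reference_repeats,
    bin_enrichment,
    call_complex_centromeres,
    correlate_abundance,
    map_reads,
    read_alignments_sam,
)
from _oracles import spearman_bruteforce
from conftest import make_read


class TestUniqueMapper:
    def test_background_read_maps_uniquely(self, small_truth):
        seq = small_truth.genome["chr1"][100_000:100_150]
        (rec,) = map_reads([make_read(seq, rid="bg")], small_truth.genome)
        assert rec.unique and rec.chrom == "chr1" and rec.start == 100_000
        assert rec.strand == "+"

    def test_reverse_strand_read_recovered(self, small_truth):
        seq = revcomp(small_truth.genome["chr1"][70_000:70_150])
        (rec,) = map_reads([make_read(seq, rid="rev")], small_truth.genome)
        assert rec.unique and rec.start == 70_000 and rec.strand == "-"

    def test_homogeneous_array_read_is_non_unique(self, small_truth):
        # fully inside the rate-0 CentC array: >= 2 identical loci
        seq = small_truth.genome["chr1"][52_000:52_150]
        (rec,) = map_reads([make_read(seq, rid="sat")], small_truth.genome)
        assert not rec.unique

    def test_foreign_read_unplaced(self, small_truth, rng):
        recs = map_reads([make_read(random_dna(150, rng))], small_truth.genome)
        assert recs == []

    def test_read_with_errors_still_places(self, small_truth, rng):
        seq = list(small_truth.genome["chr1"][120_000:120_150])
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        seq[90] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[90]]
        (rec,) = map_reads([make_read("".join(seq))], small_truth.genome)
        assert rec.unique and rec.start == 120_000 and rec.n_mismatches == 2

    def test_empty_genome_rejected(self):
        with pytest.raises(EmptyInputError):
            map_reads([], {})


def _recs(chrom, starts, prefix="r"):
    return [
        AlignmentRecord(f"{prefix}{i}", chrom, s, "+", True) for i, s in enumerate(starts)
    ]


class TestBinEnrichment:
    SIZES = {"chr1": 100_000}

    def test_identical_channels_give_unit_enrichment(self):
        starts = list(range(0, 100_000, 500))
        track = bin_enrichment(
            _recs("chr1", starts), _recs("chr1", starts), self.SIZES, bin_size=10_000
        )
        ok = track.mask["chr1"] == MASK_OK
        assert ok.all()
        np.testing.assert_allclose(track.enrichment["chr1"], 1.0)

    def test_library_size_normalization(self):
        starts = list(range(0, 100_000, 500))
        doubled = starts + starts
        track = bin_enrichment(
            _recs("chr1", doubled), _recs("chr1", starts), self.SIZES, bin_size=10_000
        )
        np.testing.assert_allclose(track.enrichment["chr1"], 1.0)

    def test_zero_input_bin_masked(self):
        chip = _recs("chr1", list(range(0, 100_000, 500)))
        inp = [r for r in chip if not (30_000 <= r.start < 40_000)]
        track = bin_enrichment(chip, inp, self.SIZES, bin_size=10_000)
        assert track.mask["chr1"][3] == MASK_ZERO_INPUT
        assert np.isnan(track.enrichment["chr1"][3])

    def test_satellite_bins_flagged(self):
        starts = list(range(0, 100_000, 500))
        track = bin_enrichment(
            _recs("chr1", starts),
            _recs("chr1", starts),
            self.SIZES,
            bin_size=10_000,
            satellite_mask=[("chr1", 52_000, 68_000)],
        )
        assert (track.mask["chr1"][5:7] == MASK_SATELLITE).all()

    def test_coverage_conservation(self):
        rng = np.random.default_rng(0)
        chip = _recs("chr1", rng.integers(0, 100_000, size=777))
        inp = _recs("chr1", rng.integers(0, 100_000, size=555))
        # mark some chip records non-unique: they must not enter coverage
        chip[0] = AlignmentRecord("x", "chr1", 5, "+", False)
        track = bin_enrichment(chip, inp, self.SIZES, bin_size=10_000)
        assert track.chip["chr1"].sum() == track.chip_total == 776
        assert track.input["chr1"].sum() == track.input_total == 555

    def test_empty_channel_rejected(self):
        with pytest.raises(EmptyInputError):
            bin_enrichment([], _recs("chr1", [1]), self.SIZES)


class TestAnnotateReferenceRepeats:
    def test_planted_array_recovered_within_one_monomer(self, small_truth):
        (iv,) = annotate_reference_repeats(small_truth.genome, ZEA_CENTC)
        chrom, start, end = iv
        truth = small_truth.array_intervals[0]
        assert chrom == "chr1"
        assert abs(start - truth[1]) <= 156 and abs(end - truth[2]) <= 156

    def test_reverse_strand_array_detected(self):
        spec = sim.GenomeSpec(
            chromosomes=[("chr1", 60_000)],
            arrays=[sim.SatelliteArray("chr1", 20_000, "CentC", 50, 0.04, strand="-")],
            rng_seed=9,
        )
        truth = sim.build_genome(spec)
        (iv,) = annotate_reference_repeats(truth.genome, ZEA_CENTC)
        assert abs(iv[1] - 20_000) <= 156 and abs(iv[2] - (20_000 + 50 * 156)) <= 156

    def test_no_satellite_gives_empty_bed(self):
        truth = sim.build_genome(sim.GenomeSpec(chromosomes=[("chr1", 50_000)], rng_seed=1))
        assert annotate_reference_repeats(truth.genome, ZEA_CENTC) == []


def make_track(values, bin_size=20_000, mask=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    size = len(values) * bin_size
    m = np.full(len(values), MASK_OK, dtype=np.int8) if mask is None else np.asarray(mask, dtype=np.int8)
    enr = values.copy()
    enr[m != MASK_OK] = np.nan
    ones = np.ones(len(values), dtype=np.int64)
    return EnrichmentTrack(
        bin_size=bin_size,
        chrom_sizes={chrom: size},
        chip={chrom: ones},
        input={chrom: ones},
        enrichment={chrom: enr},
        mask={chrom: m},
        chip_total=len(values),
        input_total=len(values),
    )


class TestCallComplexCentromeres:
    def test_600kb_run_is_one_complex_centromere(self):
        values = [0.5] * 20 + [3.0] * 30 + [0.5] * 20  # 600 kb above threshold
        calls = call_complex_centromeres(make_track(values))
        (peak,) = calls.peaks
        assert peak.length == 600_000 and calls.per_chromosome["chr1"] == 1

    def test_400kb_run_is_rejected(self):
        values = [0.5] * 20 + [3.0] * 20 + [0.5] * 20
        calls = call_complex_centromeres(make_track(values))
        assert calls.peaks == [] and calls.n_complex == 0

    def test_two_peaks_count_once_per_chromosome(self):
        values = [0.5] * 5 + [3.0] * 31 + [0.5] * 10 + [3.0] * 31 + [0.5] * 5
        calls = call_complex_centromeres(make_track(values))
        assert len(calls.peaks) == 2
        assert calls.per_chromosome["chr1"] == 1 and calls.n_complex == 1

    def test_interior_gaps_tolerated_up_to_limit(self):
        base = [3.0] * 31
        with_gap = base[:10] + [0.5, 0.5] + base[10:]
        calls = call_complex_centromeres(make_track(with_gap), max_gap_bins=2)
        assert len(calls.peaks) == 1  # 2-bin dip bridged
        with_big_gap = base[:16] + [0.5] * 3 + base[16:]
        calls2 = call_complex_centromeres(make_track(with_big_gap), max_gap_bins=2)
        assert calls2.peaks == []  # split into two sub-500kb runs

    def test_masked_bins_do_not_seed_peaks(self):
        values = [3.0] * 40
        mask = [MASK_SATELLITE] * 40
        calls = call_complex_centromeres(make_track(values, mask=mask))
        assert calls.peaks == []


class TestCorrelateAbundance:
    def test_monotone_decreasing_gives_minus_one(self):
        counts = [9, 7, 5, 3]
        fracs = [0.05, 0.10, 0.20, 0.40]
        rho, _ = correlate_abundance(counts, fracs)
        assert rho == -1.0

    def test_matches_bruteforce_midranks_with_ties(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=12).tolist()  # ties guaranteed
        fracs = rng.uniform(0.04, 0.45, size=12).round(2).tolist()
        rho, _ = correlate_abundance(counts, fracs)
        assert rho == pytest.approx(spearman_bruteforce(counts, fracs), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedComparisonError):
            correlate_abundance([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidSpecError):
            correlate_abundance([1, 2], [0.1, 0.2])


class TestSamIngestion:
    def test_mapq_filter_applied_literally(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "r2\t16\tchr1\t201\t5\t50M\t*\t0\t0\t" + "C" * 50 + "\t" + "I" * 50 + "\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "G" * 50 + "\t" + "I" * 50 + "\n"
        )
        recs = read_alignments_sam(sam, min_mapq=20)
        assert len(recs) == 2  # unmapped r3 dropped
        by_id = {r.read_id: r for r in recs}
        assert by_id["r1"].unique and by_id["r1"].start == 100
        assert not by_id["r2"].unique and by_id["r2"].strand == "-"


class TestBedgraphRoundTrip:
    def test_track_survives_bedgraph_round_trip(self, tmp_path):
        values = [0.5] * 5 + [3.0] * 31 + [0.5] * 4
        track = make_track(values)
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(path)
        back = profile.track_from_bedgraph(path, track.chrom_sizes, bin_size=20_000)
        np.testing.assert_allclose(back.enrichment["chr1"], track.enrichment["chr1"])
        calls = call_complex_centromeres(back)
        assert len(calls.peaks) == 1
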