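"""Positional comparison of CENH3 profiles between samples.

Centromere "drift" — stochastic, non-heritable shifts of the cenH3
distribution among genetically identical individuals — is quantified here
by three window-level statistics on binned enrichment profiles:

* centroid shift (bp): mass-weighted mean position of B minus that of A;
* normalized L1 profile distance in [0, 2], zero iff the unit-mass
  profiles agree on the jointly unmasked bins;
* asymmetry delta: (right-half mass - left-half mass) of B minus the same
  for A, positive when B's cenH3 sits further right than A's — the
  quantitative analog of a centromere whose coverage is "higher on the
  right side and lower on the left".

The replicate-concordance floor (two ChIP halves of one sample) gives the
technical-noise scale against which sibling drift is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, IncomparableTracksError
from .profile import AlignmentRecord, CentromerePeak, EnrichmentTrack, MASK_OK, bin_enrichment


@dataclass(frozen=True)
class DriftReport:
    """Window-level profile comparison of two samples (B minus A)."""

    chrom: str
    start: int
    end: int
    centroid_shift: float  # bp
    l1_distance: float  # in [0, 2]
    asymmetry_delta: float
    n_bins: int


def _window_profile(
    track: EnrichmentTrack, chrom: str, lo_bin: int, hi_bin: int
) -> tuple[np.ndarray, np.ndarray]:
    enr = track.enrichment[chrom][lo_bin:hi_bin]
    ok = track.mask[chrom][lo_bin:hi_bin] == MASK_OK
    return np.where(ok, enr, np.nan), ok


def profile_distance(
    track_a: EnrichmentTrack,
    track_b: EnrichmentTrack,
    window: tuple[str, int, int],
) -> DriftReport:
    """Compare two enrichment profiles over a genomic window.

    Each profile is normalized to unit mass over the jointly unmasked bins;
    the centroid is the mass-weighted mean bin midpoint and the asymmetry
    is the mass right of the window midpoint minus the mass left of it.
    """
    chrom, start, end = window
    if track_a.bin_size != track_b.bin_size:
        raise IncomparableTracksError("tracks have different bin sizes")
    if chrom not in track_a.chrom_sizes or chrom not in track_b.chrom_sizes:
        raise IncomparableTracksError(f"chromosome {chrom!r} missing from a track")
    bs = track_a.bin_size
    lo_bin = max(0, start // bs)
    hi_bin = min(-(-end // bs), len(track_a.enrichment[chrom]))
    pa, ok_a = _window_profile(track_a, chrom, lo_bin, hi_bin)
    pb, ok_b = _window_profile(track_b, chrom, lo_bin, hi_bin)
    joint = ok_a & ok_b
    if not joint.any():
        raise IncomparableTracksError("no jointly unmasked bins in window")
    wa = np.where(joint, np.nan_to_num(pa), 0.0)
    wb = np.where(joint, np.nan_to_num(pb), 0.0)
    if wa.sum() <= 0 or wb.sum() <= 0:
        raise IncomparableTracksError("zero profile mass in window")
    wa = wa / wa.sum()
    wb = wb / wb.sum()
    midpoints = (np.arange(lo_bin, hi_bin) + 0.5) * bs
    centroid_a = float((wa * midpoints).sum())
    centroid_b = float((wb * midpoints).sum())
    window_mid = (start + end) / 2.0
    asym_a = float(wa[midpoints > window_mid].sum() - wa[midpoints < window_mid].sum())
    asym_b = float(wb[midpoints > window_mid].sum() - wb[midpoints < window_mid].sum())
    return DriftReport(
        chrom=chrom,
        start=start,
        end=end,
        centroid_shift=centroid_b - centroid_a,
        l1_distance=float(np.abs(wa - wb).sum()),
        asymmetry_delta=asym_b - asym_a,
        n_bins=int(joint.sum()),
    )


def replicate_concordance(
    chip_half1: Iterable[AlignmentRecord],
    chip_half2: Iterable[AlignmentRecord],
    input_records: Sequence[AlignmentRecord],
    chrom_sizes: dict[str, int],
    window: tuple[str, int, int],
    bin_size: int = 20_000,
    satellite_mask=None,
) -> DriftReport:
    """Technical-noise floor: profile distance between two ChIP halves of
    one sample, each normalized against the same input."""
    half1 = list(chip_half1)
    half2 = list(chip_half2)
    if not half1 or not half2:
        raise EmptyInputError("empty ChIP half")
    track1 = bin_enrichment(
        half1, input_records, chrom_sizes, bin_size=bin_size, satellite_mask=satellite_mask
    )
    track2 = bin_enrichment(
        half2, input_records, chrom_sizes, bin_size=bin_size, satellite_mask=satellite_mask
    )
    return profile_distance(track1, track2, window)


def default_window(
    peaks: Sequence[CentromerePeak], chrom: str, chrom_size: int, pad: int = 500_000
) -> tuple[str, int, int]:
    """Union of called peaks on a chromosome, padded by ``pad`` bp."""
    ours = [p for p in peaks if p.chrom == chrom]
    if not ours:
        raise EmptyInputError(f"no peaks on {chrom}")
    start = max(0, min(p.start for p in ours) - pad)
    end = min(chrom_size, max(p.end for p in ours) + pad)
    return (chrom, start, end)
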