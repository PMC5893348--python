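"""Fixed-bin intensity histograms and center-of-mass alignment.

A region is summarized by the histogram of its voxel gray levels; before any
comparison all histograms are shifted so that their center of mass sits on
the central bin.  This removes global intensity offsets (scanner gain,
background level) so the Earth Mover's Distance downstream responds to
distributional shape, not to a constant additive shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError, EmptyRegionError
from .volumes_io import IntensityVolume, LabelAtlas, RegionSample

logger = logging.getLogger(__name__)

DEFAULT_BIN_COUNT = 64
DEFAULT_RANGE_PERCENTILES = (0.5, 99.5)
#: Fraction of mass clipped off the ends during alignment that triggers a warning.
CLIP_WARN_FRACTION = 0.05


@dataclass(frozen=True)
class Histogram:
    """Non-negative mass per bin for one region of one subject.

    Bins are equal-width; positions are the 0-based bin indices, so EMD values
    are expressed in bin units.
    """

    masses: np.ndarray
    subject_id: str = ""
    region_id: int = 0

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        if masses.ndim != 1 or masses.size < 2:
            raise DataError("a histogram needs at least 2 bins")
        if np.any(masses < 0) or not np.all(np.isfinite(masses)):
            raise DataError("histogram masses must be finite and non-negative")
        object.__setattr__(self, "masses", masses)

    @property
    def bin_count(self) -> int:
        return self.masses.size

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def central_bin(self) -> int:
        return self.bin_count // 2

    def normalized(self) -> "Histogram":
        total = self.total_mass
        if total <= 0:
            raise DataError("cannot normalize a zero-mass histogram")
        return replace(self, masses=self.masses / total)


def subject_intensity_range(
    volume: IntensityVolume,
    atlas: LabelAtlas,
    percentiles: tuple[float, float] = DEFAULT_RANGE_PERCENTILES,
) -> tuple[float, float]:
    """Robust per-subject intensity range over all labelled voxels.

    One range is shared by all of a subject's regions so that regional
    histograms remain comparable within the subject.
    """
    brain = volume.grid[atlas.labels > 0]
    if brain.size == 0:
        raise DataError(f"subject {volume.subject_id}: atlas labels no voxels")
    low, high = np.percentile(brain, percentiles)
    if not low < high:
        # flat volume; widen so binning stays defined
        low, high = float(brain.min()) - 0.5, float(brain.max()) + 0.5
    return float(low), float(high)


def build_histogram(
    sample: RegionSample,
    bin_count: int = DEFAULT_BIN_COUNT,
    intensity_range: tuple[float, float] = (0.0, 1.0),
) -> Histogram:
    """Histogram a region sample into equal-width bins and normalize to unit mass.

    Values outside ``intensity_range`` are clipped into the end bins.  An
    empty (missing) region raises :class:`EmptyRegionError`, which callers
    turn into an absent feature rather than a failure.
    """
    if sample.missing or sample.values.size == 0:
        raise EmptyRegionError(
            f"subject {sample.subject_id}: region {sample.region_id} is empty"
        )
    low, high = intensity_range
    if not low < high:
        raise DataError(f"invalid intensity range ({low}, {high})")
    if bin_count < 2:
        raise DataError("bin_count must be at least 2")
    clipped = np.clip(sample.values, low, high)
    counts, _ = np.histogram(clipped, bins=bin_count, range=(low, high))
    masses = counts / counts.sum()
    return Histogram(masses, subject_id=sample.subject_id, region_id=sample.region_id)


def center_of_mass(h: Histogram) -> float:
    """Mean bin index weighted by mass (0-based)."""
    total = h.total_mass
    if total <= 0:
        raise DataError("center of mass undefined for zero total mass")
    return float(np.dot(np.arange(h.bin_count), h.masses) / total)


def align_center_of_mass(h: Histogram) -> Histogram:
    """Shift a histogram by an integer offset so its center of mass lies on
    the central bin.

    Mass shifted past either end is clipped and the result renormalized;
    large clipped fractions are logged.  The shift is integer (no
    interpolation), so a pure intensity offset that maps bins to bins exactly
    leaves the aligned histogram unchanged up to the offset — such pairs have
    EMD 0.
    """
    com = center_of_mass(h)
    offset = int(round(h.central_bin - com))
    if offset == 0:
        return h.normalized()
    shifted = np.zeros_like(h.masses)
    if offset > 0:
        shifted[offset:] = h.masses[:-offset]
    else:
        shifted[:offset] = h.masses[-offset:]
    clipped_fraction = 1.0 - shifted.sum() / h.total_mass
    if clipped_fraction > CLIP_WARN_FRACTION:
        logger.warning(
            "subject %s region %d: alignment clipped %.1f%% of histogram mass",
            h.subject_id,
            h.region_id,
            100 * clipped_fraction,
        )
    if shifted.sum() <= 0:
        raise DataError(
            f"subject {h.subject_id} region {h.region_id}: "
            "alignment clipped all histogram mass"
        )
    return replace(h, masses=shifted / shifted.sum())


def histograms_to_frame(histograms: list[Histogram]) -> pd.DataFrame:
    """Serialize histograms to a flat table (subject_id, region_id, bin columns)."""
    if not histograms:
        raise DataError("no histograms to serialize")
    n_bins = histograms[0].bin_count
    rows = []
    for h in histograms:
        if h.bin_count != n_bins:
            raise DataError("histograms differ in bin count")
        rows.append([h.subject_id, h.region_id, *h.masses])
    cols = ["subject_id", "region_id"] + [f"bin_{i}" for i in range(n_bins)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_histograms(df: pd.DataFrame) -> list[Histogram]:
    """Inverse of :func:`histograms_to_frame`."""
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    if not bin_cols:
        raise DataError("no bin columns in histogram table")
    return [
        Histogram(
            row[bin_cols].to_numpy(dtype=float),
            subject_id=str(row["subject_id"]),
            region_id=int(row["region_id"]),
        )
        for _, row in df.iterrows()
    ]
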