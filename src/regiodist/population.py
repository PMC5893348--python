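"""Subject-level distances, the control-group medoid, and distance features.

A subject is a set of aligned regional histograms.  The distance between two
subjects aggregates the per-region EMDs (sum by default).  The medoid of the
control group — the control subject with minimal summed distance to the rest
of the controls — becomes the reference, and every brain is then featurized
as its vector of per-region EMDs to that reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emd import emd_closed_form
from .errors import DataError, EmptyRegionError
from .histograms import (
    Histogram,
    align_center_of_mass,
    build_histogram,
    subject_intensity_range,
)
from .volumes_io import (
    IntensityVolume,
    LabelAtlas,
    RegionLabel,
    extract_region_samples,
)

logger = logging.getLogger(__name__)

AGGREGATIONS = ("sum", "mean", "max")


@dataclass
class SubjectProfile:
    """Aligned histogram per region for one subject.

    ``histograms`` maps region_id -> Histogram, or None for regions with no
    voxels (missing); missing regions are excluded from distances and become
    NaN feature entries.
    """

    subject_id: str
    group: str = ""
    histograms: dict[int, Histogram | None] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.histograms)

    @property
    def missing_regions(self) -> list[int]:
        return sorted(r for r, h in self.histograms.items() if h is None)


def build_profile(
    volume: IntensityVolume,
    atlas: LabelAtlas,
    group: str = "",
    bin_count: int = 64,
    intensity_range: tuple[float, float] | None = None,
    range_percentiles: tuple[float, float] = (0.5, 99.5),
) -> SubjectProfile:
    """Extract, bin, and center-of-mass-align every region of one subject.

    When ``intensity_range`` is None a robust per-subject range (percentiles
    of all labelled voxels) is used, shared across the subject's regions.
    """
    if intensity_range is None:
        intensity_range = subject_intensity_range(volume, atlas, range_percentiles)
    samples = extract_region_samples(volume, atlas)
    histograms: dict[int, Histogram | None] = {}
    for sample in samples:
        try:
            h = build_histogram(sample, bin_count, intensity_range)
        except EmptyRegionError:
            histograms[sample.region_id] = None
            continue
        histograms[sample.region_id] = align_center_of_mass(h)
    return SubjectProfile(
        subject_id=volume.subject_id, group=group, histograms=histograms
    )


def subject_distance(
    a: SubjectProfile, b: SubjectProfile, aggregate: str = "sum"
) -> float:
    """Aggregate per-region EMDs into one subject-level distance δ(a, b).

    Regions missing in either subject are skipped (logged); disjoint region
    sets are an error.
    """
    if aggregate not in AGGREGATIONS:
        raise DataError(f"unknown aggregation {aggregate!r}; pick from {AGGREGATIONS}")
    if set(a.histograms) != set(b.histograms):
        raise DataError(
            f"subjects {a.subject_id} and {b.subject_id} have different region sets"
        )
    per_region = []
    for region_id in a.region_ids:
        ha, hb = a.histograms[region_id], b.histograms[region_id]
        if ha is None or hb is None:
            logger.debug(
                "region %d missing in %s or %s; excluded from δ",
                region_id,
                a.subject_id,
                b.subject_id,
            )
            continue
        per_region.append(emd_closed_form(ha, hb))
    if not per_region:
        raise DataError(
            f"no shared regions between {a.subject_id} and {b.subject_id}"
        )
    values = np.asarray(per_region)
    if aggregate == "sum":
        return float(values.sum())
    if aggregate == "mean":
        return float(values.mean())
    return float(values.max())


def pairwise_subject_distances(
    cohort: list[SubjectProfile], aggregate: str = "sum"
) -> pd.DataFrame:
    """Symmetric matrix of δ over a cohort, indexed by subject id."""
    ids = [p.subject_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate subject ids in cohort")
    n = len(cohort)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = subject_distance(cohort[i], cohort[j], aggregate)
    return pd.DataFrame(mat, index=ids, columns=ids)


def medoid_from_distances(distances: pd.DataFrame) -> str:
    """Id of the element with minimal summed distance; exact ties resolve to
    the lexicographically smallest id."""
    if distances.empty:
        raise DataError("empty distance matrix")
    sums = distances.sum(axis=1)
    best = sums.min()
    tied = sorted(str(i) for i in sums.index[sums == best])
    return tied[0]


def find_medoid(cohort: list[SubjectProfile], aggregate: str = "sum") -> str:
    """Subject id minimizing the summed distance to all cohort members."""
    if not cohort:
        raise DataError("cannot take the medoid of an empty cohort")
    if len(cohort) == 1:
        return cohort[0].subject_id
    return medoid_from_distances(pairwise_subject_distances(cohort, aggregate))


def features_to_reference(
    cohort: list[SubjectProfile],
    reference: SubjectProfile,
    label_table: dict[int, RegionLabel] | None = None,
) -> pd.DataFrame:
    """Subjects × regions matrix of EMDs to the reference's regions.

    Columns are region names when a label table is given, else ``region_<id>``.
    Missing regions (in subject or reference) produce NaN entries, handled by
    the classifier as abstentions.
    """
    region_ids = reference.region_ids
    rows = {}
    for profile in cohort:
        if set(profile.histograms) != set(region_ids):
            raise DataError(
                f"subject {profile.subject_id} region set differs from reference"
            )
        row = []
        for region_id in region_ids:
            hs, hr = profile.histograms[region_id], reference.histograms[region_id]
            row.append(
                np.nan if hs is None or hr is None else emd_closed_form(hs, hr)
            )
        rows[profile.subject_id] = row
    if label_table is not None:
        columns = [label_table[r].full_name for r in region_ids]
    else:
        columns = [f"region_{r}" for r in region_ids]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "subject_id"
    return df


def group_profile(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Median distance-to-reference per group and region.

    The polar/box-plot style summaries of disease progression are drawn from
    this table.
    """
    groups = groups.reindex(features.index)
    if groups.isna().any():
        raise DataError("every subject in the feature matrix needs a group label")
    out = features.groupby(groups).median()
    if (features.groupby(groups).size() < 1).any():
        raise DataError("empty group in group_profile")
    out.index.name = "group"
    return out
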