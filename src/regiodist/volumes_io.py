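"""Reading atlas-space brain volumes and extracting per-region intensity samples.

The package consumes skull-stripped volumes that are already registered to a
common atlas space (registration itself is external); alongside each volume
sits an integer label atlas partitioning the brain into named regions, with
0 reserved for background.  The bundled default label table follows the
Harvard-Oxford parcellation: 48 cortical regions per hemisphere plus 17
subcortical structures, 113 regions in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, ShapeMismatchError, UnknownLabelError

logger = logging.getLogger(__name__)

#: Dice threshold below which a subject/atlas brain-mask overlap is flagged.
DEFAULT_DICE_WARN = 0.90


@dataclass(frozen=True)
class RegionLabel:
    """One row of a label table: a named region in one hemisphere."""

    label_id: int
    region_name: str
    hemisphere: str = ""

    @property
    def full_name(self) -> str:
        if self.hemisphere:
            return f"{self.hemisphere} {self.region_name}"
        return self.region_name


@dataclass
class LabelAtlas:
    """3D integer label grid plus the table naming each label.

    Label 0 is background and never appears in the table.
    """

    labels: np.ndarray
    label_table: dict[int, RegionLabel]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError(f"atlas grid must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise DataError("atlas grid holds non-integer labels")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise DataError("atlas labels must be non-negative")
        if 0 in self.label_table:
            raise DataError("label 0 is reserved for background")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise UnknownLabelError(
                f"atlas grid contains labels absent from table: {sorted(unknown)}"
            )

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.label_table)

    def region_name(self, label_id: int) -> str:
        return self.label_table[label_id].full_name

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class IntensityVolume:
    """3D scalar grid of one subject's brain in atlas space.

    Intensities are in arbitrary MR units; voxels outside the brain mask are
    expected to be exactly zero (the preprocessing contract).
    """

    grid: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise DataError(f"intensity grid must be 3D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise DataError(f"non-finite intensities in volume {self.subject_id!r}")

    def brain_mask(self) -> np.ndarray:
        return self.grid != 0


@dataclass
class RegionSample:
    """All intensity values carried by voxels of one labelled region."""

    subject_id: str
    region_id: int
    values: np.ndarray
    missing: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.missing = self.values.size == 0


def load_label_table(path: str | Path) -> dict[int, RegionLabel]:
    """Read a TSV label table (columns: label_id, region_name[, hemisphere])."""
    df = pd.read_csv(path, sep="\t", dtype={"region_name": str})
    if "label_id" not in df.columns or "region_name" not in df.columns:
        raise DataError(f"label table {path} needs label_id and region_name columns")
    table: dict[int, RegionLabel] = {}
    for row in df.itertuples(index=False):
        lid = int(row.label_id)
        if lid == 0:
            raise DataError("label table may not define background label 0")
        if lid in table:
            raise DataError(f"duplicate label id {lid} in {path}")
        hemi = str(getattr(row, "hemisphere", "") or "")
        table[lid] = RegionLabel(lid, str(row.region_name), hemi)
    return table


def default_label_table() -> dict[int, RegionLabel]:
    """The bundled 113-region Harvard-Oxford style table."""
    ref = resources.files("regiodist.data") / "harvard_oxford_113.tsv"
    with resources.as_file(ref) as path:
        return load_label_table(path)


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise DataError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def reduce_probabilistic_atlas(prob_maps: np.ndarray) -> np.ndarray:
    """Collapse a 4D probabilistic atlas to a maximum-probability label map.

    Labels are 1-based in map order; ties resolve to the lowest label id and
    voxels where every map is zero become background.
    """
    if prob_maps.ndim != 4:
        raise DataError("probabilistic atlas must be 4D (x, y, z, label)")
    winner = np.argmax(prob_maps, axis=3).astype(np.int32) + 1
    winner[prob_maps.max(axis=3) <= 0] = 0
    return winner


def load_subject(
    volume_path: str | Path,
    atlas_path: str | Path,
    label_table: dict[int, RegionLabel] | str | Path | None = None,
) -> tuple[IntensityVolume, LabelAtlas]:
    """Load a paired intensity volume and label atlas from NIfTI files.

    ``label_table`` may be a mapping, a TSV path, or None for the bundled
    113-region default.  Raises on dimension mismatch or labels missing from
    the table.
    """
    grid, zooms = _read_nifti(volume_path)
    if grid.ndim != 3:
        raise DataError(f"{volume_path}: expected a 3D volume, got {grid.ndim}D")
    atlas_grid, _ = _read_nifti(atlas_path)
    if atlas_grid.ndim == 4:
        atlas_grid = reduce_probabilistic_atlas(atlas_grid)
    if grid.shape != atlas_grid.shape:
        raise ShapeMismatchError(
            f"volume {grid.shape} and atlas {atlas_grid.shape} dimensions differ"
        )
    if label_table is None:
        table = default_label_table()
    elif isinstance(label_table, (str, Path)):
        table = load_label_table(label_table)
    else:
        table = label_table
    subject_id = Path(volume_path).name.split(".")[0]
    volume = IntensityVolume(grid=grid, voxel_dims=zooms, subject_id=subject_id)
    atlas = LabelAtlas(labels=atlas_grid, label_table=table)
    return volume, atlas


def extract_region_samples(
    volume: IntensityVolume, atlas: LabelAtlas
) -> list[RegionSample]:
    """Collect the intensity values of every region in the label table.

    Regions listed in the table but absent from the grid yield an empty
    sample flagged ``missing``.  Zero-intensity voxels inside labelled
    regions are retained: global background-level differences are removed
    later by center-of-mass alignment of the histograms.
    """
    if volume.grid.shape != atlas.labels.shape:
        raise ShapeMismatchError(
            f"volume {volume.grid.shape} vs atlas {atlas.labels.shape}"
        )
    labels = atlas.labels.ravel()
    values = volume.grid.ravel()
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    sorted_values = values[order]
    bounds = np.searchsorted(sorted_labels, np.arange(sorted_labels.max() + 2))
    samples = []
    for region_id in atlas.region_ids:
        if region_id < len(bounds) - 1:
            lo, hi = bounds[region_id], bounds[region_id + 1]
            vals = sorted_values[lo:hi]
        else:
            vals = np.empty(0)
        if vals.size == 0:
            logger.warning(
                "subject %s: region %d (%s) has no voxels",
                volume.subject_id,
                region_id,
                atlas.region_name(region_id),
            )
        samples.append(RegionSample(volume.subject_id, region_id, vals))
    return samples


def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a = int(a.sum())
    size_b = int(b.sum())
    if size_a + size_b == 0:
        raise DataError("Dice overlap undefined: both masks are empty")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (size_a + size_b)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV (subject_id, volume_path, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "volume_path", "group"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise DataError(f"manifest {path} has duplicate subject ids")
    return df
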