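"""Phantom cohorts: label atlases and volumes with planted group effects.

Each phantom brain is a ball of "tissue" partitioned into contiguous regions
by a seeded nearest-centroid tessellation.  Voxel intensities follow a
two-component Gaussian mixture per region — a bright "dense tissue"
component and a darker "rarefied" one — mirroring the reading of regional
gray-level histograms as proxies for neuronal density.  In patient subjects
the designated affected regions lose dense-tissue fraction (the effect
size), shifting the regional intensity distribution the way neuronal loss
would.  A per-subject global intensity offset emulates scanner gain and is
removed downstream by center-of-mass alignment.

Everything is reproducible from (spec, seed): atlases, volumes and cohort
manifests regenerate identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .volumes_io import IntensityVolume, LabelAtlas, RegionLabel

#: Default group effect: the dense-tissue mixing fraction drops by this much
#: in affected regions of patient subjects.
DEFAULT_EFFECT_SIZE = 0.3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue mixture, and planted group effect of a phantom cohort.

    Intensities are arbitrary units picked to resemble T1 gray/white contrast;
    the mixture parameters matter only through the induced histogram shapes.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    region_count: int = 20
    affected_regions: tuple[int, ...] = (1, 2, 3)
    effect_size: float = DEFAULT_EFFECT_SIZE
    dense_mean: float = 700.0
    rarefied_mean: float = 400.0
    intensity_sd: float = 60.0
    dense_fraction: float = 0.6
    biological_sd: float = 0.12
    subject_offset_sd: float = 20.0
    min_region_voxels: int = 50
    patient_label: str = "AD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_count < 2:
            raise ConfigError("phantom needs at least 2 regions")
        if not 0.0 <= self.effect_size <= self.dense_fraction:
            raise ConfigError(
                "effect_size must lie in [0, dense_fraction] so mixing "
                "fractions stay in [0, 1]"
            )
        bad = [r for r in self.affected_regions if not 1 <= r <= self.region_count]
        if bad:
            raise ConfigError(f"affected regions outside 1..region_count: {bad}")


#: Cohort presets: (spec, n_cn, n_patient).  ``oasis-like`` mirrors a 66
#: control / 20 patient imbalance; ``small`` is sized for quick runs.
PRESETS: dict[str, tuple[PhantomSpec, int, int]] = {
    "small": (PhantomSpec(), 30, 12),
    "oasis-like": (PhantomSpec(shape=(48, 48, 48)), 66, 20),
}


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal brain with a background shell of ~10% per axis."""
    coords = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    dist2 = sum(
        ((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3)
    )
    return dist2 <= 1.0


def phantom_label_table(region_count: int) -> dict[int, RegionLabel]:
    return {
        i: RegionLabel(i, f"Phantom Region {i:03d}") for i in range(1, region_count + 1)
    }


def make_atlas_phantom(spec: PhantomSpec) -> LabelAtlas:
    """Seeded nearest-centroid tessellation of the brain ball into contiguous
    regions, 1..region_count, with background label 0."""
    mask = _brain_mask(spec.shape)
    brain_voxels = np.argwhere(mask)
    if brain_voxels.shape[0] < spec.region_count * spec.min_region_voxels:
        raise ConfigError(
            f"grid {spec.shape} too small for {spec.region_count} regions of "
            f">= {spec.min_region_voxels} voxels"
        )
    rng = np.random.default_rng(spec.seed)
    # resample centroids until no region starves; seeded, so deterministic
    for _ in range(50):
        picks = rng.choice(brain_voxels.shape[0], spec.region_count, replace=False)
        centroids = brain_voxels[picks].astype(float)
        diffs = brain_voxels[:, None, :] - centroids[None, :, :]
        nearest = np.argmin((diffs**2).sum(axis=2), axis=1)
        counts = np.bincount(nearest, minlength=spec.region_count)
        if counts.min() >= spec.min_region_voxels:
            break
    else:
        raise ConfigError(
            f"could not tessellate {spec.shape} into {spec.region_count} regions "
            f"of >= {spec.min_region_voxels} voxels"
        )
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[tuple(brain_voxels.T)] = nearest + 1
    return LabelAtlas(labels=labels, label_table=phantom_label_table(spec.region_count))


def simulate_subject(
    atlas: LabelAtlas,
    spec: PhantomSpec,
    group: str,
    seed: int,
    subject_id: str = "",
) -> IntensityVolume:
    """Draw one subject's volume from the region-wise tissue mixtures.

    Controls use the baseline mixture everywhere; patients use the shifted
    (dense-fraction reduced) mixture in the affected regions.
    """
    if group not in ("CN", spec.patient_label):
        raise DataError(f"unknown group {group!r}; expected CN or {spec.patient_label}")
    rng = np.random.default_rng(seed)
    grid = np.zeros(spec.shape, dtype=float)
    offset = rng.normal(0.0, spec.subject_offset_sd)
    for region_id in atlas.region_ids:
        where = atlas.labels == region_id
        n = int(where.sum())
        if n == 0:
            continue
        # normal anatomical variability: every subject's regional tissue
        # composition jitters around the population baseline
        frac = spec.dense_fraction + rng.normal(0.0, spec.biological_sd)
        if group == spec.patient_label and region_id in spec.affected_regions:
            frac -= spec.effect_size
        dense = rng.random(n) < np.clip(frac, 0.02, 0.98)
        means = np.where(dense, spec.dense_mean, spec.rarefied_mean)
        grid[where] = rng.normal(means + offset, spec.intensity_sd)
    volume = IntensityVolume(
        grid=grid, voxel_dims=(1.0, 1.0, 1.0), subject_id=subject_id or f"{group}-{seed}"
    )
    return volume


def simulate_cohort(
    spec: PhantomSpec,
    n_cn: int,
    n_patient: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[LabelAtlas, list[IntensityVolume], pd.DataFrame]:
    """Generate a labelled cohort; optionally write NIfTI volumes + manifest.

    Subject seeds derive from (seed, subject index) so the cohort is fully
    reproducible: regenerating yields voxel-identical volumes and a
    byte-identical manifest.
    """
    if n_cn < 2 or n_patient < 1:
        raise ConfigError("need n_cn >= 2 and n_patient >= 1")
    atlas = make_atlas_phantom(replace(spec, seed=seed))
    groups = ["CN"] * n_cn + [spec.patient_label] * n_patient
    volumes = []
    rows = []
    for idx, group in enumerate(groups):
        subject_id = f"sub-{idx:03d}-{group}"
        subj_seed = np.random.SeedSequence([seed, idx])
        volume = simulate_subject(
            atlas,
            spec,
            group,
            seed=int(subj_seed.generate_state(1)[0]),
            subject_id=subject_id,
        )
        volumes.append(volume)
        rows.append(
            {"subject_id": subject_id, "volume_path": f"{subject_id}.nii.gz", "group": group}
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        nib.save(
            nib.Nifti1Image(atlas.labels.astype(np.int16), affine),
            out / "atlas.nii.gz",
        )
        table = pd.DataFrame(
            {
                "label_id": atlas.region_ids,
                "region_name": [atlas.label_table[r].region_name for r in atlas.region_ids],
                "hemisphere": [atlas.label_table[r].hemisphere for r in atlas.region_ids],
            }
        )
        table.to_csv(out / "labels.tsv", sep="\t", index=False)
        for volume in volumes:
            nib.save(
                nib.Nifti1Image(volume.grid.astype(np.float32), affine),
                out / f"{volume.subject_id}.nii.gz",
            )
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return atlas, volumes, manifest
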