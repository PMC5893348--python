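"""Pipeline stages: extract → featurize → train → evaluate / apply / rank.

Every stage reads and writes plain-text artifacts (TSV/JSON) and records the
histogram configuration hash, so a model trained on one cohort can only be
applied to features built under the identical configuration and reference —
the guard that keeps cross-database transfer experiments valid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, population
from .errors import ConfigError, DataError
from .histograms import (
    DEFAULT_BIN_COUNT,
    DEFAULT_RANGE_PERCENTILES,
    Histogram,
    frame_to_histograms,
    histograms_to_frame,
)
from .synthetic import PhantomSpec, simulate_cohort
from .volumes_io import (
    DEFAULT_DICE_WARN,
    LabelAtlas,
    default_label_table,
    dice_overlap,
    load_subject,
    read_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized verbatim next to every output."""

    bins: int = DEFAULT_BIN_COUNT
    range_percentiles: tuple[float, float] = DEFAULT_RANGE_PERCENTILES
    aggregate: str = "sum"
    rounds: int = classify.DEFAULT_ROUNDS
    seed: int = 0
    negative_class: str = "CN"
    positive_class: str = "AD"
    dice_warn: float = DEFAULT_DICE_WARN

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ConfigError("bins must be >= 2")
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")
        if self.aggregate not in population.AGGREGATIONS:
            raise ConfigError(f"aggregate must be one of {population.AGGREGATIONS}")
        lo, hi = self.range_percentiles
        if not 0 <= lo < hi <= 100:
            raise ConfigError("range_percentiles must satisfy 0 <= lo < hi <= 100")

    @property
    def classes(self) -> tuple[str, str]:
        return (self.negative_class, self.positive_class)

    def feature_config_hash(self) -> str:
        """Hash of the settings that shape histograms and features."""
        payload = {
            "bins": self.bins,
            "range_percentiles": list(self.range_percentiles),
            "aggregate": self.aggregate,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "range_percentiles" in raw:
            raw["range_percentiles"] = tuple(raw["range_percentiles"])
        return cls(**raw)

    def write(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["range_percentiles"] = list(self.range_percentiles)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _write_run_manifest(out_dir: Path, stage: str, cfg: RunConfig) -> None:
    manifest = {
        "stage": stage,
        "feature_config_hash": cfg.feature_config_hash(),
        "seed": cfg.seed,
    }
    (out_dir / f"{stage}_run.json").write_text(json.dumps(manifest, indent=1) + "\n")


def stage_extract(
    manifest_path: str | Path,
    atlas_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig,
    label_table_path: str | Path | None = None,
) -> pd.DataFrame:
    """Load every cohort volume, build aligned histograms, and QC overlap.

    Writes ``histograms.tsv`` (one row per subject·region), ``dice_qc.tsv``
    (subject brain mask vs atlas brain mask), and the run manifest.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_rows = []
    qc_rows = []
    for rec in manifest.itertuples(index=False):
        vol_path = manifest_path.parent / rec.volume_path
        volume, atlas = load_subject(vol_path, atlas_path, label_table_path)
        volume.subject_id = rec.subject_id
        score = dice_overlap(volume.brain_mask(), atlas.brain_mask())
        if score < cfg.dice_warn:
            logger.warning(
                "subject %s: brain/atlas Dice %.3f below %.2f",
                rec.subject_id,
                score,
                cfg.dice_warn,
            )
        qc_rows.append({"subject_id": rec.subject_id, "dice": score})
        profile = population.build_profile(
            volume,
            atlas,
            group=rec.group,
            bin_count=cfg.bins,
            range_percentiles=cfg.range_percentiles,
        )
        hists = [h for h in profile.histograms.values() if h is not None]
        all_rows.append(histograms_to_frame(hists))
    frame = pd.concat(all_rows, ignore_index=True)
    frame.to_csv(out / "histograms.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(out / "dice_qc.tsv", sep="\t", index=False)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    _write_run_manifest(out, "extract", cfg)
    return frame


def profiles_from_histogram_frame(
    frame: pd.DataFrame, manifest: pd.DataFrame, region_ids: list[int]
) -> list[population.SubjectProfile]:
    """Rehydrate SubjectProfiles from the cached histogram table."""
    groups = dict(zip(manifest["subject_id"], manifest["group"]))
    histograms = frame_to_histograms(frame)
    by_subject: dict[str, dict[int, Histogram | None]] = {
        str(s): {r: None for r in region_ids} for s in manifest["subject_id"]
    }
    for h in histograms:
        if h.subject_id not in by_subject:
            raise DataError(f"histogram for unknown subject {h.subject_id}")
        by_subject[h.subject_id][h.region_id] = h
    return [
        population.SubjectProfile(subject_id=s, group=groups[s], histograms=hs)
        for s, hs in by_subject.items()
    ]


def save_reference_profile(
    path: str | Path, reference: population.SubjectProfile, cfg: RunConfig
) -> None:
    payload = {
        "subject_id": reference.subject_id,
        "group": reference.group,
        "feature_config_hash": cfg.feature_config_hash(),
        "histograms": {
            str(r): (None if h is None else [float(v) for v in h.masses])
            for r, h in reference.histograms.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_reference_profile(
    path: str | Path,
) -> tuple[population.SubjectProfile, str]:
    payload = json.loads(Path(path).read_text())
    histograms = {
        int(r): (
            None
            if masses is None
            else Histogram(
                np.asarray(masses), subject_id=payload["subject_id"], region_id=int(r)
            )
        )
        for r, masses in payload["histograms"].items()
    }
    profile = population.SubjectProfile(
        subject_id=payload["subject_id"],
        group=payload.get("group", ""),
        histograms=histograms,
    )
    return profile, payload["feature_config_hash"]


def stage_featurize(
    extract_dir: str | Path,
    out_dir: str | Path,
    cfg: RunConfig,
    reference_path: str | Path | None = None,
) -> pd.DataFrame:
    """Find the control medoid (or load a stored reference) and build the
    distance feature matrix.

    Writes ``features.tsv``, ``reference.json`` and ``groups.tsv``.  When a
    stored reference is supplied its configuration hash must match the
    current configuration — applying a reference built under different
    histogram settings would silently invalidate the distances.
    """
    extract_dir = Path(extract_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(extract_dir / "histograms.tsv", sep="\t")
    manifest = read_manifest(extract_dir / "manifest.tsv")
    run_meta = json.loads((extract_dir / "extract_run.json").read_text())
    if run_meta["feature_config_hash"] != cfg.feature_config_hash():
        raise ConfigError(
            "histogram cache was built under a different configuration; re-extract"
        )
    if reference_path is not None:
        reference, ref_hash = load_reference_profile(reference_path)
        if ref_hash != cfg.feature_config_hash():
            raise ConfigError(
                "stored reference profile was built under a different "
                "histogram configuration; refusing to featurize against it"
            )
        region_ids = reference.region_ids
        profiles = profiles_from_histogram_frame(frame, manifest, region_ids)
    else:
        region_ids = sorted(frame["region_id"].unique())
        profiles = profiles_from_histogram_frame(frame, manifest, region_ids)
        controls = [p for p in profiles if p.group == cfg.negative_class]
        if not controls:
            raise DataError(f"no {cfg.negative_class} subjects to take the medoid of")
        medoid_id = population.find_medoid(controls, cfg.aggregate)
        reference = next(p for p in profiles if p.subject_id == medoid_id)
    features = population.features_to_reference(profiles, reference)
    features.to_csv(out / "features.tsv", sep="\t")
    manifest[["subject_id", "group"]].to_csv(out / "groups.tsv", sep="\t", index=False)
    save_reference_profile(out / "reference.json", reference, cfg)
    _write_run_manifest(out, "featurize", cfg)
    return features


def _load_features(feature_dir: str | Path) -> tuple[pd.DataFrame, pd.Series, str]:
    feature_dir = Path(feature_dir)
    features = pd.read_csv(feature_dir / "features.tsv", sep="\t", index_col="subject_id")
    groups = pd.read_csv(feature_dir / "groups.tsv", sep="\t", index_col="subject_id")[
        "group"
    ]
    run_meta = json.loads((feature_dir / "featurize_run.json").read_text())
    return features, groups.reindex(features.index), run_meta["feature_config_hash"]


def stage_train(
    feature_dir: str | Path, out_dir: str | Path, cfg: RunConfig
) -> classify.BoostedEnsemble:
    """Train one RUSBoost ensemble on the whole cohort and save it."""
    features, groups, feat_hash = _load_features(feature_dir)
    mask = groups.isin(cfg.classes)
    model = classify.train_rusboost(
        features[mask],
        groups[mask],
        rounds=cfg.rounds,
        seed=cfg.seed,
        classes=cfg.classes,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = model.to_dict()
    payload["feature_config_hash"] = feat_hash
    payload["feature_columns"] = list(features.columns)
    (out / "model.json").write_text(json.dumps(payload, indent=1) + "\n")
    _write_run_manifest(out, "train", cfg)
    return model


def stage_evaluate_loocv(
    feature_dir: str | Path, out_dir: str | Path, cfg: RunConfig
) -> tuple[classify.ROCResult, pd.Series]:
    """Leave-one-out ROC plus averaged region importance; writes roc.tsv,
    importance.tsv, scores.tsv and summary.json."""
    features, groups, _ = _load_features(feature_dir)
    mask = groups.isin(cfg.classes)
    roc, models = classify.loocv_evaluate(
        features[mask],
        groups[mask],
        rounds=cfg.rounds,
        seed=cfg.seed,
        classes=cfg.classes,
    )
    importance = classify.feature_importance(models, list(features.columns))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roc.to_frame().to_csv(out / "roc.tsv", sep="\t", index=False)
    ranked = importance.sort_values(ascending=False, kind="stable")
    ranked.rename_axis("region").to_csv(out / "importance.tsv", sep="\t")
    pd.DataFrame(
        {"subject_id": roc.scores.index, "score": roc.scores.values, "group": roc.labels.values}
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps({"auc": roc.auc, "eer": roc.eer, "n": int(mask.sum())}, indent=1)
        + "\n"
    )
    _write_run_manifest(out, "evaluate", cfg)
    return roc, importance


def stage_apply(
    model_path: str | Path, feature_dir: str | Path, out_dir: str | Path, cfg: RunConfig
) -> pd.DataFrame:
    """Score a new cohort with a stored model (the transfer experiment).

    Hard-errors when the feature matrix was built under a histogram
    configuration different from the one the model was trained on.
    """
    payload = json.loads(Path(model_path).read_text())
    model = classify.BoostedEnsemble.from_dict(payload)
    features, groups, feat_hash = _load_features(feature_dir)
    if payload.get("feature_config_hash") != feat_hash:
        raise ConfigError(
            "model was trained under a different feature configuration "
            f"({payload.get('feature_config_hash')} vs {feat_hash}); "
            "re-featurize with the training configuration and reference"
        )
    scores = classify.ensemble_score(model, features.to_numpy(dtype=float))
    neg, pos = model.classes
    predictions = pd.DataFrame(
        {
            "subject_id": features.index,
            "score": scores,
            "predicted": np.where(scores > 0, pos, neg),
            "group": groups.values,
        }
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    known = predictions["group"].isin(model.classes)
    if known.any():
        sub = predictions[known]
        tp = ((sub.group == pos) & (sub.predicted == pos)).sum()
        tn = ((sub.group == neg) & (sub.predicted == neg)).sum()
        n_pos = (sub.group == pos).sum()
        n_neg = (sub.group == neg).sum()
        summary = {
            "sensitivity": float(tp / n_pos) if n_pos else None,
            "specificity": float(tn / n_neg) if n_neg else None,
            "n": int(known.sum()),
        }
        (out / "apply_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    _write_run_manifest(out, "apply", cfg)
    return predictions


def phantom_experiment(
    spec: PhantomSpec,
    n_cn: int = 30,
    n_patient: int = 12,
    master_seed: int = 0,
    rounds: int = classify.DEFAULT_ROUNDS,
    bins: int = DEFAULT_BIN_COUNT,
    top_k: int = 5,
) -> dict:
    """Full in-memory pipeline on one simulated cohort.

    Simulates the cohort, builds aligned histograms, takes the control
    medoid, featurizes, runs leave-one-out RUSBoost, and checks how many of
    the planted affected regions land in the top-``top_k`` of the averaged
    importance ranking.
    """
    atlas, volumes, manifest = simulate_cohort(spec, n_cn, n_patient, seed=master_seed)
    profiles = [
        population.build_profile(v, atlas, group=g, bin_count=bins)
        for v, g in zip(volumes, manifest["group"])
    ]
    controls = [p for p in profiles if p.group == "CN"]
    medoid_id = population.find_medoid(controls)
    reference = next(p for p in profiles if p.subject_id == medoid_id)
    features = population.features_to_reference(profiles, reference, atlas.label_table)
    labels = pd.Series(manifest["group"].to_numpy(), index=features.index)
    roc, models = classify.loocv_evaluate(
        features,
        labels,
        rounds=rounds,
        seed=master_seed,
        classes=("CN", spec.patient_label),
    )
    importance = classify.feature_importance(models, list(features.columns))
    # only regions the ensembles actually used can occupy a rank
    ranked = importance[importance > 0].sort_values(ascending=False, kind="stable")
    planted = {atlas.label_table[r].full_name for r in spec.affected_regions}
    planted_in_top = len(planted & set(ranked.head(top_k).index))
    return {
        "auc": roc.auc,
        "eer": roc.eer,
        "roc": roc,
        "importance": importance,
        "planted_in_top": planted_in_top,
        "medoid": medoid_id,
        "features": features,
        "labels": labels,
        "atlas": atlas,
    }
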