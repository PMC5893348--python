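"""RUSBoost ensemble of decision stumps, region importance, and LOOCV ROC.

The weak learner is a single-feature threshold on the distance to the
control-medoid for one region.  Because patient groups are typically much
smaller than the control group, each boosting round first randomly
undersamples the majority class down to the minority size (RUSBoost), fits
the stump on that balanced subset, then evaluates its weighted error and
updates weights on the full cohort (AdaBoost rule).  Region importance is
the alpha-weighted share of stumps using each region, averaged over the
leave-one-out models and normalized to percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .errors import ConfigError, DataError

DEFAULT_ROUNDS = 100
_EPS_CLAMP = 1e-10


@dataclass(frozen=True)
class DecisionStump:
    """Threshold on one region's feature; polarity +1 votes patient above it."""

    region_index: int
    threshold: float
    polarity: int
    alpha: float = 0.0
    degenerate: bool = False

    def votes(self, features: np.ndarray) -> np.ndarray:
        """±1 votes per sample; NaN features abstain with 0."""
        values = np.atleast_2d(features)[:, self.region_index]
        out = np.where(values > self.threshold, self.polarity, -self.polarity)
        return np.where(np.isnan(values), 0, out).astype(float)


@dataclass
class BoostedEnsemble:
    """Ordered weighted stumps plus the training configuration."""

    stumps: list[DecisionStump] = field(default_factory=list)
    n_features: int = 0
    rounds: int = 0
    seed: int | None = None
    classes: tuple[str, str] = ("CN", "AD")  # (negative, positive)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_features": self.n_features,
            "rounds": self.rounds,
            "seed": self.seed,
            "stumps": [
                {
                    "region_index": s.region_index,
                    "threshold": s.threshold,
                    "polarity": s.polarity,
                    "alpha": s.alpha,
                }
                for s in self.stumps
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BoostedEnsemble":
        return cls(
            stumps=[DecisionStump(**s) for s in payload["stumps"]],
            n_features=payload["n_features"],
            rounds=payload["rounds"],
            seed=payload.get("seed"),
            classes=tuple(payload["classes"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BoostedEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ROCResult:
    """Pooled out-of-fold ROC with AUC and equal error rate."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    eer: float
    scores: pd.Series
    labels: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def _as_signed(labels: np.ndarray, classes: tuple[str, str]) -> np.ndarray:
    neg, pos = classes
    labels = np.asarray(labels)
    known = np.isin(labels, [neg, pos])
    if not known.all():
        raise DataError(f"labels outside {classes}: {set(labels[~known])}")
    return np.where(labels == pos, 1.0, -1.0)


def fit_stump(
    features: np.ndarray, y: np.ndarray, sample_weights: np.ndarray
) -> DecisionStump:
    """Exhaustive best single-feature threshold under weighted 0-1 loss.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each region; ties resolve to the lowest region index, then the
    lowest threshold, then polarity +1.  NaN feature values make the stump
    abstain on that sample, which costs half its weight.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.asarray(sample_weights, dtype=float)
    if features.shape[0] != y.size or y.size != w.size:
        raise DataError("features, labels and weights must agree in length")
    pos_w = w[y > 0].sum()
    neg_w = w[y < 0].sum()
    if pos_w <= 0 or neg_w <= 0:
        raise DataError("both classes need positive total weight")
    best: tuple[float, int, float, int] | None = None  # (err, region, thr, pol)
    best_degenerate = False
    for region in range(features.shape[1]):
        values = features[:, region]
        present = ~np.isnan(values)
        abstain_cost = 0.5 * w[~present].sum()
        v, yy, ww = values[present], y[present], w[present]
        order = np.argsort(v, kind="stable")
        v, yy, ww = v[order], yy[order], ww[order]
        if v.size == 0:
            continue
        distinct = np.nonzero(np.diff(v) > 0)[0]  # split after these positions
        if distinct.size == 0:
            candidates = np.array([v[0]])
            degenerate = True
        else:
            candidates = (v[distinct] + v[distinct + 1]) / 2.0
            degenerate = False
        # error of polarity +1 with k samples at/below the threshold:
        #   misses = positives below + negatives above
        cum_pos = np.cumsum(np.where(yy > 0, ww, 0.0))
        cum_neg = np.cumsum(np.where(yy < 0, ww, 0.0))
        ks = (distinct + 1) if distinct.size else np.array([v.size])
        err_pos = cum_pos[ks - 1] + (cum_neg[-1] - cum_neg[ks - 1]) + abstain_cost
        # flipping polarity swaps right/wrong on present samples only; the
        # two abstention half-costs cancel, leaving total − err_pos
        err_neg = (pos_w + neg_w) - err_pos
        for thr, ep, en in zip(candidates, err_pos, err_neg):
            for err, pol in ((ep, 1), (en, -1)):
                key = (err, region, thr, -pol)
                if best is None or key < best:
                    best = key
                    best_degenerate = degenerate
    if best is None:
        raise DataError("no usable feature values to fit a stump")
    err, region, thr, neg_pol = best
    return DecisionStump(
        region_index=int(region),
        threshold=float(thr),
        polarity=int(-neg_pol),
        degenerate=best_degenerate,
    )


def train_rusboost(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    rounds: int = DEFAULT_ROUNDS,
    seed: int | None = None,
    classes: tuple[str, str] = ("CN", "AD"),
) -> BoostedEnsemble:
    """Boost decision stumps with per-round random undersampling.

    Each round draws a balanced subset (majority class undersampled to the
    minority size, without replacement, seeded), fits the stump there, then
    computes the weighted error ε on the FULL cohort; alpha = ½·ln((1−ε)/ε)
    with ε clamped away from {0, ½}.  Training stops early when ε ≥ ½.
    Deterministic given (inputs, seed).
    """
    if rounds < 1:
        raise ConfigError("rounds must be >= 1")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _as_signed(np.asarray(labels), classes)
    n = y.size
    if X.shape[0] != n:
        raise DataError("feature rows and labels disagree")
    if (y > 0).sum() == 0 or (y < 0).sum() == 0:
        raise DataError("training needs both classes present")
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    pos_idx = np.flatnonzero(y > 0)
    neg_idx = np.flatnonzero(y < 0)
    minority, majority = sorted((pos_idx, neg_idx), key=len)
    ensemble = BoostedEnsemble(
        n_features=X.shape[1], rounds=rounds, seed=seed, classes=classes
    )
    for _ in range(rounds):
        kept = rng.choice(majority, size=len(minority), replace=False)
        subset = np.sort(np.concatenate([minority, kept]))
        sub_w = w[subset]
        stump = fit_stump(X[subset], y[subset], sub_w / sub_w.sum())
        votes = stump.votes(X)
        # abstentions (vote 0) cost half weight; wrong votes full weight
        eps = float(np.sum(w * (1.0 - y * votes) / 2.0))
        if eps >= 0.5:
            break
        eps_c = min(max(eps, _EPS_CLAMP), 0.5 - _EPS_CLAMP)
        alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
        ensemble.stumps.append(
            DecisionStump(
                stump.region_index,
                stump.threshold,
                stump.polarity,
                alpha=float(alpha),
                degenerate=stump.degenerate,
            )
        )
        w = w * np.exp(-alpha * y * votes)
        w = w / w.sum()
    return ensemble


def ensemble_score(
    model: BoostedEnsemble, feature_row: np.ndarray
) -> float | np.ndarray:
    """Alpha-weighted sum of stump votes; larger means more patient-like."""
    row = np.asarray(feature_row, dtype=float)
    single = row.ndim == 1
    X = np.atleast_2d(row)
    if model.n_features and X.shape[1] != model.n_features:
        raise DataError(
            f"feature length {X.shape[1]} does not match model ({model.n_features})"
        )
    scores = np.zeros(X.shape[0])
    for stump in model.stumps:
        scores += stump.alpha * stump.votes(X)
    return float(scores[0]) if single else scores


def feature_importance(
    ensembles: list[BoostedEnsemble],
    region_names: list[str] | None = None,
) -> pd.Series:
    """Per-region relevance as percentages summing to 100.

    Within each ensemble a region's raw importance is the sum of the alphas
    of the stumps that threshold it; the shares are averaged across
    ensembles (e.g. the leave-one-out models) and scaled to percent.
    """
    if not ensembles:
        raise DataError("feature importance needs at least one ensemble")
    n_features = max(e.n_features for e in ensembles)
    shares = np.zeros(n_features)
    contributing = 0
    for ensemble in ensembles:
        raw = np.zeros(n_features)
        for stump in ensemble.stumps:
            raw[stump.region_index] += stump.alpha
        total = raw.sum()
        if total > 0:
            shares += raw / total
            contributing += 1
    if contributing == 0:
        raise DataError("all ensembles are empty; no importance defined")
    percent = 100.0 * shares / shares.sum()
    if region_names is None:
        region_names = [f"region_{i}" for i in range(n_features)]
    return pd.Series(percent, index=region_names, name="importance_percent")


def roc_from_scores(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    classes: tuple[str, str] = ("CN", "AD"),
) -> ROCResult:
    """ROC, trapezoid AUC and interpolated equal error rate from pooled scores."""
    s = pd.Series(np.asarray(scores, dtype=float))
    y = _as_signed(np.asarray(labels), classes)
    fpr, tpr, thr = roc_curve(y, s.to_numpy(), pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    eer = _equal_error_rate(fpr, tpr)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        eer=eer,
        scores=s,
        labels=pd.Series(np.asarray(labels)),
    )


def _equal_error_rate(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """FPR at the point where FPR = FNR, linearly interpolating between
    adjacent ROC vertices."""
    fnr = 1.0 - tpr
    gap = fpr - fnr  # non-decreasing along the curve from -1 to +1
    idx = int(np.searchsorted(gap, 0.0, side="left"))
    if idx == 0:
        return float(fpr[0])
    if idx >= gap.size:
        return float(fpr[-1])
    g0, g1 = gap[idx - 1], gap[idx]
    if g1 == g0:
        return float(fpr[idx])
    t = -g0 / (g1 - g0)
    return float(fpr[idx - 1] + t * (fpr[idx] - fpr[idx - 1]))


def loocv_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    rounds: int = DEFAULT_ROUNDS,
    seed: int | None = None,
    classes: tuple[str, str] = ("CN", "AD"),
) -> tuple[ROCResult, list[BoostedEnsemble]]:
    """Leave-one-out evaluation: n models, each scoring its held-out subject.

    Out-of-fold scores are pooled into one ROC.  Per-fold seeds derive
    deterministically from the master seed, so the whole evaluation is
    reproducible bit-for-bit.  Returns the ROC and the per-fold models (for
    importance averaging).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = y.size
    if n < 3:
        raise DataError("leave-one-out needs at least 3 subjects")
    signed = _as_signed(y, classes)
    if (signed > 0).sum() < 2 or (signed < 0).sum() < 2:
        raise DataError("each class needs >= 2 subjects so every fold keeps both")
    scores = np.zeros(n)
    models = []
    for i in range(n):
        keep = np.arange(n) != i
        fold_seed = np.random.SeedSequence([0 if seed is None else seed, i])
        model = train_rusboost(
            X[keep],
            y[keep],
            rounds=rounds,
            seed=int(fold_seed.generate_state(1)[0]),
            classes=classes,
        )
        scores[i] = ensemble_score(model, X[i])
        models.append(model)
    roc = roc_from_scores(
        pd.Series(scores, index=features.index), y, classes=classes
    )
    return roc, models
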