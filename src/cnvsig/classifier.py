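"""Nearest-shrunken-centroid outcome classifier and cross-batch normalization.

The classifier follows the shrunken-centroid construction: per-probe class
centroids are standardised against the overall centroid using the pooled
within-class scatter s_i plus a fudge constant s0 (median of s_i by default),
soft-thresholded by a shrinkage level delta, and samples are assigned to the
class whose shrunken centroid is nearest in standardised squared distance,
penalised by -2 log(prior).  Delta is chosen by stratified cross-validated
misclassification error with ties broken toward more shrinkage.

Validation cohorts profiled in a separate array batch are first rescaled so
that each gene's median (linear-scale) expression matches the reference
batch's median for that gene — an exact, idempotent per-gene multiplicative
correction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# median-match normalization
# ---------------------------------------------------------------------------

def median_match_normalize(
    batch: pd.DataFrame,
    reference: pd.DataFrame,
    data_scale: str = "log2",
) -> pd.DataFrame:
    """Rescale ``batch`` so each gene's median matches the reference median.

    The per-gene factor is reference_median / batch_median on the linear
    scale; for ``data_scale='log2'`` matrices this is the equivalent additive
    per-gene offset of log2(factor).  The operation is exact (post-hoc batch
    medians equal reference medians to floating tolerance) and idempotent.
    """
    if data_scale not in ("log2", "linear"):
        raise ValueError("data_scale must be 'log2' or 'linear'")
    common = batch.index.intersection(reference.index)
    if len(common) < len(batch.index):
        raise ValueError("reference lacks some genes of the batch")
    if data_scale == "linear":
        if (batch.to_numpy() <= 0).any() or (reference.to_numpy() <= 0).any():
            raise ValueError("linear intensities must be positive")
        batch_med = batch.median(axis=1)
        ref_med = reference.loc[batch.index].median(axis=1)
        if (batch_med == 0).any():
            raise ValueError("zero batch median; factor undefined")
        return batch.mul(ref_med / batch_med, axis=0)
    # log2 scale: match medians of the anti-logged values via an additive shift
    batch_med = np.exp2(batch).median(axis=1)
    ref_med = np.exp2(reference.loc[batch.index]).median(axis=1)
    if (batch_med <= 0).any():
        raise ValueError("zero batch median; factor undefined")
    return batch.add(np.log2(ref_med / batch_med), axis=0)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    probe_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray          # (p,)
    class_centroids: np.ndarray           # (K, p) raw
    shrunken_offsets: np.ndarray          # (K, p) soft-thresholded d'_ik
    s: np.ndarray                         # (p,) pooled within-class scatter
    s0: float
    mk: np.ndarray                        # (K,) sqrt(1/n_k - 1/n)
    delta: float
    priors: np.ndarray                    # (K,)
    delta_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_fold_errors: list[list[int]] = field(default_factory=list)
    seed: int | None = None

    def shrunken_centroids(self) -> np.ndarray:
        """(K, p) class centroids after shrinkage toward the overall centroid."""
        scale = self.mk[:, None] * (self.s + self.s0)[None, :]
        return self.overall_centroid[None, :] + scale * self.shrunken_offsets

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probe_ids": self.probe_ids, "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_offsets": self.shrunken_offsets.tolist(),
            "s": self.s.tolist(), "s0": self.s0, "mk": self.mk.tolist(),
            "delta": self.delta, "priors": self.priors.tolist(),
            "delta_grid": self.delta_grid.tolist(),
            "cv_errors": self.cv_errors.tolist(), "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        d = json.loads(Path(path).read_text())
        return cls(
            probe_ids=list(d["probe_ids"]), classes=list(d["classes"]),
            overall_centroid=np.array(d["overall_centroid"]),
            class_centroids=np.array(d["class_centroids"]),
            shrunken_offsets=np.array(d["shrunken_offsets"]),
            s=np.array(d["s"]), s0=float(d["s0"]), mk=np.array(d["mk"]),
            delta=float(d["delta"]), priors=np.array(d["priors"]),
            delta_grid=np.array(d["delta_grid"]),
            cv_errors=np.array(d["cv_errors"]), seed=d.get("seed"))


@dataclass
class PredictionResult:
    predicted: pd.Series                 # class label per sample
    discriminant: pd.DataFrame           # samples x classes scores (lower = closer)
    posterior: pd.DataFrame              # softmax(-score/2) weights


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _fit_components(X: np.ndarray, y: np.ndarray, classes: list[str],
                    s0: float | None):
    """Raw centroids, pooled scatter and standardised offsets d_ik."""
    n, p = X.shape[1], X.shape[0]
    overall = X.mean(axis=1)
    cents, counts = [], []
    ss = np.zeros(p)
    for k in classes:
        cols = X[:, y == k]
        counts.append(cols.shape[1])
        mu = cols.mean(axis=1)
        cents.append(mu)
        ss += ((cols - mu[:, None]) ** 2).sum(axis=1)
    counts = np.array(counts)
    cents = np.stack(cents)
    s = np.sqrt(ss / (n - len(classes)))
    if s0 is None:
        s0 = float(np.median(s))
    mk = np.sqrt(1.0 / counts - 1.0 / n)
    dik = (cents - overall[None, :]) / (mk[:, None] * (s + s0)[None, :])
    return overall, cents, s, s0, mk, dik, counts


def nsc_train(
    expression: pd.DataFrame,
    labels: pd.Series,
    delta_grid: np.ndarray | int | None = 30,
    cv_folds: int = 10,
    seed: int | None = None,
    priors: str = "empirical",
    s0: float | None = None,
) -> CentroidModel:
    """Fit the shrunken-centroid model with cross-validated shrinkage.

    ``expression`` is probes x samples (log2); ``labels`` maps sample ids to
    class names.  ``delta_grid`` is either an explicit grid or the number of
    grid points spread over [0, max standardised offset].  Stratified
    ``cv_folds``-fold CV picks delta (minimum misclassification, ties toward
    the largest delta); when a class has fewer members than ``cv_folds`` the
    fold count is reduced to the smallest class size, with a warning.
    """
    if priors not in ("empirical", "uniform"):
        raise ValueError("priors must be 'empirical' or 'uniform'")
    labels = labels.reindex(expression.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    X = expression.to_numpy(dtype=float)
    y = labels.to_numpy()
    overall, cents, s, s0_, mk, dik, counts = _fit_components(X, y, classes, s0)

    if isinstance(delta_grid, (int, np.integer)) or delta_grid is None:
        n_points = 30 if delta_grid is None else int(delta_grid)
        grid = np.linspace(0.0, float(np.abs(dik).max()), n_points)
    else:
        grid = np.asarray(delta_grid, dtype=float)

    min_class = counts.min()
    folds = int(min(cv_folds, min_class))
    if folds < cv_folds:
        warnings.warn(f"reducing CV folds to smallest class size ({folds})",
                      stacklevel=2)
    if folds < 2:
        raise ValueError("smallest class has fewer than 2 members; cannot CV")

    prior_vec = counts / counts.sum() if priors == "empirical" \
        else np.full(len(classes), 1.0 / len(classes))

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_errors: list[list[int]] = [[] for _ in grid]
    for train_idx, test_idx in skf.split(X.T, y):
        ov, _, s_f, s0_f, mk_f, dik_f, counts_f = _fit_components(
            X[:, train_idx], y[train_idx], classes, s0)
        pri = counts_f / counts_f.sum() if priors == "empirical" \
            else np.full(len(classes), 1.0 / len(classes))
        Xt = X[:, test_idx]
        for gi, delta in enumerate(grid):
            shrunk = ov[None, :] + mk_f[:, None] * (s_f + s0_f)[None, :] \
                * _soft_threshold(dik_f, delta)
            scores = _discriminant(Xt, shrunk, s_f, s0_f, pri)
            pred = np.array(classes)[np.argmin(scores, axis=1)]
            fold_errors[gi].append(int((pred != y[test_idx]).sum()))
    cv_errors = np.array([sum(fe) for fe in fold_errors], dtype=float) / len(y)
    best = np.flatnonzero(cv_errors == cv_errors.min())[-1]  # ties -> more shrinkage
    delta = float(grid[best])

    return CentroidModel(
        probe_ids=list(expression.index), classes=classes,
        overall_centroid=overall, class_centroids=cents,
        shrunken_offsets=_soft_threshold(dik, delta),
        s=s, s0=s0_, mk=mk, delta=delta, priors=prior_vec,
        delta_grid=grid, cv_errors=cv_errors, cv_fold_errors=fold_errors,
        seed=seed)


def _discriminant(X: np.ndarray, shrunken: np.ndarray, s: np.ndarray,
                  s0: float, priors: np.ndarray) -> np.ndarray:
    """Scores (samples x classes): standardised squared distance - 2 log prior."""
    denom = (s + s0)[:, None]
    scores = np.empty((X.shape[1], shrunken.shape[0]))
    for k in range(shrunken.shape[0]):
        scores[:, k] = (((X - shrunken[k][:, None]) / denom) ** 2).sum(axis=0) \
            - 2.0 * math.log(priors[k])
    return scores


def nsc_predict(model: CentroidModel, expression: pd.DataFrame) -> PredictionResult:
    """Assign each sample (column) to the nearest shrunken class centroid.

    Every model probe must be present in ``expression`` (missing probes raise
    rather than being dropped silently).  Ties in the discriminant go to the
    first class in the model's (sorted) class order — deterministic.
    """
    missing = [p for p in model.probe_ids if p not in expression.index]
    if missing:
        raise KeyError(f"expression matrix lacks model probes: {missing[:5]}...")
    X = expression.loc[model.probe_ids].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    scores = _discriminant(X, model.shrunken_centroids(), model.s, model.s0,
                           model.priors)
    pred = np.array(model.classes)[np.argmin(scores, axis=1)]
    disc = pd.DataFrame(scores, index=expression.columns, columns=model.classes)
    w = np.exp(-0.5 * (scores - scores.min(axis=1, keepdims=True)))
    posterior = pd.DataFrame(w / w.sum(axis=1, keepdims=True),
                             index=expression.columns, columns=model.classes)
    return PredictionResult(pd.Series(pred, index=expression.columns),
                            disc, posterior)
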