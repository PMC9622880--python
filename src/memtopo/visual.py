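"""Predicting memory ratings from per-video visual features.

Implements the cross-validated support-vector-regression protocol: per
session, 25 random 80/20 train/test splits of the videos; a linear-kernel
SVR (features standardized on the training rows only) predicts the
target, and the iteration's score is the Pearson r between prediction and
truth on the held-out rows. Group inference uses Wilcoxon signed-rank
tests (one-sample against a zero median, or paired between two feature
sets), which avoid normality assumptions on correlation coefficients.

Feature extraction itself (DNN layer activations, optical-flow motion) is
a pluggable input; this module implements the prediction and correlation
protocols only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .datatypes import SampleSession


@dataclass
class PredictionScore:
    sample_id: str
    mean_r: float
    per_iteration_r: np.ndarray
    n_iterations: int
    train_fraction: float
    seed: int


def svr_cv_score(
    features: np.ndarray,
    target: np.ndarray,
    sample_id: str = "sample",
    train_fraction: float = 0.8,
    n_iterations: int = 25,
    seed: int = 0,
) -> PredictionScore:
    """Mean held-out Pearson r of a linear SVR over random splits.

    An iteration with constant predictions (or a constant held-out
    target) scores 0 with a warning; the target overall must vary.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be [n_videos x n_features] aligned to target")
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 videos")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and target must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant target; correlation undefined")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    if not 1 <= n_train <= n - 2:
        raise ValueError("train_fraction leaves too few train or test rows")
    rs = np.empty(n_iterations)
    for it in range(n_iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        scaler = StandardScaler().fit(X[tr])
        model = SVR(kernel="linear")
        model.fit(scaler.transform(X[tr]), y[tr])
        pred = model.predict(scaler.transform(X[te]))
        if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
            warnings.warn(
                f"{sample_id}: iteration {it} had constant predictions or "
                "held-out targets; scoring 0", stacklevel=2,
            )
            rs[it] = 0.0
        else:
            rs[it] = np.corrcoef(pred, y[te])[0, 1]
    return PredictionScore(
        sample_id=sample_id, mean_r=float(rs.mean()), per_iteration_r=rs,
        n_iterations=n_iterations, train_fraction=train_fraction, seed=seed,
    )


def group_prediction_test(
    scores: Sequence[PredictionScore],
    paired_scores: Optional[Sequence[PredictionScore]] = None,
) -> dict:
    """Wilcoxon signed-rank of per-session mean r against a zero median;
    optionally a paired signed-rank between two score sets."""
    r = np.array([s.mean_r for s in scores], dtype=float)
    if r.size < 5:
        raise ValueError("group test needs >= 5 samples")
    res = stats.wilcoxon(r, alternative="two-sided")
    out = {"statistic": float(res.statistic), "p": float(res.pvalue),
           "n": r.size, "median_r": float(np.median(r))}
    if paired_scores is not None:
        r2 = np.array([s.mean_r for s in paired_scores], dtype=float)
        if r2.size != r.size:
            raise ValueError("paired score sets differ in length")
        pres = stats.wilcoxon(r, r2, alternative="two-sided")
        out["paired"] = {"statistic": float(pres.statistic),
                         "p": float(pres.pvalue)}
    return out


def motion_spearman(
    motion_by_sample: Sequence[np.ndarray],
    sessions: Sequence[SampleSession],
    target: str = "memory_strength",
) -> dict:
    """Per-session Spearman rho between per-video motion magnitude and a
    rating, with a group Wilcoxon signed-rank against a zero median."""
    if len(motion_by_sample) != len(sessions):
        raise ValueError("one motion vector per session required")
    rhos = []
    for m, s in zip(motion_by_sample, sessions):
        m = np.asarray(m, dtype=float)
        y = s.predictor(target)
        if m.shape != y.shape:
            raise ValueError(f"session {s.sample_id}: motion length mismatch")
        r, _ = stats.spearmanr(m, y)
        rhos.append(float(r))
    rhos = np.array(rhos)
    res = stats.wilcoxon(rhos, alternative="two-sided")
    return {"per_sample_rho": rhos, "mean_rho": float(rhos.mean()),
            "statistic": float(res.statistic), "p": float(res.pvalue)}


def predict_region_activity(
    features: np.ndarray,
    region_means: np.ndarray,
    sample_id: str = "sample",
    **kwargs,
) -> PredictionScore:
    """SVR protocol with a region's per-video mean activity as the target
    (delegates to :func:`svr_cv_score`)."""
    return svr_cv_score(features, region_means, sample_id=sample_id, **kwargs)
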