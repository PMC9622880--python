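"""Rank-based voxelwise regression of memory features.

Within one session, the per-video outcome (ROI-mean or searchlight-sphere
mean t-statistic) is rank-transformed (average ranks for ties) and
regressed by OLS on the raw-unit behavioral predictors — memory age
(days), memory strength (1-5), emotion (1-5), and geodesic distance (km)
— either one at a time (simple model) or jointly (combined model). The
rank transform frees the outcome from any assumed response scale: only
the ordering of voxel values matters, so per-sample slopes are invariant
to monotone transforms of the raw signal.

Group inference compares per-session slopes against zero with a one-sample
two-tailed t-test; effect size is the one-sample Cohen's d (mean/SD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    PREDICTORS,
    BetaStack,
    GroupStatMap,
    SampleSession,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionSpec:
    """Which predictors enter the model; outcome is rank-transformed by
    default and the intercept is always included."""

    predictors: Tuple[str, ...]
    rank_outcome: bool = True

    def __post_init__(self) -> None:
        if len(self.predictors) < 1:
            raise ValueError("at least one predictor required")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        unknown = [p for p in self.predictors if p not in PREDICTORS]
        if unknown:
            raise ValueError(f"unknown predictors {unknown}; expected {PREDICTORS}")


#: The combined four-predictor model.
COMBINED_SPEC = RegressionSpec(predictors=PREDICTORS)


@dataclass
class SampleBetas:
    """Per-session regression result."""

    sample_id: str
    betas: Dict[str, float]
    intercept: float
    residual_variance: float
    n_videos: int


@dataclass
class GroupSlopeResult:
    predictor: str
    mean_beta: float
    t_value: float
    df: int
    p_value: float
    cohens_d: float
    n_samples: int


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with average ranks for ties."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_transform requires finite values")
    return stats.rankdata(values, method="average")


def design_matrix(
    session: SampleSession, predictors: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """Design matrix [n_kept x (p+1)] with intercept column last, plus the
    boolean keep-mask of videos with all predictors present (videos with a
    missing distance are dropped listwise when distance is in the model)."""
    cols = [session.predictor(p) for p in predictors]
    X = np.column_stack(cols)
    keep = np.all(np.isfinite(X), axis=1)
    if not np.all(keep):
        logger.info(
            "session %s: dropping %d videos with missing predictors",
            session.sample_id, int((~keep).sum()),
        )
    X = np.column_stack([X[keep], np.ones(int(keep.sum()))])
    return X, keep


def _check_design_rank(X: np.ndarray, predictors: Sequence[str]) -> None:
    # scale-free deficiency test: standardize the predictor columns so a
    # near-exact linear dependence shows up regardless of raw units
    Z = X.copy()
    for j in range(Z.shape[1] - 1):
        sd = Z[:, j].std()
        if sd > 0:
            Z[:, j] = (Z[:, j] - Z[:, j].mean()) / sd
    s = np.linalg.svd(Z, compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        # identify the offending pair for the error message
        worst = None
        for i in range(len(predictors)):
            for j in range(i + 1, len(predictors)):
                r = abs(np.corrcoef(X[:, i], X[:, j])[0, 1])
                if worst is None or r > worst[0]:
                    worst = (r, predictors[i], predictors[j])
        detail = (
            f" (collinear pair: {worst[1]!r} and {worst[2]!r}, |r|={worst[0]:.3f})"
            if worst else ""
        )
        raise ValueError(f"rank-deficient design matrix{detail}")


def fit_rank_regression(
    outcome: np.ndarray,
    session: SampleSession,
    spec: RegressionSpec,
) -> SampleBetas:
    """OLS of the (rank-transformed) outcome on the spec's predictors."""
    outcome = np.asarray(outcome, dtype=float)
    if outcome.shape != (session.n_videos,):
        raise ValueError("outcome must have one value per video")
    X, keep = design_matrix(session, spec.predictors)
    y = outcome[keep]
    p = len(spec.predictors)
    if y.size < p + 2:
        raise ValueError(
            f"session {session.sample_id}: {y.size} usable videos < {p + 2}"
        )
    if spec.rank_outcome:
        y = rank_transform(y)
    _check_design_rank(X, spec.predictors)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = y.size - X.shape[1]
    return SampleBetas(
        sample_id=session.sample_id,
        betas={p_: float(c) for p_, c in zip(spec.predictors, coef[:-1])},
        intercept=float(coef[-1]),
        residual_variance=float(resid @ resid / dof) if dof > 0 else float("nan"),
        n_videos=int(y.size),
    )


def group_slope_test(
    sample_betas: Sequence[SampleBetas], predictor: str
) -> GroupSlopeResult:
    """One-sample two-tailed t-test of per-session slopes against zero."""
    b = np.array([sb.betas[predictor] for sb in sample_betas], dtype=float)
    if b.size < 2:
        raise ValueError("group test needs at least 2 samples")
    t, p = stats.ttest_1samp(b, 0.0)
    sd = b.std(ddof=1)
    d = float(b.mean() / sd) if sd > 0 else float("nan")
    return GroupSlopeResult(
        predictor=predictor,
        mean_beta=float(b.mean()),
        t_value=float(t),
        df=b.size - 1,
        p_value=float(p),
        cohens_d=d,
        n_samples=b.size,
    )


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (significant, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def collinearity_check(
    session: SampleSession, spec: RegressionSpec
) -> Tuple[float, np.ndarray]:
    """Max pairwise |Pearson r| among predictors plus the full matrix;
    warns above the conventional 0.8 multicollinearity rule of thumb."""
    X, keep = design_matrix(session, spec.predictors)
    if int(keep.sum()) < 3:
        raise ValueError("collinearity check needs at least 3 videos")
    if len(spec.predictors) < 2:
        return 0.0, np.ones((1, 1))
    R = np.corrcoef(X[:, :-1].T)
    off = np.abs(R[~np.eye(len(spec.predictors), dtype=bool)])
    max_r = float(off.max())
    if max_r >= 0.8:
        warnings.warn(
            f"session {session.sample_id}: predictor collinearity "
            f"|r|={max_r:.2f} >= 0.80", stacklevel=2,
        )
    return max_r, R


# ---------------------------------------------------------------------------
# Searchlight


def sphere_offsets(diameter: int) -> np.ndarray:
    """Integer voxel offsets within Euclidean radius (diameter-1)/2 of the
    center (ties at exactly the radius included)."""
    if diameter % 2 == 0 or diameter < 1:
        raise ValueError("searchlight diameter must be odd and positive")
    r = (diameter - 1) // 2
    g = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(g, g, g, indexing="ij")
    keep = ii**2 + jj**2 + kk**2 <= r**2 + 1e-9
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def _sphere_kernel(diameter: int) -> np.ndarray:
    off = sphere_offsets(diameter)
    r = (diameter - 1) // 2
    k = np.zeros((diameter,) * 3)
    k[off[:, 0] + r, off[:, 1] + r, off[:, 2] + r] = 1.0
    return k


def sphere_mean_outcomes(
    stack: BetaStack, diameter: int = 5, min_voxels: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-video sphere-mean outcome at every in-mask center.

    Returns (Y [n_videos x n_centers], counts [n_centers]); centers whose
    sphere holds fewer than ``min_voxels`` in-mask voxels get NaN columns.
    Computed by 3-D convolution of the masked volumes with a spherical
    kernel, which is exactly the in-mask sphere mean.
    """
    kernel = _sphere_kernel(diameter)
    mask = stack.mask.astype(float)
    counts3 = ndimage.convolve(mask, kernel, mode="constant", cval=0.0)
    counts = np.maximum(np.rint(counts3[stack.mask]), 1).astype(int)
    Y = np.empty((stack.n_videos, stack.n_voxels))
    vol = np.zeros(stack.mask.shape)
    for v in range(stack.n_videos):
        vol[stack.mask] = stack.values[v]
        summed = ndimage.convolve(vol * mask, kernel, mode="constant", cval=0.0)
        Y[v] = summed[stack.mask] / counts
    valid = counts >= min(min_voxels, int(kernel.sum()))
    Y[:, ~valid] = np.nan
    return Y, counts


def searchlight_regression(
    stack: BetaStack,
    session: SampleSession,
    spec: RegressionSpec,
    diameter: int = 5,
    min_voxels: int = 10,
) -> Dict[str, np.ndarray]:
    """Per-voxel-center rank regression of sphere-mean outcomes.

    Returns {predictor: per-center slope vector}; centers with undersized
    spheres are NaN. Diameter 1 degenerates to voxelwise regression.
    """
    stack.check_aligned(session)
    X, keep = design_matrix(session, spec.predictors)
    if int(keep.sum()) < len(spec.predictors) + 2:
        raise ValueError("too few usable videos for the regression")
    _check_design_rank(X, spec.predictors)
    Y, _ = sphere_mean_outcomes(stack, diameter=diameter, min_voxels=min_voxels)
    Y = Y[keep]
    valid = ~np.any(np.isnan(Y), axis=0)
    out = {p: np.full(stack.n_voxels, np.nan) for p in spec.predictors}
    if valid.any():
        Yv = Y[:, valid]
        if spec.rank_outcome:
            Yv = stats.rankdata(Yv, axis=0, method="average")
        coef = np.linalg.pinv(X) @ Yv  # [(p+1) x n_valid]
        for i, p in enumerate(spec.predictors):
            out[p][valid] = coef[i]
    return out


def group_searchlight(
    stacks: Sequence[BetaStack],
    sessions: Sequence[SampleSession],
    spec: RegressionSpec,
    diameter: int = 5,
    min_voxels: int = 10,
) -> Dict[str, GroupStatMap]:
    """Searchlight regression per session, then per-voxel group slope
    tests; voxels lacking a valid slope in any session are NaN."""
    if len(stacks) != len(sessions) or len(stacks) < 2:
        raise ValueError("need matched stacks/sessions for >= 2 samples")
    per_sample = [
        searchlight_regression(st, se, spec, diameter, min_voxels)
        for st, se in zip(stacks, sessions)
    ]
    return group_maps_from_betas(per_sample, stacks[0], spec.predictors)


def group_maps_from_betas(
    per_sample: Sequence[Mapping[str, np.ndarray]],
    reference: BetaStack,
    predictors: Sequence[str],
) -> Dict[str, GroupStatMap]:
    """Vectorized per-voxel one-sample t-tests over per-sample beta maps."""
    out = {}
    n = len(per_sample)
    for p in predictors:
        B = np.vstack([ps[p] for ps in per_sample])  # [n_samples x n_voxels]
        valid = ~np.any(np.isnan(B), axis=0)
        mean = np.full(B.shape[1], np.nan)
        tval = np.full(B.shape[1], np.nan)
        pval = np.full(B.shape[1], np.nan)
        d = np.full(B.shape[1], np.nan)
        if valid.any():
            Bv = B[:, valid]
            m = Bv.mean(axis=0)
            sd = Bv.std(axis=0, ddof=1)
            se = sd / np.sqrt(n)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, m / se, 0.0)
                dd = np.where(sd > 0, m / sd, np.nan)
            mean[valid] = m
            tval[valid] = t
            pval[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
            d[valid] = dd
        out[p] = GroupStatMap(
            predictor=p, mean_beta=mean, t_value=tval, p_value=pval,
            cohens_d=d, n_samples=n, mask=reference.mask,
            affine=reference.affine,
        )
    return out


def crossed_control_regression(
    stack_a: BetaStack,
    session_b: SampleSession,
    spec: RegressionSpec,
    outcome: Optional[np.ndarray] = None,
) -> SampleBetas:
    """Control model: participant A's brain activity while viewing B's
    videos, predicted from B's ratings of those videos. Identical machinery
    to :func:`fit_rank_regression`; ``outcome`` defaults to the whole-mask
    mean per video (pass an ROI series for ROI-level controls)."""
    stack_a.check_aligned(session_b)
    if outcome is None:
        outcome = stack_a.values.mean(axis=1)
    return fit_rank_regression(outcome, session_b, spec)
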