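"""Representational similarity analysis (RSA).

Neural dissimilarity between two videos is 1 minus the Pearson
correlation of their multivoxel patterns. Behavioral dissimilarity is the
absolute difference of a (possibly log10-transformed) scalar measure, or,
for geographic location, the Euclidean distance between planar
"log-magnitude" memory vectors anchored at the scan site. The combined
RSA model regresses the neural representational dissimilarity matrix
(RDM) on the behavioral RDMs (log10 age, strength, emotion, log10
distance) over strict upper triangles, per session, with group t-tests on
the per-session slopes.

Temporal-code comparison pits three hypothesized pairwise-distance
structures over memory timestamps against a region's neural RDM: linear
|tB - tA|, logarithmic |log10 tB - log10 tA|, and exponential
|10^tB - 10^tA| (ages rescaled before exponentiation; see
:func:`temporal_model_rdm`). Each model is scored by the Spearman
correlation of upper triangles, Fisher z-transformed for group and
paired tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import BetaStack, GroupStatMap, SampleSession
from .geo import geodesic_km, initial_bearing_deg
from .univariate import GroupSlopeResult, group_maps_from_betas, sphere_offsets

TEMPORAL_MODELS = ("linear", "log", "exp")


@dataclass
class RDM:
    """Symmetric zero-diagonal pairwise-dissimilarity matrix."""

    matrix: np.ndarray
    item_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m
        if self.item_ids is not None and len(self.item_ids) != m.shape[0]:
            raise ValueError("item_ids length must match matrix size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        """Strict upper triangle as a vector (diagonal excluded)."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


def neural_rdm(patterns: np.ndarray, item_ids: Optional[List[str]] = None) -> RDM:
    """1 - Pearson correlation between multivoxel patterns (rows)."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("patterns must be [n_items x n_voxels] with >= 2 voxels")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        which = [item_ids[i] for i in bad] if item_ids else bad.tolist()
        raise ValueError(f"constant pattern(s) for items {which}; correlation undefined")
    z = (patterns - patterns.mean(axis=1, keepdims=True)) / sd[:, None]
    r = z @ z.T / patterns.shape[1]
    r = np.clip(r, -1.0, 1.0)
    m = 1.0 - r
    np.fill_diagonal(m, 0.0)
    return RDM(matrix=(m + m.T) / 2.0, item_ids=item_ids)


def scalar_rdm(
    values: np.ndarray,
    transform: str = "identity",
    floor: float = 1.0,
    item_ids: Optional[List[str]] = None,
) -> RDM:
    """|f(v_i) - f(v_j)| with f identity or log10 (values clamped >= floor
    before the log)."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("scalar_rdm requires finite values")
    if transform == "log10":
        v = np.log10(np.maximum(v, floor))
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'log10'")
    return RDM(matrix=np.abs(v[:, None] - v[None, :]), item_ids=item_ids)


def geo_vector_rdm(
    latitudes: np.ndarray,
    longitudes: np.ndarray,
    scan_site: Tuple[float, float],
    floor_km: float = 0.1,
    convention: str = "scaled_endpoint",
    item_ids: Optional[List[str]] = None,
) -> RDM:
    """Pairwise spatial dissimilarity from log-magnitude memory vectors.

    Each memory is a planar vector anchored at the scan site, pointing
    along the initial great-circle bearing toward the memory location,
    with length log10 of the geodesic distance (clamped to >= floor_km).
    The dissimilarity is the Euclidean distance between the two endpoints.
    For collinear bearings this reduces to |log10 dA - log10 dB|. Note
    that distances below 1 km give negative log-lengths, i.e. an endpoint
    on the opposite bearing; the alternative ``convention="log_latlon"``
    instead takes Euclidean distance in (lat, lon) degrees after scaling
    the radial coordinate logarithmically.
    """
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("geo_vector_rdm requires complete coordinates; drop "
                         "videos with missing locations first")
    d = geodesic_km(lat, lon, np.full_like(lat, scan_site[0]),
                    np.full_like(lon, scan_site[1]))
    d = np.maximum(np.atleast_1d(d), floor_km)
    L = np.log10(d)
    if convention == "scaled_endpoint":
        theta = np.radians(
            initial_bearing_deg(
                np.full_like(lat, scan_site[0]), np.full_like(lon, scan_site[1]),
                lat, lon,
            )
        )
        x = L * np.sin(theta)
        y = L * np.cos(theta)
    elif convention == "log_latlon":
        dx = lon - scan_site[1]
        dy = lat - scan_site[0]
        rr = np.hypot(dx, dy)
        scale = np.where(rr > 0, np.log10(np.maximum(rr, 1e-6) + 1.0) / np.maximum(rr, 1e-12), 0.0)
        x, y = dx * scale, dy * scale
    else:
        raise ValueError("convention must be 'scaled_endpoint' or 'log_latlon'")
    pts = np.column_stack([x, y])
    diff = pts[:, None, :] - pts[None, :, :]
    return RDM(matrix=np.sqrt((diff**2).sum(axis=2)), item_ids=item_ids)


def temporal_model_rdm(
    ages_days: np.ndarray,
    model: str,
    exp_scale: Optional[float] = None,
    item_ids: Optional[List[str]] = None,
) -> RDM:
    """Hypothesized pairwise temporal-distance structure.

    linear: |tB - tA|; log: |log10 tB - log10 tA| (ages clamped >= 1 day);
    exp: |10^uB - 10^uA| with u = age / exp_scale. ``exp_scale`` defaults
    to the maximum age so 10^u stays within [1, 10]; exponentiating raw
    day counts would overflow while the rescaling preserves the model's
    ordinal geometry.
    """
    t = np.asarray(ages_days, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("ages must be finite and non-negative")
    if model == "linear":
        f = t
    elif model == "log":
        f = np.log10(np.maximum(t, 1.0))
    elif model == "exp":
        scale = float(exp_scale) if exp_scale is not None else float(t.max())
        if scale <= 0:
            raise ValueError("exp_scale must be positive")
        u = t / scale
        if u.max() > 300:
            raise ValueError("exp model overflow; supply a larger exp_scale")
        f = 10.0 ** u
        if not np.all(np.isfinite(f)):
            raise ValueError("exp model overflow; supply a larger exp_scale")
    else:
        raise ValueError(f"model must be one of {TEMPORAL_MODELS}")
    return RDM(matrix=np.abs(f[:, None] - f[None, :]), item_ids=item_ids)


def behavioral_rdms(
    session: SampleSession,
    age_floor_days: float = 1.0,
    distance_floor_km: float = 0.1,
) -> Dict[str, RDM]:
    """The combined model's four predictor RDMs for one session (log10
    age, strength, emotion, log-vector distance). Requires complete
    coordinates; filter the session first if locations are missing."""
    ids = session.video_ids
    lat = np.array([v.latitude for v in session.videos], dtype=float)
    lon = np.array([v.longitude for v in session.videos], dtype=float)
    return {
        "log_age": scalar_rdm(session.predictor("age_days"), "log10",
                              floor=age_floor_days, item_ids=ids),
        "memory_strength": scalar_rdm(session.predictor("memory_strength"),
                                      item_ids=ids),
        "emotion": scalar_rdm(session.predictor("emotion"), item_ids=ids),
        "log_distance": geo_vector_rdm(
            lat, lon, (session.scan_lat, session.scan_lon),
            floor_km=distance_floor_km, item_ids=ids,
        ),
    }


# ---------------------------------------------------------------------------
# RDM regression


@dataclass
class RdmRegressionResult:
    sample_id: str
    betas: Dict[str, float]
    intercept: float
    n_items: int


def _rdm_design(predictors: Mapping[str, RDM]) -> Tuple[np.ndarray, List[str]]:
    names = list(predictors)
    cols = [predictors[k].upper() for k in names]
    n_items = {predictors[k].n for k in names}
    if len(n_items) != 1:
        raise ValueError("predictor RDMs differ in item count")
    X = np.column_stack(cols + [np.ones(cols[0].size)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        worst = (0.0, None, None)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = abs(np.corrcoef(cols[i], cols[j])[0, 1])
                if r > worst[0]:
                    worst = (r, names[i], names[j])
        raise ValueError(
            f"collinear predictor RDMs: {worst[1]!r} vs {worst[2]!r} "
            f"(|r|={worst[0]:.3f})"
        )
    return X, names


def rdm_regression(
    target: RDM,
    predictors: Mapping[str, RDM],
    sample_id: str = "sample",
) -> RdmRegressionResult:
    """OLS of the target RDM's strict upper triangle on the predictor
    RDMs' upper triangles, with intercept."""
    if target.n < 3:
        raise ValueError("RDM regression needs >= 3 items")
    for name, rdm in predictors.items():
        if rdm.n != target.n:
            raise ValueError(f"predictor RDM {name!r} item count differs from target")
    X, names = _rdm_design(predictors)
    y = target.upper()
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return RdmRegressionResult(
        sample_id=sample_id,
        betas={n: float(c) for n, c in zip(names, coef[:-1])},
        intercept=float(coef[-1]),
        n_items=target.n,
    )


def group_rdm_test(
    results: Sequence[RdmRegressionResult], predictor: str
) -> GroupSlopeResult:
    """Group one-sample t-test of per-session RDM-regression slopes."""
    b = np.array([r.betas[predictor] for r in results], dtype=float)
    if b.size < 2:
        raise ValueError("group test needs >= 2 samples")
    t, p = stats.ttest_1samp(b, 0.0)
    sd = b.std(ddof=1)
    return GroupSlopeResult(
        predictor=predictor, mean_beta=float(b.mean()), t_value=float(t),
        df=b.size - 1, p_value=float(p),
        cohens_d=float(b.mean() / sd) if sd > 0 else float("nan"),
        n_samples=b.size,
    )


# ---------------------------------------------------------------------------
# Temporal-code model comparison


@dataclass
class ModelComparisonResult:
    """Per-session Spearman correlations (and Fisher z) of a brain RDM
    with each temporal-code model RDM."""

    sample_id: str
    rho: Dict[str, float]
    fisher_z: Dict[str, float]


def rdm_model_comparison(
    brain: RDM,
    models: Mapping[str, RDM],
    sample_id: str = "sample",
) -> ModelComparisonResult:
    """Spearman rank correlation between strict upper triangles of the
    brain RDM and each model RDM, Fisher z-transformed."""
    if brain.n < 3:
        raise ValueError("model comparison needs >= 3 items")
    rho = {}
    for name, rdm in models.items():
        if rdm.n != brain.n:
            raise ValueError(f"model RDM {name!r} item count differs from brain")
        r, _ = stats.spearmanr(brain.upper(), rdm.upper())
        rho[name] = float(r)
    z = {k: float(np.arctanh(np.clip(v, -0.999999, 0.999999)))
         for k, v in rho.items()}
    return ModelComparisonResult(sample_id=sample_id, rho=rho, fisher_z=z)


def group_model_comparison(
    per_sample: Sequence[ModelComparisonResult],
) -> Dict[str, dict]:
    """Group tests over per-session Fisher-z correlations: one-sample t
    vs 0 per model, plus paired t-tests between every model pair."""
    if len(per_sample) < 2:
        raise ValueError("group comparison needs >= 2 samples")
    names = list(per_sample[0].rho)
    out: Dict[str, dict] = {"one_sample": {}, "paired": {}}
    Z = {n: np.array([r.fisher_z[n] for r in per_sample]) for n in names}
    R = {n: np.array([r.rho[n] for r in per_sample]) for n in names}
    for n in names:
        t, p = stats.ttest_1samp(Z[n], 0.0)
        out["one_sample"][n] = {
            "mean_rho": float(R[n].mean()), "t": float(t),
            "df": len(per_sample) - 1, "p": float(p),
        }
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            t, p = stats.ttest_rel(Z[a], Z[b])
            out["paired"][(a, b)] = {"t": float(t), "p": float(p),
                                     "df": len(per_sample) - 1}
    return out


# ---------------------------------------------------------------------------
# RSA searchlight


def searchlight_rsa(
    stack: BetaStack,
    predictor_rdms: Mapping[str, RDM],
    diameter: int = 5,
    min_voxels: int = 10,
    analysis_mask: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Per-center RDM regression: the neural RDM of each searchlight
    sphere's patterns is regressed on the predictor RDMs.

    Returns {predictor: per-center slope vector}; centers with undersized
    spheres or degenerate patterns are NaN. ``analysis_mask`` optionally
    restricts which centers are evaluated (spheres still draw voxels from
    the full brain mask).
    """
    X, names = _rdm_design(predictor_rdms)
    n_items = next(iter(predictor_rdms.values())).n
    if n_items != stack.n_videos:
        raise ValueError("predictor RDM item count differs from stack videos")
    pinv = np.linalg.pinv(X)
    iu = np.triu_indices(n_items, k=1)

    offs = sphere_offsets(diameter)
    shape = stack.mask.shape
    col_of = np.full(shape, -1, dtype=int)
    col_of[stack.mask] = np.arange(stack.n_voxels)
    centers = np.argwhere(
        stack.mask if analysis_mask is None else (stack.mask & analysis_mask)
    )
    out = {n: np.full(stack.n_voxels, np.nan) for n in names}
    min_k = max(2, min_voxels if offs.shape[0] >= min_voxels else offs.shape[0])
    vals = stack.values
    for c in centers:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        cols = col_of[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        cols = cols[cols >= 0]
        if cols.size < min_k:
            continue
        pat = vals[:, cols]
        sd = pat.std(axis=1)
        if np.any(sd == 0):
            continue
        z = (pat - pat.mean(axis=1, keepdims=True)) / sd[:, None]
        r = np.clip(z @ z.T / cols.size, -1.0, 1.0)
        y = 1.0 - r[iu]
        coef = pinv @ y
        cc = col_of[c[0], c[1], c[2]]
        for i, n in enumerate(names):
            out[n][cc] = coef[i]
    return out


def group_searchlight_rsa(
    stacks: Sequence[BetaStack],
    sessions: Sequence[SampleSession],
    diameter: int = 5,
    min_voxels: int = 10,
    analysis_mask: Optional[np.ndarray] = None,
    rdm_builder=behavioral_rdms,
) -> Dict[str, GroupStatMap]:
    """RSA searchlight per session, then per-voxel group slope tests."""
    if len(stacks) != len(sessions) or len(stacks) < 2:
        raise ValueError("need matched stacks/sessions for >= 2 samples")
    per_sample = []
    names = None
    for st, se in zip(stacks, sessions):
        st.check_aligned(se)
        rdms = rdm_builder(se)
        names = list(rdms)
        per_sample.append(
            searchlight_rsa(st, rdms, diameter, min_voxels, analysis_mask)
        )
    return group_maps_from_betas(per_sample, stacks[0], names)
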