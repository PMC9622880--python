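"""Synthetic study generator.

Emulates the structure of a diary-video memory study: ~32 experimental
sessions of ~300 one-second memory videos each, with behavioral
annotations (memory age up to ~7 years, geographic location, 1-5
memory-strength and emotion ratings, people/place content labels) and
per-video voxel statistic stacks in which known effects are planted.

Behavioral structure
--------------------
Ratings are coupled to memory age and distance through a Gaussian copula:
latent standard normals with correlation chosen so the induced Spearman
correlations approach configured targets, then mapped through the marginal
quantile functions (uniform age, heavy-tailed two-component log-uniform
distance mixture, configured discrete marginals for the ratings). Content
booleans are drawn at configured proportions, with novel places upweighted
at large distances and (optionally) given a memory-strength boost.

Brain structure
---------------
Voxel values are Gaussian noise plus planted linear effects of
standardized predictors inside named ROIs, plus (optionally) a planted
representational geometry: inside one ROI, each video's multivoxel
pattern lies on a circular arc parameterized by a chosen transform of
memory age (linear, log10, or scaled exponential), so that pattern
dissimilarity (1 - Pearson r) increases monotonically with the transformed
age difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import BetaStack, RoiAtlas, SampleSession, VideoRecord
from .geo import destination_point

#: Scanning center used by the generator (Bethesda, MD area).
SCAN_SITE = (39.0026, -77.1028)

_DEFAULT_TARGETS = {
    ("age_days", "memory_strength"): -0.16,
    ("distance_km", "memory_strength"): 0.19,
    ("age_days", "emotion"): -0.07,
    ("distance_km", "emotion"): 0.19,
}

_DEFAULT_CONTENT = {
    "has_people": 0.743,
    "people_familiar_given_people": 0.932,
    "self_given_people": 0.20,
    "place_familiar": 0.80,
}


@dataclass
class GeneratorConfig:
    """Study-level conditions for the behavioral generator.

    Defaults are the observed study conditions: 32 sessions of 300 videos,
    ages up to 2547 days, a near-uniform strength marginal, a positively
    skewed emotion marginal, and small cross-feature Spearman couplings.
    """

    n_samples: int = 32
    n_videos_per_sample: int = 300
    max_age_days: float = 2547.0
    #: mixture of per-sample recorded time spans (probability, lo, hi days;
    #: hi None means max_age_days), mirroring the study's composition of
    #: participants with ~0.5-1, 1-2, and 2-7 years of videos. Ages are
    #: uniform on [2, sample_span].
    span_composition: Tuple[Tuple[float, float, Optional[float]], ...] = (
        (11 / 23, 183.0, 365.0),
        (6 / 23, 365.0, 730.0),
        (6 / 23, 730.0, None),
    )
    seed: int = 0
    target_correlations: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    content_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTENT)
    )
    emotion_marginals: Sequence[float] = (0.011, 0.041, 0.275, 0.378, 0.295)
    strength_marginals: Sequence[float] = (0.180, 0.174, 0.209, 0.202, 0.235)
    #: distance mixture: local mass below 50 km, long-range mass above.
    local_fraction: float = 0.70
    local_range_km: Tuple[float, float] = (0.1, 50.0)
    far_range_km: Tuple[float, float] = (50.0, 15000.0)
    #: fraction of videos pinned to a per-session "home" point (~1 km out);
    #: assigned to the locally nearest draws so distance ranks are preserved.
    home_fraction: float = 0.30
    #: latent-scale memory-strength boost for novel-place videos
    #: (mean-centred so the strength marginal is preserved).
    place_new_strength_boost: float = 0.30
    #: steepness of the novel-place upweighting in log10 distance.
    place_new_distance_slope: float = 1.0
    scan_site: Tuple[float, float] = SCAN_SITE

    def __post_init__(self) -> None:
        if self.n_videos_per_sample < 10:
            raise ValueError("n_videos_per_sample must be >= 10")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("emotion_marginals", "strength_marginals"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (5,) or np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 5 probabilities summing to 1")
        for pair, rho in self.target_correlations.items():
            if abs(rho) >= 1:
                raise ValueError(f"target correlation for {pair} must be in (-1, 1)")
        probs = [w for w, _, _ in self.span_composition]
        if abs(sum(probs) - 1.0) > 1e-9 or any(w < 0 for w in probs):
            raise ValueError("span_composition probabilities must sum to 1")


_COPULA_ORDER = ("age_days", "distance_km", "memory_strength", "emotion")


def _copula_matrix(targets: Mapping[Tuple[str, str], float]) -> np.ndarray:
    """Latent normal correlation matrix inducing the target Spearman
    correlations (r = 2 sin(pi * rho_s / 6)); raises if not PSD."""
    r = np.eye(4)
    idx = {n: i for i, n in enumerate(_COPULA_ORDER)}
    for (a, b), rho in targets.items():
        latent = 2.0 * np.sin(np.pi * rho / 6.0)
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = latent
    eig = np.linalg.eigvalsh(r)
    if eig.min() < -1e-10:
        raise ValueError(
            f"correlation targets give a non-PSD copula matrix:\n{r}\n"
            f"eigenvalues {eig}"
        )
    return r


def _discretize(u: np.ndarray, marginals: Sequence[float]) -> np.ndarray:
    """Map uniforms to 1..5 ratings with the given marginal probabilities."""
    cum = np.cumsum(np.asarray(marginals, dtype=float))
    cum[-1] = 1.0 + 1e-12
    return np.searchsorted(cum, u, side="right") + 1


def _mixture_distance_quantile(u: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Quantile function of the local/far log-uniform distance mixture."""
    d = np.empty_like(u)
    lo = u < cfg.local_fraction
    for sel, (a, b), offset, span in (
        (lo, cfg.local_range_km, 0.0, cfg.local_fraction),
        (~lo, cfg.far_range_km, cfg.local_fraction, 1.0 - cfg.local_fraction),
    ):
        if not np.any(sel):
            continue
        v = np.clip((u[sel] - offset) / span, 0.0, 1.0)
        d[sel] = 10.0 ** (np.log10(a) + v * (np.log10(b) - np.log10(a)))
    return d


def _calibrate_place_new(
    log_d: np.ndarray, target_rate: float, slope: float
) -> np.ndarray:
    """Per-video novel-place probability, logistic in log10 distance, with
    the intercept solved by bisection so the mean probability matches the
    configured marginal."""
    centered = log_d - np.median(log_d)

    def mean_rate(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + slope * centered)))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    return 1.0 / (1.0 + np.exp(-(a + slope * centered)))


def generate_behavior(config: GeneratorConfig) -> List[SampleSession]:
    """Generate one synthetic session per sample; deterministic per seed."""
    rng_root = np.random.default_rng(config.seed)
    corr = _copula_matrix(config.target_correlations)
    # eigen square root is robust at the PSD boundary
    w, v = np.linalg.eigh(corr)
    sqrt_corr = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    sessions = []
    for s in range(config.n_samples):
        rng = np.random.default_rng(rng_root.integers(2**31))
        n = config.n_videos_per_sample
        z = rng.standard_normal((n, 4)) @ sqrt_corr.T
        u = stats.norm.cdf(z)
        # per-sample recorded span drawn from the study composition
        probs = np.array([w for w, _, _ in config.span_composition])
        pick = rng.choice(len(probs), p=probs / probs.sum())
        _, lo_span, hi_span = config.span_composition[pick]
        hi_span = config.max_age_days if hi_span is None else hi_span
        sample_span = rng.uniform(lo_span, min(hi_span, config.max_age_days))
        ages = 2.0 + u[:, 0] * (sample_span - 2.0)
        dist = _mixture_distance_quantile(u[:, 1], config)

        # pin the nearest draws to a per-session home point (rank-preserving)
        home_bearing = rng.uniform(0.0, 360.0)
        home_dist = rng.uniform(0.5, 2.0)
        n_home = int(round(config.home_fraction * n))
        if n_home > 0:
            order = np.argsort(dist)
            dist[order[:n_home]] = home_dist
        home_lat, home_lon = destination_point(
            config.scan_site[0], config.scan_site[1], home_bearing, home_dist
        )

        # content labels
        cp = config.content_proportions
        has_people = rng.random(n) < cp["has_people"]
        people_new = has_people & (
            rng.random(n) >= cp["people_familiar_given_people"]
        )
        contains_self = has_people & (
            rng.random(n) < cp.get("self_given_people", 0.20)
        )
        p_new = _calibrate_place_new(
            np.log10(dist), 1.0 - cp["place_familiar"],
            config.place_new_distance_slope,
        )
        place_new = rng.random(n) < p_new

        # novel-place strength boost on the latent scale, mean-centred so
        # the configured strength marginal is preserved
        boost = config.place_new_strength_boost
        ind = place_new.astype(float)
        z_str = z[:, 2] + boost * (ind - ind.mean())
        z_str = z_str / np.sqrt(1.0 + boost**2 * ind.var())
        strength = _discretize(stats.norm.cdf(z_str), config.strength_marginals)
        emotion = _discretize(u[:, 3], config.emotion_marginals)

        bearings = rng.uniform(0.0, 360.0, n)
        lats, lons = destination_point(
            np.full(n, config.scan_site[0]), np.full(n, config.scan_site[1]),
            bearings, dist,
        )
        if n_home > 0:
            lats[order[:n_home]] = home_lat
            lons[order[:n_home]] = home_lon

        videos = [
            VideoRecord(
                video_id=f"s{s:02d}v{i:04d}",
                age_days=float(ages[i]),
                memory_strength=int(strength[i]),
                emotion=int(emotion[i]),
                has_people=bool(has_people[i]),
                people_new=bool(people_new[i]),
                contains_self=bool(contains_self[i]),
                place_new=bool(place_new[i]),
                latitude=float(lats[i]),
                longitude=float(lons[i]),
            )
            for i in range(n)
        ]
        sessions.append(
            SampleSession(
                sample_id=f"sample{s:02d}",
                participant_id=f"p{s % max(1, (config.n_samples + 1) // 2):02d}",
                scan_lat=config.scan_site[0],
                scan_lon=config.scan_site[1],
                videos=videos,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# ROI atlas


_ATLAS_PLAN = (
    # name, lattice cell (cx, cy, cz) on a 3x3x3 grid, size at a 24^3 grid
    ("hippocampus", (0, 0, 0), 5),
    ("amygdala", (0, 0, 2), 3),
    ("erc", (0, 2, 0), 4),
    ("phc", (0, 2, 2), 4),
    ("mpc_age", (2, 0, 0), 5),
    ("mpc_strength", (2, 0, 2), 5),
    ("mpc_people", (2, 2, 0), 4),
    ("mpc_place", (2, 2, 2), 4),
    ("timecode", (1, 1, 1), 4),
    ("noise_region", (0, 1, 1), 4),
)


def make_atlas(shape: Tuple[int, int, int] = (24, 24, 24)) -> RoiAtlas:
    """Synthetic ROI atlas: a box brain mask (1-voxel border excluded) with
    disjoint cubic ROIs, including four medial-parietal factor regions, a
    planted-geometry region, and a pure-noise control region. ``mpc`` is
    the union bounding block of the four mpc_* regions.

    ROIs are cubes centred in the cells of a 3x3x3 lattice spanning the
    brain interior, so they stay disjoint at any grid size >= 14.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 14:
        raise ValueError("atlas grid must be at least 14 voxels per axis")
    brain = np.zeros(shape, dtype=bool)
    brain[1:-1, 1:-1, 1:-1] = True
    scale = min(shape) / 24.0
    rois: Dict[str, np.ndarray] = {}
    occupancy = np.zeros(shape, dtype=int)
    for name, cell, base_size in _ATLAS_PLAN:
        size = max(3, int(round(base_size * scale)))
        m = np.zeros(shape, dtype=bool)
        sl = []
        for ax in range(3):
            interior = shape[ax] - 2
            cell_len = interior / 3.0
            size_ax = min(size, int(cell_len))
            start = 1 + int(round(cell[ax] * cell_len
                                  + (cell_len - size_ax) / 2.0))
            sl.append(slice(start, start + size_ax))
        m[tuple(sl)] = True
        rois[name] = m
        occupancy += m
    if occupancy.max() > 1:
        raise ValueError(f"atlas ROIs overlap on grid {shape}; use a larger grid")
    mpc_names = [n for n in rois if n.startswith("mpc_")]
    idx = np.argwhere(np.any([rois[n] for n in mpc_names], axis=0))
    mpc = np.zeros(shape, dtype=bool)
    lo = np.maximum(idx.min(axis=0) - 1, 1)
    hi = np.minimum(idx.max(axis=0) + 2, np.array(shape) - 1)
    mpc[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    rois["mpc"] = mpc & brain
    return RoiAtlas(brain_mask=brain, rois=rois)


# ---------------------------------------------------------------------------
# Brain generator


@dataclass
class PlantedEffects:
    """Ground truth planted into synthetic voxel stacks.

    ``roi_slopes`` maps ROI name -> {predictor: slope}: the ROI's voxels
    gain slope * standardized(predictor). ``contrast_rois`` maps ROI name
    -> (factor, effect): a mean shift of +effect/2 for the factor's first
    group and -effect/2 for its second ("people_new_vs_familiar",
    "place_new_vs_familiar", or "recent_vs_remote"). ``rdm_code_roi``
    carries the arc-embedded temporal geometry instead of a linear effect.
    """

    roi_slopes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    contrast_rois: Mapping[str, Tuple[str, float]] = field(default_factory=dict)
    rdm_code_roi: Optional[str] = None
    rdm_code: str = "log"
    rdm_strength: float = 1.5
    recent_cutoff_days: float = 90.0
    noise_sd: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0 (0 is the exact noiseless limit)")
        if self.rdm_code not in ("linear", "log", "exp"):
            raise ValueError("rdm_code must be linear, log, or exp")

    def check_rois(self, atlas: RoiAtlas) -> None:
        for name in list(self.roi_slopes) + list(self.contrast_rois):
            if name not in atlas:
                raise KeyError(f"planted effect references unknown ROI {name!r}")
        if self.rdm_code_roi is not None and self.rdm_code_roi not in atlas:
            raise KeyError(
                f"rdm_code_roi references unknown ROI {self.rdm_code_roi!r}"
            )


def default_effects(noise_sd: float = 1.0) -> PlantedEffects:
    """Planted effects mirroring the study's qualitative findings: strength
    and emotion effects in the MTL ROIs, and four factor-specific
    medial-parietal regions plus a log-time geometry region."""
    return PlantedEffects(
        roi_slopes={
            "hippocampus": {"memory_strength": 0.5, "emotion": 0.3},
            "amygdala": {"memory_strength": 0.45, "emotion": 0.35},
            "erc": {"memory_strength": 0.45, "emotion": 0.3},
            "phc": {"memory_strength": 0.4, "emotion": 0.25},
            "mpc_age": {"age_days": 0.5},
            "mpc_strength": {"memory_strength": 0.5},
        },
        contrast_rois={
            "mpc_people": ("people_new_vs_familiar", 1.0),
            "mpc_place": ("place_new_vs_familiar", 1.0),
        },
        rdm_code_roi="timecode",
        rdm_code="log",
        noise_sd=noise_sd,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _age_code(ages: np.ndarray, code: str) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if code == "linear":
        return ages
    if code == "log":
        return np.log10(np.maximum(ages, 1.0))
    if code == "exp":
        return 10.0 ** (ages / ages.max())
    raise ValueError(f"unknown temporal code {code!r}")


def _contrast_indicator(session: SampleSession, factor: str,
                        recent_cutoff_days: float) -> np.ndarray:
    """+1 for group one, -1 for group two, 0 for excluded videos."""
    out = np.zeros(session.n_videos)
    for i, v in enumerate(session.videos):
        if factor == "people_new_vs_familiar":
            cat = v.people_category()
            out[i] = {"new": 1.0, "familiar": -1.0}.get(cat, 0.0)
        elif factor == "place_new_vs_familiar":
            out[i] = 1.0 if v.place_new else -1.0
        elif factor == "recent_vs_remote":
            out[i] = 1.0 if v.age_days <= recent_cutoff_days else -1.0
        else:
            raise ValueError(f"unknown contrast factor {factor!r}")
    return out


def _arc_embedding(ages: np.ndarray, code: str, strength: float,
                   n_voxels: int, rng: np.random.Generator,
                   arc_radians: float = 2.5) -> np.ndarray:
    """Patterns on a circular arc in voxel space, parameterized by the
    coded age; pattern dissimilarity grows monotonically with coded-age
    difference while the arc stays within pi radians."""
    f = _age_code(ages, code)
    span = f.max() - f.min()
    s = (f - f.min()) / span if span > 0 else np.zeros_like(f)
    theta = arc_radians * s
    basis = rng.standard_normal((n_voxels, 2))
    basis -= basis.mean(axis=0)
    q, _ = np.linalg.qr(basis)
    q *= np.sqrt(n_voxels)  # per-voxel unit scale
    circ = np.column_stack([np.cos(theta), np.sin(theta)])
    return strength * circ @ q.T


def generate_brain(
    sessions: Sequence[SampleSession],
    atlas: RoiAtlas,
    effects: PlantedEffects,
    seed: int = 0,
) -> List[BetaStack]:
    """Per-session voxel stacks with the configured planted effects."""
    if len(sessions) == 0:
        raise ValueError("sessions must be nonempty")
    effects.check_rois(atlas)
    rng_root = np.random.default_rng(seed)
    affine = np.diag([2.5, 2.5, 2.5, 1.0])
    n_cols = int(atlas.brain_mask.sum())
    stacks = []
    for session in sessions:
        rng = np.random.default_rng(rng_root.integers(2**31))
        n = session.n_videos
        values = effects.baseline + rng.normal(0.0, effects.noise_sd, (n, n_cols))
        for roi, slopes in effects.roi_slopes.items():
            cols = atlas.columns(roi)
            for predictor, slope in slopes.items():
                zp = _standardize(session.predictor(predictor))
                values[:, cols] += slope * zp[:, None]
        for roi, (factor, eff) in effects.contrast_rois.items():
            cols = atlas.columns(roi)
            ind = _contrast_indicator(session, factor, effects.recent_cutoff_days)
            values[:, cols] += (eff / 2.0) * ind[:, None]
        if effects.rdm_code_roi is not None:
            cols = atlas.columns(effects.rdm_code_roi)
            ages = session.predictor("age_days")
            values[:, cols] += _arc_embedding(
                ages, effects.rdm_code, effects.rdm_strength, len(cols), rng
            )
        stacks.append(
            BetaStack(values=values, mask=atlas.brain_mask, affine=affine,
                      video_ids=session.video_ids)
        )
    return stacks


def generate_pair(
    session_a: SampleSession,
    session_b: SampleSession,
    atlas: RoiAtlas,
    effects: PlantedEffects,
    seed: int = 0,
    leakage: float = 0.15,
) -> BetaStack:
    """Stack for participant A viewing participant B's videos.

    Contains no planted dependence on B's ratings except an optional
    stimulus-memorability leakage: a small shared effect of B's memory
    strength in the ROIs where strength effects are planted, emulating
    memory strength being partially carried by the stimulus itself.
    """
    if session_a.n_videos != session_b.n_videos:
        raise ValueError(
            f"paired sessions must have equal video counts "
            f"({session_a.n_videos} vs {session_b.n_videos})"
        )
    effects.check_rois(atlas)
    rng = np.random.default_rng(seed)
    n_cols = int(atlas.brain_mask.sum())
    n = session_b.n_videos
    values = effects.baseline + rng.normal(0.0, effects.noise_sd, (n, n_cols))
    if leakage != 0.0:
        zb = _standardize(session_b.predictor("memory_strength"))
        for roi, slopes in effects.roi_slopes.items():
            if "memory_strength" in slopes:
                cols = atlas.columns(roi)
                values[:, cols] += leakage * zb[:, None]
    return BetaStack(values=values, mask=atlas.brain_mask,
                     affine=np.diag([2.5, 2.5, 2.5, 1.0]),
                     video_ids=session_b.video_ids)


# ---------------------------------------------------------------------------
# Feature matrices, motion, run assignment


def generate_feature_matrix(
    session: SampleSession,
    planted_r: float,
    n_features: int,
    seed: int = 0,
    target: str = "memory_strength",
) -> np.ndarray:
    """Per-video feature matrix whose best linear readout has population
    correlation ``planted_r`` with the target rating.

    Construction: a single latent signal s = r*z(target) + sqrt(1-r^2)*g
    (g independent noise) is spread across features with random loadings
    plus small feature noise; the optimal readout recovers s, whose
    correlation with the target is r by construction.
    """
    if not -1.0 <= planted_r <= 1.0:
        raise ValueError("planted_r must be in [-1, 1]")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    z = _standardize(session.predictor(target))
    n = session.n_videos
    s = planted_r * z + np.sqrt(max(0.0, 1.0 - planted_r**2)) * rng.standard_normal(n)
    loadings = rng.normal(1.0, 0.3, n_features)
    feats = s[:, None] * loadings[None, :]
    feats += 0.05 * rng.standard_normal((n, n_features))
    return feats


def generate_motion(
    session: SampleSession,
    r_emotion: float = 0.3,
    r_strength: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-video motion scalars with planted rating correlations."""
    if r_emotion**2 + r_strength**2 > 1.0:
        raise ValueError("r_emotion^2 + r_strength^2 must be <= 1")
    rng = np.random.default_rng(seed)
    ze = _standardize(session.predictor("emotion"))
    zs = _standardize(session.predictor("memory_strength"))
    resid = np.sqrt(1.0 - r_emotion**2 - r_strength**2)
    return r_emotion * ze + r_strength * zs + resid * rng.standard_normal(
        session.n_videos
    )


def assign_runs(
    session: SampleSession,
    n_runs: int = 10,
    per_run: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Assign videos to scanner runs so each run evenly samples the full
    recorded time span, with jittered within-stratum choice.

    Returns an integer vector aligned to the session's videos: run number
    1..n_runs for selected videos, 0 for unselected ones. When ``per_run``
    is None, ``n_videos // n_runs`` videos go to each run (all videos are
    used when the count divides evenly).
    """
    n = session.n_videos
    if per_run is None:
        per_run = n // n_runs
    need = n_runs * per_run
    if need > n:
        raise ValueError(
            f"need {need} videos for {n_runs} runs x {per_run}, have {n} "
            f"(short by {need - n})"
        )
    if per_run < 1:
        raise ValueError("per_run must be >= 1")
    rng = np.random.default_rng(seed)
    ages = session.predictor("age_days")
    order = np.argsort(ages, kind="stable")
    # one equal-count stratum per within-run slot; jittered pick inside each
    strata = np.array_split(order, need)
    chosen = np.array([rng.choice(s) for s in strata])
    labels = np.zeros(n, dtype=int)
    # consecutive blocks of n_runs strata span the time axis; permute each
    # block across runs so every run receives one video per block
    for b in range(per_run):
        block = chosen[b * n_runs:(b + 1) * n_runs]
        runs = rng.permutation(n_runs) + 1
        labels[block] = runs
    return labels
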