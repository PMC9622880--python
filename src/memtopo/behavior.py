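"""Behavioral analyses of the memory annotations.

All group inference runs at the session ("sample") level: a statistic is
computed within each session, then the per-session values are compared
across sessions (one-sample two-tailed t-tests). Sessions failing a
factor's inclusion rule (fewer than five videos in either group, the
study's rule generalized to every contrast) are excluded and listed with
the reason. Group t-tests run on raw per-session Spearman rho (no Fisher
transform), matching how the study-level correlations are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import SampleSession
from .geo import geodesic_km

CONTRASTS = (
    "people_new_vs_familiar",
    "people_new_vs_self",
    "people_self_vs_familiar",
    "place_new_vs_familiar",
    "location_unique_vs_common",
    "emotion_negative_vs_positive",
)

OUTCOMES = ("memory_strength", "emotion", "distance_km")

MIN_PER_GROUP = 5


@dataclass
class ContrastResult:
    contrast: str
    outcome: str
    per_sample_diff: Dict[str, float]
    mean_diff: float
    t_value: float
    df: int
    p_value: float
    n_included: int
    excluded: Dict[str, str] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    pair: str
    per_sample_rho: Dict[str, float]
    mean_rho: float
    t_value: float
    df: int
    p_value: float
    n_negative: int
    n_positive: int
    excluded: Dict[str, str] = field(default_factory=dict)


def rating_distributions(sessions: Sequence[SampleSession]) -> dict:
    """Across-session mean (and SD) of per-session rating-bin proportions
    and content proportions."""
    if len(sessions) == 0:
        raise ValueError("sessions must be nonempty")
    strength = []
    emotion = []
    people = []
    familiar_given_people = []
    place_familiar = []
    for s in sessions:
        if s.n_videos == 0:
            raise ValueError(f"session {s.sample_id} is empty")
        st = s.predictor("memory_strength").astype(int)
        em = s.predictor("emotion").astype(int)
        strength.append([np.mean(st == k) for k in range(1, 6)])
        emotion.append([np.mean(em == k) for k in range(1, 6)])
        hp = np.array([v.has_people for v in s.videos])
        people.append(hp.mean())
        if hp.any():
            fam = np.array([
                v.has_people and not v.people_new for v in s.videos
            ])
            familiar_given_people.append(fam.sum() / hp.sum())
        place_familiar.append(np.mean([not v.place_new for v in s.videos]))
    def _ms(x):
        x = np.asarray(x, dtype=float)
        return {"mean": x.mean(axis=0).tolist() if x.ndim > 1 else float(x.mean()),
                "sd": (x.std(axis=0, ddof=1).tolist() if x.ndim > 1
                       else float(x.std(ddof=1))) if x.shape[0] > 1 else None}
    return {
        "strength_proportions": _ms(strength),
        "emotion_proportions": _ms(emotion),
        "has_people": _ms(people),
        "people_familiar_given_people": _ms(familiar_given_people),
        "place_familiar": _ms(place_familiar),
    }


def _contrast_groups(
    session: SampleSession, contrast: str,
    merge_radius_km: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean (group1, group2) masks over the session's videos."""
    vids = session.videos
    cats = np.array([v.people_category() or "none" for v in vids])
    if contrast == "people_new_vs_familiar":
        return cats == "new", cats == "familiar"
    if contrast == "people_new_vs_self":
        return cats == "new", cats == "self"
    if contrast == "people_self_vs_familiar":
        return cats == "self", cats == "familiar"
    if contrast == "place_new_vs_familiar":
        new = np.array([v.place_new for v in vids])
        return new, ~new
    if contrast == "location_unique_vs_common":
        labels = classify_location_uniqueness(session, merge_radius_km)
        return labels == "unique", labels == "common"
    if contrast == "emotion_negative_vs_positive":
        em = session.predictor("emotion")
        return em <= 2, em >= 4
    raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")


def content_contrast(
    sessions: Sequence[SampleSession],
    contrast: str,
    outcome: str = "memory_strength",
    min_per_group: int = MIN_PER_GROUP,
) -> ContrastResult:
    """Per-session group1-minus-group2 mean outcome, tested against zero
    across sessions. Sessions with fewer than ``min_per_group`` videos in
    either group are excluded with a logged reason."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    diffs: Dict[str, float] = {}
    excluded: Dict[str, str] = {}
    for s in sessions:
        g1, g2 = _contrast_groups(s, contrast)
        y = s.predictor(outcome)
        ok = np.isfinite(y)
        g1, g2 = g1 & ok, g2 & ok
        if g1.sum() < min_per_group or g2.sum() < min_per_group:
            excluded[s.sample_id] = (
                f"min {min_per_group} videos per group "
                f"(had {int(g1.sum())} vs {int(g2.sum())})"
            )
            continue
        diffs[s.sample_id] = float(y[g1].mean() - y[g2].mean())
    if len(diffs) < 2:
        raise ValueError(
            f"insufficient samples for contrast {contrast!r}: "
            f"{len(diffs)} included"
        )
    d = np.array(list(diffs.values()))
    if np.allclose(d, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(d, 0.0)
    return ContrastResult(
        contrast=contrast, outcome=outcome, per_sample_diff=diffs,
        mean_diff=float(d.mean()), t_value=float(t), df=d.size - 1,
        p_value=float(p), n_included=d.size, excluded=excluded,
    )


def feature_spearman(
    sessions: Sequence[SampleSession],
    x: str,
    y: str,
) -> CorrelationResult:
    """Per-session Spearman rho of raw x (age_days or distance_km) versus
    raw y (memory_strength or emotion), with a group t-test of the
    per-session rho against zero and sign counts.

    Note on sign convention: rho is reported for the raw measures, so a
    recency effect (recent memories remembered better) appears as a
    negative rho of age versus strength.
    """
    if x not in ("age_days", "distance_km") or y not in ("memory_strength", "emotion"):
        raise ValueError(f"unsupported pair ({x!r}, {y!r})")
    rhos: Dict[str, float] = {}
    excluded: Dict[str, str] = {}
    for s in sessions:
        xv, yv = s.predictor(x), s.predictor(y)
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.sum() < 3:
            excluded[s.sample_id] = "fewer than 3 complete pairs"
            continue
        if np.ptp(xv[ok]) == 0 or np.ptp(yv[ok]) == 0:
            excluded[s.sample_id] = "constant measure; rho undefined"
            continue
        r, _ = stats.spearmanr(xv[ok], yv[ok])
        rhos[s.sample_id] = float(r)
    if len(rhos) < 2:
        raise ValueError("insufficient samples with defined correlations")
    r = np.array(list(rhos.values()))
    t, p = stats.ttest_1samp(r, 0.0)
    return CorrelationResult(
        pair=f"{x}*{y}", per_sample_rho=rhos, mean_rho=float(r.mean()),
        t_value=float(t), df=r.size - 1, p_value=float(p),
        n_negative=int((r < 0).sum()), n_positive=int((r >= 0).sum()),
        excluded=excluded,
    )


def fitline_sign_counts(
    sessions: Sequence[SampleSession], x: str, y: str
) -> dict:
    """Per-session OLS fit lines of y on x and slope sign counts (zero
    slopes counted positive, a documented tie rule)."""
    lines: Dict[str, Tuple[float, float]] = {}
    excluded: Dict[str, str] = {}
    for s in sessions:
        xv, yv = s.predictor(x), s.predictor(y)
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.sum() < 2 or np.ptp(xv[ok]) == 0:
            excluded[s.sample_id] = "constant or insufficient x"
            continue
        xv, yv = xv[ok], yv[ok]
        xc = xv - xv.mean()
        slope = float(xc @ (yv - yv.mean()) / (xc @ xc))
        lines[s.sample_id] = (float(yv.mean() - slope * xv.mean()), slope)
    slopes = np.array([b for _, b in lines.values()])
    return {
        "lines": lines,  # sample_id -> (intercept, slope)
        "n_negative": int((slopes < 0).sum()),
        "n_positive": int((slopes >= 0).sum()),
        "excluded": excluded,
    }


def classify_location_uniqueness(
    session: SampleSession, merge_radius_km: float = 0.05
) -> np.ndarray:
    """Label each video 'unique', 'common', or 'other' by single-linkage
    clustering of locations within ``merge_radius_km``.

    Size-1 clusters are unique; the largest cluster (>= 2 videos; ties
    broken by earliest video position) is common; everything else is
    'other'. Videos without coordinates are labeled 'other'.
    """
    n = session.n_videos
    lat = np.array([v.latitude if v.has_location else np.nan for v in session.videos])
    lon = np.array([v.longitude if v.has_location else np.nan for v in session.videos])
    ok = np.isfinite(lat) & np.isfinite(lon)
    if not ok.any():
        raise ValueError("all coordinates missing; cannot classify locations")
    labels = np.array(["other"] * n, dtype=object)
    idx = np.where(ok)[0]
    if idx.size == 1:
        labels[idx[0]] = "unique"
        return labels
    la, lo = lat[idx], lon[idx]
    d = geodesic_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    d = np.asarray(d)
    np.fill_diagonal(d, 0.0)
    cl = fcluster(linkage(squareform(d, checks=False), method="single"),
                  t=merge_radius_km, criterion="distance")
    sizes = np.bincount(cl)
    for i, c in zip(idx, cl):
        if sizes[c] == 1:
            labels[i] = "unique"
    largest = sizes.max()
    if largest >= 2:
        tied = np.where(sizes == largest)[0]
        # earliest-video tie break
        first_pos = {c: np.min(idx[cl == c]) for c in tied}
        winner = min(tied, key=lambda c: first_pos[c])
        for i, c in zip(idx, cl):
            if c == winner:
                labels[i] = "common"
    return labels


def filter_by_distance(session: SampleSession, max_km: float) -> SampleSession:
    """Retain videos with distance_km <= max_km (order preserved); videos
    with missing distance are dropped."""
    d = session.predictor("distance_km")
    keep = np.isfinite(d) & (d <= max_km)
    if not keep.any():
        raise ValueError(f"no videos within {max_km} km")
    return session.subset(keep)


def behavioral_summary(sessions: Sequence[SampleSession]) -> dict:
    """The headline behavioral battery: rating/content distributions, the
    four feature correlations with sign counts, and the content
    contrasts on memory strength."""
    out: dict = {"distributions": rating_distributions(sessions)}
    corr = {}
    for x in ("age_days", "distance_km"):
        for y in ("memory_strength", "emotion"):
            r = feature_spearman(sessions, x, y)
            signs = fitline_sign_counts(sessions, x, y)
            corr[f"{x}*{y}"] = {
                "mean_rho": r.mean_rho, "t": r.t_value, "df": r.df,
                "p": r.p_value, "n_negative_rho": r.n_negative,
                "n_positive_rho": r.n_positive,
                "n_negative_slopes": signs["n_negative"],
                "n_positive_slopes": signs["n_positive"],
            }
    out["correlations"] = corr
    contrasts = {}
    for c in CONTRASTS:
        try:
            res = content_contrast(sessions, c, "memory_strength")
            contrasts[c] = {
                "mean_diff": res.mean_diff, "t": res.t_value,
                "df": res.df, "p": res.p_value,
                "n_included": res.n_included,
                "n_excluded": len(res.excluded),
            }
        except ValueError as exc:
            contrasts[c] = {"error": str(exc)}
    out["strength_contrasts"] = contrasts
    return out
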