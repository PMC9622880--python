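"""Medial-parietal topography analysis.

Per session, each memory factor yields a per-voxel effect map: recent
minus remote mean activity (memory age, 90-day cutoff by default),
familiar minus novel people (selfie videos excluded from both groups),
familiar minus novel places, own minus other's videos, or per-level mean
maps for the five-level rating factors (memory strength, emotion). Group
maps are per-voxel one-sample t-tests of the contrast effects (or a
repeated-measures one-way ANOVA over the five level means, with session
as the repeated unit).

Peak regions are the top-K voxels by |statistic| among those passing an
uncorrected p threshold (optionally restricted to a supplied
medial-parietal mask). Leave-one-session-out selectivity re-derives each
factor's region from all-but-one session, z-scores the held-out session's
effect map across all in-mask voxels, averages it within each region, and
finally tests every (region, factor) cell against zero with BH-FDR over
all cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BetaStack, SampleSession
from .univariate import fdr_correct

logger = logging.getLogger(__name__)

CONTRAST_FACTORS = ("memory_age", "people_familiarity", "place_familiarity",
                    "own_vs_other")
ANOVA_FACTORS = ("memory_strength", "emotion")
FACTORS = CONTRAST_FACTORS[:3] + ANOVA_FACTORS + ("own_vs_other",)

N_LEVELS = 5


class SampleExcluded(ValueError):
    """A session failing a factor's inclusion rule."""


@dataclass
class EffectMap:
    """One session's per-voxel effect for one factor: a contrast map
    [n_voxels] or per-level means [5 x n_voxels]."""

    sample_id: str
    factor: str
    kind: str  # "contrast" | "levels"
    data: np.ndarray


@dataclass
class FactorContrastMap:
    factor: str
    stat: np.ndarray  # t (contrast) or F (ANOVA) per voxel
    p_value: np.ndarray
    mean_effect: Optional[np.ndarray]
    n_included: int
    excluded: Dict[str, str] = field(default_factory=dict)


@dataclass
class PeakRegion:
    factor: str
    selected: np.ndarray  # boolean over in-mask columns
    k_requested: int
    k_obtained: int


def _factor_groups(
    session: SampleSession, factor: str, recent_cutoff_days: float
) -> Tuple[np.ndarray, np.ndarray]:
    """(group1, group2) masks; group1 minus group2 is the effect."""
    if factor == "memory_age":
        age = session.predictor("age_days")
        return age <= recent_cutoff_days, age > recent_cutoff_days
    if factor == "people_familiarity":
        cats = np.array([v.people_category() or "none" for v in session.videos])
        return cats == "familiar", cats == "new"
    if factor == "place_familiarity":
        new = np.array([v.place_new for v in session.videos])
        return ~new, new
    raise ValueError(f"unknown contrast factor {factor!r}")


def per_sample_effect_map(
    stack: BetaStack,
    session: SampleSession,
    factor: str,
    recent_cutoff_days: float = 90.0,
    min_per_cell: int = 5,
    stack_other: Optional[BetaStack] = None,
) -> EffectMap:
    """One session's effect map for a factor; raises
    :class:`SampleExcluded` when a cell has fewer than ``min_per_cell``
    videos. ``own_vs_other`` needs the paired other-videos stack."""
    stack.check_aligned(session)
    if factor == "own_vs_other":
        if stack_other is None:
            raise ValueError("own_vs_other requires stack_other")
        data = stack.values.mean(axis=0) - stack_other.values.mean(axis=0)
        return EffectMap(session.sample_id, factor, "contrast", data)
    if factor in ("memory_age", "people_familiarity", "place_familiarity"):
        g1, g2 = _factor_groups(session, factor, recent_cutoff_days)
        if g1.sum() < min_per_cell or g2.sum() < min_per_cell:
            raise SampleExcluded(
                f"{session.sample_id}: fewer than {min_per_cell} videos in a "
                f"{factor} group ({int(g1.sum())} vs {int(g2.sum())})"
            )
        data = stack.values[g1].mean(axis=0) - stack.values[g2].mean(axis=0)
        return EffectMap(session.sample_id, factor, "contrast", data)
    if factor in ANOVA_FACTORS:
        r = session.predictor(factor).astype(int)
        counts = [int((r == k).sum()) for k in range(1, N_LEVELS + 1)]
        if min(counts) < min_per_cell:
            raise SampleExcluded(
                f"{session.sample_id}: fewer than {min_per_cell} videos at a "
                f"{factor} level (counts {counts})"
            )
        data = np.vstack([
            stack.values[r == k].mean(axis=0) for k in range(1, N_LEVELS + 1)
        ])
        return EffectMap(session.sample_id, factor, "levels", data)
    raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")


def collect_effect_maps(
    stacks: Sequence[BetaStack],
    sessions: Sequence[SampleSession],
    factor: str,
    stacks_other: Optional[Sequence[BetaStack]] = None,
    **kwargs,
) -> Tuple[List[EffectMap], Dict[str, str]]:
    maps, excluded = [], {}
    for i, (st, se) in enumerate(zip(stacks, sessions)):
        other = stacks_other[i] if stacks_other is not None else None
        try:
            maps.append(per_sample_effect_map(st, se, factor,
                                              stack_other=other, **kwargs))
        except SampleExcluded as exc:
            excluded[se.sample_id] = str(exc)
            logger.info("excluding %s for %s: %s", se.sample_id, factor, exc)
    return maps, excluded


def group_contrast_map(
    effect_maps: Sequence[EffectMap],
    excluded: Optional[Dict[str, str]] = None,
) -> FactorContrastMap:
    """Per-voxel one-sample two-tailed t-test of contrast effects vs 0."""
    if len(effect_maps) < 2:
        raise ValueError("group contrast needs >= 2 included samples")
    if any(m.kind != "contrast" for m in effect_maps):
        raise ValueError("group_contrast_map expects contrast-kind maps")
    E = np.vstack([m.data for m in effect_maps])
    n = E.shape[0]
    mean = E.mean(axis=0)
    sd = E.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return FactorContrastMap(
        factor=effect_maps[0].factor, stat=t, p_value=p, mean_effect=mean,
        n_included=n, excluded=excluded or {},
    )


def group_anova_map(
    level_maps: Sequence[EffectMap],
    excluded: Optional[Dict[str, str]] = None,
) -> FactorContrastMap:
    """Per-voxel one-way repeated-measures ANOVA across the five rating
    levels, with session as the repeated unit (level x session interaction
    as the error term)."""
    if len(level_maps) < 2:
        raise ValueError("group ANOVA needs >= 2 included samples")
    if any(m.kind != "levels" for m in level_maps):
        raise ValueError("group_anova_map expects level-mean maps")
    X = np.stack([m.data for m in level_maps])  # [n_samples, 5, n_voxels]
    ns, nl, nv = X.shape
    grand = X.mean(axis=(0, 1))
    level_means = X.mean(axis=0)            # [5, n_voxels]
    sample_means = X.mean(axis=1)           # [n_samples, n_voxels]
    ss_level = ns * ((level_means - grand) ** 2).sum(axis=0)
    resid = X - level_means[None] - sample_means[:, None, :] + grand[None, None]
    ss_err = (resid**2).sum(axis=(0, 1))
    df1 = nl - 1
    df2 = (ns - 1) * (nl - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ss_err > 0, (ss_level / df1) / (ss_err / df2), 0.0)
    p = stats.f.sf(F, df1, df2)
    p = np.where(ss_err > 0, p, 1.0)
    return FactorContrastMap(
        factor=level_maps[0].factor, stat=F, p_value=p, mean_effect=None,
        n_included=ns, excluded=excluded or {},
    )


def levels_to_contrast(effect: EffectMap) -> EffectMap:
    """Reduce per-level means to a per-voxel linear trend across levels
    (OLS slope on level index), the held-out effect used for ANOVA-defined
    factors in the leave-one-out analysis."""
    if effect.kind != "levels":
        return effect
    levels = np.arange(1, N_LEVELS + 1, dtype=float)
    lc = levels - levels.mean()
    slope = lc @ effect.data / (lc @ lc)
    return EffectMap(effect.sample_id, effect.factor, "contrast", slope)


def top_k_region(
    group_map: FactorContrastMap,
    k: int = 1000,
    p_threshold: float = 0.05,
    restrict_mask_cols: Optional[np.ndarray] = None,
) -> PeakRegion:
    """Top-``k`` voxels by |statistic| among those with p below the
    threshold (optionally restricted to a voxel-column mask); ties at the
    k-th value break by ascending voxel index. Returns fewer than k when
    the supply is short."""
    stat = np.abs(group_map.stat)
    with np.errstate(invalid="ignore"):
        eligible = np.isfinite(stat) & (group_map.p_value < p_threshold)
    if restrict_mask_cols is not None:
        eligible &= np.asarray(restrict_mask_cols, dtype=bool)
    selected = np.zeros(stat.size, dtype=bool)
    idx = np.where(eligible)[0]
    if idx.size > 0:
        # stable sort: descending stat, ascending index on ties
        order = idx[np.lexsort((idx, -stat[idx]))]
        selected[order[:k]] = True
    return PeakRegion(
        factor=group_map.factor, selected=selected, k_requested=k,
        k_obtained=int(selected.sum()),
    )


def region_overlap(regions: Sequence[PeakRegion]) -> pd.DataFrame:
    """Pairwise intersection counts and Jaccard indices."""
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            a, b = regions[i].selected, regions[j].selected
            inter = int((a & b).sum())
            union = int((a | b).sum())
            rows.append({
                "region_a": regions[i].factor, "region_b": regions[j].factor,
                "intersection": inter, "union": union,
                "jaccard": inter / union if union else 0.0,
            })
    return pd.DataFrame(rows)


def _zscore_map(effect: np.ndarray) -> np.ndarray:
    """Standardize an effect map across in-mask voxels.

    Centred on the across-voxel median rather than the mean: a small,
    strongly driven region would otherwise shift the reference mean and
    leak a systematic offset of opposite sign into every other region.
    """
    sd = effect.std()
    if sd == 0:
        return np.zeros_like(effect)
    return (effect - np.median(effect)) / sd


def loo_selectivity(
    stacks: Sequence[BetaStack],
    sessions: Sequence[SampleSession],
    factors: Sequence[str] = ("memory_age", "people_familiarity",
                              "place_familiarity", "memory_strength"),
    mpc_mask_cols: Optional[np.ndarray] = None,
    k: int = 1000,
    p_threshold: float = 0.05,
    q_fdr: float = 0.05,
    recent_cutoff_days: float = 90.0,
    min_per_cell: int = 5,
) -> dict:
    """Leave-one-session-out selectivity of factor-defined peak regions.

    For each held-out session, each factor's group map is recomputed from
    the remaining sessions and its top-k region taken (within the
    medial-parietal mask when given); the held-out session's z-scored
    effect map for every factor is then averaged within every region.
    Regions may overlap (no winner-take-all). Returns the per-fold table,
    per-(region, factor) group t-tests, and their BH-FDR decisions.
    """
    n = len(sessions)
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 samples")
    rows = []
    for held in range(n):
        rest = [i for i in range(n) if i != held]
        regions: Dict[str, PeakRegion] = {}
        for factor in factors:
            maps, excl = collect_effect_maps(
                [stacks[i] for i in rest], [sessions[i] for i in rest], factor,
                recent_cutoff_days=recent_cutoff_days,
                min_per_cell=min_per_cell,
            )
            if len(maps) < 2:
                continue
            if factor in ANOVA_FACTORS:
                gmap = group_anova_map(maps, excl)
            else:
                gmap = group_contrast_map(maps, excl)
            region = top_k_region(gmap, k=k, p_threshold=p_threshold,
                                  restrict_mask_cols=mpc_mask_cols)
            if region.k_obtained == 0:
                logger.info("fold %d: empty region for %s; skipped", held, factor)
                continue
            regions[factor] = region
        # held-out effect maps, z-scored across all in-mask voxels
        held_effects: Dict[str, np.ndarray] = {}
        for factor in factors:
            try:
                em = per_sample_effect_map(
                    stacks[held], sessions[held], factor,
                    recent_cutoff_days=recent_cutoff_days,
                    min_per_cell=min_per_cell,
                )
            except SampleExcluded:
                continue
            held_effects[factor] = _zscore_map(levels_to_contrast(em).data)
        for region_factor, region in regions.items():
            for factor, zmap in held_effects.items():
                rows.append({
                    "held_out": sessions[held].sample_id,
                    "region": region_factor,
                    "factor": factor,
                    "mean_z_beta": float(zmap[region.selected].mean()),
                })
    table = pd.DataFrame(
        rows, columns=["held_out", "region", "factor", "mean_z_beta"]
    )
    tests = []
    for (region, factor), grp in table.groupby(["region", "factor"]):
        v = grp["mean_z_beta"].to_numpy()
        if v.size < 2:
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        tests.append({"region": region, "factor": factor, "n_folds": v.size,
                      "mean_z_beta": float(v.mean()), "t": float(t),
                      "p": float(p)})
    tests = pd.DataFrame(tests)
    if len(tests):
        sig, p_adj = fdr_correct(tests["p"].to_numpy(), q=q_fdr)
        tests["p_fdr"] = p_adj
        tests["significant"] = sig
    return {"per_fold": table, "tests": tests}
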