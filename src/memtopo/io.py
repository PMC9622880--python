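"""File I/O: behavioral tables (CSV/TSV), voxel stacks (NIfTI-1), result
maps (NIfTI-1 + JSON sidecar), and YAML/JSON analysis configs.

Behavioral table header::

    video_id,age_days,latitude,longitude,memory_strength,emotion,
    has_people,people_new,contains_self,place_new

latitude/longitude columns (or cells) may be absent/empty: locations are
protected in the public deposit, so distance is treated as optional
everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import BetaStack, GroupStatMap, SampleSession, VideoRecord

REQUIRED_COLUMNS = (
    "video_id",
    "age_days",
    "memory_strength",
    "emotion",
    "has_people",
    "people_new",
    "contains_self",
    "place_new",
)

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"row {row}: column {column!r} value {value!r} is not boolean")
    s = str(value).strip().lower()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"row {row}: column {column!r} value {value!r} is not boolean")


def load_behavior_table(
    path,
    scan_site: Tuple[float, float],
    sample_id: Optional[str] = None,
    participant_id: Optional[str] = None,
) -> SampleSession:
    """Read a behavioral table into a validated :class:`SampleSession`.

    ``scan_site`` is the (lat, lon) of the scanning center; distances are
    derived from it for every row with coordinates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    has_coords = "latitude" in df.columns and "longitude" in df.columns
    videos = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            lat = lon = None
            if has_coords:
                lat = rec["latitude"]
                lon = rec["longitude"]
                lat = None if pd.isna(lat) else float(lat)
                lon = None if pd.isna(lon) else float(lon)
            videos.append(
                VideoRecord(
                    video_id=str(rec["video_id"]),
                    age_days=float(rec["age_days"]),
                    memory_strength=int(rec["memory_strength"]),
                    emotion=int(rec["emotion"]),
                    has_people=_parse_bool(rec["has_people"], "has_people", i),
                    people_new=_parse_bool(rec["people_new"], "people_new", i),
                    contains_self=_parse_bool(rec["contains_self"], "contains_self", i),
                    place_new=_parse_bool(rec["place_new"], "place_new", i),
                    latitude=lat,
                    longitude=lon,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: row {i}: {exc}") from exc
    return SampleSession(
        sample_id=sample_id or path.stem,
        participant_id=participant_id or (sample_id or path.stem),
        scan_lat=scan_site[0],
        scan_lon=scan_site[1],
        videos=videos,
    )


def write_behavior_table(session: SampleSession, path) -> None:
    """Write a session back out in the documented table format."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = session.to_frame().drop(columns=["distance_km"])
    df.to_csv(path, sep=sep, index=False)


def read_beta_stack(
    stack_path,
    mask_path,
    video_ids: Optional[Sequence[str]] = None,
) -> BetaStack:
    """Load a 4-D statistic image plus its 3-D mask into a BetaStack."""
    img = nib.load(str(stack_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0
    if data.ndim != 4:
        raise ValueError(f"statistic image must be 4-D, got shape {data.shape}")
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: stack {data.shape[:3]} vs mask {mask.shape}"
        )
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise ValueError("stack and mask affines differ")
    n_videos = data.shape[3]
    if video_ids is None:
        video_ids = [f"v{i:04d}" for i in range(n_videos)]
    elif len(video_ids) != n_videos:
        raise ValueError(
            f"behavior table has {len(video_ids)} videos but image has "
            f"{n_videos} volumes"
        )
    values = data[mask].T  # [n_videos, n_mask_voxels], C-order voxel scan
    return BetaStack(values=values, mask=mask, affine=img.affine,
                     video_ids=list(video_ids))


def write_beta_stack(stack: BetaStack, stack_path, mask_path) -> None:
    """Write a BetaStack as a 4-D NIfTI plus a uint8 mask NIfTI.

    Round trip through :func:`read_beta_stack` is lossless (values are
    stored as float64); out-of-mask voxels are written as zero.
    """
    shape = stack.mask.shape + (stack.n_videos,)
    vol = np.zeros(shape, dtype=np.float64)
    vol[stack.mask] = stack.values.T
    nib.save(nib.Nifti1Image(vol, stack.affine), str(stack_path))
    nib.save(
        nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine), str(mask_path)
    )


def write_stat_map(stat_map: GroupStatMap, path) -> None:
    """Write a group map as float32 NIfTI (t values) plus a JSON sidecar
    carrying the predictor label and the full per-voxel statistics."""
    path = Path(path)
    vol = stat_map.to_volume("t_value", fill=0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, stat_map.affine), str(path))
    sidecar = {
        "predictor": stat_map.predictor,
        "n_samples": int(stat_map.n_samples),
        "mean_beta": stat_map.mean_beta.tolist(),
        "t_value": stat_map.t_value.tolist(),
        "p_value": stat_map.p_value.tolist(),
        "cohens_d": stat_map.cohens_d.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_config(path) -> dict:
    """Load a YAML or JSON analysis configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
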