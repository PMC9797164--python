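"""Experiment runner: the four-method comparison (i / ri / fi / fri).

Each method is purely a weight mask over the same registration code path,
so the comparison isolates the contribution of the fiducial and region
terms. Reports mirror the TRE-by-group and contour-propagation layout
(deformed tumor+2 vs tumor bed, deformed tumor+3 vs boost-CTV).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import expand_margin, propagate_mask
from .evaluation import dice, hausdorff, target_registration_error
from .metrics import MetricWeights
from .phantom import PhantomCase, PhantomConfig
from .pointsets import PairedPointSet, read_points, write_points
from .registration import RegistrationConfig, register_multimetric
from .transforms import read_transform, write_transform
from .volio import read_mask, read_volume, write_mask, write_volume

__all__ = [
    "METHOD_WEIGHTS",
    "run_method_comparison",
    "write_case",
    "read_case",
]

METHOD_WEIGHTS: dict[str, MetricWeights] = {
    "i": MetricWeights(0.0, 0.0, 100.0),
    "ri": MetricWeights(0.0, 1.0, 100.0),
    "fi": MetricWeights(1.0, 0.0, 100.0),
    "fri": MetricWeights(1.0, 1.0, 100.0),
}

_CASE_FILES = {
    "moving": "moving.mha",
    "fixed": "fixed.mha",
    "gt_transform": "gt_transform.json",
    "gland_moving": "gland_moving.mha",
    "gland_fixed": "gland_fixed.mha",
    "body_moving": "body_moving.mha",
    "body_fixed": "body_fixed.mha",
    "tumor_moving": "tumor_moving.mha",
    "tumor_bed": "tumor_bed.mha",
    "boost_ctv": "boost_ctv.mha",
    "landmarks_fixed": "landmarks_fixed.txt",
    "landmarks_moving": "landmarks_moving.txt",
    "fiducials_fixed": "fiducials_fixed.txt",
    "fiducials_moving": "fiducials_moving.txt",
}


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Serialize a phantom case plus a JSON manifest of every artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.moving, out / _CASE_FILES["moving"])
    write_volume(case.fixed, out / _CASE_FILES["fixed"])
    write_transform(case.gt_transform, out / _CASE_FILES["gt_transform"])
    for key in (
        "gland_moving", "gland_fixed", "body_moving", "body_fixed",
        "tumor_moving", "tumor_bed", "boost_ctv",
    ):
        write_mask(getattr(case, key), out / _CASE_FILES[key])
    write_points(out / _CASE_FILES["landmarks_fixed"], case.landmarks.fixed_points)
    write_points(out / _CASE_FILES["landmarks_moving"], case.landmarks.moving_points)
    write_points(out / _CASE_FILES["fiducials_fixed"], case.fiducials.fixed_points)
    write_points(out / _CASE_FILES["fiducials_moving"], case.fiducials.moving_points)
    manifest = {
        "files": dict(_CASE_FILES),
        "landmark_groups": list(case.landmarks.groups),
        "config": dataclasses.asdict(case.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def read_case(case_dir: str | Path) -> PhantomCase:
    """Load a case written by :func:`write_case`; missing artifacts are
    errors naming the artifact."""
    case_dir = Path(case_dir)
    manifest_path = case_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    files = manifest.get("files", {})
    for key in _CASE_FILES:
        if key not in files:
            raise ValueError(f"manifest missing artifact entry: {key}")
        if not (case_dir / files[key]).exists():
            raise FileNotFoundError(f"missing case artifact {key}: {files[key]}")

    moving = read_volume(case_dir / files["moving"])
    fixed = read_volume(case_dir / files["fixed"])
    landmarks = PairedPointSet(
        read_points(case_dir / files["landmarks_fixed"]),
        read_points(case_dir / files["landmarks_moving"]),
        tuple(manifest.get("landmark_groups", ())),
    )
    fiducials = PairedPointSet(
        read_points(case_dir / files["fiducials_fixed"]),
        read_points(case_dir / files["fiducials_moving"]),
    )
    cfg_data = manifest.get("config", {})
    for k in ("shape", "spacing", "tumor_center_mm"):
        if isinstance(cfg_data.get(k), list):
            cfg_data[k] = tuple(cfg_data[k])
    return PhantomCase(
        moving=moving,
        fixed=fixed,
        gt_transform=read_transform(case_dir / files["gt_transform"]),
        landmarks=landmarks,
        fiducials=fiducials,
        gland_moving=read_mask(case_dir / files["gland_moving"], like=moving),
        gland_fixed=read_mask(case_dir / files["gland_fixed"], like=fixed),
        body_moving=read_mask(case_dir / files["body_moving"], like=moving),
        body_fixed=read_mask(case_dir / files["body_fixed"], like=fixed),
        tumor_moving=read_mask(case_dir / files["tumor_moving"], like=moving),
        tumor_bed=read_mask(case_dir / files["tumor_bed"], like=fixed),
        boost_ctv=read_mask(case_dir / files["boost_ctv"], like=fixed),
        config=PhantomConfig(**cfg_data),
    )


def _method_row(case: PhantomCase, method: str, cfg: RegistrationConfig) -> dict:
    w = METHOD_WEIGHTS[method]
    result = register_multimetric(
        case.fixed,
        case.moving,
        replace(cfg, weights=w),
        pairs=case.fiducials if w.fiducial > 0 else None,
        roi_fixed=case.gland_fixed if w.region > 0 else None,
        roi_moving=case.gland_moving if w.region > 0 else None,
        fixed_body=case.body_fixed,
    )
    t = result.transform
    tre = target_registration_error(case.landmarks, t)
    stats = tre.group_stats()
    row: dict = {"method": method}
    for group in ("soft_tissue", "rigid", "boundary"):
        mean, sd = stats.get(group, (np.nan, np.nan))
        row[f"tre_{group}_mean_mm"] = mean
        row[f"tre_{group}_sd_mm"] = sd
    row["tre_all_mean_mm"] = tre.mean
    row["tre_all_median_mm"] = tre.median

    tumor_p2 = expand_margin(case.tumor_moving, 20.0, limit=case.body_moving)
    tumor_p3 = expand_margin(case.tumor_moving, 30.0, limit=case.body_moving)
    deformed_p2 = propagate_mask(tumor_p2, t, case.fixed)
    deformed_p3 = propagate_mask(tumor_p3, t, case.fixed)
    row["dsc_tumor2_bed"] = dice(deformed_p2, case.tumor_bed)
    row["hd_tumor2_bed_mm"] = hausdorff(deformed_p2, case.tumor_bed)
    row["dsc_tumor3_ctv"] = dice(deformed_p3, case.boost_ctv)
    row["hd_tumor3_ctv_mm"] = hausdorff(deformed_p3, case.boost_ctv)
    row["iterations"] = int(sum(result.iterations))
    row["elapsed_s"] = result.elapsed_s
    return row


def run_method_comparison(
    case: PhantomCase | str | Path,
    methods=("i", "ri", "fi", "fri"),
    cfg: RegistrationConfig = RegistrationConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Run the requested methods on one case; one report row per method.

    Deterministic per ``(case, cfg, seed)``. An ``unregistered`` baseline
    row (identity transform TRE) is always included first.
    """
    if not isinstance(case, PhantomCase):
        case = read_case(case)
    bad = sorted(set(methods) - set(METHOD_WEIGHTS))
    if bad:
        raise ValueError(f"unknown methods: {', '.join(bad)}")
    cfg = replace(cfg, seed=seed)

    tre0 = target_registration_error(case.landmarks, _Identity())
    stats0 = tre0.group_stats()
    base = {"method": "unregistered"}
    for group in ("soft_tissue", "rigid", "boundary"):
        mean, sd = stats0.get(group, (np.nan, np.nan))
        base[f"tre_{group}_mean_mm"] = mean
        base[f"tre_{group}_sd_mm"] = sd
    base["tre_all_mean_mm"] = tre0.mean
    base["tre_all_median_mm"] = tre0.median

    rows = [base] + [_method_row(case, m, cfg) for m in methods]
    return pd.DataFrame(rows)


class _Identity:
    def apply(self, pts):
        return np.asarray(pts, dtype=float)

    bspline = None
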