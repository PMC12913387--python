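"""File formats: NIfTI volumes, reason maps, JSON masks, text report."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SpecimenVolume
from .voxelclean import CleanFlatImage, REASON_NAMES

__all__ = [
    "save_volume",
    "load_volume",
    "save_flat_image",
    "save_reason_map",
    "mask_to_json",
    "mask_from_json",
    "format_report",
]


def _affine(voxel_size_mm: float, slice_thickness_mm: float) -> np.ndarray:
    return np.diag([slice_thickness_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(volume: SpecimenVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          _affine(volume.voxel_size_mm,
                                  volume.slice_thickness_mm))
    img.header.set_zooms((volume.slice_thickness_mm,
                          volume.voxel_size_mm, volume.voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path, specimen_id: str = "", diagnosis: int = 0
                ) -> SpecimenVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return SpecimenVolume(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=float(zooms[1]),
        slice_thickness_mm=float(zooms[0]),
        specimen_id=specimen_id or Path(path).stem,
        diagnosis=diagnosis,
    )


def save_flat_image(flat: CleanFlatImage, path) -> None:
    """Cleaned 2D intensity and CNR as a single-slice two-volume NIfTI."""
    stack = np.stack([
        np.where(flat.valid, flat.intensity, np.nan),
        flat.cnr if flat.cnr is not None
        else np.full_like(flat.intensity, np.nan),
    ])
    img = nib.Nifti1Image(stack.astype(np.float32)[:, None, :, :], np.eye(4))
    nib.save(img, str(path))


def save_reason_map(flat: CleanFlatImage, path) -> None:
    """Per-pixel removal reasons as long-format CSV (row, col, reason)."""
    rows, cols = np.nonzero(np.ones_like(flat.reasons, dtype=bool))
    pd.DataFrame({
        "row": rows, "col": cols,
        "reason": [REASON_NAMES[int(r)] for r in flat.reasons.ravel()],
    }).to_csv(path, index=False)


def mask_to_json(mask: np.ndarray, path) -> None:
    """2D boolean mask as an index-list JSON ({shape, indices})."""
    idx = np.flatnonzero(np.asarray(mask, bool))
    with open(path, "w") as fh:
        json.dump({"shape": list(mask.shape), "indices": idx.tolist()}, fh)


def mask_from_json(path) -> np.ndarray:
    with open(path) as fh:
        d = json.load(fh)
    mask = np.zeros(int(np.prod(d["shape"])), dtype=bool)
    mask[d["indices"]] = True
    return mask.reshape(d["shape"])


def format_report(report: dict) -> str:
    """Human-readable fit report: mixed models, then the regional
    group-difference table (metric x region, difference + 95% credible
    interval, '*' when the interval excludes zero)."""
    lines = []
    for sub, fit in report.get("mixed_model", {}).items():
        lines.append(f"Mixed model ({sub}): n = {fit['n_sections']} sections, "
                     f"{fit['n_specimens']} specimens, df = {fit['df']}")
        for name, c in fit["coefficients"].items():
            lines.append(
                f"  {name:<10s} {c['estimate']: .4g} "
                f"(95% CI {c['ci95'][0]: .4g} to {c['ci95'][1]: .4g}, "
                f"t = {c['t']: .3g}, p = {c['p']:.3g})"
            )
        lines.append(f"  R2 (fixed effects) = {fit['r2']:.3f} "
                     f"(1 - RSS/TSS = {fit['r2_rss']:.3f})")
        lines.append("")
    gd = report.get("group_differences", {})
    if gd:
        lines.append("Group differences (PD - AD), posterior mean "
                     "(95% credible interval):")
        for key in sorted(gd):
            r = gd[key]
            lo, hi = r["ci95"]
            star = "*" if lo > 0 or hi < 0 else " "
            flag = "" if r["converged"] else "  [NON-CONVERGED]"
            lines.append(f"  {key:<16s} {r['estimate']: .4g}{star} "
                         f"({lo: .4g} to {hi: .4g}){flag}")
    return "\n".join(lines) + "\n"
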