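"""Voxel-to-grid-section mapping and per-section aggregation.

The dissection grid is a rigid square lattice (3.5 mm pitch) placed over
the flattened 2D specimen image.  Each occupied lattice cell is one grid
section carrying a region label.  Indexing is 0-based ``(row, col)`` with
row 0 at the medial aspect (image top) and the highest column at the
anterior aspect (image right); posterior-midbrain sections therefore sit
in the low columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AD, PD, POSTERIOR  # noqa: F401  (AD/PD re-exported for callers)

__all__ = [
    "GridSection",
    "GridLayout",
    "GridGeometryError",
    "section_index_map",
    "register_grid",
    "merge_partial_sections",
    "aggregate_sections",
    "SECTION_TABLE_COLUMNS",
]

#: Fixed column order of the section table CSV.
SECTION_TABLE_COLUMNS = [
    "specimen_id", "diagnosis", "grid_row", "grid_col", "region",
    "mean_cnr", "sn_voxel_fraction", "nm_conc", "fe_conc", "n_voxels",
]


class GridGeometryError(ValueError):
    """Grid transform incompatible with the image."""


@dataclass(frozen=True)
class GridSection:
    region: str
    is_valid: bool = True

    @property
    def is_sn(self) -> bool:
        return self.region == "SN"

    @property
    def is_posterior(self) -> bool:
        return self.region == POSTERIOR


@dataclass
class GridLayout:
    """Rigid grid geometry plus per-section labels.

    ``origin`` is the voxel coordinate (row, col) of grid node (0, 0);
    ``spacing_vox`` the section pitch in voxels (grid pitch in mm divided
    by the in-plane voxel size); ``rotation_deg`` rotates the grid axes
    counter-clockwise relative to the image axes.
    """

    origin: tuple[float, float]
    spacing_vox: float
    n_rows: int
    n_cols: int
    sections: dict[tuple[int, int], GridSection]
    rotation_deg: float = 0.0
    well_markers: tuple[tuple[float, float], ...] = ()
    specimen_id: str = ""
    diagnosis: int = 0

    def __post_init__(self) -> None:
        if self.spacing_vox <= 0:
            raise GridGeometryError("grid spacing must be positive")
        for (r, c) in self.sections:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise GridGeometryError(f"section ({r}, {c}) outside grid bounds")

    # -- integer section ids -------------------------------------------------

    def section_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def id_to_rowcol(self, sid: int) -> tuple[int, int]:
        return divmod(sid, self.n_cols)

    def sn_section_ids(self) -> set[int]:
        return {self.section_id(r, c) for (r, c), s in self.sections.items()
                if s.is_sn}

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing_vox": self.spacing_vox,
            "rotation_deg": self.rotation_deg,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "well_markers": [list(p) for p in self.well_markers],
            "specimen_id": self.specimen_id,
            "diagnosis": self.diagnosis,
            "sections": [
                {"row": r, "col": c, "region": s.region, "is_valid": s.is_valid}
                for (r, c), s in sorted(self.sections.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return cls(
            origin=tuple(d["origin"]),
            spacing_vox=d["spacing_vox"],
            rotation_deg=d.get("rotation_deg", 0.0),
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            well_markers=tuple(tuple(p) for p in d.get("well_markers", [])),
            specimen_id=d.get("specimen_id", ""),
            diagnosis=d.get("diagnosis", 0),
            sections={
                (s["row"], s["col"]): GridSection(s["region"], s.get("is_valid", True))
                for s in d["sections"]
            },
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GridLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _grid_coords(shape: tuple[int, int], layout: GridLayout):
    """Continuous grid coordinates (u, v) of every pixel center."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    dy = rows - layout.origin[0]
    dx = cols - layout.origin[1]
    th = np.deg2rad(layout.rotation_deg)
    # inverse rigid transform: rotate image offsets back into grid axes
    u = (np.cos(th) * dy + np.sin(th) * dx) / layout.spacing_vox
    v = (-np.sin(th) * dy + np.cos(th) * dx) / layout.spacing_vox
    return u, v


def section_index_map(shape: tuple[int, int], layout: GridLayout) -> np.ndarray:
    """Map every pixel to a section id, or -1 where no section lies.

    A pixel with grid coordinate u in (k, k+1] belongs to grid row k:
    pixels exactly on a grid line are assigned to the lower-index section.
    """
    u, v = _grid_coords(shape, layout)
    r = np.ceil(u).astype(int) - 1
    c = np.ceil(v).astype(int) - 1
    inside = (r >= 0) & (r < layout.n_rows) & (c >= 0) & (c < layout.n_cols)
    out = np.full(shape, -1, dtype=int)
    occupied = np.zeros((layout.n_rows, layout.n_cols), dtype=bool)
    for (rr, cc) in layout.sections:
        occupied[rr, cc] = True
    sel = inside.copy()
    sel[inside] = occupied[r[inside], c[inside]]
    out[sel] = r[sel] * layout.n_cols + c[sel]
    return out


def register_grid(shape: tuple[int, int], layout: GridLayout) -> np.ndarray:
    """Assign each pixel of a flattened image to a grid section.

    Returns an integer map of section ids (-1 outside any labeled
    section).  Raises :class:`GridGeometryError` if a labeled section has
    no pixels inside the image, i.e. the transform places it outside.
    """
    smap = section_index_map(shape, layout)
    present = set(np.unique(smap)) - {-1}
    missing = [rc for rc in layout.sections
               if layout.section_id(*rc) not in present]
    if missing:
        raise GridGeometryError(
            f"sections {sorted(missing)} fall outside the image; "
            "check grid origin/rotation"
        )
    return smap


def merge_partial_sections(
    smap: np.ndarray,
    layout: GridLayout,
    valid: np.ndarray,
    min_fraction: float = 0.5,
) -> tuple[np.ndarray, dict[int, int]]:
    """Merge partial rim sections into their adjacent full section.

    A section whose valid-pixel count is below ``min_fraction`` of the
    median count is merged into the neighboring section with which it
    shares the longest boundary (most 4-adjacent pixel pairs).  Returns
    the updated map and a ``{partial_id: target_id}`` record.  Sections
    with no adjacent full section are left unmerged.
    """
    ids = [layout.section_id(*rc) for rc in layout.sections]
    counts = {i: int(np.sum((smap == i) & valid)) for i in ids}
    nonzero = [c for c in counts.values() if c > 0]
    if not nonzero:
        return smap, {}
    cutoff = min_fraction * float(np.median(nonzero))
    partial = {i for i, c in counts.items() if 0 < c < cutoff}
    merged = smap.copy()
    record: dict[int, int] = {}
    for pid in sorted(partial):
        mask = merged == pid
        shared: dict[int, int] = {}
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            neigh = np.roll(merged, shift, axis=axis)
            # rolled-in border values are not true neighbors
            if axis == 0:
                edge = slice(0, 1) if shift == 1 else slice(-1, None)
                sl = (edge, slice(None))
            else:
                edge = slice(0, 1) if shift == 1 else slice(-1, None)
                sl = (slice(None), edge)
            neigh = neigh.copy()
            neigh[sl] = -1
            for nid in np.unique(neigh[mask]):
                if nid >= 0 and nid != pid and nid not in partial:
                    shared[nid] = shared.get(int(nid), 0) + int(
                        np.sum(neigh[mask] == nid))
        if shared:
            target = max(sorted(shared), key=lambda k: shared[k])
            merged[mask] = target
            record[pid] = int(target)
    return merged, record


def aggregate_sections(
    cnr: np.ndarray,
    valid: np.ndarray,
    smap: np.ndarray,
    layout: GridLayout,
    concentrations: pd.DataFrame,
    sn_cnr_min_pct: float = 10.0,
) -> pd.DataFrame:
    """Build the per-section table from a cleaned flat image.

    ``mean_cnr`` is the arithmetic mean CNR (percent) of the section's
    valid pixels; for SN sections ``sn_voxel_fraction`` is the fraction of
    valid pixels with CNR above ``sn_cnr_min_pct``.  NM/Fe concentrations
    are joined from ``concentrations`` (columns grid_row, grid_col,
    nm_conc, fe_conc, valid); sections flagged invalid there are dropped.
    Sections with zero valid pixels are emitted with missing ``mean_cnr``
    and a warning.
    """
    conc = concentrations.set_index(["grid_row", "grid_col"])
    rows = []
    for (r, c), sec in sorted(layout.sections.items()):
        sid = layout.section_id(r, c)
        sel = (smap == sid) & valid
        n_vox = int(np.sum(sel))
        if n_vox == 0:
            warnings.warn(
                f"section ({r}, {c}) of specimen {layout.specimen_id!r} has "
                "no valid voxels; mean CNR missing",
                stacklevel=2,
            )
            mean_cnr = np.nan
        else:
            mean_cnr = float(np.mean(cnr[sel]))
        sn_frac = np.nan
        if sec.is_sn and n_vox > 0:
            sn_frac = float(np.mean(cnr[sel] > sn_cnr_min_pct))
        try:
            crow = conc.loc[(r, c)]
        except KeyError:
            raise KeyError(
                f"no concentration row for section ({r}, {c}) of specimen "
                f"{layout.specimen_id!r}"
            ) from None
        usable = sec.is_valid and bool(crow.get("valid", True))
        if not usable:
            continue
        rows.append({
            "specimen_id": layout.specimen_id,
            "diagnosis": layout.diagnosis,
            "grid_row": r,
            "grid_col": c,
            "region": sec.region,
            "mean_cnr": mean_cnr,
            "sn_voxel_fraction": sn_frac,
            "nm_conc": float(crow["nm_conc"]),
            "fe_conc": float(crow["fe_conc"]),
            "n_voxels": n_vox,
        })
    return pd.DataFrame(rows, columns=SECTION_TABLE_COLUMNS)
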