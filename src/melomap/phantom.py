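"""Synthetic specimen generator.

Generates, per cohort: a ground-truth table of grid sections (measured NM
and Fe concentrations, true section CNR, subject intercepts), a grid
layout per specimen, and rendered 3D image volumes with the artifacts the
cleaning chain is designed to remove (bright specimen rim, signal-dropout
voxels, water well markers).

Voxel intensities map the true section CNR (percent) multiplicatively:

    I = tissue_level * (1 + cnr / 100)

inside the specimen and ``background_level`` outside, giving a bimodal
intensity histogram.  No magnetization-transfer physics is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import (
    AD,
    PD,
    GROUPS,
    CENTRAL_REGIONS,
    POSTERIOR,
    ConfigurationError,
    PhantomConfig,
)
from .gridmap import GridLayout, GridSection, section_index_map

__all__ = [
    "SpecimenVolume",
    "SpecimenRender",
    "Cohort",
    "TRUTH_COLUMNS",
    "rng_stream",
    "allocate_sections",
    "build_layouts",
    "generate_concentrations",
    "generate_section_cnr",
    "render_volume",
    "generate_cohort",
]

#: Fixed column order of the ground-truth CSV.
TRUTH_COLUMNS = [
    "specimen_id", "diagnosis", "grid_row", "grid_col", "region",
    "nm_conc", "fe_conc", "true_cnr", "valid",
]

#: Raster fill order of regions within a specimen grid (column-major from
#: the posterior/left side, anterior at the right).
_FILL_ORDER = (POSTERIOR, "CC", "SN", "RN", "PAG", "SC", "unassigned")

_GRID_ROWS = 3


def rng_stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for stage ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass
class SpecimenVolume:
    """3D intensity volume (slices, rows, cols) of one specimen."""

    data: np.ndarray
    voxel_size_mm: float
    slice_thickness_mm: float
    specimen_id: str
    diagnosis: int


@dataclass
class SpecimenRender:
    """Rendered specimen plus the generator's own ground truth."""

    volume: SpecimenVolume
    layout: GridLayout
    section_map: np.ndarray       # 2D ground-truth pixel -> section id
    dropout_mask: np.ndarray      # 3D bool
    tissue_mask: np.ndarray       # 2D bool, in-specimen pixels


@dataclass
class Cohort:
    config: PhantomConfig
    truth: pd.DataFrame
    subject_intercepts: pd.Series     # per specimen_id
    renders: list[SpecimenRender]


def _distribute(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + 1] * rem + [base] * (k - rem)


def allocate_sections(cfg: PhantomConfig) -> pd.DataFrame:
    """One row per grid section with specimen, region and validity.

    Each (region, group) cell count is spread near-evenly over the group's
    specimens.  The invalid sections (dissection/assay failures) are extra
    unassigned-region sections added to the first specimen of each group.
    """
    cfg = cfg.resolve()
    rows = []
    specimen_ids = {
        AD: [f"AD{i + 1:02d}" for i in range(cfg.n_specimens_ad)],
        PD: [f"PD{i + 1:02d}" for i in range(cfg.n_specimens_pd)],
    }
    for group in GROUPS:
        ids = specimen_ids[group]
        for region in CENTRAL_REGIONS + (POSTERIOR,):
            counts = _distribute(cfg.section_counts[(region, group)], len(ids))
            for sid, n in zip(ids, counts):
                rows.extend(
                    {"specimen_id": sid, "diagnosis": group, "region": region,
                     "valid": True}
                    for _ in range(n)
                )
    df = pd.DataFrame(rows)
    # invalid extras: one unassigned section on the first specimen per group
    extras = []
    for group in list(GROUPS)[: cfg.n_invalid_sections]:
        extras.append({
            "specimen_id": specimen_ids[group][0], "diagnosis": group,
            "region": "unassigned", "valid": False,
        })
    for i in range(len(extras), cfg.n_invalid_sections):
        extras.append({
            "specimen_id": specimen_ids[AD][i % cfg.n_specimens_ad],
            "diagnosis": AD, "region": "unassigned", "valid": False,
        })
    df = pd.concat([df, pd.DataFrame(extras)], ignore_index=True)

    per_specimen = df.groupby("specimen_id").size()
    bad = per_specimen[(per_specimen < 13) | (per_specimen > 36)]
    if len(bad):
        raise ConfigurationError(
            f"sections per specimen outside [13, 36]: {bad.to_dict()}"
        )
    return df


def build_layouts(cfg: PhantomConfig, allocation: pd.DataFrame) -> list[GridLayout]:
    """Assign grid positions and build a :class:`GridLayout` per specimen.

    Sections fill a 3-row grid column-major from the left, in the order
    posterior, CC, SN, RN, PAG, SC, unassigned, so posterior tissue sits
    at the posterior (left) side.  Trailing cells stay empty (outside the
    specimen).  The layout geometry is the generator's ground truth; the
    cleaning pipeline re-derives the mapping from it.
    """
    cfg = cfg.resolve()
    img = cfg.image_params
    spacing = img.grid_pitch_mm / img.voxel_size_mm
    layouts = []
    for sid, spec_df in allocation.groupby("specimen_id", sort=True):
        order = {region: i for i, region in enumerate(_FILL_ORDER)}
        spec_df = spec_df.sort_values(
            by=["region", "valid"],
            key=lambda s: s.map(order) if s.name == "region" else s,
            kind="stable",
        )
        total = len(spec_df)
        n_rows = _GRID_ROWS
        n_cols = math.ceil(total / n_rows)
        cells = [(r, c) for c in range(n_cols) for r in range(n_rows)]
        sections = {}
        positions = []
        for (r, c), (_, row) in zip(cells, spec_df.iterrows()):
            sections[(r, c)] = GridSection(region=row["region"],
                                           is_valid=bool(row["valid"]))
            positions.append((r, c))
        ny = 2 * img.margin_voxels + math.ceil(n_rows * spacing)
        nx = 2 * img.margin_voxels + math.ceil(n_cols * spacing)
        m = img.margin_voxels
        wells = ((m / 2, nx / 2), (ny - m / 2, nx / 2),
                 (ny / 2, m / 2), (ny / 2, nx - m / 2))
        layout = GridLayout(
            origin=(float(m), float(m)),
            spacing_vox=spacing,
            n_rows=n_rows,
            n_cols=n_cols,
            sections=sections,
            well_markers=wells,
            specimen_id=str(sid),
            diagnosis=int(spec_df["diagnosis"].iloc[0]),
        )
        allocation.loc[spec_df.index, "grid_row"] = [p[0] for p in positions]
        allocation.loc[spec_df.index, "grid_col"] = [p[1] for p in positions]
        layouts.append(layout)
    allocation["grid_row"] = allocation["grid_row"].astype(int)
    allocation["grid_col"] = allocation["grid_col"].astype(int)
    return layouts


def _draw_truncated(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (concentrations are >= 0)."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_concentrations(cfg: PhantomConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw measured NM and Fe concentrations for every grid section.

    NM and Fe are drawn independently per section from the (region, group)
    truncated-normal cells; the table also fixes specimen membership and
    grid positions.  Reproducible under a fixed config seed.
    """
    cfg = cfg.resolve()
    if rng is None:
        rng = rng_stream(cfg.seed, 1)
    allocation = allocate_sections(cfg)
    build_layouts(cfg, allocation)
    nm = np.empty(len(allocation))
    fe = np.empty(len(allocation))
    for (region, group), idx in allocation.groupby(
            ["region", "diagnosis"], sort=True).groups.items():
        params = cfg.region_params[(region, group)]
        idx = np.asarray(idx)
        nm[idx] = _draw_truncated(rng, *params["nm"], size=len(idx))
        fe[idx] = _draw_truncated(rng, *params["fe"], size=len(idx))
    allocation["nm_conc"] = nm
    allocation["fe_conc"] = fe
    return allocation


def generate_section_cnr(
    truth: pd.DataFrame,
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compute the true CNR (percent) of every section.

    Central-anterior sections follow the linear signal model plus the
    regional baseline field; posterior sections draw CNR independently of
    NM and Fe.  One subject intercept is drawn per specimen.  Returns the
    completed truth table and the per-specimen intercepts.
    """
    cfg = cfg.resolve()
    if rng is None:
        rng = rng_stream(cfg.seed, 2)
    sc = cfg.signal_coeffs
    gamma = cfg.baseline
    truth = truth.copy()

    specimens = sorted(truth["specimen_id"].unique())
    b0 = pd.Series(
        rng.normal(0.0, sc.subject_intercept_sd, size=len(specimens)),
        index=specimens, name="subject_intercept",
    )

    is_post = truth["region"] == POSTERIOR
    gam = np.array([
        0.0 if p else gamma[(reg, int(g))]
        for p, reg, g in zip(is_post, truth["region"], truth["diagnosis"])
    ])
    linear = (sc.beta0
              + sc.beta1 * truth["nm_conc"].to_numpy()
              + sc.beta2 * truth["fe_conc"].to_numpy()
              + sc.beta3 * truth["diagnosis"].to_numpy()
              + gam)
    eps = rng.normal(0.0, sc.residual_sd, size=len(truth))
    post_mean = np.where(truth["diagnosis"] == PD,
                         cfg.posterior_cnr_mean_pct[1],
                         cfg.posterior_cnr_mean_pct[0])
    eps_post = rng.normal(0.0, cfg.posterior_cnr_sd_pct, size=len(truth))
    cnr = np.where(is_post, post_mean + eps_post, linear + eps)
    cnr = cnr + b0.loc[truth["specimen_id"]].to_numpy()
    truth["true_cnr"] = cnr
    return truth[TRUTH_COLUMNS], b0


def render_volume(
    truth_specimen: pd.DataFrame,
    layout: GridLayout,
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> SpecimenRender:
    """Render one specimen volume from its true section CNRs.

    In-specimen voxels get ``tissue_level * (1 + cnr/100)``; the rim of
    the specimen is brightened by the edge-artifact amplitude, dropout
    voxels are set to the background level, and four water well markers
    are placed at the dish rim.  The exact voxel-to-section map is
    returned as ground truth.
    """
    cfg = cfg.resolve()
    img = cfg.image_params
    if rng is None:
        rng = rng_stream(cfg.seed, 3)

    n_rows, n_cols = layout.n_rows, layout.n_cols
    ny = 2 * img.margin_voxels + math.ceil(n_rows * layout.spacing_vox)
    nx = 2 * img.margin_voxels + math.ceil(n_cols * layout.spacing_vox)
    grid_extent = (layout.origin[0] + n_rows * layout.spacing_vox,
                   layout.origin[1] + n_cols * layout.spacing_vox)
    if grid_extent[0] > ny or grid_extent[1] > nx:
        raise ConfigurationError("grid does not fit inside the volume")

    smap = section_index_map((ny, nx), layout)
    cnr_by_id = {
        layout.section_id(int(r.grid_row), int(r.grid_col)): float(r.true_cnr)
        for r in truth_specimen.itertuples()
    }
    base = np.full((ny, nx), img.background_level, dtype=float)
    tissue_mask = smap >= 0
    for sid, cnr in cnr_by_id.items():
        base[smap == sid] = img.tissue_level * (1.0 + cnr / 100.0)

    # bright rim along the specimen boundary (city-block distance)
    if img.edge_artifact_amplitude > 0 and img.edge_artifact_width > 0:
        d = ndimage.distance_transform_cdt(tissue_mask, metric="taxicab")
        rim = tissue_mask & (d <= img.edge_artifact_width)
        base[rim] *= 1.0 + img.edge_artifact_amplitude

    data = np.repeat(base[None, :, :], img.n_slices, axis=0)
    if img.voxel_noise_sd > 0:
        data = data * (1.0 + rng.normal(0.0, img.voxel_noise_sd, size=data.shape))

    dropout = np.zeros(data.shape, dtype=bool)
    if img.dropout_probability > 0:
        dropout = (rng.random(data.shape) < img.dropout_probability) \
            & tissue_mask[None, :, :]
        data[dropout] = img.background_level

    for (wy, wx) in layout.well_markers:
        iy, ix = int(round(wy)), int(round(wx))
        if not (0 <= iy < ny and 0 <= ix < nx):
            raise ConfigurationError("well marker outside the volume")
        data[:, max(iy - 1, 0):iy + 1, max(ix - 1, 0):ix + 1] = \
            img.well_marker_level

    volume = SpecimenVolume(
        data=data,
        voxel_size_mm=img.voxel_size_mm,
        slice_thickness_mm=img.slice_thickness_mm,
        specimen_id=layout.specimen_id,
        diagnosis=layout.diagnosis,
    )
    return SpecimenRender(volume=volume, layout=layout, section_map=smap,
                          dropout_mask=dropout, tissue_mask=tissue_mask)


def generate_cohort(cfg: PhantomConfig, render: bool = True) -> Cohort:
    """Generate the full synthetic cohort (truth table, layouts, volumes)."""
    cfg = cfg.resolve()
    truth = generate_concentrations(cfg, rng_stream(cfg.seed, 1))
    truth, b0 = generate_section_cnr(truth, cfg, rng_stream(cfg.seed, 2))
    allocation = allocate_sections(cfg)
    layouts = build_layouts(cfg, allocation)
    renders = []
    if render:
        for k, layout in enumerate(layouts):
            spec_truth = truth[truth["specimen_id"] == layout.specimen_id]
            renders.append(render_volume(spec_truth, layout, cfg,
                                         rng_stream(cfg.seed, 3, k)))
    return Cohort(config=cfg, truth=truth, subject_intercepts=b0,
                  renders=renders)
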