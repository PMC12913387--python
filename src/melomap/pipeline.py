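"""End-to-end orchestration: phantom -> clean -> aggregate -> fit.

``clean_specimen`` wires the voxel-cleaning chain for one specimen in the
fixed order: 3D low-signal threshold -> flatten -> unconditional border
removal -> provisional CNR (reference mode from the post-border image) ->
conditional band removal -> per-section Cook's filtering -> final CNR
recomputation with the final reference mode.

``run_cohort`` runs a whole synthetic cohort through that chain and fits
the section-level models; ``run_pipeline`` additionally writes all
artifacts (NIfTI volumes, CSV tables, JSON reports) with a checksummed
manifest so identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridmap, phantom, stats, voxelclean
from .config import CleaningParams, PhantomConfig, default_config
from .gridmap import GridLayout
from .voxelclean import REASON_CODES, CleanFlatImage

__all__ = [
    "CleanResult",
    "CohortResult",
    "RunConfig",
    "clean_specimen",
    "run_cohort",
    "run_pipeline",
]

log = logging.getLogger("melomap")


@dataclass
class CleanResult:
    flat: CleanFlatImage
    section_map: np.ndarray
    layout: GridLayout


@dataclass
class CohortResult:
    cohort: phantom.Cohort
    sections: pd.DataFrame
    clean_results: list[CleanResult] = field(default_factory=list)


def _section_region_mask(smap: np.ndarray, layout: GridLayout,
                         predicate) -> np.ndarray:
    ids = [layout.section_id(r, c) for (r, c), s in layout.sections.items()
           if predicate(s)]
    return np.isin(smap, ids)


def clean_specimen(
    volume: np.ndarray,
    layout: GridLayout,
    params: CleaningParams = CleaningParams(),
    reference_region: str = "CC",
    reference_mask: np.ndarray | None = None,
    sn_mask: np.ndarray | None = None,
) -> CleanResult:
    """Run the full cleaning chain on one specimen volume.

    The reference region defaults to the crus cerebri sections of the
    grid layout; pass a different region label, or explicit 2D masks for
    the reference region and the SN sections, to override.
    """
    thr = voxelclean.low_signal_threshold(volume, params)
    valid3d = np.asarray(volume) >= thr
    intensity, counts = voxelclean.flatten(volume, valid3d)

    reasons = voxelclean.classify_low_signal(counts == 0)
    smap = gridmap.register_grid(intensity.shape, layout)
    if sn_mask is None:
        sn_mask = _section_region_mask(smap, layout, lambda s: s.is_sn)
    if reference_mask is None:
        ref_mask = _section_region_mask(smap, layout,
                                        lambda s: s.region == reference_region)
    else:
        ref_mask = np.asarray(reference_mask, bool)

    # (a) unconditional border removal
    reasons = voxelclean.remove_edge_artifacts(reasons, None, sn_mask, params,
                                               apply_band=False)
    # provisional CNR from the post-border image
    valid = reasons == REASON_CODES["valid"]
    prov_cnr, _ = voxelclean.compute_cnr(intensity, valid, ref_mask, params)
    # (b) conditional band removal
    reasons = voxelclean.remove_edge_artifacts(reasons, prov_cnr, sn_mask,
                                               params, apply_band=True)
    # per-section Cook's filtering on provisional CNR values
    valid = reasons == REASON_CODES["valid"]
    for sid in np.unique(smap[smap >= 0]):
        sel = (smap == sid) & valid
        idx = np.argwhere(sel)
        if idx.size == 0:
            continue
        keep = voxelclean.cooks_outlier_filter(prov_cnr[sel],
                                               params.cooks_multiplier)
        flagged = idx[~keep]
        reasons[flagged[:, 0], flagged[:, 1]] = REASON_CODES["cooks_outlier"]
    # final CNR with the final reference mode
    valid = reasons == REASON_CODES["valid"]
    cnr, mode = voxelclean.compute_cnr(intensity, valid, ref_mask, params)

    flat = CleanFlatImage(intensity=intensity, reasons=reasons, cnr=cnr,
                         reference_mode=mode, low_signal_threshold=thr)
    counts_by_reason = flat.removal_counts()
    log.info("specimen %s cleaned: %s", layout.specimen_id,
             {k: v for k, v in counts_by_reason.items() if k != "valid"})
    return CleanResult(flat=flat, section_map=smap, layout=layout)


def run_cohort(
    cfg: PhantomConfig | None = None,
    seed: int | None = None,
    keep_images: bool = False,
) -> CohortResult:
    """Generate a cohort, clean every specimen, and aggregate sections."""
    if cfg is None:
        cfg = default_config()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg = cfg.resolve()
    cohort = phantom.generate_cohort(cfg, render=True)
    tables = []
    cleans = []
    for render in cohort.renders:
        result = clean_specimen(render.volume.data, render.layout,
                                cfg.cleaning_params)
        conc = cohort.truth[
            cohort.truth["specimen_id"] == render.layout.specimen_id]
        table = gridmap.aggregate_sections(
            result.flat.cnr, result.flat.valid, result.section_map,
            render.layout, conc,
            sn_cnr_min_pct=cfg.cleaning_params.sn_cnr_min_pct,
        )
        tables.append(table)
        if keep_images:
            cleans.append(result)
    sections = pd.concat(tables, ignore_index=True)
    return CohortResult(cohort=cohort, sections=sections,
                        clean_results=cleans)


# ----------------------------------------------------------------------
# full run with artifacts
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full reproducible run.

    Per-stage seeds are split from the master seed with a counter-based
    scheme (SeedSequence([seed, stage])), so stages can be rerun in
    isolation.  Any cleaning-parameter override is echoed to the log.
    """

    out_dir: str = "melomap-run"
    seed: int = 0
    stages: tuple[str, ...] = ("phantom", "clean", "aggregate", "fit")
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    mcmc_steps: int = 2000
    mcmc_burn: int = 750
    mcmc_walkers: int = 16
    mcmc_chains: int = 4
    group_diff_metrics: tuple[str, ...] = ("nm_mri", "nm_conc", "fe_conc")
    group_diff_regions: tuple[str, ...] = ("SN", "RN", "CC", "SC", "PAG")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        defaults = CleaningParams()
        if isinstance(ph, dict):
            cleaning = ph.pop("cleaning_params", {})
            image = ph.pop("image_params", {})
            from .config import ImageParams
            cp = CleaningParams(**{**dataclasses.asdict(defaults), **cleaning})
            for name in cleaning:
                log.info("cleaning override: %s = %r", name, cleaning[name])
            ph = PhantomConfig(
                **ph,
                cleaning_params=cp,
                image_params=ImageParams(**image) if image else ImageParams(),
            )
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(phantom=ph, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(run_cfg: RunConfig) -> Path:
    """Execute the configured stages, writing artifacts and a manifest.

    Stage failure raises with the failing stage named; artifacts written
    before the failure are preserved.
    """
    from . import io as mio

    out = Path(run_cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(run_cfg.phantom, seed=run_cfg.seed).resolve()
    artifacts: list[Path] = []
    stage = "setup"
    try:
        stage = "phantom"
        cohort = phantom.generate_cohort(cfg, render=True)
        truth_path = out / "truth.csv"
        cohort.truth.to_csv(truth_path, index=False)
        artifacts.append(truth_path)
        for render in cohort.renders:
            vp = out / f"{render.layout.specimen_id}.nii"
            mio.save_volume(render.volume, vp)
            lp = out / f"{render.layout.specimen_id}.grid.json"
            render.layout.to_json(lp)
            artifacts.extend([vp, lp])

        sections = None
        if "clean" in run_cfg.stages or "aggregate" in run_cfg.stages:
            stage = "clean"
            tables = []
            removal_log = {}
            for render in cohort.renders:
                result = clean_specimen(render.volume.data, render.layout,
                                        cfg.cleaning_params)
                removal_log[render.layout.specimen_id] = \
                    result.flat.removal_counts()
                mio.save_flat_image(
                    result.flat, out / f"{render.layout.specimen_id}.clean.nii")
                reasons_path = out / f"{render.layout.specimen_id}.reasons.csv"
                mio.save_reason_map(result.flat, reasons_path)
                artifacts.append(reasons_path)
                stage = "aggregate"
                conc = cohort.truth[cohort.truth["specimen_id"]
                                    == render.layout.specimen_id]
                tables.append(gridmap.aggregate_sections(
                    result.flat.cnr, result.flat.valid, result.section_map,
                    render.layout, conc,
                    sn_cnr_min_pct=cfg.cleaning_params.sn_cnr_min_pct,
                ))
                stage = "clean"
            (out / "removal_counts.json").write_text(
                json.dumps(removal_log, indent=1, sort_keys=True))
            artifacts.append(out / "removal_counts.json")
            stage = "aggregate"
            sections = pd.concat(tables, ignore_index=True)
            sec_path = out / "sections.csv"
            sections.to_csv(sec_path, index=False)
            artifacts.append(sec_path)

        if "fit" in run_cfg.stages and sections is not None:
            stage = "fit"
            report = {
                "mixed_model": {
                    sub: stats.fit_mixed(sections, subset=sub).to_dict()
                    for sub in ("central_anterior", "posterior")
                },
                "group_differences": {},
            }
            for region in run_cfg.group_diff_regions:
                for metric in run_cfg.group_diff_metrics:
                    gd = stats.fit_group_difference(
                        sections, region, metric,
                        seed=int(np.random.SeedSequence(
                            [run_cfg.seed, 4]).generate_state(1)[0] % (2**31)),
                        n_chains=run_cfg.mcmc_chains,
                        n_walkers=run_cfg.mcmc_walkers,
                        n_steps=run_cfg.mcmc_steps,
                        n_burn=run_cfg.mcmc_burn,
                    )
                    report["group_differences"][f"{region}/{metric}"] = \
                        gd.to_dict()
            rp = out / "report.json"
            rp.write_text(json.dumps(report, indent=1, sort_keys=True))
            artifacts.append(rp)
            tp = out / "report.txt"
            tp.write_text(mio.format_report(report))
            artifacts.append(tp)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": run_cfg.seed,
        "stages": list(run_cfg.stages),
        "files": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out
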