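"""Default configuration for the synthetic midbrain specimen cohort.

The phantom emulates a post mortem cohort of 11 hemi-midbrain specimens
(7 Alzheimer's-type dementia, 4 Parkinson's disease), each sliced and
dissected into 13-36 grid sections of 3.5 x 3.5 mm.  Per grid section the
phantom provides a measured neuromelanin concentration (ug NM / mg wet
tissue), a measured iron concentration (ng Fe / mg wet tissue), and a true
NM-MRI contrast-to-noise ratio (CNR).

Conventions
-----------
* CNR is expressed in **percent** throughout the package: a voxel 10 %
  brighter than the reference-region mode has CNR 10.0.  On this scale the
  signal model's concentration slopes (7.37 % CNR per ug NM/mg; 0.050 %
  CNR per ng Fe/mg) and the regional CNR summaries (roughly 0-32 %) are
  mutually consistent.
* Diagnosis is coded AD = 0, PD = 1.

Signal model
------------
For central-anterior sections the true section CNR is exactly the linear
model

    cnr = beta0 + beta1*nm + beta2*fe + beta3*diag + b0_specimen + eps

with a single shared diagnosis offset ``beta3``.  Because section CNR is
measured relative to the mode of the crus-cerebri (CC) reference region
of the *same specimen*, a global per-group signal offset cannot survive
the normalization; the default coefficients therefore anchor the
reference region at zero in both groups: ``beta0`` sets the AD CC cell
to expected CNR 0 and ``beta3`` cancels the concentration-mediated CC
group difference so the PD CC cell is 0 as well.  This matches the
observed CC summaries (0.00 AD / 0.04 PD on the fractional scale) and
makes the noise-free render-clean-aggregate-fit round trip exact.

A deliberate limitation: a single ``beta3`` cannot reproduce
*region-specific* NM-MRI group differences (the observed pattern ranges
from ~3 %CNR in SN to ~21 %CNR in PAG).  A region-resolved baseline
field that matches those differences is incompatible with unbiased
recovery of the concentration slopes (see docs/methods.md for the
quantitative argument), so the generator keeps the pure linear model;
the regional CNR group-difference table below is retained as reference
data only.

Posterior-midbrain sections receive CNR drawn independently of NM and Fe
(no signal-concentration coupling is observed there).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AD",
    "PD",
    "CENTRAL_REGIONS",
    "POSTERIOR",
    "REGION_CONCENTRATIONS",
    "REGION_CNR_GROUP_DIFF_PCT",
    "SECTION_COUNTS",
    "SignalCoeffs",
    "ImageParams",
    "CleaningParams",
    "PhantomConfig",
    "ConfigurationError",
    "derive_signal_field",
    "default_config",
    "noise_free_config",
]

AD, PD = 0, 1
GROUPS = (AD, PD)

#: Central-anterior midbrain region labels.  ``unassigned`` are grid
#: sections not attributed to a named nucleus (white-matter-adjacent
#: tissue; parameterized like crus cerebri).
CENTRAL_REGIONS = ("SN", "RN", "CC", "SC", "PAG", "unassigned")
POSTERIOR = "posterior"
ALL_REGIONS = CENTRAL_REGIONS + (POSTERIOR,)

#: (mean, sd) of measured NM concentration [ug/mg wet tissue] and Fe
#: concentration [ng/mg wet tissue] per (region, group).  The SDs are SDs
#: of measured section values and therefore subsume assay variability
#: (spectrophotometric NM, ICP-OES Fe; repeatability RSD 6-17 %).
REGION_CONCENTRATIONS: Mapping[tuple[str, int], dict[str, tuple[float, float]]] = {
    ("SN", AD): {"nm": (0.57, 0.15), "fe": (69.0, 25.0)},
    ("SN", PD): {"nm": (0.61, 0.12), "fe": (103.0, 50.0)},
    ("RN", AD): {"nm": (0.33, 0.07), "fe": (38.0, 10.0)},
    ("RN", PD): {"nm": (0.24, 0.07), "fe": (38.0, 17.0)},
    ("CC", AD): {"nm": (0.29, 0.09), "fe": (42.0, 11.0)},
    ("CC", PD): {"nm": (0.33, 0.05), "fe": (42.0, 25.0)},
    ("SC", AD): {"nm": (0.34, 0.11), "fe": (54.0, 21.0)},
    ("SC", PD): {"nm": (0.24, 0.07), "fe": (25.0, 7.0)},
    ("PAG", AD): {"nm": (0.35, 0.13), "fe": (46.0, 13.0)},
    ("PAG", PD): {"nm": (0.31, 0.06), "fe": (33.0, 9.0)},
    # unassigned central-anterior tissue: crus-cerebri-like
    ("unassigned", AD): {"nm": (0.29, 0.09), "fe": (42.0, 11.0)},
    ("unassigned", PD): {"nm": (0.33, 0.05), "fe": (42.0, 25.0)},
    # posterior midbrain: not characterized region-wise; typical non-SN values
    ("posterior", AD): {"nm": (0.30, 0.10), "fe": (40.0, 15.0)},
    ("posterior", PD): {"nm": (0.30, 0.10), "fe": (40.0, 15.0)},
}

#: Target total PD - AD difference in section CNR (percent) per
#: central-anterior region, encoding the observed regional NM-MRI group
#: differences (0.03/0.05/0.04/0.12/0.21 on the fractional scale).
REGION_CNR_GROUP_DIFF_PCT: Mapping[str, float] = {
    "SN": 3.0,
    "RN": 5.0,
    "CC": 4.0,
    "SC": 12.0,
    "PAG": 21.0,
    "unassigned": 4.0,  # crus-cerebri-like
}

#: Usable grid-section counts per (region, group).  Regional totals are
#: SN 60, RN 22, CC 35, SC 17, PAG 18, unassigned 11 (163 central-anterior,
#: split 87 AD / 76 PD) plus 56 posterior sections.  Two further sections
#: (one AD, one PD, unassigned region) are generated but flagged invalid,
#: emulating dissection/assay failures, for 221 sections in total.
SECTION_COUNTS: Mapping[tuple[str, int], int] = {
    ("SN", AD): 32, ("SN", PD): 28,
    ("RN", AD): 12, ("RN", PD): 10,
    ("CC", AD): 19, ("CC", PD): 16,
    ("SC", AD): 9, ("SC", PD): 8,
    ("PAG", AD): 10, ("PAG", PD): 8,
    ("unassigned", AD): 5, ("unassigned", PD): 6,
    ("posterior", AD): 36, ("posterior", PD): 20,
}

#: Residual SD of the section-level signal model (percent CNR), calibrated
#: once by simulation at defaults so the fixed-effect R^2 of the mixed
#: model fitted to full-pipeline output is ~0.30; see docs/methods.md.
RESIDUAL_SD_CALIBRATED = 3.6


class ConfigurationError(ValueError):
    """Invalid phantom or pipeline configuration."""


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Expected value of a Normal(mean, sd) truncated at zero.

    Concentration draws are truncated at zero (negative concentrations are
    unphysical), which raises the realized cell mean above the nominal one
    whenever ``mean/sd`` is small; the signal-field derivation uses these
    realized means so its orthogonality constraints match the draws.
    """
    if sd == 0:
        return mean
    from scipy.stats import norm

    alpha = -mean / sd
    z = 1.0 - norm.cdf(alpha)
    return mean + sd * norm.pdf(alpha) / z


@dataclass(frozen=True)
class SignalCoeffs:
    """Fixed-effect coefficients of the section-level CNR model.

    Units: ``beta1`` percent CNR per (ug NM / mg tissue); ``beta2`` percent
    CNR per (ng Fe / mg tissue); ``beta3`` percent CNR (PD vs AD);
    ``subject_intercept_sd`` / ``residual_sd`` percent CNR.
    """

    beta0: float
    beta1: float = 7.37
    beta2: float = 0.050
    beta3: float = 0.0
    subject_intercept_sd: float = 0.25 * RESIDUAL_SD_CALIBRATED
    residual_sd: float = RESIDUAL_SD_CALIBRATED

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


@dataclass(frozen=True)
class ImageParams:
    """Rendering parameters for the synthetic specimen volumes."""

    voxel_size_mm: float = 0.3125       # in-plane; grid pitch 3.5 mm -> 11.2 voxels
    slice_thickness_mm: float = 0.6
    n_slices: int = 5
    grid_pitch_mm: float = 3.5
    margin_voxels: int = 8              # background frame around the grid
    background_level: float = 100.0
    tissue_level: float = 1000.0        # intensity of CNR = 0 tissue
    edge_artifact_amplitude: float = 0.5  # bright rim, relative to local signal
    edge_artifact_width: int = 2        # rim thickness in voxels
    dropout_probability: float = 0.02
    voxel_noise_sd: float = 0.05        # multiplicative voxel noise (fraction)
    well_marker_level: float = 2000.0


@dataclass(frozen=True)
class CleaningParams:
    """Parameters of the voxel-cleaning chain (CNR cutoffs in percent)."""

    kde_bandwidth: float | str = "silverman"
    kde_grid_points: int = 512
    border_width: int = 2               # unconditional dilation of the perimeter
    band_width: int = 5                 # conditional band beyond the border
    edge_cnr_max_pct: float = 40.0      # band voxels above this CNR are removed
    sn_cnr_min_pct: float = 10.0        # SN-voxel counting threshold
    cooks_multiplier: float = 4.0       # Cook's distance cutoff = multiplier / n


@dataclass(frozen=True)
class PhantomConfig:
    """Full configuration of the synthetic cohort.

    ``baseline`` selects the region x group baseline CNR field gamma:
    ``"auto"`` derives it from the regional reference statistics (see
    module docstring), ``"zero"`` disables it (pure linear signal model),
    or an explicit ``{(region, group): value}`` mapping may be given.
    """

    n_specimens_ad: int = 7
    n_specimens_pd: int = 4
    region_params: Mapping[tuple[str, int], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: dict(REGION_CONCENTRATIONS)
    )
    section_counts: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: dict(SECTION_COUNTS)
    )
    cnr_group_diff_pct: Mapping[str, float] = field(
        default_factory=lambda: dict(REGION_CNR_GROUP_DIFF_PCT)
    )
    signal_coeffs: SignalCoeffs | None = None   # None -> derived defaults
    baseline: str | Mapping[tuple[str, int], float] = "auto"
    posterior_cnr_mean_pct: tuple[float, float] = (5.0, 5.0)  # (AD, PD)
    posterior_cnr_sd_pct: float = 6.0
    n_invalid_sections: int = 2
    image_params: ImageParams = field(default_factory=ImageParams)
    cleaning_params: CleaningParams = field(default_factory=CleaningParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for (region, group), params in self.region_params.items():
            for metric, (mean, sd) in params.items():
                if sd < 0:
                    raise ConfigurationError(
                        f"negative SD for {metric} in region {region!r}, "
                        f"group {group}"
                    )
                if mean < 0:
                    raise ConfigurationError(
                        f"negative mean {metric} concentration in region "
                        f"{region!r}, group {group}"
                    )
        for (region, group), n in self.section_counts.items():
            if n < 0:
                raise ConfigurationError(
                    f"negative section count for region {region!r}, group {group}"
                )
        if self.signal_coeffs is not None:
            sc = self.signal_coeffs
            if sc.subject_intercept_sd < 0 or sc.residual_sd < 0:
                raise ConfigurationError("signal-model SDs must be >= 0")

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------

    def resolve(self) -> "PhantomConfig":
        """Return a config with derived signal coefficients and baseline.

        Idempotent: explicit ``signal_coeffs`` / ``baseline`` are kept.
        """
        coeffs = self.signal_coeffs
        baseline = self.baseline
        if coeffs is None or baseline == "auto":
            beta1 = coeffs.beta1 if coeffs is not None else 7.37
            beta2 = coeffs.beta2 if coeffs is not None else 0.050
            beta0, beta3, gamma = derive_signal_field(
                self.region_params, self.section_counts,
                self.cnr_group_diff_pct, beta1, beta2,
            )
            if coeffs is None:
                coeffs = SignalCoeffs(beta0=beta0, beta1=beta1, beta2=beta2,
                                      beta3=beta3)
            if baseline == "auto":
                baseline = gamma
        if baseline == "zero":
            baseline = {(r, g): 0.0 for r in CENTRAL_REGIONS for g in GROUPS}
        return replace(self, signal_coeffs=coeffs, baseline=baseline)

    @property
    def n_specimens(self) -> int:
        return self.n_specimens_ad + self.n_specimens_pd

    def specimens_per_group(self, group: int) -> int:
        return self.n_specimens_ad if group == AD else self.n_specimens_pd


def derive_signal_field(
    region_params: Mapping[tuple[str, int], dict],
    section_counts: Mapping[tuple[str, int], int],
    cnr_group_diff_pct: Mapping[str, float],
    beta1: float,
    beta2: float,
) -> tuple[float, float, dict[tuple[str, int], float]]:
    """Derive (beta0, beta3, gamma) of the section-level signal model.

    Reference-region anchoring (see the module docstring): ``beta0``
    sets the AD crus-cerebri cell to expected CNR zero and ``beta3``
    cancels the concentration-mediated CC group difference so the PD CC
    cell is zero too -- per-specimen reference normalization makes any
    further global diagnosis offset unobservable.  Cell means are taken
    from the truncated draw distribution.  The returned regional baseline
    field ``gamma`` is identically zero: the generator deliberately keeps
    the pure linear model (see the module docstring).
    """
    regions = list(CENTRAL_REGIONS)
    for r in regions:
        for g in GROUPS:
            if section_counts[(r, g)] <= 0:
                raise ConfigurationError(
                    "central-anterior cell counts must be positive")

    def cell_mean(c, metric):
        return truncated_normal_mean(*region_params[c][metric])

    gamma = {(r, g): 0.0 for r in regions for g in GROUPS}

    # anchor the AD crus-cerebri cell at CNR exactly 0 ...
    cc_ad, cc_pd = ("CC", AD), ("CC", PD)
    beta0 = -(beta1 * cell_mean(cc_ad, "nm")
              + beta2 * cell_mean(cc_ad, "fe"))
    # ... and cancel the CC concentration group difference for PD
    beta3 = -(beta1 * (cell_mean(cc_pd, "nm") - cell_mean(cc_ad, "nm"))
              + beta2 * (cell_mean(cc_pd, "fe") - cell_mean(cc_ad, "fe")))
    return float(beta0), float(beta3), gamma


def default_config(seed: int = 0) -> PhantomConfig:
    """The default 11-specimen cohort configuration, fully resolved."""
    return PhantomConfig(seed=seed).resolve()


def noise_free_config(seed: int = 0) -> PhantomConfig:
    """Default cohort with every noise source switched off.

    Concentration SDs, residual and subject-intercept SDs, voxel noise,
    edge artifacts and dropout are all zero; the signal coefficients are
    re-derived for the zero-SD cells (no truncation shift).  Used for
    exact end-to-end recovery checks.
    """
    base = PhantomConfig(seed=seed)
    rp = {cell: {m: (v[0], 0.0) for m, v in params.items()}
          for cell, params in base.region_params.items()}
    img = replace(base.image_params, edge_artifact_amplitude=0.0,
                  dropout_probability=0.0, voxel_noise_sd=0.0)
    cfg = replace(base, region_params=rp, image_params=img,
                  posterior_cnr_sd_pct=0.0).resolve()
    return replace(cfg, signal_coeffs=replace(
        cfg.signal_coeffs, residual_sd=0.0, subject_intercept_sd=0.0))
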