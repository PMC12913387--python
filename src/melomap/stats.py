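"""Section-level statistics.

Two models operate on the section table:

* a Gaussian random-intercept mixed model of section CNR on NM
  concentration, Fe concentration and diagnosis, fitted by maximum
  likelihood with the likelihood profiled over the single variance ratio
  (one random intercept per specimen reduces the covariance structure to
  ``sigma_e^2 (I + lambda Z Z')`` with scalar ``lambda``); and

* a Bayesian hierarchical group-difference model per region and metric,
  ``y = alpha + delta * diagnosis + b0_specimen + eps``, with the subject
  intercepts marginalized analytically and the remaining four parameters
  sampled by affine-invariant ensemble MCMC (emcee).

Wald inference for the mixed model uses residual degrees of freedom
``n - 4`` (number of sections minus fixed effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "MixedModelFit",
    "GroupDiffPosterior",
    "SingularDesignError",
    "fit_mixed",
    "fit_group_difference",
    "split_rhat",
    "METRIC_COLUMNS",
]

#: Metric name -> section-table column.
METRIC_COLUMNS = {"nm_mri": "mean_cnr", "nm_conc": "nm_conc",
                  "fe_conc": "fe_conc"}

FIXED_EFFECTS = ("intercept", "nm_conc", "fe_conc", "diagnosis")


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass
class MixedModelFit:
    """Random-intercept mixed-model fit summary.

    ``beta`` is ordered (intercept, NM slope, Fe slope, diagnosis);
    ``r2`` is the squared correlation between fixed-effect predictions
    and observed CNR, ``r2_rss`` the 1 - RSS/TSS variant.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci95: np.ndarray                # (4, 2)
    df: int
    n_sections: int
    n_specimens: int
    sigma2_subject: float
    sigma2_residual: float
    r2: float
    r2_rss: float
    coef_names: tuple[str, ...] = FIXED_EFFECTS

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "estimate": float(b), "se": float(s), "t": float(t_),
                    "p": float(p_), "ci95": [float(c) for c in ci],
                }
                for name, b, s, t_, p_, ci in zip(
                    self.coef_names, self.beta, self.se, self.t, self.p,
                    self.ci95)
            },
            "df": self.df,
            "n_sections": self.n_sections,
            "n_specimens": self.n_specimens,
            "sigma2_subject": float(self.sigma2_subject),
            "sigma2_residual": float(self.sigma2_residual),
            "r2": float(self.r2),
            "r2_rss": float(self.r2_rss),
        }


def _check_design(X: np.ndarray, names=FIXED_EFFECTS) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via pairwise correlation
        bad = []
        for i in range(1, X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                xi, xj = X[:, i], X[:, j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    continue
                if abs(np.corrcoef(xi, xj)[0, 1]) > 1 - 1e-10:
                    bad.append((names[i], names[j]))
        zero_var = [names[i] for i in range(1, X.shape[1])
                    if np.std(X[:, i]) == 0]
        raise SingularDesignError(
            f"singular design: collinear columns {bad or zero_var}"
        )


def _profile_terms(X, y, group_idx, group_sizes, lam):
    """GLS building blocks for V = I + lam * Z Z' (block diagonal)."""
    c = lam / (1.0 + lam * group_sizes)        # per group
    sums_X = np.stack([np.bincount(group_idx, weights=X[:, k])
                       for k in range(X.shape[1])], axis=1)
    sums_y = np.bincount(group_idx, weights=y)
    XtVX = X.T @ X - (sums_X * c[:, None]).T @ sums_X
    XtVy = X.T @ y - (sums_X * c[:, None]).T @ sums_y
    return XtVX, XtVy, c, sums_y


def _profile_loglik(X, y, group_idx, group_sizes, lam):
    XtVX, XtVy, c, _ = _profile_terms(X, y, group_idx, group_sizes, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    e = y - X @ beta
    sums_e = np.bincount(group_idx, weights=e)
    rss_v = float(e @ e - np.sum(c * sums_e ** 2))
    n = y.size
    sigma2 = max(rss_v / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n
                 + np.sum(np.log1p(lam * group_sizes)))
    return ll, beta, sigma2, XtVX


def fit_mixed(
    sections: pd.DataFrame,
    subset: str = "central_anterior",
) -> MixedModelFit:
    """Fit the random-intercept model of mean section CNR on NM, Fe and
    diagnosis.

    ``subset`` selects ``"central_anterior"`` (all non-posterior regions;
    the primary analysis) or ``"posterior"``.  Rows with missing
    ``mean_cnr`` are dropped with a warning.  The variance ratio
    ``lambda = sigma_b^2 / sigma_e^2`` is profiled out by bounded scalar
    search (tolerance 1e-10); estimates are maximum likelihood.
    """
    if subset == "central_anterior":
        df = sections[sections["region"] != "posterior"]
    elif subset == "posterior":
        df = sections[sections["region"] == "posterior"]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    missing = df["mean_cnr"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} sections with missing "
                      "mean CNR", stacklevel=2)
        df = df[~missing]

    n = len(df)
    specimens, group_idx = np.unique(df["specimen_id"], return_inverse=True)
    if len(specimens) < 2:
        raise ValueError("need at least 2 specimens")
    if n < 10:
        raise ValueError("need at least 10 sections")

    y = df["mean_cnr"].to_numpy(float)
    X = np.column_stack([
        np.ones(n),
        df["nm_conc"].to_numpy(float),
        df["fe_conc"].to_numpy(float),
        df["diagnosis"].to_numpy(float),
    ])
    _check_design(X)
    group_sizes = np.bincount(group_idx).astype(float)

    def neg_ll(log_lam):
        return -_profile_loglik(X, y, group_idx, group_sizes,
                                np.exp(log_lam))[0]

    # bounded search on log lambda, plus the lambda = 0 boundary
    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(1e-10), np.log(1e6)), method="bounded",
        options={"xatol": 1e-10},
    )
    ll_hat = -res.fun
    lam = float(np.exp(res.x))
    ll0 = _profile_loglik(X, y, group_idx, group_sizes, 0.0)[0]
    if ll0 >= ll_hat:
        lam = 0.0

    _, beta, sigma2, XtVX = _profile_loglik(X, y, group_idx, group_sizes, lam)
    cov = np.linalg.inv(XtVX) * sigma2
    se = np.sqrt(np.diag(cov))
    dof = n - X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    tcrit = sps.t.ppf(0.975, dof)
    ci95 = np.column_stack([beta - tcrit * se, beta + tcrit * se])

    yhat = X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - yhat) ** 2))
    if np.std(yhat) > 0 and tss > 0:
        r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    r2_rss = 1.0 - rss / tss if tss > 0 else 0.0

    return MixedModelFit(
        beta=beta, se=se, t=t, p=p, ci95=ci95, df=dof,
        n_sections=n, n_specimens=len(specimens),
        sigma2_subject=lam * sigma2, sigma2_residual=sigma2,
        r2=r2, r2_rss=r2_rss,
    )


# ----------------------------------------------------------------------
# Bayesian group difference
# ----------------------------------------------------------------------

@dataclass
class GroupDiffPosterior:
    """Posterior summary of the AD-to-PD difference for one region/metric."""

    region: str
    metric: str
    draws: np.ndarray              # post-warmup draws of delta
    estimate: float                # posterior mean
    ci95: tuple[float, float]
    rhat: dict[str, float]
    converged: bool
    n_divergent: int | None = None  # not applicable to ensemble MCMC
    param_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "region": self.region, "metric": self.metric,
            "estimate": float(self.estimate),
            "ci95": [float(c) for c in self.ci95],
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "converged": bool(self.converged),
            "n_draws": int(self.draws.size),
        }


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    and R-hat compares within- to between-half variance.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]],
                            axis=0)
    n = half
    means = splits.mean(axis=1)
    w = np.mean(np.var(splits, axis=1, ddof=1))
    b = n * np.var(means, ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _marginal_loglik_batch(y, d, Z, group_sizes, alpha, delta,
                           sigma_b2, sigma_e2):
    """Vectorized Gaussian log likelihood, subject intercepts integrated out.

    ``alpha``/``delta``/``sigma_*2`` are 1-D arrays over walkers; ``Z`` is
    the (n, n_specimens) indicator matrix.  Returns one log likelihood per
    walker.
    """
    e = y[None, :] - alpha[:, None] - delta[:, None] * d[None, :]
    lam = sigma_b2 / sigma_e2                      # (w,)
    c = lam[:, None] / (1.0 + lam[:, None] * group_sizes[None, :])
    sums_e = e @ Z                                 # (w, n_specimens)
    rss_v = np.einsum("wn,wn->w", e, e) - np.sum(c * sums_e ** 2, axis=1)
    n = y.size
    logdet = np.sum(np.log1p(lam[:, None] * group_sizes[None, :]), axis=1) \
        + n * np.log(sigma_e2)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + rss_v / sigma_e2)


def fit_group_difference(
    sections: pd.DataFrame,
    region: str,
    metric: str,
    seed: int = 0,
    n_chains: int = 4,
    n_walkers: int = 16,
    n_steps: int = 2000,
    n_burn: int = 750,
    include_subject_intercept: bool = True,
    fix_sigma: float | None = None,
    flat_priors: bool = False,
) -> GroupDiffPosterior:
    """Posterior of the PD-minus-AD difference in ``metric`` for ``region``.

    The model is ``y = alpha + delta * diagnosis + b0_specimen + eps``
    with weakly informative priors: Normal(0, 10 sd(y)) on alpha and
    delta, half-Normal(0, 5 sd(y)) on both scales.  Subject intercepts
    are marginalized analytically; (alpha, delta, log sigma_b, log
    sigma_e) are sampled by ``n_chains`` independent affine-invariant
    ensembles (emcee) with randomized start values, each taking
    ``n_steps`` samples of which the first ``n_burn`` are discarded.
    The split R-hat diagnostic treats each ensemble as one chain; a
    result with any R-hat >= 1.01 is flagged non-converged (warning,
    not an error).

    ``include_subject_intercept=False`` and ``fix_sigma`` expose the
    conjugate special case (fixed known noise SD, no random effect) used
    for closed-form validation.
    """
    import emcee

    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    df = sections[sections["region"] == region]
    col = METRIC_COLUMNS[metric]
    df = df[df[col].notna()]
    groups_present = set(df["diagnosis"].unique())
    if groups_present != {0, 1}:
        raise ValueError(
            f"region {region!r} lacks sections from both diagnosis groups"
        )
    y = df[col].to_numpy(float)
    d = df["diagnosis"].to_numpy(float)
    specimens, group_idx = np.unique(df["specimen_id"], return_inverse=True)
    group_sizes = np.bincount(group_idx).astype(float)
    Z = np.zeros((y.size, len(specimens)))
    Z[np.arange(y.size), group_idx] = 1.0

    sd_y = float(np.std(y)) or 1.0
    prior_loc_sd = 10.0 * sd_y
    prior_scale_sd = 5.0 * sd_y

    sample_scales = fix_sigma is None
    names = ["alpha", "delta"]
    if sample_scales:
        if include_subject_intercept:
            names += ["log_sigma_b", "log_sigma_e"]
        else:
            names += ["log_sigma_e"]
    ndim = len(names)

    log_norm_const = -0.5 * np.log(2 * np.pi) - np.log(prior_loc_sd)
    hn_const = 0.5 * np.log(2 / np.pi) - np.log(prior_scale_sd)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        alpha, delta = theta[:, 0], theta[:, 1]
        lp = np.zeros(len(theta))
        if not flat_priors:
            lp += (2 * log_norm_const
                   - 0.5 * ((alpha / prior_loc_sd) ** 2
                            + (delta / prior_loc_sd) ** 2))
        if sample_scales:
            log_sigmas = theta[:, 2:]
            bad = np.any(np.abs(log_sigmas) > 30, axis=1)
            log_sigmas = np.clip(log_sigmas, -30, 30)
            sigmas = np.exp(log_sigmas)
            # half-normal prior on each sigma, with log-scale Jacobian
            lp += np.sum(hn_const - 0.5 * (sigmas / prior_scale_sd) ** 2
                         + log_sigmas, axis=1)
            if include_subject_intercept:
                sigma_b2, sigma_e2 = sigmas[:, 0] ** 2, sigmas[:, 1] ** 2
            else:
                sigma_b2 = np.zeros(len(theta))
                sigma_e2 = sigmas[:, 0] ** 2
        else:
            bad = np.zeros(len(theta), bool)
            sigma_b2 = np.zeros(len(theta))
            sigma_e2 = np.full(len(theta), float(fix_sigma) ** 2)
        ll = _marginal_loglik_batch(y, d, Z, group_sizes, alpha, delta,
                                    sigma_b2, sigma_e2)
        out = lp + ll
        out[bad] = -np.inf
        return out

    # data-driven start, jittered per walker and per chain
    mean_ad = y[d == 0].mean()
    mean_pd = y[d == 1].mean()
    resid_sd = max(float(np.std(y - np.where(d > 0, mean_pd, mean_ad))),
                   1e-6 * sd_y)
    start = [mean_ad, mean_pd - mean_ad]
    if sample_scales:
        if include_subject_intercept:
            start += [np.log(resid_sd / 2), np.log(resid_sd)]
        else:
            start += [np.log(resid_sd)]
    start = np.asarray(start)

    # jitter on the scale of the posterior, not the parameter magnitude
    sigma_est = resid_sd if sample_scales else float(fix_sigma)
    jitter = np.full(ndim, 0.3)
    jitter[:2] = max(3.0 * sigma_est / np.sqrt(y.size), 1e-6 * sd_y)

    chains = []
    for chain in range(n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0xBA, chain]))
        p0 = start + jitter * rng.standard_normal((n_walkers, ndim))
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_post, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2 ** 31))).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False,
                         skip_initial_state_check=True)
        # post-warmup draws, step-major so temporal order is preserved
        chains.append(sampler.get_chain()[n_burn:])

    post = np.stack(chains)                 # (chain, step, walker, ndim)
    pooled = post.reshape(n_chains, -1, ndim)
    rhat = {name: split_rhat(pooled[:, :, k]) for k, name in enumerate(names)}
    converged = all(v < 1.01 for v in rhat.values())
    if not converged:
        warnings.warn(
            f"group-difference fit ({region}, {metric}) flagged "
            f"non-converged: R-hat {rhat}",
            stacklevel=2,
        )
    draws = pooled[:, :, 1].ravel()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return GroupDiffPosterior(
        region=region, metric=metric, draws=draws,
        estimate=float(draws.mean()), ci95=(float(lo), float(hi)),
        rhat=rhat, converged=converged, param_names=tuple(names),
    )
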