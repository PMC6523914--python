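"""Covariate adjustment and clustering corrections for methylation counts.

Both region tests operate on *adjusted methylation counts*: the observed
methylated count minus its expectation under a logistic model fitted to
all samples jointly (the model deliberately excludes the group label —
the group effect is what the tests measure).  With an intercept-only
model the adjustment reduces to subtracting the pooled methylation rate
times the coverage.

For the scan statistic, two further corrections are applied: a marginal
(exchangeable-correlation) fit when covariates are present, and a
per-site design-effect deflation ``deff = 1 + (c̄ − 1)·ρ̂`` that accounts
for correlated reads within a CpG site, with the intra-site correlation
ρ̂ estimated by the one-way ANOVA moment (intraclass correlation)
estimator across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MethylationDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedCounts",
    "SiteGroupSummary",
    "DesignEffectCounts",
    "FitError",
    "fit_covariate_model",
    "mixed_model_adjust",
    "estimate_exchangeable_correlation",
    "site_group_summaries",
    "design_effect_adjust",
    "design_effect",
    "anova_icc",
    "recentred_group_counts",
]


class FitError(RuntimeError):
    """The adjustment model failed to converge."""


@dataclass
class AdjustedCounts:
    """Residual methylation counts after covariate adjustment.

    ``r[i, j] = meth[i, j] - p_hat[i, j] * coverage[i, j]`` for every
    cell; with an intercept in the model the residuals sum to zero over
    all observations (the logistic score equation).
    """

    r: np.ndarray
    p_hat: np.ndarray
    model_coefficients: np.ndarray
    covariate_names: tuple[str, ...] = field(default_factory=tuple)
    method: str = "logistic"


@dataclass
class SiteGroupSummary:
    """Per-site, per-group sums of adjusted counts and coverages.

    ``r[k, j] = Σ_i r_kij``, ``C[k, j] = Σ_i c_kij``, group rates
    ``beta = r / C`` and, for two groups, the site-wise difference
    ``delta = beta[0] - beta[1]`` (first group label minus second).
    Sites where any group has zero coverage are dropped (``kept`` masks
    the original site axis).
    """

    group_labels: list
    r: np.ndarray          # (G, m_kept)
    C: np.ndarray          # (G, m_kept)
    beta: np.ndarray       # (G, m_kept)
    delta: np.ndarray | None
    kept: np.ndarray       # bool over original sites
    sites: pd.DataFrame    # kept site coordinates

    @property
    def n_sites(self) -> int:
        return self.r.shape[1]


@dataclass
class DesignEffectCounts:
    """Group-level counts deflated by the per-site design effect.

    ``r_tilde = R / deff`` and ``C_tilde = C / deff`` where ``R`` is the
    recentred group residual count (equal to the raw methylated count
    when no covariates were fitted) and ``deff = 1 + (c̄ − 1)·ρ̂ ≥ floor``.
    """

    group_labels: list
    r_tilde: np.ndarray    # (G, m_kept)
    C_tilde: np.ndarray    # (G, m_kept)
    deff: np.ndarray       # (G, m_kept)
    rho_site: np.ndarray   # (m_kept,) intra-site ANOVA ICC
    kept: np.ndarray
    sites: pd.DataFrame


# ---------------------------------------------------------------------------
# logistic covariate adjustment
# ---------------------------------------------------------------------------

def _pooled_fit(data: MethylationDataset) -> AdjustedCounts:
    total_c = data.coverage.sum()
    if total_c == 0:
        raise ValidationError("all-zero coverage: nothing to fit")
    p = data.meth.sum() / total_c
    p_hat = np.full(data.meth.shape, p)
    r = data.meth - p_hat * data.coverage
    # intercept on the logit scale; guard the degenerate boundary
    eps = np.clip(p, 1e-12, 1 - 1e-12)
    beta0 = np.log(eps / (1 - eps))
    return AdjustedCounts(r=r, p_hat=p_hat,
                          model_coefficients=np.array([beta0]))


def fit_covariate_model(
    data: MethylationDataset,
    covariates: Sequence[str] | None = None,
) -> AdjustedCounts:
    """Binomial logistic regression of methylation on sample covariates.

    One model is fitted over all cells with trials = coverage; the
    covariates are sample-level, so the fit is computed on per-sample
    totals (identical likelihood, one row per sample).  The group label
    must not be among the covariates.  With no covariates the fitted
    rate is the pooled proportion Σm/Σc for every cell.
    """
    names = tuple(covariates) if covariates is not None else ()
    if "group" in names:
        raise ValueError(
            "'group' cannot be a covariate: the group effect is the "
            "quantity under test"
        )
    if data.coverage.sum() == 0:
        raise ValidationError("all-zero coverage: nothing to fit")
    if not names:
        return _pooled_fit(data)

    import statsmodels.api as sm

    X = sm.add_constant(data.covariates(names), has_constant="add")
    succ = data.meth.sum(axis=1).astype(float)
    fail = data.coverage.sum(axis=1).astype(float) - succ
    endog = np.column_stack([succ, fail])
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        except Exception as exc:  # separation, singular design, ...
            raise FitError(
                f"logistic adjustment failed for covariates {list(names)}: "
                f"{exc}"
            ) from exc
    if not np.all(np.isfinite(fit.params)):
        raise FitError(
            f"non-finite coefficients for covariates {list(names)} "
            "(possible separation)"
        )
    p_sample = fit.predict(X)                      # (n,)
    p_hat = np.repeat(p_sample[:, None], data.n_sites, axis=1)
    r = data.meth - p_hat * data.coverage
    return AdjustedCounts(r=r, p_hat=p_hat,
                          model_coefficients=np.asarray(fit.params),
                          covariate_names=names)


def mixed_model_adjust(
    data: MethylationDataset,
    covariates: Sequence[str] | None = None,
) -> AdjustedCounts:
    """Marginal fit with per-subject exchangeable correlation.

    Same contract as :func:`fit_covariate_model`, but when covariates
    are present the coefficients come from a generalized estimating
    equation fit (binomial family, exchangeable working correlation per
    subject, robust sandwich covariance) so that within-subject
    correlation across CpG sites does not bias the adjustment.  With no
    covariates the marginal mean model is a single rate and the fit
    coincides with the pooled proportion, so the simple adjustment is
    returned directly.  Estimation failure falls back to
    :func:`fit_covariate_model` with a logged warning.
    """
    names = tuple(covariates) if covariates is not None else ()
    if not names:
        out = _pooled_fit(data)
        out.method = "marginal-exchangeable"
        return out
    if data.n_sites < 2:
        raise ValidationError(
            "the exchangeable-correlation fit needs >= 2 sites per subject"
        )
    try:
        fit = _gee_fit(data, names)
    except Exception as exc:
        logger.warning(
            "exchangeable-correlation fit failed (%s); falling back to "
            "independence logistic fit", exc,
        )
        out = fit_covariate_model(data, names)
        out.method = "marginal-exchangeable (independence fallback)"
        return out
    import statsmodels.api as sm

    X = sm.add_constant(data.covariates(names), has_constant="add")
    p_sample = np.asarray(fit.predict(X))
    p_hat = np.repeat(p_sample[:, None], data.n_sites, axis=1)
    r = data.meth - p_hat * data.coverage
    return AdjustedCounts(r=r, p_hat=p_hat,
                          model_coefficients=np.asarray(fit.params),
                          covariate_names=names,
                          method="marginal-exchangeable")


def _gee_fit(data: MethylationDataset, names: tuple[str, ...]):
    """GEE fit on per-cell proportions, clusters = subjects."""
    import statsmodels.api as sm

    n, m = data.n_samples, data.n_sites
    cov = data.coverage.astype(float)
    ok = cov > 0
    y = np.where(ok, data.meth / np.maximum(cov, 1.0), 0.0)[ok.nonzero()]
    w = cov[ok]
    Xs = sm.add_constant(data.covariates(names), has_constant="add")
    X = np.repeat(Xs, m, axis=0)[ok.ravel()]
    subj = np.repeat(np.arange(n), m)[ok.ravel()]
    model = sm.GEE(
        y, X, groups=subj, family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(), weights=w,
    )
    return model.fit()


def estimate_exchangeable_correlation(
    data: MethylationDataset,
    covariates: Sequence[str] | None = None,
) -> float:
    """Exchangeable within-subject correlation from the marginal fit.

    Always runs the estimating-equation machinery (intercept-only when
    no covariates are given) and returns the estimated common
    correlation of a subject's site-level Pearson residuals.
    """
    names = tuple(covariates) if covariates is not None else ()
    fit = _gee_fit(data, names)
    return float(fit.cov_struct.dep_params)


# ---------------------------------------------------------------------------
# site/group aggregation
# ---------------------------------------------------------------------------

def site_group_summaries(
    adj: AdjustedCounts,
    data: MethylationDataset,
) -> SiteGroupSummary:
    """Sum adjusted counts and coverages per site within each group.

    Sites where any group has zero total coverage are excluded (the
    group rate is undefined there) and logged.  For two groups the
    site-wise rate difference ``delta`` is also returned, ordered as
    first-seen group minus second.
    """
    labels = data.group_labels
    G = len(labels)
    r = np.empty((G, data.n_sites))
    C = np.empty((G, data.n_sites))
    g = data.groups
    for k, lab in enumerate(labels):
        rows = g == lab
        r[k] = adj.r[rows].sum(axis=0)
        C[k] = data.coverage[rows].sum(axis=0)
    kept = (C > 0).all(axis=0)
    if not kept.all():
        logger.info(
            "excluding %d site(s) with zero group coverage",
            int((~kept).sum()),
        )
    r, C = r[:, kept], C[:, kept]
    beta = r / C
    delta = beta[0] - beta[1] if G == 2 else None
    return SiteGroupSummary(
        group_labels=labels, r=r, C=C, beta=beta, delta=delta,
        kept=kept, sites=data.sites.loc[kept].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# design-effect (clustered reads) adjustment
# ---------------------------------------------------------------------------

def design_effect(cbar, rho, floor: float = 1.0):
    """Variance-inflation factor ``max(1 + (c̄ − 1)·ρ̂, floor)`` for
    clustered reads with mean cluster size ``c̄`` and intraclass
    correlation ``ρ̂``; equals 1 when ρ̂ = 0 or c̄ = 1."""
    return np.maximum(1.0 + (np.asarray(cbar, dtype=float) - 1.0) * rho,
                      floor)


def anova_icc(meth: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """ANOVA moment intraclass correlation per site, samples as clusters.

    Treats each sample's reads at a site as a cluster of Bernoulli
    outcomes with ``m`` successes out of ``c``.  Returns ρ̂ per site,
    clipped to [0, 1); NaN where fewer than two samples have coverage.
    """
    c = np.asarray(coverage, dtype=float)
    m = np.asarray(meth, dtype=float)
    has = c > 0
    K = has.sum(axis=0)                      # clusters per site
    N = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = m.sum(axis=0) / N
        pi = np.where(has, m / np.maximum(c, 1.0), 0.0)
        msb = np.where(has, c * (pi - p) ** 2, 0.0).sum(axis=0)
        msw = np.where(has, c * pi * (1.0 - pi), 0.0).sum(axis=0)
        out = np.full(m.shape[1], np.nan)
        est = K >= 2
        dfw = N - K
        msb_v = msb / np.maximum(K - 1, 1)
        msw_v = np.where(dfw > 0, msw / np.maximum(dfw, 1), 0.0)
        n0 = (N - (np.where(has, c, 0.0) ** 2).sum(axis=0) / np.maximum(N, 1))
        n0 = n0 / np.maximum(K - 1, 1)
        denom = msb_v + (n0 - 1.0) * msw_v
        rho = np.where(denom > 0, (msb_v - msw_v) / np.where(denom > 0, denom, 1.0), 0.0)
    out[est] = np.clip(rho[est], 0.0, 1.0 - 1e-12)
    return out


def recentred_group_counts(
    adj: AdjustedCounts,
    data: MethylationDataset,
) -> np.ndarray:
    """Per-sample recentred residual counts for the scan statistic.

    The zero-centred residuals cannot feed a binomial likelihood, so the
    grand-mean fitted count is added back per cell:
    ``Rc[i, j] = m[i, j] − (p̂[i, j] − p̄)·c[i, j]`` with ``p̄`` the
    coverage-weighted mean fitted rate.  When no covariates were fitted
    (p̂ constant) this returns the raw methylated counts exactly.
    """
    tot = data.coverage.sum()
    p_bar = (adj.p_hat * data.coverage).sum() / tot if tot > 0 else 0.0
    return data.meth - (adj.p_hat - p_bar) * data.coverage


def design_effect_adjust(
    adj: AdjustedCounts,
    data: MethylationDataset,
    floor: float = 1.0,
) -> DesignEffectCounts:
    """Deflate group counts by the clustered-reads design effect.

    Per site ``j`` and group ``k``: ``deff_kj = 1 + (c̄_kj − 1)·ρ̂_j``
    with ``c̄_kj`` the group's mean coverage at the site and ``ρ̂_j`` the
    intra-site ANOVA intraclass correlation across all samples, floored
    at ``floor`` (default 1).  The recentred group counts are clamped to
    ``[0, C_kj]`` before deflation.  ρ̂ undefined (a single covered
    sample) gives ``deff = 1`` with a warning.
    """
    labels = data.group_labels
    G = len(labels)
    rho = anova_icc(data.meth, data.coverage)
    und = np.isnan(rho)
    if und.any():
        logger.warning(
            "intra-site correlation undefined at %d site(s); deff = 1 there",
            int(und.sum()),
        )
        rho = np.where(und, 0.0, rho)
    Rc = recentred_group_counts(adj, data)
    g = data.groups
    R = np.empty((G, data.n_sites))
    C = np.empty((G, data.n_sites))
    nsamp = np.empty((G, 1))
    for k, lab in enumerate(labels):
        rows = g == lab
        R[k] = Rc[rows].sum(axis=0)
        C[k] = data.coverage[rows].sum(axis=0)
        nsamp[k, 0] = rows.sum()
    kept = (C > 0).all(axis=0)
    if not kept.all():
        logger.info(
            "excluding %d site(s) with zero group coverage",
            int((~kept).sum()),
        )
    R, C, rho = R[:, kept], C[:, kept], rho[kept]
    R = np.clip(R, 0.0, C)
    deff = design_effect(C / nsamp, rho[None, :], floor)
    return DesignEffectCounts(
        group_labels=labels, r_tilde=R / deff, C_tilde=C / deff,
        deff=deff, rho_site=rho, kept=kept,
        sites=data.sites.loc[kept].reset_index(drop=True),
    )
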