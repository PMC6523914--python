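"""Synthetic bisulfite-sequencing methylation data.

The generator reproduces the simulation design used to calibrate both
region tests: per-cell methylation rates with Beta marginals, made
spatially dependent through a Gaussian copula whose correlation between
sites ``i`` and ``j`` is ``ρ / |i − j|`` (adjacent-site correlation ρ,
decaying with distance); coverage drawn as a rounded Normal(30, 13)
clamped at a minimum of 5; methylated counts binomial given coverage
and rate.  Cases carry a block of ``dmr_sites`` consecutive sites in
the middle of the region whose Beta parameters differ from the
background, with effect size
``d = α_A/(α_A+β_A) − α_U/(α_U+β_U)``.

The copula transform is applied exactly in the form
``p = 1 − Φ(C·Φ⁻¹(1 − X))`` with ``X`` the Beta draws and ``C`` the
Cholesky factor of the correlation matrix.  Note this correlates the
*tail-transformed* Beta draws directly, which distorts the Beta
marginals slightly whenever ρ > 0; an optional ``proper_copula`` mode
maps the draws through their Beta CDF first (preserving marginals
exactly) but is off by default because the calibration study is defined
with the direct transform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import MethylationDataset

__all__ = [
    "SimulationConfig",
    "correlation_matrix",
    "simulate_dataset",
    "write_simulated_files",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic methylation study.

    Defaults are the calibration-study conditions: 24 cases and 24
    controls over 24 equally spaced CpG sites, background rates from
    Beta(0.1, 0.9) (mean methylation 10%), a 6-site central DMR,
    adjacent-site copula correlation 0.5, coverage ~ round N(30, 13²)
    clamped at 5.  ``alpha_A = alpha_U`` gives a null dataset (d = 0).
    """

    n_cases: int = 24
    n_controls: int = 24
    n_sites: int = 24
    dmr_sites: int = 6
    alpha_U: float = 0.1
    beta_U: float = 0.9
    alpha_A: float = 0.1
    beta_A: float = 0.9
    rho: float = 0.5
    coverage_mean: float = 30.0
    coverage_sd: float = 13.0
    coverage_min: int = 5
    site_spacing: int = 1  # bp between adjacent sites (1 → bp == index units)
    chromosome: str = "chrS"
    proper_copula: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dmr_sites > self.n_sites:
            raise ValueError("dmr_sites cannot exceed n_sites")
        for name in ("alpha_U", "beta_U", "alpha_A", "beta_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.n_cases < 1 or self.n_controls < 1 or self.n_sites < 1:
            raise ValueError("sample and site counts must be positive")

    @property
    def effect_size(self) -> float:
        """d = mean(Beta_A) − mean(Beta_U)."""
        return (self.alpha_A / (self.alpha_A + self.beta_A)
                - self.alpha_U / (self.alpha_U + self.beta_U))

    @property
    def is_null(self) -> bool:
        return self.alpha_A == self.alpha_U and self.beta_A == self.beta_U

    @property
    def dmr_slice(self) -> slice:
        """Central run of dmr_sites sites; centering ties go low."""
        start = (self.n_sites - self.dmr_sites) // 2
        return slice(start, start + self.dmr_sites)

    def with_seed(self, seed: int | None) -> "SimulationConfig":
        return replace(self, seed=seed)


def correlation_matrix(
    m: int, rho: float, positions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-decaying correlation ``Σ_ij = ρ/|i−j|`` and its Cholesky
    factor.

    ``positions`` defaults to site indices 0..m−1 (equally spaced
    sites).  Raises if Σ is not positive definite for the requested ρ
    (happens for ρ ≳ 0.86 at these sizes) — choose a smaller ρ.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    x = np.arange(m, dtype=float) if positions is None \
        else np.asarray(positions, dtype=float)
    D = np.abs(x[:, None] - x[None, :])
    with np.errstate(divide="ignore"):
        Sigma = np.where(D == 0.0, 1.0, rho / np.where(D == 0.0, 1.0, D))
    try:
        C = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"correlation matrix with rho={rho} over {m} sites is not "
            "positive definite; use a smaller rho"
        ) from exc
    return Sigma, C


def simulate_dataset(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> MethylationDataset:
    """Draw one synthetic dataset; deterministic given the seed/rng."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    m = cfg.n_sites
    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.n_cases] = True

    a = np.full((n, m), cfg.alpha_U)
    b = np.full((n, m), cfg.beta_U)
    if not cfg.is_null:
        a[np.ix_(is_case, range(m)[cfg.dmr_slice])] = cfg.alpha_A
        b[np.ix_(is_case, range(m)[cfg.dmr_slice])] = cfg.beta_A
    X = rng.beta(a, b)
    # guard the exact boundary before the normal quantile transform
    X = np.clip(X, 1e-300, 1.0 - 1e-16)

    if cfg.rho > 0.0 and m > 1:
        _, C = correlation_matrix(m, cfg.rho)
        if cfg.proper_copula:
            u = stats.beta.cdf(X, a, b)
            z = stats.norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))
            zc = z @ C.T
            p = stats.beta.ppf(stats.norm.cdf(zc), a, b)
        else:
            # Φ⁻¹(1−X) computed as the upper-tail quantile to keep
            # precision for X near 0 (Beta(0.1, ·) mass piles up there)
            z = stats.norm.isf(X)
            p = stats.norm.sf(z @ C.T)     # 1 − Φ(C·Φ⁻¹(1−X)) per subject
    else:
        p = X
    p = np.clip(p, 0.0, 1.0)

    cov = np.rint(rng.normal(cfg.coverage_mean, cfg.coverage_sd, size=(n, m)))
    cov = np.maximum(cov, cfg.coverage_min).astype(np.int64)
    meth = rng.binomial(cov, p)

    positions = 1 + cfg.site_spacing * np.arange(m, dtype=np.int64)
    sites = pd.DataFrame(
        {"chromosome": cfg.chromosome, "position": positions}
    )
    samples = pd.DataFrame(
        {"sample_id": [f"case{i+1}" for i in range(cfg.n_cases)]
                      + [f"ctrl{i+1}" for i in range(cfg.n_controls)],
         "group": np.where(is_case, "A", "U")}
    )
    return MethylationDataset(
        sites=sites, samples=samples, meth=meth, coverage=cov,
    )


def write_simulated_files(
    data: MethylationDataset, outdir: str, prefix: str = "sim",
) -> str:
    """Write one bismark-coverage file per sample plus a sample sheet.

    Returns the sample-sheet path; the files round-trip through
    :func:`dmrscan.data.read_coverage_files`.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i in range(data.n_samples):
        sid = data.samples["sample_id"].iloc[i]
        fname = f"{prefix}_{sid}.cov"
        fpath = os.path.join(outdir, fname)
        with open(fpath, "w") as fh:
            for j in range(data.n_sites):
                c = int(data.coverage[i, j])
                mm = int(data.meth[i, j])
                pct = 100.0 * mm / c if c > 0 else 0.0
                pos = int(data.sites["position"].iloc[j])
                chrom = data.sites["chromosome"].iloc[j]
                fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6g}\t{mm}\t{c - mm}\n")
        rows.append({"sample_id": sid, "path": fname,
                     "group": data.samples["group"].iloc[i]})
    sheet_path = os.path.join(outdir, f"{prefix}_samples.tsv")
    pd.DataFrame(rows).to_csv(sheet_path, sep="\t", index=False)
    return sheet_path
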