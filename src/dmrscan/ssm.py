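"""Binomial scan statistic for differentially methylated regions.

Moving windows of variable size slide along the CpG sites; within each
window the group-summed (design-effect-deflated, pseudo-counted)
methylated counts are modelled as binomial and the window statistic is
the log likelihood ratio of separate group rates against a common rate.
The window with the highest statistic defines the candidate DMR, the
maximum over all windows and sizes is the global test statistic, and
inference is by permutation of subject group labels.  Per-window
p-values are referred to the permutation distribution of the global
maximum, which controls the family-wise error across windows.

A pseudo-count of one methylated and one unmethylated read per CpG site
keeps all window proportions strictly inside (0, 1), so the likelihood
ratio is always finite.  The statistic extends to any number of nominal
groups (multinomial form); ordered group responses are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .adjust import (
    AdjustedCounts,
    DesignEffectCounts,
    anova_icc,
    fit_covariate_model,
    mixed_model_adjust,
    recentred_group_counts,
)
from .data import DmrCall, MethylationDataset

__all__ = [
    "WindowSpec",
    "ScanResult",
    "BinomialScanTest",
    "window_lr",
    "multinomial_window_lr",
    "apply_pseudocounts",
    "window_scan",
    "scan",
    "multinomial_scan",
    "call_dmrs",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window sizes (in CpG sites) and the start step of the scan."""

    sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    step: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=int)
        if s.size == 0 or np.any(s <= 0):
            raise ValueError("window sizes must be positive")
        if np.any(np.diff(s) <= 0):
            raise ValueError("window sizes must be strictly increasing")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _binom_ll(r, c, p):
    return r * np.log(p) + (c - r) * np.log1p(-p)


def window_lr(rA: float, CA: float, rU: float, CU: float) -> float:
    """Binomial log likelihood ratio for one window, two groups.

    ``LR = ℓ(p̂_A, p̂_U) − ℓ(p̂)`` with per-group MLEs ``p̂_k = r_k/C_k``
    and the pooled ``p̂ = (r_A+r_U)/(C_A+C_U)``; always ≥ 0, zero iff
    the two proportions coincide.  Inputs may be real-valued (design-
    effect-deflated counts) but must satisfy ``0 < r < C`` per group —
    guaranteed upstream by the pseudo-counts.
    """
    if not (0 < rA < CA and 0 < rU < CU):
        raise ValueError(
            "degenerate window proportions; apply pseudo-counts upstream"
        )
    pA, pU = rA / CA, rU / CU
    p0 = (rA + rU) / (CA + CU)
    return float(
        _binom_ll(rA, CA, pA) + _binom_ll(rU, CU, pU)
        - _binom_ll(rA + rU, CA + CU, p0)
    )


def multinomial_window_lr(r: Sequence[float], C: Sequence[float]) -> float:
    """Window log likelihood ratio for G ≥ 2 nominal groups.

    ``LR = Σ_k [r_k log p̂_k + (C_k − r_k) log(1 − p̂_k)] − ℓ(p̂)`` with
    ``p̂_k = r_k/C_k`` and pooled ``p̂``; reduces exactly to
    :func:`window_lr` for two groups.
    """
    r = np.asarray(r, dtype=float)
    C = np.asarray(C, dtype=float)
    if r.shape != C.shape or r.size < 2:
        raise ValueError("need aligned counts for >= 2 groups")
    if np.any(r <= 0) or np.any(r >= C):
        raise ValueError(
            "degenerate window proportions; apply pseudo-counts upstream"
        )
    p = r / C
    p0 = r.sum() / C.sum()
    return float(_binom_ll(r, C, p).sum() - _binom_ll(r.sum(), C.sum(), p0))


def apply_pseudocounts(dec: DesignEffectCounts) -> DesignEffectCounts:
    """Add one methylated and one unmethylated read per group and site:
    ``r̃ → r̃ + 1`` and ``C̃ → C̃ + 2``."""
    return DesignEffectCounts(
        group_labels=dec.group_labels,
        r_tilde=dec.r_tilde + 1.0,
        C_tilde=dec.C_tilde + 2.0,
        deff=dec.deff,
        rho_site=dec.rho_site,
        kept=dec.kept,
        sites=dec.sites,
    )


@dataclass
class ScanResult:
    """Fitted binomial scan test.

    ``per_window`` holds one row per (size, start offset) with the
    window LR and its FWE-controlling permutation p-value;
    ``global_LR = max LR_w`` and ``global_p`` its permutation p-value;
    ``calls`` are the greedily selected non-overlapping significant
    windows.
    """

    per_window: pd.DataFrame
    global_LR: float
    global_p: float
    n_permutations: int
    alpha: float
    calls: list[DmrCall]
    sites: pd.DataFrame
    group_labels: list
    null_LR: np.ndarray | None = field(default=None, repr=False)

    @property
    def best_window(self) -> pd.Series:
        return self.per_window.loc[self.per_window["LR"].idxmax()]

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        best = self.best_window
        # bracket access: .size/.start are pandas Series attributes
        w0, w = int(best["start"]), int(best["size"])
        rows = [
            ["global LR", f"{self.global_LR:.6g}"],
            ["global p-value", f"{self.global_p:.6g}"],
            ["best window", f"sites {w0}..{w0 + w - 1} (w={w})"],
            ["windows scanned", f"{len(self.per_window)}"],
            ["permutations", f"{self.n_permutations}"],
            [f"DMRs called (alpha={self.alpha:g})", f"{len(self.calls)}"],
        ]
        return str(SimpleTable(rows, title="Binomial Scan Test"))


# ---------------------------------------------------------------------------
# window enumeration and the vectorised engine
# ---------------------------------------------------------------------------

def _windows(m: int, spec: WindowSpec) -> list[tuple[int, np.ndarray]]:
    """Usable (size, start offsets) pairs; oversized windows are skipped."""
    out = []
    for w in spec.sizes:
        if w > m:
            import logging
            logging.getLogger(__name__).warning(
                "window size %d exceeds region length %d; skipped", w, m
            )
            continue
        out.append((int(w), np.arange(0, m - w + 1, spec.step)))
    if not out:
        raise ValueError("no window size fits the region")
    return out


def _window_lr_batch(
    R: np.ndarray, C: np.ndarray, nsamp: np.ndarray,
    rho: np.ndarray, windows, design_effect: bool, deff_floor: float,
) -> np.ndarray:
    """LR for every window, for a batch of group assignments.

    R, C : (G, B, m) group sums of recentred counts and coverage.
    Returns (B, n_windows_total) in the order given by ``windows``.
    """
    R = np.clip(R, 0.0, C)
    if design_effect:
        cbar = C / nsamp[:, None, None]
        deff = np.maximum(1.0 + (cbar - 1.0) * rho[None, None, :], deff_floor)
        r_t, C_t = R / deff, C / deff
    else:
        r_t, C_t = R, C
    # pseudo-count per site, then cumulative sums for sliding windows
    r_t = r_t + 1.0
    C_t = C_t + 2.0
    zeros = np.zeros(r_t.shape[:2] + (1,))
    cr = np.concatenate([zeros, np.cumsum(r_t, axis=2)], axis=2)
    cc = np.concatenate([zeros, np.cumsum(C_t, axis=2)], axis=2)
    pieces = []
    for w, starts in windows:
        rW = cr[:, :, starts + w] - cr[:, :, starts]    # (G, B, S)
        CW = cc[:, :, starts + w] - cc[:, :, starts]
        pk = rW / CW
        r0 = rW.sum(axis=0)
        C0 = CW.sum(axis=0)
        lr = _binom_ll(rW, CW, pk).sum(axis=0) - _binom_ll(r0, C0, r0 / C0)
        pieces.append(lr)
    return np.concatenate(pieces, axis=1)


def _scan_engine(
    data: MethylationDataset,
    adjusted: AdjustedCounts,
    spec: WindowSpec,
    permutations: int,
    rng: np.random.Generator,
    design_effect: bool,
    deff_floor: float,
    alpha: float,
    keep_null: bool,
) -> ScanResult:
    labels = data.group_labels
    G = len(labels)
    g = data.groups
    nsamp = np.array([(g == lab).sum() for lab in labels], dtype=float)
    if np.any(nsamp == 0):
        raise ValueError("cannot permute: a group is empty")

    Rc = recentred_group_counts(adjusted, data)
    cov = data.coverage.astype(float)
    # keep sites where every group has coverage (rates defined)
    onehot = np.stack([(g == lab).astype(float) for lab in labels])  # (G, n)
    C_obs_site = onehot @ cov
    kept = (C_obs_site > 0).all(axis=0)
    Rc, cov = Rc[:, kept], cov[:, kept]
    sites = data.sites.loc[kept].reset_index(drop=True)
    m = Rc.shape[1]

    rho = anova_icc(data.meth[:, kept], data.coverage[:, kept])
    rho = np.where(np.isnan(rho), 0.0, rho)
    windows = _windows(m, spec)

    def group_sums(L):  # L: (G, B, n) -> (G, B, m) sums
        return L @ Rc, L @ cov

    # observed
    L_obs = onehot[:, None, :]
    R, C = group_sums(L_obs)
    lr_obs = _window_lr_batch(
        R, C, nsamp, rho, windows, design_effect, deff_floor
    )[0]
    global_LR = float(lr_obs.max())

    # permutation null of the global maximum
    B = int(permutations)
    if B < 1:
        raise ValueError("need at least one permutation")
    n = data.n_samples
    order = np.argsort(rng.random((B, n)), axis=1)
    g_perm = g[order]                                   # (B, n)
    L = np.stack([(g_perm == lab).astype(float) for lab in labels])
    Rp, Cp = group_sums(L)
    lr_perm = _window_lr_batch(
        Rp, Cp, nsamp, rho, windows, design_effect, deff_floor
    ).max(axis=1)                                        # (B,)

    global_p = (1.0 + np.count_nonzero(lr_perm >= global_LR)) / (B + 1.0)
    exceed = (lr_perm[:, None] >= lr_obs[None, :]).sum(axis=0)
    p_window = (1.0 + exceed) / (B + 1.0)

    rows = []
    pos = sites["position"].to_numpy()
    chrom = sites["chromosome"].to_numpy()
    i = 0
    for w, starts in windows:
        for s in starts:
            rows.append(
                {"start": int(s), "size": w,
                 "chromosome": chrom[s],
                 "start_bp": int(pos[s]), "end_bp": int(pos[s + w - 1]),
                 "LR": float(lr_obs[i]), "p_value": float(p_window[i])}
            )
            i += 1
    per_window = pd.DataFrame(rows)

    result = ScanResult(
        per_window=per_window, global_LR=global_LR,
        global_p=float(global_p), n_permutations=B, alpha=alpha,
        calls=[], sites=sites, group_labels=labels,
        null_LR=lr_perm if keep_null else None,
    )
    result.calls = call_dmrs(result, alpha)
    return result


def window_scan(dec: DesignEffectCounts, spec: WindowSpec) -> pd.DataFrame:
    """Per-window LR from already-aggregated design-effect counts.

    No permutation inference — this is the deterministic core of the
    scan, applied to pseudo-counted group counts.
    """
    pc = apply_pseudocounts(dec)
    G, m = pc.r_tilde.shape
    windows = _windows(m, spec)
    cr = np.concatenate(
        [np.zeros((G, 1)), np.cumsum(pc.r_tilde, axis=1)], axis=1)
    cc = np.concatenate(
        [np.zeros((G, 1)), np.cumsum(pc.C_tilde, axis=1)], axis=1)
    rows = []
    for w, starts in windows:
        for s in starts:
            rW = cr[:, s + w] - cr[:, s]
            CW = cc[:, s + w] - cc[:, s]
            rows.append({"start": int(s), "size": w,
                         "LR": multinomial_window_lr(rW, CW)})
    return pd.DataFrame(rows)


def scan(
    data: MethylationDataset,
    spec: WindowSpec,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    adjusted: AdjustedCounts | None = None,
    covariates: Sequence[str] | None = None,
    adjustment: str = "mixed",
    design_effect: bool = True,
    deff_floor: float = 1.0,
    alpha: float = 0.05,
    keep_null: bool = False,
) -> ScanResult:
    """Two-group binomial scan with permutation inference.

    The adjustment model (simple logistic or marginal exchangeable) is
    fitted once — it excludes the group label, so permuting labels
    leaves it unchanged — and permutations only rebuild the group sums
    and the design-effect deflation.
    """
    if len(data.group_labels) != 2:
        raise ValueError(
            "scan() compares exactly two groups; use multinomial_scan() "
            "for more"
        )
    return multinomial_scan(
        data, spec, permutations=permutations, seed=seed, adjusted=adjusted,
        covariates=covariates, adjustment=adjustment,
        design_effect=design_effect, deff_floor=deff_floor, alpha=alpha,
        keep_null=keep_null,
    )


def multinomial_scan(
    data: MethylationDataset,
    spec: WindowSpec,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    adjusted: AdjustedCounts | None = None,
    covariates: Sequence[str] | None = None,
    adjustment: str = "mixed",
    design_effect: bool = True,
    deff_floor: float = 1.0,
    alpha: float = 0.05,
    ordered: bool = False,
    keep_null: bool = False,
) -> ScanResult:
    """Scan test for G ≥ 2 nominal groups (identical to :func:`scan`
    when G = 2)."""
    if ordered:
        raise NotImplementedError(
            "ordered group responses are not supported: the constrained "
            "maximum likelihood estimates are intractable"
        )
    if adjusted is None:
        if adjustment == "mixed":
            adjusted = mixed_model_adjust(data, covariates)
        elif adjustment == "simple":
            adjusted = fit_covariate_model(data, covariates)
        else:
            raise ValueError("adjustment must be 'simple' or 'mixed'")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return _scan_engine(
        data, adjusted, spec, permutations, rng,
        design_effect, deff_floor, alpha, keep_null,
    )


def call_dmrs(result: ScanResult, alpha: float) -> list[DmrCall]:
    """Greedy non-overlapping DMR selection.

    Repeatedly take the window with the largest LR among windows with
    ``p ≤ alpha`` that do not overlap (in sites) an already selected
    window; return the calls ordered by genomic position.
    """
    sig = result.per_window[result.per_window["p_value"] <= alpha]
    chosen: list[pd.Series] = []
    for _, row in sig.sort_values("LR", ascending=False).iterrows():
        s = int(row["start"])
        e = s + int(row["size"]) - 1
        if any(
            not (e < int(c["start"])
                 or s > int(c["start"]) + int(c["size"]) - 1)
            and c["chromosome"] == row["chromosome"]
            for c in chosen
        ):
            continue
        chosen.append(row)
    chosen.sort(key=lambda r: (str(r["chromosome"]), int(r["start_bp"])))
    return [
        DmrCall(
            chromosome=str(r["chromosome"]), start_bp=int(r["start_bp"]),
            end_bp=int(r["end_bp"]), n_sites=int(r["size"]),
            statistic=float(r["LR"]), p_value=float(r["p_value"]),
            method="SSM",
        )
        for r in chosen
    ]


class BinomialScanTest:
    """Model object for the binomial scan DMR test.

    Parameters
    ----------
    data : MethylationDataset (two or more nominal groups).
    covariates : sample-sheet columns to adjust for.
    window_sizes, step : scan geometry in CpG sites.
    adjustment : ``"mixed"`` (marginal exchangeable fit, default) or
        ``"simple"`` (independence logistic fit).
    design_effect : deflate counts by ``1 + (c̄ − 1)ρ̂`` per site.

    ``fit()`` returns a :class:`ScanResult`.
    """

    def __init__(
        self,
        data: MethylationDataset,
        covariates: Sequence[str] | None = None,
        window_sizes: Sequence[int] = (5, 10, 15, 20, 25, 30),
        step: int = 1,
        adjustment: str = "mixed",
        design_effect: bool = True,
        deff_floor: float = 1.0,
    ) -> None:
        self.data = data
        self.covariates = tuple(covariates) if covariates else ()
        self.spec = WindowSpec(sizes=tuple(int(w) for w in window_sizes),
                               step=step)
        self.design_effect = design_effect
        self.deff_floor = deff_floor
        if adjustment == "mixed":
            self.adjusted = mixed_model_adjust(data, self.covariates)
        elif adjustment == "simple":
            self.adjusted = fit_covariate_model(data, self.covariates)
        else:
            raise ValueError("adjustment must be 'simple' or 'mixed'")

    def fit(
        self,
        permutations: int = 999,
        seed: int | np.random.Generator | None = None,
        alpha: float = 0.05,
        keep_null: bool = False,
    ) -> ScanResult:
        return multinomial_scan(
            self.data, self.spec, permutations=permutations, seed=seed,
            adjusted=self.adjusted, design_effect=self.design_effect,
            deff_floor=self.deff_floor, alpha=alpha, keep_null=keep_null,
        )
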