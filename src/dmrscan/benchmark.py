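"""Type-I-error and power experiments for the two region tests.

Each replicate simulates a fresh dataset, runs the covariate-free
adjustment once (the pooled rate; the simulation design includes no
covariates) and applies both tests with permutation inference.  The
calibration study uses a single kernel bandwidth τ = 6 and a single
moving-window size of 6 CpG sites — the length of the simulated DMR —
with distances in site-index units (the simulated sites are equally
spaced).

Per-replicate random streams are spawned from one ``SeedSequence`` so a
benchmark is reproducible for a given seed and independent of how it is
chunked.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .adjust import fit_covariate_model
from .kdm import KernelSpec, kdm_test
from .simulate import SimulationConfig, simulate_dataset
from .ssm import WindowSpec, scan

__all__ = ["null_pvalues", "benchmark_type1", "benchmark_power"]

_METHODS = ("KDM", "SSM")


def _replicate_pvalues(
    cfg: SimulationConfig,
    n_reps: int,
    methods: Sequence[str],
    permutations: int,
    seed: int | np.random.SeedSequence | None,
    tau: float,
    window_size: int,
) -> dict[str, np.ndarray]:
    for meth in methods:
        if meth not in _METHODS:
            raise ValueError(f"unknown method {meth!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    kspec = KernelSpec(tau_grid=(float(tau),), distance_unit="index")
    wspec = WindowSpec(sizes=(int(window_size),), step=1)
    out = {meth: np.empty(n_reps) for meth in methods}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        data = simulate_dataset(cfg, rng)
        adj = fit_covariate_model(data)  # no covariates: pooled rate
        if "KDM" in methods:
            res = kdm_test(data, kspec, permutations=permutations,
                           seed=rng, adjusted=adj)
            out["KDM"][i] = res.p_value
        if "SSM" in methods:
            res = scan(data, wspec, permutations=permutations, seed=rng,
                       adjusted=adj)
            out["SSM"][i] = res.global_p
    return out


def null_pvalues(
    cfg: SimulationConfig,
    n_reps: int = 1000,
    methods: Sequence[str] = _METHODS,
    permutations: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    tau: float = 6.0,
    window_size: int = 6,
) -> dict[str, np.ndarray]:
    """Per-replicate p-values under the null (refuses non-null configs)."""
    if not cfg.is_null:
        raise ValueError(
            "null_pvalues/benchmark_type1 need a null configuration "
            f"(effect size is {cfg.effect_size:g}); equalise the Beta "
            "parameters"
        )
    return _replicate_pvalues(
        cfg, n_reps, methods, permutations, seed, tau, window_size,
    )


def _rates_table(
    pvals: dict[str, np.ndarray], alpha_levels: Sequence[float],
    colname: str,
) -> pd.DataFrame:
    rows = []
    for meth, p in pvals.items():
        n = p.size
        for a in alpha_levels:
            rate = float(np.mean(p <= a))
            rows.append({
                "method": meth, "alpha": float(a), colname: rate,
                "mc_se": float(np.sqrt(rate * (1.0 - rate) / n)),
                "n_reps": n,
            })
    return pd.DataFrame(rows)


def benchmark_type1(
    cfg: SimulationConfig,
    n_reps: int = 1000,
    alpha_levels: Sequence[float] = (0.05, 0.01),
    methods: Sequence[str] = _METHODS,
    permutations: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    tau: float = 6.0,
    window_size: int = 6,
    return_pvalues: bool = False,
):
    """Empirical type-I error of each test at the given nominal levels.

    Returns a table with columns method, alpha, rejection_rate, mc_se
    (binomial Monte-Carlo standard error) and n_reps; optionally also
    the raw per-replicate p-values.
    """
    pvals = null_pvalues(cfg, n_reps, methods, permutations, seed,
                         tau, window_size)
    table = _rates_table(pvals, alpha_levels, "rejection_rate")
    return (table, pvals) if return_pvalues else table


def benchmark_power(
    base_cfg: SimulationConfig,
    alpha_A_values: Sequence[float],
    n_reps: int = 500,
    alpha: float = 0.05,
    methods: Sequence[str] = _METHODS,
    permutations: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    tau: float = 6.0,
    window_size: int = 6,
) -> pd.DataFrame:
    """Empirical power across case Beta-α values (hence effect sizes).

    Each α_A must exceed the shared background α_U so the effect size
    ``d > 0``; columns: method, alpha_A, effect_size, alpha, power,
    mc_se, n_reps.
    """
    from dataclasses import replace

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    frames = []
    for aA, child in zip(alpha_A_values, ss.spawn(len(list(alpha_A_values)))):
        cfg = replace(base_cfg, alpha_A=float(aA))
        if cfg.effect_size <= 0:
            raise ValueError(
                f"alpha_A={aA} gives non-positive effect size "
                f"{cfg.effect_size:g}; power runs need d > 0"
            )
        pvals = _replicate_pvalues(
            cfg, n_reps, methods, permutations, child, tau, window_size,
        )
        t = _rates_table(pvals, (alpha,), "power")
        t.insert(1, "alpha_A", float(aA))
        t.insert(2, "effect_size", cfg.effect_size)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
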