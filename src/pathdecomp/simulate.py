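"""Seeded multivariate-normal data generation and null calibration batteries.

One master seed drives everything: per-replicate generators are derived
with :class:`numpy.random.SeedSequence` spawning, so a battery is
reproducible as a whole and each replicate is independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from . import config
from .model_core import CorrelationSystem, build_system, correlation_from_data, fit
from .inference import bartlett_independence_test, coefficient_t_test

__all__ = ["SimulationSpec", "sample", "sample_replicates", "null_system", "null_battery"]


@dataclass(frozen=True)
class SimulationSpec:
    """A sampling plan: truth matrix, sample size, seed, replicate count."""

    system: CorrelationSystem
    n: int
    seed: int
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _draw(system: CorrelationSystem, n: int, rng: np.random.Generator) -> pd.DataFrame:
    L = np.linalg.cholesky(system.R)
    Z = rng.standard_normal((n, system.R.shape[0]))
    data = Z @ L.T
    return pd.DataFrame(data, columns=list(system.names_x) + list(system.names_y))

def sample(spec: SimulationSpec) -> pd.DataFrame:
    """Draw one n x (m+p) table from N(0, R_true) via Cholesky.

    Only the first replicate stream is consumed; use
    :func:`sample_replicates` to iterate over all of them.
    """
    return next(sample_replicates(spec))


def sample_replicates(spec: SimulationSpec) -> Iterator[pd.DataFrame]:
    """Yield ``spec.replicates`` independent tables, one per derived stream."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    for ss in streams:
        yield _draw(spec.system, spec.n, np.random.default_rng(ss))


def null_system(
    m: int, p: int, n: int, *, rho: float = config.NULL_WITHIN_BLOCK_RHO
) -> CorrelationSystem:
    """Block-diagonal truth with independent X and Y blocks.

    Within each block the correlation is exchangeable with parameter
    ``rho`` (default from config); across blocks it is exactly zero, so
    every independence test run on data drawn from it operates under its
    null hypothesis.
    """
    def exch(k: int) -> np.ndarray:
        M = np.full((k, k), rho)
        np.fill_diagonal(M, 1.0)
        return M

    R = np.zeros((m + p, m + p))
    R[:m, :m] = exch(m)
    R[m:, m:] = exch(p)
    names_x = [f"x{i}" for i in range(1, m + 1)]
    names_y = [f"y{i}" for i in range(1, p + 1)]
    return build_system(R, n, names_x, names_y)


def null_battery(
    m: int,
    p: int,
    n: int,
    replicates: int,
    seed: int,
    *,
    rho: float = config.NULL_WITHIN_BLOCK_RHO,
    levels: tuple[float, ...] = config.NULL_BATTERY_LEVELS,
) -> pd.DataFrame:
    """Empirical type-I error of the block-independence and coefficient tests.

    For each replicate, draws data from the block-diagonal null, recomputes
    the sample correlation system, fits, and records the p-values of the
    block-independence chi-square test and of the (1, 1) path-coefficient
    t test.  Returns a tidy frame with one row per (test, level) and the
    rejection rate over replicates.
    """
    truth = null_system(m, p, n, rho=rho)
    spec = SimulationSpec(system=truth, n=n, seed=seed, replicates=replicates)
    p_bartlett = np.empty(replicates)
    p_coef = np.empty(replicates)
    for i, table in enumerate(sample_replicates(spec)):
        sys_i = correlation_from_data(table, truth.names_x, truth.names_y)
        fit_i = fit(sys_i)
        p_bartlett[i] = bartlett_independence_test(fit_i).p_value
        p_coef[i] = coefficient_t_test(fit_i, 1, 1).p_value
    rows = []
    for name, pv in (("bartlett_independence", p_bartlett), ("coefficient_t", p_coef)):
        for level in levels:
            rows.append(
                {
                    "test": name,
                    "level": level,
                    "rejection_rate": float(np.mean(pv < level)),
                    "replicates": replicates,
                    "n": n,
                    "m": m,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
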