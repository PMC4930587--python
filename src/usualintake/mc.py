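"""Monte-Carlo reference method for habitual weekly intake quantiles.

This is the simulation procedure (as in the NCI usual-intake workflow) that
the numerical integration method replaces: draw N pairs of person effects
(u, v) from their fitted bivariate normal law, push each through the
habitual weekly intake formula for a fixed covariate pattern, and take
empirical quantiles of the resulting sample. Precision then depends on N;
the convergence table contrasts empirical quantiles at increasing draw
counts with the (simulation-free) numerical values.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .habitual import (
    DEFAULT_QUANTILE_GRID,
    CovariatePattern,
    IntakeDistribution,
    expected_weekly_intake,
    intake_quantile,
)
from .twopart import ModelParams, QuadratureSpec

__all__ = ["MCSpec", "mc_weekly_sample", "mc_quantiles", "convergence_table"]

#: Draw counts used in the convergence study (per covariate pattern).
DEFAULT_DRAW_COUNTS = (1000, 5000, 10000, 50000)

#: Sample-quantile convention: linear interpolation of order statistics.
QUANTILE_METHOD = "linear"  # numpy's default, a.k.a. type 7


@dataclasses.dataclass(frozen=True)
class MCSpec:
    """Monte-Carlo settings: draw count, seed and quantile grid."""

    n_draws: int = 10000
    seed: int = 0
    quantile_grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if not all(0.0 < p < 1.0 for p in self.quantile_grid):
            raise ValueError("quantile grid probabilities must lie in (0, 1)")


def _draw_effects(params: ModelParams, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """N draws of (u, v) ~ N(0, Sigma) via the Cholesky factor of Sigma."""
    sigma = params.sigma_mat
    if not np.all(np.isfinite(sigma)):
        raise ValueError("invalid random-effect covariance")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    # lower Cholesky factor of the 2x2 covariance, valid also at sigma = 0
    c11 = params.sigma_u
    c21 = params.rho * params.sigma_v
    c22 = params.sigma_v * np.sqrt(1.0 - params.rho**2)
    u = c11 * z[:, 0]
    v = c21 * z[:, 0] + c22 * z[:, 1]
    return u, v


def mc_weekly_sample(
    params: ModelParams, pattern: CovariatePattern, spec: MCSpec
) -> np.ndarray:
    """N simulated habitual weekly intakes (grams/week) for one pattern.

    Reproducible: the same seed yields the identical vector.
    """
    params.validate()
    u, v = _draw_effects(params, spec.n_draws, spec.seed)
    return np.asarray(expected_weekly_intake(params, pattern, u, v))


def mc_quantiles(
    params: ModelParams, pattern: CovariatePattern, spec: MCSpec
) -> pd.Series:
    """Empirical quantiles (type-7) of the simulated weekly intake sample."""
    pmin = min(min(spec.quantile_grid), 1.0 - max(spec.quantile_grid))
    if spec.n_draws < 1.0 / pmin:
        warnings.warn(
            f"{spec.n_draws} draws cannot resolve tail probability {pmin:g}",
            stacklevel=2,
        )
    sample = mc_weekly_sample(params, pattern, spec)
    q = np.quantile(sample, spec.quantile_grid, method=QUANTILE_METHOD)
    return pd.Series(q, index=[f"q{p:g}" for p in spec.quantile_grid])


def convergence_table(
    params: ModelParams,
    patterns: Sequence[CovariatePattern],
    draw_counts: Sequence[int] = DEFAULT_DRAW_COUNTS,
    probs: Sequence[float] = DEFAULT_QUANTILE_GRID,
    seed: int = 0,
    quad: QuadratureSpec = QuadratureSpec(n_nodes=41, adaptive=False),
) -> pd.DataFrame:
    """Numerical quantiles next to MC quantiles at increasing draw counts.

    One "numerical" row per pattern (computed once, independent of any MC
    settings) and one row per (pattern, draw count). Patterns use independent
    but reproducible streams seeded as seed + pattern index. The sample-
    quantile convention is recorded in the ``quantile_method`` column.
    """
    rows = []
    for i, pattern in enumerate(patterns):
        label = pattern.label or f"pattern_{i}"
        dist = IntakeDistribution(params, pattern, quad)
        row = {"pattern": label, "method": "numerical", "quantile_method": ""}
        for p in probs:
            row[f"q{p:g}"] = intake_quantile(p, dist)
        rows.append(row)
        for n in draw_counts:
            spec = MCSpec(n_draws=n, seed=seed + i, quantile_grid=tuple(probs))
            q = mc_quantiles(params, pattern, spec)
            row = {
                "pattern": label,
                "method": f"MC{n}",
                "quantile_method": QUANTILE_METHOD,
            }
            row.update(q.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
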