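"""Synthetic two-channel cells for calibrating and benchmarking the metrics.

Three generators are provided:

* :func:`simulate_uniform_cell` — the null design: two independent,
  uniformly distributed channels (score matrices should average to ~0).
* :func:`simulate_two_population_cell` — a mixture of two equal-count pixel
  populations whose means can be pulled apart stepwise; population 1 may be
  positively correlated, uncorrelated or negatively correlated between
  channels, population 2 is always uncorrelated.
* :func:`simulate_condition_cell` / :func:`sweep_conditions` — the
  classifier benchmark: condition-positive and condition-negative cell
  populations mixing a positively correlated off-target component of
  varying slope with an on-target component that is positively (positive
  condition) or negatively (negative condition) correlated, under
  independent multiplicative Gaussian noise.

All randomness flows from explicit integer seeds; a sweep spawns one child
stream per cell so results are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .core import CellPixels
from .errors import InvalidInputError

__all__ = [
    "TwoPopulationConfig",
    "ConditionConfig",
    "simulate_uniform_cell",
    "simulate_two_population_cell",
    "simulate_condition_cell",
    "sweep_conditions",
    "sweep_manifest",
]

Correlation = Literal["positive", "none", "negative"]


def simulate_uniform_cell(
    n_pixels: int, seed: int | np.random.Generator, high: float = 1e4
) -> CellPixels:
    """Two independent channels of uniform intensities on [0, high)."""
    if n_pixels < 2:
        raise InvalidInputError("n_pixels must be >= 2")
    rng = np.random.default_rng(seed)
    return CellPixels(
        rng.uniform(0.0, high, n_pixels),
        rng.uniform(0.0, high, n_pixels),
        cell_id=f"uniform-{n_pixels}",
    )


def _correlated_pair(
    rng: np.random.Generator, n: int, span: float, correlation: Correlation
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform deviate pairs on [0, span) with the requested sign of
    correlation: shared deviate (+1), independent (0), or complementary
    ``(u, span - u)`` (-1)."""
    u = rng.uniform(0.0, span, n)
    if correlation == "positive":
        return u, u.copy()
    if correlation == "negative":
        return u, span - u
    if correlation == "none":
        return u, rng.uniform(0.0, span, n)
    raise InvalidInputError(f"unknown correlation {correlation!r}")


@dataclass(frozen=True)
class TwoPopulationConfig:
    """Mixed-pattern design: two equal-count populations, one mean shifted
    stepwise from ``mean_start`` down to ``mean_end``."""

    n_per_population: int = 300
    noise_span: float = 1e4
    pop1_correlation: Correlation = "none"
    mean_start: float = 6.5e4
    mean_end: float = 2.5e4
    n_increments: int = 40
    shifted_population: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_end >= self.mean_start:
            raise InvalidInputError("mean_end must be below mean_start")
        if self.n_increments < 1:
            raise InvalidInputError("n_increments must be >= 1")
        if self.shifted_population not in (1, 2):
            raise InvalidInputError("shifted_population must be 1 or 2")

    def shift_distance(self, increment: int) -> float:
        """Signed distance between population means at ``increment`` steps,
        positive when population 1 has the lower mean."""
        step = (self.mean_start - self.mean_end) / self.n_increments
        d = increment * step
        return -d if self.shifted_population == 2 else d


def simulate_two_population_cell(
    config: TwoPopulationConfig,
    increment: int,
    rng: np.random.Generator | None = None,
) -> CellPixels:
    """One cell of the two-population design at a given shift increment.

    ``increment`` counts steps (0 .. n_increments) the shifted population's
    mean has moved down from ``mean_start`` toward ``mean_end``.
    """
    if not (0 <= increment <= config.n_increments):
        raise InvalidInputError(
            f"increment must be in 0..{config.n_increments}, got {increment}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    step = (config.mean_start - config.mean_end) / config.n_increments
    mean1 = mean2 = config.mean_start
    if config.shifted_population == 1:
        mean1 -= increment * step
    else:
        mean2 -= increment * step

    n = config.n_per_population
    p1a, p1b = _correlated_pair(rng, n, config.noise_span, config.pop1_correlation)
    p2a, p2b = _correlated_pair(rng, n, config.noise_span, "none")
    s1 = np.concatenate([mean1 + p1a, mean2 + p2a])
    s2 = np.concatenate([mean1 + p1b, mean2 + p2b])
    return CellPixels(
        s1, s2, cell_id=f"twopop-{config.pop1_correlation}-inc{increment}"
    )


@dataclass(frozen=True)
class ConditionConfig:
    """Classifier-benchmark cell: half off-target pixels along a line of
    slope ``theta = exp(q)``, half on-target pixels correlated positively
    (condition positive) or negatively (condition negative); every value is
    multiplied by an independent Gaussian(1.0, ``noise_sigma``) factor."""

    condition: Literal["positive", "negative"] = "positive"
    q: float = 0.0
    n_pixels: int = 600
    off_mean: float = 20000.0
    on_mean: float = 30000.0
    base_halfwidth: float = 10000.0
    noise_sigma: float = 0.2
    #: pivot the off-target line about (off_mean, off_mean) instead of the
    #: origin, keeping both channel means at off_mean for every slope
    recenter_off_target: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 2 or self.n_pixels % 2:
            raise InvalidInputError("n_pixels must be an even count >= 2")
        if self.condition not in ("positive", "negative"):
            raise InvalidInputError("condition must be 'positive' or 'negative'")

    @property
    def theta(self) -> float:
        return float(np.exp(self.q))


def simulate_condition_cell(
    config: ConditionConfig, rng: np.random.Generator | None = None
) -> CellPixels:
    """One condition-positive or condition-negative cell.

    Off-target: base ``b`` uniform on ``off_mean ± base_halfwidth``, channel
    pair ``(b, theta*b)``.  On-target positive: a shared base around
    ``on_mean`` in both channels; on-target negative: complementary pair
    ``(b, 2*on_mean - b)``.  Multiplicative noise is applied per channel and
    pixel; negative results are clamped at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    half = config.n_pixels // 2
    hw = config.base_halfwidth

    b_off = rng.uniform(config.off_mean - hw, config.off_mean + hw, half)
    if config.recenter_off_target:
        off2 = config.theta * (b_off - config.off_mean) + config.off_mean
    else:
        off2 = config.theta * b_off
    off1 = b_off

    b_on = rng.uniform(config.on_mean - hw, config.on_mean + hw, half)
    if config.condition == "positive":
        on1, on2 = b_on, b_on.copy()
    else:
        on1, on2 = b_on, 2.0 * config.on_mean - b_on

    s1 = np.concatenate([off1, on1])
    s2 = np.concatenate([off2, on2])
    if config.noise_sigma > 0:
        s1 = s1 * rng.normal(1.0, config.noise_sigma, s1.size)
        s2 = s2 * rng.normal(1.0, config.noise_sigma, s2.size)
    s1 = np.clip(s1, 0.0, None)
    s2 = np.clip(s2, 0.0, None)
    return CellPixels(
        s1, s2, cell_id=f"{config.condition}-q{config.q:+.4f}"
    )


def sweep_manifest(
    n_slopes: int = 141, cells_per_slope: int = 50
) -> dict:
    """Bookkeeping for a condition sweep: the q grid and cell counts."""
    if n_slopes < 1 or cells_per_slope < 1:
        raise InvalidInputError("counts must be >= 1")
    q_values = np.linspace(-0.7, 0.7, n_slopes)
    return {
        "q_values": q_values.tolist(),
        "n_slopes": n_slopes,
        "cells_per_slope": cells_per_slope,
        "cells_per_condition": n_slopes * cells_per_slope,
        "conditions": ["positive", "negative"],
    }


def sweep_conditions(
    n_slopes: int = 141,
    cells_per_slope: int = 50,
    seed: int = 0,
    **config_kwargs,
) -> dict[str, list[CellPixels]]:
    """Full two-condition sweep over equally spaced slopes.

    Returns ``{"positive": [...], "negative": [...]}`` with
    ``n_slopes * cells_per_slope`` cells per condition.  One child random
    stream is spawned per cell from the global seed.
    """
    manifest = sweep_manifest(n_slopes, cells_per_slope)
    q_values = manifest["q_values"]
    n_cells = manifest["cells_per_condition"]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_cells)
    out: dict[str, list[CellPixels]] = {}
    idx = 0
    for condition in ("positive", "negative"):
        cells = []
        for q in q_values:
            for _ in range(cells_per_slope):
                cfg = ConditionConfig(condition=condition, q=q, **config_kwargs)
                rng = np.random.default_rng(children[idx])
                cells.append(simulate_condition_cell(cfg, rng))
                idx += 1
        out[condition] = cells
    return out
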