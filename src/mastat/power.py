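"""Simulation-based power analysis for two-group Poisson rate comparisons.

An MA experiment harvests few mutations, so a non-significant rate
comparison needs a power analysis before it supports a negative
conclusion.  The procedure: for each hypothetical multiplicative
effect size f, draw replicate experiments

    x1 ~ Poisson(mu * g1),    x2 ~ Poisson(mu * (1 + f) * g2),

apply the exact conditional binomial test of x2 out of x1 + x2
against p0 = g2/(g1 + g2) at level alpha (one-sided toward an
increase by default — the alternative of interest is mutagenicity),
and report the rejection fraction.  Setting ``fixed_control`` holds
x1 at the observed control count instead of redrawing it, answering
"what could this experiment, as realised, detect".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PowerConfig",
    "PowerCurve",
    "simulate_once",
    "power_curve",
    "minimum_detectable_effect",
]


def _default_grid() -> tuple[float, ...]:
    # multiplicative increases 0%..300% in 10% steps
    return tuple(round(0.1 * i, 10) for i in range(31))


@dataclass(frozen=True)
class PowerConfig:
    """Parameters of the Monte-Carlo power analysis.

    Defaults are the study conditions of a paired MA experiment:
    control rate 3.58e-11 per site per division, exposures
    g1 = 5.02822e11 and g2 = 5.37022e11 site-division-lines, 1,000
    replicates per effect size, alpha = 0.05 one-sided.
    """

    mu_control: float = 3.58e-11
    g1: float = 5.02822e11
    g2: float = 5.37022e11
    effect_grid: tuple[float, ...] = field(default_factory=_default_grid)
    reps: int = 1000
    alpha: float = 0.05
    sided: str = "one"  # "one" (toward increase) or "two"
    fixed_control: Optional[int] = None  # condition on an observed x1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(e < 0 for e in self.effect_grid):
            raise ValueError("effect sizes must be >= 0")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if self.g1 <= 0 or self.g2 <= 0 or self.mu_control < 0:
            raise ValueError("exposures must be positive, mu non-negative")


@dataclass(frozen=True)
class PowerCurve:
    """Estimated rejection probability vs multiplicative effect size."""

    effects: tuple[float, ...]
    power: tuple[float, ...]
    mc_se: tuple[float, ...]  # binomial MC standard errors sqrt(p(1-p)/reps)
    reps: int
    alpha: float
    sided: str

    def to_rows(self) -> list[dict]:
        return [
            {"effect": e, "power": p, "mc_se": se}
            for e, p, se in zip(self.effects, self.power, self.mc_se)
        ]


def _p_values(x2: np.ndarray, n: np.ndarray, p0: float, sided: str) -> np.ndarray:
    """Exact conditional binomial p-values, vectorised over replicates."""
    if sided == "one":
        # P(X >= x2) under Binomial(n, p0)
        return stats.binom.sf(x2 - 1, np.maximum(n, 1), p0)
    return np.array([
        stats.binomtest(int(x), int(nn), p0).pvalue if nn > 0 else 1.0
        for x, nn in zip(x2, n)
    ])


def _rejections(cfg: PowerConfig, effect: float, rng: np.random.Generator
                ) -> np.ndarray:
    if cfg.fixed_control is not None:
        x1 = np.full(cfg.reps, cfg.fixed_control, dtype=np.int64)
    else:
        x1 = rng.poisson(cfg.mu_control * cfg.g1, cfg.reps)
    x2 = rng.poisson(cfg.mu_control * (1 + effect) * cfg.g2, cfg.reps)
    n = x1 + x2
    p0 = cfg.g2 / (cfg.g1 + cfg.g2)
    pvals = _p_values(x2, n, p0, cfg.sided)
    return (pvals <= cfg.alpha) & (n > 0)  # an empty experiment never rejects


def simulate_once(cfg: PowerConfig, effect: float,
                  rng: Optional[np.random.Generator] = None) -> bool:
    """One replicate: does the rate-comparison test reject at this effect?

    Deterministic for a given (cfg, effect) when ``rng`` is omitted
    (a fresh generator is built from cfg.seed).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    one = replace(cfg, reps=1)
    return bool(_rejections(one, effect, rng)[0])


def power_curve(cfg: PowerConfig) -> PowerCurve:
    """Rejection fraction at every grid effect, with MC standard errors.

    Each effect size gets an independent child stream of cfg.seed, so
    the curve is reproducible and insensitive to grid order.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.effect_grid))
    power, mc_se = [], []
    for effect, ss in zip(cfg.effect_grid, streams):
        rej = _rejections(cfg, effect, np.random.default_rng(ss))
        p = rej.mean()
        power.append(float(p))
        mc_se.append(float(math.sqrt(p * (1 - p) / cfg.reps)))
    return PowerCurve(
        effects=tuple(cfg.effect_grid), power=tuple(power), mc_se=tuple(mc_se),
        reps=cfg.reps, alpha=cfg.alpha, sided=cfg.sided,
    )


def minimum_detectable_effect(
    cfg: PowerConfig, target_power: float,
    curve: Optional[PowerCurve] = None,
) -> Optional[float]:
    """Smallest grid effect whose estimated power reaches the target.

    Returns ``None`` when no grid point reaches the target (the grid
    is too short or the design underpowered).
    """
    if not 0 <= target_power < 1:
        raise ValueError("target_power must be in [0, 1)")
    if curve is None:
        curve = power_curve(cfg)
    for effect, p in sorted(zip(curve.effects, curve.power)):
        if p >= target_power:
            return effect
    return None
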