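"""Simulation-based power for the mixed-ANOVA design effects.

The original sample size (16 per condition) was chosen for .95 power to
detect the Condition x Trial Type interaction at alpha = 0.05, based on the
effect size of the predecessor length experiment — an effect size that is
not published.  This module therefore takes effect specifications as input
(coefficient deltas for the generator) and reports Monte-Carlo power with
its binomial standard error, rather than claiming to reproduce any
particular figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classical import mixed_anova
from .simulate import GeneratorConfig, simulate_experiment

__all__ = ["PowerRequest", "PowerResult", "estimate_power", "power_curve"]


@dataclass
class PowerRequest:
    """One power computation: generating config, tested effect, alpha."""

    config: GeneratorConfig
    effect: str = "Condition × Trial Type"
    conditions: tuple[str, ...] = ("congruent", "incongruent")
    alpha: float = 0.05
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100 for a usable MC-SE")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n_sims: int
    n_rejections: int
    effect: str
    alpha: float
    n_per_cell: int


def estimate_power(request: PowerRequest) -> PowerResult:
    """Fraction of simulated datasets on which the named mixed-ANOVA effect
    rejects at alpha, with binomial Monte-Carlo standard error."""
    root = np.random.SeedSequence(entropy=request.seed, spawn_key=(7,))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(request.n_sims)]
    rejections = 0
    checked = False
    for sim_seed in seeds:
        config = replace(request.config, seed=sim_seed)
        trials = simulate_experiment(config, conditions=request.conditions)
        fit = mixed_anova(trials)
        if not checked:
            if request.effect not in fit.table.index:
                raise ValueError(
                    f"effect {request.effect!r} not in the design; available: "
                    f"{[e for e in fit.table.index if not e.startswith('Error')]}"
                )
            checked = True
        p = fit.table.loc[request.effect, "p"]
        if p < request.alpha:
            rejections += 1
    power = rejections / request.n_sims
    mc_se = math.sqrt(power * (1 - power) / request.n_sims)
    return PowerResult(power=power, mc_se=mc_se, n_sims=request.n_sims,
                       n_rejections=rejections, effect=request.effect,
                       alpha=request.alpha, n_per_cell=request.config.n_per_cell)


def power_curve(
    base: PowerRequest,
    n_per_cell_grid: Sequence[int],
    effect_scales: Sequence[float] = (1.0,),
    interaction_terms: Sequence[str] = (
        "(Cong—Shape) × (2-Change − 1-Change)",
        "(Incong—Shape) × (2-Change − 1-Change)",
    ),
) -> pd.DataFrame:
    """Power over a grid of sample sizes and interaction-effect scalings.

    ``effect_scales`` multiplies the listed interaction coefficients of the
    generating beta; 0 gives the type-I calibration row.
    """
    rows = []
    for scale in effect_scales:
        beta = dict(base.config.beta)
        for term in interaction_terms:
            if term in beta:
                beta[term] = beta[term] * scale
        for n in n_per_cell_grid:
            config = replace(base.config, beta=beta, n_per_cell=n)
            res = estimate_power(replace(base, config=config))
            rows.append(dict(n_per_cell=n, effect_scale=scale, power=res.power,
                             mc_se=res.mc_se, n_sims=res.n_sims))
    return pd.DataFrame(rows)
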