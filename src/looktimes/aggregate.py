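"""Cross-experiment aggregate model: brightness plus number/duration-length.

Combines the brightness experiment (congruent / incongruent / shape-change)
with the earlier number/duration-length experiment (congruent / incongruent
only) and fits the censored log-normal hierarchical regression over the
21-term nested contrast scheme.  The shape-change control exists only in
the brightness experiment, so condition structure is coded on the five
condition x experiment cells directly: a shape-vs-magnitude contrast plus
congruent-incongruent, brightness-length and their product defined on the
four magnitude cells (zero on shape-change rows).  Subject intercept
variance is shared across experiments (a single hyperparameter).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .bayes import ModelSpec, PosteriorFit, PriorSpec, sample_posterior
from .design import EXPERIMENT_CONDITIONS, build_contrast_scheme

__all__ = ["validate_aggregate", "fit_aggregate", "derived_contrast",
           "incongruent_dimension_weights"]


def validate_aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the combined dataset spans both experiments with the right
    condition sets (the length experiment has no shape-change control)."""
    present = set(trials["experiment"])
    missing = {"brightness", "length"} - present
    if missing:
        raise ValueError(f"aggregate fit requires both experiments; missing {missing}")
    for exp, grp in trials.groupby("experiment"):
        extra = set(grp["condition"]) - set(EXPERIMENT_CONDITIONS[exp])
        if extra:
            raise ValueError(f"experiment {exp!r} contains invalid conditions {extra}")
    return trials


def fit_aggregate(
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    *,
    censoring: str = "latent",
    n_chains: int = 4,
    n_draws: int = 1000,
    n_warmup: int = 500,
    seed: int = 0,
    **kwargs,
) -> PosteriorFit:
    """Censored log-normal fit over the 21-term aggregate scheme."""
    validate_aggregate(trials)
    spec = ModelSpec(
        likelihood="lognormal",
        censoring=censoring,
        priors=priors,
        scheme=build_contrast_scheme("aggregate"),
    )
    return sample_posterior(spec, trials, n_chains=n_chains, n_draws=n_draws,
                            n_warmup=n_warmup, seed=seed, **kwargs)


def derived_contrast(fit: PosteriorFit, weights: Mapping[tuple, float]) -> dict:
    """Posterior of a weighted combination of implied cell means (log scale).

    ``weights`` maps design cells — (experiment, condition, first_test,
    trial_type) tuples, matching ``fit.cells`` — to real weights.  Returns
    the per-draw values with median and 95% equal-tailed interval.
    """
    from .bayes import _cell_rows

    cell_index = {cell: i for i, cell in enumerate(fit.cells)}
    unknown = [c for c in weights if c not in cell_index]
    if unknown:
        raise ValueError(f"unknown design cell(s): {unknown}")
    rows = _cell_rows(fit)
    beta = fit.flat("beta")
    eta = beta @ rows.T
    vec = np.zeros(len(fit.cells))
    for cell, wt in weights.items():
        vec[cell_index[cell]] += wt
    combo = eta @ vec
    lo, hi = np.quantile(combo, [0.025, 0.975])
    return {"draws": combo, "median": float(np.median(combo)),
            "lower_95": float(lo), "upper_95": float(hi)}


def incongruent_dimension_weights() -> dict[tuple, float]:
    """Weights for the incongruent-condition difference across dimensions
    (brightness minus length), averaging over trial type and trial order."""
    weights: dict[tuple, float] = {}
    for ft in ("one_change_first", "two_change_first"):
        for tt in ("one_change", "two_change"):
            weights[("brightness", "incongruent", ft, tt)] = 0.25
            weights[("length", "incongruent", ft, tt)] = -0.25
    return weights
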