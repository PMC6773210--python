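"""Synthetic trial-table generator with the study's design and censoring.

The generator emulates the statistical structure the analysis assumes:

* log-normally distributed looking times — for each subject an intercept
  ``u ~ Normal(0, sigma_subject)`` on the log-seconds scale, and for each
  trial ``log T = x·beta + u + Normal(0, sigma_obs)``;
* exact counterbalancing of first-test order and familiarization group
  (6 vs 18 syllables) within condition;
* a two-coder measurement model: each trial is timed by two coders with
  independent Normal measurement error, and a third coder is consulted when
  the first two disagree by more than 5 s, the recorded value being the
  average of the two closest readings;
* right-censoring at the 60-s maximum trial length, applied after coder
  averaging (online coding is the censoring authority in the procedure);
* familiarization looking generated as 60 s times a Beta-distributed
  attentiveness fraction correlated with the subject intercept.

Default parameters are the study's conditions: the coefficient vector is the
fitted log-scale coefficient set of the brightness experiment, the variance
components are back-derived from its reported standard errors and pseudo-R²
values, and the coder SD is set so that the third coder is needed on ~34% of
trials (the observed rate).  See ``docs/methods.md`` for the derivations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    CENSOR_LIMIT_S,
    EXPERIMENT_CONDITIONS,
    FIRST_TESTS,
    FAMILIARIZATION_GROUPS,
    ContrastScheme,
    build_contrast_scheme,
    cell_code_row,
    validate_trial_table,
)

__all__ = [
    "DEFAULT_SINGLE_BETA",
    "DEFAULT_AGGREGATE_BETA",
    "GeneratorConfig",
    "StimulusSpec",
    "simulate_experiment",
    "simulate_aggregate",
    "apply_coder_model",
    "stimulus_schedule",
]

#: Log-scale coefficients of the brightness experiment (its fitted
#: log-transformed-LT model), used as the generating truth by default.
DEFAULT_SINGLE_BETA: dict[str, float] = {
    "(Intercept)": 3.37,
    "Familiarization Time": 0.07,
    "Congruent—Shape Change": -0.44,
    "Incongruent—Shape Change": -0.21,
    "2-Change − 1-Change": 0.33,
    "2-Change First − 1-Change First": 0.10,
    "(Cong—Shape) × (2-Change − 1-Change)": 0.61,
    "(Incong—Shape) × (2-Change − 1-Change)": 0.28,
    "(Cong—Shape) × (2-Change First − 1-Change First)": -0.71,
    "(Incong—Shape) × (2-Change First − 1-Change First)": -0.39,
    "(2-Change − 1-Change) × (2-Change First − 1-Change First)": 0.18,
    "(Cong—Shape) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": -0.25,
    "(Incong—Shape) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": 0.63,
}

#: Log-scale coefficients for the 21-term aggregate (brightness + length)
#: model, the published posterior medians of the aggregate fit.
DEFAULT_AGGREGATE_BETA: dict[str, float] = {
    "(Intercept)": 3.3360451,
    "Familiarization Time": 0.0271806,
    "Congruent—Incongruent": 0.0794864,
    "Brightness—Length": 0.2863105,
    "(Congruent-Incongruent) × (Brightness-Length)": -2.2519872,
    "Shape Change—Magnitude": 0.6874970,
    "2-Change − 1-Change": 0.4804811,
    "2-Change First − 1-Change First": -0.1797578,
    "(Congruent—Incongruent) × (2-Change − 1-Change)": 1.0985407,
    "(Brightness—Length) × (2-Change − 1-Change)": -0.2820748,
    "(Cong-Incong × Bright-Length) × (2-Change − 1-Change)": -1.1926824,
    "(Shape Change—Magnitude) × (2-Change − 1-Change)": -1.0276952,
    "(Congruent—Incongruent) × (2-Change First − 1-Change First)": 0.9148912,
    "(Brightness—Length) × (2-Change First − 1-Change First)": 0.7597305,
    "(Cong-Incong × Bright-Length) × (2-Change First − 1-Change First)": -0.2590027,
    "(Shape Change—Magnitude) × (2-Change First − 1-Change First)": -0.6943224,
    "(2-Change − 1-Change) × (2-Change First − 1-Change First)": -0.1838091,
    "(Cong—Incong) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": -0.7659517,
    "(Brightness—Length) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": -0.6228855,
    "(Cong-Incong × Bright-Length) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": 2.4559398,
    "(Shape Change—Magnitude) × (2-Change − 1-Change) × (2-Change First − 1-Change First)": 0.1466036,
}


@dataclass
class GeneratorConfig:
    """True parameter vector and nuisance structure for the generator.

    ``beta`` maps contrast-scheme term names to log-seconds coefficients;
    terms not listed are zero.  ``n_per_cell`` is the number of subjects per
    condition x first-test-order cell (the study used 8, i.e. 16 per
    condition); it must be even so the familiarization group can be
    counterbalanced exactly.
    """

    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SINGLE_BETA))
    sigma_subject: float = 0.32
    sigma_obs: float = 0.49
    censor_limit_s: float = CENSOR_LIMIT_S
    n_per_cell: int = 8
    coder_sd_s: float = 3.7
    coder_threshold_s: float = 5.0
    familiarization_duration_s: float = 60.0
    fam_beta_a: float = 3.0
    fam_beta_b: float = 2.0
    fam_attention_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_obs, self.coder_sd_s) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1 < self.fam_attention_corr < 1:
            raise ValueError("fam_attention_corr must be in (-1, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = dict(self.beta)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class StimulusSpec:
    """Auditory/visual stimulus metadata for one familiarization schedule."""

    n_syllables: int
    sequence_duration_s: float
    inter_sequence_silence_s: float
    luminance_cd_m2: float

    def __post_init__(self) -> None:
        if self.n_syllables not in (6, 18):
            raise ValueError("n_syllables must be 6 or 18")
        expected = self.n_syllables * (1.4 / 6)
        if not math.isclose(self.sequence_duration_s, expected, rel_tol=1e-9):
            raise ValueError("sequence_duration_s inconsistent with syllable count")
        if not 2.0 <= self.inter_sequence_silence_s <= 3.0:
            raise ValueError("inter-sequence silence must lie in [2, 3] s")
        if self.luminance_cd_m2 not in (6.0, 46.0, 31.0):
            raise ValueError("luminance must be one of 6, 46, 31 cd/m^2")


def stimulus_schedule(
    n_syllables: int,
    rng: np.random.Generator | None = None,
    luminance_cd_m2: float = 6.0,
) -> StimulusSpec:
    """Stimulus metadata: per-syllable timing is constant, so the 18-syllable
    sequence lasts three times the 1.4-s six-syllable sequence; the silence
    between sequences is uniform on [2, 3] s."""
    if n_syllables not in (6, 18):
        raise ValueError(f"n_syllables must be 6 or 18, got {n_syllables}")
    rng = np.random.default_rng() if rng is None else rng
    return StimulusSpec(
        n_syllables=n_syllables,
        sequence_duration_s=n_syllables * (1.4 / 6),
        inter_sequence_silence_s=float(rng.uniform(2.0, 3.0)),
        luminance_cd_m2=luminance_cd_m2,
    )


def apply_coder_model(
    true_looking_s: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    return_detail: bool = False,
):
    """Recorded looking time under the two-(or three-)coder rule.

    Two coders read ``true ± Normal(0, coder_sd)``; if they disagree by more
    than the threshold a third reading is drawn and the two closest readings
    are averaged.  The result is clamped into ``(0, censor_limit_s]``
    afterwards (the ceiling is enforced by the trial procedure itself).
    """
    if true_looking_s <= 0:
        raise ValueError("true looking time must be positive")
    sd = config.coder_sd_s
    readings = true_looking_s + sd * rng.standard_normal(2)
    third = False
    if abs(readings[0] - readings[1]) > config.coder_threshold_s:
        third = True
        readings = np.append(readings, true_looking_s + sd * rng.standard_normal())
        # average of the closest pair among the three
        pairs = [(0, 1), (0, 2), (1, 2)]
        i, j = min(pairs, key=lambda p: abs(readings[p[0]] - readings[p[1]]))
        recorded = 0.5 * (readings[i] + readings[j])
    else:
        recorded = 0.5 * (readings[0] + readings[1])
    recorded = float(min(max(recorded, 0.01), config.censor_limit_s))
    if return_detail:
        return recorded, third
    return recorded


def _fam_moments(config: GeneratorConfig) -> tuple[float, float]:
    a, b = config.fam_beta_a, config.fam_beta_b
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    d = config.familiarization_duration_s
    return d * mean, d * math.sqrt(var)


def _subject_rng(seed: int, cell_index: int, slot: int) -> np.random.Generator:
    # per-subject substream keyed by (cell, slot): adding subjects or cells
    # never perturbs the draws of existing ones
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell_index, slot))
    return np.random.default_rng(ss)


def simulate_experiment(
    config: GeneratorConfig,
    scheme: ContrastScheme | None = None,
    experiment: str = "brightness",
    conditions: Sequence[str] | None = None,
    _cell_offset: int = 0,
    _id_prefix: str = "",
) -> pd.DataFrame:
    """Generate a validated trial table for one experiment.

    Subjects are laid out in condition x first-test cells of ``n_per_cell``
    subjects each, familiarization group alternating exactly within cell.
    """
    if scheme is None:
        scheme = build_contrast_scheme("single_experiment")
    if conditions is None:
        conditions = EXPERIMENT_CONDITIONS[experiment]
    if config.n_per_cell % 2 != 0:
        raise ValueError(
            "n_per_cell must be even for exact familiarization-group counterbalancing"
        )
    beta = np.array([config.beta.get(name, 0.0) for name in scheme.term_names])
    fam_mean, fam_sd = _fam_moments(config)
    rho = config.fam_attention_corr
    beta_cov = sum(beta[j] for j, t in enumerate(scheme.terms) if t.kind == "covariate")

    # fixed-effect dot product per design cell (covariate handled separately)
    cell_dot: dict[tuple[str, str], float] = {}
    for condition in conditions:
        for trial_type in ("one_change", "two_change"):
            for first_test in FIRST_TESTS:
                row = cell_code_row(scheme, condition=condition,
                                    trial_type=trial_type, first_test=first_test,
                                    experiment=experiment, covariate=0.0)
                cell_dot[(condition, trial_type, first_test)] = float(row @ beta)

    # subject layout and per-subject substreams; the Gaussian pair driving
    # the intercept and attentiveness is drawn per subject first so the Beta
    # quantile transform can be vectorized across subjects
    subjects = []
    for ci, condition in enumerate(conditions):
        for fi, first_test in enumerate(FIRST_TESTS):
            cell_index = _cell_offset + ci * len(FIRST_TESTS) + fi
            for slot in range(config.n_per_cell):
                rng = _subject_rng(config.seed, cell_index, slot)
                g1 = rng.standard_normal()
                g2 = rng.standard_normal()
                subjects.append(
                    (condition, first_test, cell_index, slot, rng, g1, g2)
                )
    g1s = np.array([s[5] for s in subjects])
    g2s = np.array([s[6] for s in subjects])
    z_att = rho * g1s + math.sqrt(1.0 - rho**2) * g2s
    fracs = stats.beta.ppf(stats.norm.cdf(z_att), config.fam_beta_a, config.fam_beta_b)
    fam_times = np.clip(fracs * config.familiarization_duration_s, 0.01,
                        config.familiarization_duration_s)

    rows: list[dict] = []
    for k, (condition, first_test, cell_index, slot, rng, g1, _g2) in enumerate(subjects):
        fam_group = FAMILIARIZATION_GROUPS[slot % 2]
        subject_id = f"{_id_prefix}s{cell_index:02d}_{slot:03d}"
        u = config.sigma_subject * g1
        fam_time = float(fam_times[k])
        fam_z = (fam_time - fam_mean) / fam_sd
        order = (
            ("one_change", "two_change")
            if first_test == "one_change_first"
            else ("two_change", "one_change")
        )
        for trial_index, trial_type in enumerate(order, start=1):
            mean_log = (cell_dot[(condition, trial_type, first_test)]
                        + beta_cov * fam_z + u)
            latent_log = mean_log + config.sigma_obs * rng.standard_normal()
            true_t = math.exp(latent_log)
            observed = min(true_t, config.censor_limit_s)
            if config.coder_sd_s > 0:
                recorded = apply_coder_model(observed, config, rng)
            else:
                recorded = min(observed, config.censor_limit_s)
            censored = bool(recorded >= config.censor_limit_s)
            rows.append(
                dict(
                    subject_id=subject_id,
                    experiment=experiment,
                    condition=condition,
                    familiarization_group=fam_group,
                    first_test=first_test,
                    trial_type=trial_type,
                    trial_index=trial_index,
                    familiarization_looking_s=fam_time,
                    looking_s=recorded,
                    censored=censored,
                )
            )
    frame = pd.DataFrame(rows)
    if math.isfinite(config.censor_limit_s):
        return validate_trial_table(
            frame, censor_limit_s=config.censor_limit_s,
            familiarization_limit_s=config.familiarization_duration_s,
        )
    return frame


def implied_conditional_covariate_slope(
    config: GeneratorConfig, n_mc: int = 2_000_000, seed: int = 12345
) -> float:
    """Projection of the subject intercept onto the familiarization z-score.

    The generator couples attentiveness (hence the familiarization covariate)
    with the subject intercept (``fam_attention_corr``), so the covariate is
    endogenous: a model that conditions on familiarization time estimates
    ``beta_cov + slope``, where ``slope = cov(u, fam_z) / var(fam_z)``.  This
    helper computes that slope by large-sample Monte Carlo, defining the
    conditional estimand that parameter-recovery checks must target.
    """
    rng = np.random.default_rng(seed)
    g1 = rng.standard_normal(n_mc)
    g2 = rng.standard_normal(n_mc)
    rho = config.fam_attention_corr
    z_att = rho * g1 + math.sqrt(1.0 - rho**2) * g2
    frac = stats.beta.ppf(stats.norm.cdf(z_att), config.fam_beta_a, config.fam_beta_b)
    fam = np.clip(frac * config.familiarization_duration_s, 0.01,
                  config.familiarization_duration_s)
    fam_mean, fam_sd = _fam_moments(config)
    fam_z = (fam - fam_mean) / fam_sd
    u = config.sigma_subject * g1
    return float(np.cov(u, fam_z)[0, 1] / np.var(fam_z))


def simulate_aggregate(
    config: GeneratorConfig,
    scheme: ContrastScheme | None = None,
) -> pd.DataFrame:
    """Generate the combined brightness + length trial table.

    The brightness experiment has three conditions, the length experiment
    two (no shape-change control); both are balanced with ``n_per_cell``
    subjects per condition x order cell.  ``config.beta`` should name the
    21-term aggregate scheme (``DEFAULT_AGGREGATE_BETA`` by default is the
    published aggregate coefficient set).
    """
    if scheme is None:
        scheme = build_contrast_scheme("aggregate")
    bright = simulate_experiment(
        config, scheme, experiment="brightness",
        conditions=EXPERIMENT_CONDITIONS["brightness"],
        _cell_offset=0, _id_prefix="b_",
    )
    length = simulate_experiment(
        config, scheme, experiment="length",
        conditions=EXPERIMENT_CONDITIONS["length"],
        _cell_offset=6, _id_prefix="l_",
    )
    return pd.concat([bright, length], ignore_index=True)
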