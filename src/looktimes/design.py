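"""Experimental design vocabulary, trial-table schema, and contrast coding.

The study is a bimodal familiarization/test design: each newborn is
familiarized for 60 s to an auditory number/duration paired with a visual
stimulus, then sees two test trials with a novel number/duration — one with
no visual change (1-Change) and one where the visual feature changes too
(2-Change).  Between-subject factors are Condition (congruent / incongruent
brightness change, or a shape-change control) and which test trial came
first; Trial Type is within subject.  Looking time per test trial, ceiling-
censored at the 60-s maximum trial length, is the dependent measure.

This module defines the trial-table file format and the two sum-to-zero
contrast schemes used by every downstream fit: a 13-term scheme for a single
experiment and a 21-term nested scheme for the cross-experiment aggregate
model (brightness plus the historical number/duration-length experiment).
Coding is chosen so that each coefficient equals the cell-mean difference
named by its label (difference coding, +/-1/2, for two-level factors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CENSOR_LIMIT_S",
    "CONDITIONS",
    "EXPERIMENTS",
    "FIRST_TESTS",
    "TRIAL_TYPES",
    "FAMILIARIZATION_GROUPS",
    "TRIAL_TABLE_COLUMNS",
    "TrialObservation",
    "SchemaError",
    "ContrastTerm",
    "ContrastScheme",
    "DesignMatrix",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "trials_to_frame",
    "frame_to_trials",
    "build_contrast_scheme",
    "build_design_matrix",
]

CENSOR_LIMIT_S = 60.0

EXPERIMENTS = ("brightness", "length")
CONDITIONS = ("congruent", "incongruent", "shape_change")
FAMILIARIZATION_GROUPS = ("small", "large")  # 6 vs 18 syllables
FIRST_TESTS = ("one_change_first", "two_change_first")
TRIAL_TYPES = ("one_change", "two_change")

TRIAL_TABLE_COLUMNS = (
    "subject_id",
    "experiment",
    "condition",
    "familiarization_group",
    "first_test",
    "trial_type",
    "trial_index",
    "familiarization_looking_s",
    "looking_s",
    "censored",
)

#: conditions available in each experiment: the length experiment has no
#: shape-change control.
EXPERIMENT_CONDITIONS = {
    "brightness": ("congruent", "incongruent", "shape_change"),
    "length": ("congruent", "incongruent"),
}


class SchemaError(ValueError):
    """A trial table violates the documented schema."""


@dataclass(frozen=True)
class TrialObservation:
    """One test-trial record."""

    subject_id: str
    experiment: str
    condition: str
    familiarization_group: str
    first_test: str
    trial_type: str
    trial_index: int
    familiarization_looking_s: float
    looking_s: float
    censored: bool


def trials_to_frame(trials: Iterable[TrialObservation]) -> pd.DataFrame:
    rows = [vars(t) for t in trials]
    df = pd.DataFrame(rows, columns=list(TRIAL_TABLE_COLUMNS))
    return df


def frame_to_trials(frame: pd.DataFrame) -> list[TrialObservation]:
    return [
        TrialObservation(
            subject_id=str(r.subject_id),
            experiment=r.experiment,
            condition=r.condition,
            familiarization_group=r.familiarization_group,
            first_test=r.first_test,
            trial_type=r.trial_type,
            trial_index=int(r.trial_index),
            familiarization_looking_s=float(r.familiarization_looking_s),
            looking_s=float(r.looking_s),
            censored=bool(r.censored),
        )
        for r in frame.itertuples(index=False)
    ]


def validate_trial_table(
    frame: pd.DataFrame,
    censor_limit_s: float = CENSOR_LIMIT_S,
    familiarization_limit_s: float = 60.0,
) -> pd.DataFrame:
    """Validate a trial table against the schema; return a clean copy.

    Raises :class:`SchemaError` naming the offending column/row on the first
    violation found.
    """
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = frame.loc[:, list(TRIAL_TABLE_COLUMNS)].copy()
    if len(df) == 0:
        return df

    df["subject_id"] = df["subject_id"].astype(str)
    df["trial_index"] = df["trial_index"].astype(int)
    if df["censored"].dtype != bool:
        df["censored"] = (
            df["censored"].astype(str).str.lower().map({"true": True, "false": False,
                                                        "1": True, "0": False})
        )
        if df["censored"].isna().any():
            row = int(df.index[df["censored"].isna()][0])
            raise SchemaError(f"row {row}: unparsable censored flag")
    for col, levels in (
        ("experiment", EXPERIMENTS),
        ("condition", CONDITIONS),
        ("familiarization_group", FAMILIARIZATION_GROUPS),
        ("first_test", FIRST_TESTS),
        ("trial_type", TRIAL_TYPES),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"row {row}: invalid {col} {df.loc[row, col]!r}")

    for col, limit in (("familiarization_looking_s", familiarization_limit_s),
                       ("looking_s", censor_limit_s)):
        vals = df[col].astype(float)
        df[col] = vals
        bad = ~((vals > 0) & (vals <= limit))
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"row {row}: {col} = {vals[row]} outside (0, {limit}]"
            )

    at_limit = df["looking_s"].to_numpy() >= censor_limit_s - 1e-9
    mismatch = at_limit != df["censored"].to_numpy()
    if mismatch.any():
        row = int(df.index[mismatch][0])
        raise SchemaError(
            f"row {row}: censored flag inconsistent with looking_s "
            f"= {df.loc[row, 'looking_s']} at limit {censor_limit_s}"
        )

    shape_wrong = (df["condition"] == "shape_change") & (df["experiment"] != "brightness")
    if shape_wrong.any():
        row = int(df.index[shape_wrong][0])
        raise SchemaError(f"row {row}: shape_change condition outside brightness experiment")

    for sid, grp in df.groupby("subject_id", sort=False):
        if len(grp) != 2 or set(grp["trial_type"]) != set(TRIAL_TYPES):
            raise SchemaError(
                f"subject {sid!r}: expected one one_change and one two_change trial, "
                f"got {list(grp['trial_type'])}"
            )
        for col in ("experiment", "condition", "familiarization_group", "first_test",
                    "familiarization_looking_s"):
            if grp[col].nunique() != 1:
                raise SchemaError(f"subject {sid!r}: inconsistent {col} across trials")
        first = grp.loc[grp["trial_index"] == 1, "trial_type"]
        if set(grp["trial_index"]) != {1, 2} or len(first) != 1:
            raise SchemaError(f"subject {sid!r}: trial_index must be {{1, 2}}")
        expected = "one_change" if grp["first_test"].iloc[0] == "one_change_first" else "two_change"
        if first.iloc[0] != expected:
            raise SchemaError(
                f"subject {sid!r}: trial_index inconsistent with first_test "
                f"{grp['first_test'].iloc[0]!r}"
            )
    return df


def read_trial_table(
    path: str | Path, censor_limit_s: float = CENSOR_LIMIT_S
) -> pd.DataFrame:
    """Read and validate a trial-table CSV (UTF-8, comma-separated, header row)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_trial_table(df, censor_limit_s=censor_limit_s)


def write_trial_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as CSV with >= 2 decimal digits on seconds."""
    out = frame.loc[:, list(TRIAL_TABLE_COLUMNS)].copy()
    for col in ("familiarization_looking_s", "looking_s"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Contrast schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastTerm:
    """One design-matrix column.

    ``kind`` is ``intercept``, ``covariate``, or ``contrast``.  A contrast
    term's code for a trial is the product of its base-contrast codes; each
    base maps a factor value (or an (experiment, condition) pair) to a
    numeric code.  ``factors`` names the experimental factors the term
    involves, used to group terms into ANOVA-summary coefficient sets.
    """

    name: str
    kind: str
    bases: tuple[str, ...] = ()
    factors: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContrastScheme:
    scope: str
    terms: tuple[ContrastTerm, ...]
    #: base-contrast name -> (factor key, {level: code}); factor key is a
    #: column name, or "experiment:condition" for the joint aggregate factor.
    bases: Mapping[str, tuple[str, Mapping[object, float]]]
    covariate_column: str = "familiarization_looking_s"

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def base_codes(self, base: str, frame: pd.DataFrame) -> np.ndarray:
        factor, mapping = self.bases[base]
        if factor == "experiment:condition":
            keys = list(zip(frame["experiment"], frame["condition"]))
            return np.array([mapping[k] for k in keys], dtype=float)
        return frame[factor].map(mapping).to_numpy(dtype=float)

    def to_json(self, path: str | Path | None = None) -> str:
        """Export the scheme (term list and cell-code maps) for audit."""
        payload = {
            "scope": self.scope,
            "terms": [
                {"name": t.name, "kind": t.kind, "bases": list(t.bases),
                 "factors": list(t.factors)}
                for t in self.terms
            ],
            "bases": {
                name: {"factor": factor,
                       "codes": {str(k): v for k, v in mapping.items()}}
                for name, (factor, mapping) in self.bases.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# printed labels, reproduced verbatim from the published coefficient tables
_TT = "2-Change − 1-Change"
_FT = "2-Change First − 1-Change First"

_SINGLE_TERMS: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
    ("(Intercept)", "intercept", (), ()),
    ("Familiarization Time", "covariate", (), ("familiarization",)),
    ("Congruent—Shape Change", "contrast", ("cond1",), ("condition",)),
    ("Incongruent—Shape Change", "contrast", ("cond2",), ("condition",)),
    (_TT, "contrast", ("tt",), ("trial_type",)),
    (_FT, "contrast", ("ft",), ("first_test",)),
    (f"(Cong—Shape) × ({_TT})", "contrast", ("cond1", "tt"),
     ("condition", "trial_type")),
    (f"(Incong—Shape) × ({_TT})", "contrast", ("cond2", "tt"),
     ("condition", "trial_type")),
    (f"(Cong—Shape) × ({_FT})", "contrast", ("cond1", "ft"),
     ("condition", "first_test")),
    (f"(Incong—Shape) × ({_FT})", "contrast", ("cond2", "ft"),
     ("condition", "first_test")),
    (f"({_TT}) × ({_FT})", "contrast", ("tt", "ft"),
     ("trial_type", "first_test")),
    (f"(Cong—Shape) × ({_TT}) × ({_FT})", "contrast",
     ("cond1", "tt", "ft"), ("condition", "trial_type", "first_test")),
    (f"(Incong—Shape) × ({_TT}) × ({_FT})", "contrast",
     ("cond2", "tt", "ft"), ("condition", "trial_type", "first_test")),
]

_SINGLE_BASES = {
    # codes invert to: coefficient = mean(named cell) - mean(reference cell),
    # intercept = unweighted mean of the three condition cells
    "cond1": ("condition",
              {"congruent": 2 / 3, "incongruent": -1 / 3, "shape_change": -1 / 3}),
    "cond2": ("condition",
              {"congruent": -1 / 3, "incongruent": 2 / 3, "shape_change": -1 / 3}),
    "tt": ("trial_type", {"two_change": 0.5, "one_change": -0.5}),
    "ft": ("first_test", {"two_change_first": 0.5, "one_change_first": -0.5}),
}


def _aggregate_condition_codes() -> dict[str, dict[tuple[str, str], float]]:
    """Cell-code table for the five condition x experiment cells.

    Solved from the linear functionals each coefficient must equal
    (e.g. Congruent-Incongruent = mean of congruent cells minus mean of
    incongruent cells over the four magnitude cells, zero weight on the
    shape-change cell; intercept = unweighted mean of the five cells).
    """
    cells = [
        ("brightness", "congruent"),
        ("brightness", "incongruent"),
        ("brightness", "shape_change"),
        ("length", "congruent"),
        ("length", "incongruent"),
    ]
    functionals = np.array(
        [
            [0.2, 0.2, 0.2, 0.2, 0.2],        # intercept
            [0.5, -0.5, 0.0, 0.5, -0.5],      # congruent - incongruent
            [0.5, 0.5, 0.0, -0.5, -0.5],      # brightness - length
            [1.0, -1.0, 0.0, -1.0, 1.0],      # (C-I) x (B-L)
            [-0.25, -0.25, 1.0, -0.25, -0.25],  # shape change - magnitude
        ]
    )
    codes = np.linalg.inv(functionals)  # column j = codes for coefficient j
    names = ["agg_intercept", "ci", "bl", "cibl", "shape_mag"]
    return {
        name: {cell: float(codes[i, j]) for i, cell in enumerate(cells)}
        for j, name in enumerate(names)
    }


_AGG_COND_LABELS = [
    ("ci", "Congruent—Incongruent"),
    ("bl", "Brightness—Length"),
    ("cibl", "(Congruent-Incongruent) × (Brightness-Length)"),
    ("shape_mag", "Shape Change—Magnitude"),
]
# the published table abbreviates condition labels inside interaction terms
_AGG_COND_SHORT = {
    "ci": {"tt": "Congruent—Incongruent", "ft": "Congruent—Incongruent",
           "ttft": "Cong—Incong"},
    "bl": {"tt": "Brightness—Length", "ft": "Brightness—Length",
           "ttft": "Brightness—Length"},
    "cibl": {"tt": "Cong-Incong × Bright-Length",
             "ft": "Cong-Incong × Bright-Length",
             "ttft": "Cong-Incong × Bright-Length"},
    "shape_mag": {"tt": "Shape Change—Magnitude",
                  "ft": "Shape Change—Magnitude",
                  "ttft": "Shape Change—Magnitude"},
}


def _aggregate_terms() -> list[tuple[str, str, tuple[str, ...], tuple[str, ...]]]:
    terms: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
        ("(Intercept)", "intercept", (), ()),
        ("Familiarization Time", "covariate", (), ("familiarization",)),
    ]
    for base, label in _AGG_COND_LABELS:
        terms.append((label, "contrast", (base,), ("condition",)))
    terms.append((_TT, "contrast", ("tt",), ("trial_type",)))
    terms.append((_FT, "contrast", ("ft",), ("first_test",)))
    for base, _ in _AGG_COND_LABELS:
        short = _AGG_COND_SHORT[base]["tt"]
        terms.append((f"({short}) × ({_TT})", "contrast", (base, "tt"),
                      ("condition", "trial_type")))
    for base, _ in _AGG_COND_LABELS:
        short = _AGG_COND_SHORT[base]["ft"]
        terms.append((f"({short}) × ({_FT})", "contrast", (base, "ft"),
                      ("condition", "first_test")))
    terms.append((f"({_TT}) × ({_FT})", "contrast", ("tt", "ft"),
                  ("trial_type", "first_test")))
    for base, _ in _AGG_COND_LABELS:
        short = _AGG_COND_SHORT[base]["ttft"]
        terms.append((f"({short}) × ({_TT}) × ({_FT})", "contrast",
                      (base, "tt", "ft"),
                      ("condition", "trial_type", "first_test")))
    return terms


def build_contrast_scheme(scope: str = "single_experiment") -> ContrastScheme:
    """Build the 13-term single-experiment or 21-term aggregate scheme.

    Every coefficient of the resulting regression equals the cell-mean
    difference its label names; all non-intercept, non-covariate columns sum
    to zero over the balanced cell set they are defined on.
    """
    if scope == "single_experiment":
        terms = tuple(ContrastTerm(*t) for t in _SINGLE_TERMS)
        return ContrastScheme(scope=scope, terms=terms, bases=dict(_SINGLE_BASES))
    if scope == "aggregate":
        cond_codes = _aggregate_condition_codes()
        bases: dict[str, tuple[str, Mapping[object, float]]] = {
            name: ("experiment:condition", cond_codes[name])
            for name, _ in _AGG_COND_LABELS
        }
        bases["tt"] = _SINGLE_BASES["tt"]
        bases["ft"] = _SINGLE_BASES["ft"]
        terms = tuple(ContrastTerm(*t) for t in _aggregate_terms())
        return ContrastScheme(scope=scope, terms=terms, bases=bases)
    raise ValueError(f"unknown scheme scope {scope!r}")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Numeric design matrix aligned to a trial table and a contrast scheme.

    ``covariate_center``/``covariate_scale`` record the familiarization-time
    standardization actually applied (subject-level mean and SD by default),
    so fitted covariate coefficients are interpretable and reproducible.
    """

    matrix: pd.DataFrame
    scheme: ContrastScheme
    subject_ids: np.ndarray
    covariate_center: float
    covariate_scale: float

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)


def cell_code_row(
    scheme: ContrastScheme,
    *,
    condition: str,
    trial_type: str,
    first_test: str,
    experiment: str = "brightness",
    covariate: float = 0.0,
) -> np.ndarray:
    """Design-matrix row for one design cell (covariate at a given z-value)."""
    frame = pd.DataFrame(
        {
            "experiment": [experiment],
            "condition": [condition],
            "trial_type": [trial_type],
            "first_test": [first_test],
        }
    )
    row = np.empty(len(scheme))
    for j, term in enumerate(scheme.terms):
        if term.kind == "intercept":
            row[j] = 1.0
        elif term.kind == "covariate":
            row[j] = covariate
        else:
            code = 1.0
            for base in term.bases:
                code *= scheme.base_codes(base, frame)[0]
            row[j] = code
    return row


def build_design_matrix(
    trials: pd.DataFrame,
    scheme: ContrastScheme,
    *,
    standardize_covariate: bool = True,
) -> DesignMatrix:
    """One design-matrix row per trial; interaction columns are elementwise
    products of their parent columns; the familiarization covariate is
    centered and scaled by its subject-level mean and SD."""
    if scheme.scope == "aggregate":
        present = set(trials["experiment"])
        if not {"brightness", "length"} <= present:
            raise ValueError(
                "aggregate scheme requires both brightness and length experiments; "
                f"found {sorted(present)}"
            )
    cov_raw = trials[scheme.covariate_column].to_numpy(dtype=float)
    subj_vals = trials.groupby("subject_id", sort=False)[scheme.covariate_column].first()
    if standardize_covariate and len(subj_vals) > 1:
        center = float(subj_vals.mean())
        scale = float(subj_vals.std(ddof=1))
        if scale == 0:
            scale = 1.0
    else:
        center, scale = 0.0, 1.0
    cov = (cov_raw - center) / scale

    cols: dict[str, np.ndarray] = {}
    base_cache: dict[str, np.ndarray] = {}
    for term in scheme.terms:
        if term.kind == "intercept":
            cols[term.name] = np.ones(len(trials))
        elif term.kind == "covariate":
            cols[term.name] = cov
        else:
            code = np.ones(len(trials))
            for base in term.bases:
                if base not in base_cache:
                    base_cache[base] = scheme.base_codes(base, trials)
                code = code * base_cache[base]
            cols[term.name] = code
    matrix = pd.DataFrame(cols, index=trials.index)
    return DesignMatrix(
        matrix=matrix,
        scheme=scheme,
        subject_ids=trials["subject_id"].to_numpy(),
        covariate_center=center,
        covariate_scale=scale,
    )
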