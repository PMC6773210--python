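"""Frequentist stack: ANOVAs, Tukey-adjusted marginal means, ML multilevel fits.

Three layers mirror the usual looking-time analysis sequence:

* a one-way fixed-effects ANOVA on familiarization looking times;
* a mixed-design (split-plot) ANOVA on raw test-trial looking times with
  Condition and First Test between subjects and Trial Type within, with
  partial eta-squared per effect and the two error strata the balanced
  design implies (subjects-within-cells for between effects, the Trial Type
  x subject stratum for within effects);
* random-intercept linear regressions on raw or log looking times fitted by
  maximum likelihood (profiled over the subject/residual variance ratio),
  with containment degrees of freedom (observations minus subjects) and
  marginal/conditional pseudo-R².

Estimated marginal means average model cell means with equal weights and
propagate variance through the two ANOVA strata; pairwise comparisons use
the studentized-range (Tukey) distribution within each comparison family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignMatrix

__all__ = [
    "AnovaTable",
    "MixedAnovaFit",
    "EmmGrid",
    "CoefficientTable",
    "oneway_anova",
    "mixed_anova",
    "marginal_means",
    "tukey_pairwise",
    "fit_ml_multilevel",
    "anova_summary",
]


@dataclass
class AnovaTable:
    """Effect table with SS, MS, df pair, F, partial eta^2 and p per row."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def oneway_anova(data, value_col: str = "familiarization_looking_s",
                 group_col: str = "condition") -> AnovaTable:
    """Fixed-effects one-way ANOVA (familiarization looking by condition).

    ``data`` is a trial table (one familiarization value per subject is
    extracted) or a mapping ``group -> array of values``.
    """
    if isinstance(data, pd.DataFrame):
        per_subj = data.groupby("subject_id", sort=False).first()
        groups = {g: grp[value_col].to_numpy(dtype=float)
                  for g, grp in per_subj.groupby(group_col, sort=False)}
    else:
        groups = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    warnings: list[str] = []
    if ss_within == 0:
        warnings.append("zero within-group variance: F undefined")
        f = p = np.nan
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    table = pd.DataFrame(
        {
            "effect": [group_col.capitalize(), "Error"],
            "ss": [ss_between, ss_within],
            "df_num": [df_b, df_w],
            "df_den": [df_w, np.nan],
            "ms": [ss_between / df_b, ss_within / df_w if df_w else np.nan],
            "F": [f, np.nan],
            "partial_eta_sq": [ss_between / (ss_between + ss_within), np.nan],
            "p": [p, np.nan],
        }
    ).set_index("effect")
    return AnovaTable(table=table, warnings=warnings)


# ---------------------------------------------------------------------------
# Mixed-design (split-plot) ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaFit:
    """Mixed ANOVA result: effect table, cell means, and error strata."""

    anova: AnovaTable
    cell_means: pd.Series  # index (condition, first_test, trial_type)
    n_per_cell: int
    ms_between: float
    df_between: int
    ms_within: float
    df_within: int
    conditions: tuple[str, ...]
    first_tests: tuple[str, ...]
    trial_types: tuple[str, ...]

    @property
    def table(self) -> pd.DataFrame:
        return self.anova.table


def mixed_anova(trials: pd.DataFrame, value_col: str = "looking_s") -> MixedAnovaFit:
    """Split-plot ANOVA: Condition x First Test between, Trial Type within.

    Requires a balanced design with one observation per subject per trial
    type.  Between effects are tested against subjects-within-cells; within
    effects against the Trial Type x subject stratum.
    """
    df = trials.copy()
    conds = tuple(dict.fromkeys(df["condition"]))
    fts = tuple(dict.fromkeys(df["first_test"]))
    tts = tuple(dict.fromkeys(df["trial_type"]))
    a, b, w = len(conds), len(fts), len(tts)

    pivot = df.pivot_table(index=["condition", "first_test", "subject_id"],
                           columns="trial_type", values=value_col, aggfunc="first")
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index[0]
        raise ValueError(f"subject {missing[-1]!r} is missing a trial-type level")
    counts = pivot.groupby(level=["condition", "first_test"]).size()
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced across condition x first-test cells")
    n = int(counts.iloc[0])

    y = pivot.to_numpy(dtype=float)          # (subjects, w)
    subj_means = y.mean(axis=1)
    grand = y.mean()
    cell_idx = pivot.index.droplevel("subject_id")

    def _mean_by(levels: pd.Index, arr: np.ndarray) -> pd.Series:
        return pd.Series(arr, index=levels).groupby(level=list(range(levels.nlevels))).mean()

    m_ab = _mean_by(cell_idx, subj_means)                       # (a, b)
    m_a = pd.Series(subj_means, index=cell_idx).groupby(level="condition").mean()
    m_b = pd.Series(subj_means, index=cell_idx).groupby(level="first_test").mean()
    m_w = pd.Series(y.mean(axis=0), index=pd.Index(pivot.columns, name="trial_type"))

    # cell means per (condition, first_test, trial_type)
    long = pivot.stack()
    long.index = long.index.reorder_levels(["condition", "first_test", "subject_id",
                                            "trial_type"])
    m_abw = long.groupby(level=["condition", "first_test", "trial_type"]).mean()
    m_aw = long.groupby(level=["condition", "trial_type"]).mean()
    m_bw = long.groupby(level=["first_test", "trial_type"]).mean()

    ss_a = w * b * n * ((m_a - grand) ** 2).sum()
    ss_b = w * a * n * ((m_b - grand) ** 2).sum()
    ss_ab = w * n * sum(
        (m_ab[ci, fi] - m_a[ci] - m_b[fi] + grand) ** 2
        for ci, fi in m_ab.index
    )
    ss_s = w * sum(
        (subj_means[i] - m_ab[cell_idx[i]]) ** 2 for i in range(len(subj_means))
    )
    ss_w = a * b * n * ((m_w - grand) ** 2).sum()
    ss_aw = b * n * sum(
        (m_aw[ci, wi] - m_a[ci] - m_w[wi] + grand) ** 2 for ci, wi in m_aw.index
    )
    ss_bw = a * n * sum(
        (m_bw[fi, wi] - m_b[fi] - m_w[wi] + grand) ** 2 for fi, wi in m_bw.index
    )
    ss_abw = n * sum(
        (m_abw[ci, fi, wi] - m_ab[ci, fi] - m_aw[ci, wi] - m_bw[fi, wi]
         + m_a[ci] + m_b[fi] + m_w[wi] - grand) ** 2
        for ci, fi, wi in m_abw.index
    )
    # within-stratum residual: y - cell mean - (subject mean - between-cell mean)
    fitted = np.array([m_abw[ci, fi, wi] for (ci, fi, _s, wi) in long.index])
    subj_dev = np.repeat(subj_means - np.array([m_ab[k] for k in cell_idx]), w)
    # long is ordered subject-major after stack, so repeat matches
    ss_ws = float(((long.to_numpy() - fitted - subj_dev) ** 2).sum())

    df_between = a * b * (n - 1)
    df_within = a * b * (n - 1) * (w - 1)
    ms_s = ss_s / df_between
    ms_ws = ss_ws / df_within

    rows = []
    warnings: list[str] = []

    def add(effect, ss, dfn, err_ss, err_df):
        if dfn == 0:  # single-level factor: effect not estimable, omit row
            return
        ms = ss / dfn
        err_ms = err_ss / err_df
        if ms == 0:
            f = 0.0
        elif err_ms > 0:
            f = ms / err_ms
        else:
            f = np.nan
            warnings.append(f"{effect}: zero error variance, F undefined")
        rows.append(
            dict(effect=effect, ss=ss, df_num=dfn, df_den=err_df, ms=ms, F=f,
                 partial_eta_sq=ss / (ss + err_ss) if (ss + err_ss) > 0 else np.nan,
                 p=float(stats.f.sf(f, dfn, err_df)) if np.isfinite(f) else np.nan)
        )

    add("Condition", ss_a, a - 1, ss_s, df_between)
    add("First Test", ss_b, b - 1, ss_s, df_between)
    add("Condition × First Test", ss_ab, (a - 1) * (b - 1), ss_s, df_between)
    add("Trial Type", ss_w, w - 1, ss_ws, df_within)
    add("Condition × Trial Type", ss_aw, (a - 1) * (w - 1), ss_ws, df_within)
    add("First Test × Trial Type", ss_bw, (b - 1) * (w - 1), ss_ws, df_within)
    add("Condition × First Test × Trial Type", ss_abw, (a - 1) * (b - 1) * (w - 1),
        ss_ws, df_within)
    rows.append(dict(effect="Error (between)", ss=ss_s, df_num=df_between,
                     df_den=np.nan, ms=ms_s, F=np.nan, partial_eta_sq=np.nan,
                     p=np.nan))
    rows.append(dict(effect="Error (within)", ss=ss_ws, df_num=df_within,
                     df_den=np.nan, ms=ms_ws, F=np.nan, partial_eta_sq=np.nan,
                     p=np.nan))
    table = pd.DataFrame(rows).set_index("effect")

    return MixedAnovaFit(
        anova=AnovaTable(table=table, warnings=warnings),
        cell_means=m_abw,
        n_per_cell=n,
        ms_between=float(ms_s),
        df_between=df_between,
        ms_within=float(ms_ws),
        df_within=df_within,
        conditions=conds,
        first_tests=fts,
        trial_types=tts,
    )


# ---------------------------------------------------------------------------
# Estimated marginal means and Tukey comparisons
# ---------------------------------------------------------------------------

_FACTORS = ("condition", "first_test", "trial_type")


def _contrast_variance(fit: MixedAnovaFit, weights: Mapping[tuple, float]):
    """Variance, df and stratum of a linear combination of the 12 cell means.

    With subject variance sigma_s^2 and residual sigma_e^2, a combination
    with cell weights c has variance
    ``sigma_s^2 * sum_ab (sum_w c)^2 / n + sigma_e^2 * sum_abw c^2 / n``.
    Substituting the stratum expectations (MS_between = sigma_e^2 +
    w*sigma_s^2, MS_within = sigma_e^2) expresses it in the two mean
    squares; pure between- or within-subject combinations take the df of a
    single stratum (contrasts mixing strata are not supported).
    """
    n = fit.n_per_cell
    w_levels = fit.trial_types
    wlen = len(w_levels)
    cells_ab: dict[tuple, np.ndarray] = {}
    for (ci, fi, wi), c in weights.items():
        arr = cells_ab.setdefault((ci, fi), np.zeros(wlen))
        arr[w_levels.index(wi)] += c
    A = sum(arr.sum() ** 2 for arr in cells_ab.values()) / n
    B = sum((arr**2).sum() for arr in cells_ab.values()) / n
    coef_between = A / wlen
    coef_within = B - A / wlen
    var = coef_between * fit.ms_between + coef_within * fit.ms_within
    tol = 1e-12
    if coef_within <= tol * max(B, 1e-300):
        return var, fit.df_between
    if coef_between <= tol * max(B, 1e-300):
        return var, fit.df_within
    raise ValueError(
        "contrast mixes between- and within-subject strata; no single-stratum df"
    )


@dataclass
class EmmGrid:
    """Estimated marginal means over a grouping, with SEs and df."""

    fit: MixedAnovaFit
    grouping: tuple[str, ...]
    at: dict[str, str]
    rows: pd.DataFrame          # columns: levels..., mean, se, df
    weights: list[dict]         # per-row cell-weight maps


def marginal_means(fit: MixedAnovaFit, grouping: Sequence[str],
                   at: Mapping[str, str] | None = None) -> EmmGrid:
    """Model cell means averaged with equal weights over unconditioned
    factors (optionally fixing factors via ``at``)."""
    grouping = tuple(grouping)
    at = dict(at or {})
    for name in list(grouping) + list(at):
        if name not in _FACTORS:
            raise ValueError(f"unknown factor {name!r}")
    levels = {"condition": fit.conditions, "first_test": fit.first_tests,
              "trial_type": fit.trial_types}
    rows = []
    weight_maps = []
    for combo in itertools.product(*(levels[g] for g in grouping)):
        sel = dict(zip(grouping, combo))
        sel.update(at)
        cells = [
            key for key in fit.cell_means.index
            if all(key[_FACTORS.index(f)] == v for f, v in sel.items())
        ]
        wmap = {key: 1.0 / len(cells) for key in cells}
        mean = sum(wt * fit.cell_means[key] for key, wt in wmap.items())
        try:
            var, df = _contrast_variance(fit, wmap)
        except ValueError:
            var, df = np.nan, np.nan
        rows.append({**{g: v for g, v in zip(grouping, combo)},
                     "mean": mean, "se": math.sqrt(var) if var == var else np.nan,
                     "df": df})
        weight_maps.append(wmap)
    return EmmGrid(fit=fit, grouping=grouping, at=at,
                   rows=pd.DataFrame(rows), weights=weight_maps)


def tukey_pairwise(grid: EmmGrid) -> pd.DataFrame:
    """All pairwise comparisons within the grid's family, Tukey-adjusted.

    The adjusted p uses the studentized-range distribution with the family
    size k and the error-stratum df of the comparison.
    """
    k = len(grid.rows)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        wmap: dict[tuple, float] = dict(grid.weights[i])
        for key, wt in grid.weights[j].items():
            wmap[key] = wmap.get(key, 0.0) - wt
        est = sum(wt * grid.fit.cell_means[key] for key, wt in wmap.items())
        var, df = _contrast_variance(grid.fit, wmap)
        se = math.sqrt(var)
        t = est / se if se > 0 else np.nan
        label_i = "/".join(str(grid.rows.iloc[i][g]) for g in grid.grouping)
        label_j = "/".join(str(grid.rows.iloc[j][g]) for g in grid.grouping)
        if k > 2:
            p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2), k, df))
        else:
            p = float(2 * stats.t.sf(abs(t), df))
        out.append(dict(contrast=f"{label_i} − {label_j}", estimate=est, se=se,
                        df=df, t=t, p_tukey=min(p, 1.0)))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ML multilevel regression (random subject intercept)
# ---------------------------------------------------------------------------

@dataclass
class CoefficientTable:
    """ML multilevel fit: coefficient table, variance components, pseudo-R²."""

    table: pd.DataFrame          # term, estimate, se, df, t, p
    sigma_subject: float
    sigma_obs: float
    r2_marginal: float
    r2_conditional: float
    response_scale: str
    loglik: float
    n_obs: int
    n_subjects: int
    cov: np.ndarray
    design: DesignMatrix
    metadata: dict = field(default_factory=dict)


def _profile_pieces(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    _, starts = np.unique(gs, return_index=True)
    starts.sort()
    n_g = np.diff(np.append(starts, len(gs)))
    SX = np.add.reduceat(Xs, starts, axis=0)
    Sy = np.add.reduceat(ys, starts)
    return Xs, ys, n_g, SX, Sy


def fit_ml_multilevel(
    trials: pd.DataFrame,
    design: DesignMatrix,
    response_scale: str = "log",
    value_col: str = "looking_s",
) -> CoefficientTable:
    """Random-intercept linear model by maximum likelihood.

    The likelihood is profiled over the variance ratio lambda =
    sigma_subject^2 / sigma_obs^2 (closed-form GLS given lambda), then
    maximized in one dimension.  Coefficient df follow the containment rule:
    observations minus subject-level units.  Censored observations are
    treated as exact (these models deliberately ignore censoring; the
    Bayesian module handles it).
    """
    if response_scale not in ("raw", "log"):
        raise ValueError("response_scale must be 'raw' or 'log'")
    y = trials[value_col].to_numpy(dtype=float)
    if response_scale == "log":
        if (y <= 0).any():
            raise ValueError("non-positive looking time under log scale")
        y = np.log(y)
    X = design.values
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    groups = design.subject_ids
    N, p = X.shape
    Xs, ys, n_g, SX, Sy = _profile_pieces(X, y, groups)
    G = len(n_g)
    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)

    def neg_profile_loglik(t: float) -> float:
        lam = math.exp(t)
        c = lam / (1.0 + n_g * lam)
        XtWX = XtX - (SX * c[:, None]).T @ SX
        XtWy = Xty - SX.T @ (c * Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        rwr = yty - (c * Sy**2).sum() - beta @ (2 * XtWy - XtWX @ beta)
        sigma2 = max(rwr / N, 1e-300)
        logdet = np.log1p(n_g * lam).sum()
        ll = -0.5 * (N * math.log(2 * math.pi * sigma2) + N + logdet)
        return -ll

    res = optimize.minimize_scalar(neg_profile_loglik, bounds=(-15.0, 10.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"profile-likelihood optimization failed: {res}")
    lam = math.exp(res.x)
    c = lam / (1.0 + n_g * lam)
    XtWX = XtX - (SX * c[:, None]).T @ SX
    XtWy = Xty - SX.T @ (c * Sy)
    beta = np.linalg.solve(XtWX, XtWy)
    rwr = yty - (c * Sy**2).sum() - beta @ (2 * XtWy - XtWX @ beta)
    sigma2_e = rwr / N
    sigma2_u = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    df = N - G
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)

    var_fixed = float(np.var(X @ beta))
    total = var_fixed + sigma2_u + sigma2_e
    table = pd.DataFrame(
        {"term": design.term_names, "estimate": beta, "se": se,
         "df": df, "t": tvals, "p": pvals}
    ).set_index("term")
    return CoefficientTable(
        table=table,
        sigma_subject=math.sqrt(sigma2_u),
        sigma_obs=math.sqrt(sigma2_e),
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + sigma2_u) / total,
        response_scale=response_scale,
        loglik=-res.fun,
        n_obs=N,
        n_subjects=G,
        cov=cov,
        design=design,
        metadata={
            "covariate_center": design.covariate_center,
            "covariate_scale": design.covariate_scale,
            "df_rule": "containment (n_obs - n_subjects)",
        },
    )


_GROUP_LABELS = [
    (frozenset({"familiarization"}), "Familiarization Time"),
    (frozenset({"first_test"}), "First Test"),
    (frozenset({"condition"}), "Condition"),
    (frozenset({"trial_type"}), "Trial Type"),
    (frozenset({"condition", "first_test"}), "First Test × Condition"),
    (frozenset({"first_test", "trial_type"}), "First Test × Trial Type"),
    (frozenset({"condition", "trial_type"}), "Condition × Trial Type"),
    (frozenset({"condition", "first_test", "trial_type"}),
     "First Test × Condition × Trial Type"),
]


def anova_summary(fit: CoefficientTable) -> pd.DataFrame:
    """Type-III-style term tests of the ML regression (Wald F per
    coefficient set, consistent with the sum-to-zero coding).

    SS is reported on the residual-variance scale (SS = q F sigma_e^2), so
    SS/MS/F are mutually consistent with MS_error = sigma_e^2.
    """
    terms = fit.design.scheme.terms
    names = list(fit.table.index)
    rows = []
    df_den = fit.n_obs - fit.n_subjects
    for factors, label in _GROUP_LABELS:
        idx = [i for i, t in enumerate(terms) if frozenset(t.factors) == factors]
        if not idx:
            continue
        q = len(idx)
        b = fit.table["estimate"].to_numpy()[idx]
        V = fit.cov[np.ix_(idx, idx)]
        F = float(b @ np.linalg.solve(V, b)) / q
        ss = q * F * fit.sigma_obs**2
        rows.append(dict(coefficient_set=label, ss=ss, ms=ss / q,
                         df_num=q, df_den=df_den, F=F,
                         p=float(stats.f.sf(F, q, df_den))))
    return pd.DataFrame(rows).set_index("coefficient_set")
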