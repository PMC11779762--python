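"""Condition-level summaries and inferential statistics.

Covers the downstream analyses of the fitted log-hyperparameters and the
per-problem cluster counts: design-cell means, a balanced fixed-effects
factorial ANOVA (used on the 24 per-problem cluster counts, 2 replicates
per 3 x 2 x 2 cell), a three-way repeated-measures ANOVA on a chosen
log-parameter with participant as the random blocking factor, pooled
parameter intercorrelations, and within-observer consistency via the
average pairwise across-participant correlation over trial pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .exceptions import InvalidArgumentError, UndefinedCorrelationError

__all__ = [
    "AnovaTable",
    "ConsistencyResult",
    "LOG_PARAM_COLUMNS",
    "records_to_frame",
    "condition_means",
    "factorial_anova",
    "parameter_anova",
    "parameter_correlations",
    "consistency_analysis",
]

LOG_PARAM_COLUMNS = ("log_lambda", "log_signal_var", "log_noise_var")

_FACTORS = ("generator", "n_points", "scale")


@dataclass(frozen=True)
class AnovaTable:
    """Sums of squares, df, MS, F and p per effect, plus the error row.

    ``table`` is indexed by effect name ("generator", "n_points:scale", ...,
    "Residual"). ``zero_variance`` flags the degenerate all-values-equal
    input, for which every F is reported as 0 with p = 1.
    """

    table: pd.DataFrame
    zero_variance: bool = False

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    @property
    def ss_total(self) -> float:
        return float(self.table["SS"].sum())

    def to_json_dict(self) -> dict:
        return {
            "zero_variance": self.zero_variance,
            "effects": {
                name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for name, row in self.table.to_dict("index").items()
            },
        }


@dataclass(frozen=True)
class ConsistencyResult:
    """Average pairwise across-participant correlation for one parameter."""

    parameter: str
    mean_r: float
    t: float
    df: int
    p: float
    n_pairs: int
    n_skipped: int


def records_to_frame(records, design=None) -> pd.DataFrame:
    """Tabulate HyperParamRecords, optionally joining design-cell factors.

    ``design`` maps problem_id to a DesignCell; when given, generator /
    n_points / scale / replicate columns are added.
    """
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "problem_id": r.problem_id,
            "log_lambda": np.log(r.theta.length_scale),
            "log_signal_var": np.log(r.theta.signal_var),
            "log_noise_var": np.log(r.theta.noise_var),
            "lml": r.lml,
            "converged": r.converged,
        }
        if design is not None:
            cell = design[r.problem_id]
            row.update(
                generator=cell.generator,
                n_points=cell.n_points,
                scale=cell.scale,
                replicate=cell.replicate,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def condition_means(records: pd.DataFrame) -> pd.DataFrame:
    """Cell means and SEs of each log-hyperparameter by design cell.

    Cells absent from the records appear as missing rows, not errors.
    Returns one row per generator x n_points x scale cell.
    """
    if records.empty:
        raise InvalidArgumentError("records table is empty")
    cols = [c for c in LOG_PARAM_COLUMNS if c in records.columns]
    if not cols:
        raise InvalidArgumentError("no log-parameter columns present")
    grouped = records.groupby(list(_FACTORS), observed=True)[cols]
    mean = grouped.mean()
    se = grouped.sem()
    out = mean.join(se, lsuffix="_mean", rsuffix="_se")
    full_index = pd.MultiIndex.from_product(
        [["linear", "quadratic", "cubic"], [6, 24], ["small", "large"]],
        names=_FACTORS,
    )
    return out.reindex(full_index).reset_index()


def _zero_variance_table(effects: list[str], df_effects: list[int], df_resid: int) -> AnovaTable:
    rows = {
        name: {"SS": 0.0, "df": df, "MS": 0.0, "F": 0.0, "p": 1.0}
        for name, df in zip(effects, df_effects)
    }
    rows["Residual"] = {"SS": 0.0, "df": df_resid, "MS": 0.0, "F": np.nan, "p": np.nan}
    return AnovaTable(pd.DataFrame(rows).T, zero_variance=True)


def factorial_anova(values, design) -> AnovaTable:
    """Balanced 3 x 2 x 2 fixed-effects ANOVA with replicates within cells.

    ``values`` is one number per problem (e.g. its cluster count);
    ``design`` the matching DesignCells (or a DataFrame with generator /
    n_points / scale columns). The design must be fully crossed with an
    equal number of replicates per cell.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(design, pd.DataFrame):
        df = design.loc[:, list(_FACTORS)].copy()
    else:
        df = pd.DataFrame(
            [{"generator": c.generator, "n_points": c.n_points, "scale": c.scale} for c in design]
        )
    if len(df) != values.size:
        raise InvalidArgumentError("values and design lengths disagree")
    df["value"] = values
    counts = df.groupby(list(_FACTORS), observed=True).size()
    if len(counts) != 12 or counts.nunique() != 1 or counts.iloc[0] < 2:
        raise InvalidArgumentError(
            "design must be fully crossed with equal replicates (>= 2) per cell"
        )

    effects = [
        "generator",
        "n_points",
        "scale",
        "generator:n_points",
        "generator:scale",
        "n_points:scale",
        "generator:n_points:scale",
    ]
    df_effects = [2, 1, 1, 2, 2, 1, 2]
    n = values.size
    df_resid = n - 12
    if np.ptp(values) == 0:
        return _zero_variance_table(effects, df_effects, df_resid)

    model = smf.ols(
        "value ~ C(generator) * C(n_points) * C(scale)", data=df
    ).fit()
    aov = anova_lm(model, typ=2)
    rename = {
        "C(generator)": "generator",
        "C(n_points)": "n_points",
        "C(scale)": "scale",
        "C(generator):C(n_points)": "generator:n_points",
        "C(generator):C(scale)": "generator:scale",
        "C(n_points):C(scale)": "n_points:scale",
        "C(generator):C(n_points):C(scale)": "generator:n_points:scale",
    }
    aov = aov.rename(index=rename)
    table = pd.DataFrame(
        {
            "SS": aov["sum_sq"],
            "df": aov["df"].astype(int),
            "MS": aov["sum_sq"] / aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    ).loc[effects + ["Residual"]]
    return AnovaTable(table)


def _effect_ss(y: np.ndarray, subset: tuple[int, ...]) -> float:
    """Sum of squares of one effect in a fully balanced array with one
    observation per cell, via inclusion-exclusion over marginal means."""
    full_axes = tuple(range(y.ndim))
    effect = np.zeros_like(y)
    for r in range(len(subset) + 1):
        for kept in itertools.combinations(subset, r):
            drop = tuple(ax for ax in full_axes if ax not in kept)
            m = y.mean(axis=drop, keepdims=True)
            effect = effect + ((-1) ** (len(subset) - r)) * m
    return float(np.sum(effect**2))


def parameter_anova(records: pd.DataFrame, parameter: str) -> AnovaTable:
    """Three-way repeated-measures ANOVA on one log-parameter.

    Participant is the random blocking factor; replicates within a design
    cell are averaged per participant first, and each within-subject effect
    is tested against its own effect x participant interaction MS.
    Participants without data in every design cell are dropped listwise.
    """
    if parameter not in records.columns:
        raise InvalidArgumentError(f"column {parameter!r} not in records")
    needed = list(_FACTORS) + ["participant_id", parameter]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise InvalidArgumentError(f"records table lacks columns {missing}")
    cellmeans = (
        records.groupby(["participant_id", *_FACTORS], observed=True)[parameter]
        .mean()
        .reset_index()
    )
    counts = cellmeans.groupby("participant_id", observed=True).size()
    complete = counts[counts == 12].index
    cellmeans = cellmeans[cellmeans["participant_id"].isin(complete)]
    subjects = sorted(cellmeans["participant_id"].unique())
    if len(subjects) < 2:
        raise InvalidArgumentError("need >= 2 participants with complete designs")

    gens, ns, scales = ["linear", "quadratic", "cubic"], [6, 24], ["small", "large"]
    y = np.full((3, 2, 2, len(subjects)), np.nan)
    pivot = cellmeans.set_index(["generator", "n_points", "scale", "participant_id"])[
        parameter
    ]
    for ia, a in enumerate(gens):
        for ib, b in enumerate(ns):
            for ic, c in enumerate(scales):
                for is_, s in enumerate(subjects):
                    y[ia, ib, ic, is_] = pivot.loc[(a, b, c, s)]

    # Axes: 0=generator, 1=n_points, 2=scale, 3=participant.
    effect_axes = {
        "generator": (0,),
        "n_points": (1,),
        "scale": (2,),
        "generator:n_points": (0, 1),
        "generator:scale": (0, 2),
        "n_points:scale": (1, 2),
        "generator:n_points:scale": (0, 1, 2),
    }
    levels = y.shape
    rows = {}
    for name, axes in effect_axes.items():
        ss_e = _effect_ss(y, axes)
        df_e = int(np.prod([levels[ax] - 1 for ax in axes]))
        ss_err = _effect_ss(y, axes + (3,))
        df_err = df_e * (levels[3] - 1)
        ms_e, ms_err = ss_e / df_e, ss_err / df_err
        if ms_err <= 1e-12 * max(ms_e, 1.0):
            f_stat, p = 0.0, 1.0
        else:
            f_stat = ms_e / ms_err
            p = float(sps.f.sf(f_stat, df_e, df_err))
        rows[name] = {"SS": ss_e, "df": df_e, "MS": ms_e, "F": f_stat, "p": p}
        rows[f"{name} x participant"] = {
            "SS": ss_err,
            "df": df_err,
            "MS": ms_err,
            "F": np.nan,
            "p": np.nan,
        }
    ss_subj = _effect_ss(y, (3,))
    rows["participant"] = {
        "SS": ss_subj,
        "df": levels[3] - 1,
        "MS": ss_subj / (levels[3] - 1),
        "F": np.nan,
        "p": np.nan,
    }
    zero_var = float(np.ptp(y)) == 0.0
    return AnovaTable(pd.DataFrame(rows).T, zero_variance=zero_var)


def parameter_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-sided p) for the three log-parameter pairs, pooled."""
    if len(records) < 3:
        raise InvalidArgumentError("need at least 3 records")
    rows = []
    for a, b in itertools.combinations(LOG_PARAM_COLUMNS, 2):
        xa = records[a].to_numpy(dtype=float)
        xb = records[b].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            raise UndefinedCorrelationError(
                f"zero-variance column in pair ({a}, {b})"
            )
        r, p = sps.pearsonr(xa, xb)
        rows.append({"pair": f"{a}~{b}", "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def consistency_analysis(
    records: pd.DataFrame, parameters=LOG_PARAM_COLUMNS
) -> list[ConsistencyResult]:
    """Within-observer consistency of each log-parameter across trials.

    For every pair of problems, the across-participant Pearson correlation
    of the parameter is computed (participants present in both problems;
    pairs with fewer than 3 such participants or a zero-variance side are
    skipped and counted); the result is the mean pairwise r with a
    one-sample t-test against zero, df = (#computed pairs) - 1.
    """
    results = []
    for param in parameters:
        pivot = records.pivot_table(
            index="participant_id", columns="problem_id", values=param
        )
        problems = list(pivot.columns)
        if len(problems) < 2:
            raise InvalidArgumentError("need at least 2 problems")
        rs = []
        skipped = 0
        for p1, p2 in itertools.combinations(problems, 2):
            sub = pivot[[p1, p2]].dropna()
            if len(sub) < 3:
                skipped += 1
                continue
            a = sub[p1].to_numpy()
            b = sub[p2].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                skipped += 1
                continue
            rs.append(float(sps.pearsonr(a, b)[0]))
        if not rs:
            raise UndefinedCorrelationError(
                f"every trial-pair correlation undefined for {param}"
            )
        rs = np.asarray(rs)
        t, p = sps.ttest_1samp(rs, 0.0)
        results.append(
            ConsistencyResult(
                parameter=param,
                mean_r=float(rs.mean()),
                t=float(t),
                df=len(rs) - 1,
                p=float(p),
                n_pairs=len(rs),
                n_skipped=skipped,
            )
        )
    return results
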