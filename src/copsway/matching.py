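"""Propensity-score matching and matched/adjusted/stratified comparisons.

Fallers (>= 1 fall in 12 months) are the treated group; the estimand is the
average treatment effect on the treated (ATT).  The propensity model is a
logistic regression of fall status on the eight background covariates;
matching is 1:1 nearest-neighbor without replacement on the logit propensity
score with a caliper of 0.2 SD of the logit scores.  Balance is reported as
absolute standardized mean differences before/after matching; matched group
differences use Welch's t-test, with covariate-adjusted and propensity-
stratified estimates as sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from copsway.core import PS_COVARIATES, ParticipantRecord

__all__ = [
    "PropensityFit",
    "MatchResult",
    "fit_propensity",
    "nn_caliper_match",
    "smd_table",
    "welch_compare",
    "sensitivity_analyses",
    "records_frame",
]

_BINARY_COVARIATES = {"sex", "adl", "illness", "disability", "orthosis"}


def records_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Covariate table indexed by participant id, with a ``faller`` column."""
    rows = []
    for r in records:
        if r.falls12m is None:
            raise ValueError(f"{r.participant_id}: fall history missing")
        rows.append(
            {
                "participant_id": r.participant_id,
                **{c: getattr(r, c) for c in PS_COVARIATES},
                "faller": int(r.falls12m >= 1),
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


@dataclass
class PropensityFit:
    """Fitted propensity model: coefficients, scores and logit scores."""

    coefficients: pd.Series  # per covariate, plus const
    ps: pd.Series  # P(faller | covariates), indexed by participant id
    logit_ps: pd.Series
    penalized: bool = False  # True when the ridge fallback was used


def fit_propensity(
    records: Sequence[ParticipantRecord],
    covariates: Sequence[str] = PS_COVARIATES,
    ridge_lambda: float = 1e-4,
) -> PropensityFit:
    """Maximum-likelihood logistic fit of faller status on the covariates.

    When the ML fit fails to converge or separates, the model falls back to
    a weakly ridge-penalized fit (``ridge_lambda`` on standardized
    covariates) with a warning.
    """
    df = records_frame(records)
    if df["faller"].nunique() < 2:
        raise ValueError("need at least one faller and one non-faller")
    X = sm.add_constant(df[list(covariates)].astype(float), has_constant="add")
    y = df["faller"].astype(float)
    penalized = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # promote separation warnings
        try:
            res = sm.Logit(y, X).fit(disp=0)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e3:
                params = res.params
        except Exception:  # noqa: BLE001 - any fit failure triggers the fallback
            params = None
    if params is None:
        warnings.warn(
            "propensity ML fit failed (separation or non-convergence); "
            f"using ridge fallback (lambda={ridge_lambda}) on standardized covariates"
        )
        penalized = True
        Z = df[list(covariates)].astype(float)
        mu, sd = Z.mean(), Z.std(ddof=0).replace(0.0, 1.0)
        Zs = sm.add_constant((Z - mu) / sd, has_constant="add")
        alpha = np.full(Zs.shape[1], ridge_lambda)
        alpha[0] = 0.0  # never penalize the intercept
        res = sm.Logit(y, Zs).fit_regularized(alpha=alpha, L1_wt=0.0, disp=0)
        # map standardized coefficients back to the raw covariate scale
        beta_std = res.params.iloc[1:]
        beta_raw = beta_std / sd
        const = res.params.iloc[0] - float((beta_std * mu / sd).sum())
        params = pd.concat([pd.Series({"const": const}), beta_raw])
    lin = (X * params).sum(axis=1)
    ps = 1.0 / (1.0 + np.exp(-lin))
    eps = np.finfo(float).tiny
    logit_ps = np.log(ps.clip(eps, 1 - 1e-15) / (1 - ps).clip(eps, 1 - 1e-15))
    return PropensityFit(
        coefficients=params, ps=ps, logit_ps=logit_ps, penalized=penalized
    )


@dataclass
class MatchResult:
    """1:1 matched pairs with the caliper used and diagnostics."""

    pairs: List[Tuple[str, str]]  # (faller_id, nonfaller_id)
    caliper: float  # logit-PS units
    n_pairs: int
    unmatched: List[str]  # treated left without a control

    @property
    def matched_ids(self) -> List[str]:
        return [pid for pair in self.pairs for pid in pair]


def nn_caliper_match(
    fit: PropensityFit,
    records: Sequence[ParticipantRecord],
    caliper_factor: float = 0.2,
    order: str = "descending",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    Treated (fallers) are processed in descending propensity-score order
    (``order='ascending'`` and ``'data'`` are available); each is matched to
    the nearest unmatched control by absolute logit-PS distance, if that
    distance is within ``caliper_factor`` SD of the logit scores.  Ties are
    broken by input record order.
    """
    df = records_frame(records)
    logit = fit.logit_ps
    caliper = caliper_factor * float(np.std(logit.loc[df.index], ddof=1))

    treated = [pid for pid in df.index if df.loc[pid, "faller"] == 1]
    controls = [pid for pid in df.index if df.loc[pid, "faller"] == 0]
    if order == "descending":
        treated = sorted(treated, key=lambda p: -fit.ps[p])
    elif order == "ascending":
        treated = sorted(treated, key=lambda p: fit.ps[p])
    elif order != "data":
        raise ValueError("order must be 'descending', 'ascending' or 'data'")

    available = list(controls)
    pairs: List[Tuple[str, str]] = []
    unmatched: List[str] = []
    for t in treated:
        if not available:
            unmatched.append(t)
            continue
        dists = np.array([abs(logit[t] - logit[c]) for c in available])
        j = int(np.argmin(dists))  # argmin keeps the first (input-order) tie
        if dists[j] <= caliper:
            pairs.append((t, available.pop(j)))
        else:
            unmatched.append(t)
    return MatchResult(pairs=pairs, caliper=caliper, n_pairs=len(pairs), unmatched=unmatched)


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------

def _smd(x1: np.ndarray, x0: np.ndarray, binary: bool) -> float:
    if binary:
        p1, p0 = float(np.mean(x1)), float(np.mean(x0))
        denom = math.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    else:
        denom = math.sqrt((np.var(x1, ddof=1) + np.var(x0, ddof=1)) / 2.0)
    if denom == 0:
        return float("nan")
    return abs(float(np.mean(x1)) - float(np.mean(x0))) / denom


def smd_table(
    records: Sequence[ParticipantRecord],
    match: MatchResult,
    covariates: Sequence[str] = PS_COVARIATES,
) -> pd.DataFrame:
    """Absolute standardized mean differences before and after matching.

    Continuous covariates use the pooled-variance denominator; binary ones
    the pooled Bernoulli variance.  Love-plot ready (one row per covariate,
    columns ``smd_before`` / ``smd_after``).
    """
    df = records_frame(records)
    matched = df.loc[match.matched_ids] if match.n_pairs else df.iloc[0:0]
    rows = {}
    for cov in covariates:
        binary = cov in _BINARY_COVARIATES
        before = _smd(
            df.loc[df["faller"] == 1, cov].to_numpy(dtype=float),
            df.loc[df["faller"] == 0, cov].to_numpy(dtype=float),
            binary,
        )
        if match.n_pairs >= 2:
            after = _smd(
                matched.loc[matched["faller"] == 1, cov].to_numpy(dtype=float),
                matched.loc[matched["faller"] == 0, cov].to_numpy(dtype=float),
                binary,
            )
        else:
            after = float("nan")
        rows[cov] = {"smd_before": before, "smd_after": after}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def welch_compare(
    features: pd.DataFrame,
    match: MatchResult,
    group_col: str = "faller",
    bh_extra: bool = True,
) -> pd.DataFrame:
    """Welch t-tests of every metric between matched groups, per condition.

    ``features`` is the trial-averaged table with one row per participant x
    condition (columns: participant_id, condition, faller, metrics...).
    Returns one row per (condition, metric) with group means, Welch t,
    Satterthwaite df and the two-tailed p, interpreted descriptively (no
    multiplicity correction); a Benjamini-Hochberg column is appended as
    clearly-labeled optional extra output.
    """
    ids = set(match.matched_ids)
    sub = features[features["participant_id"].isin(ids)]
    metric_cols = [
        c for c in features.columns if c not in ("participant_id", "condition", group_col)
    ]
    rows = []
    for cond, block in sub.groupby("condition"):
        g1 = block[block[group_col] == 1]
        g0 = block[block[group_col] == 0]
        for metric in metric_cols:
            x1 = g1[metric].dropna().to_numpy(dtype=float)
            x0 = g0[metric].dropna().to_numpy(dtype=float)
            if len(x1) < 2 or len(x0) < 2:
                rows.append(
                    {
                        "condition": cond, "metric": metric,
                        "mean_fallers": np.nan, "mean_nonfallers": np.nan,
                        "t": np.nan, "df": np.nan, "p": np.nan,
                        "flag": "group with n < 2",
                    }
                )
                continue
            res = stats.ttest_ind(x1, x0, equal_var=False)
            rows.append(
                {
                    "condition": cond, "metric": metric,
                    "mean_fallers": float(np.mean(x1)),
                    "mean_nonfallers": float(np.mean(x0)),
                    "t": float(res.statistic), "df": float(res.df),
                    "p": float(res.pvalue), "flag": "",
                }
            )
    out = pd.DataFrame(rows)
    if bh_extra and len(out):
        # non-primary extra column: BH-adjusted p within each condition
        out["p_bh_extra"] = np.nan
        for cond, block in out.groupby("condition"):
            mask = block["p"].notna()
            if mask.any():
                from statsmodels.stats.multitest import multipletests

                adj = multipletests(block.loc[mask, "p"], method="fdr_bh")[1]
                out.loc[block.index[mask], "p_bh_extra"] = adj
    return out


def sensitivity_analyses(
    features: pd.DataFrame,
    records: Sequence[ParticipantRecord],
    fit: PropensityFit,
    covariates: Sequence[str] = PS_COVARIATES,
    n_strata: int = 5,
    group_col: str = "faller",
) -> pd.DataFrame:
    """Covariate-adjusted and propensity-stratified group-difference estimates.

    Adjusted: per (condition, metric), OLS of the metric on group + the
    eight covariates over the full cohort; reports the group coefficient
    and its p-value.  Stratified: propensity-score quintile strata; the
    within-stratum faller minus non-faller mean difference is combined with
    stratum-size weights (strata containing a single group are dropped with
    a warning).
    """
    cov_df = records_frame(records)
    metric_cols = [
        c for c in features.columns if c not in ("participant_id", "condition", group_col)
    ]
    try:
        strata = pd.qcut(fit.ps.loc[cov_df.index], q=n_strata, labels=False, duplicates="drop")
    except ValueError:
        strata = pd.Series(0, index=cov_df.index)
    # strata that cannot contribute a group contrast are dropped once, up front
    viable = []
    for s in np.unique(strata):
        if cov_df.loc[strata == s, group_col].nunique() == 2:
            viable.append(s)
        else:
            warnings.warn(f"stratum {s} has a single group; dropped")

    rows = []
    for cond, block in features.groupby("condition"):
        block = block.set_index("participant_id")
        for metric in metric_cols:
            y = block[metric].astype(float)
            valid = y.dropna().index.intersection(cov_df.index)
            y = y.loc[valid]
            X = cov_df.loc[valid, [group_col] + list(covariates)].astype(float)
            adj_est = adj_p = np.nan
            if y.size > X.shape[1] + 1 and X[group_col].nunique() == 2:
                ols = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
                adj_est = float(ols.params[group_col])
                adj_p = float(ols.pvalues[group_col])
            # stratified estimate over the viable strata
            diffs, weights = [], []
            for s in viable:
                sel = valid[strata.loc[valid] == s]
                g = cov_df.loc[sel, group_col]
                if g.nunique() < 2:  # can still degenerate through missing values
                    continue
                diffs.append(y.loc[sel][g == 1].mean() - y.loc[sel][g == 0].mean())
                weights.append(len(sel))
            strat_est = (
                float(np.average(diffs, weights=weights)) if diffs else np.nan
            )
            rows.append(
                {
                    "condition": cond, "metric": metric,
                    "adjusted_estimate": adj_est, "adjusted_p": adj_p,
                    "stratified_estimate": strat_est,
                    "n_strata_used": len(diffs),
                }
            )
    return pd.DataFrame(rows)
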