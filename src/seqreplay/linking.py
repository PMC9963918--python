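"""Linking trial-wise sequenceness to task variables.

Planning-period current-world forward sequenceness is regressed on a
different-vs-same start-state indicator (the benefit-of-planning contrast)
and on model-predicted mean state value; feedback-period other-world
backward sequenceness is regressed on the rarity of recent other-world
experience.  Null-expected cells are backed by TOST equivalence tests,
current-vs-other contrasts and planning-vs-feedback contrasts by one-tailed
z tests on coefficient differences, and the across-participant trade-off
between the two signatures by a Pearson correlation.  A within-participant
median split of pre-world-change feedback replay feeds the replay-modulated
choice model.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .behavior import rarity_series, value_trajectory
from .stats import _result_frame, tost_equivalence

__all__ = [
    "build_regressor_table", "link_glm", "lag_profile",
    "across_participant_correlation", "dissociation_test",
    "replay_split_labels",
]

logger = logging.getLogger(__name__)


def build_regressor_table(choices: pd.DataFrame, fits=None,
                          rarity_rate: float = 0.10,
                          n_worlds: int = 2) -> pd.DataFrame:
    """Per-trial covariates for the replay regressions.

    ``choices`` must carry the covariates from
    :func:`seqreplay.stats.derive_trial_covariates`.  ``fits`` maps
    participant id to a :class:`~seqreplay.behavior.FitResult` (or
    ``AgentParams``); when given, model-predicted mean state value and reward
    prediction error are recomputed from the fitted parameters.  Rarity
    columns are the pre-trial exponentially weighted traces (rate 0.10) of
    the current and the other world.
    """
    out = []
    for pid, grp in choices.groupby("participant", sort=False):
        grp = grp.sort_values("trial").copy()
        f = rarity_series(grp["world"].to_numpy(int), n_worlds, rarity_rate)
        rarity = 1.0 - f
        w = grp["world"].to_numpy(int)
        grp["rarity_current"] = rarity[np.arange(len(grp)), w]
        # valid for the 2-world task; generalize with care
        grp["rarity_other"] = rarity[np.arange(len(grp)), 1 - w]
        grp["other_world_gap"] = 1.0 - grp["world_change"]
        if fits is not None:
            fit = fits[pid]
            params = getattr(fit, "estimates", fit)
            model = getattr(fit, "model", "hybrid")
            traj = value_trajectory(grp, params, model)
            if len(traj) != len(grp):
                raise ValueError("value trajectory misaligned with trials")
            grp["mean_state_value"] = traj["mean_value"].to_numpy()
            grp["rpe"] = traj["rpe"].to_numpy()
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _zscore_within(df: pd.DataFrame, col: str, by: str = "participant") -> pd.Series:
    def z(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)
    return df.groupby(by, sort=False)[col].transform(z)


def link_glm(scores: pd.DataFrame, table: pd.DataFrame, regressors,
             score_col: str = "score", tost_terms=(), tost_bound: float = 0.5,
             random_slope: bool = False, standardize: bool = True) -> pd.DataFrame:
    """Multilevel regression of trial-wise sequenceness on task regressors.

    ``scores`` has columns participant, trial and ``score_col``; scores are
    z-scored within participant before fitting, and (with ``standardize``)
    continuous regressors are z-scored within participant too, so all
    coefficients are on an approximately standardized (per-SD) scale -
    binary indicators are left as 0/1.  Constant regressors are dropped with
    a log message.  Terms in ``tost_terms`` additionally get a TOST
    equivalence p against ``tost_bound`` (columns ``tost_p``/``tost_bound``).
    """
    df = scores.merge(table, on=["participant", "trial"], how="inner")
    if len(df) != len(scores):
        logger.info("dropped %d score rows without matching covariates",
                    len(scores) - len(df))
    df = df.dropna(subset=list(regressors)).copy()
    df["_score_z"] = _zscore_within(df, score_col)
    if standardize:
        for r in regressors:
            vals = df[r].dropna().unique()
            if not set(np.round(vals, 12)).issubset({0.0, 1.0}):
                df[r] = _zscore_within(df, r)
    kept = [r for r in regressors if df[r].nunique() > 1]
    for r in set(regressors) - set(kept):
        logger.warning("dropping constant regressor %s", r)
    formula = "_score_z ~ " + " + ".join(kept)
    res = None
    if df["participant"].nunique() >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                re_formula = ("~" + kept[0]) if (random_slope and kept) else None
                md = smf.mixedlm(formula, df, groups=df["participant"],
                                 re_formula=re_formula)
                fit = md.fit(reml=True)
            k = len(fit.fe_params)
            if np.all(np.isfinite(fit.bse.to_numpy()[:k])):
                res = _result_frame(list(fit.fe_params.index),
                                    fit.fe_params.to_numpy(),
                                    fit.bse.to_numpy()[:k],
                                    "mixedlm")
        except Exception as err:  # noqa: BLE001
            logger.info("mixedlm failed (%s); cluster-robust OLS fallback", err)
    if res is None:
        if df["participant"].nunique() >= 2:
            ols = smf.ols(formula, df).fit(
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(df["participant"])[0]})
            engine = "ols_cluster_robust"
        else:
            ols = smf.ols(formula, df).fit()
            engine = "ols_single_participant"
        res = _result_frame(list(ols.params.index), ols.params.to_numpy(),
                            ols.bse.to_numpy(), engine)
    res["tost_p"] = np.nan
    res["tost_bound"] = np.nan
    for term in tost_terms:
        row = res["term"] == term
        if row.any():
            t = tost_equivalence(float(res.loc[row, "estimate"].iloc[0]),
                                 float(res.loc[row, "se"].iloc[0]), tost_bound)
            res.loc[row, "tost_p"] = t["p_equiv"]
            res.loc[row, "tost_bound"] = tost_bound
    return res


def lag_profile(scores_by_lag: dict, table: pd.DataFrame, regressor: str,
                score_col: str = "score") -> pd.DataFrame:
    """Linking coefficient for one regressor at each lag (10-130 ms style plot)."""
    rows = []
    for lag_ms in sorted(scores_by_lag):
        res = link_glm(scores_by_lag[lag_ms], table, [regressor], score_col)
        r = res[res["term"] == regressor].iloc[0]
        rows.append((lag_ms, r["estimate"], r["se"], r["z"], r["p"]))
    return pd.DataFrame(rows, columns=["lag_ms", "estimate", "se", "z", "p"])


def across_participant_correlation(effect_a, effect_b,
                                   sidedness: str = "two-sided") -> dict:
    """Pearson correlation of two per-participant effect vectors."""
    a = np.asarray(effect_a, float)
    b = np.asarray(effect_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        return {"r": float("nan"), "p": float("nan"), "flag": "zero variance"}
    alt = {"two-sided": "two-sided", "less": "less", "greater": "greater"}[sidedness]
    res = sps.pearsonr(a, b, alternative=alt)
    return {"r": float(res.statistic), "p": float(res.pvalue),
            "sidedness": sidedness}


def dissociation_test(coef_a: float, se_a: float, coef_b: float,
                      se_b: float) -> dict:
    """One-tailed z test of coefficient a > coefficient b (independent SEs)."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (coef_a - coef_b) / np.hypot(se_a, se_b)
    return {"z": float(z), "p_one_tailed": float(sps.norm.sf(z)),
            "sidedness": "one-tailed"}


def replay_split_labels(feedback_scores: pd.DataFrame, table: pd.DataFrame,
                        score_col: str = "score") -> pd.DataFrame:
    """High/low labels for world-change choices from preceding feedback replay.

    Eligible feedback trials are those followed by a world change; the
    feedback backward sequenceness (of the next trial's world, i.e. the
    current trial's other world) is median-split within participant, ties to
    "low", and each label is attached to the *following* world-change choice
    trial.  Returns columns participant, trial (the choice trial), label.
    """
    df = feedback_scores.merge(
        table[["participant", "trial", "world_change_next"]],
        on=["participant", "trial"], how="inner")
    df = df[df["world_change_next"] == 1].copy()
    rows = []
    for pid, grp in df.groupby("participant", sort=False):
        vals = grp[score_col].to_numpy(float)
        if len(vals) == 0:
            continue
        if np.all(vals == vals[0]):
            logger.warning("participant %s: degenerate (constant) replay "
                           "scores; all labels set to 'low'", pid)
            labels = ["low"] * len(vals)
        else:
            med = np.median(vals)
            labels = ["high" if v > med else "low" for v in vals]
        for trial, lab in zip(grp["trial"], labels):
            rows.append((pid, int(trial) + 1, lab))
    return pd.DataFrame(rows, columns=["participant", "trial", "label"])
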