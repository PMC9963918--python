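"""Regression-based behavioral analyses.

The central analysis is a multilevel logistic regression of stay choices
(repeating the previously chosen path in a world) on the previous same-world
reward, a same-start-state indicator, and their interaction.  Under a
model-based controller the reward effect generalizes across equivalent start
states, so the interaction is null (supported by a TOST equivalence test);
a model-free controller produces a positive interaction.  A linear multilevel
regression quantifies the reaction-time cost of start-state changes, and
memory summaries score three-stage sequence probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "derive_trial_covariates", "stay_glm", "rt_glm",
    "tost_equivalence", "tost_bound_logodds", "memory_summary",
]

logger = logging.getLogger(__name__)


def derive_trial_covariates(data: pd.DataFrame) -> pd.DataFrame:
    """Attach stay/same-start/previous-reward covariates per participant.

    For each trial, the reference is the previous trial *in the same world*
    (not simply the previous row): ``stay`` = chose the same path, and
    ``same_start`` = same start state, as on that reference trial.
    ``prev_reward`` is the reference trial's reward, z-scored within
    participant (``prev_reward_z``).  Each world's first trial has these
    fields undefined (NaN).  Also derives ``world_change`` (world differs
    from the immediately preceding row) and ``world_change_next``.
    """
    if data["world"].isna().any():
        raise ValueError("unknown (missing) world label")
    out = []
    for pid, grp in data.groupby("participant", sort=False):
        grp = grp.sort_values("trial").copy()
        prev = grp.groupby("world", sort=False)[["path", "start_state", "reward"]].shift(1)
        grp["stay"] = (grp["path"] == prev["path"]).astype(float)
        grp["same_start"] = (grp["start_state"] == prev["start_state"]).astype(float)
        grp.loc[prev["path"].isna(), ["stay", "same_start"]] = np.nan
        grp["prev_reward"] = prev["reward"]
        mu, sd = grp["prev_reward"].mean(), grp["prev_reward"].std()
        grp["prev_reward_z"] = (grp["prev_reward"] - mu) / (sd if sd > 0 else 1.0)
        grp["different_start"] = 1.0 - grp["same_start"]
        grp["world_change"] = (grp["world"] != grp["world"].shift(1)).astype(float)
        grp.loc[grp.index[0], "world_change"] = np.nan
        grp["world_change_next"] = grp["world_change"].shift(-1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _result_frame(terms, est, se, engine, sidedness="two-sided") -> pd.DataFrame:
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    z = est / se
    p = 2 * sps.norm.sf(np.abs(z))
    res = pd.DataFrame({
        "term": terms, "estimate": est, "se": se,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        "z": z, "p": p, "sidedness": sidedness,
    })
    res.attrs["engine"] = engine
    return res


def _mixed_logit(df: pd.DataFrame, formula: str, slope_term: str | None,
                 engine: str = "auto") -> pd.DataFrame:
    """Multilevel logistic regression with a graceful fallback chain.

    Tries a variational Bayes mixed GLM with a random intercept and (if
    ``slope_term``) a random slope per participant; on failure falls back to
    a random-intercept-only model, then to a pooled logit with
    cluster-robust (by participant) standard errors.  ``engine='cluster'``
    goes straight to the robust pooled fit.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if engine == "auto":
        vcs = [{"icept": "0 + C(participant)"}]
        if slope_term:
            vcs.insert(0, {"icept": "0 + C(participant)",
                           "slope": f"0 + C(participant):{slope_term}"})
        for vc in vcs:
            label = "bayes_mixed(" + "+".join(vc) + ")"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = BinomialBayesMixedGLM.from_formula(formula, vc, df)
                    fit = md.fit_vb()
                names = md.exog_names
                k = len(names)
                est, se = fit.fe_mean[:k], fit.fe_sd[:k]
                if np.all(np.isfinite(est)) and np.all(se > 0):
                    return _result_frame(names, est, se, label)
            except Exception as err:  # noqa: BLE001 - fall through the chain
                logger.info("mixed logit engine %s failed (%s); falling back",
                            label, err)
    glm = smf.logit(formula, df).fit(
        disp=0, cov_type="cluster",
        cov_kwds={"groups": pd.factorize(df["participant"])[0]})
    return _result_frame(list(glm.params.index), glm.params.to_numpy(),
                         glm.bse.to_numpy(), "logit_cluster_robust")


def stay_glm(data: pd.DataFrame, engine: str = "auto") -> pd.DataFrame:
    """Stay ~ previous reward x same start state, grouped by participant.

    Expects the covariates from :func:`derive_trial_covariates`; rows with
    undefined covariates (each world's first trial) are dropped.
    """
    need = ["stay", "prev_reward_z", "same_start", "participant"]
    df = data.dropna(subset=need[:3]).copy()
    return _mixed_logit(df, "stay ~ prev_reward_z * same_start",
                        slope_term="prev_reward_z", engine=engine)


def rt_glm(data: pd.DataFrame) -> pd.DataFrame:
    """Reaction time ~ different-vs-same start, random intercept per participant.

    Nonpositive RTs are dropped (count logged).  With a single participant
    the model degrades to an ordinary regression, flagged via the result's
    ``engine`` attribute.
    """
    df = data.dropna(subset=["rt", "different_start"]).copy()
    n_bad = int((df["rt"] <= 0).sum())
    if n_bad:
        logger.warning("dropping %d nonpositive RTs", n_bad)
        df = df[df["rt"] > 0]
    if df["participant"].nunique() < 2:
        ols = smf.ols("rt ~ different_start", df).fit()
        return _result_frame(list(ols.params.index), ols.params.to_numpy(),
                             ols.bse.to_numpy(), "ols_single_participant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("rt ~ different_start", df, groups=df["participant"])
        fit = md.fit(reml=True)
    k = len(fit.fe_params)
    return _result_frame(list(fit.fe_params.index), fit.fe_params.to_numpy(),
                         fit.bse.to_numpy()[:k], "mixedlm_random_intercept")


def tost_bound_logodds(d: float = 0.5, sd_x: float = 1.0) -> float:
    """Map a standardized effect size d to a log-odds bound (d * pi/sqrt(3) * sd_x)."""
    return d * np.pi / np.sqrt(3.0) * sd_x


def tost_equivalence(estimate: float, se: float, bound: float) -> dict:
    """Two one-sided tests against symmetric bounds (-bound, +bound).

    Returns the equivalence p (max of the two one-sided normal p values); a
    small p rejects effects at least as large as the bound.
    """
    if bound <= 0:
        raise ValueError("equivalence bound must be positive")
    if se <= 0:
        raise ValueError("standard error must be positive")
    p_lower = sps.norm.sf((estimate + bound) / se)   # H0: effect <= -bound
    p_upper = sps.norm.cdf((estimate - bound) / se)  # H0: effect >= +bound
    return {"p_equiv": float(max(p_lower, p_upper)),
            "p_lower": float(p_lower), "p_upper": float(p_upper),
            "bound": float(bound)}


def memory_summary(probes: pd.DataFrame, n_stages: int = 3,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """Score three-stage sequence memory probes.

    A probe is correct only when every stage selection is correct.  Probes
    missing a stage are excluded (count logged).  Returns overall and
    per-block percent correct with participant-level bootstrap 95% CIs, and
    mean confidence if present.
    """
    grp = probes.groupby(["participant", "block", "probe"])
    counts = grp["correct"].count()
    complete = counts[counts == n_stages].index
    n_dropped = int((counts != n_stages).sum())
    if n_dropped:
        logger.warning("excluding %d incomplete probes", n_dropped)
    correct = grp["correct"].min().loc[complete].rename("probe_correct")
    per_part = correct.groupby("participant").mean() * 100.0
    rng = np.random.default_rng(seed)
    vals = per_part.to_numpy()
    boots = rng.choice(vals, size=(n_boot, len(vals))).mean(axis=1)
    per_block = (correct.groupby("block").mean() * 100.0).to_dict()
    out = {
        "percent_correct": float(per_part.mean()),
        "ci95": [float(np.percentile(boots, 2.5)),
                 float(np.percentile(boots, 97.5))],
        "per_block_percent": per_block,
        "n_excluded_probes": n_dropped,
    }
    if "confidence" in probes.columns:
        conf = probes.groupby(["participant", "block", "probe"])["confidence"].first()
        out["mean_confidence"] = float(conf.loc[complete].mean())
    return out
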