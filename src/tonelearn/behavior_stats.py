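"""Behavioral statistics for the tone-learning task.

Implements the full behavioral analysis battery: trial-level binomial-logit
mixed models of learning (group x trial with subject and tone random
intercepts), the generalization-block model (group x block against Block 1),
between-block retention of correct stimulus-response associations and its
linear mixed model, false-positive rates for target tone sets, per-subject
accuracy-improvement summaries, the Monte-Carlo comparison of a group mean
against resampled sub-populations of the aggregate cohort, psychometric
slope fitting for the tone-continuum identification task, and classical
one-way ANOVA / two-sample t utilities.

Trial tables are long-format DataFrames; see
:data:`tonelearn.synthgen.TRIAL_COLUMNS` for the column dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .glmm import MixedModelFit, fit_binomial_glmm

__all__ = [
    "fit_trial_glmm",
    "fit_generalization_glmm",
    "compute_retention",
    "fit_retention_lmm",
    "false_positive_rate",
    "mean_accuracy_improvement",
    "aggregate_improvement",
    "monte_carlo_group_p",
    "fit_psychometric_slope",
    "oneway_anova",
    "two_sample_t",
    "PsychometricFit",
    "AnovaResult",
]


# ---------------------------------------------------------------------------
# mixed models over trial outcomes
# ---------------------------------------------------------------------------

def fit_trial_glmm(
    trials: pd.DataFrame,
    fixed: tuple[str, ...] = ("group", "trial", "group:trial"),
    random: tuple[str, ...] = ("participant", "tone"),
    reference_levels: dict | None = None,
    tones: set[str] | None = None,
) -> MixedModelFit:
    """Trial-by-trial learning model: outcome ~ group*trial + (1|subject) + (1|tone).

    Restricted to the training phase.  ``tones`` optionally restricts the
    analysis to a tone subset (e.g. only the stimulation-paired categories).
    The Control group is the default reference level, so the
    ``group[...]:trial`` interaction terms test each group's per-trial
    learning-rate advantage over unstimulated training.
    """
    refs = {"group": "Control"} | dict(reference_levels or {})
    data = trials[trials["phase"] == "training"]
    if tones is not None:
        data = data[data["tone"].isin(tones)]
    data = data.reset_index(drop=True)
    return fit_binomial_glmm(data, "outcome", list(fixed), list(random), refs)


def fit_generalization_glmm(
    trials: pd.DataFrame,
    reference_levels: dict | None = None,
) -> MixedModelFit:
    """Generalization model: outcome ~ group*block + (1|subject) + (1|tone).

    Uses only Block 1 and the generalization block, with Block 1 as the
    block reference: group main effects test baseline differences at the
    start of training, group x block interactions test generalization gains.
    """
    first = trials[(trials["phase"] == "training") & (trials["block"] == 1)]
    gen = trials[trials["phase"] == "generalization"]
    if gen.empty:
        raise ValueError("trial table has no generalization block")
    data = pd.concat([first, gen]).reset_index(drop=True)
    data["blockcat"] = np.where(data["phase"] == "generalization", "gen", "block1")
    refs = {"group": "Control", "blockcat": "block1"} | dict(reference_levels or {})
    return fit_binomial_glmm(
        data,
        "outcome",
        ["group", "blockcat", "group:blockcat"],
        ["participant", "tone"],
        refs,
    )


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def compute_retention(trials: pd.DataFrame) -> pd.DataFrame:
    """Percent of training stimuli answered correctly in blocks n and n-1.

    Returns one row per participant and block n >= 2 with columns
    ``participant, group, block, retention`` (percent in [0, 100]).  The
    generalization block is excluded because it uses different stimuli.
    """
    train = trials[trials["phase"] == "training"].copy()
    if train["block"].nunique() < 2:
        raise ValueError("retention requires at least two training blocks")
    train["stim_id"] = (
        train["syllable"].astype(str)
        + "/"
        + train["talker"].astype(str)
        + "/"
        + train["tone"].astype(str)
    )
    n_stimuli = train["stim_id"].nunique()
    counts = train.groupby(["participant", "block"])["stim_id"].nunique()
    sizes = train.groupby(["participant", "block"])["stim_id"].size()
    if not ((counts == n_stimuli) & (sizes == n_stimuli)).all():
        raise ValueError(
            "each training stimulus must appear exactly once per block per participant"
        )
    rows = []
    for (participant, group), sub in train.groupby(["participant", "group"], sort=True):
        by_block = {
            b: set(blk.loc[blk["outcome"] == 1, "stim_id"])
            for b, blk in sub.groupby("block")
        }
        blocks = sorted(by_block)
        for prev, cur in zip(blocks, blocks[1:]):
            kept = by_block[cur] & by_block[prev]
            rows.append((participant, group, cur, 100.0 * len(kept) / n_stimuli))
    return pd.DataFrame(rows, columns=["participant", "group", "block", "retention"])


def fit_retention_lmm(
    retention: pd.DataFrame,
    reference_levels: dict | None = None,
) -> MixedModelFit:
    """Linear mixed model: retention ~ group*block + (1|subject).

    Block is categorical with block 2 (the first defined retention block)
    as the reference level; the group x block interactions test, per block,
    whether a stimulation group retained more associations than Control.
    Wald statistics are reported on the z scale (coef / se).
    """
    refs = {"group": "Control", "block": 2} | dict(reference_levels or {})
    data = retention.copy()
    data["block"] = data["block"].astype(int)
    formula = (
        f"retention ~ C(group, Treatment('{refs['group']}'))"
        f" * C(block, Treatment({refs['block']}))"
    )
    diagnostics: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant"])
        try:
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"LMM fit failed: {exc}")
            nan = pd.Series(dtype=float)
            return MixedModelFit(
                formula="retention ~ group*block + (1|subject)",
                params=nan, bse=nan, z=nan, p=nan,
                converged=False, vc={}, reference_levels=refs,
                diagnostics=diagnostics, method="reml-lmm",
            )
    names = {
        name: _clean_lmm_term(name) for name in fit.fe_params.index
    }
    params = fit.fe_params.rename(names)
    bse = fit.bse_fe.rename(names)
    z = params / bse
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)
    if not converged:
        diagnostics.append("LMM did not converge")
    return MixedModelFit(
        formula="retention ~ group*block + (1|subject)",
        params=params,
        bse=bse,
        z=z,
        p=p,
        converged=converged,
        vc={
            "participant": float(np.asarray(fit.cov_re)[0, 0]),
            "residual": float(fit.scale),
        },
        reference_levels=refs,
        diagnostics=diagnostics,
        method="reml-lmm",
    )


def _clean_lmm_term(name: str) -> str:
    """Map statsmodels patsy term names onto the package's compact style."""
    out = name
    out = out.replace("C(group, Treatment('Control'))", "group")
    out = out.replace("C(block, Treatment(2))", "block")
    out = out.replace("C(session, Treatment('pre'))", "session")
    out = out.replace("[T.", "[").replace("]", "]")
    return out


# ---------------------------------------------------------------------------
# false positives and improvement summaries
# ---------------------------------------------------------------------------

def false_positive_rate(
    trials: pd.DataFrame,
    target_tones: set[str] = frozenset({"T1", "T3"}),
    denominator: str = "nontarget",
) -> pd.DataFrame:
    """Percent of non-target-tone trials answered with a target tone.

    A false positive for the target set is a trial whose true tone is
    outside the set but whose response falls inside it.  By default the
    denominator is the non-target-tone trials; ``denominator="all"`` uses
    all trials instead.  Returns per group/block percentages; a group/block
    with an empty denominator yields ``NaN``.
    """
    if denominator not in {"nontarget", "all"}:
        raise ValueError("denominator must be 'nontarget' or 'all'")
    data = trials[trials["phase"] == "training"].copy()
    data["is_fp"] = (
        ~data["tone"].isin(target_tones) & data["response"].isin(target_tones)
    )
    rows = []
    for (group, block), sub in data.groupby(["group", "block"], sort=True):
        denom = sub if denominator == "all" else sub[~sub["tone"].isin(target_tones)]
        pct = 100.0 * sub["is_fp"].sum() / len(denom) if len(denom) else np.nan
        rows.append((group, block, pct, len(denom)))
    return pd.DataFrame(rows, columns=["group", "block", "fp_pct", "n_denominator"])


def mean_accuracy_improvement(
    trials: pd.DataFrame, method: str = "mean_gain"
) -> pd.Series:
    """Per-participant accuracy improvement in percentage points.

    ``mean_gain`` (default) is the mean over blocks b >= 2 of
    (accuracy_b - accuracy_1); ``last_minus_first`` is the last block's
    gain over Block 1.
    """
    if method not in {"mean_gain", "last_minus_first"}:
        raise ValueError("method must be 'mean_gain' or 'last_minus_first'")
    train = trials[trials["phase"] == "training"]
    if train["block"].nunique() < 2:
        raise ValueError("improvement requires at least two training blocks")
    acc = (
        train.groupby(["participant", "block"])["outcome"].mean().unstack("block")
        * 100.0
    )
    gains = acc.drop(columns=acc.columns[0]).sub(acc.iloc[:, 0], axis=0)
    out = gains.mean(axis=1) if method == "mean_gain" else gains.iloc[:, -1]
    out.name = "improvement_pct"
    out.attrs["definition"] = (
        "mean over blocks >= 2 of (accuracy_b - accuracy_1), percentage points"
        if method == "mean_gain"
        else "last-block accuracy minus Block-1 accuracy, percentage points"
    )
    return out


def aggregate_improvement(aggregate: pd.DataFrame) -> pd.Series:
    """Per-learner mean accuracy improvement from an aggregate block table."""
    acc = aggregate.pivot(index="learner", columns="block", values="accuracy_pct")
    gains = acc.drop(columns=acc.columns[0]).sub(acc.iloc[:, 0], axis=0)
    out = gains.mean(axis=1)
    out.name = "improvement_pct"
    return out


def monte_carlo_group_p(
    aggregate: pd.DataFrame,
    group_mean: float,
    n_draws: int = 1000,
    group_size: int = 12,
    seed: int | None = None,
) -> float:
    """Monte-Carlo probability that a random aggregate sub-population
    improves at least as much as the observed group.

    Draws ``n_draws`` sub-populations of ``group_size`` learners without
    replacement from the aggregate improvement distribution and returns the
    proportion of sub-population means at or above ``group_mean`` (one-sided
    upper tail; ties count as exceeding).
    """
    improvements = aggregate_improvement(aggregate).to_numpy()
    if group_size > improvements.size:
        raise ValueError(
            f"group_size {group_size} exceeds aggregate size {improvements.size}"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(n_draws)
    for i in range(n_draws):
        means[i] = improvements[
            rng.choice(improvements.size, size=group_size, replace=False)
        ].mean()
    return float(np.mean(means >= group_mean))


# ---------------------------------------------------------------------------
# psychometric slope
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    """Logistic identification curve over a stimulus continuum."""

    proportions: pd.Series  # P("rising") per step
    slope: float  # |beta| of the logistic regression on step index
    boundary: float  # step index where P = 0.5
    converged: bool
    diagnostics: list = field(default_factory=list)


def fit_psychometric_slope(step_responses: pd.DataFrame) -> PsychometricFit:
    """Fit the identification curve from per-step binary responses.

    ``step_responses`` needs columns ``step`` (ordinal continuum index) and
    ``response`` (1 = "rising").  The perceptual-acuity metric is the
    absolute logistic slope; steeper means a more categorical boundary.
    Perfectly separated data (a step-function responder) cannot bound the
    slope, so the fit is flagged and the optimizer-bound estimate returned.
    """
    if step_responses["step"].nunique() < 2:
        raise ValueError("need responses at >= 2 continuum steps")
    x = sm.add_constant(step_responses["step"].to_numpy(dtype=float))
    yv = step_responses["response"].to_numpy(dtype=float)
    diagnostics: list[str] = []
    props = step_responses.groupby("step")["response"].mean()
    if yv.min() == yv.max():
        return PsychometricFit(
            proportions=props,
            slope=0.0,
            boundary=np.nan,
            converged=False,
            diagnostics=["all responses identical; slope unidentified"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(yv, x, family=sm.families.Binomial()).fit(maxiter=100)
            intercept, beta = res.params
            converged = bool(res.converged)
        except Exception as exc:
            diagnostics.append(f"logistic fit failed: {exc}")
            intercept, beta, converged = np.nan, np.nan, False
    if np.isfinite(beta) and abs(beta) > 10:
        diagnostics.append("separation: slope at optimizer bound")
        converged = False
    boundary = -intercept / beta if beta not in (0.0,) and np.isfinite(beta) else np.nan
    return PsychometricFit(
        proportions=props,
        slope=float(abs(beta)) if np.isfinite(beta) else np.inf,
        boundary=float(boundary) if np.isfinite(boundary) else np.nan,
        converged=converged,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    posthoc: pd.DataFrame | None = None


def oneway_anova(
    values: np.ndarray, labels: np.ndarray, posthoc: bool = False
) -> AnovaResult:
    """Classical one-way ANOVA with explicit degrees of freedom.

    With ``posthoc=True`` a Tukey HSD table over group pairs is attached.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    F, p = stats.f_oneway(*groups)
    result = AnovaResult(
        F=float(F),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=values.size - len(groups),
    )
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(values, labels)
        result.posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return result


def two_sample_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, int]:
    """Two-sample t-test (pooled variance); returns (t, p, df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p), a.size + b.size - 2
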