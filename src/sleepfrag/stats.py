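"""Cohort-level statistical comparison with mixed-effects models.

Group and predictor effects on fragmentation outcomes are estimated with
linear mixed-effects models (LME): a family-ID random intercept absorbs
within-family correlation for patient-vs-sibling comparisons, and a
participant-ID random intercept accounts for repeated measures in the
split-night models. Numerical fitting is delegated to
:mod:`statsmodels` (``MixedLM``; ordinary least squares for the
patients-only predictor models, where subjects are unrelated); the layer
here owns the model specification, the effect-size derivation and the
multiple-testing scheme:

* effects are reported as the fixed-effect coefficient (β) with a 95% Wald
  confidence interval and p-value;
* standardized effect size (Cohen's d) = coefficient / residual standard
  deviation of the model;
* outcomes are natural-log transformed when the residual-skewness proxy for
  non-normality fires (``|skew| > 1`` by default) — a mechanization of the
  usual Q-Q plot inspection;
* the per-cell transition-probability grid (5 x 5 cells x resolutions, 50
  models at the two canonical resolutions) is corrected jointly with the
  Benjamini-Hochberg step-up procedure at FDR 0.05; exploratory predictor
  models are deliberately left uncorrected.

A random-effect variance estimated at (or collapsing to) zero degrades
gracefully to the fixed-effects model with a logged notice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .markov import STAGE_LABELS

logger = logging.getLogger(__name__)

RESOLUTIONS = ("epoch30", "miniepoch5")


@dataclass
class ModelResult:
    """One fitted fixed-effect contrast."""

    outcome_name: str
    term: str
    coefficient: float
    ci95_low: float
    ci95_high: float
    p_value: float
    cohens_d: float
    residual_sd: float
    n_subjects: int
    n_observations: int
    transformed_flag: bool
    model_descriptor: str

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "term": self.term,
            "coefficient": self.coefficient,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p_value": self.p_value,
            "cohens_d": self.cohens_d,
            "residual_sd": self.residual_sd,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "transformed": self.transformed_flag,
            "model": self.model_descriptor,
        }


def maybe_log_transform(
    values: pd.Series | np.ndarray,
    policy: str = "auto",
    skew_threshold: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Natural-log transform an outcome column under the stated policy.

    ``auto`` transforms when the skewness proxy for non-normality fires
    (|skew| above threshold) and all values are strictly positive;
    nonpositive values under ``auto`` fall back to identity with a logged
    notice. ``always`` requires strictly positive values. ``never`` is the
    identity.
    """
    vals = np.asarray(values, dtype=float)
    if policy == "never":
        return vals, False
    positive = bool(np.all(vals > 0))
    if policy == "always":
        if not positive:
            raise ValueError("log transform requires strictly positive values")
        return np.log(vals), True
    if policy != "auto":
        raise ValueError(f"unknown transform policy {policy!r}")
    skew = scipy.stats.skew(vals, bias=False) if vals.size > 2 else 0.0
    if abs(skew) > skew_threshold:
        if not positive:
            logger.info(
                "auto log transform skipped: nonpositive values present "
                "(skew %.2f)", skew,
            )
            return vals, False
        return np.log(vals), True
    return vals, False


def benjamini_hochberg(
    p_values, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(rejected, adjusted_p)``; adjusted p-values are monotone
    nondecreasing in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric-code the standard categorical covariates for modelling."""
    out = df.copy()
    if "group" in out.columns and out["group"].dtype == object:
        out["group"] = (out["group"] == "patient").astype(float)
    if "sex" in out.columns and out["sex"].dtype == object:
        out["sex"] = (out["sex"] == "M").astype(float)
    if "half" in out.columns and out["half"].dtype == object:
        out["half"] = (out["half"] == "second").astype(float)
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(float)
    return out


def _check_design(df: pd.DataFrame, columns: list[str]) -> None:
    X = df[columns].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        base = np.ones((len(X), 1))
        for j, col in enumerate(columns):
            cand = np.column_stack([base, X[:, j + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                collinear.append(col)
            else:
                base = cand
        raise ValueError(f"singular design; collinear columns: {collinear}")


def fit_group_comparison(
    table: pd.DataFrame,
    outcome: str,
    term: str = "group",
    fixed_covariates: tuple[str, ...] = ("age_years", "sex"),
    random_term: str | None = "family_id",
    transform_policy: str = "auto",
    skew_threshold: float = 1.0,
) -> ModelResult:
    """Fit one LME (or OLS) contrast and derive the standardized effect.

    ``term`` is the fixed effect of interest (reported); other
    ``fixed_covariates`` adjust. ``random_term`` names the random-intercept
    grouping column (``None`` → plain multiple regression). Under the
    ``auto`` transform policy the outcome is log-transformed and refitted
    when the residual skewness of the initial fit exceeds the threshold.
    """
    predictors = [term] + [c for c in fixed_covariates if c != term]
    needed = [outcome] + predictors + ([random_term] if random_term else [])
    df = table[needed].dropna().reset_index(drop=True)
    df = _encode(df)
    if df[outcome].nunique() <= 1:
        raise ValueError(f"outcome {outcome!r} is constant; nothing to model")
    if df[term].nunique() < 2:
        raise ValueError(f"term {term!r} has fewer than 2 levels after exclusions")
    _check_design(df, predictors)

    y, transformed = df[outcome].to_numpy(dtype=float), False
    formula = f"Q('{outcome}') ~ " + " + ".join(f"Q('{c}')" for c in predictors)

    def _fit(frame: pd.DataFrame):
        if random_term is None:
            res = smf.ols(formula, data=frame).fit()
            return res, "ols"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = smf.mixedlm(
                    formula, data=frame, groups=frame[random_term]
                ).fit(reml=True, method="lbfgs")
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is None or not np.isfinite(res.params).all():
            logger.info(
                "mixed model for %s failed to converge; falling back to OLS",
                outcome,
            )
            return smf.ols(formula, data=frame).fit(), "ols-fallback"
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        if re_var <= 1e-10 * max(res.scale, 1e-300):
            logger.info(
                "random-effect variance for %s estimated at zero; "
                "degrading to fixed-effects model", outcome,
            )
            return smf.ols(formula, data=frame).fit(), "ols-degenerate-re"
        return res, "lme"

    result, kind = _fit(df)
    if transform_policy in ("auto", "always"):
        if transform_policy == "always":
            do_log = True
        else:
            resid = np.asarray(result.resid)
            do_log = abs(scipy.stats.skew(resid, bias=False)) > skew_threshold
        if do_log:
            if np.all(y > 0):
                df = df.assign(**{outcome: np.log(y)})
                result, kind = _fit(df)
                transformed = True
            elif transform_policy == "always":
                raise ValueError(
                    "log transform requires strictly positive values"
                )
            else:
                logger.info(
                    "auto log transform for %s skipped: nonpositive values",
                    outcome,
                )

    pname = f"Q('{term}')"
    coef = float(result.params[pname])
    ci = result.conf_int()
    ci_low, ci_high = float(ci.loc[pname, 0]), float(ci.loc[pname, 1])
    p = float(result.pvalues[pname])
    resid_sd = float(np.sqrt(result.scale))
    # one row per subject unless the random term is the participant itself
    n_subj = df[random_term].nunique() if random_term == "subject_id" else len(df)
    descriptor = (
        f"{kind}: {outcome} ~ {' + '.join(predictors)}"
        + (f" + (1|{random_term})" if random_term and kind == "lme" else "")
        + "; Wald CI"
    )
    return ModelResult(
        outcome_name=outcome,
        term=term,
        coefficient=coef,
        ci95_low=ci_low,
        ci95_high=ci_high,
        p_value=p,
        cohens_d=coef / resid_sd,
        residual_sd=resid_sd,
        n_subjects=int(n_subj),
        n_observations=len(df),
        transformed_flag=transformed,
        model_descriptor=descriptor,
    )


# -- transition-probability grid -------------------------------------------


@dataclass
class ComparisonGrid:
    """Per-cell group comparisons of transition probabilities with joint BH."""

    cells: dict[tuple[str, str, str], ModelResult]
    bh_rejected: dict[tuple[str, str, str], bool]
    adjusted_p: dict[tuple[str, str, str], float]
    unfit: dict[tuple[str, str, str], str]
    n_models: int
    fdr_q: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, res in self.cells.items():
            resolution, frm, to = key
            rows.append(
                {
                    "resolution": resolution,
                    "from_stage": frm,
                    "to_stage": to,
                    **res.to_row(),
                    "adjusted_p": self.adjusted_p.get(key, np.nan),
                    "bh_rejected": self.bh_rejected.get(key, False),
                    "unfit": False,
                }
            )
        for key, reason in self.unfit.items():
            resolution, frm, to = key
            rows.append(
                {
                    "resolution": resolution,
                    "from_stage": frm,
                    "to_stage": to,
                    "unfit": True,
                    "model": reason,
                }
            )
        return pd.DataFrame(rows)


def compare_transition_probabilities(
    long_table: pd.DataFrame,
    cohort: pd.DataFrame,
    fixed_covariates: tuple[str, ...] = ("age_years", "sex"),
    random_term: str = "family_id",
    fdr_q: float = 0.05,
    min_subjects: int = 10,
    transform_policy: str = "never",
) -> ComparisonGrid:
    """One group LME per matrix cell per resolution, BH over the whole grid.

    ``long_table`` is the long-format matrix export (subject_id, resolution,
    from_stage, to_stage, prob). Subjects whose originating-stage row is
    undefined (NaN probability) are excluded from that cell only. Cells with
    fewer than ``min_subjects`` subjects after exclusions are marked unfit
    and excluded from the BH family with a logged count.
    """
    resolutions = [r for r in RESOLUTIONS if r in set(long_table["resolution"])]
    if not resolutions:
        resolutions = sorted(set(long_table["resolution"]))
    if len(resolutions) < 2:
        logger.info("grid restricted to resolutions %s", resolutions)
    cells: dict[tuple[str, str, str], ModelResult] = {}
    unfit: dict[tuple[str, str, str], str] = {}
    for resolution in resolutions:
        sub = long_table[long_table["resolution"] == resolution]
        for frm in STAGE_LABELS:
            for to in STAGE_LABELS:
                key = (resolution, frm, to)
                cell = sub[
                    (sub["from_stage"] == frm) & (sub["to_stage"] == to)
                ][["subject_id", "prob"]].dropna()
                merged = cell.merge(cohort, on="subject_id", how="inner")
                if len(merged) < min_subjects:
                    unfit[key] = f"unfit: {len(merged)} subjects < {min_subjects}"
                    continue
                try:
                    cells[key] = fit_group_comparison(
                        merged,
                        outcome="prob",
                        term="group",
                        fixed_covariates=fixed_covariates,
                        random_term=random_term,
                        transform_policy=transform_policy,
                    )
                    cells[key].outcome_name = f"P({frm}->{to})"
                except ValueError as exc:
                    unfit[key] = f"unfit: {exc}"
    if unfit:
        logger.info("%d grid cells unfit, excluded from BH family", len(unfit))
    keys = list(cells)
    rejected, adjusted = benjamini_hochberg(
        [cells[k].p_value for k in keys], q=fdr_q
    )
    return ComparisonGrid(
        cells=cells,
        bh_rejected=dict(zip(keys, (bool(r) for r in rejected))),
        adjusted_p=dict(zip(keys, (float(a) for a in adjusted))),
        unfit=unfit,
        n_models=25 * len(resolutions),
        fdr_q=fdr_q,
    )


# -- split-night repeated-measures models -----------------------------------

SPLIT_CONTRASTS = (
    "interaction",
    "half_effect_in_siblings",
    "half_effect_in_patients",
    "group_difference_first_half",
    "group_difference_second_half",
)


def split_night_model(
    long_table: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str,
    fixed_covariates: tuple[str, ...] = ("age_years", "sex"),
    transform_policy: str = "auto",
) -> dict[str, ModelResult]:
    """Night-half x group interaction model and its four post-hoc contrasts.

    ``long_table`` holds one row per subject x half with columns
    subject_id, half ∈ {first, second}, metric, value. Fits, with a
    participant random intercept for repeated measures:

    * the group x night-half interaction model;
    * within-group night-half effects (patients; siblings);
    * within-half group differences (first; second), with a family random
      intercept since each subject contributes one value per half.

    Subjects with only one half are excluded with a logged count;
    duplicated half rows are an error.
    """
    rows = long_table[long_table["metric"] == metric][
        ["subject_id", "half", "value"]
    ].copy()
    if rows.duplicated(["subject_id", "half"]).any():
        dup = rows[rows.duplicated(["subject_id", "half"])].iloc[0]
        raise ValueError(
            f"duplicated half rows for subject {dup['subject_id']!r}"
        )
    n_halves = rows.groupby("subject_id")["half"].nunique()
    complete = n_halves[n_halves == 2].index
    dropped = rows["subject_id"].nunique() - len(complete)
    if dropped:
        logger.info(
            "%d subjects excluded from %s split-night model (one half only)",
            dropped, metric,
        )
    rows = rows[rows["subject_id"].isin(complete)]
    data = rows.merge(cohort, on="subject_id", how="inner")
    enc = _encode(data)
    enc["group_x_half"] = enc["group"] * enc["half"]

    out: dict[str, ModelResult] = {}
    inter = fit_group_comparison(
        enc,
        outcome="value",
        term="group_x_half",
        fixed_covariates=("group", "half") + tuple(fixed_covariates),
        random_term="subject_id",
        transform_policy=transform_policy,
    )
    inter.outcome_name = metric
    out["interaction"] = inter

    for label, grp in (("siblings", 0.0), ("patients", 1.0)):
        sub = enc[enc["group"] == grp]
        res = fit_group_comparison(
            sub,
            outcome="value",
            term="half",
            fixed_covariates=fixed_covariates,
            random_term="subject_id",
            transform_policy=transform_policy,
        )
        res.outcome_name = metric
        out[f"half_effect_in_{label}"] = res

    for label, half in (("first", 0.0), ("second", 1.0)):
        sub = enc[enc["half"] == half]
        res = fit_group_comparison(
            sub,
            outcome="value",
            term="group",
            fixed_covariates=fixed_covariates,
            random_term="family_id",
            transform_policy=transform_policy,
        )
        res.outcome_name = metric
        out[f"group_difference_{label}_half"] = res
    return out
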