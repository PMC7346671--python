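"""Mixed-effects association of diurnal SB patterns with physical functioning.

The outcome model is a linear mixed model with a person-level random
intercept:

    pf_it = pattern_i + t_it + pattern_i x t_it + covariates_i + b_i + e_it

with time in years since baseline (t = 0 at baseline, so the intercept
surface is "baseline PF"). Effect modification by MVPA is tested by adding a
binary MVPA stratum (median split), its two-way terms and the pattern x time
x MVPA three-way interaction, compared to the reduced model by a likelihood
ratio test on ML fits. Stratified baseline/slope estimates per pattern x
MVPA cell are adjusted means at covariate means (continuous) / reference
levels (categorical), with delta-method standard errors and Wald contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "MixedModelFit",
    "StratifiedEstimates",
    "mvpa_split",
    "build_analysis_frame",
    "fit_pf_model",
    "lrt_effect_modification",
    "stratified_estimates",
]

DEFAULT_COVARIATES = [
    "age",
    "bmi",
    "race_ethnicity",
    "education",
    "smoker",
    "alcohol",
    "morbidity_count",
    "self_rated_health",
]

_CATEGORICAL = {
    "race_ethnicity",
    "education",
    "smoker",
    "alcohol",
    "morbidity_count",
    "self_rated_health",
}

# Levels at which stratified "baseline" cells are evaluated: the natural
# clinical reference for each covariate. Unknown categoricals fall back to
# the first level in sorted order.
DEFAULT_REFERENCE_LEVELS = {
    "race_ethnicity": "White",
    "education": "hs_or_less",
    "smoker": False,
    "alcohol": "none",
    "morbidity_count": "0",
    "self_rated_health": "excellent_vg",
}


def mvpa_split(covariates: pd.DataFrame) -> tuple[pd.Series, float]:
    """Median split of daily MVPA minutes: high iff strictly above the median.

    Participants exactly at the median fall in the low stratum.
    """
    mvpa = covariates.set_index("participant_id")["mvpa_min"].astype(float)
    if mvpa.isna().any():
        raise ValueError("mvpa_min missing for some analytic participants")
    split = float(mvpa.median())
    high = (mvpa > split).astype(int)
    if high.nunique() == 1:
        warnings.warn("degenerate MVPA split: all participants in one stratum")
    high.name = "mvpa_high"
    return high, split


def build_analysis_frame(
    panel: pd.DataFrame,
    patterns: pd.Series,
    covariates: pd.DataFrame,
    mvpa_high: pd.Series | None = None,
) -> pd.DataFrame:
    """Merge outcome panel, pattern labels and covariates into model rows."""
    frame = panel.rename(columns={"year": "t"}).copy()
    frame["pattern"] = frame["participant_id"].map(patterns)
    frame = frame[frame["pattern"].notna()]
    frame["pattern"] = frame["pattern"].astype(int)
    frame = frame.merge(covariates, on="participant_id", how="left")
    if mvpa_high is not None:
        frame["mvpa_high"] = frame["participant_id"].map(mvpa_high)
    return frame


@dataclass
class MixedModelFit:
    """A fitted random-intercept linear mixed model plus its context."""

    result: object  # statsmodels MixedLMResults
    formula: str
    reml: bool
    n_obs: int
    n_participants: int
    covariate_means: dict = field(default_factory=dict)  # continuous -> mean
    covariate_reference: dict = field(default_factory=dict)  # categorical -> level
    has_mvpa_interaction: bool = False

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def cov_fe(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    @property
    def random_intercept_variance(self) -> float:
        return float(np.asarray(self.result.cov_re)[0, 0])

    @property
    def residual_variance(self) -> float:
        return float(self.result.scale)

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "reml": self.reml,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "loglik": self.loglik,
            "random_intercept_variance": self.random_intercept_variance,
            "residual_variance": self.residual_variance,
            "fixed_effects": {
                name: {"estimate": float(est), "se": float(se)}
                for name, est, se in zip(
                    self.fe_params.index, self.fe_params, self.result.bse_fe
                )
            },
        }


def _formula(
    covariate_cols: list[str], include_sedentary: bool, include_mvpa_interaction: bool,
    reference_pattern: int,
) -> str:
    pattern_term = f"C(pattern, Treatment({reference_pattern}))"
    if include_mvpa_interaction:
        rhs = [f"{pattern_term} * t * mvpa_high"]
    else:
        rhs = [f"{pattern_term} * t"]
    for col in covariate_cols:
        rhs.append(f"C({col})" if col in _CATEGORICAL else col)
    if include_sedentary:
        rhs.append("total_sedentary_min")
    return "pf ~ " + " + ".join(rhs)


def fit_pf_model(
    panel: pd.DataFrame,
    patterns: pd.Series,
    covariates: pd.DataFrame,
    *,
    include_sedentary: bool = True,
    include_mvpa_interaction: bool = False,
    mvpa_high: pd.Series | None = None,
    covariate_cols: list[str] | None = None,
    reference_pattern: int = 1,
    reml: bool = True,
) -> MixedModelFit:
    """Fit the PF mixed model on complete cases.

    ``patterns`` maps participant_id to pattern 1..K. When
    ``include_mvpa_interaction`` is set, ``mvpa_high`` (participant_id -> 0/1)
    must be supplied and the pattern x time x MVPA surface is estimated.
    REML is used for reported estimates; pass ``reml=False`` for the ML fits
    that likelihood-ratio tests require.
    """
    covariate_cols = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    covariate_cols = [c for c in covariate_cols if c in covariates.columns]
    if include_mvpa_interaction and mvpa_high is None:
        raise ValueError("mvpa_high is required for the interaction model")
    frame = build_analysis_frame(panel, patterns, covariates, mvpa_high)
    used = ["pf", "t", "pattern", "participant_id"] + covariate_cols
    if include_sedentary:
        used.append("total_sedentary_min")
    if include_mvpa_interaction:
        used.append("mvpa_high")
    frame = frame[used].dropna().reset_index(drop=True)

    # Rank check: every pattern (x stratum) cell must be populated.
    if include_mvpa_interaction:
        cells = frame.groupby(["pattern", "mvpa_high"], observed=True).size()
        for p in sorted(frame["pattern"].unique()):
            for s in (0, 1):
                if (p, s) not in cells.index:
                    raise ValueError(
                        f"empty pattern x MVPA cell: pattern={p}, "
                        f"mvpa={'high' if s else 'low'}"
                    )
    elif frame["pattern"].nunique() < 2:
        raise ValueError("need at least two populated patterns")

    formula = _formula(
        covariate_cols, include_sedentary, include_mvpa_interaction, reference_pattern
    )
    model = smf.mixedlm(formula, frame, groups=frame["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    means = {
        c: float(frame[c].mean())
        for c in covariate_cols + (["total_sedentary_min"] if include_sedentary else [])
        if c not in _CATEGORICAL
    }
    reference = {}
    for c in covariate_cols:
        if c not in _CATEGORICAL:
            continue
        levels = set(frame[c].unique())
        preferred = DEFAULT_REFERENCE_LEVELS.get(c)
        reference[c] = preferred if preferred in levels else sorted(levels)[0]
    return MixedModelFit(
        result=result,
        formula=formula,
        reml=reml,
        n_obs=len(frame),
        n_participants=frame["participant_id"].nunique(),
        covariate_means=means,
        covariate_reference=reference,
        has_mvpa_interaction=include_mvpa_interaction,
    )


def lrt_effect_modification(
    full: MixedModelFit, reduced: MixedModelFit
) -> tuple[float, int, float]:
    """Likelihood ratio test of the full vs the nested reduced model (ML fits)."""
    if full.reml or reduced.reml:
        raise ValueError("likelihood ratio tests require ML fits (reml=False)")
    if full.n_obs != reduced.n_obs or full.n_participants != reduced.n_participants:
        raise ValueError("models were fitted on different rows")
    df = len(full.fe_params) - len(reduced.fe_params)
    if df < 0:
        raise ValueError("reduced model is not nested in the full model")
    statistic = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


@dataclass
class StratifiedEstimates:
    """Per pattern x MVPA stratum adjusted baselines and annual slopes."""

    cells: pd.DataFrame  # pattern, mvpa_high, baseline, baseline_se, slope, slope_se
    pattern_contrasts: pd.DataFrame  # within-stratum pairwise pattern contrasts
    mvpa_contrasts: pd.DataFrame  # within-pattern high-vs-low contrasts
    mvpa_split_value: float | None = None

    def cell(self, pattern: int, mvpa_high: int) -> pd.Series:
        m = self.cells
        return m[(m["pattern"] == pattern) & (m["mvpa_high"] == mvpa_high)].iloc[0]


def _prediction_row(fit: MixedModelFit, pattern: int, mvpa: int, t: float) -> dict:
    row = {"pattern": pattern, "mvpa_high": mvpa, "t": t}
    row.update(fit.covariate_means)
    row.update(fit.covariate_reference)
    return row


def _design(fit: MixedModelFit, rows: list[dict]) -> np.ndarray:
    design_info = fit.result.model.data.design_info
    (X,) = patsy.build_design_matrices([design_info], pd.DataFrame(rows))
    return np.asarray(X)


def _wald(diff: float, se: float) -> tuple[float, float]:
    z = diff / se if se > 0 else np.nan
    return z, float(2 * stats.norm.sf(abs(z))) if se > 0 else np.nan


def stratified_estimates(
    fit: MixedModelFit,
    *,
    mvpa_split_value: float | None = None,
    adjust: str | None = None,
) -> StratifiedEstimates:
    """Adjusted baseline and slope per pattern x MVPA cell, with contrasts.

    Baselines are the linear predictor at t = 0, continuous covariates at
    their sample means and categoricals at reference levels; slopes are the
    time derivative of the linear predictor. Standard errors come from the
    fixed-effect covariance by the delta method. Pairwise Wald contrasts are
    reported unadjusted by default; ``adjust`` may name a multiple-testing
    correction understood by statsmodels (e.g. ``"bonferroni"``, ``"holm"``).
    """
    if not fit.has_mvpa_interaction:
        raise ValueError("stratified estimates require the 3-way interaction model")
    beta = fit.fe_params.to_numpy()
    cov = fit.cov_fe
    frame = fit.result.model.data.frame
    patterns = sorted(pd.unique(frame["pattern"]))

    cells = []
    vectors: dict[tuple[int, int, str], np.ndarray] = {}
    for p in patterns:
        for s in (0, 1):
            X = _design(
                fit,
                [_prediction_row(fit, p, s, 0.0), _prediction_row(fit, p, s, 1.0)],
            )
            x_base = X[0]
            x_slope = X[1] - X[0]
            vectors[(p, s, "baseline")] = x_base
            vectors[(p, s, "slope")] = x_slope
            cells.append(
                {
                    "pattern": p,
                    "mvpa_high": s,
                    "baseline": float(x_base @ beta),
                    "baseline_se": float(np.sqrt(x_base @ cov @ x_base)),
                    "slope": float(x_slope @ beta),
                    "slope_se": float(np.sqrt(x_slope @ cov @ x_slope)),
                }
            )

    pattern_rows = []
    for quantity in ("baseline", "slope"):
        for s in (0, 1):
            for i, pa in enumerate(patterns):
                for pb in patterns[i + 1 :]:
                    c = vectors[(pa, s, quantity)] - vectors[(pb, s, quantity)]
                    diff = float(c @ beta)
                    se = float(np.sqrt(c @ cov @ c))
                    z, pval = _wald(diff, se)
                    pattern_rows.append(
                        {
                            "quantity": quantity,
                            "mvpa_high": s,
                            "pattern_a": pa,
                            "pattern_b": pb,
                            "diff": diff,
                            "se": se,
                            "z": z,
                            "p": pval,
                        }
                    )
    mvpa_rows = []
    for quantity in ("baseline", "slope"):
        for p in patterns:
            c = vectors[(p, 1, quantity)] - vectors[(p, 0, quantity)]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            z, pval = _wald(diff, se)
            mvpa_rows.append(
                {"quantity": quantity, "pattern": p, "diff": diff, "se": se, "z": z, "p": pval}
            )
    pattern_contrasts = pd.DataFrame(pattern_rows)
    mvpa_contrasts = pd.DataFrame(mvpa_rows)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        for tbl in (pattern_contrasts, mvpa_contrasts):
            tbl["p_adjusted"] = multipletests(tbl["p"].to_numpy(), method=adjust)[1]
    return StratifiedEstimates(
        cells=pd.DataFrame(cells),
        pattern_contrasts=pattern_contrasts,
        mvpa_contrasts=mvpa_contrasts,
        mvpa_split_value=mvpa_split_value,
    )
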