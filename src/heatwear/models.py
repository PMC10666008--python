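"""Linear mixed-effects exposure-response workflow.

The analysis relates a wearable outcome Y (daily steps, nightly sleep
duration in hours, or mean nighttime heart rate) for participant *i* to
heat and rainfall exposure with a random intercept per participant:

    Y_i = b0 + b1*Heat_i + [b2*Heat_i^2] + b3*Precipitation_i + bz*Z_i + e_i

estimated by maximum likelihood.  Heat is the daytime maximum WBGT for
steps and the nighttime minimum heat index for sleep and heart rate.
Z collects calendar and demographic covariates (month, weekend, age
group, sex, BMI group) selected stepwise by likelihood-ratio tests;
curvature is handled by a quadratic heat term kept only when an LRT
supports it.  Model variants swap continuous exposures for binary
extreme-weather flags, add heat-by-subgroup interactions, and compare
heat metrics by AIC.  Performance is assessed by leave-one-subject-out
cross-validation with fixed-effects-only prediction.

Fitting is delegated to :mod:`statsmodels` (``MixedLM``); everything the
workflow adds — selection, contrasts, marginal effects, cross-validation,
and the design calculations — lives here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "LOSOResult",
    "FitError",
    "fit_lmm",
    "lrt",
    "stepwise_build",
    "add_quadratic_if_curved",
    "marginal_effect",
    "subgroup_sensitivity",
    "extreme_contrast",
    "compare_heat_metrics",
    "loso_cv",
    "cochran_sample_size",
    "attrition",
    "proportion_summary",
]

#: default covariate entry order for stepwise building
CANDIDATE_ORDER = ("month", "weekend", "age_group", "sex", "bmi_group")

_CATEGORICAL = {"month", "age_group", "sex", "bmi_group", "season"}

INTERACTION_FACTORS = ("age_group", "bmi_group", "sex", "month")


class FitError(RuntimeError):
    """Raised when a mixed model fails to converge or is singular."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``heat`` and ``precip`` name panel columns; ``quadratic`` adds a
    squared heat term (only meaningful with a heat term present);
    ``covariates`` are adjustment terms; ``interaction`` multiplies the
    heat term(s) with a categorical factor.  The random part is always a
    per-participant intercept; estimation is maximum likelihood.
    """

    outcome: str
    heat: str | None = None
    quadratic: bool = False
    precip: str | None = None
    covariates: tuple[str, ...] = ()
    interaction: str | None = None
    group: str = "participant_id"

    def __post_init__(self) -> None:
        if self.quadratic and self.heat is None:
            raise ValueError("quadratic term requires a heat term")
        if self.interaction is not None:
            if self.heat is None:
                raise ValueError("interaction requires a heat term")
            if self.interaction not in INTERACTION_FACTORS:
                raise ValueError(
                    f"interaction factor must be one of {INTERACTION_FACTORS}"
                )

    def _term(self, name: str) -> str:
        return f"C({name})" if name in _CATEGORICAL else name

    def terms(self) -> list[str]:
        out: list[str] = []
        if self.heat:
            out.append(self.heat)
            if self.quadratic:
                out.append(f"I({self.heat}**2)")
            if self.interaction:
                fac = self._term(self.interaction)
                out.append(f"{self.heat}:{fac}")
                if self.quadratic:
                    out.append(f"I({self.heat}**2):{fac}")
                if self.interaction not in self.covariates:
                    out.append(fac)
        if self.precip:
            out.append(self.precip)
        out.extend(self._term(c) for c in self.covariates)
        return out

    def formula(self) -> str:
        rhs = " + ".join(self.terms()) or "1"
        return f"{self.outcome} ~ {rhs}"

    def columns(self) -> list[str]:
        cols = [self.outcome, self.group]
        if self.heat:
            cols.append(self.heat)
        if self.precip:
            cols.append(self.precip)
        cols.extend(self.covariates)
        if self.interaction and self.interaction not in cols:
            cols.append(self.interaction)
        return cols

    def with_covariate(self, name: str) -> "ModelSpec":
        if name in self.covariates:
            return self
        return replace(self, covariates=self.covariates + (name,))

    def with_quadratic(self, on: bool = True) -> "ModelSpec":
        return replace(self, quadratic=on)


@dataclass
class FitResult:
    """Fixed effects, variance components and fit statistics of one model."""

    spec: ModelSpec
    params: pd.Series          # fixed effects
    bse: pd.Series             # standard errors
    pvalues: pd.Series
    conf_int: pd.DataFrame     # columns lower, upper (Wald +-1.96 SE)
    re_var: float              # random-intercept variance
    resid_var: float           # residual variance
    loglik: float
    k_params: int              # fixed effects + 2 variance parameters
    nobs: int
    n_participants: int
    _result: object = field(default=None, repr=False, compare=False)
    _data: pd.DataFrame = field(default=None, repr=False, compare=False)

    @property
    def aic(self) -> float:
        """AIC = 2k - 2*loglik with k counting fixed effects and both
        variance parameters."""
        return 2.0 * self.k_params - 2.0 * self.loglik

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only prediction (population level)."""
        return np.asarray(self._result.predict(exog=data))

    def residual_table(self) -> pd.DataFrame:
        """Residuals against the heat exposure, for inspection of
        linearity (exported in place of a residual plot)."""
        tab = pd.DataFrame(
            {
                "fitted": np.asarray(self._result.fittedvalues),
                "residual": np.asarray(self._result.resid),
            },
            index=self._data.index,
        )
        if self.spec.heat:
            tab[self.spec.heat] = self._data[self.spec.heat]
        return tab


def _model_frame(spec: ModelSpec, panel: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in dict.fromkeys(spec.columns()) if c in panel.columns]
    missing = set(spec.columns()) - set(cols)
    if missing:
        raise ValueError(f"panel lacks model columns: {sorted(missing)}")
    data = panel[cols].dropna()
    # flags may arrive as pandas nullable booleans; cast for patsy
    for c in data.columns:
        if data[c].dtype == object or str(data[c].dtype) == "boolean":
            if set(data[c].dropna().unique()) <= {True, False}:
                data[c] = data[c].astype(bool)
    return data


def fit_lmm(spec: ModelSpec, panel: pd.DataFrame) -> FitResult:
    """Fit one random-intercept linear mixed model by maximum likelihood.

    Rows with any missing model variable are dropped listwise.  The fit
    is deterministic given the data.  Non-convergence or undefined
    standard errors raise :class:`FitError` rather than returning a
    silently degraded result.
    """
    data = _model_frame(spec, panel)
    if data[spec.group].nunique() < 2:
        raise FitError("need at least 2 participants to fit a mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), data, groups=data[spec.group])
        res = None
        try:
            res = model.fit(reml=False)
            if not res.converged or not np.isfinite(res.llf):
                res = model.fit(reml=False, method="powell")
        except Exception as exc:  # noqa: BLE001 - surfaced as diagnostic
            raise FitError(f"mixed model failed: {exc}") from exc
    if not res.converged or not np.isfinite(res.llf):
        raise FitError("mixed model did not converge")
    fe = res.fe_params
    if fe.isna().any() or res.bse_fe.isna().any():
        raise FitError("singular fit: undefined fixed-effect standard errors")
    se = res.bse_fe
    ci = pd.DataFrame(
        {"lower": fe - 1.96 * se, "upper": fe + 1.96 * se}, index=fe.index
    )
    z = fe / se
    pvals = pd.Series(
        2.0 * scipy.stats.norm.sf(np.abs(z)), index=fe.index, name="p"
    )
    return FitResult(
        spec=spec,
        params=fe,
        bse=se,
        pvalues=pvals,
        conf_int=ci,
        re_var=float(res.cov_re.iloc[0, 0]),
        resid_var=float(res.scale),
        loglik=float(res.llf),
        k_params=len(fe) + 2,
        nobs=int(res.nobs),
        n_participants=int(data[spec.group].nunique()),
        _result=res,
        _data=data,
    )


def lrt(nested: FitResult, full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model.

    Statistic 2*(loglik_full - loglik_nested) referred to chi-square with
    df equal to the parameter-count difference.  Both fits must use the
    same rows.
    """
    if full.nobs != nested.nobs:
        raise ValueError(
            f"fits use different rows ({nested.nobs} vs {full.nobs}); "
            "refit on a common listwise-complete frame"
        )
    df = full.k_params - nested.k_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(stat, df))
    return stat, df, p


def stepwise_build(
    base: ModelSpec,
    candidates: Sequence[str],
    panel: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Hierarchical covariate selection by likelihood-ratio testing.

    Candidates are offered one at a time in the given order (default
    month, weekend, age group, sex, BMI group); each is kept iff adding
    it improves the likelihood at level ``alpha``.  All fits share one
    listwise-complete frame over base plus all candidates, so every LRT
    compares the same rows.  Returns the final spec and an audit trail
    with one row per test.
    """
    probe = base
    for cand in candidates:
        probe = probe.with_covariate(cand)
    frame = _model_frame(probe, panel)

    current = base
    current_fit = fit_lmm(current, frame)
    trail = []
    for cand in candidates:
        trial = current.with_covariate(cand)
        trial_fit = fit_lmm(trial, frame)
        stat, df, p = lrt(current_fit, trial_fit)
        keep = p < alpha
        trail.append(
            {
                "candidate": cand,
                "lrt_stat": stat,
                "df": df,
                "p": p,
                "kept": keep,
                "loglik_without": current_fit.loglik,
                "loglik_with": trial_fit.loglik,
            }
        )
        if keep:
            current, current_fit = trial, trial_fit
    return current, pd.DataFrame(trail)


def add_quadratic_if_curved(
    spec: ModelSpec,
    panel: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame, pd.DataFrame]:
    """Keep a squared heat term iff an LRT supports curvature.

    An automated surrogate for visual residual inspection: the model is
    fitted with and without Heat^2 and the quadratic is retained when the
    LRT p-value is below ``alpha``.  Also returns the linear model's
    residuals-vs-heat table for optional plotting, and the audit row.
    """
    if spec.heat is None:
        raise ValueError("spec has no heat term")
    linear = spec.with_quadratic(False)
    lin_fit = fit_lmm(linear, panel)
    quad_fit = fit_lmm(spec.with_quadratic(True), panel)
    stat, df, p = lrt(lin_fit, quad_fit)
    keep = p < alpha
    audit = pd.DataFrame(
        [{"term": f"I({spec.heat}**2)", "lrt_stat": stat, "df": df, "p": p,
          "kept": keep}]
    )
    chosen = spec.with_quadratic(keep)
    return chosen, audit, lin_fit.residual_table()


def marginal_effect(b1: float, b2: float, x: float) -> float:
    """Predicted outcome change for a +1 degC step from exposure ``x``
    in a model with linear (b1) and quadratic (b2) heat terms:
    b1 + b2*((x+1)^2 - x^2) = b1 + b2*(2x + 1)."""
    return float(b1) + float(b2) * (2.0 * float(x) + 1.0)


def subgroup_sensitivity(
    spec: ModelSpec,
    panel: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
    effect_at: tuple[float, ...] = (20.0, 30.0),
) -> dict:
    """Heat-by-subgroup interaction test with per-level refits.

    Adds an interaction between the heat term(s) and ``factor``
    (age_group, bmi_group, sex or month).  If the interaction improves
    the model at level ``alpha``, the base model is refitted on each
    level's subset and the heat estimates, p-values and marginal effects
    at the reference exposures are tabulated.  Levels with fewer than two
    participants are skipped with a warning.
    """
    if factor not in INTERACTION_FACTORS:
        raise ValueError(f"factor must be one of {INTERACTION_FACTORS}")
    with_int = replace(spec, interaction=factor)
    frame = _model_frame(with_int, panel)
    levels = pd.unique(frame[factor])
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level; no contrast")

    base_fit = fit_lmm(spec, frame)
    int_fit = fit_lmm(with_int, frame)
    stat, df, p = lrt(base_fit, int_fit)
    out = {
        "factor": factor,
        "lrt_stat": stat,
        "df": df,
        "p": p,
        "significant": p < alpha,
        "per_level": None,
        "warnings": [],
    }
    if not out["significant"]:
        return out

    rows = []
    for level in sorted(levels, key=str):
        sub = frame[frame[factor] == level]
        if sub[spec.group].nunique() < 2:
            out["warnings"].append(
                f"level {level!r} skipped: fewer than 2 participants"
            )
            continue
        sub_spec = replace(
            spec,
            covariates=tuple(c for c in spec.covariates if c != factor),
        )
        fit = fit_lmm(sub_spec, sub)
        row = {
            "level": level,
            "n_participants": fit.n_participants,
            "heat_estimate": fit.params.get(spec.heat, np.nan),
            "heat_p": fit.pvalues.get(spec.heat, np.nan),
        }
        b2 = fit.params.get(f"I({spec.heat} ** 2)", 0.0)
        if spec.quadratic:
            row["heat2_estimate"] = b2
            row["heat2_p"] = fit.pvalues.get(f"I({spec.heat} ** 2)", np.nan)
        for x in effect_at:
            row[f"effect_at_{x:g}C"] = marginal_effect(
                row["heat_estimate"], b2, x
            )
        rows.append(row)
    out["per_level"] = pd.DataFrame(rows)
    return out


def extreme_contrast(spec: ModelSpec, panel: pd.DataFrame) -> FitResult:
    """Refit with binary extreme-weather exposures.

    Replaces the continuous heat and rain terms with the corresponding
    flags (heat-stress day/night and heavy-rain day), keeping the same
    covariates.  A flag that never varies in the analysed rows raises,
    since it carries no contrast.
    """
    frame = _model_frame(spec, panel)
    for col in (spec.heat, spec.precip):
        if col is not None:
            vals = frame[col].astype(int)
            if vals.nunique() < 2:
                raise ValueError(f"flag column {col!r} has no contrast")
    binary_spec = replace(spec, quadratic=False)
    frame = frame.copy()
    for col in (spec.heat, spec.precip):
        if col is not None:
            frame[col] = frame[col].astype(int)
    return fit_lmm(binary_spec, frame)


def compare_heat_metrics(
    spec: ModelSpec,
    panel: pd.DataFrame,
    metrics: Mapping[str, str],
) -> pd.DataFrame:
    """Fit the same specification once per heat metric and rank by AIC.

    ``metrics`` maps a display name to a panel column (for example WBGT
    versus plain air temperature).  All fits share the rows complete for
    every candidate metric, so AICs are comparable.  Lower AIC ranks
    first.
    """
    extra = [c for c in metrics.values() if c in panel.columns]
    probe_cols = list(dict.fromkeys(sum((replace(spec, heat=c).columns()
                                         for c in extra), [])))
    frame = panel[probe_cols].dropna()
    rows = []
    for name, col in metrics.items():
        fit = fit_lmm(replace(spec, heat=col), frame)
        rows.append({"metric": name, "column": col, "aic": fit.aic,
                     "loglik": fit.loglik, "nobs": fit.nobs})
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class LOSOResult:
    """Leave-one-subject-out cross-validation summary."""

    per_participant: pd.DataFrame  # participant_id, n_rows, r2, rmse
    mean_r2: float
    mean_rmse: float
    warnings: list[str]


def loso_cv(spec: ModelSpec, panel: pd.DataFrame) -> LOSOResult:
    """Leave-one-subject-out cross-validation.

    For each participant the model is refitted on everyone else and the
    held-out rows are predicted from fixed effects only (the random
    intercept of an unseen subject is unavailable).  Per participant:
    R^2 = 1 - SSE/SST with SST about the held-out rows' own mean (missing
    when SST is zero), and RMSE.  Means are taken over per-participant
    values, skipping missing R^2.
    """
    frame = _model_frame(spec, panel)
    pids = sorted(frame[spec.group].unique(), key=str)
    if len(pids) < 3:
        raise ValueError("LOSO needs at least 3 participants")
    rows, warns = [], []
    for pid in pids:
        test = frame[frame[spec.group] == pid]
        if len(test) < 2:
            warns.append(f"participant {pid!r} skipped: fewer than 2 rows")
            continue
        train = frame[frame[spec.group] != pid]
        fit = fit_lmm(spec, train)
        pred = fit.predict(test)
        y = test[spec.outcome].to_numpy(dtype=float)
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = np.nan if sst == 0.0 else 1.0 - sse / sst
        rows.append(
            {
                "participant_id": pid,
                "n_rows": len(test),
                "r2": r2,
                "rmse": float(np.sqrt(sse / len(test))),
            }
        )
    per = pd.DataFrame(rows)
    return LOSOResult(
        per_participant=per,
        mean_r2=float(np.nanmean(per["r2"])) if len(per) else np.nan,
        mean_rmse=float(per["rmse"].mean()) if len(per) else np.nan,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Design and descriptive calculations
# ---------------------------------------------------------------------------

def cochran_sample_size(
    population: int | None,
    confidence: float,
    margin: float,
    p: float = 0.5,
) -> int:
    """Finite-population-corrected sample size for estimating a proportion.

    n0 = z^2 p (1-p) / e^2 with z the two-sided normal quantile for the
    confidence level, corrected as n = n0 / (1 + (n0 - 1)/N) and rounded
    to the nearest integer.  ``population=None`` skips the correction.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must be in (0, 1)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    z = scipy.stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    n0 = z * z * p * (1.0 - p) / (margin * margin)
    if population is None:
        return int(round(n0))
    if population <= 0:
        raise ValueError("population must be positive")
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return int(round(n))


def attrition(enrolled: int, losses: Iterable[int]) -> int:
    """Final cohort size after subtracting each loss category."""
    losses = list(losses)
    if enrolled < 0 or any(x < 0 for x in losses):
        raise ValueError("counts must be non-negative")
    final = enrolled - sum(losses)
    if final < 0:
        raise ValueError("losses exceed enrolment")
    return final


def proportion_summary(k: int, n: int) -> str:
    """Format a count as ``"k/n, p%"`` with the percentage to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return f"{k}/{n}, {100.0 * k / n:.1f}%"
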