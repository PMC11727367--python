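"""Linear mixed models with likelihood-ratio selection and Tukey post-hocs.

Memory indices (d' or Hu) are modeled with Gaussian linear mixed models
fitted by full maximum likelihood: fixed effects for affective category and
(candidate) methodological factors, random intercepts for participant and
for study-group (the study x group combination, 11 levels in the pooled
design).  Participants are nested within study-groups, so the crossed
specification reduces to a two-level nested one, which is how the model is
parameterized internally.

Model selection is parsimonious and forward-stepwise: a candidate fixed
effect is retained only if the chi-square likelihood-ratio test against the
reduced model (both fits under ML, identical rows) is significant;
interactions are offered only among retained main effects.  Affective
category is never dropped.

Post-hoc pairwise comparisons are run on estimated marginal means (cell
means averaged with equal weights over the levels of the other fixed
factors) with Tukey-HSD adjustment via the studentized-range distribution.
Denominator degrees of freedom use the residual approximation
(n_observations - n_fixed_coefficients); t-values are df-free and are the
stable comparison quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.stats import studentized_range
import statsmodels.formula.api as smf

#: Treatment-coding reference level per factor.
REFERENCE_LEVELS = {
    "affective_category": "neutral",
    "memory_type": "know",
    "encoding_instruction": "free_viewing",
    "group": "control",
    "retrieval_task": "remember_know",
    "environment": "EEG",
}

#: Documented stepwise order in which candidate main effects are offered.
DEFAULT_CANDIDATE_ORDER = (
    "encoding_instruction",
    "retrieval_task",
    "environment",
    "group",
    "n_new_items",
)

_CONTINUOUS = {"n_new_items"}


class ModelError(ValueError):
    """A model specification cannot be fitted as requested."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of one mixed model.

    ``fixed_terms`` are factor names or ``a:b`` interaction labels; the
    analysis models always carry ``affective_category`` (the selection
    routine enforces this), but null models without it are legal specs so
    that likelihood-ratio calibration and Bayes-factor null comparisons can
    be expressed.  Random terms are intercepts only.  Estimation is always
    full maximum likelihood.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ("participant", "study_group")

    def all_fixed(self) -> tuple[str, ...]:
        return tuple(self.fixed_terms)

    def formula(self) -> str:
        rhs = " + ".join(self.all_fixed()) or "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """A fitted mixed model: fixed-effect table plus fit statistics."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float
    aic: float
    bic: float
    df_fixed: int
    n_obs: int
    n_participants: int
    converged: bool
    formula: str
    result: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table in the b / SE / CI / t / p layout."""
        return pd.DataFrame({
            "b": self.params,
            "SE": self.bse,
            "CI_low": self.conf_int[0],
            "CI_high": self.conf_int[1],
            "t": self.tvalues,
            "p": self.pvalues,
        })

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "formula": self.formula,
            "coefficients": {
                name: {
                    "b": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "ci": [float(self.conf_int.loc[name, 0]), float(self.conf_int.loc[name, 1])],
                    "t": float(self.tvalues[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "log_likelihood": float(self.llf),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_observations": int(self.n_obs),
            "n_participants": int(self.n_participants),
            "converged": bool(self.converged),
            "reference_levels": {
                f: REFERENCE_LEVELS[f]
                for f in _factors_in(self.spec.all_fixed())
                if f in REFERENCE_LEVELS
            },
        }


@dataclass(frozen=True)
class LRTResult:
    """Chi-square likelihood-ratio test between nested ML fits."""

    chi_square: float
    df: int
    p: float


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey-adjusted pairwise comparison of estimated marginal means."""

    pair: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


def _factors_in(terms: Sequence[str]) -> list[str]:
    out = []
    for term in terms:
        for f in term.split(":"):
            if f not in out:
                out.append(f)
    return out


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.response not in table.columns:
        raise ModelError(f"response column {spec.response!r} not in table")
    data = table.dropna(subset=[spec.response]).copy()
    if not len(data):
        raise ModelError("no non-missing response rows")
    for f in _factors_in(spec.all_fixed()):
        if f not in data.columns:
            raise ModelError(f"fixed term {f!r} not in table")
        if f in _CONTINUOUS:
            data[f] = data[f].astype(float)
            continue
        levels = pd.unique(data[f].astype(str))
        if len(levels) < 2:
            raise ModelError(f"fixed term {f!r} has a single level and is unidentifiable")
        ref = REFERENCE_LEVELS.get(f)
        ordered = ([ref] if ref in levels else []) + sorted(
            l for l in levels if l != ref
        )
        data[f] = pd.Categorical(data[f].astype(str), categories=ordered)
    return data


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit a mixed model by full maximum likelihood.

    Treatment coding with the documented reference levels (neutral, know,
    free_viewing, control, remember_know, EEG); random intercepts for
    participant and, when it has more than one level, study-group.  A
    singular random-effect structure is reported as near-zero variance with
    the fitter's warning, not an error.
    """
    data = _prepare(table, spec)
    formula = spec.formula()

    use_sg = (
        "study_group" in spec.random_terms
        and "study_group" in data.columns
        and data["study_group"].nunique() > 1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_sg:
            # participants are nested in study-groups: fit as a two-level model
            nested = data.groupby("participant")["study_group"].nunique()
            if (nested > 1).any():
                raise ModelError("participants must be nested within study_group")
            model = smf.mixedlm(
                formula, data, groups=data["study_group"], re_formula="1",
                vc_formula={"participant": "0 + C(participant)"},
            )
        else:
            model = smf.mixedlm(formula, data, groups=data["participant"], re_formula="1")
        exog = np.asarray(model.exog)
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ModelError(
                f"fixed-effect design for {formula!r} is rank deficient "
                "(aliased or confounded terms)"
            )
        try:
            result = model.fit(reml=False)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"fit of {formula!r} failed: {exc}") from exc

    fe = result.fe_params
    names = list(fe.index)
    bse = result.bse.loc[names]
    conf = pd.DataFrame(
        {0: fe - 1.96 * bse, 1: fe + 1.96 * bse}, index=names
    )
    tvals = fe / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(tvals)), index=names)

    return ModelFit(
        spec=spec,
        params=fe,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        conf_int=conf,
        llf=float(result.llf),
        aic=float(result.aic),
        bic=float(result.bic),
        df_fixed=len(names),
        n_obs=int(len(data)),
        n_participants=int(data["participant"].nunique()) if "participant" in data else 0,
        converged=bool(result.converged),
        formula=formula,
        result=result,
        data=data,
    )


def lr_test(fit_small: ModelFit, fit_large: ModelFit) -> LRTResult:
    """Chi-square likelihood-ratio test of nested ML fits on identical rows."""
    if fit_small.n_obs != fit_large.n_obs:
        raise ModelError(
            f"fits use different rows ({fit_small.n_obs} vs {fit_large.n_obs})"
        )
    small_names = set(fit_small.params.index)
    large_names = set(fit_large.params.index)
    if not small_names <= large_names:
        raise ModelError("models are not nested (smaller fit has extra coefficients)")
    df = fit_large.df_fixed - fit_small.df_fixed
    chi2 = max(0.0, 2.0 * (fit_large.llf - fit_small.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi_square=chi2, df=df, p=p)


def select_parsimonious(
    table: pd.DataFrame,
    response: str,
    candidate_terms: Sequence[str] = DEFAULT_CANDIDATE_ORDER,
    base_terms: Sequence[str] = (),
    *,
    alpha: float = 0.05,
    extra_interactions: Sequence[str] = (),
    random_terms: tuple[str, ...] = ("participant", "study_group"),
) -> tuple[ModelSpec, ModelFit, list[dict]]:
    """Forward-stepwise parsimonious model selection by likelihood ratio.

    Affective category is always part of the model and never tested for
    removal.  Candidate main effects are added in the given order and kept
    iff the LRT against the current model has p < ``alpha``; pairwise
    interactions among retained terms (including affective category) are
    then offered under the same rule, followed by any ``extra_interactions``
    (e.g. three-way terms) whose constituent factors were all retained.

    Returns the selected spec, its fit, and the selection trace (one record
    per tested term with its chi-square, df, p, and whether it was kept).
    """
    if not len(table):
        raise ModelError("empty index table")

    def spec_for(terms: Sequence[str]) -> ModelSpec:
        return ModelSpec(response=response, fixed_terms=tuple(terms), random_terms=random_terms)

    def identifiable(term: str, current_fit: ModelFit) -> bool:
        for f in term.split(":"):
            if f in _CONTINUOUS:
                continue
            if current_fit.data[f].astype(str).nunique() < 2:
                return False
        return True

    current_terms: list[str] = list(dict.fromkeys(["affective_category", *base_terms]))
    current = fit_lmm(table, spec_for(current_terms))
    trace: list[dict] = []

    def consider(term: str) -> None:
        nonlocal current, current_terms
        try:
            larger = fit_lmm(table, spec_for(current_terms + [term]))
            lrt = lr_test(current, larger)
        except ModelError as exc:
            trace.append({"term": term, "kept": False, "note": str(exc)})
            return
        kept = lrt.p < alpha
        trace.append({
            "term": term, "chi_square": lrt.chi_square, "df": lrt.df,
            "p": lrt.p, "kept": kept,
        })
        if kept:
            current_terms = current_terms + [term]
            current = larger

    for term in candidate_terms:
        consider(term)

    retained = ["affective_category"] + [t for t in current_terms if ":" not in t]
    for a, b in combinations(dict.fromkeys(retained), 2):
        consider(f"{a}:{b}")

    for term in extra_interactions:
        if all(f in retained for f in term.split(":")):
            consider(term)
        else:
            trace.append({"term": term, "kept": False,
                          "note": "constituent main effect not retained"})

    return current.spec, current, trace


def _marginal_rows(fit: ModelFit, factors: Sequence[str]) -> tuple[list[str], np.ndarray]:
    """Equal-weight averaged design rows, one per cell of the factor grid."""
    data = fit.data
    design_info = fit.result.model.data.design_info
    model_factors = [f for f in _factors_in(fit.spec.all_fixed()) if f not in _CONTINUOUS]
    for f in factors:
        if f not in model_factors:
            raise ModelError(f"factor {f!r} is not a fixed factor of this model")
        if data[f].astype(str).nunique() < 2:
            raise ModelError(f"factor {f!r} has a single level")

    level_sets = {f: list(data[f].cat.categories) for f in model_factors}
    grid = pd.DataFrame(
        [dict(zip(model_factors, combo))
         for combo in pd.MultiIndex.from_product([level_sets[f] for f in model_factors])],
        columns=model_factors,
    )
    for f in model_factors:
        grid[f] = pd.Categorical(grid[f], categories=level_sets[f])
    for cov in _CONTINUOUS:
        if cov in _factors_in(fit.spec.all_fixed()):
            grid[cov] = float(data[cov].mean())

    (X,) = patsy.build_design_matrices([design_info], grid)
    X = np.asarray(X)
    cell_key = grid[list(factors)].astype(str).agg(", ".join, axis=1)
    labels = sorted(cell_key.unique())
    rows = np.vstack([X[cell_key == lab].mean(axis=0) for lab in labels])
    return labels, rows


def tukey_contrasts(fit: ModelFit, factors: str | Sequence[str]) -> list[ContrastResult]:
    """All pairwise Tukey-HSD contrasts of estimated marginal means.

    Marginal means average the model's cell predictions with equal weights
    over the levels of the fixed factors not in the requested grid.  The
    Tukey family is every pair within the grid; p-values come from the
    studentized-range distribution with residual degrees of freedom.
    """
    if isinstance(factors, str):
        factors = (factors,)
    labels, rows = _marginal_rows(fit, list(factors))
    beta = fit.params.to_numpy()
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    k = len(labels)
    df = max(fit.n_obs - fit.df_fixed, 1)

    out = []
    for i, j in combinations(range(k), 2):
        L = rows[i] - rows[j]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else 0.0
        p = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df)) if se > 0 else 1.0
        out.append(ContrastResult(
            pair=f"{labels[i]} - {labels[j]}", estimate=est, se=se,
            t=t, df=float(df), p=min(1.0, p),
        ))
    return out


def contrasts_frame(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    """Contrast results as a tidy table."""
    return pd.DataFrame([c.__dict__ for c in contrasts])
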