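"""Association testing between chemical levels and reproductive risk factors.

Concentrations and feature areas are square-root transformed to tame
left-skewed distributions, screened with Spearman (raw values vs risk
factors) and Pearson (transformed values within chemical class)
correlations, and modelled outcome-by-outcome with linear mixed models
carrying a subject-specific random intercept for the repeated biobank
samples:

    sqrt(y_ij) = b0 + b1 * exposure_ij + covariates_ij * g + u_i + e_ij

with u_i ~ N(0, s_u^2) the subject intercept.  Exposures are age at
sampling, number of pregnancies, number of deliveries, and age at
menarche, each with its own adjustment set.  Highly correlated PFAS are
additionally summed into predeclared co-exposure groups.  Untargeted
scans are flagged at three tiers: nominal alpha, the 0.005 literature
threshold, and the Bonferroni cutoff alpha / n_tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AGE = "age"
PREGNANCIES = "n_pregnancies"
DELIVERIES = "n_deliveries"
MENARCHE = "age_menarche"
EXPOSURES = (AGE, PREGNANCIES, DELIVERIES, MENARCHE)

#: default adjustment set per exposure
DEFAULT_ADJUSTMENTS: dict[str, tuple[str, ...]] = {
    AGE: ("bmi", PREGNANCIES, "sample_year", MENARCHE, "tobacco_ever"),
    PREGNANCIES: (AGE, "birth_year", MENARCHE, "tobacco_ever"),
    DELIVERIES: (AGE, "birth_year", MENARCHE, "tobacco_ever"),
    MENARCHE: (AGE, "bmi", "birth_year"),
}

#: predeclared PFAS co-exposure groups (members summed on the transformed scale)
DEFAULT_PFAS_GROUPS: dict[str, tuple[str, ...]] = {
    "Group 1": ("PFDA", "PFNA", "PFUnDA"),
    "Group 2": ("FOSA", "FOSAA", "NEtFOSAA"),
    "Group 3": ("PFOS", "PFHpS", "PFOA", "PFHxS"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One (outcome, exposure) mixed-model specification."""

    outcome: str
    exposure: str
    covariates: tuple[str, ...] | None = None  # None -> DEFAULT_ADJUSTMENTS
    interaction: tuple[str, str] | None = None
    subject_col: str = "participant_id"

    def resolved_covariates(self) -> tuple[str, ...]:
        cov = self.covariates
        if cov is None:
            cov = DEFAULT_ADJUSTMENTS.get(self.exposure, ())
        cov = tuple(c for c in cov if c != self.exposure)
        if self.exposure in (self.covariates or ()):
            raise ValueError(f"exposure {self.exposure!r} duplicated in covariates")
        return cov


@dataclass
class ModelResult:
    """Exposure-coefficient summary from one fitted model."""

    outcome: str
    exposure: str
    coefficient: float
    se: float
    p_value: float
    n_samples: int
    n_subjects: int
    converged: bool
    method: str = "lmm"
    covariates: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class MultiplicityDecision:
    """Three-tier significance flags for a family of tests."""

    alpha: float
    n_tests: int
    threshold_literature: float
    bonferroni_threshold: float
    flags: pd.DataFrame  # columns pass_alpha, pass_literature, pass_bonferroni


# ---------------------------------------------------------------------------
# transforms and correlation structure


def transform_sqrt(values):
    """Square-root transform for left-skewed concentration distributions."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("square-root transform requires non-negative values")
    out = np.sqrt(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class CorrelationStructure:
    spearman_rho: pd.DataFrame  # raw values x risk factors
    spearman_p: pd.DataFrame
    pearson_r: pd.DataFrame  # transformed values x transformed values
    pearson_p: pd.DataFrame


def _pairwise_corr(x: pd.Series, y: pd.Series, method: str) -> tuple[float, float]:
    mask = x.notna() & y.notna()
    if mask.sum() < 3:
        return np.nan, np.nan
    xs, ys = x[mask], y[mask]
    if xs.nunique() < 2 or ys.nunique() < 2:
        return np.nan, np.nan  # constant column: correlation undefined
    if method == "spearman":
        r, p = stats.spearmanr(xs, ys)
    else:
        r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def correlation_structure(
    values: pd.DataFrame, risk_factors: pd.DataFrame
) -> CorrelationStructure:
    """Spearman (raw vs risk factors) and Pearson (transformed, pairwise) maps.

    ``values``: samples x analytes raw concentrations; ``risk_factors``:
    samples x factors.  Pairwise-complete handling; undefined cells
    (constant column or < 3 complete pairs) are NaN.
    """
    values, risk_factors = values.align(risk_factors, join="inner", axis=0)
    s_rho = pd.DataFrame(index=values.columns, columns=risk_factors.columns, dtype=float)
    s_p = s_rho.copy()
    for a in values.columns:
        for f in risk_factors.columns:
            s_rho.loc[a, f], s_p.loc[a, f] = _pairwise_corr(
                values[a], risk_factors[f], "spearman"
            )
    transformed = transform_sqrt(values)
    p_r = pd.DataFrame(index=values.columns, columns=values.columns, dtype=float)
    p_p = p_r.copy()
    for i, a in enumerate(values.columns):
        for b in values.columns[i:]:
            r, p = _pairwise_corr(transformed[a], transformed[b], "pearson")
            p_r.loc[a, b] = p_r.loc[b, a] = r
            p_p.loc[a, b] = p_p.loc[b, a] = p
    return CorrelationStructure(s_rho, s_p, p_r, p_p)


def group_and_sum(
    transformed: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Sum transformed member values into co-exposure group scores.

    ``transformed``: samples x analytes on the transformed scale.  Member
    names match a column exactly or its ``"<name> (total)"`` variant.
    Members stay in the matrix individually; this only adds group columns.
    """
    if groups is None:
        groups = DEFAULT_PFAS_GROUPS
    out = {}
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} has no members")
        cols = []
        for m in members:
            if m in transformed.columns:
                cols.append(m)
            elif f"{m} (total)" in transformed.columns:
                cols.append(f"{m} (total)")
            else:
                raise ValueError(f"group member {m!r} absent from matrix")
        out[gname] = transformed[cols].sum(axis=1)
    return pd.DataFrame(out, index=transformed.index)


def cluster_groups(
    pearson_r: pd.DataFrame, threshold: float = 0.6, min_size: int = 2
) -> dict[str, list[str]]:
    """Average-linkage clustering of |r| >= threshold as group discovery.

    Offered for new datasets in place of predeclared group lists.
    """
    from scipy.cluster import hierarchy

    r = pearson_r.fillna(0.0).to_numpy()
    dist = 1.0 - np.abs((r + r.T) / 2)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    if condensed.size == 0:
        return {}
    link = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")
    groups: dict[str, list[str]] = {}
    for lab in sorted(set(labels)):
        members = [a for a, l in zip(pearson_r.index, labels) if l == lab]
        if len(members) >= min_size:
            groups[f"Cluster {lab}"] = members
    return groups


# ---------------------------------------------------------------------------
# mixed models


def _model_frame(
    spec: ModelSpec, data: pd.DataFrame, extra_terms: Sequence[str] = ()
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    cov = spec.resolved_covariates()
    cols = [spec.outcome, spec.exposure, *cov, *extra_terms, spec.subject_col]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"model columns absent from data: {missing}")
    frame = data[list(dict.fromkeys(cols))].copy()
    for c in frame.columns:
        if frame[c].dtype == bool:
            frame[c] = frame[c].astype(float)
    n_before = len(frame)
    frame = frame.dropna()
    if n_before - len(frame):
        logger.debug(
            "%s ~ %s: %d incomplete rows dropped", spec.outcome, spec.exposure,
            n_before - len(frame),
        )
    return frame, cov


def _wald_p(z: float, df: float | None) -> float:
    if df is None:
        return float(2 * stats.norm.sf(abs(z)))
    return float(2 * stats.t.sf(abs(z), df))


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    reml: bool = True,
    p_reference: str = "normal",
    term: str | None = None,
) -> ModelResult:
    """REML fit of outcome ~ exposure + covariates + (1 | subject).

    Complete-case rows only.  When fewer than two subjects contribute
    repeated measures the model degenerates to OLS with a warning.  The
    Wald p-value for the exposure coefficient uses the normal reference by
    default; ``p_reference='t-resid'`` uses a t distribution on residual
    degrees of freedom (n - p - n_subjects_with_repeats) as a small-sample
    option.  ``term`` overrides which fixed-effect coefficient is
    reported (used for interaction terms).  A singular design is flagged
    as non-converged so it can be excluded from multiplicity counts.
    """
    import statsmodels.api as sm

    extra = [term] if term is not None and term not in (spec.exposure,) else []
    frame, cov = _model_frame(spec, data, extra_terms=[t for t in extra if t in data.columns])
    if term is not None and term not in frame.columns and ":" in term:
        a, b = term.split(":")
        frame[term] = frame[a] * frame[b]
    report = term if term is not None else spec.exposure
    fixed = list(dict.fromkeys([spec.exposure, *cov, *([term] if term else [])]))
    y = frame[spec.outcome].to_numpy(dtype=float)
    # fit on a standardized outcome with centered covariates for numerical
    # conditioning; the reported coefficient/SE are rescaled back exactly
    y_scale = float(np.std(y))
    if not np.isfinite(y_scale) or y_scale == 0:
        logger.warning("constant outcome %s; model degenerate", spec.outcome)
        return ModelResult(spec.outcome, report, np.nan, np.nan, np.nan,
                           len(frame), frame[spec.subject_col].nunique(), False, "lmm", cov)
    Xraw = frame[fixed].to_numpy(dtype=float)
    X = sm.add_constant(Xraw - Xraw.mean(axis=0, keepdims=True))
    names = ["const", *fixed]
    y = (y - y.mean()) / y_scale
    groups = frame[spec.subject_col].to_numpy()
    n_subjects = len(pd.unique(groups))
    repeats = pd.Series(groups).value_counts()
    n_repeated = int((repeats > 1).sum())

    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("singular design for %s ~ %s", spec.outcome, report)
        return ModelResult(spec.outcome, report, np.nan, np.nan, np.nan,
                           len(frame), n_subjects, False, "lmm", cov)

    if n_repeated < 2:
        warnings.warn(
            f"fewer than 2 subjects with repeated measures for {spec.outcome!r}; "
            "falling back to OLS"
        )
        fit = sm.OLS(y, X).fit()
        i = names.index(report)
        return ModelResult(spec.outcome, report, float(fit.params[i]) * y_scale,
                           float(fit.bse[i]) * y_scale,
                           float(fit.pvalues[i]), len(frame), n_subjects, True, "ols", cov)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed for %s ~ %s: %s", spec.outcome, report, exc)
            return ModelResult(spec.outcome, report, np.nan, np.nan, np.nan,
                               len(frame), n_subjects, False, "lmm", cov)
    i = names.index(report)
    beta = float(fit.params[i]) * y_scale
    se = float(fit.bse[i]) * y_scale
    converged = bool(np.isfinite(beta) and np.isfinite(se) and se > 0)
    if not converged:
        return ModelResult(spec.outcome, report, beta, se, np.nan,
                           len(frame), n_subjects, False, "lmm", cov)
    df = len(frame) - X.shape[1] - n_repeated if p_reference == "t-resid" else None
    p = _wald_p(beta / se, df if df is None or df > 0 else None)
    return ModelResult(spec.outcome, report, beta, se, p,
                       len(frame), n_subjects, True, "lmm", cov)


def interaction_age_pregnancies(
    data: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] | None = None,
    **kwargs,
) -> ModelResult:
    """Mixed model with an age x pregnancies product term; reports that term."""
    if covariates is None:
        covariates = tuple(
            c for c in DEFAULT_ADJUSTMENTS[AGE] if c != PREGNANCIES
        ) + (PREGNANCIES,)
    spec = ModelSpec(outcome=outcome, exposure=AGE, covariates=covariates)
    return fit_lmm(spec, data, term=f"{AGE}:{PREGNANCIES}", **kwargs)


def sensitivity_parous_only(
    spec: ModelSpec, data: pd.DataFrame, by: str = "pregnancies", **kwargs
) -> ModelResult:
    """Refit the model on parous women only.

    ``by='pregnancies'`` keeps subjects with n_pregnancies >= 1 (default);
    ``by='deliveries'`` uses n_deliveries >= 1.
    """
    col = {"pregnancies": PREGNANCIES, "deliveries": DELIVERIES}[by]
    if col not in data.columns:
        raise ValueError(f"parity column {col!r} absent from data")
    subset = data[data[col] >= 1]
    if subset.empty:
        raise ValueError("no parous subjects in data; sensitivity subset is empty")
    return fit_lmm(spec, subset, **kwargs)


# ---------------------------------------------------------------------------
# multiplicity


def adjust_multiplicity(
    p_values: pd.Series | Sequence[float],
    alpha: float = 0.05,
    literature_threshold: float = 0.005,
) -> MultiplicityDecision:
    """Flag each p-value at nominal, literature (0.005) and Bonferroni tiers.

    ``n_tests`` counts the finite p-values (non-converged models excluded);
    the Bonferroni cutoff is alpha / n_tests.
    """
    p = pd.Series(p_values, dtype=float)
    finite = p.notna()
    n_tests = int(finite.sum())
    if n_tests < 1:
        raise ValueError("multiplicity adjustment requires at least one test")
    bonf = alpha / n_tests
    flags = pd.DataFrame(
        {
            "pass_alpha": p < alpha,
            "pass_literature": p < literature_threshold,
            "pass_bonferroni": p < bonf,
        },
        index=p.index,
    )
    flags[~finite] = False
    return MultiplicityDecision(alpha, n_tests, literature_threshold, bonf, flags)


# ---------------------------------------------------------------------------
# simulation-based calibration


def recovery_simulation(
    n_replicates: int = 500,
    beta_age: float = 0.01,
    subject_sd: float = 0.5,
    residual_sd: float = 1.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model parameter recovery over replicate synthetic cohorts.

    Each replicate draws a fresh cohort at the default scale (100 women,
    161 samples), plants ``beta_age`` on the log-concentration scale for a
    single analyte, fits the subject-random-intercept model of log
    concentration on age, and records the estimate, its Wald interval
    coverage of the truth, and the p-value.  With ``beta_age=0`` the
    rejection rate at ``alpha`` estimates the type-I error.
    """
    from . import synthetic_data

    rows = []
    z = stats.norm.ppf(1 - alpha / 2)
    spec = ModelSpec(outcome="log_conc", exposure=AGE, covariates=())
    for rep in range(n_replicates):
        rep_seed = (seed * 100003 + rep) % (2**31)
        cohort = synthetic_data.generate_cohort(seed=rep_seed)
        effects = {
            "X": synthetic_data.EffectSpec(
                baseline_log_mean=0.0,
                coefficients={AGE: beta_age},
                subject_sd=subject_sd,
                residual_sd=residual_sd,
            )
        }
        matrix, _ = synthetic_data.generate_target_truth(
            cohort, effects, {"X": 1e-12}, seed=rep_seed
        )
        data = cohort.covariate_frame()
        data["log_conc"] = np.log(matrix.values.loc["X"].reindex(data.index))
        res = fit_lmm(spec, data)
        covered = (
            res.converged
            and res.coefficient - z * res.se <= beta_age <= res.coefficient + z * res.se
        )
        rows.append(
            {"replicate": rep, "beta_hat": res.coefficient, "se": res.se,
             "p_value": res.p_value, "converged": res.converged, "covered": bool(covered)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scans


def association_scan(
    outcomes: pd.DataFrame,
    data: pd.DataFrame,
    exposures: Sequence[str] = EXPOSURES,
    adjustments: Mapping[str, Sequence[str]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit one mixed model per (outcome column, exposure); tidy results.

    ``outcomes``: samples x outcome variables (already transformed);
    ``data``: samples x covariates including the subject column.  Returns
    a tidy frame with coefficient, se, p-value, counts and convergence.
    """
    rows = []
    merged = data.join(outcomes, how="inner")
    for out in outcomes.columns:
        for exp in exposures:
            cov = tuple(adjustments[exp]) if adjustments else None
            res = fit_lmm(ModelSpec(outcome=out, exposure=exp, covariates=cov),
                          merged, **kwargs)
            rows.append(
                {
                    "outcome": res.outcome, "exposure": res.exposure,
                    "coefficient": res.coefficient, "se": res.se,
                    "p_value": res.p_value, "n_samples": res.n_samples,
                    "n_subjects": res.n_subjects, "converged": res.converged,
                    "method": res.method,
                    "adjustment": "+".join(res.covariates),
                }
            )
    return pd.DataFrame(rows)
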