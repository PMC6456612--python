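"""Inter-eye-clustered association analysis.

Both eyes of a participant are correlated, so ordinary least squares would
understate the uncertainty of eye-level regressions.  Associations are
therefore estimated with generalized estimating equations (GEE): a linear
mean model with identity link, an exchangeable working correlation within
subject clusters (the natural choice for two-eye clusters), and robust
(sandwich) standard errors.  Confidence intervals are normal-approximation
Wald intervals on the robust SEs.

Covariate screening follows the two-step convention: every candidate factor
is fitted univariately; factors with p < 0.10 plus the forced biologically
plausible set (age, sex, diabetes) enter the multivariate model, with the
mutually exclusive ambulatory-BP summaries (overall/day/night, systolic vs
diastolic) fitted in separate adjusted models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import OUTCOME_COLUMNS, PER10_FACTORS

__all__ = [
    "AssociationResult",
    "RankDeficiencyError",
    "InsufficientDataError",
    "BP_FACTORS",
    "inter_eye_correlation",
    "fit_univariate",
    "fit_multivariate",
    "univariate_screen",
    "select_covariates",
    "multivariate_designs",
    "compare_groups",
    "association_table",
]


class RankDeficiencyError(ValueError):
    """The design matrix is singular (collinear columns)."""


class InsufficientDataError(ValueError):
    """Too few observations/clusters for the requested estimate."""


#: Mutually exclusive ambulatory-BP summaries: each enters its own
#: multivariate model.
BP_FACTORS = ("sbp_overall", "sbp_day", "sbp_night", "dbp_overall", "dbp_day", "dbp_night")

#: Categorical factors with their reference level and remaining levels
#: (reference first: male sex, never-smoker, intensive control, one class).
CATEGORICAL_FACTORS: dict[str, tuple[str, tuple[str, ...]]] = {
    "sex": ("male", ("female",)),
    "smoking": ("never", ("past", "current")),
    "bp_control": ("intensive", ("standard", "poor")),
    "n_meds_class": ("1", ("2", "3+")),
}

_SCALE_NOTES = {
    "age": "per 10 years",
    "sbp_overall": "per 10 mmHg",
    "sbp_day": "per 10 mmHg",
    "sbp_night": "per 10 mmHg",
    "dbp_overall": "per 10 mmHg",
    "dbp_day": "per 10 mmHg",
    "dbp_night": "per 10 mmHg",
}


@dataclass(frozen=True)
class AssociationResult:
    """One regression coefficient with its robust 95% CI and p-value."""

    outcome: str
    factor: str
    scale_note: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # "univariate" | "multivariate"
    n_eyes: int
    n_subjects: int

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low - 1e-12 <= self.beta <= self.ci_high + 1e-12):
                raise ValueError("beta outside its own confidence interval")
        if self.n_eyes < self.n_subjects:
            raise ValueError("n_eyes cannot be smaller than n_subjects")


def _outcome_column(table: pd.DataFrame, outcome: str) -> str:
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    if col not in table.columns:
        raise KeyError(f"outcome column {col!r} not in table")
    return col


def _encode_factor(table: pd.DataFrame, factor: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand one factor into design columns; returns (columns, labels)."""
    if factor in CATEGORICAL_FACTORS:
        ref, levels = CATEGORICAL_FACTORS[factor]
        observed = set(table[factor].dropna().unique())
        unknown = observed - {ref} - set(levels)
        if unknown:
            raise ValueError(f"unknown {factor} levels {sorted(unknown)}")
        cols, labels = {}, {}
        for lvl in levels:
            if lvl in observed:
                name = f"{factor}[{lvl}]"
                cols[name] = (table[factor] == lvl).astype(float)
                labels[name] = f"{factor}: {lvl} vs {ref}"
        return pd.DataFrame(cols, index=table.index), labels
    if factor not in table.columns:
        raise KeyError(f"factor column {factor!r} not in table")
    vals = table[factor]
    if vals.dtype == bool:
        vals = vals.astype(float)
    vals = pd.to_numeric(vals)
    if factor in PER10_FACTORS:
        vals = vals / 10.0
    return pd.DataFrame({factor: vals.astype(float)}, index=table.index), {factor: factor}


def _build_design(
    table: pd.DataFrame, factors: Sequence[str], outcome: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict[str, str]]:
    """Complete-case design matrix with intercept, plus outcome and groups."""
    ocol = _outcome_column(table, outcome)
    pieces, labels = [], {}
    raw_cols = set()
    for factor in factors:
        cols, lab = _encode_factor(table, factor)
        pieces.append(cols)
        labels.update(lab)
        raw_cols.add(factor if factor in table.columns else factor)
    X = pd.concat(pieces, axis=1)
    frame = pd.concat([table[[ocol, "subject_id"]], X], axis=1)
    frame = frame.dropna()
    if len(frame) == 0:
        raise InsufficientDataError("no complete cases")
    X = frame[X.columns]
    X = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns: {list(X.columns)})"
        )
    return X, frame[ocol], frame["subject_id"], labels


def _fit_gee(
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series,
    cov_struct: str = "exchangeable",
):
    sizes = groups.value_counts()
    if cov_struct == "independence" or (sizes <= 1).all():
        # no intra-cluster pairs: the exchangeable parameter is undefined and
        # the estimator reduces to (robust-SE) OLS
        dep = sm.cov_struct.Independence()
    elif cov_struct == "exchangeable":
        dep = sm.cov_struct.Exchangeable()
    else:
        raise ValueError(f"unknown working correlation {cov_struct!r}")
    model = sm.GEE(
        endog=np.asarray(y, dtype=float),
        exog=X,
        groups=np.asarray(groups),
        family=sm.families.Gaussian(),
        cov_struct=dep,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return model.fit(maxiter=100)


def _results_from_fit(
    res,
    labels: Mapping[str, str],
    outcome: str,
    model_tag: str,
    n_eyes: int,
    n_subjects: int,
    factor_of_col: Mapping[str, str],
) -> list[AssociationResult]:
    ci = res.conf_int()
    out = []
    for col in res.params.index:
        if col == "const":
            continue
        beta = float(res.params[col])
        lo, hi = float(ci.loc[col, 0]), float(ci.loc[col, 1])
        p = float(res.pvalues[col])
        base = factor_of_col[col]
        out.append(
            AssociationResult(
                outcome=outcome,
                factor=labels.get(col, col),
                scale_note=_SCALE_NOTES.get(base, ""),
                beta=beta,
                ci_low=min(lo, beta),
                ci_high=max(hi, beta),
                p_value=p,
                model=model_tag,
                n_eyes=n_eyes,
                n_subjects=n_subjects,
            )
        )
    return out


def _fit_factors(
    table: pd.DataFrame,
    factors: Sequence[str],
    outcome: str,
    model_tag: str,
    cov_struct: str,
    min_clusters: int,
) -> list[AssociationResult]:
    X, y, groups, labels = _build_design(table, factors, outcome)
    n_subjects = groups.nunique()
    if n_subjects < min_clusters:
        raise InsufficientDataError(
            f"need >= {min_clusters} clusters, got {n_subjects}"
        )
    factor_of_col = {}
    for factor in factors:
        if factor in CATEGORICAL_FACTORS:
            _, levels = CATEGORICAL_FACTORS[factor][0], CATEGORICAL_FACTORS[factor][1]
            for lvl in levels:
                factor_of_col[f"{factor}[{lvl}]"] = factor
        else:
            factor_of_col[factor] = factor
    res = _fit_gee(X, y, groups, cov_struct)
    return _results_from_fit(
        res, labels, outcome, model_tag, n_eyes=len(y), n_subjects=n_subjects,
        factor_of_col=factor_of_col,
    )


def fit_univariate(
    table: pd.DataFrame,
    factor: str,
    outcome: str,
    cov_struct: str = "exchangeable",
    min_clusters: int = 10,
) -> list[AssociationResult]:
    """GEE regression of one outcome on a single factor.

    Returns one result per design column (categorical factors expand against
    their reference level).
    """
    return _fit_factors(table, [factor], outcome, "univariate", cov_struct, min_clusters)


def fit_multivariate(
    table: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str,
    cov_struct: str = "exchangeable",
    min_clusters: int = 10,
) -> list[AssociationResult]:
    """Joint GEE model; one result per covariate column."""
    return _fit_factors(
        table, list(covariates), outcome, "multivariate", cov_struct, min_clusters
    )


def univariate_screen(
    table: pd.DataFrame,
    factors: Sequence[str],
    outcome: str,
    cov_struct: str = "exchangeable",
) -> tuple[list[AssociationResult], dict[str, float]]:
    """Fit every candidate factor univariately.

    Returns all per-column results plus one screening p-value per factor
    (the smallest level p-value for categorical factors).
    """
    results: list[AssociationResult] = []
    pvalues: dict[str, float] = {}
    for factor in factors:
        rows = fit_univariate(table, factor, outcome, cov_struct=cov_struct)
        results.extend(rows)
        pvalues[factor] = min(r.p_value for r in rows)
    return results, pvalues


def select_covariates(
    pvalues: Mapping[str, float],
    p_threshold: float = 0.10,
    forced: Sequence[str] = ("age", "sex", "diabetes"),
) -> list[str]:
    """Forced covariates plus every factor with univariate p strictly below
    the threshold (p exactly at the threshold is excluded)."""
    selected = list(forced)
    for factor, p in pvalues.items():
        if factor not in selected and p < p_threshold:
            selected.append(factor)
    return selected


def multivariate_designs(covariates: Sequence[str]) -> list[list[str]]:
    """Split a covariate set into adjusted models, one per ambulatory-BP
    summary (the six BP summaries are near-collinear and never co-enter)."""
    base = [c for c in covariates if c not in BP_FACTORS]
    bps = [c for c in covariates if c in BP_FACTORS]
    if not bps:
        return [base]
    return [base + [bp] for bp in bps]


def inter_eye_correlation(
    eyes: pd.DataFrame, metric: str, min_pairs: int = 3
) -> tuple[float, float]:
    """Pearson correlation of a metric between right and left eyes.

    Restricted to subjects contributing both eyes; returns ``(r, p)``.
    """
    col = OUTCOME_COLUMNS.get(metric, metric)
    wide = eyes.pivot_table(index="subject_id", columns="eye", values=col)
    if "OD" not in wide.columns or "OS" not in wide.columns:
        raise InsufficientDataError("need both OD and OS eyes")
    wide = wide[["OD", "OS"]].dropna()
    if len(wide) < min_pairs:
        raise InsufficientDataError(
            f"need >= {min_pairs} two-eyed subjects, got {len(wide)}"
        )
    r, p = sps.pearsonr(wide["OD"], wide["OS"])
    return float(r), float(p)


# --- descriptive group comparisons -------------------------------------------


def _fisher_p(table: np.ndarray, rng: np.random.Generator, n_mc: int) -> float:
    """Exact p for 2x2; fixed-margin Monte Carlo for larger tables."""
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table)[1])
    row, col = table.sum(axis=1), table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_stat = np.nansum((table - expected) ** 2 / expected)
    dist = sps.random_table(row, col)
    samples = dist.rvs(n_mc, random_state=rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_mc = np.nansum((samples - expected) ** 2 / expected, axis=(1, 2))
    # add-one correction keeps the MC p-value valid
    return float((1 + np.sum(stats_mc >= obs_stat - 1e-12)) / (1 + n_mc))


def compare_groups(
    participants: pd.DataFrame,
    by: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    alpha: float = 0.05,
    mc_iterations: int = 5000,
    seed: int = 2301,
) -> pd.DataFrame:
    """Descriptive comparison of participant characteristics across groups.

    Continuous variables: a Shapiro-Wilk test on the pooled within-group
    residuals (alpha = 0.05) routes each variable to one-way ANOVA (summary
    mean +/- SD) or Kruskal-Wallis (median (IQR)).  Categorical variables:
    chi-square, switching to Fisher's exact test (Monte Carlo for tables
    larger than 2x2) whenever an expected cell count is below 5.  Degenerate
    one-level factors are reported as not applicable with p = 1.
    """
    groups = participants.groupby(by, observed=True)
    if groups.ngroups < 2:
        raise ValueError(f"need >= 2 groups in {by!r}, got {groups.ngroups}")
    if (groups.size() < 2).any():
        raise ValueError("every group must have >= 2 members")
    rng = np.random.default_rng(seed)
    rows = []
    group_names = list(groups.groups)
    for var in continuous:
        per_group = [g[var].dropna().to_numpy(float) for _, g in groups]
        pooled_resid = np.concatenate([v - v.mean() for v in per_group])
        sw_p = float(sps.shapiro(pooled_resid).pvalue)
        if sw_p >= alpha:
            stat, p = sps.f_oneway(*per_group)
            test = "anova"
            summaries = [f"{v.mean():.1f} ± {v.std(ddof=1):.1f}" for v in per_group]
        else:
            stat, p = sps.kruskal(*per_group)
            test = "kruskal-wallis"
            summaries = [
                f"{np.median(v):.1f} ({np.percentile(v, 25):.1f}-{np.percentile(v, 75):.1f})"
                for v in per_group
            ]
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "test": test,
                "shapiro_p": sw_p,
                "statistic": float(stat),
                "p_value": float(p),
                **dict(zip(group_names, summaries)),
            }
        )
    for var in categorical:
        ct = pd.crosstab(participants[var], participants[by])
        counts = ct.to_numpy()
        col_tot = counts.sum(axis=0)
        summaries = [
            "; ".join(
                f"{lvl}: {ct.iloc[i, j]} ({100 * ct.iloc[i, j] / col_tot[j]:.0f}%)"
                for i, lvl in enumerate(ct.index)
            )
            for j in range(ct.shape[1])
        ]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            rows.append(
                {
                    "variable": var,
                    "kind": "categorical",
                    "test": "not_applicable",
                    "shapiro_p": np.nan,
                    "statistic": np.nan,
                    "p_value": 1.0,
                    **dict(zip(group_names, summaries)),
                }
            )
            continue
        chi2, chi_p, _, expected = sps.chi2_contingency(counts)
        if (expected < 5).any():
            p = _fisher_p(counts, rng, mc_iterations)
            test, stat = "fisher", np.nan
        else:
            test, stat, p = "chi-square", float(chi2), float(chi_p)
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                "test": test,
                "shapiro_p": np.nan,
                "statistic": stat,
                "p_value": float(p),
                **dict(zip(group_names, summaries)),
            }
        )
    return pd.DataFrame(rows)


def association_table(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Flatten association results for CSV export (p shown to 3 decimals in
    reports; stored here at full precision)."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "factor": r.factor,
                "scale": r.scale_note,
                "model": r.model,
                "beta": r.beta,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_eyes": r.n_eyes,
                "n_subjects": r.n_subjects,
            }
            for r in results
        ]
    )
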