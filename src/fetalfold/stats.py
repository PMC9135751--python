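"""Cohort statistics: demographics tests, GEE battery, FDR, ICC, growth fits.

The modelling core follows the repeated-scans design of the cohort: mothers
may contribute up to two fetal scans, so cohort comparisons use generalized
estimating equations (Gaussian family, identity link, exchangeable working
correlation, robust sandwich covariance clustered on mother).  The
declarative battery enumerator expands the full analysis plan — cohort
effects on distress (Step 1), on brain volumes and cortical features with
and without distress adjustment (Step 2), within distress strata (Step 3),
plus distress-association, gestational-age interaction, sensitivity,
laterality and parental sub-analyses — and every battery carries its
false-discovery-rate family (6 tissues, 4 lobes, or 3 global features).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .distress import DEFAULT_THRESHOLDS, MEASURES
from .errors import ConvergenceError, ValidationError
from .volume import LOBES, TISSUES

log = logging.getLogger(__name__)

FEATURES = ("area", "lgi", "depth")
BASE_COVARIATES = ("cohort", "ga_mri_weeks", "sex")

#: the 18 brain outcomes of the main battery: 6 tissue volumes and
#: 3 cortical features on 4 lobes
VOLUME_OUTCOMES: tuple[str, ...] = tuple(TISSUES)
FEATURE_OUTCOMES: tuple[str, ...] = tuple(
    f"{f}_{lobe}" for f in FEATURES for lobe in LOBES
)
GLOBAL_OUTCOMES: tuple[str, ...] = tuple(f"{f}_global" for f in FEATURES)
BRAIN_OUTCOMES: tuple[str, ...] = VOLUME_OUTCOMES + FEATURE_OUTCOMES


# -- simple screens and tests -------------------------------------------------


def normality_screen(x) -> float:
    """Two-sided Shapiro-Wilk p-value for departure from normality."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("sample is constant; normality test undefined")
    return float(sps.shapiro(x).pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration for small tie-free samples (both n <= 8); otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    has_ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square test (no continuity correction) on an r x c table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValidationError("table must be a 2-D contingency table")
    res = sps.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValidationError("all expected counts must be positive")
    return float(res.statistic), float(res.pvalue)


def icc_agreement(ratings) -> float:
    """Two-way random, absolute-agreement, single-measure ICC — ICC(2,1).

    ``ratings`` is an items x raters matrix (>= 3 items).  Computed from the
    standard two-way ANOVA mean squares; identical raters give exactly 1.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValidationError("ratings must be (items >= 3) x (raters >= 2)")
    if not np.all(np.isfinite(r)):
        raise ValidationError("ratings must be complete")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((r - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValidationError("ratings have no variance; ICC undefined")
    return float((msr - mse) / denom)


# -- multiple testing ----------------------------------------------------------


@dataclass
class FDRResult:
    """Benjamini-Hochberg q-values for one declared outcome family."""

    family: str
    pvalues: np.ndarray
    qvalues: np.ndarray


def bh_fdr(pvalues, family: str = "") -> FDRResult:
    """Benjamini-Hochberg step-up q-values with the monotonicity pass."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return FDRResult(family=family, pvalues=p, qvalues=q)


# -- growth-curve fits ---------------------------------------------------------


@dataclass
class GrowthFit:
    """Least-squares growth curve of an outcome against gestational age.

    Exponential fits are log-linearized: ``y = exp(a + b * GA)``.
    """

    form: str
    intercept: float
    slope: float

    def predict(self, ga) -> np.ndarray:
        ga = np.asarray(ga, dtype=float)
        lin = self.intercept + self.slope * ga
        return np.exp(lin) if self.form == "exponential" else lin


def growth_fit(ga, y, form: str = "exponential") -> GrowthFit:
    """Fit an exponential (log-linear) or linear growth curve."""
    ga = np.asarray(ga, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(ga) & np.isfinite(y)
    ga, y = ga[ok], y[ok]
    if len(ga) < 2:
        raise ValidationError("need at least two points for a growth fit")
    if form == "exponential":
        if np.any(y <= 0):
            raise ValidationError("exponential fit requires positive outcomes")
        b, a = np.polyfit(ga, np.log(y), 1)
    elif form == "linear":
        b, a = np.polyfit(ga, y, 1)
    else:
        raise ValidationError(f"unknown growth form {form!r}")
    return GrowthFit(form=form, intercept=float(a), slope=float(b))


# -- GEE machinery -------------------------------------------------------------


class _FixedExchangeable(sm.cov_struct.Exchangeable):
    """Exchangeable working correlation frozen at a given value."""

    def __init__(self, rho: float) -> None:
        super().__init__()
        self.dep_params = rho

    def update(self, params) -> None:  # noqa: ARG002 - fixed by construction
        return


def _one_step_rho(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, rho_lo: float
) -> float:
    """One-step moment estimate of the exchangeable correlation.

    Uses OLS residuals: mean within-cluster cross-product over the residual
    variance, clipped strictly inside the feasible range.
    """
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    scale = float(resid @ resid) / max(len(y) - X.shape[1], 1)
    num = 0.0
    npairs = 0
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    r = resid[order]
    boundaries = np.r_[0, np.nonzero(g[1:] != g[:-1])[0] + 1, len(g)]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        e = r[a:b]
        if len(e) > 1:
            num += (e.sum() ** 2 - (e**2).sum()) / 2.0
            npairs += len(e) * (len(e) - 1) // 2
    if npairs == 0 or scale == 0:
        return 0.0
    rho = num / (npairs * scale)
    return float(np.clip(rho, rho_lo + 1e-3, 0.999))


@dataclass(frozen=True)
class GEESpec:
    """Declarative specification of one GEE model.

    ``covariates`` name record columns; an entry ``"a:b"`` adds the product
    interaction of two columns.  ``term`` is the coefficient under test.
    ``subset`` is a pandas query string applied before fitting.
    """

    outcome: str
    covariates: tuple[str, ...]
    term: str = "cohort"
    subset: str | None = None
    fdr_family: str = ""
    battery: str = ""
    cluster: str = "subject_id"

    def __post_init__(self) -> None:
        if self.outcome in self.covariates:
            raise ValidationError("outcome cannot appear among covariates")
        if self.term not in self.covariates:
            raise ValidationError(f"tested term {self.term!r} not in covariates")

    @property
    def label(self) -> str:
        sub = f" | {self.subset}" if self.subset else ""
        return f"{self.outcome} ~ {' + '.join(self.covariates)}{sub}"


@dataclass
class GEEFit:
    """A fitted GEE: coefficients, robust covariance, Wald tests, LS-means."""

    spec: GEESpec
    params: pd.Series
    cov: pd.DataFrame
    pvalues: pd.Series
    n_obs: int
    n_clusters: int
    converged: bool
    working_correlation: float
    correlation_structure: str
    covariate_means: pd.Series

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def _base_columns(covariates: tuple[str, ...]) -> list[str]:
    cols: list[str] = []
    for c in covariates:
        for part in c.split(":"):
            if part not in cols:
                cols.append(part)
    return cols


def _design_matrix(df: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for c in covariates:
        if ":" in c:
            a, b = c.split(":")
            X[c] = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            X[c] = df[c].to_numpy(float)
    return X


def fit_gee(records: pd.DataFrame, spec: GEESpec) -> GEEFit:
    """Fit one Gaussian-identity GEE with exchangeable working correlation.

    Rows with missing values in any used column are dropped (complete-case);
    the robust sandwich covariance clusters on ``spec.cluster``.
    """
    cols = [spec.outcome, *_base_columns(spec.covariates), spec.cluster]
    for c in cols:
        if c not in records.columns:
            raise ValidationError(f"column {c!r} not in records")
    df = records.query(spec.subset) if spec.subset else records
    df = df[cols].dropna()
    if df[spec.cluster].nunique() < 2:
        raise ValidationError(
            f"fewer than 2 clusters after filtering for {spec.label}"
        )
    X = _design_matrix(df, spec.covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError(f"design matrix is rank deficient for {spec.label}")

    y = df[spec.outcome].to_numpy(float)
    groups = df[spec.cluster].to_numpy()

    if np.ptp(y) == 0:
        # degenerate but well-defined: intercept carries the constant,
        # every slope is zero, and no sampling variability exists
        names = list(X.columns)
        params = pd.Series(0.0, index=names)
        params["intercept"] = float(y[0])
        zeros = pd.DataFrame(0.0, index=names, columns=names)
        return GEEFit(
            spec=spec,
            params=params,
            cov=zeros,
            pvalues=pd.Series(np.nan, index=names),
            n_obs=len(df),
            n_clusters=df[spec.cluster].nunique(),
            converged=True,
            working_correlation=0.0,
            correlation_structure="degenerate (constant outcome)",
            covariate_means=X.mean(axis=0),
        )

    def _fit(cov_struct):
        model = sm.GEE(
            y,
            X.to_numpy(),
            groups=groups,
            family=sm.families.Gaussian(),
            cov_struct=cov_struct,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IterationLimitWarning)
            # the unstable correlation update can transiently divide by zero
            # before the fixed-correlation fallback takes over
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(maxiter=100, ctol=1e-8)
        return model, res

    structure = "exchangeable"
    model, res = _fit(sm.cov_struct.Exchangeable())
    rho = float(np.atleast_1d(model.cov_struct.dep_params)[0])
    max_size = int(np.max(np.unique(groups, return_counts=True)[1]))
    rho_lo = -1.0 / (max_size - 1) if max_size > 1 else -1.0
    if not getattr(res, "converged", True) or not rho_lo < rho < 1.0:
        # the jointly iterated correlation estimate can cycle (and escape its
        # valid range) when pairs are scarce; freeze the correlation at the
        # stable one-step moment estimate and solve the coefficients under it
        rho = _one_step_rho(y, X.to_numpy(), groups, rho_lo)
        log.warning(
            "exchangeable GEE did not settle for %s; refitting with the "
            "correlation fixed at %.3f", spec.label, rho,
        )
        structure = "exchangeable (one-step)"
        model, res = _fit(_FixedExchangeable(rho))
        if not getattr(res, "converged", True):
            raise ConvergenceError(f"GEE did not converge for {spec.label}")

    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    pvals = pd.Series(res.pvalues, index=names)
    means = X.mean(axis=0)
    return GEEFit(
        spec=spec,
        params=params,
        cov=cov,
        pvalues=pvals,
        n_obs=len(df),
        n_clusters=df[spec.cluster].nunique(),
        converged=True,
        working_correlation=(
            0.0
            if model.cov_struct.dep_params is None
            else float(np.atleast_1d(model.cov_struct.dep_params)[0])
        ),
        correlation_structure=structure,
        covariate_means=means,
    )


def ls_means(fit: GEEFit, levels: tuple[float, float] = (0.0, 1.0)) -> pd.DataFrame:
    """Cohort least-squares means: predictions at reference covariate values.

    Non-cohort covariates are held at their fitted-sample means (sex at its
    sample proportion); interactions involving cohort are recomputed at each
    cohort level.  With the identity link the LS-mean difference equals the
    cohort coefficient exactly.
    """
    if "cohort" not in fit.params.index:
        raise ValidationError("model does not contain a cohort term")
    rows = []
    for level in levels:
        x = fit.covariate_means.copy()
        x["cohort"] = level
        for name in fit.params.index:
            if ":" in name:
                a, b = name.split(":")
                if "cohort" in (a, b):
                    other = b if a == "cohort" else a
                    x[name] = level * fit.covariate_means[other]
        xv = x[fit.params.index].to_numpy(float)
        mean = float(xv @ fit.params.to_numpy())
        se = float(np.sqrt(xv @ fit.cov.to_numpy() @ xv))
        rows.append({"cohort": level, "lsmean": mean, "se": se})
    return pd.DataFrame(rows)


# -- the analysis-plan enumerator ---------------------------------------------

BATTERY_NAMES = (
    "step1",
    "step2",
    "step3",
    "distress_association",
    "interaction",
    "sensitivity",
    "laterality",
    "parental",
)


def _family(outcome: str, tag: str) -> str:
    """FDR family of an outcome: 6 tissues, one 4-lobe family per feature,
    or the 3 global features."""
    if outcome in VOLUME_OUTCOMES or outcome.rsplit("_", 1)[0] in VOLUME_OUTCOMES:
        return f"{tag}:volumes"
    if outcome in GLOBAL_OUTCOMES or outcome.startswith(
        tuple(f"{f}_global" for f in FEATURES)
    ):
        return f"{tag}:global"
    return f"{tag}:{outcome.split('_')[0]}"


def enumerate_models(
    battery: str,
    step3_measures: tuple[str, ...] = ("pss", "epds"),
    thresholds: dict[str, int] | None = None,
) -> list[GEESpec]:
    """Expand one named battery of the analysis plan into GEE specs.

    The expansion is deterministic and order-stable.  ``step3_measures`` is
    the explicit list of distress measures carried into the stratified
    Step-3 battery (the measures found cohort-associated in Step 1).
    """
    th = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    specs: list[GEESpec] = []

    if battery == "step1":
        for m in MEASURES:
            for stratum, subset in (
                ("all", None),
                ("low", f"{m} <= {th[m]}"),
                ("high", f"{m} > {th[m]}"),
            ):
                specs.append(
                    GEESpec(
                        outcome=m,
                        covariates=BASE_COVARIATES,
                        term="cohort",
                        subset=subset,
                        fdr_family=f"step1:{stratum}",
                        battery=battery,
                    )
                )
    elif battery == "step2":
        for outcome in BRAIN_OUTCOMES:
            specs.append(
                GEESpec(
                    outcome=outcome,
                    covariates=BASE_COVARIATES,
                    fdr_family=_family(outcome, "step2:unadjusted"),
                    battery=battery,
                )
            )
        for m in MEASURES:
            for outcome in BRAIN_OUTCOMES:
                specs.append(
                    GEESpec(
                        outcome=outcome,
                        covariates=(*BASE_COVARIATES, m),
                        fdr_family=_family(outcome, f"step2:adj_{m}"),
                        battery=battery,
                    )
                )
    elif battery == "step3":
        for m in step3_measures:
            for stratum, op in (("low", "<="), ("high", ">")):
                subset = f"{m} {op} {th[m]}"
                for outcome in (*VOLUME_OUTCOMES, *GLOBAL_OUTCOMES):
                    specs.append(
                        GEESpec(
                            outcome=outcome,
                            covariates=BASE_COVARIATES,
                            subset=subset,
                            fdr_family=_family(outcome, f"step3:{m}:{stratum}"),
                            battery=battery,
                        )
                    )
    elif battery == "distress_association":
        for m in MEASURES:
            for outcome in BRAIN_OUTCOMES:
                specs.append(
                    GEESpec(
                        outcome=outcome,
                        covariates=(m, "ga_mri_weeks", "sex"),
                        term=m,
                        fdr_family=_family(outcome, f"assoc:{m}"),
                        battery=battery,
                    )
                )
    elif battery == "interaction":
        for outcome in FEATURE_OUTCOMES:
            specs.append(
                GEESpec(
                    outcome=outcome,
                    covariates=(*BASE_COVARIATES, "cohort:ga_mri_weeks"),
                    term="cohort:ga_mri_weeks",
                    fdr_family=_family(outcome, "interaction"),
                    battery=battery,
                )
            )
    elif battery == "sensitivity":
        scenarios = (
            ("ga28", "ga_mri_weeks >= 28"),
            ("age40", "maternal_age <= 40"),
        )
        for tag, subset in scenarios:
            for base in enumerate_models("step2", step3_measures, thresholds):
                specs.append(
                    GEESpec(
                        outcome=base.outcome,
                        covariates=base.covariates,
                        term=base.term,
                        subset=subset,
                        fdr_family=f"sens:{tag}:{base.fdr_family}",
                        battery=battery,
                    )
                )
    elif battery == "laterality":
        for hemi in ("left", "right"):
            for outcome in BRAIN_OUTCOMES:
                specs.append(
                    GEESpec(
                        outcome=f"{outcome}_{hemi}",
                        covariates=BASE_COVARIATES,
                        fdr_family=_family(outcome, f"laterality:{hemi}"),
                        battery=battery,
                    )
                )
    elif battery == "parental":
        for var in ("mat_edu", "pat_edu", "mat_empl", "pat_empl"):
            for outcome in BRAIN_OUTCOMES:
                specs.append(
                    GEESpec(
                        outcome=outcome,
                        covariates=(var, "ga_mri_weeks", "sex"),
                        term=var,
                        fdr_family=_family(outcome, f"parental:{var}"),
                        battery=battery,
                    )
                )
    else:
        raise ValidationError(
            f"unknown battery {battery!r}; expected one of {BATTERY_NAMES}"
        )
    return specs


def battery_sizes() -> dict[str, int]:
    """Number of models in each named battery of the analysis plan."""
    return {name: len(enumerate_models(name)) for name in BATTERY_NAMES}


def run_battery(
    records: pd.DataFrame,
    specs: list[GEESpec],
    alpha: float = 0.05,
    with_lsmeans: bool = False,
) -> pd.DataFrame:
    """Fit a battery and assemble the Table-2-style results grid.

    One row per model: tested-term coefficient, robust SE, Wald p, BH q
    within the model's FDR family, and the dual significance flags
    (``bold_p`` for raw p < alpha, ``fdr_pass`` for q < alpha).
    """
    rows = []
    for spec in specs:
        fit = fit_gee(records, spec)
        row = {
            "battery": spec.battery,
            "outcome": spec.outcome,
            "term": spec.term,
            "subset": spec.subset or "",
            "covariates": " + ".join(spec.covariates),
            "fdr_family": spec.fdr_family,
            "beta": fit.params[spec.term],
            "se": fit.se[spec.term],
            "p": fit.pvalues[spec.term],
            "n_obs": fit.n_obs,
            "n_clusters": fit.n_clusters,
        }
        if with_lsmeans and "cohort" in spec.covariates:
            lsm = ls_means(fit)
            row["lsmean_pre"] = lsm.loc[0, "lsmean"]
            row["lsmean_se_pre"] = lsm.loc[0, "se"]
            row["lsmean_pandemic"] = lsm.loc[1, "lsmean"]
            row["lsmean_se_pandemic"] = lsm.loc[1, "se"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for fam, idx in out.groupby("fdr_family").groups.items():
        res = bh_fdr(out.loc[idx, "p"].to_numpy(), family=str(fam))
        out.loc[idx, "q"] = res.qvalues
    out["bold_p"] = out["p"] < alpha
    out["fdr_pass"] = out["q"] < alpha
    return out
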