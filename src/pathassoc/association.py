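"""Per-SNP logistic-regression inference.

Case/control status is regressed on minor-allele dosage (0/1/2), optionally
adjusted for sex, attained (or referent) age in four categories and year of
birth as an ordinal. The 1-df trend p-value is Wald by default with a
likelihood-ratio variant behind a flag. Genotype-category odds ratios use the
common homozygote as reference. A fully vectorised crude (covariate-free)
trend fitter serves the permutation inner loop of the ARTP stage.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .data_model import Dataset

__all__ = [
    "ModelSpec",
    "FitSummary",
    "AssociationResult",
    "fit_logistic",
    "build_design",
    "trend_test",
    "genotype_category_or",
    "interaction_lrt",
    "crude_or_2x2",
    "trend_p_matrix",
]

AGE_BREAKS = (35, 45, 55)       # <35, 35-44, 45-54, 55+ (left-closed lower bounds)
BIRTH_YEAR_BREAKS = (1940, 1950)  # <1940 -> 0, 1940-1949 -> 1, 1950+ -> 2
_SEPARATION_BOUND = 15.0        # |beta| beyond this flags quasi-complete separation


@dataclasses.dataclass
class ModelSpec:
    """Covariate specification for the per-SNP logistic models.

    ``adjusted=True`` includes sex, the four attained-age categories and the
    birth-year ordinal; extra covariate column names may be appended.
    ``trend_statistic`` selects Wald (default) or LRT for the 1-df trend p.
    """

    adjusted: bool = True
    extra_covariates: tuple[str, ...] = ()
    trend_statistic: str = "wald"


@dataclasses.dataclass
class FitSummary:
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_iter: int
    converged: bool
    column_names: list[str]
    dropped_columns: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class AssociationResult:
    snp_id: str
    counts_cases: tuple[int, int, int]
    counts_controls: tuple[int, int, int]
    per_allele_or: float
    per_allele_ci: tuple[float, float]
    p_trend: float
    or_het: float | None
    ci_het: tuple[float, float] | None
    or_hom: float | None
    ci_hom: tuple[float, float] | None
    converged: bool


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Deterministically drop rightmost columns until the design has full rank."""
    keep = list(range(X.shape[1]))
    dropped: list[str] = []
    while keep and np.linalg.matrix_rank(X[:, keep]) < len(keep):
        # remove the rightmost column involved in the deficiency
        for j in range(len(keep) - 1, 0, -1):
            sub = keep[:j] + keep[j + 1:]
            if np.linalg.matrix_rank(X[:, sub]) == np.linalg.matrix_rank(X[:, keep]):
                dropped.append(names[keep[j]])
                keep = sub
                break
        else:
            break
    return X[:, keep], [names[i] for i in keep], dropped


def fit_logistic(outcome: np.ndarray, design: np.ndarray | pd.DataFrame,
                 column_names: list[str] | None = None) -> FitSummary:
    """Maximum-likelihood logistic fit (Newton scoring) with separation and
    rank-deficiency handling.

    Diverging coefficients (|beta| > 15 on the logit scale) or failure to
    converge are flagged; downstream consumers report undefined odds ratios
    for flagged fits rather than numbers.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(design, pd.DataFrame):
        column_names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        column_names = column_names or [f"x{i}" for i in range(X.shape[1])]
    if y.min() == y.max():
        raise ValueError("outcome needs at least one case and one control")

    X, kept_names, dropped = _drop_aliased(X, column_names)
    with np.errstate(all="ignore"):
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
            llf = float(res.llf)
            n_iter = int(res.mle_retvals.get("iterations", 0))
        except (np.linalg.LinAlgError, ValueError):
            converged = False
            params = np.full(X.shape[1], np.nan)
            cov = np.full((X.shape[1], X.shape[1]), np.nan)
            llf = float("nan")
            n_iter = 0
    if converged and np.any(np.abs(params) > _SEPARATION_BOUND):
        converged = False  # quasi-complete separation
    return FitSummary(params=params, cov_params=cov, llf=llf, n_iter=n_iter,
                      converged=converged, column_names=kept_names,
                      dropped_columns=dropped)


def age_category(age: np.ndarray) -> np.ndarray:
    """0: <35, 1: 35-44, 2: 45-54, 3: 55+ (boundary goes up: 35 -> '35-44')."""
    a = np.asarray(age, dtype=float)
    return np.digitize(a, AGE_BREAKS)


def birth_year_ordinal(birth_year: np.ndarray) -> np.ndarray:
    return np.digitize(np.asarray(birth_year, dtype=float), BIRTH_YEAR_BREAKS)


def build_design(subjects: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Covariate design matrix (with intercept, without the genotype term)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(subjects))}
    if spec.adjusted:
        cols["male"] = (subjects["sex"] == "M").to_numpy(dtype=float)
        cat = age_category(subjects["age"].to_numpy(dtype=float))
        for k, label in ((1, "age_35_44"), (2, "age_45_54"), (3, "age_55plus")):
            cols[label] = (cat == k).astype(float)
        cols["birth_year_ord"] = birth_year_ordinal(
            subjects["birth_year"].to_numpy(dtype=float)
        ).astype(float)
    for name in spec.extra_covariates:
        cols[name] = subjects[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=subjects.index)


def _wald_or_ci(beta: float, se: float) -> tuple[float, tuple[float, float]]:
    return math.exp(beta), (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))


def _complete_rows(dosage: np.ndarray, design: pd.DataFrame) -> np.ndarray:
    ok = ~np.isnan(dosage)
    ok &= ~design.isna().any(axis=1).to_numpy()
    return ok


def trend_test(dosage: np.ndarray, dataset: Dataset, spec: ModelSpec | None = None):
    """1-df per-allele trend test: genotype as a single 0/1/2 term.

    Returns ``(per_allele_or, (ci_lo, ci_hi), p_trend, fit)``; a flagged
    (non-converged / separated) fit yields NaN OR and p.
    """
    spec = spec or ModelSpec()
    dosage = np.asarray(dosage, dtype=float)
    design = build_design(dataset.subjects.table, spec)
    ok = _complete_rows(dosage, design)
    g = dosage[ok]
    if np.nanvar(g) == 0:
        return math.nan, (math.nan, math.nan), math.nan, None
    X = design.loc[ok].copy()
    X["dosage"] = g
    y = dataset.status[ok]
    fit = fit_logistic(y, X)
    if not fit.converged or "dosage" not in fit.column_names:
        return math.nan, (math.nan, math.nan), math.nan, fit
    j = fit.column_names.index("dosage")
    beta = float(fit.params[j])
    se = float(math.sqrt(fit.cov_params[j, j]))
    if spec.trend_statistic == "lrt":
        reduced = fit_logistic(y, design.loc[ok])
        lr = 2.0 * (fit.llf - reduced.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        p = float(stats.chi2.sf((beta / se) ** 2, df=1))
    or_, ci = _wald_or_ci(beta, se)
    return or_, ci, p, fit


def genotype_category_or(dosage: np.ndarray, dataset: Dataset, spec: ModelSpec | None = None):
    """Heterozygote and variant-homozygote ORs vs the common homozygote.

    Returns ``(or_het, ci_het, or_hom, ci_hom, fit)``; contrasts with an
    empty genotype class come back as None.
    """
    spec = spec or ModelSpec()
    dosage = np.asarray(dosage, dtype=float)
    design = build_design(dataset.subjects.table, spec)
    ok = _complete_rows(dosage, design)
    g = dosage[ok]
    y = dataset.status[ok]
    X = design.loc[ok].copy()
    classes = [np.sum(g == k) for k in (0, 1, 2)]
    X["het"] = (g == 1).astype(float)
    X["hom"] = (g == 2).astype(float)
    fit = fit_logistic(y, X)
    out: list = []
    for name, present in (("het", classes[1] > 0), ("hom", classes[2] > 0)):
        if not present or not fit.converged or name not in fit.column_names:
            out.extend([None, None])
            continue
        j = fit.column_names.index(name)
        or_, ci = _wald_or_ci(float(fit.params[j]), math.sqrt(float(fit.cov_params[j, j])))
        out.extend([or_, ci])
    return out[0], out[1], out[2], out[3], fit


def interaction_lrt(dosage: np.ndarray, modifier: np.ndarray, dataset: Dataset,
                    spec: ModelSpec | None = None) -> float:
    """1-df likelihood-ratio test of a dosage x modifier product term.

    Compares a model with genotype and modifier main effects against one
    adding their multiplicative interaction. NaN when either fit fails.
    """
    spec = spec or ModelSpec()
    dosage = np.asarray(dosage, dtype=float)
    modifier = np.asarray(modifier, dtype=float)
    design = build_design(dataset.subjects.table, spec)
    ok = _complete_rows(dosage, design) & ~np.isnan(modifier)
    y = dataset.status[ok]
    X0 = design.loc[ok].copy()
    X0["dosage"] = dosage[ok]
    X0["modifier"] = modifier[ok]
    X1 = X0.copy()
    X1["interaction"] = dosage[ok] * modifier[ok]
    f0 = fit_logistic(y, X0)
    f1 = fit_logistic(y, X1)
    if not (f0.converged and f1.converged):
        return math.nan
    if "interaction" not in f1.column_names:  # aliased: models identical
        return 1.0
    lr = 2.0 * (f1.llf - f0.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def crude_or_2x2(a: float, b: float, c: float, d: float):
    """Crude odds ratio ``ad/bc`` with Wald 95% CI from a 2x2 table
    ((a, b) exposed/unexposed cases, (c, d) exposed/unexposed controls).
    Zero cells get the 0.5 continuity correction and a flag."""
    cells = [float(a), float(b), float(c), float(d)]
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)), corrected


def trend_p_matrix(Y: np.ndarray, G: np.ndarray, max_iter: int = 25,
                   tol: float = 1e-8) -> np.ndarray:
    """Crude per-SNP trend p-values for many outcome vectors at once.

    ``Y`` is (R, n) of 0/1 outcomes (rows are permutations), ``G`` is (n, K)
    of dosages (NaN = missing). Fits the two-parameter logistic model
    ``logit P(y=1) = b0 + b1 g`` by Newton scoring for every (row, SNP) pair
    simultaneously and returns the (R, K) matrix of Wald p-values. Cells
    whose fit diverges or whose SNP is monomorphic get p = 1.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    R, n = Y.shape
    K = G.shape[1]
    W_obs = ~np.isnan(G)                      # (n, K) observation mask
    Gf = np.where(W_obs, G, 0.0)
    b0 = np.zeros((R, K))
    b1 = np.zeros((R, K))
    active = np.ones((R, K), dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None, :] + b1[:, None, :] * Gf[None, :, :]   # (R, n, K)
        mu = expit(eta)
        w = mu * (1.0 - mu) * W_obs[None, :, :]
        resid = (Y[:, :, None] - mu) * W_obs[None, :, :]
        s0 = resid.sum(axis=1)
        s1 = (resid * Gf[None, :, :]).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * Gf[None, :, :]).sum(axis=1)
        h11 = (w * Gf[None, :, :] ** 2).sum(axis=1)
        det = h00 * h11 - h01 * h01
        bad = det <= 1e-12
        det = np.where(bad, 1.0, det)
        d0 = (h11 * s0 - h01 * s1) / det
        d1 = (h00 * s1 - h01 * s0) / det
        step_ok = active & ~bad
        b0 += np.where(step_ok, d0, 0.0)
        b1 += np.where(step_ok, d1, 0.0)
        conv = (np.abs(s0) < tol) & (np.abs(s1) < tol)
        active &= ~conv
        if not active.any():
            break
    eta = b0[:, None, :] + b1[:, None, :] * Gf[None, :, :]
    mu = expit(eta)
    w = mu * (1.0 - mu) * W_obs[None, :, :]
    h00 = w.sum(axis=1)
    h01 = (w * Gf[None, :, :]).sum(axis=1)
    h11 = (w * Gf[None, :, :] ** 2).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(all="ignore"):
        var_b1 = h00 / det
        z2 = b1 ** 2 / var_b1
        p = stats.chi2.sf(z2, df=1)
    invalid = (det <= 1e-12) | ~np.isfinite(p) | (np.abs(b1) > _SEPARATION_BOUND)
    # monomorphic SNPs (within observed rows) are uninformative
    mono = np.array([np.nanvar(G[:, k]) == 0 for k in range(K)])
    invalid |= mono[None, :]
    return np.where(invalid, 1.0, p)
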