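"""Covariate-adjusted association screens (steps 1 and 2 of the paradigm).

Step 1 (in vivo): for every (species, metabolite) pair, OLS of the log fecal
concentration on a species predictor — presence (0/1) or standardized
abundance (unit sample variance) — adjusting for host covariates (age, BMI,
sex, study group, or whatever covariate columns the study provides), with
heteroscedasticity-robust standard errors.  Zero concentrations are treated
as below detection and dropped under the log transform.

Step 2 (in silico): the same regressions with the community net-secretion
flux as response, not log-transformed and with no samples dropped.

Both screens are BH-FDR adjusted over all pairs of the screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    SampleSizeError,
    ScreenConfigError,
    StateError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_PREVALENCE = 0.10
DEFAULT_MIN_NONZERO = 0.50
DEFAULT_COV_TYPE = "HC1"

PREDICTOR_KINDS = ("presence", "abundance")
RESPONSE_KINDS = ("concentration", "flux")


@dataclass
class StudyTables:
    """Aligned sample x feature tables of one study.

    All tables share an identical sample index; ``flux`` may be None until
    the community-modeling stage has produced it.
    """

    abundance: pd.DataFrame
    metabolome: pd.DataFrame
    covariates: pd.DataFrame
    flux: pd.DataFrame | None = None

    def validate(self) -> None:
        idx = self.abundance.index
        for name, df in (("metabolome", self.metabolome),
                         ("covariates", self.covariates),
                         ("flux", self.flux)):
            if df is None:
                continue
            if not df.index.equals(idx):
                raise ValueError(f"{name} table index does not match abundance")
        if ((self.abundance < 0) | (self.abundance > 1)).any().any():
            raise ValueError("abundance entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.abundance)

    def require_flux(self) -> pd.DataFrame:
        if self.flux is None:
            raise StateError(
                "flux table missing: run the community-modeling stage (or the "
                "simulator) before the in silico screen"
            )
        return self.flux


@dataclass
class AssociationResult:
    """One covariate-adjusted species-response regression."""

    metabolite: str
    species: str
    predictor_kind: str
    response_kind: str
    coefficient: float
    robust_se: float
    p: float
    q: float = math.nan
    n_used: int = 0
    flag: str = ""


# ---------------------------------------------------------------------------
# Filters and predictor encoding
# ---------------------------------------------------------------------------

def filter_species(
    abundance: pd.DataFrame, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> list[str]:
    """Species with nonzero abundance in at least ``min_prevalence`` of samples."""
    if (abundance < 0).any().any():
        raise ValueError("abundance must be nonnegative")
    n = len(abundance)
    threshold = math.ceil(min_prevalence * n - 1e-9)
    kept = [s for s in abundance.columns if int((abundance[s] > 0).sum()) >= threshold]
    if not kept:
        raise ScreenConfigError(
            f"no species reaches {min_prevalence:.0%} prevalence in {n} samples"
        )
    return kept


def filter_metabolites(
    metabolome: pd.DataFrame, min_nonzero: float = DEFAULT_MIN_NONZERO
) -> list[str]:
    """Metabolites with nonzero (above-detection) values in >= ``min_nonzero`` of samples."""
    if (metabolome < 0).any().any():
        raise ValueError("metabolome must be nonnegative")
    n = len(metabolome)
    return [m for m in metabolome.columns
            if int((metabolome[m] > 0).sum()) >= min_nonzero * n - 1e-9]


def encode_predictors(
    abundance: pd.DataFrame, species: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence indicators and unit-variance standardized abundances.

    Standardization subtracts the sample mean and divides by the n-1 sample
    standard deviation, so every returned abundance column has sample
    variance exactly 1.  Species whose abundance has zero variance cannot be
    standardized and are dropped with a warning.
    """
    presence = (abundance[species] > 0).astype(float)
    sub = abundance[species]
    sd = sub.std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        logger.warning("dropping zero-variance species from standardization: %s",
                       degenerate)
    keep = [s for s in species if s not in degenerate]
    standardized = (sub[keep] - sub[keep].mean()) / sd[keep]
    return presence[keep], standardized


# ---------------------------------------------------------------------------
# Single fits
# ---------------------------------------------------------------------------

def _design(predictor: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + predictor + non-constant covariates."""
    cov = covariates.loc[predictor.index]
    keep = [c for c in cov.columns if cov[c].nunique() > 1]
    X = pd.concat([predictor.rename("predictor"), cov[keep]], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_association(
    response: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame,
    log_response: bool = False,
    drop_zero_response: bool = False,
    cov_type: str = DEFAULT_COV_TYPE,
    metabolite: str = "",
    species: str = "",
    predictor_kind: str = "presence",
    response_kind: str = "concentration",
) -> AssociationResult:
    """One covariate-adjusted OLS with robust standard errors.

    Under ``log_response`` with ``drop_zero_response``, samples with zero
    (below-detection) response are removed before taking the natural log.
    The reported p-value is the two-sided test of the predictor coefficient
    using the requested heteroscedasticity-robust covariance (HC1 default).
    """
    data = pd.concat(
        [response.rename("response"), predictor.rename("predictor"), covariates],
        axis=1,
    ).dropna()
    if log_response and drop_zero_response:
        data = data[data["response"] > 0]
    y = np.log(data["response"]) if log_response else data["response"]
    X = _design(data["predictor"], data[covariates.columns])

    n_used = len(data)
    if n_used < X.shape[1] + 2:
        raise SampleSizeError(
            f"{n_used} usable samples for {X.shape[1]} model terms "
            f"({metabolite} ~ {species})"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError(
            f"predictor collinear with covariates ({metabolite} ~ {species})"
        )

    if y.nunique() <= 1:
        # Constant response: zero effect by definition, no sampling variance.
        return AssociationResult(metabolite, species, predictor_kind, response_kind,
                                 0.0, 0.0, 1.0, n_used=n_used, flag="constant_response")

    fit = sm.OLS(np.asarray(y, dtype=float), X).fit(cov_type=cov_type)
    return AssociationResult(
        metabolite=metabolite,
        species=species,
        predictor_kind=predictor_kind,
        response_kind=response_kind,
        coefficient=float(fit.params["predictor"]),
        robust_se=float(fit.bse["predictor"]),
        p=float(fit.pvalues["predictor"]),
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1).

    NaN entries are excluded from the number of tests and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return q
    sub = p[mask]
    if np.any((sub < 0) | (sub > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q_sub, _, _ = multipletests(sub, method="fdr_bh")
    q[mask] = q_sub
    return q


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def association_screen(
    tables: StudyTables,
    predictor_kind: str,
    response_kind: str,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_nonzero: float = DEFAULT_MIN_NONZERO,
    cov_type: str = DEFAULT_COV_TYPE,
) -> list[AssociationResult]:
    """All (species, metabolite) fits of one screen, BH-adjusted jointly.

    Concentration responses are log-transformed with zeros dropped; flux
    responses are used untransformed with all samples kept.  Per-fit failures
    become flagged NA rows rather than aborting the screen.
    """
    if predictor_kind not in PREDICTOR_KINDS:
        raise ValueError(f"unknown predictor_kind {predictor_kind!r}")
    if response_kind not in RESPONSE_KINDS:
        raise ValueError(f"unknown response_kind {response_kind!r}")
    tables.validate()

    species = filter_species(tables.abundance, min_prevalence)
    presence, standardized = encode_predictors(tables.abundance, species)
    predictors = presence if predictor_kind == "presence" else standardized

    if response_kind == "concentration":
        responses = tables.metabolome
        metabolites = filter_metabolites(tables.metabolome, min_nonzero)
        log_response = drop_zero = True
    else:
        responses = tables.require_flux()
        metabolites = [m for m in filter_metabolites(tables.metabolome, min_nonzero)
                       if m in responses.columns]
        log_response = drop_zero = False

    results: list[AssociationResult] = []
    for metabolite in metabolites:
        for sp in predictors.columns:
            try:
                res = fit_association(
                    responses[metabolite], predictors[sp], tables.covariates,
                    log_response=log_response, drop_zero_response=drop_zero,
                    cov_type=cov_type, metabolite=metabolite, species=sp,
                    predictor_kind=predictor_kind, response_kind=response_kind,
                )
            except (SampleSizeError, CollinearityError) as exc:
                res = AssociationResult(
                    metabolite, sp, predictor_kind, response_kind,
                    math.nan, math.nan, math.nan, flag=type(exc).__name__,
                )
            results.append(res)

    qvals = fdr_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Screen results as a tidy DataFrame (one row per pair)."""
    return pd.DataFrame(
        [{
            "metabolite": r.metabolite, "species": r.species,
            "predictor_kind": r.predictor_kind, "response_kind": r.response_kind,
            "beta": r.coefficient, "robust_se": r.robust_se,
            "p": r.p, "q": r.q, "n_used": r.n_used, "flag": r.flag,
        } for r in results]
    )


# ---------------------------------------------------------------------------
# Fast residualized coefficients (shared with the permutation engine)
# ---------------------------------------------------------------------------

def residualizer(covariates: pd.DataFrame | np.ndarray):
    """Projection onto the orthogonal complement of [1, covariates].

    Returns a function mapping an (n,) or (n, B) array to its covariate
    residuals.  Constant covariate columns are dropped (the intercept
    already spans them).
    """
    if isinstance(covariates, pd.DataFrame):
        keep = [c for c in covariates.columns if covariates[c].nunique() > 1]
        Z = covariates[keep].to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
        Z = Z[:, Z.std(axis=0) > 0]
    n = Z.shape[0]
    X = np.column_stack([np.ones(n), Z])
    Q, _ = np.linalg.qr(X)

    def resid(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return v - Q @ (Q.T @ v)

    return resid


def fwl_coefficients(
    responses: np.ndarray,
    predictors: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Per-predictor adjusted OLS coefficients via Frisch-Waugh-Lovell.

    For each predictor column p (fitted one at a time alongside the
    covariates) and each response column y, returns the coefficient of p in
    the full OLS of y on [1, p, covariates].  Residualizing p against the
    covariates reduces each coefficient to a ratio of inner products, which
    vectorizes over thousands of permuted responses.  Output shape is
    (n_predictors,) for a single response or (n_predictors, n_responses).
    """
    resid = residualizer(covariates)
    P = resid(np.asarray(predictors, dtype=float))
    denom = (P * P).sum(axis=0)
    denom[denom == 0] = np.nan
    Y = np.asarray(responses, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    B = (P.T @ Y) / denom[:, None]
    return B[:, 0] if single else B
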