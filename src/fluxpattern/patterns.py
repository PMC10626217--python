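"""In silico / in vivo association pattern analysis (step 3).

For each metabolite, the vector of in vivo association statistics across
species (concentration regressions) is regressed on the corresponding vector
of in silico statistics (flux regressions).  Because both vectors are built
from intercorrelated compositional data, their coefficients are mutually
dependent and the parametric F-test of the slope is too liberal; significance
is therefore assessed by shuffling the metabolite's flux vector across
samples, recomputing the entire in silico screen for that metabolite per
permutation, and comparing the observed fit statistic

    F = R^2 / (1 - R^2) * (n_species - 2)

against its permutation distribution.  Sign agreement between the two
patterns is tabulated and tested against the same permutation distribution
(both tails: concordance and discordance are each meaningful — a
significantly inverted pattern reads as net consumption).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .associations import (
    DEFAULT_COV_TYPE,
    DEFAULT_MIN_NONZERO,
    DEFAULT_MIN_PREVALENCE,
    StudyTables,
    association_screen,
    encode_predictors,
    fdr_adjust,
    filter_metabolites,
    filter_species,
    fwl_coefficients,
    residualizer,
    results_to_frame,
)
from .errors import DegeneratePatternError, StateError

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 5000
DEFAULT_ALPHA = 0.05
#: Cap applied to F when R^2 is numerically 1 (perfect fit).
F_CAP = 1e12


@dataclass
class PatternResult:
    """Per-metabolite outcome of the pattern analysis."""

    metabolite: str
    predictor_kind: str
    slope: float = math.nan
    intercept: float = math.nan
    robust_se: float = math.nan
    parametric_p: float = math.nan
    F_measure: float = math.nan
    perm_p_value: float = math.nan
    perm_p_sign: float = math.nan
    perm_p_sign_high: float = math.nan
    perm_p_sign_low: float = math.nan
    sign_table: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), int))
    n_species: int = 0
    n_permutations: int = 0
    classification: str = "none"
    q_perm: float = math.nan
    flag: str = ""


# ---------------------------------------------------------------------------
# Pattern regression
# ---------------------------------------------------------------------------

def _f_measure(r2: float, n: int) -> float:
    if r2 >= 1.0 - 1e-12:
        return F_CAP
    return r2 / (1.0 - r2) * (n - 2)


def pattern_regression(
    b_ca: np.ndarray, b_fa: np.ndarray, cov_type: str = DEFAULT_COV_TYPE
) -> tuple[float, float, float, float, float]:
    """OLS of the in vivo on the in silico pattern for one metabolite.

    Returns (slope, intercept, robust_se, parametric_p, F_measure).  The
    F measure is R^2/(1-R^2)*(n-2), capped when the fit is numerically
    perfect.
    """
    b_ca = np.asarray(b_ca, dtype=float)
    b_fa = np.asarray(b_fa, dtype=float)
    mask = np.isfinite(b_ca) & np.isfinite(b_fa)
    b_ca, b_fa = b_ca[mask], b_fa[mask]
    if len(b_ca) < 4:
        raise DegeneratePatternError(
            f"need >= 4 species with finite statistics (got {len(b_ca)})"
        )
    if np.var(b_fa) == 0:
        raise DegeneratePatternError("in silico pattern has zero variance")
    X = sm.add_constant(b_fa)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits emit divide warnings
        fit = sm.OLS(b_ca, X).fit(cov_type=cov_type)
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    f = _f_measure(float(fit.rsquared), len(b_ca))
    return slope, intercept, se, p, f


def sign_agreement(
    b_ca: np.ndarray, b_fa: np.ndarray
) -> tuple[np.ndarray, int]:
    """Tabulate the signs of the two patterns; return (2x2 table, concordant count).

    Table layout: rows = in vivo sign (+, -), columns = in silico sign (+, -).
    Coefficients that are exactly zero are excluded.  The concordance
    statistic is the number of species whose two statistics share a sign.
    """
    b_ca = np.asarray(b_ca, dtype=float)
    b_fa = np.asarray(b_fa, dtype=float)
    sv, sf = np.sign(b_ca), np.sign(b_fa)
    mask = (sv != 0) & (sf != 0) & np.isfinite(sv) & np.isfinite(sf)
    sv, sf = sv[mask], sf[mask]
    table = np.array([
        [int(((sv > 0) & (sf > 0)).sum()), int(((sv > 0) & (sf < 0)).sum())],
        [int(((sv < 0) & (sf > 0)).sum()), int(((sv < 0) & (sf < 0)).sum())],
    ])
    concordant = int(table[0, 0] + table[1, 1])
    return table, concordant


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

def _fast_pattern_stats(b_ca: np.ndarray, b_fa_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (F, concordant-count) over columns of permuted patterns.

    ``b_fa_mat`` is (L, B): one in silico pattern per permutation; ``b_ca``
    is the fixed in vivo pattern.  Uses the closed form
    R^2 = cov(x, y)^2 / (var(x) var(y)).
    """
    L, B = b_fa_mat.shape
    y = b_ca - b_ca.mean()
    vy = float(y @ y)
    Xc = b_fa_mat - b_fa_mat.mean(axis=0, keepdims=True)
    vx = (Xc * Xc).sum(axis=0)
    cov = y @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    F = np.where(r2 >= 1 - 1e-12, F_CAP, r2 / (1 - r2) * (L - 2))
    sy = np.sign(y + b_ca.mean())[:, None]
    sx = np.sign(b_fa_mat)
    concordant = ((sy == sx) & (sy != 0) & (sx != 0)).sum(axis=0)
    return F, concordant


def flux_permutation_test(
    tables: StudyTables,
    metabolite: str,
    predictor_kind: str,
    B: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    in_vivo_stats: np.ndarray | None = None,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    cov_type: str = DEFAULT_COV_TYPE,
    batch: int = 512,
) -> tuple[float, float, dict]:
    """Permutation significance of one metabolite's pattern.

    The in vivo statistics are computed once (or passed in precomputed) and
    held fixed.  Each permutation shuffles the metabolite's flux vector
    across samples, recomputes the whole in silico screen for that metabolite
    (per-species covariate-adjusted coefficients), and re-evaluates the fit
    measure F and the sign-concordance count.  P-values use the add-one rule
    (1 + #{stat_perm >= stat_obs}) / (B + 1) with the ">=" count, so p is
    never 0 and never below 1/(B+1).  Deterministic given ``seed``.

    Returns ``(perm_p_value, perm_p_sign, summary)``; the summary carries the
    observed statistics, both sign-test tails and permutation quantiles.
    """
    if B < 100:
        warnings.warn(f"B={B} permutations gives poor p-value resolution", stacklevel=2)
    flux = tables.require_flux()
    if metabolite not in flux.columns:
        raise KeyError(f"no flux column for metabolite {metabolite!r}")
    f_obs = flux[metabolite].to_numpy(dtype=float)
    if np.var(f_obs) == 0:
        raise DegeneratePatternError(f"flux of {metabolite!r} is constant")

    species = filter_species(tables.abundance, min_prevalence)
    presence, standardized = encode_predictors(tables.abundance, species)
    P = (presence if predictor_kind == "presence" else standardized).to_numpy(float)

    resid = residualizer(tables.covariates)
    Pr = resid(P)
    denom = (Pr * Pr).sum(axis=0)
    denom[denom == 0] = np.nan

    b_fa_obs = (Pr.T @ f_obs) / denom

    if in_vivo_stats is None:
        results = association_screen(
            tables, predictor_kind, "concentration", min_prevalence=min_prevalence,
            cov_type=cov_type,
        )
        b_ca = np.array([r.coefficient for r in results
                         if r.metabolite == metabolite])
        if b_ca.size == 0:
            raise StateError(
                f"metabolite {metabolite!r} not in the in vivo screen "
                "(below the detection-fraction filter?)"
            )
    else:
        b_ca = np.asarray(in_vivo_stats, dtype=float)
    if len(b_ca) != Pr.shape[1]:
        raise ValueError("in vivo statistics length does not match species set")

    mask = np.isfinite(b_ca) & np.isfinite(b_fa_obs)
    b_ca_m = b_ca[mask]
    F_obs, S_obs = _fast_pattern_stats(b_ca_m, b_fa_obs[mask][:, None])
    F_obs, S_obs = float(F_obs[0]), int(S_obs[0])

    rng = np.random.default_rng(seed)
    n = len(f_obs)
    count_F = count_S_hi = count_S_lo = 0
    f_quantile_pool = []
    done = 0
    while done < B:
        b = min(batch, B - done)
        perm_block = np.empty((n, b))
        for i in range(b):
            perm_block[:, i] = f_obs[rng.permutation(n)]
        # Pr is already orthogonal to the covariate span, so residualizing
        # the permuted responses would be a no-op: Pr.T @ M f == Pr.T @ f.
        b_fa_perm = (Pr.T @ perm_block) / denom[:, None]
        F_perm, S_perm = _fast_pattern_stats(b_ca_m, b_fa_perm[mask])
        count_F += int((F_perm >= F_obs).sum())
        count_S_hi += int((S_perm >= S_obs).sum())
        count_S_lo += int((S_perm <= S_obs).sum())
        f_quantile_pool.append(F_perm)
        done += b

    perm_p_value = (1 + count_F) / (B + 1)
    p_sign_high = (1 + count_S_hi) / (B + 1)
    p_sign_low = (1 + count_S_lo) / (B + 1)
    perm_p_sign = min(1.0, 2 * min(p_sign_high, p_sign_low))

    F_all = np.concatenate(f_quantile_pool)
    summary = {
        "F_obs": F_obs,
        "sign_concordant_obs": S_obs,
        "p_sign_high": p_sign_high,
        "p_sign_low": p_sign_low,
        "F_perm_quantiles": {
            q: float(np.quantile(F_all, q)) for q in (0.5, 0.9, 0.95, 0.99)
        },
        "B": B,
        "n_species": int(mask.sum()),
    }
    return perm_p_value, perm_p_sign, summary


# ---------------------------------------------------------------------------
# Classification and the full step-3 run
# ---------------------------------------------------------------------------

def classify_pattern(result: PatternResult, alpha: float = DEFAULT_ALPHA) -> str:
    """Concordant / discordant / none from slope sign and permutation p-values.

    A pattern is significant when either the value test (perm_p_value) or the
    sign test (perm_p_sign) is below alpha.  Significant with positive slope
    and sign agreement >= disagreement -> concordant (net secretion drives
    the in vivo pattern); significant with negative slope -> discordant (the
    flux capacity reads as net consumption); otherwise none.
    """
    if math.isnan(result.perm_p_value):
        raise StateError("permutation p-values missing; run flux_permutation_test first")
    significant = (result.perm_p_value < alpha) or (result.perm_p_sign < alpha)
    if not significant or math.isnan(result.slope):
        return "none"
    table = result.sign_table
    agree = table[0, 0] + table[1, 1]
    disagree = table[0, 1] + table[1, 0]
    if result.slope > 0 and agree >= disagree:
        return "concordant"
    if result.slope < 0:
        return "discordant"
    return "none"


def run_pattern_analysis(
    tables: StudyTables,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_nonzero: float = DEFAULT_MIN_NONZERO,
    cov_type: str = DEFAULT_COV_TYPE,
    significant_only: bool = False,
    predictor_kinds: tuple[str, ...] = ("presence", "abundance"),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict]:
    """Steps 1-3 end to end: screens, pattern tests, classification.

    For each predictor kind, runs the concentration and flux screens, then
    per metabolite the pattern regression, the flux-shuffling permutation
    test (value and sign), and the concordant/discordant call;
    permutation p-values are additionally BH-adjusted across metabolites per
    comparison set.  ``significant_only`` restricts each pattern regression
    to species whose in vivo association reached q < alpha in the screen.

    Returns ``(pattern_df, screen_frames, summary)``.
    """
    tables.validate()
    tables.require_flux()
    results: list[PatternResult] = []
    screen_frames: dict[str, pd.DataFrame] = {}
    metabolites = [m for m in filter_metabolites(tables.metabolome, min_nonzero)
                   if m in tables.flux.columns]

    for kind_index, kind in enumerate(predictor_kinds):
        conc = association_screen(tables, kind, "concentration",
                                  min_prevalence, min_nonzero, cov_type)
        flx = association_screen(tables, kind, "flux",
                                 min_prevalence, min_nonzero, cov_type)
        screen_frames[f"{kind}_concentration"] = results_to_frame(conc)
        screen_frames[f"{kind}_flux"] = results_to_frame(flx)
        conc_by_met: dict[str, list] = {}
        flx_by_met: dict[str, list] = {}
        for r in conc:
            conc_by_met.setdefault(r.metabolite, []).append(r)
        for r in flx:
            flx_by_met.setdefault(r.metabolite, []).append(r)

        for met_index, met in enumerate(metabolites):
            res = PatternResult(metabolite=met, predictor_kind=kind,
                                n_permutations=n_permutations)
            try:
                c_rows = conc_by_met.get(met, [])
                f_rows = flx_by_met.get(met, [])
                b_ca = np.array([r.coefficient for r in c_rows])
                b_fa = np.array([r.coefficient for r in f_rows])
                b_ca_perm = b_ca
                if significant_only:
                    sig = np.array([r.q < alpha for r in c_rows])
                    b_ca_fit, b_fa_fit = b_ca[sig], b_fa[sig]
                    b_ca_perm = np.where(sig, b_ca, np.nan)
                else:
                    b_ca_fit, b_fa_fit = b_ca, b_fa
                (res.slope, res.intercept, res.robust_se,
                 res.parametric_p, res.F_measure) = pattern_regression(
                    b_ca_fit, b_fa_fit, cov_type)
                res.sign_table, _ = sign_agreement(b_ca_fit, b_fa_fit)
                res.n_species = int(np.isfinite(b_ca_fit).sum())
                # Independent permutation substream per (kind, metabolite).
                sub_seed = np.random.SeedSequence(
                    (seed, kind_index, met_index)).generate_state(1)[0]
                (res.perm_p_value, res.perm_p_sign, summary) = flux_permutation_test(
                    tables, met, kind, B=n_permutations, seed=int(sub_seed),
                    in_vivo_stats=b_ca_perm, min_prevalence=min_prevalence,
                    cov_type=cov_type,
                )
                res.perm_p_sign_high = summary["p_sign_high"]
                res.perm_p_sign_low = summary["p_sign_low"]
                res.classification = classify_pattern(res, alpha)
            except DegeneratePatternError as exc:
                res.flag = str(exc)
                res.classification = "none"
            except Exception as exc:  # noqa: BLE001 - per-metabolite failure
                logger.warning("pattern for %s (%s) failed: %s", met, kind, exc)
                res.flag = f"{type(exc).__name__}: {exc}"
            results.append(res)

    # BH across metabolites within each comparison set.
    for kind in predictor_kinds:
        rows = [r for r in results if r.predictor_kind == kind]
        qvals = fdr_adjust([r.perm_p_value for r in rows])
        for r, q in zip(rows, qvals):
            r.q_perm = float(q)

    pattern_df = pd.DataFrame([{
        "metabolite": r.metabolite, "predictor_kind": r.predictor_kind,
        "slope": r.slope, "robust_se": r.robust_se,
        "parametric_p": r.parametric_p, "F": r.F_measure,
        "perm_p": r.perm_p_value, "perm_p_sign": r.perm_p_sign,
        "perm_p_sign_high": r.perm_p_sign_high,
        "perm_p_sign_low": r.perm_p_sign_low,
        "q_perm": r.q_perm, "n_species": r.n_species,
        "sign_pp": r.sign_table[0, 0], "sign_pm": r.sign_table[0, 1],
        "sign_mp": r.sign_table[1, 0], "sign_mm": r.sign_table[1, 1],
        "classification": r.classification, "flag": r.flag,
    } for r in results])

    # Consistency: one metabolite must not be called both concordant and
    # discordant across its comparison sets (net secretion and net
    # consumption are mutually exclusive readings).
    conflicts = []
    for met, grp in pattern_df.groupby("metabolite"):
        calls = set(grp["classification"]) - {"none"}
        if {"concordant", "discordant"} <= calls:
            conflicts.append(met)
    if conflicts:
        logger.warning("conflicting concordant/discordant calls: %s", conflicts)
        pattern_df.loc[pattern_df["metabolite"].isin(conflicts), "flag"] = (
            pattern_df.loc[pattern_df["metabolite"].isin(conflicts), "flag"]
            .apply(lambda s: (s + "; " if s else "") + "conflicting_classification")
        )

    summary = {
        "n_metabolites": len(metabolites),
        "conflicts": conflicts,
    }
    for kind in predictor_kinds:
        sub = pattern_df[pattern_df["predictor_kind"] == kind]
        summary[kind] = {
            "n_concordant": int((sub["classification"] == "concordant").sum()),
            "n_discordant": int((sub["classification"] == "discordant").sum()),
            "n_none": int((sub["classification"] == "none").sum()),
        }
    return pattern_df, screen_frames, summary
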