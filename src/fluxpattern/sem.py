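"""Structural-equation simulator of metabolic microbiome-host systems.

The generative model is a linear structural equation system over four blocks
of variables describing one individual:

* ``h`` — K latent host factors (age-like, diet-like, ...), standard normal;
* ``a`` — L relative species abundances on the simplex,
  ``a = u + s * B_ah @ h`` with an intrinsic-microbiome term ``u`` drawn from
  a symmetric Dirichlet and a post-hoc repair step that keeps ``a`` on the
  simplex;
* ``f`` — J community net-secretion fluxes, an exact linear image of the
  abundances, ``f = B_fa @ a`` (no error term: fluxes are computed, not
  measured);
* ``c`` — J metabolite concentrations in the host,
  ``c = B_cf @ f + B_ch @ h + eps``.

Two structural constraints carry the causal-identification argument:
every column of ``B_ah`` sums to zero (a consequence of compositional
closure), and ``B_fa @ B_ah = 0`` (host effects on abundances are orthogonal
to abundance effects on fluxes, because the flux map knows nothing about the
host).  Under these constraints, covariate patterns of in vivo
(concentration) and in silico (flux) association statistics across species
share variance if and only if the flux->concentration effect ``B_cf`` is
nonzero; the simulator exists to exercise exactly that criterion.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, SimulationError

SCENARIOS = ("null", "secretion", "consumption", "mixed")

#: Default scale of B_fa rows.  Net-secretion fluxes live on a
#: mmol/person/day scale, two to three orders of magnitude above relative
#: abundances; a row norm of 10 reproduces that separation of scales.
DEFAULT_FLUX_SCALE = 10.0

#: Default host-confounding scale for B_ah columns and B_ch entries.
DEFAULT_CONFOUND_SCALE = 1.0

#: Default symmetric Dirichlet concentration for the intrinsic microbiome.
DEFAULT_DIRICHLET_ALPHA = 1.0

#: Default concentration-noise standard deviation.
DEFAULT_SIGMA_EPS = 1.0


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SEMParameters:
    """Coefficient matrices and noise scales of the structural system.

    ``B_ah`` is L x K (host -> abundance), ``B_fa`` is J x L
    (abundance -> flux), ``B_cf`` is J x J diagonal (flux -> concentration),
    ``B_ch`` is J x K (host -> concentration, the confounding path).
    ``dirichlet_alpha`` is the symmetric Dirichlet concentration of the
    intrinsic microbiome term ``u`` (smaller alpha = more dispersion) and
    ``sigma_eps`` the standard deviation of the concentration noise.
    """

    L: int
    K: int
    J: int
    B_ah: np.ndarray
    B_fa: np.ndarray
    B_cf: np.ndarray
    B_ch: np.ndarray
    scenario: str
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA
    sigma_eps: float = DEFAULT_SIGMA_EPS
    host_effect_scale: float | str = "auto"
    effect_scale: float = 1.0
    seed: int | None = None

    def validate(self, atol: float = 1e-10) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.B_ah.shape != (self.L, self.K):
            raise ValueError(f"B_ah must be {self.L}x{self.K}")
        if self.B_fa.shape != (self.J, self.L):
            raise ValueError(f"B_fa must be {self.J}x{self.L}")
        if self.B_cf.shape != (self.J, self.J):
            raise ValueError(f"B_cf must be {self.J}x{self.J}")
        if self.B_ch.shape != (self.J, self.K):
            raise ValueError(f"B_ch must be {self.J}x{self.K}")
        col_sums = self.B_ah.sum(axis=0)
        if np.max(np.abs(col_sums)) > atol:
            raise ValueError(
                f"B_ah columns must sum to 0; max |sum| = {np.max(np.abs(col_sums)):.3g}"
            )
        prod = self.B_fa @ self.B_ah
        if np.max(np.abs(prod)) > atol:
            raise ValueError(
                f"B_fa @ B_ah must vanish; max |entry| = {np.max(np.abs(prod)):.3g}"
            )
        off_diag = self.B_cf - np.diag(np.diag(self.B_cf))
        if np.any(off_diag != 0):
            raise ValueError("B_cf must be diagonal")
        diag = np.diag(self.B_cf)
        if self.scenario == "null" and np.any(diag != 0):
            raise ValueError("null scenario requires B_cf = 0")
        if self.scenario == "secretion" and not np.all(diag > 0):
            raise ValueError("secretion scenario requires positive B_cf diagonal")
        if self.scenario == "consumption" and not np.all(diag < 0):
            raise ValueError("consumption scenario requires negative B_cf diagonal")

    def to_dict(self) -> dict:
        """JSON-serializable representation (truth sidecar)."""
        d = dataclasses.asdict(self)
        for key in ("B_ah", "B_fa", "B_cf", "B_ch"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SEMParameters":
        d = dict(d)
        for key in ("B_ah", "B_fa", "B_cf", "B_ch"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def make_parameters(
    L: int,
    K: int,
    J: int,
    scenario: str = "null",
    effect_scale: float = 1.0,
    seed: int = 0,
    *,
    confound_scale: float = DEFAULT_CONFOUND_SCALE,
    flux_scale: float = DEFAULT_FLUX_SCALE,
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA,
    sigma_eps: float = DEFAULT_SIGMA_EPS,
    host_effect_scale: float | str = "auto",
    ortho_noise: float = 0.0,
) -> SEMParameters:
    """Draw a parameter set satisfying the structural constraints exactly.

    ``B_ah`` columns are standard-normal draws projected onto the zero-sum
    subspace and scaled to norm ``confound_scale``; ``B_fa`` rows are draws
    projected onto the orthogonal complement of the column span of ``B_ah``
    and scaled to norm ``flux_scale``; the ``B_cf`` diagonal is set to
    ``+effect_scale`` (secretion), ``-effect_scale`` (consumption), zero
    (null) or random signs (mixed).  ``ortho_noise > 0`` re-injects a
    component inside the span of ``B_ah`` to probe approximate (rather than
    exact) orthogonality.

    Deterministic given ``seed``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if L < K + J + 1:
        raise DimensionError(
            f"L={L} too small: need L >= K + J + 1 = {K + J + 1} so that "
            "B_fa rows can be drawn orthogonal to the B_ah columns"
        )
    if effect_scale <= 0:
        raise ValueError("effect_scale must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    # Host -> abundance effects: zero-sum columns of norm confound_scale.
    B_ah = rng.standard_normal((L, K))
    B_ah -= B_ah.mean(axis=0, keepdims=True)
    B_ah /= np.linalg.norm(B_ah, axis=0, keepdims=True)
    B_ah *= confound_scale

    # Abundance -> flux effects: rows orthogonal to every column of B_ah.
    basis, _ = np.linalg.qr(B_ah)  # orthonormal basis of span{B_ah columns}
    B_fa = rng.standard_normal((J, L))
    B_fa -= (B_fa @ basis) @ basis.T
    B_fa /= np.linalg.norm(B_fa, axis=1, keepdims=True)
    B_fa *= flux_scale
    if ortho_noise > 0:
        inside = rng.standard_normal((J, K)) @ basis.T
        inside /= np.linalg.norm(inside, axis=1, keepdims=True)
        B_fa = B_fa + ortho_noise * flux_scale * inside

    if scenario == "null":
        diag = np.zeros(J)
    elif scenario == "secretion":
        diag = np.full(J, effect_scale)
    elif scenario == "consumption":
        diag = np.full(J, -effect_scale)
    else:  # mixed
        diag = effect_scale * rng.choice([-1.0, 1.0], size=J)
    B_cf = np.diag(diag)

    B_ch = confound_scale * rng.standard_normal((J, K))

    params = SEMParameters(
        L=L, K=K, J=J,
        B_ah=B_ah, B_fa=B_fa, B_cf=B_cf, B_ch=B_ch,
        scenario=scenario,
        dirichlet_alpha=dirichlet_alpha,
        sigma_eps=sigma_eps,
        host_effect_scale=host_effect_scale,
        effect_scale=effect_scale,
        seed=seed,
    )
    if ortho_noise == 0:
        params.validate()
    return params


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SEMCohort:
    """One sampled cohort: n realizations of (h, u, a, f, c)."""

    n: int
    H: np.ndarray  # n x K host factors
    U: np.ndarray  # n x L intrinsic microbiome (pre-repair, on the simplex)
    A: np.ndarray  # n x L abundances (post-repair, on the simplex)
    F: np.ndarray  # n x J fluxes, F = A @ B_fa.T exactly
    C: np.ndarray  # n x J concentrations
    E: np.ndarray  # n x J concentration noise
    host_effect_scale_used: float = 0.0
    repair_fraction: float = 0.0
    realized_B_ah: np.ndarray | None = field(default=None, repr=False)


def _repair_fraction(A: np.ndarray) -> float:
    """Fraction of rows with any entry outside [0, 1]."""
    bad = (A < 0) | (A > 1)
    return float(bad.any(axis=1).mean())


def simulate_cohort(params: SEMParameters, n: int, seed: int = 0) -> SEMCohort:
    """Sample a cohort of ``n`` individuals from the structural system.

    ``h`` is i.i.d. standard normal, ``u`` symmetric Dirichlet (hence on the
    simplex), ``eps`` i.i.d. normal(0, sigma_eps^2); all three mutually
    independent.  Abundances are ``u + s * B_ah @ h`` with ``s`` either given
    (``params.host_effect_scale`` numeric) or auto-halved until fewer than 5%
    of rows leave [0, 1]; offending rows are clipped at 0 and renormalized to
    sum 1.  Fluxes and concentrations then follow their structural equations
    exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_h = np.random.default_rng(streams[0])
    rng_u = np.random.default_rng(streams[1])
    rng_e = np.random.default_rng(streams[2])

    L, K, J = params.L, params.K, params.J
    H = rng_h.standard_normal((n, K))
    U = rng_u.dirichlet(np.full(L, params.dirichlet_alpha), size=n)
    delta = H @ params.B_ah.T  # n x L host displacement; rows sum to 0

    if params.host_effect_scale == "auto":
        s = 1.0
        while s > 1e-8 and _repair_fraction(U + s * delta) >= 0.05:
            s /= 2.0
    else:
        s = float(params.host_effect_scale)
        frac = _repair_fraction(U + s * delta)
        if frac > 0.5:
            raise SimulationError(
                f"host_effect_scale={s} pushes {frac:.0%} of abundance rows off "
                "the simplex; reduce the scale (or use 'auto')"
            )

    A = U + s * delta
    repair = _repair_fraction(A)
    A = np.clip(A, 0.0, None)
    A /= A.sum(axis=1, keepdims=True)

    # Realized (post-repair) host->abundance coefficients: per-species OLS of
    # abundance on the host factors, reported alongside the nominal s*B_ah.
    X = np.column_stack([np.ones(n), H])
    coefs, *_ = np.linalg.lstsq(X, A, rcond=None)
    realized_B_ah = coefs[1:].T  # L x K

    F = A @ params.B_fa.T
    E = params.sigma_eps * rng_e.standard_normal((n, J))
    C = F @ params.B_cf.T + H @ params.B_ch.T + E

    return SEMCohort(
        n=n, H=H, U=U, A=A, F=F, C=C, E=E,
        host_effect_scale_used=s,
        repair_fraction=repair,
        realized_B_ah=realized_B_ah,
    )


# ---------------------------------------------------------------------------
# Association statistics and their theoretical moments
# ---------------------------------------------------------------------------

def empirical_association_statistics(
    responses: np.ndarray, abundance: np.ndarray
) -> np.ndarray:
    """Per-species simple-regression coefficients on standardized abundances.

    Returns the J x L matrix with entry (j, l) equal to the OLS coefficient of
    response j on the standardized abundance of species l, i.e.
    ``COV(y_j, a_l) / SD(a_l)``.  This is the raw (covariate-free) version of
    the association statistics; the covariate-adjusted screens live in
    :mod:`fluxpattern.associations`.
    """
    responses = np.asarray(responses, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    n = abundance.shape[0]
    if responses.shape[0] != n:
        raise ValueError("responses and abundance must share the sample axis")
    Yc = responses - responses.mean(axis=0)
    Ac = abundance - abundance.mean(axis=0)
    sd = Ac.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    cov = Yc.T @ Ac / (n - 1)  # J x L
    return cov / sd


def theoretical_association_moments(
    params: SEMParameters, cohort: SEMCohort
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied values of ``VAR(a_l) * b_fa_jl`` and ``VAR(a_l) * b_ca_jl``.

    Evaluated from the known generative matrices and the empirical covariance
    matrices of ``u`` and ``h``:

    * in silico moment: ``B_fa @ COV(U)`` — entry (j, l) is
      ``COV(sum_i b_fa_ji u_i, u_l)``;
    * in vivo moment: ``B_cf @ (B_fa @ COV(U)) + B_ch @ COV(H) @ B_ah.T`` —
      the causal path through the flux plus the confounding path through the
      host factors.

    These are the oracle targets the regression layer must converge to at
    large n.
    """
    if cohort.U.shape[1] != params.L or cohort.H.shape[1] != params.K:
        raise ValueError("cohort dimensions do not match parameters")
    sigma_u = np.cov(cohort.U.T)
    sigma_h = np.atleast_2d(np.cov(cohort.H.T))
    s = cohort.host_effect_scale_used
    m_fa = params.B_fa @ sigma_u  # J x L
    m_ca = params.B_cf @ m_fa + params.B_ch @ sigma_h @ (s * params.B_ah).T
    return m_fa, m_ca


def association_pattern_covariance(
    in_vivo: np.ndarray, in_silico: np.ndarray
) -> np.ndarray:
    """Covariance across species between in vivo and in silico statistics.

    Both inputs are J x L matrices of per-species association statistics; the
    result is the length-J vector of sample covariances (across the species
    axis) between the two patterns of each metabolite.  This is the quantity
    whose nonzero-ness encodes a causal flux->concentration effect.
    """
    in_vivo = np.atleast_2d(in_vivo)
    in_silico = np.atleast_2d(in_silico)
    if in_vivo.shape != in_silico.shape:
        raise ValueError("pattern matrices must have identical shape")
    L = in_vivo.shape[1]
    v = in_vivo - in_vivo.mean(axis=1, keepdims=True)
    s = in_silico - in_silico.mean(axis=1, keepdims=True)
    return (v * s).sum(axis=1) / (L - 1)
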