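"""Unified Gibbs sampler for the Bayesian additive-dominance marker models.

All eight MCMC methods share one machinery over the marker model
y = Xb + W m_a + S m_d + e and differ only in the prior placed on the
marker effects, indexed by the prior degrees of freedom (df1 for the
residual variance, df2 for the marker-variance / shrinkage parameter):

======================  ==================  ====  ====
method                  effect prior        df1   df2
======================  ==================  ====  ====
BRR(-2,-2)              normal, common var   -2    -2
IBLASSO(4,-2)           Laplace              4     -2
IBLASSO(4,2)            Laplace              4     2
BAYESA*B*(-2,6)         Student-t            -2    6
BAYESA*B*(4,6)          Student-t            4     6
BAYESA*B*(-2,8)         Student-t            -2    8
RR-HET(-2,-2)           normal, fixed het    -2    -2
BLASSO(4,2)             Laplace (scaled)     4     2
======================  ==================  ====  ====

df = -2 denotes the flat (improper-uniform) limit of the scaled inverse
chi-square prior on a variance.  The Student-t prior arises by giving each
locus its own variance with a scaled-inv-chi-square(df2, S^2) prior inside
the Bayesian-Lasso machinery (hence "t-BLASSO"); the Laplace prior by the
exponential mixture of normals; BLASSO differs from IBLASSO in scaling the
effect variances by the residual variance (single-variance-component
parameterization).  RR-HET fixes per-locus variances at the posterior means
obtained from an IBLASSO(4,-2) run on the same data.

Full-conditional updates (documented inline in the kernel) are the standard
conjugate results; marker effects are updated one locus at a time in fixed
order, GS3-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import warnings

import numpy as np
from numba import njit
from numba.core.errors import NumbaPerformanceWarning

# column slices of Fortran-ordered inputs are typed as non-contiguous by the
# compiler even though access is unit-stride; the advisory warning is noise
warnings.filterwarnings("ignore", category=NumbaPerformanceWarning)

__all__ = [
    "ModelConfig",
    "MCMCChain",
    "PosteriorSummary",
    "MCMC_METHODS",
    "model_config",
    "prior_for",
    "sample_prior_effects",
    "moment_variance_components",
    "gibbs_run",
    "rr_het_variances",
    "geweke",
    "posterior_summary",
]

# prior-family codes shared with the numba kernel
_FAM_NORMAL = 0   # common variance across loci (BRR)
_FAM_LAPLACE = 1  # exponential mixture, two variance components (IBLASSO)
_FAM_T = 2        # per-locus scaled-inv-chi2 variances (BAYESA*B*)
_FAM_FIXED = 3    # fixed per-locus variances (RR-HET)
_FAM_LAPLACE_SCALED = 4  # exponential mixture scaled by sigma_e2 (BLASSO)

_FAMILY_NAMES = {
    _FAM_NORMAL: "normal-homogeneous",
    _FAM_LAPLACE: "laplace",
    _FAM_T: "student-t",
    _FAM_FIXED: "fixed-heterogeneous",
    _FAM_LAPLACE_SCALED: "laplace",
}

#: Table of the eight MCMC methods: name -> (family, df1, df2)
MCMC_METHODS = {
    "brr(-2,-2)": (_FAM_NORMAL, -2.0, -2.0),
    "iblasso(4,-2)": (_FAM_LAPLACE, 4.0, -2.0),
    "iblasso(4,2)": (_FAM_LAPLACE, 4.0, 2.0),
    "bayesa*b*(-2,6)": (_FAM_T, -2.0, 6.0),
    "bayesa*b*(4,6)": (_FAM_T, 4.0, 6.0),
    "bayesa*b*(-2,8)": (_FAM_T, -2.0, 8.0),
    "rr-het(-2,-2)": (_FAM_FIXED, -2.0, -2.0),
    "blasso(4,2)": (_FAM_LAPLACE_SCALED, 4.0, 2.0),
}


def _normalize(name: str) -> str:
    return name.lower().replace(" ", "").replace("_", "")


@dataclass
class ModelConfig:
    """Gibbs-sampler controls for one method.

    Defaults follow the study protocol: 120,000 iterations, 20,000 burn-in,
    thinning 10, hence 10,000 retained samples.  Prior scales default to
    method-of-moments values computed from the data at run time.
    """

    method: str
    prior_family: str
    df1: float
    df2: float
    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    scale_ma: float | None = None
    scale_md: float | None = None
    scale_e: float | None = None
    fixed_ta: np.ndarray | None = None
    fixed_td: np.ndarray | None = None
    store_effects: bool = False

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def model_config(method: str, **overrides) -> ModelConfig:
    """Build a :class:`ModelConfig` for a named method from the registry."""
    key = _normalize(method)
    if key not in MCMC_METHODS:
        raise ValueError(
            f"unknown MCMC method {method!r}; known: {sorted(MCMC_METHODS)}"
        )
    fam, df1, df2 = MCMC_METHODS[key]
    cfg = ModelConfig(method=key, prior_family=_FAMILY_NAMES[fam], df1=df1, df2=df2)
    return replace(cfg, **overrides) if overrides else cfg


def prior_for(method: str) -> dict:
    """Effective marginal prior on the marker effects for a named method."""
    key = _normalize(method)
    if key not in MCMC_METHODS:
        raise ValueError(f"unknown MCMC method {method!r}")
    fam, df1, df2 = MCMC_METHODS[key]
    if fam in (_FAM_NORMAL, _FAM_FIXED):
        family = "normal"
    elif fam in (_FAM_LAPLACE, _FAM_LAPLACE_SCALED):
        family = "laplace"
    else:
        family = "student-t"
    return {"family": family, "df": df2 if family == "student-t" else None,
            "df1": df1, "df2": df2}


def sample_prior_effects(method: str, size: int, scale: float = 1.0,
                         df2: float | None = None, seed=None) -> np.ndarray:
    """Draw marker effects from a method's marginal prior (unit-ish scale).

    Used to verify distributional limits, e.g. the Student-t prior of the
    t-BLASSO methods converging to the normal (ridge) prior as df2 grows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    info = prior_for(method)
    fam = info["family"]
    if fam == "normal":
        return rng.normal(0.0, scale, size)
    if fam == "laplace":
        return rng.laplace(0.0, scale / np.sqrt(2.0), size)
    df = float(df2 if df2 is not None else info["df"])
    # t with matched variance: scale^2 = var = df/(df-2) * s^2
    s = scale * np.sqrt((df - 2.0) / df) if df > 2 else scale
    return s * rng.standard_t(df, size)


def moment_variance_components(y, Ga, Gd):
    """Method-of-moments (sigma_a2, sigma_d2, sigma_e2) from kinship traces.

    Least-squares fit of the empirical covariance yc yc' to
    sigma_a2*Ga + sigma_d2*Gd + sigma_e2*I (a Haseman-Elston-type
    regression), solved through the 3x3 system of kinship cross-traces.
    Components are clipped below at 2% of var(y) so they can serve as prior
    scales.
    """
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    vy = float(yc @ yc) / y.size
    Ks = [Ga, Gd, np.eye(y.size)]
    M = np.array([[float(np.sum(Ki * Kj)) for Kj in Ks] for Ki in Ks])
    rhs = np.array([float(yc @ Ki @ yc) for Ki in Ks])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        sol = np.full(3, vy / 3.0)
    return tuple(float(np.clip(s, 0.02 * vy, None)) for s in sol)


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _invgauss(mu, lam):
    # Michael-Schucany-Haas sampler for the inverse-Gaussian distribution
    if mu > 1e8:
        mu = 1e8
    v = np.random.standard_normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _scaled_inv_chi2(df, nu_times_scale):
    # draw sigma2 ~ scaled-inv-chi2: (df * S^2) / chi2_df
    return nu_times_scale / np.random.chisquare(df)


@njit(cache=True)
def _update_effects(E, M, Tmat, tau2, sigma_e2, tt, scaled):
    # site-by-site Gibbs over marker effects, fixed locus order.
    # Full conditional: m_i | . ~ N(rhs/prec, 1/prec) with
    #   prec = t_i't_i/sigma_e2 + 1/v_i,  rhs = t_i'(e + t_i m_i)/sigma_e2,
    # where v_i = tau2_i (IBLASSO/t/ridge) or tau2_i*sigma_e2 (BLASSO).
    n_loci = M.shape[0]
    for i in range(n_loci):
        vi = tau2[i] * sigma_e2 if scaled else tau2[i]
        if vi < 1e-300:
            vi = 1e-300
        prec = tt[i] / sigma_e2 + 1.0 / vi
        rhs = (np.dot(Tmat[:, i], E) + tt[i] * M[i]) / sigma_e2
        mean = rhs / prec
        new = mean + np.random.standard_normal() / np.sqrt(prec)
        diff = M[i] - new
        if diff != 0.0:
            for j in range(E.shape[0]):
                E[j] += Tmat[j, i] * diff
        M[i] = new


@njit(cache=True)
def _update_tau2(M, tau2, family, df2, S2, lam2, sigma_e2):
    # per-locus (or common) marker-variance update for one effect block
    n = M.shape[0]
    if family == 0:
        # BRR: common variance, scaled-inv-chi2(df2 + n, (df2*S2 + sum m^2)/(.))
        ss = 0.0
        for i in range(n):
            ss += M[i] * M[i]
        nu_s = ss + (df2 * S2 if df2 > 0 else 0.0)
        common = _scaled_inv_chi2(df2 + n, nu_s)
        for i in range(n):
            tau2[i] = common
    elif family == 2:
        # Student-t: tau2_i ~ scaled-inv-chi2(df2 + 1, df2*S2 + m_i^2)
        for i in range(n):
            tau2[i] = _scaled_inv_chi2(df2 + 1.0, df2 * S2 + M[i] * M[i])
    elif family == 1 or family == 4:
        # Laplace mixture: 1/tau2_i ~ InvGauss(sqrt(lam2*c/m_i^2), lam2),
        # c = sigma_e2 for the scaled (BLASSO) parameterization, else 1
        c = sigma_e2 if family == 4 else 1.0
        for i in range(n):
            m2 = M[i] * M[i]
            if m2 < 1e-300:
                m2 = 1e-300
            mu = np.sqrt(lam2 * c / m2)
            x = _invgauss(mu, lam2)
            tau2[i] = 1.0 / x
    # family 3: fixed variances, nothing to update
    return tau2


@njit(cache=True)
def _update_lambda2(tau2, df2, rate_prior):
    # lam2 | tau ~ Gamma(n + df2/2, sum(tau2)/2 + rate_prior); the Gamma
    # prior on lam2 is induced by a scaled-inv-chi2(df2, S2) on the implied
    # prior effect variance 2/lam2 (flat limit at df2 = -2 gives shape n-1)
    n = tau2.shape[0]
    st = 0.0
    for i in range(n):
        st += tau2[i]
    shape = n + 0.5 * df2 if df2 > 0 else n - 1.0
    rate = 0.5 * st + rate_prior
    return np.random.gamma(shape, 1.0 / rate)


@njit(cache=True)
def _run_chain(
    y, W, S, wa, wd, family, df1, df2,
    Se2, Sma2, Smd2, ta2, td2,
    n_iter, burn_in, thin, seed, store_effects,
):
    np.random.seed(seed)
    N = y.shape[0]
    na = W.shape[1]
    nd = S.shape[1]
    wtw = np.empty(na)
    for i in range(na):
        wtw[i] = np.dot(W[:, i], W[:, i])
    sts = np.empty(nd)
    for i in range(nd):
        sts[i] = np.dot(S[:, i], S[:, i])

    b = y.mean()
    ma = np.zeros(na)
    md = np.zeros(nd)
    e = y - b
    sigma_e2 = Se2
    lam_a2 = 2.0 / Sma2
    lam_d2 = 2.0 / Smd2
    scaled = family == 4
    if scaled:
        lam_a2 = 2.0 * Se2 / Sma2
        lam_d2 = 2.0 * Se2 / Smd2
    # Gamma-prior rate for lam2 (see _update_lambda2); constant through the run
    rate_a = df2 * Sma2 / (4.0 * (Se2 if scaled else 1.0)) if df2 > 0 else 0.0
    rate_d = df2 * Smd2 / (4.0 * (Se2 if scaled else 1.0)) if df2 > 0 else 0.0

    n_keep = (n_iter - burn_in) // thin
    out_se2 = np.empty(n_keep)
    out_sa2 = np.empty(n_keep)
    out_sd2 = np.empty(n_keep)
    out_ma = np.empty((n_keep if store_effects else 0, na))
    out_md = np.empty((n_keep if store_effects else 0, nd))
    sum_ma = np.zeros(na)
    sum_md = np.zeros(nd)
    sum_ta2 = np.zeros(na)
    sum_td2 = np.zeros(nd)
    kept = 0

    for it in range(1, n_iter + 1):
        # intercept (flat prior): b | . ~ N(1'(e + 1b)/N, sigma_e2/N)
        tot = b + e.mean()
        newb = tot + np.random.standard_normal() * np.sqrt(sigma_e2 / N)
        for j in range(N):
            e[j] += b - newb
        b = newb

        _update_effects(e, ma, W, ta2, sigma_e2, wtw, scaled)
        _update_effects(e, md, S, td2, sigma_e2, sts, scaled)

        _update_tau2(ma, ta2, family, df2, Sma2, lam_a2, sigma_e2)
        _update_tau2(md, td2, family, df2, Smd2, lam_d2, sigma_e2)
        if family == 1 or family == 4:
            lam_a2 = _update_lambda2(ta2, df2, rate_a)
            lam_d2 = _update_lambda2(td2, df2, rate_d)

        # residual variance: scaled-inv-chi2(df1 + N [+ n], (df1*Se2 + SS)/(.))
        ss = 0.0
        for j in range(N):
            ss += e[j] * e[j]
        df_e = df1 + N
        if scaled:
            # BLASSO: effect variances are tau2*sigma_e2, so the effects'
            # quadratic forms enter the residual-variance conditional
            for i in range(na):
                ss += ma[i] * ma[i] / ta2[i]
            for i in range(nd):
                ss += md[i] * md[i] / td2[i]
            df_e += na + nd
        nu_s = ss + (df1 * Se2 if df1 > 0 else 0.0)
        sigma_e2 = _scaled_inv_chi2(df_e, nu_s)

        if it > burn_in and (it - burn_in) % thin == 0:
            # derived genetic variances: sigma_a2 = sum 2pq m_a^2,
            # sigma_d2 = sum (2pq)^2 m_d^2
            sa2 = 0.0
            for i in range(na):
                sa2 += wa[i] * ma[i] * ma[i]
            sd2 = 0.0
            for i in range(nd):
                sd2 += wd[i] * md[i] * md[i]
            out_se2[kept] = sigma_e2
            out_sa2[kept] = sa2
            out_sd2[kept] = sd2
            if store_effects:
                for i in range(na):
                    out_ma[kept, i] = ma[i]
                for i in range(nd):
                    out_md[kept, i] = md[i]
            for i in range(na):
                sum_ma[i] += ma[i]
                sum_ta2[i] += ta2[i] * sigma_e2 if scaled else ta2[i]
            for i in range(nd):
                sum_md[i] += md[i]
                sum_td2[i] += td2[i] * sigma_e2 if scaled else td2[i]
            kept += 1

    inv = 1.0 / max(kept, 1)
    return (
        out_se2, out_sa2, out_sd2,
        sum_ma * inv, sum_md * inv, sum_ta2 * inv, sum_td2 * inv,
        out_ma, out_md,
    )


# ---------------------------------------------------------------------------
# Chain container and driver
# ---------------------------------------------------------------------------

@dataclass
class MCMCChain:
    """Retained Gibbs samples and posterior-mean effect vectors."""

    config: ModelConfig
    sigma_e2: np.ndarray
    sigma_a2: np.ndarray
    sigma_d2: np.ndarray
    mean_ma: np.ndarray
    mean_md: np.ndarray
    mean_ta2: np.ndarray
    mean_td2: np.ndarray
    p: np.ndarray
    ma_samples: np.ndarray | None = None
    md_samples: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.sigma_e2.size

    @property
    def h2a(self) -> np.ndarray:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_d2 + self.sigma_e2)

    @property
    def h2d(self) -> np.ndarray:
        return self.sigma_d2 / (self.sigma_a2 + self.sigma_d2 + self.sigma_e2)


def gibbs_run(y, W, S, config: ModelConfig, p: np.ndarray | None = None) -> MCMCChain:
    """Run the Gibbs sampler for one method on coded marker data.

    ``p`` (per-locus allele frequencies) feeds the derived genetic-variance
    identities; it defaults to frequencies recovered from the W coding.
    Reproducible: the chain is fully determined by ``config.seed``.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.asfortranarray(W, dtype=float)  # column access in the kernel
    S = np.asfortranarray(S, dtype=float)
    if W.shape[0] != y.size or S.shape[0] != y.size:
        raise ValueError("marker matrices are not aligned with the phenotype")
    if config.n_iter <= config.burn_in:
        raise ValueError("n_iter must exceed burn_in")
    fam, _, _ = MCMC_METHODS[_normalize(config.method)]

    if p is None:
        # W = dosage - 2p with dosage mean 2p_hat; cohort-frequency coding
        # makes columns mean-zero, so recover p from the code range
        p = np.clip((2.0 - W.max(axis=0)) / 2.0, 1e-6, 1 - 1e-6)
    p = np.asarray(p, dtype=float)
    wa = 2.0 * p * (1.0 - p)
    wd = wa**2

    # method-of-moments prior scales (per-locus effect-variance scale)
    if config.scale_ma is None or config.scale_md is None or config.scale_e is None:
        from .coding import build_Ga, build_Gd

        sa, sd, se = moment_variance_components(
            y, build_Ga(W, p), build_Gd(S, p)
        )
        scale_ma = config.scale_ma if config.scale_ma is not None else sa / wa.sum()
        scale_md = config.scale_md if config.scale_md is not None else sd / wd.sum()
        scale_e = config.scale_e if config.scale_e is not None else se
    else:
        scale_ma, scale_md, scale_e = config.scale_ma, config.scale_md, config.scale_e

    if fam == _FAM_FIXED:
        if config.fixed_ta is None or config.fixed_td is None:
            raise ValueError(
                "RR-HET requires fixed per-locus variances (run IBLASSO(4,-2) "
                "first and pass rr_het_variances output)"
            )
        ta2 = np.ascontiguousarray(config.fixed_ta, dtype=float)
        td2 = np.ascontiguousarray(config.fixed_td, dtype=float)
        if ta2.size != W.shape[1] or td2.size != S.shape[1]:
            raise ValueError("fixed variance vectors do not match the marker count")
    else:
        ta2 = np.full(W.shape[1], scale_ma)
        td2 = np.full(S.shape[1], scale_md)
        if fam == _FAM_LAPLACE_SCALED:
            ta2 = ta2 / scale_e
            td2 = td2 / scale_e

    out = _run_chain(
        y, W, S, wa, wd, fam, float(config.df1), float(config.df2),
        float(scale_e), float(scale_ma), float(scale_md),
        ta2.copy(), td2.copy(),
        int(config.n_iter), int(config.burn_in), int(config.thin),
        int(config.seed) & 0x7FFFFFFF, bool(config.store_effects),
    )
    se2, sa2, sd2, mean_ma, mean_md, mean_ta2, mean_td2, ma_s, md_s = out
    return MCMCChain(
        config=config,
        sigma_e2=se2, sigma_a2=sa2, sigma_d2=sd2,
        mean_ma=mean_ma, mean_md=mean_md,
        mean_ta2=mean_ta2, mean_td2=mean_td2,
        p=p,
        ma_samples=ma_s if config.store_effects else None,
        md_samples=md_s if config.store_effects else None,
    )


def rr_het_variances(source_chain: MCMCChain) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus variance diagonals (D_a, D_d) for RR-HET.

    Posterior means of the per-locus effect variances from an IBLASSO(4,-2)
    chain on the same data.
    """
    if _normalize(source_chain.config.method) != "iblasso(4,-2)":
        raise ValueError("RR-HET variances come from an IBLASSO(4,-2) chain")
    return source_chain.mean_ta2.copy(), source_chain.mean_td2.copy()


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def _spectral_var(x: np.ndarray) -> float:
    """Spectral density of a chain segment at frequency zero (Bartlett window)."""
    n = x.size
    xc = x - x.mean()
    L = max(1, int(n ** (1.0 / 3.0)))
    g0 = float(xc @ xc) / n
    s = g0
    for lag in range(1, L + 1):
        g = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * g
    return max(s, 0.0)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> np.ndarray:
    """Geweke convergence z-scores comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(S1(0)/n1 + S2(0)/n2) with
    spectral-density variance estimates; |z| > ~3 flags non-stationarity.
    1-D input gives a scalar array of shape (); 2-D input one z per column.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    n = x.shape[0]
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 100)")
    n1 = int(first * n)
    n2 = int(last * n)
    z = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        a, bseg = x[:n1, j], x[n - n2 :, j]
        v = _spectral_var(a) / n1 + _spectral_var(bseg) / n2
        if v <= 0:
            raise ValueError("degenerate (constant) chain: Geweke z undefined")
        z[j] = (a.mean() - bseg.mean()) / np.sqrt(v)
    return z[0] if squeeze else z


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of the variance components plus point predictions."""

    method: str
    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    sd_sigma_a2: float
    sd_sigma_d2: float
    sd_sigma_e2: float
    h2a: float
    h2d: float
    vd_va: float
    mean_ma: np.ndarray = field(repr=False)
    mean_md: np.ndarray = field(repr=False)
    u_a: np.ndarray | None = field(default=None, repr=False)
    u_d: np.ndarray | None = field(default=None, repr=False)

    @property
    def h2g(self) -> float:
        return self.h2a + self.h2d


def posterior_summary(chain: MCMCChain, W=None, S=None) -> PosteriorSummary:
    """Posterior summary; supplying W/S adds u_a = W m_a-bar, u_d = S m_d-bar."""
    if chain.n_retained == 0:
        raise ValueError("empty chain")
    h2a = chain.h2a
    h2d = chain.h2d
    return PosteriorSummary(
        method=chain.config.method,
        sigma_a2=float(chain.sigma_a2.mean()),
        sigma_d2=float(chain.sigma_d2.mean()),
        sigma_e2=float(chain.sigma_e2.mean()),
        sd_sigma_a2=float(chain.sigma_a2.std()),
        sd_sigma_d2=float(chain.sigma_d2.std()),
        sd_sigma_e2=float(chain.sigma_e2.std()),
        h2a=float(h2a.mean()),
        h2d=float(h2d.mean()),
        vd_va=float((chain.sigma_d2 / chain.sigma_a2).mean()),
        mean_ma=chain.mean_ma,
        mean_md=chain.mean_md,
        u_a=None if W is None else np.asarray(W) @ chain.mean_ma,
        u_d=None if S is None else np.asarray(S) @ chain.mean_md,
    )
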