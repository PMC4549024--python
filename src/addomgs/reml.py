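"""REML variance components and BLUP for the additive-dominance mixed model.

Model: y = Xb + Z u_a + Z u_d + e with u_a ~ N(0, Ka * sigma_a2),
u_d ~ N(0, Kd * sigma_d2), e ~ N(0, I * sigma_e2).  Ka/Kd are either the
genomic relationship matrices (G-BLUP) or the pedigree matrices A/D
(pedigree-BLUP).  Variance components are estimated by EM-REML on the
phenotypic covariance V = sigma_a2*Ka + sigma_d2*Kd + sigma_e2*I; the EM
update is monotone in the restricted likelihood, which the test suite
exploits as an invariant.  BLUP solutions come from Henderson's mixed model
equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .coding import add_ridge

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "reml_loglik",
    "fit_reml",
    "solve_mme",
    "solve_marker_mme",
]

_TINY = 1e-12


@dataclass
class MixedModelSpec:
    """Data and covariance structure for one additive-dominance fit."""

    y: np.ndarray
    covA: np.ndarray
    covD: np.ndarray | None = None
    X: np.ndarray | None = None  # default: intercept only

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != n or self.covA.shape != (n, n):
            raise ValueError("dimensions are not conformable")
        if self.covD is not None and self.covD.shape != (n, n):
            raise ValueError("dimensions are not conformable")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design matrix is singular")
        # working phenotype with fixed effects projected out: REML depends on
        # y only through Py (PX = 0), and using the projection explicitly
        # keeps estimates invariant to shifts in the fixed part
        Q, _ = np.linalg.qr(self.X)
        self._y_work = self.y - Q @ (Q.T @ self.y)

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class VarianceComponents:
    """Estimated variances with the derived heritabilities."""

    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    converged: bool = True
    loglik: float = np.nan
    n_iter: int = 0

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_d2 + self.sigma_e2

    @property
    def h2a(self) -> float:
        return self.sigma_a2 / self.total

    @property
    def h2d(self) -> float:
        return self.sigma_d2 / self.total

    @property
    def h2g(self) -> float:
        return self.h2a + self.h2d

    @property
    def vd_va(self) -> float:
        return self.sigma_d2 / self.sigma_a2 if self.sigma_a2 > 0 else np.nan


def _v_matrix(spec, sa2, sd2, se2):
    V = se2 * np.eye(spec.n) + sa2 * spec.covA
    if spec.covD is not None:
        V = V + sd2 * spec.covD
    return V


def _reml_pieces(spec, sa2, sd2, se2):
    """P matrix, Py and restricted log-likelihood for given components."""
    V = _v_matrix(spec, sa2, sd2, se2)
    cho = linalg.cho_factor(V, lower=True)
    Vi = linalg.cho_solve(cho, np.eye(spec.n))
    X = spec.X
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    Py = P @ spec._y_work
    yPy = float(spec._y_work @ Py)
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    sign, logdet_X = np.linalg.slogdet(XtViX)
    ll = -0.5 * (logdet_V + logdet_X + yPy)
    return P, Py, ll


def reml_loglik(spec: MixedModelSpec, sigma_a2, sigma_d2, sigma_e2) -> float:
    """Restricted log-likelihood (up to an additive constant)."""
    _, _, ll = _reml_pieces(spec, sigma_a2, sigma_d2, sigma_e2)
    return ll


def _em_step(spec, P, Py, comps, floor):
    """One EM-REML update; monotone in the restricted likelihood.

    For component i with covariance K_i * s_i (q_i = n levels):
        s_i <- s_i + s_i^2 * (y'P K_i P y - tr(P K_i)) / n
    tr(P K) is computed as sum(P * K) (both symmetric).
    """
    n = spec.n
    Ks = [spec.covA, None, np.eye(n)] if spec.covD is None else [
        spec.covA, spec.covD, np.eye(n)
    ]
    out = []
    for s, K in zip(comps, Ks):
        if K is None:
            out.append(0.0)
            continue
        out.append(max(s + s * s * (Py @ K @ Py - float(np.sum(P * K))) / n, floor))
    return out


def _ai_step(spec, P, Py, comps, floor):
    """Average-information update: solve AI * delta = score.

    score_i = -0.5 (tr(P K_i) - y'P K_i P y);
    AI_ij   =  0.5  y'P K_i P K_j P y.
    Returns None when the proposed step leaves the admissible region badly.
    """
    Ks = [spec.covA, spec.covD, np.eye(spec.n)]
    active = [k for k, K in enumerate(Ks) if K is not None]
    KPy = [Ks[k] @ Py for k in active]
    PKPy = [P @ v for v in KPy]
    score = np.array(
        [-0.5 * (float(np.sum(P * Ks[k])) - Py @ Ks[k] @ Py) for k in active]
    )
    AI = 0.5 * np.array([[KPy[i] @ PKPy[j] for j in range(len(active))]
                         for i in range(len(active))])
    # a near-singular AI matrix signals a flat (non-identified) direction:
    # AI steps along it are arbitrary and huge, so fall back to EM there
    if np.linalg.cond(AI) > 1e8:
        return None
    try:
        delta = np.linalg.solve(AI, score)
    except np.linalg.LinAlgError:
        return None
    new = list(comps)
    for j, k in enumerate(active):
        new[k] = comps[k] + delta[j]
    if min(new[k] for k in active) < -10.0 * floor:
        return None
    for k in active:
        new[k] = max(new[k], floor)
    return new


def fit_reml(
    spec: MixedModelSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
    start: tuple[float, float, float] | None = None,
    method: str = "ai",
) -> VarianceComponents:
    """REML estimates of (sigma_a2, sigma_d2, sigma_e2).

    ``method='ai'`` (default) runs a few monotone EM warm-up sweeps and then
    average-information iterations, falling back to an EM step whenever the
    AI step leaves the parameter space or lowers the restricted likelihood;
    ``method='em'`` runs pure EM.  Components are floored at 1e-8 * var(y)
    (EM can stall at the zero boundary); convergence is declared when the
    largest relative change drops below ``tol``.  Non-convergence is
    flagged, not raised.
    """
    vy = float(np.var(spec.y))
    if vy < 1e-30:  # degenerate input: constant phenotype
        return VarianceComponents(_TINY, _TINY, _TINY, True, 0.0, 0)
    floor = 1e-8 * vy
    has_d = spec.covD is not None
    if start is None:
        comps = [vy / 3.0, vy / 3.0 if has_d else 0.0, vy / 3.0]
    else:
        comps = list(start)
    ll = ll_prev = -np.inf
    warmup = 5 if method == "ai" else max_iter
    for it in range(1, max_iter + 1):
        P, Py, ll = _reml_pieces(spec, *comps)
        # flat-likelihood stop: on a non-identified ridge the parameter
        # change never settles while the likelihood is already stationary
        if method == "ai" and abs(ll - ll_prev) < 1e-10 * max(1.0, abs(ll)):
            return VarianceComponents(*comps, True, ll, it)
        ll_prev = ll
        if method == "ai" and it > warmup:
            new = _ai_step(spec, P, Py, comps, floor)
            if new is not None:
                _, _, ll_new = _reml_pieces(spec, *new)
                if not np.isfinite(ll_new) or ll_new < ll - 1e-10:
                    new = None
            if new is None:
                new = _em_step(spec, P, Py, comps, floor)
        else:
            new = _em_step(spec, P, Py, comps, floor)
        rel = max(
            abs(n - s) / max(s, floor)
            for n, s, use in zip(new, comps, (True, has_d, True))
            if use
        )
        comps = new
        if rel < tol:
            _, _, ll = _reml_pieces(spec, *comps)
            return VarianceComponents(*comps, True, ll, it)
    return VarianceComponents(*comps, False, ll, max_iter)


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents):
    """BLUP solutions (b_hat, u_a_hat, u_d_hat) of Henderson's equations.

    Singular relationship matrices receive a small diagonal ridge before
    inversion.  A variance at (or below) its numerical floor yields complete
    shrinkage: the corresponding random effect is returned as zeros.
    """
    if vc.sigma_e2 <= 0:
        raise ValueError("residual variance must be positive")
    n = spec.n
    X = spec.X
    vy = float(np.var(spec.y))
    cut = max(1e-6 * vy, _TINY)
    use_a = vc.sigma_a2 > cut
    use_d = spec.covD is not None and vc.sigma_d2 > cut

    blocks = [X]
    if use_a:
        blocks.append(np.eye(n))
    if use_d:
        blocks.append(np.eye(n))
    T = np.hstack(blocks)
    C = T.T @ T
    rhs = T.T @ spec.y
    p = X.shape[1]
    pos = p
    if use_a:
        Gai = np.linalg.inv(add_ridge(spec.covA))
        C[pos : pos + n, pos : pos + n] += Gai * (vc.sigma_e2 / vc.sigma_a2)
        pos += n
    if use_d:
        Gdi = np.linalg.inv(add_ridge(spec.covD))
        C[pos : pos + n, pos : pos + n] += Gdi * (vc.sigma_e2 / vc.sigma_d2)
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular mixed-model coefficient matrix") from exc
    b = sol[:p]
    pos = p
    if use_a:
        u_a = sol[pos : pos + n]
        pos += n
    else:
        u_a = np.zeros(n)
    u_d = sol[pos : pos + n] if use_d else np.zeros(n)
    return b, u_a, u_d


def solve_marker_mme(
    y: np.ndarray,
    W: np.ndarray,
    S: np.ndarray | None,
    sigma_ma2,
    sigma_md2,
    sigma_e2: float,
    X: np.ndarray | None = None,
):
    """Ridge-regression BLUP at the marker level (Henderson MME on markers).

    Solves for (b, m_a, m_d) in y = Xb + W m_a + S m_d + e where each marker
    effect is shrunk by lambda_i = sigma_e2 / var_i; ``sigma_ma2`` and
    ``sigma_md2`` may be scalars (homogeneous ridge) or per-locus vectors
    (heterogeneous ridge, as in RR-HET).  This is the equivalent model of
    G-BLUP: W m_a equals u_a from the relationship-matrix formulation.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    blocks = [X, W] + ([S] if S is not None else [])
    T = np.hstack(blocks)
    C = T.T @ T
    rhs = T.T @ y
    p = X.shape[1]
    la = sigma_e2 / np.broadcast_to(np.asarray(sigma_ma2, float), (W.shape[1],))
    idx = np.arange(p, p + W.shape[1])
    C[idx, idx] += la
    if S is not None:
        ld = sigma_e2 / np.broadcast_to(np.asarray(sigma_md2, float), (S.shape[1],))
        idx = np.arange(p + W.shape[1], p + W.shape[1] + S.shape[1])
        C[idx, idx] += ld
    sol = np.linalg.solve(C, rhs)
    b = sol[:p]
    m_a = sol[p : p + W.shape[1]]
    m_d = sol[p + W.shape[1] :] if S is not None else np.zeros(0)
    return b, m_a, m_d
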