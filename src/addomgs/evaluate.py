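"""Accuracy evaluation: deterministic formulas, cross-replicate validation.

The deterministic (parametric) accuracies follow the selection-index
argument for genomic prediction: with N training individuals, n_QTL
effective loci, marker-capture proportion r2_mq and heritabilities h2_a,
h2_d, h2_g,

    r_a = sqrt( r2_mq * (N r2_mq h2_a / n_QTL) / (1 + N r2_mq h2_g / n_QTL) )

and analogously with h2_d for the dominance accuracy; the genotypic accuracy
combines the two in quadrature.  Empirical accuracies follow the
9-train / 1-validation protocol: marker effects estimated in each training
replicate are applied to the validation replicate's incidence matrices and
correlated with its true additive / dominance values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import mcmc as _mcmc
from .coding import build_A, build_D, build_coding, build_Ga, build_Gd
from .reml import MixedModelSpec, fit_reml, solve_mme
from .simulate import SimDataset

__all__ = [
    "AccuracyInputs",
    "ALL_METHODS",
    "parametric_accuracy_additive",
    "parametric_accuracy_dominance",
    "parametric_accuracy_genotypic",
    "empirical_accuracy_bias",
    "fit_method",
    "run_validation",
    "score_best_criteria",
]

#: the ten fitted methods: eight Gibbs samplers plus the two REML baselines
ALL_METHODS = list(_mcmc.MCMC_METHODS) + ["g-blup", "pedigree"]

METRIC_COLUMNS = ["h2a", "h2d", "cor_a", "by_a", "cor_d", "by_d", "vd_va"]


@dataclass
class AccuracyInputs:
    """Inputs to the deterministic accuracy formulas."""

    N: int
    n_qtl: int
    r2_mq: float
    h2a: float = 0.0
    h2d: float = 0.0
    h2g: float = 0.0


def _parametric_accuracy(N, n_qtl, r2_mq, h2_focal, h2g):
    if n_qtl <= 0:
        raise ValueError("n_QTL must be positive")
    num = r2_mq * (N * r2_mq * h2_focal / n_qtl)
    den = 1.0 + N * r2_mq * h2g / n_qtl
    return float(np.sqrt(num / den))


def parametric_accuracy_additive(inp: AccuracyInputs) -> float:
    """Deterministic accuracy of genomic breeding-value prediction."""
    return _parametric_accuracy(inp.N, inp.n_qtl, inp.r2_mq, inp.h2a, inp.h2g)


def parametric_accuracy_dominance(inp: AccuracyInputs) -> float:
    """Deterministic accuracy of dominance-deviation prediction."""
    return _parametric_accuracy(inp.N, inp.n_qtl, inp.r2_mq, inp.h2d, inp.h2g)


def parametric_accuracy_genotypic(ra: float, rd: float) -> float:
    """Genotypic accuracy sqrt(ra^2 + rd^2)."""
    if not (0.0 <= ra <= 1.0 and 0.0 <= rd <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    s = ra * ra + rd * rd
    if s > 1.0 + 1e-12:
        raise ValueError("ra^2 + rd^2 exceeds 1; not a valid accuracy pair")
    return float(np.sqrt(min(s, 1.0)))


def empirical_accuracy_bias(predicted, true) -> tuple[float, float]:
    """Accuracy (Pearson r) and bias (OLS slope of true on predicted).

    A slope of 1 means unbiased prediction; the tables' "byg" columns.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if predicted.size != true.size:
        raise ValueError("vectors must have equal length")
    if np.var(predicted) <= 0 or np.var(true) <= 0:
        raise ValueError("zero-variance input: accuracy undefined")
    r = float(stats.pearsonr(predicted, true).statistic)
    slope = float(np.cov(true, predicted, ddof=1)[0, 1] / np.var(predicted, ddof=1))
    return r, slope


# ---------------------------------------------------------------------------
# Fitting a named method on one replicate
# ---------------------------------------------------------------------------

@dataclass
class MethodFit:
    """One method fitted on one replicate: variance ratios + marker effects."""

    method: str
    h2a: float
    h2d: float
    vd_va: float
    m_a: np.ndarray | None  # allele-substitution effects (transferable)
    m_d: np.ndarray | None
    u_a: np.ndarray         # within-replicate predictions
    u_d: np.ndarray


def fit_method(ds: SimDataset, method: str, mcmc_overrides: dict | None = None,
               seed: int = 0) -> MethodFit:
    """Fit one of the ten methods on a replicate and return transferable
    marker effects (the REML methods via the equivalent marker model)."""
    y = ds.y
    dosages = ds.dosages
    # clip frequencies so loci monomorphic in a subset (e.g. one family)
    # yield ~zero incidence columns instead of an undefined coding
    p_obs = np.clip(dosages.mean(axis=0) / 2.0, 1e-6, 1.0 - 1e-6)
    coding = build_coding(dosages, p_obs)
    W, S, p = coding.W, coding.S, coding.p
    key = method.lower().replace(" ", "")

    if key in ("g-blup", "gblup"):
        Ga, Gd = build_Ga(W, p), build_Gd(S, p)
        spec = MixedModelSpec(y, Ga, Gd)
        vc = fit_reml(spec)
        b, u_a, u_d = solve_mme(spec, vc)
        # equivalent-model marker effects: m_a = sigma_ma2 W' V^-1 (y - Xb)
        V = vc.sigma_a2 * Ga + vc.sigma_d2 * Gd + vc.sigma_e2 * np.eye(y.size)
        r = np.linalg.solve(V, y - spec.X @ b)
        m_a = (vc.sigma_a2 / coding.sum2pq) * (W.T @ r)
        m_d = (vc.sigma_d2 / coding.sum2pq_sq) * (S.T @ r)
        return MethodFit(method, vc.h2a, vc.h2d, vc.vd_va, m_a, m_d, u_a, u_d)

    if key == "pedigree":
        sire, dam = ds.cohort.pedigree()
        A = build_A(sire, dam)
        idx = np.arange(ds.cohort.n_founders, sire.size)
        Acoh = A[np.ix_(idx, idx)]
        Dcoh = build_D(sire, dam, A)[np.ix_(idx, idx)]
        spec = MixedModelSpec(y, Acoh, Dcoh)
        vc = fit_reml(spec)
        _, u_a, u_d = solve_mme(spec, vc)
        return MethodFit(method, vc.h2a, vc.h2d, vc.vd_va, None, None, u_a, u_d)

    overrides = dict(mcmc_overrides or {})
    overrides.setdefault("seed", seed)
    if key == "rr-het(-2,-2)":
        src_cfg = _mcmc.model_config("iblasso(4,-2)", **overrides)
        src = _mcmc.gibbs_run(y, W, S, src_cfg, p)
        Da, Dd = _mcmc.rr_het_variances(src)
        overrides["fixed_ta"], overrides["fixed_td"] = Da, Dd
    cfg = _mcmc.model_config(method, **overrides)
    chain = _mcmc.gibbs_run(y, W, S, cfg, p)
    s = _mcmc.posterior_summary(chain, W, S)
    return MethodFit(method, s.h2a, s.h2d, s.vd_va, s.mean_ma, s.mean_md, s.u_a, s.u_d)


# ---------------------------------------------------------------------------
# 9-train / 1-validation protocol
# ---------------------------------------------------------------------------

def run_validation(
    replicates: list[SimDataset],
    methods: list[str] | None = None,
    mcmc_overrides: dict | None = None,
    validation_index: int = -1,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-replicate validation averaged over training replicates.

    One replicate is held out for validation; each remaining replicate is
    used in turn to estimate marker effects, which are applied to the
    validation replicate's own W/S coding and correlated with its true
    breeding values / dominance deviations.  The pedigree method carries no
    marker effects, so its accuracy is computed within the training
    replicate (pedigree relationships across independent replicates vanish).

    Returns a DataFrame indexed by method with the seven table metrics and
    their across-replicate SDs.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates (train + validation)")
    methods = list(methods) if methods is not None else list(ALL_METHODS)
    n_loci = {ds.dosages.shape[1] for ds in replicates}
    if len(n_loci) != 1:
        raise ValueError("marker panels differ across replicates")

    val = replicates[validation_index]
    train = [ds for k, ds in enumerate(replicates)
             if k % len(replicates) != validation_index % len(replicates)]
    val_coding = build_coding(val.dosages)

    rows = {}
    sds = {}
    for method in methods:
        per_rep = []
        for k, ds in enumerate(train):
            fit = fit_method(ds, method, mcmc_overrides, seed=seed + 1000 * k)
            if fit.m_a is not None:
                ua_hat = val_coding.W @ fit.m_a
                ud_hat = val_coding.S @ fit.m_d
                cor_a, by_a = empirical_accuracy_bias(ua_hat, val.u_a)
                cor_d, by_d = empirical_accuracy_bias(ud_hat, val.u_d)
            else:
                cor_a, by_a = empirical_accuracy_bias(fit.u_a, ds.u_a)
                cor_d, by_d = empirical_accuracy_bias(fit.u_d, ds.u_d)
            per_rep.append(
                [fit.h2a, fit.h2d, cor_a, by_a, cor_d, by_d, fit.vd_va]
            )
        arr = np.asarray(per_rep)
        rows[method] = arr.mean(axis=0)
        sds[method] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(7)

    report = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)
    for j, col in enumerate(METRIC_COLUMNS):
        report[f"sd_{col}"] = [sds[m][j] for m in report.index]
    report.index.name = "method"
    return report


# ---------------------------------------------------------------------------
# "Number of criteria best" scoring
# ---------------------------------------------------------------------------

def score_best_criteria(report: pd.DataFrame, parametric: dict) -> pd.Series:
    """Count, per method, how many of the seven criteria it scores as best.

    Scoring rule (reconstructed from the comparison tables): for h2a, h2d and
    Vd/Va a method scores when within 0.02 of the method value closest to the
    parametric one; for the accuracies cor_a/cor_d when within 0.02 of the
    highest; for the bias slopes when inside [0.5, 1.5].  Missing entries
    (e.g. Vd/Va for pedigree-BLUP) simply do not score.
    """
    counts = pd.Series(0, index=report.index, dtype=int)
    for col in ("h2a", "h2d", "vd_va"):
        vals = report[col].astype(float)
        ok = vals.notna()
        if not ok.any() or col not in parametric:
            continue
        best = vals[ok].iloc[(vals[ok] - parametric[col]).abs().argmin()]
        counts += ((vals - best).abs() <= 0.02 + 1e-9).fillna(False).astype(int)
    for col in ("cor_a", "cor_d"):
        vals = report[col].astype(float)
        best = vals.max()
        counts += ((best - vals) <= 0.02 + 1e-9).fillna(False).astype(int)
    for col in ("by_a", "by_d"):
        vals = report[col].astype(float)
        counts += ((vals >= 0.5) & (vals <= 1.5)).fillna(False).astype(int)
    return counts
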