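"""Partition of genomic heritability and accuracy into LD, co-segregation
and pedigree-relationship information.

Genomic prediction draws on three quantitative-genetic information sources:
population-level linkage disequilibrium between markers and QTL (LD),
within-family disequilibrium from linkage (co-segregation, CS), and
identity-by-descent relationships at the same locus (pedigree
relationships).  They are separated by re-analysing the same cohort three
ways:

1. raw          — phenotypes as observed           -> CS + LD + family IBD
2. AWF          — within-family deviations, all
                  families together                -> CS + LD
3. DMS          — one family at a time on
                  family-corrected phenotypes,
                  averaged over families           -> LD only

plus a pedigree-only analysis (-> CS + individual IBD).  Heritability
components follow by subtraction (CS = AWF - DMS, family IBD = raw - AWF,
individual IBD = pedigree - CS) while accuracy components combine in
quadrature, sqrt(x^2 - y^2), mirroring the published table arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "within_family_deviations",
    "per_family_fit_average",
    "quadrature_difference",
    "combine_related_accuracy",
    "AnalysisResult",
    "build_decomposition",
    "decompose_information",
]


def within_family_deviations(y, family_id) -> np.ndarray:
    """Phenotypes corrected for family effects: y minus its family mean."""
    y = np.asarray(y, dtype=float).ravel()
    family_id = np.asarray(family_id).ravel()
    if y.size != family_id.size:
        raise ValueError("y and family labels must align")
    fams, inv, counts = np.unique(family_id, return_inverse=True, return_counts=True)
    if fams.size < 2:
        raise ValueError("need at least two families")
    if np.any(counts == 1):
        warnings.warn("singleton family: its deviation is identically 0")
    means = np.bincount(inv, weights=y) / counts
    return y - means[inv]


def per_family_fit_average(
    datasets_by_family: dict,
    fit_fn,
    min_family_size: int = 10,
):
    """Fit a model separately per family and average the results.

    ``datasets_by_family`` maps family label -> per-family data (whatever
    ``fit_fn`` accepts); ``fit_fn`` returns a mapping of scalar metrics
    (e.g. h2a, cor_a).  Families smaller than ``min_family_size`` are
    skipped with a warning.  Returns the unweighted across-family mean of
    each metric (equal family sizes in the default design).
    """
    rows = []
    for fam, data in datasets_by_family.items():
        n = len(data[0]) if isinstance(data, tuple) else len(data)
        if n < min_family_size:
            warnings.warn(f"family {fam!r} too small to fit (n={n}); skipped")
            continue
        rows.append(fit_fn(data))
    if not rows:
        raise ValueError("no family large enough to fit")
    keys = rows[0].keys()
    return {k: float(np.mean([r[k] for r in rows])) for k in keys}


def quadrature_difference(x: float, y: float) -> float:
    """Accuracy of an isolated information source, sqrt(x^2 - y^2)."""
    if not (x >= y >= 0):
        raise ValueError("need x >= y >= 0 for a quadrature difference")
    return float(np.sqrt(x * x - y * y))


def combine_related_accuracy(r_ped: float, r_unrelated: float) -> float:
    """Accuracy for related individuals: r_ped + (1 - r_ped) * r_unrelated."""
    if not (0.0 <= r_ped <= 1.0 and 0.0 <= r_unrelated <= 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    return float(r_ped + (1.0 - r_ped) * r_unrelated)


@dataclass
class AnalysisResult:
    """Additive heritability and additive accuracy of one analysis."""

    h2a: float
    accuracy: float


def build_decomposition(
    raw: AnalysisResult,
    awf: AnalysisResult,
    dms: AnalysisResult,
    ped: AnalysisResult,
    parametric_h2a: float | None = None,
) -> pd.DataFrame:
    """Assemble the information-partition table from the four analyses.

    Heritability components are simple differences; accuracy components are
    quadrature differences (negative derived values are floored at 0 with a
    warning).  Also reports the composed related-individual accuracy
    r_ped + (1 - r_ped) * r_LD and the fraction of pedigree information
    captured by markers, h2(I-IBD-R) / h2(LD).
    """
    def _sub(x, y, label):
        d = x - y
        if d < 0:
            warnings.warn(f"negative derived component {label}; reported as 0")
            return 0.0
        return d

    cs_h2 = _sub(awf.h2a, dms.h2a, "CS h2")
    fibd_h2 = _sub(raw.h2a, awf.h2a, "F-IBD-R h2")
    iibd_h2 = _sub(ped.h2a, cs_h2, "I-IBD-R h2")
    cs_acc = quadrature_difference(max(awf.accuracy, dms.accuracy), dms.accuracy)
    iibd_acc = quadrature_difference(max(ped.accuracy, cs_acc), cs_acc)

    rows = [
        ("raw", "COSEG + IBD-LD + F-IBD-R", raw.h2a, raw.accuracy),
        ("AWF", "COSEG + LD", awf.h2a, awf.accuracy),
        ("DMS", "LD", dms.h2a, dms.accuracy),
        ("CS = AWF - DMS", "COSEG", cs_h2, cs_acc),
        ("F-IBD-R = raw - AWF", "F-IBD-R", fibd_h2, np.nan),
        ("pedigree-raw", "COSEG + I-IBD-R", ped.h2a, ped.accuracy),
        ("I-IBD-R = pedigree - CS", "I-IBD-R", iibd_h2, iibd_acc),
    ]
    if parametric_h2a is not None:
        rows.append(("parametric", "ALL", parametric_h2a, np.nan))
    table = pd.DataFrame(rows, columns=["analysis", "information", "h2a", "accuracy"])
    table.attrs["related_accuracy_composed"] = combine_related_accuracy(
        min(ped.accuracy, 1.0), min(dms.accuracy, 1.0)
    )
    table.attrs["ld_captured_fraction"] = (
        iibd_h2 / dms.h2a if dms.h2a > 0 else np.nan
    )
    return table


def decompose_information(
    ds,
    method: str = "bayesa*b*(-2,8)",
    mcmc_overrides: dict | None = None,
    parametric_h2a: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the three-dataset decomposition on one simulated replicate.

    Fits ``method`` on the raw phenotypes, on within-family deviations
    (all families), and within each family separately (averaged), plus
    pedigree-BLUP on the raw phenotypes; assembles the partition table.
    Accuracies are within-cohort correlations of predictions with the true
    breeding values.
    """
    from dataclasses import replace as _dc_replace

    from .evaluate import empirical_accuracy_bias, fit_method

    def _acc(u_hat, u_true):
        return empirical_accuracy_bias(u_hat, u_true)[0]

    # 1: raw
    fit = fit_method(ds, method, mcmc_overrides, seed=seed)
    raw = AnalysisResult(fit.h2a, _acc(fit.u_a, ds.u_a))

    # 2: AWF — family-corrected phenotypes, all families together
    y_awf = within_family_deviations(ds.y, ds.cohort.family_id)
    ds_awf = _dc_replace(ds, y=y_awf)
    fit = fit_method(ds_awf, method, mcmc_overrides, seed=seed)
    awf = AnalysisResult(fit.h2a, _acc(fit.u_a, ds.u_a))

    # 3: DMS — one family at a time with posterior averaging
    fam = np.asarray(ds.cohort.family_id)

    def _fit_family(members):
        sub = _subset_dataset(ds, members, y_awf)
        f = fit_method(sub, method, mcmc_overrides, seed=seed)
        return {"h2a": f.h2a, "accuracy": _acc(f.u_a, ds.u_a[members])}

    fams = {f: np.flatnonzero(fam == f) for f in np.unique(fam)}
    dms_metrics = per_family_fit_average(fams, _fit_family)
    dms = AnalysisResult(dms_metrics["h2a"], dms_metrics["accuracy"])

    # 6: pedigree on raw phenotypes
    fit = fit_method(ds, "pedigree", seed=seed)
    ped = AnalysisResult(fit.h2a, _acc(fit.u_a, ds.u_a))

    return build_decomposition(raw, awf, dms, ped, parametric_h2a)


def _subset_dataset(ds, members, y_corrected):
    """View of one family as a standalone dataset for per-family fitting."""
    from dataclasses import replace as _dc_replace

    sub_cohort = _dc_replace(
        ds.cohort,
        haplotypes=ds.cohort.haplotypes[members],
        family_id=ds.cohort.family_id[members],
        sire=ds.cohort.sire[members],
        dam=ds.cohort.dam[members],
    )
    return _dc_replace(
        ds,
        cohort=sub_cohort,
        y=y_corrected[members],
        g=ds.g[members],
        u_a=ds.u_a[members],
        u_d=ds.u_d[members],
    )
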