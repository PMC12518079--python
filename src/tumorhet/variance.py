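"""Per-gene variance-components decomposition and the ITVS statistic.

Each gene's expression across a multi-region cohort is modelled as a
one-way random-effects (random-intercept) model:

    y_pr = mu + b_p + e_pr,   b_p ~ N(0, B),  e_pr ~ N(0, W)

where ``p`` indexes patients and ``r`` regions within a patient.  ``W``
is the within-tumor (residual) variance, ``B`` the between-tumor
(patient-level) variance, and the intra-tumoral variability score is

    ITVS = W / (W + B)

so values near 1 mean within-tumor variability dominates the signal.

Two estimators are provided.  The default is the closed-form one-way
ANOVA method of moments with the unbalanced-design correction for the
effective group size n0 = (N - sum(n_p^2)/N) / (a - 1): W = MSW and
B = (MSB - MSW)/n0, with negative B truncated to zero (standard
variance-components practice, recorded in ``degenerate``).  It is
deterministic and vectorizes over tens of thousands of genes.  REML via
:class:`statsmodels.regression.mixed_linear_model.MixedLM` is available
as ``method="reml"``; per-gene fit failures are flagged, never fatal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datamodel import DataModelError, ExpressionMatrix, SampleMap

logger = logging.getLogger(__name__)

__all__ = ["itvs", "partition_variance"]

#: Relative tolerance below which a gene's total variance counts as zero.
_DEGENERATE_TOL = 1e-12


def itvs(w: float, b: float) -> float:
    """Intra-tumoral variability score W / (W + B).

    Returns NaN (undefined) when both components are zero.  Negative
    components are rejected: truncation happens upstream in the estimator.
    """
    if w < 0 or b < 0:
        raise ValueError(f"variance components must be >= 0, got W={w}, B={b}")
    total = w + b
    if total <= 0:
        return float("nan")
    return float(w / total)


def _design_arrays(
    expr: ExpressionMatrix, smap: SampleMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, patient codes, group sizes) in matrix sample order."""
    patients = smap.patients_of(expr.sample_ids)
    labels, inverse = np.unique(patients, return_inverse=True)
    sizes = np.bincount(inverse)
    if len(labels) < 2:
        raise DataModelError("heterogeneity estimation requires >= 2 patients")
    if (sizes >= 2).sum() < 1:
        raise DataModelError(
            "within-tumor variance is inestimable: no patient has >= 2 regions"
        )
    return expr.values, inverse, sizes


def _mom(values: np.ndarray, groups: np.ndarray, sizes: np.ndarray):
    """Vectorized one-way ANOVA method of moments over all genes at once."""
    n_genes, n = values.shape
    a = sizes.size
    indicator = np.zeros((a, n))
    indicator[groups, np.arange(n)] = 1.0
    group_sums = values @ indicator.T  # (G, a)
    group_means = group_sums / sizes
    grand_mean = values.mean(axis=1)

    ssw = (values**2).sum(axis=1) - (sizes * group_means**2).sum(axis=1)
    ssb = (sizes * group_means**2).sum(axis=1) - n * grand_mean**2
    ssw = np.maximum(ssw, 0.0)  # guard fp cancellation
    ssb = np.maximum(ssb, 0.0)

    msw = ssw / (n - a)
    msb = ssb / (a - 1)
    n0 = (n - (sizes**2).sum() / n) / (a - 1)  # effective group size
    b_raw = (msb - msw) / n0
    truncated = b_raw < 0
    b = np.maximum(b_raw, 0.0)
    return msw, b, truncated


def _reml_one(y: np.ndarray, groups: np.ndarray) -> tuple[float, float, bool]:
    """REML variance components for one gene; (W, B, ok)."""
    import statsmodels.api as sm

    exog = np.ones((y.size, 1))
    # boundary fits (B ~ 0) can break an optimizer; walk a fallback chain
    for method in ("lbfgs", "bfgs", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, exog, groups=groups)
                fit = model.fit(reml=True, method=method)
                w = float(fit.scale)
                b = float(np.asarray(fit.cov_re)[0, 0])
            except Exception:  # per-gene failure must not abort the batch
                continue
        if np.isfinite(w) and np.isfinite(b):
            return max(w, 0.0), max(b, 0.0), True
    return np.nan, np.nan, False


def partition_variance(
    expr: ExpressionMatrix,
    smap: SampleMap,
    method: str = "mom",
) -> pd.DataFrame:
    """Estimate W, B and ITVS for every gene.

    Parameters
    ----------
    expr, smap
        Aligned expression matrix and sample map (same samples, same order;
        use :func:`tumorhet.datamodel.align` first).
    method
        ``"mom"`` (closed-form ANOVA method of moments, default) or
        ``"reml"`` (per-gene mixed-model REML fit).

    Returns
    -------
    DataFrame with columns ``gene_id, W, B, ITVS, estimator, degenerate``.
    ``degenerate`` is True when the gene is constant (ITVS undefined, NaN),
    when a negative moment estimate of B was truncated to zero, or when a
    REML fit failed.
    """
    if method not in ("mom", "reml"):
        raise ValueError(f"unknown estimator {method!r}; use 'mom' or 'reml'")
    values, groups, sizes = _design_arrays(expr, smap)
    gene_ids = expr.gene_ids

    total_var = values.var(axis=1)
    constant = total_var <= _DEGENERATE_TOL * np.maximum(
        1.0, np.abs(values).max(axis=1) ** 2
    )

    if method == "mom":
        w, b, truncated = _mom(values, groups, sizes)
        flagged = truncated | constant
    else:
        w = np.empty(len(gene_ids))
        b = np.empty(len(gene_ids))
        ok = np.empty(len(gene_ids), dtype=bool)
        for i in range(len(gene_ids)):
            if constant[i]:
                w[i], b[i], ok[i] = 0.0, 0.0, True
                continue
            w[i], b[i], ok[i] = _reml_one(values[i], groups)
        flagged = ~ok | constant

    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(w + b > 0, w / np.where(w + b > 0, w + b, 1.0), np.nan)
    score = np.where(constant, np.nan, score)
    w = np.where(constant, 0.0, w)
    b = np.where(constant, 0.0, b)

    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.info("partition_variance: %d/%d genes flagged", n_flagged, len(gene_ids))

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "W": w,
            "B": b,
            "ITVS": score,
            "estimator": method,
            "degenerate": flagged,
        }
    )
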