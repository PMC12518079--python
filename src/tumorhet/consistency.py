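"""Clustering-consistency scoring: PGOR curves, AUPC, CCS, IHS.

The intuition: a gene with low intra-tumor heterogeneity should cluster
regions of the same patient together at every resolution.  For one gene,
samples are hierarchically clustered on the 1-D expression values
(absolute-difference distance).  The tree is cut into k = 1..N clusters;
at each level the patient grouping odds ratio (PGOR) is the fraction of
multi-region patients whose regions all land in a single cluster.
Single-region patients carry no grouping information and are excluded
from the denominator.  The area under the PGOR-vs-k curve (AUPC, by
trapezoidal integration over unit steps) summarizes how long patient
identity survives increasing resolution, and

    CCS = 1 - AUPC / (N - 1)

maps it to [0, 1]: consistent (low-ITH) genes keep PGOR high for many k,
hence large AUPC and *small* CCS.  The integrated heterogeneity score is
the geometric mean

    IHS = sqrt(ITVS * CCS)

and genes with IHS <= 0.5 (inclusive boundary) are classified low-ITH.

Cluster endpoints are forced: k=1 puts everyone in one cluster (PGOR=1)
and k=N splits everything into singletons (PGOR=0 whenever every
evaluable patient has >= 2 regions).  No monotonicity in between is
assumed.  Agglomeration uses scipy's deterministic linkage.  Ward
linkage is the default: on simulated multi-region cohorts it makes CCS
the most faithful monotone readout of the true within-patient variance
fraction among the supported rules (average, complete, single, ward),
all of which remain selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage

from .datamodel import DataModelError, ExpressionMatrix, SampleMap
from .variance import partition_variance

logger = logging.getLogger(__name__)

__all__ = [
    "PgorCurve",
    "pgor_curve",
    "ccs",
    "ihs",
    "classify_ith",
    "score_all_genes",
]

_LINKAGES = ("average", "complete", "single", "ward")


@dataclass(frozen=True)
class PgorCurve:
    """PGOR evaluated at every cut level k = 1..N for one gene."""

    gene_id: str
    k_values: np.ndarray
    pgor_values: np.ndarray
    n_evaluable_patients: int

    @property
    def aupc(self) -> float:
        """Trapezoidal integral of PGOR over k (unit steps); <= N - 1."""
        return float(np.trapezoid(self.pgor_values, self.k_values))


def _patient_blocks(patients: np.ndarray) -> list[np.ndarray]:
    """Sample-index blocks of patients with >= 2 samples."""
    blocks = []
    for label in dict.fromkeys(patients):
        idx = np.flatnonzero(patients == label)
        if idx.size >= 2:
            blocks.append(idx)
    return blocks


def pgor_curve(
    values: np.ndarray,
    patients: np.ndarray,
    *,
    gene_id: str = "",
    linkage_rule: str = "ward",
) -> PgorCurve:
    """PGOR at every k = 1..N for a single gene's per-sample values.

    ``values`` and ``patients`` are parallel arrays over samples.  A
    patient is correctly grouped at level k iff all of its regions fall
    in one cluster of the k-cut.
    """
    values = np.asarray(values, dtype=float)
    patients = np.asarray(patients, dtype=object)
    n = values.size
    if n < 2:
        raise DataModelError("PGOR needs at least 2 samples")
    if patients.size != n:
        raise DataModelError("values and patients must be parallel")
    if linkage_rule not in _LINKAGES:
        raise ValueError(f"linkage_rule must be one of {_LINKAGES}")

    blocks = _patient_blocks(patients)
    if not blocks:
        raise DataModelError("PGOR undefined: no patient has >= 2 regions")

    tree = linkage(values[:, None], method=linkage_rule)
    # labels[:, i] = cluster assignment when the tree is cut into i+1 clusters
    labels = cut_tree(tree)  # (n, n), column j has n - j clusters
    pgor = np.empty(n)
    for k in range(1, n + 1):
        col = labels[:, n - k]
        ok = sum(1 for idx in blocks if np.unique(col[idx]).size == 1)
        pgor[k - 1] = ok / len(blocks)
    return PgorCurve(
        gene_id=gene_id,
        k_values=np.arange(1, n + 1),
        pgor_values=pgor,
        n_evaluable_patients=len(blocks),
    )


def ccs(curve: PgorCurve) -> float:
    """Clustering consistency score 1 - AUPC/(N-1), clipped to [0, 1]."""
    n = curve.k_values.size
    if n < 2:
        raise DataModelError("CCS needs N >= 2 samples")
    return float(np.clip(1.0 - curve.aupc / (n - 1), 0.0, 1.0))


def ihs(itvs_value: float, ccs_value: float) -> float:
    """Integrated heterogeneity score: geometric mean of ITVS and CCS.

    NaN in either input propagates (undefined score).
    """
    if np.isnan(itvs_value) or np.isnan(ccs_value):
        return float("nan")
    for name, v in (("ITVS", itvs_value), ("CCS", ccs_value)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(np.sqrt(itvs_value * ccs_value))


def classify_ith(scores: pd.Series | np.ndarray, threshold: float = 0.5) -> pd.Series:
    """Label genes 'low' (IHS <= threshold, inclusive) or 'high'.

    Undefined (NaN) scores get an empty label and are excluded from the
    classified counts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    s = pd.Series(scores, dtype=float)
    labels = pd.Series(
        np.where(s.isna(), "", np.where(s <= threshold, "low", "high")),
        index=s.index,
    )
    n_undef = int(s.isna().sum())
    if n_undef == len(s):
        logger.warning("classify_ith: every IHS undefined; nothing classified")
    elif n_undef:
        logger.info("classify_ith: %d gene(s) with undefined IHS skipped", n_undef)
    return labels


def score_all_genes(
    expr: ExpressionMatrix,
    smap: SampleMap,
    *,
    method: str = "mom",
    linkage_rule: str = "ward",
    threshold: float = 0.5,
    min_mean_expression: float | None = None,
    return_curves: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-gene heterogeneity table: W, B, ITVS, AUPC, CCS, IHS, class.

    ``min_mean_expression`` optionally drops weakly expressed genes before
    scoring (default: off).  With ``return_curves=True`` a long-format
    (gene_id, k, pgor) frame of every PGOR curve is returned as well.
    """
    expr_used = expr
    if min_mean_expression is not None:
        keep = [
            g
            for g, m in zip(expr.gene_ids, expr.values.mean(axis=1))
            if m >= min_mean_expression
        ]
        if not keep:
            raise DataModelError("min_mean_expression filter removed every gene")
        expr_used = expr.subset_genes(keep)

    var_table = partition_variance(expr_used, smap, method=method)
    patients = smap.patients_of(expr_used.sample_ids)

    ccs_vals, aupc_vals, curve_rows = [], [], []
    for gene_id, row in zip(expr_used.gene_ids, expr_used.values):
        curve = pgor_curve(
            row, patients, gene_id=gene_id, linkage_rule=linkage_rule
        )
        aupc_vals.append(curve.aupc)
        ccs_vals.append(ccs(curve))
        if return_curves:
            curve_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_id,
                        "k": curve.k_values,
                        "pgor": curve.pgor_values,
                    }
                )
            )

    table = var_table.copy()
    table["AUPC"] = aupc_vals
    table["CCS"] = ccs_vals
    table["IHS"] = [
        ihs(i, c) for i, c in zip(table["ITVS"].to_numpy(), table["CCS"].to_numpy())
    ]
    table["ith_class"] = classify_ith(table["IHS"], threshold=threshold).to_numpy()

    n_low = int((table["ith_class"] == "low").sum())
    logger.info(
        "score_all_genes: %d/%d genes low-ITH at threshold %.3g",
        n_low,
        len(table),
        threshold,
    )
    if return_curves:
        curves = pd.concat(curve_rows, ignore_index=True)
        return table, curves
    return table
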