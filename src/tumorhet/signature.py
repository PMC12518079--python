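"""Low-ITH prognostic gene selection and the linear risk score.

The selection funnel mirrors a heterogeneity-aware biomarker strategy:

1. differential expression between tumor and normal groups, kept at a
   lenient fold-change cutoff |log2FC| > 0.137 (about a 10% expression
   change) with FDR < 0.05;
2. a univariate Cox proportional-hazards screen per gene, requiring
   significance and a passing PH diagnostic;
3. hazard-direction consistency between two independent cohorts;
4. intersection with the low-ITH gene set (IHS <= 0.5).

The surviving genes feed a linear risk model.  The default model is the
published two-gene signature

    risk score = 0.024 * CYP4B1 + 0.02 * GBP1

whose weights come from a random-survival-forest importance analysis and
are consumed here as fixed configuration (the forest itself is not
re-trained); externally trained weights can be supplied the same way.
Patients are stratified at the median score (> median = high risk) by
default; the split rule is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataModelError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "default_risk_model",
    "simple_de",
    "filter_degs",
    "consistent_direction",
    "intersect_low_ith",
    "select_signature_genes",
    "risk_score",
    "stratify",
    "stratify_median",
]


@dataclass(frozen=True)
class RiskModel:
    """Ordered gene list with linear weights and a stratification rule."""

    genes: tuple[str, ...]
    weights: tuple[float, ...]
    split_rule: str = "median"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise DataModelError("genes and weights must be parallel")
        if len(self.genes) == 0:
            raise DataModelError("risk model needs at least one gene")
        if not np.isfinite(self.weights).all():
            raise DataModelError("risk weights must be finite")


def default_risk_model() -> RiskModel:
    """The published two-gene signature: 0.024*CYP4B1 + 0.02*GBP1."""
    return RiskModel(genes=("CYP4B1", "GBP1"), weights=(0.024, 0.02))


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def simple_de(
    expr_tumor: ExpressionMatrix, expr_normal: ExpressionMatrix
) -> pd.DataFrame:
    """Per-gene Welch t-test between two groups on the normalized scale.

    A lightweight built-in differential test: log2FC is the mean
    difference (tumor - normal, already log-scale data) and FDR is the
    Benjamini-Hochberg adjustment over all tested genes.  Users wanting
    a specific DE engine can supply a precomputed table with columns
    ``gene_id, log2fc, fdr`` instead.
    """
    if expr_tumor.gene_ids != expr_normal.gene_ids:
        raise DataModelError("DE groups must share an identical gene list")
    if expr_tumor.shape[1] < 2 or expr_normal.shape[1] < 2:
        raise DataModelError("each DE group needs at least 2 samples")
    a, b = expr_tumor.values, expr_normal.values
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)  # constant genes: no evidence
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene_id": expr_tumor.gene_ids, "log2fc": log2fc, "p_value": p, "fdr": fdr}
    )


def filter_degs(
    de_table: pd.DataFrame, fc_cut: float = 0.137, fdr_cut: float = 0.05
) -> list[str]:
    """Genes with |log2FC| strictly > fc_cut and FDR strictly < fdr_cut."""
    for col in ("gene_id", "log2fc", "fdr"):
        if col not in de_table.columns:
            raise DataModelError(f"DE table missing column {col!r}")
    keep = (de_table["log2fc"].abs() > fc_cut) & (de_table["fdr"] < fdr_cut)
    return de_table.loc[keep, "gene_id"].tolist()


# ---------------------------------------------------------------------------
# Cross-cohort screening
# ---------------------------------------------------------------------------

def consistent_direction(
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    *,
    require_ph: bool = True,
) -> list[str]:
    """Genes significant in both Cox screens with same hazard direction.

    Direction is the sign of (HR - 1); HR exactly 1 carries no direction
    and is dropped.  With ``require_ph`` (default) both screens must also
    pass the proportional-hazards diagnostic.
    """
    a = screen_a.set_index("gene_id")
    b = screen_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise DataModelError("Cox screens share no genes")
    a, b = a.loc[shared], b.loc[shared]
    keep = (
        a["significant"].to_numpy()
        & b["significant"].to_numpy()
        & (np.sign(a["hr"].to_numpy() - 1.0) == np.sign(b["hr"].to_numpy() - 1.0))
        & (np.sign(a["hr"].to_numpy() - 1.0) != 0)
    )
    if require_ph:
        keep &= a["ph_ok"].to_numpy() & b["ph_ok"].to_numpy()
    return sorted(shared[keep])


def intersect_low_ith(
    prognostic_genes, heterogeneity_table: pd.DataFrame
) -> list[str]:
    """Intersect prognostic genes with the low-ITH class, sorted by id."""
    low = set(
        heterogeneity_table.loc[
            heterogeneity_table["ith_class"] == "low", "gene_id"
        ]
    )
    out = sorted(set(prognostic_genes) & low)
    if not out:
        logger.warning("intersect_low_ith: empty intersection")
    return out


def select_signature_genes(
    de_table: pd.DataFrame,
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    heterogeneity_table: pd.DataFrame,
    *,
    fc_cut: float = 0.137,
    fdr_cut: float = 0.05,
    require_ph: bool = True,
) -> list[str]:
    """Run the full funnel: DEGs -> dual Cox screens -> low-ITH overlap."""
    degs = set(filter_degs(de_table, fc_cut=fc_cut, fdr_cut=fdr_cut))
    prognostic = [
        g
        for g in consistent_direction(screen_a, screen_b, require_ph=require_ph)
        if g in degs
    ]
    selected = intersect_low_ith(prognostic, heterogeneity_table)
    logger.info(
        "funnel: %d DEGs -> %d direction-consistent prognostic -> %d low-ITH",
        len(degs),
        len(prognostic),
        len(selected),
    )
    return selected


# ---------------------------------------------------------------------------
# Risk scoring and stratification
# ---------------------------------------------------------------------------

def risk_score(expr: ExpressionMatrix, model: RiskModel) -> pd.Series:
    """Per-sample linear score sum_i w_i * expression_i."""
    missing = [g for g in model.genes if g not in expr.data.index]
    if missing:
        raise DataModelError(f"model genes absent from expression matrix: {missing}")
    sub = expr.data.loc[list(model.genes)]
    scores = np.asarray(model.weights) @ sub.to_numpy()
    return pd.Series(scores, index=expr.sample_ids, name="risk_score")


def stratify(scores: pd.Series, rule: str = "median", value: float | None = None) -> pd.Series:
    """Label samples 'high' / 'low' risk by a score cut.

    Rules: ``median`` (> median = high), ``tertile`` (top tertile =
    high) or ``fixed`` (requires ``value``).
    """
    scores = pd.Series(scores, dtype=float)
    if scores.size < 2:
        raise DataModelError("stratification needs at least 2 samples")
    if rule == "median":
        cut = float(scores.median())
    elif rule == "tertile":
        cut = float(scores.quantile(2.0 / 3.0))
    elif rule == "fixed":
        if value is None:
            raise DataModelError("fixed split rule needs a cut value")
        cut = float(value)
    else:
        raise DataModelError(f"unknown split rule {rule!r}")
    if rule != "fixed" and scores.nunique() == 1:
        raise DataModelError("all scores identical: no stratification possible")
    return pd.Series(
        np.where(scores > cut, "high", "low"), index=scores.index, name="risk_group"
    )


def stratify_median(scores: pd.Series) -> pd.Series:
    """Median split: score > median = 'high', <= median = 'low'."""
    return stratify(scores, rule="median")
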