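"""Mutant-allele tumor heterogeneity (MATH) from per-sample VAFs.

MATH summarizes the width of a tumor sample's variant-allele-fraction
distribution relative to its center:

    MATH = 100 * MAD(vaf) / median(vaf)

where MAD is the median absolute deviation scaled by the 1.4826
normal-consistency constant — the canonical definition.  The constant
matters: omitting it rescales every score by ~1.48x, so it is applied
explicitly here.

A sample needs at least ``min_variants`` usable VAFs (default 3) for the
statistic to mean anything; samples below that, or with median VAF 0, are
flagged with a NaN score rather than dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MutationTable

logger = logging.getLogger(__name__)

__all__ = ["MathResult", "math_score", "math_by_sample"]

#: conventional normal-consistency MAD scaling (the rounded constant the
#: MATH literature uses, not the exact 1/qnorm(0.75))
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class MathResult:
    sample_id: str
    n_variants: int
    median_vaf: float
    mad_vaf: float
    math: float  # percent-like units; NaN when undefined


def math_score(
    vafs, *, sample_id: str = "", min_variants: int = 3
) -> MathResult:
    """MATH for one sample's VAF collection.

    Raises on VAFs outside [0, 1]; returns an undefined (NaN) result when
    fewer than ``min_variants`` VAFs are supplied or the median is zero.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size and (((v < 0) | (v > 1)).any() or not np.isfinite(v).all()):
        raise ValueError("VAFs must be finite fractions in [0, 1]")
    if v.size < min_variants:
        return MathResult(sample_id, int(v.size), np.nan, np.nan, np.nan)
    med = float(np.median(v))
    mad = MAD_CONSTANT * float(np.median(np.abs(v - med)))
    if med <= 0:
        logger.warning("math_score(%s): median VAF is 0; MATH undefined", sample_id)
        return MathResult(sample_id, int(v.size), med, mad, np.nan)
    return MathResult(sample_id, int(v.size), med, mad, 100.0 * mad / med)


def math_by_sample(
    table: MutationTable,
    *,
    min_variants: int = 3,
    vaf_floor: float | None = None,
) -> pd.DataFrame:
    """MATH per sample of a mutation table.

    ``vaf_floor`` drops variants below the floor (e.g. sequencing-noise
    calls) before counting and scoring.  Samples left with too few
    variants appear in the output with NaN MATH.
    """
    rows = []
    for sample_id in table.sample_ids:
        vafs = table.vafs_of(sample_id)
        if vaf_floor is not None:
            vafs = vafs[vafs >= vaf_floor]
        res = math_score(vafs, sample_id=sample_id, min_variants=min_variants)
        rows.append(res.__dict__)
    out = pd.DataFrame(
        rows, columns=["sample_id", "n_variants", "median_vaf", "mad_vaf", "math"]
    )
    n_flagged = int(out["math"].isna().sum())
    if n_flagged:
        logger.info("math_by_sample: %d sample(s) without a defined MATH", n_flagged)
    return out
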