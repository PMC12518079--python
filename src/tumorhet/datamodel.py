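"""Core tabular data types and their TSV I/O.

Every stage of the heterogeneity pipeline consumes one of four validated
containers: an expression matrix (genes x samples, normalized / VST-like
scale), a sample map tying samples to patients and tumor regions, a
MAF-like mutation table with variant-allele fractions, and a survival
frame (time, event, covariates).  All containers are thin wrappers around
:class:`pandas.DataFrame` that enforce the invariants once at construction
so downstream numerics never re-check them.

Canonical on-disk dialect is TSV (UTF-8, header row); CSV is accepted via
``sep=","``.  Gene and sample identifiers are opaque case-sensitive
strings.  Expression input is assumed pre-normalized; a ``log2_cpm``
convenience transform is provided for raw counts as a documented
stand-in, not a variance-stabilizing transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataModelError",
    "ExpressionMatrix",
    "SampleMap",
    "MutationTable",
    "SurvivalFrame",
    "read_expression",
    "write_expression",
    "read_sample_map",
    "read_mutations",
    "read_survival",
    "align",
    "log2_cpm",
]


class DataModelError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()[:5]
        raise DataModelError(f"duplicate {what} ids: {dupes}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense genes x samples matrix of normalized expression values.

    ``data`` is indexed by gene id with one column per sample.  All values
    must be finite floats; duplicate identifiers are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise DataModelError("expression matrix is empty")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        try:
            values = self.data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataModelError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise DataModelError(f"{n_bad} non-finite expression values (NaN/inf)")
        object.__setattr__(self, "data", self.data.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """(n_genes, n_samples) float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :])


@dataclass(frozen=True)
class SampleMap:
    """Sample -> patient (-> region) annotation for a multi-region design."""

    frame: pd.DataFrame  # columns: sample_id, patient_id, region_id

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataModelError(f"sample map missing columns: {sorted(missing)}")
        frame = self.frame.copy()
        if "region_id" not in frame.columns:
            frame["region_id"] = [f"R{i + 1}" for i in range(len(frame))]
        frame = frame[["sample_id", "patient_id", "region_id"]].astype(str)
        _check_unique(frame["sample_id"], "sample")
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def patient_ids(self) -> list[str]:
        """Unique patients in first-seen order."""
        return list(dict.fromkeys(self.frame["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def patients_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Patient label per sample, aligned to ``sample_ids`` order."""
        lut = dict(zip(self.frame["sample_id"], self.frame["patient_id"]))
        try:
            return np.array([lut[s] for s in sample_ids], dtype=object)
        except KeyError as exc:
            raise DataModelError(f"sample {exc} absent from sample map") from exc

    def subset(self, sample_ids: Sequence[str]) -> "SampleMap":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda c: c.map(order))
        return SampleMap(keep)


@dataclass(frozen=True)
class MutationTable:
    """Per-variant allele fractions, one row per (sample, variant).

    Accepts either an explicit ``vaf`` column or ``alt_count`` +
    ``total_count`` pairs from which VAF is derived.
    """

    frame: pd.DataFrame  # columns: sample_id, variant_id, vaf

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        for col in ("sample_id", "variant_id"):
            if col not in frame.columns:
                raise DataModelError(f"mutation table missing column: {col}")
        if "vaf" not in frame.columns:
            if not {"alt_count", "total_count"} <= set(frame.columns):
                raise DataModelError(
                    "mutation table needs either a 'vaf' column or "
                    "'alt_count' and 'total_count'"
                )
            alt = frame["alt_count"].to_numpy(dtype=float)
            tot = frame["total_count"].to_numpy(dtype=float)
            if (alt < 0).any():
                raise DataModelError("negative alt_count")
            if (tot <= 0).any():
                raise DataModelError("total_count must be positive")
            if (alt > tot).any():
                raise DataModelError("alt_count exceeds total_count")
            frame["vaf"] = alt / tot
        vaf = frame["vaf"].to_numpy(dtype=float)
        if not np.isfinite(vaf).all():
            raise DataModelError("non-finite VAF")
        if ((vaf < 0) | (vaf > 1)).any():
            raise DataModelError("VAF outside [0, 1]")
        frame = frame[["sample_id", "variant_id", "vaf"]]
        frame = frame.astype({"sample_id": str, "variant_id": str, "vaf": float})
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def vafs_of(self, sample_id: str) -> np.ndarray:
        return self.frame.loc[
            self.frame["sample_id"] == sample_id, "vaf"
        ].to_numpy()


@dataclass(frozen=True)
class SurvivalFrame:
    """Right-censored survival data with optional numeric covariates."""

    frame: pd.DataFrame  # columns: sample_id, time, event, <covariates...>

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataModelError(f"survival frame missing columns: {sorted(missing)}")
        frame = self.frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        _check_unique(frame["sample_id"], "sample")
        time = frame["time"].to_numpy(dtype=float)
        if not np.isfinite(time).all() or (time <= 0).any():
            raise DataModelError("survival time must be finite and > 0")
        event = frame["event"].to_numpy(dtype=float)
        if not np.isin(event, (0.0, 1.0)).all():
            raise DataModelError("event must be 0 (censored) or 1 (event)")
        frame["time"] = time
        frame["event"] = event.astype(int)
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy()

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalFrame":
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SurvivalFrame(sub)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    *,
    samples_as_rows: bool = False,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Load an expression TSV (first column = gene id, genes as rows).

    Set ``samples_as_rows=True`` for the transposed orientation.  Duplicate
    identifiers, non-numeric cells and missing values are all rejected.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if samples_as_rows:
        df = df.T
    return ExpressionMatrix(df)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, *, sep: str = "\t"
) -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id")


def read_sample_map(path: str | Path, *, sep: str = "\t") -> SampleMap:
    return SampleMap(pd.read_csv(path, sep=sep, dtype=str))


def read_mutations(path: str | Path, *, sep: str = "\t") -> MutationTable:
    return MutationTable(pd.read_csv(path, sep=sep))


def read_survival(path: str | Path, *, sep: str = "\t") -> SurvivalFrame:
    return SurvivalFrame(pd.read_csv(path, sep=sep))


def align(
    expr: ExpressionMatrix, smap: SampleMap
) -> tuple[ExpressionMatrix, SampleMap, int]:
    """Restrict both containers to their shared samples, in matrix order.

    Returns the aligned pair plus the number of samples dropped from the
    union; unmatched samples are reported via a logged warning, never
    silently.  Raises if the overlap is empty.
    """
    expr_samples = expr.sample_ids
    map_samples = set(smap.sample_ids)
    shared = [s for s in expr_samples if s in map_samples]
    if not shared:
        raise DataModelError("expression matrix and sample map share no samples")
    n_dropped = (len(expr_samples) - len(shared)) + (len(map_samples) - len(shared))
    if n_dropped:
        logger.warning(
            "align: %d sample(s) present in only one input were dropped "
            "(%d retained)",
            n_dropped,
            len(shared),
        )
    return expr.subset_samples(shared), smap.subset(shared), n_dropped


def log2_cpm(counts: pd.DataFrame) -> ExpressionMatrix:
    """log2(counts-per-million + 1) of a raw count matrix (genes x samples).

    A convenience stand-in for a proper normalization + variance
    stabilization upstream; documented as such, not a VST replacement.
    """
    counts = counts.astype(float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise DataModelError("library size must be positive for every sample")
    cpm = counts.div(libsize, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0))
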