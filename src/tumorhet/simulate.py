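"""Synthetic multi-region cohorts with known heterogeneity ground truth.

The generator is the sampling counterpart of the variance decomposition
the scoring modules estimate: expression of gene g in region r of
patient p is

    y_gpr = mu_g + b_gp + e_gpr,   b_gp ~ N(0, B_g),  e_gpr ~ N(0, W_g)

with Gaussian effects (VST-scale expression is approximately
homoscedastic, so a Gaussian random-effects model is the natural
emulation).  The true intra-tumor fraction rho_g = W_g/(W_g + B_g) is
returned alongside the data, so every downstream estimator can be
checked for parameter recovery.  Region counts may be unbalanced to
exercise the unbalanced-design estimator paths.

Survival times follow an exponential proportional-hazards model with
log-hazard = log(lambda) + score, censored by an independent uniform
time whose upper bound is calibrated numerically to the requested
censoring fraction.  Per-sample VAF sets are Beta-distributed with a
given center and spread (standard deviation), the substrate for MATH.

Everything is driven by a single integer seed: identical configuration
plus seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import (
    DataModelError,
    ExpressionMatrix,
    MutationTable,
    SampleMap,
    SurvivalFrame,
)

__all__ = [
    "SyntheticConfig",
    "generate_expression",
    "generate_survival",
    "generate_vaf",
    "generate_funnel_scenario",
]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the multi-region generator.

    ``regions_per_patient`` is a scalar or one count per patient;
    ``grand_mean``, ``between_var`` and ``within_var`` are scalars or
    per-gene arrays of length ``n_genes``.
    """

    n_patients: int = 10
    regions_per_patient: int | Sequence[int] = 3
    n_genes: int = 500
    grand_mean: float | Sequence[float] = 8.0
    between_var: float | Sequence[float] = 0.5
    within_var: float | Sequence[float] = 0.5
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    vaf_center: float = 0.35
    vaf_spread: float = 0.08
    variants_per_sample: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise DataModelError("need at least 2 patients")
        if self.n_genes < 1:
            raise DataModelError("need at least 1 gene")
        regions = self.region_counts()
        if (regions < 1).any():
            raise DataModelError("every patient needs at least 1 region")
        for name in ("between_var", "within_var"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if (arr < 0).any():
                raise DataModelError(f"{name} must be >= 0")
        if self.baseline_hazard <= 0:
            raise DataModelError("baseline_hazard must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise DataModelError("censoring_rate must lie in [0, 1)")

    def region_counts(self) -> np.ndarray:
        if np.isscalar(self.regions_per_patient):
            return np.full(self.n_patients, int(self.regions_per_patient))
        counts = np.asarray(self.regions_per_patient, dtype=int)
        if counts.size != self.n_patients:
            raise DataModelError(
                "regions_per_patient must be scalar or one count per patient"
            )
        return counts

    def _per_gene(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_genes, float(arr))
        if arr.size != self.n_genes:
            raise DataModelError("per-gene parameter has wrong length")
        return arr


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleMap, pd.DataFrame]:
    """Draw a multi-region expression matrix plus its ground truth.

    Returns (expression, sample map, truth) where truth has one row per
    gene with the generating ``W``, ``B`` and ``rho`` = W/(W+B) (NaN when
    both variances are zero).
    """
    rng = np.random.default_rng(config.seed)
    regions = config.region_counts()
    n = int(regions.sum())
    g = config.n_genes
    mu = config._per_gene(config.grand_mean)
    b_var = config._per_gene(config.between_var)
    w_var = config._per_gene(config.within_var)

    patient_of = np.repeat(np.arange(config.n_patients), regions)
    b_effects = rng.normal(0.0, 1.0, size=(g, config.n_patients)) * np.sqrt(
        b_var[:, None]
    )
    noise = rng.normal(0.0, 1.0, size=(g, n)) * np.sqrt(w_var[:, None])
    values = mu[:, None] + b_effects[:, patient_of] + noise

    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    sample_ids, patient_ids, region_ids = [], [], []
    for p in range(config.n_patients):
        for r in range(regions[p]):
            sample_ids.append(f"P{p + 1:03d}_R{r + 1}")
            patient_ids.append(f"P{p + 1:03d}")
            region_ids.append(f"R{r + 1}")

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    smap = SampleMap(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": patient_ids,
                "region_id": region_ids,
            }
        )
    )
    total = w_var + b_var
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(total > 0, w_var / np.where(total > 0, total, 1.0), np.nan)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "W": w_var, "B": b_var, "rho": rho}
    )
    return expr, smap, truth


def _calibrate_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound u of Uniform(0, u) censoring achieving the target rate.

    For subject i with event rate r_i, P(censored) under C ~ U(0, u) is
    (1 - exp(-r_i u)) / (r_i u); the mean over subjects is solved for u.
    """

    def mean_censor(u):
        x = rates * u
        return float(np.mean((1.0 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1.0
    while mean_censor(hi) > 0 and hi < 1e12:
        hi *= 10.0
    return brentq(mean_censor, lo, hi, xtol=1e-12, rtol=1e-12)


def generate_survival(
    scores: pd.Series | np.ndarray,
    config: SyntheticConfig,
    *,
    sample_ids: Sequence[str] | None = None,
) -> SurvivalFrame:
    """Exponential PH survival with log-hazard = log(lambda) + score.

    Censoring is an independent Uniform(0, u) time with u calibrated so
    the expected censoring fraction matches ``config.censoring_rate``;
    a target of 0 disables censoring entirely.
    """
    if isinstance(scores, pd.Series):
        if sample_ids is None:
            sample_ids = [str(s) for s in scores.index]
        scores = scores.to_numpy()
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise DataModelError("generate_survival needs at least one score")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(scores.size)]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    rates = config.baseline_hazard * np.exp(scores)
    event_times = rng.exponential(1.0 / rates)
    if config.censoring_rate <= 0:
        time, event = event_times, np.ones(scores.size, dtype=int)
    else:
        u = _calibrate_censor_bound(rates, config.censoring_rate)
        censor_times = rng.uniform(0.0, u, size=scores.size)
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)
    time = np.maximum(time, 1e-12)  # guard strictly positive times
    return SurvivalFrame(
        pd.DataFrame({"sample_id": list(sample_ids), "time": time, "event": event})
    )


def generate_vaf(
    config: SyntheticConfig,
    *,
    n_samples: int = 10,
) -> MutationTable:
    """Beta-distributed VAF sets per sample, clipped to (0, 1).

    ``vaf_center`` m and ``vaf_spread`` s (a standard deviation)
    parameterize Beta(m*kappa, (1-m)*kappa) with
    kappa = m(1-m)/s^2 - 1; s = 0 degenerates to constant VAFs.
    """
    m, s = config.vaf_center, config.vaf_spread
    if not 0.0 < m < 1.0:
        raise DataModelError("vaf_center must lie strictly inside (0, 1)")
    if s < 0:
        raise DataModelError("vaf_spread must be >= 0")
    if config.variants_per_sample < 3:
        raise DataModelError("need at least 3 variants per sample")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7002]))
    rows = []
    for i in range(n_samples):
        if s == 0:
            vafs = np.full(config.variants_per_sample, m)
        else:
            kappa = m * (1.0 - m) / s**2 - 1.0
            if kappa <= 0:
                raise DataModelError(
                    f"vaf_spread {s} too large for center {m} "
                    f"(needs s^2 < m(1-m))"
                )
            vafs = rng.beta(m * kappa, (1.0 - m) * kappa, size=config.variants_per_sample)
            vafs = np.clip(vafs, 1e-6, 1.0 - 1e-6)
        for j, v in enumerate(vafs):
            rows.append((f"S{i + 1:04d}", f"V{j + 1:04d}", float(v)))
    return MutationTable(
        pd.DataFrame(rows, columns=["sample_id", "variant_id", "vaf"])
    )


# ---------------------------------------------------------------------------
# Two-cohort selection-funnel scenario
# ---------------------------------------------------------------------------

def generate_funnel_scenario(
    seed: int,
    *,
    n_genes: int = 500,
    n_planted: int = 2,
    het_patients: int = 10,
    het_regions: int = 3,
    cohort_size: int = 250,
    normal_size: int = 60,
    planted_beta: float = 0.45,
    planted_rho: float = 0.05,
    censoring_rate: float = 0.2,
) -> dict:
    """A complete synthetic study for the gene-selection funnel.

    Plants ``n_planted`` genes that are simultaneously (a) low-ITH
    (rho = ``planted_rho``, strong patient separation) in a multi-region
    cohort, (b) strongly differential between tumor and normal groups,
    and (c) survival-associated with the same hazard direction in two
    independent patient cohorts.  The remaining genes have high rho
    (drawn U(0.5, 0.95)), weak-to-no differential shifts and no survival
    effect, so the funnel should recover exactly the planted set.

    Returns a dict with keys ``expr``, ``smap``, ``truth`` (multi-region
    heterogeneity cohort), ``tumor``, ``normal`` (DE groups), ``cohorts``
    (list of two (ExpressionMatrix, SurvivalFrame) pairs) and
    ``planted`` (the planted gene ids).
    """
    root = np.random.SeedSequence(seed)
    s_het, s_rho, s_de, s_a, s_b = root.spawn(5)
    rng = np.random.default_rng(s_rho)

    rho = rng.uniform(0.5, 0.95, size=n_genes)
    planted_idx = np.arange(n_planted)
    rho[planted_idx] = planted_rho
    total_var = 1.0
    w_var = rho * total_var
    b_var = (1.0 - rho) * total_var
    mu = rng.uniform(5.0, 12.0, size=n_genes)

    het_cfg = SyntheticConfig(
        n_patients=het_patients,
        regions_per_patient=het_regions,
        n_genes=n_genes,
        grand_mean=mu,
        between_var=b_var,
        within_var=w_var,
        seed=int(np.random.default_rng(s_het).integers(2**31 - 1)),
    )
    expr, smap, truth = generate_expression(het_cfg)
    planted = [truth["gene_id"].iloc[i] for i in planted_idx]

    # tumor-vs-normal groups for the DE stage: planted genes shifted by a
    # large fixed amount, background genes by small random amounts (mostly failing
    # the fold-change screen)
    de_rng = np.random.default_rng(s_de)
    delta = de_rng.uniform(0.0, 0.3, size=n_genes) * de_rng.choice(
        [-1.0, 1.0], size=n_genes
    )
    delta[planted_idx] = 1.2
    gene_ids = truth["gene_id"].tolist()

    def _cohort(ss, tag, n_subjects, shift, with_survival):
        crng = np.random.default_rng(ss)
        sd = np.sqrt(total_var)
        vals = crng.normal(0.0, 1.0, size=(n_genes, n_subjects)) * sd
        vals = vals + (mu + shift)[:, None]
        cols = [f"{tag}{i + 1:04d}" for i in range(n_subjects)]
        em = ExpressionMatrix(pd.DataFrame(vals, index=gene_ids, columns=cols))
        if not with_survival:
            return em, None
        centered = vals[planted_idx] - mu[planted_idx][:, None]
        score = planted_beta * centered.sum(axis=0) / sd
        surv_cfg = SyntheticConfig(
            n_genes=1,
            censoring_rate=censoring_rate,
            seed=int(crng.integers(2**31 - 1)),
        )
        sf = generate_survival(score, surv_cfg, sample_ids=cols)
        return em, sf

    sa1, sa2 = s_a.spawn(2)
    tumor, _ = _cohort(sa1, "T", normal_size, delta, with_survival=False)
    normal, _ = _cohort(sa2, "N", normal_size, np.zeros(n_genes), with_survival=False)

    sb1, sb2 = s_b.spawn(2)
    cohort_a = _cohort(sb1, "A", cohort_size, np.zeros(n_genes), with_survival=True)
    cohort_b = _cohort(sb2, "B", cohort_size, np.zeros(n_genes), with_survival=True)

    return {
        "expr": expr,
        "smap": smap,
        "truth": truth,
        "tumor": tumor,
        "normal": normal,
        "cohorts": [cohort_a, cohort_b],
        "planted": planted,
    }
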