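"""Configuration-driven orchestration of the full analysis.

A single YAML (or dict) configuration names the inputs, toggles stages
and carries every stage parameter plus one global seed.  Stages run in
dependency order:

    synth -> heterogeneity (ITVS/CCS/IHS) -> math -> signature

Every output is a TSV under ``output_dir`` and a ``manifest.json``
records input file hashes, the resolved parameters, the seed and the
package version, so identical config + seed reproduces identical
outputs byte for byte.  A stage failure aborts the run naming the
stage; outputs of completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .datamodel import (
    DataModelError,
    align,
    read_expression,
    read_mutations,
    read_sample_map,
    read_survival,
    write_expression,
)
from .mathscore import math_by_sample
from .consistency import score_all_genes
from .signature import (
    RiskModel,
    filter_degs,
    intersect_low_ith,
    risk_score,
    select_signature_genes,
    simple_de,
    stratify,
)
from .simulate import SyntheticConfig, generate_expression, generate_survival, generate_vaf
from .survival import concordance, cox_screen, km_logrank, time_dependent_auc

logger = logging.getLogger(__name__)

__all__ = ["default_config", "validate_config", "run_pipeline", "load_config"]


def default_config() -> dict:
    """A self-contained synthetic demo configuration (no input files)."""
    return {
        "seed": 0,
        "output_dir": "tumorhet_run",
        "stages": {"synth": True, "heterogeneity": True, "math": True, "signature": True},
        "inputs": {
            "expression": None,   # TSV genes x samples; required unless synth
            "sample_map": None,
            "mutations": None,
            "survival": None,
            "de_table": None,     # optional precomputed gene_id/log2fc/fdr TSV
        },
        "synth": {
            "n_patients": 10,
            "regions_per_patient": 3,
            "n_genes": 300,
            "cohort_size": 250,
        },
        "heterogeneity": {
            "method": "mom",
            "linkage": "ward",
            "threshold": 0.5,
            "min_mean_expression": None,
        },
        "math": {"min_variants": 3, "vaf_floor": None},
        "signature": {
            "fc_cut": 0.137,
            "fdr_cut": 0.05,
            "alpha": 0.05,
            "ph_alpha": 0.05,
            "split_rule": "median",
            "horizon_quantiles": [0.25, 0.5, 0.75],
            "weights": None,  # {gene: weight}; default: training-screen coefs
        },
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML config and overlay it on the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(config: dict) -> list[str]:
    """All validation errors at once; an empty list means the config is ok."""
    errors: list[str] = []
    seed = config.get("seed")
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    stages = config.get("stages", {})
    het = config.get("heterogeneity", {})
    thr = het.get("threshold", 0.5)
    if not isinstance(thr, (int, float)) or not 0.0 <= thr <= 1.0:
        errors.append(f"heterogeneity.threshold outside [0, 1]: {thr}")
    if het.get("method", "mom") not in ("mom", "reml"):
        errors.append(f"heterogeneity.method unknown: {het.get('method')}")
    if het.get("linkage", "ward") not in ("average", "complete", "single", "ward"):
        errors.append(f"heterogeneity.linkage unknown: {het.get('linkage')}")
    sig = config.get("signature", {})
    for name in ("fdr_cut", "alpha", "ph_alpha"):
        v = sig.get(name, 0.05)
        if not isinstance(v, (int, float)) or not 0.0 < v < 1.0:
            errors.append(f"signature.{name} outside (0, 1): {v}")
    if sig.get("fc_cut", 0.137) < 0:
        errors.append("signature.fc_cut must be >= 0")
    if sig.get("split_rule", "median") not in ("median", "tertile", "fixed"):
        errors.append(f"signature.split_rule unknown: {sig.get('split_rule')}")
    inputs = config.get("inputs", {})
    if not stages.get("synth", False):
        for field in ("expression", "sample_map"):
            path = inputs.get(field)
            if path is None:
                errors.append(f"inputs.{field} required when stages.synth is off")
            elif not Path(path).exists():
                errors.append(f"inputs.{field} does not exist: {path}")
    for field, path in (inputs or {}).items():
        if path is not None and not Path(path).exists():
            errors.append(f"inputs.{field} does not exist: {path}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns a run report dict.

    The report lists per-stage outputs, counts and timings; it is also
    written as ``manifest.json`` in the output directory.
    """
    errors = validate_config(config)
    if errors:
        raise DataModelError("invalid configuration: " + "; ".join(errors))

    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    report: dict = {
        "version": _version,
        "seed": seed,
        "parameters": {
            k: config[k] for k in ("synth", "heterogeneity", "math", "signature")
        },
        "stages": {},
        "input_hashes": {},
    }
    current = "setup"
    try:
        # ------------------------------------------------------------ inputs
        expr = smap = muts = surv = None
        inputs = config.get("inputs", {})
        for field, reader in (
            ("expression", read_expression),
            ("sample_map", read_sample_map),
            ("mutations", read_mutations),
            ("survival", read_survival),
        ):
            path = inputs.get(field)
            if path:
                report["input_hashes"][field] = _sha256(Path(path))
        if inputs.get("expression"):
            expr = read_expression(inputs["expression"])
        if inputs.get("sample_map"):
            smap = read_sample_map(inputs["sample_map"])
        if inputs.get("mutations"):
            muts = read_mutations(inputs["mutations"])
        if inputs.get("survival"):
            surv = read_survival(inputs["survival"])

        # ------------------------------------------------------------- synth
        cohorts = None
        de_table = None
        if stages.get("synth"):
            current = "synth"
            t0 = time.perf_counter()
            from .simulate import generate_funnel_scenario

            sc = generate_funnel_scenario(
                seed,
                n_genes=int(config["synth"]["n_genes"]),
                het_patients=int(config["synth"]["n_patients"]),
                het_regions=int(config["synth"]["regions_per_patient"]),
                cohort_size=int(config["synth"]["cohort_size"]),
            )
            expr, smap = sc["expr"], sc["smap"]
            cohorts = sc["cohorts"]
            de_table = simple_de(sc["tumor"], sc["normal"])
            muts = generate_vaf(SyntheticConfig(seed=seed), n_samples=10)
            write_expression(expr, out / "expression.tsv")
            smap.frame.to_csv(out / "sample_map.tsv", sep="\t", index=False)
            _write_tsv(sc["truth"], out / "truth.tsv")
            report["stages"]["synth"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_genes": expr.shape[0],
                "n_samples": expr.shape[1],
                "planted": sc["planted"],
            }

        if expr is None or smap is None:
            raise DataModelError("no expression/sample map (file or synth stage)")
        expr, smap, n_dropped = align(expr, smap)

        # ----------------------------------------------------- heterogeneity
        het_table = None
        if stages.get("heterogeneity"):
            current = "heterogeneity"
            t0 = time.perf_counter()
            het = config["heterogeneity"]
            het_table = score_all_genes(
                expr,
                smap,
                method=het["method"],
                linkage_rule=het["linkage"],
                threshold=het["threshold"],
                min_mean_expression=het["min_mean_expression"],
            )
            _write_tsv(het_table, out / "heterogeneity.tsv")
            report["stages"]["heterogeneity"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_genes": int(len(het_table)),
                "n_low_ith": int((het_table["ith_class"] == "low").sum()),
                "samples_dropped_in_align": n_dropped,
            }

        # ---------------------------------------------------------- math
        if stages.get("math") and muts is not None:
            current = "math"
            t0 = time.perf_counter()
            m = config["math"]
            math_table = math_by_sample(
                muts, min_variants=int(m["min_variants"]), vaf_floor=m["vaf_floor"]
            )
            _write_tsv(math_table, out / "math.tsv")
            report["stages"]["math"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_samples": int(len(math_table)),
                "median_math": float(np.nanmedian(math_table["math"])),
            }

        # ------------------------------------------------------- signature
        if stages.get("signature"):
            current = "signature"
            t0 = time.perf_counter()
            sig = config["signature"]
            if inputs.get("de_table"):
                de_table = pd.read_csv(inputs["de_table"], sep="\t")
            if het_table is None:
                raise DataModelError("signature stage needs the heterogeneity stage")
            if cohorts is None:
                if surv is None:
                    raise DataModelError(
                        "signature stage needs survival data (file or synth stage)"
                    )
                cohorts = [(expr, surv), (expr, surv)]
            (expr_a, surv_a), (expr_b, surv_b) = cohorts
            screen_a = cox_screen(
                expr_a, surv_a, alpha=sig["alpha"], ph_alpha=sig["ph_alpha"]
            )
            screen_b = cox_screen(
                expr_b, surv_b, alpha=sig["alpha"], ph_alpha=sig["ph_alpha"]
            )
            _write_tsv(screen_a, out / "cox_screen_a.tsv")
            _write_tsv(screen_b, out / "cox_screen_b.tsv")
            if de_table is None:
                raise DataModelError("signature stage needs a DE table")
            _write_tsv(de_table, out / "de_table.tsv")
            selected = select_signature_genes(
                de_table,
                screen_a,
                screen_b,
                het_table,
                fc_cut=sig["fc_cut"],
                fdr_cut=sig["fdr_cut"],
            )
            pd.DataFrame({"gene_id": selected}).to_csv(
                out / "selected_genes.tsv", sep="\t", index=False
            )
            stage_report = {
                "seconds": None,
                "n_selected": len(selected),
                "selected": selected,
            }
            if selected:
                if sig.get("weights"):
                    model = RiskModel(
                        genes=tuple(sorted(sig["weights"])),
                        weights=tuple(
                            sig["weights"][g] for g in sorted(sig["weights"])
                        ),
                        split_rule=sig["split_rule"],
                    )
                else:
                    # hook for externally trained weights; fallback uses the
                    # training-cohort Cox coefficients as the linear weights
                    coefs = screen_a.set_index("gene_id").loc[selected, "coef"]
                    model = RiskModel(
                        genes=tuple(selected),
                        weights=tuple(float(c) for c in coefs),
                        split_rule=sig["split_rule"],
                    )
                scores = risk_score(expr_b, model)
                groups = stratify(scores, rule=sig["split_rule"])
                score_table = pd.DataFrame(
                    {
                        "sample_id": scores.index,
                        "risk_score": scores.to_numpy(),
                        "risk_group": groups.to_numpy(),
                    }
                )
                _write_tsv(score_table, out / "risk_scores.tsv")
                km = km_logrank(surv_b, groups)
                horizons = np.quantile(
                    surv_b.time[surv_b.event == 1],
                    sig["horizon_quantiles"],
                )
                auc = time_dependent_auc(scores, surv_b, horizons)
                _write_tsv(auc, out / "time_auc.tsv")
                cidx = concordance(scores, surv_b)
                summary = pd.DataFrame(
                    {
                        "metric": ["logrank_chi2", "logrank_p", "c_index"],
                        "value": [km["chi2"], km["p_value"], cidx],
                    }
                )
                _write_tsv(summary, out / "survival_summary.tsv")
                _plot_km(km, out / "km_curves.png")
                stage_report.update(
                    {
                        "logrank_chi2": km["chi2"],
                        "logrank_p": km["p_value"],
                        "c_index": cidx,
                        "auc": {
                            f"{h:.4g}": float(a)
                            for h, a in zip(auc["horizon"], auc["auc"])
                        },
                    }
                )
            stage_report["seconds"] = round(time.perf_counter() - t0, 3)
            report["stages"]["signature"] = stage_report
    except Exception as exc:
        raise DataModelError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return report


def _plot_km(km: dict, path: Path) -> None:
    """Stepwise KM curves for the two risk groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in km["curves"].items():
        ax.step(curve["time"], curve["survival"], where="post", label=group)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {km['p_value']:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
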