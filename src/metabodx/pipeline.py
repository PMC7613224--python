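"""Study orchestration: split, preprocess, train, validate, evaluate.

``run_study`` replays the full diagnostic-modelling sequence on one cohort:

1. simulate (or accept) spectra with class labels and referral order;
2. reference to lactate and integrate into the Pareto-ready bucket table;
3. split into a modelling set and an independent test set by referral
   order (the test partition is not touched again until step 6);
4. repeated stratified 10-fold external CV on the modelling set, with a
   permutation null and KS comparison per metric;
5. fit the final OPLS-DA model on the full modelling set, score VIPs and
   pick the operating threshold from the ROC point closest to the
   top-left corner (cross-validated scores by default);
6. apply the frozen scaling, model and threshold to the test set:
   confusion counts, the metric panel with Wilson intervals, the Fisher
   exact test and a DeLong comparison of the two ROC curves;
7. univariate panel (fold changes, t tests) for metabolites whose
   resonances contain VIP-significant buckets.

Every stage draws its randomness from the single run seed; two runs with
the same config produce byte-identical report JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .errors import ValidationError
from .metrics import (ConfusionCounts, confusion_panel, fisher_exact,
                      optimal_threshold_topleft, roc_curve, wilson_interval,
                      z_compare_auc)
from .opls import fit_opls, predict_scores, select_n_orthogonal, vip
from .synthetic import CohortConfig, SyntheticCohort, build_peak_library, simulate_cohort
from .univariate import definitions_from_library, fold_changes, metabolite_integrals, student_t
from .validation import external_cv, ks_compare, permutation_null


@dataclass
class RunConfig:
    """Every knob of one study run, echoed verbatim into the report."""

    seed: int = 0
    cohort: CohortConfig | None = None
    reference_to_lactate: bool = True
    region: tuple = prep.DEFAULT_REGION
    bucket_width: float = prep.DEFAULT_BUCKET_WIDTH
    excluded: tuple = prep.DEFAULT_WATER_EXCLUSION
    split_counts: tuple | None = None      # explicit (modeling, test) sizes
    modeling_fraction: float = 2 / 3
    cv_k: int = 10
    cv_repeats: int = 100
    n_perm: int = 100
    repeats_per_perm: int = 1
    internal_k: int = 7
    max_ortho: int = 9
    threshold_source: str = "cv"           # "cv" | "fit"
    vip_threshold: float = 2.0

    def __post_init__(self):
        if self.threshold_source not in ("cv", "fit"):
            raise ValidationError("threshold_source must be 'cv' or 'fit'")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(tag,)).generate_state(1)[0] % (2 ** 31))


def split_by_order(metadata: pd.DataFrame,
                   modeling_fraction: float = 2 / 3,
                   counts: tuple | None = None):
    """Deterministic modelling/test split by referral order.

    Sorts by ``referral_order`` and assigns the first ceil(fraction * n)
    samples (or exactly ``counts[0]`` when explicit counts are given) to
    the modelling set.
    """
    if "referral_order" not in metadata.columns:
        raise ValidationError("metadata needs a referral_order column")
    order = metadata["referral_order"]
    if order.duplicated().any():
        dup = order[order.duplicated()].iloc[0]
        raise ValidationError(f"duplicate referral_order value {dup!r}")
    ranked = metadata.sort_values("referral_order", kind="mergesort")
    n = len(ranked)
    if counts is not None:
        n_model, n_test = counts
        if n_model + n_test != n:
            raise ValidationError(
                f"explicit counts {counts} do not sum to cohort size {n}"
            )
    else:
        n_model = int(np.ceil(modeling_fraction * n))
    ids = ranked["sample_id"].tolist()
    return ids[:n_model], ids[n_model:]


def _panel_with_wilson(c: ConfusionCounts) -> dict:
    panel = confusion_panel(c)
    out = {"counts": dataclasses.asdict(c), "metrics": panel, "wilson_ci": {}}
    for name, (k, n) in {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "npv": (c.tn, c.tn + c.fn),
        "ppv": (c.tp, c.tp + c.fp),
        "accuracy": (c.tp + c.tn, c.total),
    }.items():
        if n > 0:
            ci = wilson_interval(k, n)
            out["wilson_ci"][name] = {"lower": ci.lower, "upper": ci.upper}
    return out


def run_study(config: RunConfig, cohort: SyntheticCohort | None = None,
              library=None) -> dict:
    """Execute the full study replica; returns a JSON-serialisable bundle."""
    log = []
    if library is None:
        library = build_peak_library()
    if cohort is None:
        cohort = simulate_cohort(config.cohort, library)
        log.append("simulate")
    else:
        log.append("load")

    spectra = cohort.spectra
    if config.reference_to_lactate:
        spectra = [prep.reference_to_lactate(s) for s in spectra]
        log.append("reference")
    table = prep.assemble_bucket_table(
        spectra, cohort.labels, config.region, config.bucket_width, config.excluded
    )
    log.append("bucket")

    meta = cohort.metadata
    modeling_ids, test_ids = split_by_order(
        meta, config.modeling_fraction, config.split_counts
    )
    log.append("split")
    id_to_row = {sid: i for i, sid in enumerate(table.sample_ids)}
    model_rows = np.array([id_to_row[s] for s in modeling_ids])
    test_rows = np.array([id_to_row[s] for s in test_ids])
    Xm_raw = table.matrix[model_rows]
    ym = table.labels[model_rows].astype(int)
    # the test partition stays untouched until after threshold selection

    cv = external_cv(Xm_raw, ym, k=config.cv_k, repeats=config.cv_repeats,
                     seed=_sub_seed(config.seed, 1), max_ortho=config.max_ortho,
                     internal_k=config.internal_k)
    log.append("external_cv")
    null = permutation_null(Xm_raw, ym, n_perm=config.n_perm, k=config.cv_k,
                            repeats_per_perm=config.repeats_per_perm,
                            seed=_sub_seed(config.seed, 2))
    log.append("permutation_null")
    ks = {}
    for name in ("accuracy", "sensitivity", "specificity", "balanced_accuracy"):
        r = ks_compare(getattr(cv, name), getattr(null, name))
        ks[name] = {"d": r.d, "p_value": r.p_value}
    log.append("ks_compare")

    model_table = table.subset(model_rows)
    scaling = prep.fit_pareto(model_table)
    Xm = prep.apply_pareto(model_table, scaling).matrix
    n_ortho, q2s = select_n_orthogonal(Xm, ym, config.max_ortho,
                                       config.internal_k,
                                       seed=_sub_seed(config.seed, 3))
    model = fit_opls(Xm, ym, n_ortho)
    model.q2 = float(q2s[n_ortho])
    vips = vip(model, config.vip_threshold)
    log.append("fit_final_model")

    if config.threshold_source == "cv":
        modeling_scores = cv.mean_oof_scores
    else:
        modeling_scores = model.fitted_scores
    roc_model = roc_curve(modeling_scores, ym)
    threshold = optimal_threshold_topleft(roc_model)
    log.append("select_threshold")
    modeling_pred = (modeling_scores >= threshold).astype(int)
    modeling_eval = _panel_with_wilson(ConfusionCounts.from_predictions(ym, modeling_pred))

    # ---- independent test set: first and only read of the held-back rows
    yt = table.labels[test_rows].astype(int)
    Xt = prep.apply_pareto(table.subset(test_rows), scaling).matrix
    test_scores = predict_scores(model, Xt)
    log.append("evaluate_test")
    roc_test = roc_curve(test_scores, yt)
    test_pred = (test_scores >= threshold).astype(int)
    test_counts = ConfusionCounts.from_predictions(yt, test_pred)
    test_eval = _panel_with_wilson(test_counts)
    test_eval["fisher"] = fisher_exact(test_counts)
    auc_comparison = z_compare_auc(roc_model, roc_test)

    # ---- univariate panel on VIP-significant metabolites
    defs = definitions_from_library(library)
    sig_centers = table.bucket_centers[vips.significant]
    sig_defs = [
        d for d in defs
        if any(((sig_centers >= lo) & (sig_centers <= hi)).any()
               for lo, hi in d.intervals)
    ]
    univariate = []
    if sig_defs:
        integrals = metabolite_integrals(table, sig_defs)
        fc = fold_changes(integrals, table.labels, reference=0)
        for d in sig_defs:
            vals = integrals[d.metabolite].to_numpy()
            tt = student_t(vals[table.labels == 1], vals[table.labels == 0])
            univariate.append({
                "metabolite": d.metabolite,
                "fold_change": float(fc[d.metabolite]),
                "t": tt["t"], "p_value": tt["p_value"],
            })
    log.append("univariate_panel")

    bundle = {
        "config": _jsonable(dataclasses.asdict(config)),
        "n_modeling": len(modeling_ids),
        "n_test": len(test_ids),
        "bucket_count": int(table.n_buckets),
        "cross_validation": {
            "n_models": int(cv.accuracy.size),
            "mean_accuracy": _nanmean(cv.accuracy),
            "mean_sensitivity": _nanmean(cv.sensitivity),
            "mean_specificity": _nanmean(cv.specificity),
            "mean_balanced_accuracy": _nanmean(cv.balanced_accuracy),
            "null_n_models": int(null.accuracy.size),
            "null_mean_balanced_accuracy": _nanmean(null.balanced_accuracy),
            "ks": ks,
        },
        "model": {
            "n_ortho": int(n_ortho),
            "q2_by_candidate": [float(q) for q in q2s],
            "q2": model.q2,
            "r2y": model.r2y,
            "vip_significant_buckets": [float(c) for c in sig_centers],
        },
        "threshold": {"source": config.threshold_source, "value": float(threshold)},
        "modeling_auc": roc_model.auc,
        "modeling_evaluation": modeling_eval,
        "test_auc": roc_test.auc,
        "test_evaluation": test_eval,
        "auc_comparison": auc_comparison,
        "univariate": univariate,
        "run_log": log,
    }
    return _jsonable(bundle)


def _nanmean(v) -> float:
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else float("nan")


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays and tuples for json.dumps."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def bundle_to_json(bundle: dict) -> str:
    return json.dumps(bundle, indent=2, sort_keys=True, allow_nan=True)
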