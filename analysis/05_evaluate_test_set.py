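"""Evaluate the frozen classifier on the independent test set.

The operating threshold is the ROC point closest to the top-left corner,
chosen on the modelling set's cross-validated scores (script 04), then
transferred unchanged to the 92 reserved patients: confusion counts, the
diagnostic panel with Wilson intervals, the Fisher exact test, and a
DeLong comparison of the modelling and test ROC curves.
"""

import json

import numpy as np

from common import RESULTS, SEED, ensure_dirs, get_bucket_table, modeling_test_rows

from metabodx import (ConfusionCounts, apply_pareto, confusion_panel,
                      fisher_exact, fit_opls, fit_pareto,
                      optimal_threshold_topleft, predict_scores, roc_curve,
                      select_n_orthogonal, wilson_interval, z_compare_auc)


def main():
    ensure_dirs()
    table, meta = get_bucket_table()
    m_rows, t_rows = modeling_test_rows(table, meta)
    y_m = table.labels[m_rows].astype(int)
    y_t = table.labels[t_rows].astype(int)

    scaling = fit_pareto(table.subset(m_rows))
    X_m = apply_pareto(table.subset(m_rows), scaling).matrix
    n_ortho, _ = select_n_orthogonal(X_m, y_m, max_ortho=9, k=7, seed=SEED)
    model = fit_opls(X_m, y_m, n_ortho)

    cv_blob = json.loads((RESULTS / "cv_validation.json").read_text())
    cv_scores = np.asarray(cv_blob["oof_mean_scores"])
    roc_m = roc_curve(cv_scores, y_m)
    threshold = optimal_threshold_topleft(roc_m)
    print(f"modelling CV ROC AUC {roc_m.auc:.3f}; "
          f"top-left threshold {threshold:.4f}")

    X_t = apply_pareto(table.subset(t_rows), scaling).matrix
    scores_t = predict_scores(model, X_t)
    roc_t = roc_curve(scores_t, y_t)
    pred = (scores_t >= threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y_t, pred)
    panel = confusion_panel(counts)
    fisher = fisher_exact(counts)
    delong = z_compare_auc(roc_m, roc_t)

    print(f"test set (n={y_t.size}, {int(y_t.sum())} cancers): "
          f"AUC {roc_t.auc:.3f}")
    print(f"  counts tp={counts.tp} fp={counts.fp} fn={counts.fn} tn={counts.tn}")
    for name in ("sensitivity", "specificity", "npv", "balanced_accuracy"):
        k, n = {
            "sensitivity": (counts.tp, counts.tp + counts.fn),
            "specificity": (counts.tn, counts.tn + counts.fp),
            "npv": (counts.tn, counts.tn + counts.fn),
            "balanced_accuracy": (None, None),
        }[name]
        if k is None:
            print(f"  {name:18s} {100 * panel[name]:.1f}%")
        else:
            ci = wilson_interval(k, n)
            print(f"  {name:18s} {100 * panel[name]:.1f}% "
                  f"(95% CI {100 * ci.lower:.0f}-{100 * ci.upper:.0f})")
    print(f"  Fisher one-sided p = {fisher['p_one_sided_greater']:.4f}; "
          f"DeLong modelling-vs-test Z = {delong['z']:.2f} "
          f"(p = {delong['p_value']:.2f})")

    out = {
        "threshold": float(threshold),
        "modeling_cv_auc": roc_m.auc,
        "test_auc": roc_t.auc,
        "counts": {"tp": counts.tp, "fp": counts.fp,
                   "fn": counts.fn, "tn": counts.tn},
        "metrics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in panel.items() if k != "undefined"},
        "fisher": fisher,
        "delong": delong,
    }
    (RESULTS / "test_evaluation.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {RESULTS / 'test_evaluation.json'}")


if __name__ == "__main__":
    main()
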