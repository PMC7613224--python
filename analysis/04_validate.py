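"""Validate the modelling-set classifier by repeated external CV.

Runs stratified 10-fold external cross-validation (Pareto scaling and
component selection refit inside every training fold) against a
permutation null, and compares the metric distributions with two-sided KS
tests.  Desk scale: 10 repeats (100 models) and 20 permutations.
"""

import json
import warnings

import numpy as np

from common import RESULTS, SEED, ensure_dirs, get_bucket_table, modeling_test_rows

from metabodx import external_cv, ks_compare, permutation_null


def main():
    ensure_dirs()
    table, meta = get_bucket_table()
    m_rows, _ = modeling_test_rows(table, meta)
    X = table.matrix[m_rows]
    y = table.labels[m_rows].astype(int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = external_cv(X, y, k=10, repeats=10, seed=SEED)
        null = permutation_null(X, y, n_perm=20, k=10, repeats_per_perm=1,
                                seed=SEED + 1)

    out = {"scheme": {"k": 10, "repeats": 10, "n_perm": 20, "seed": SEED}}
    for name in ("accuracy", "sensitivity", "specificity",
                 "balanced_accuracy"):
        res = ks_compare(getattr(cv, name), getattr(null, name))
        out[name] = {
            "real_mean": round(float(np.nanmean(getattr(cv, name))), 4),
            "null_mean": round(float(np.nanmean(getattr(null, name))), 4),
            "ks_d": round(res.d, 4),
            "ks_p": float(res.p_value),
        }
        print(f"{name:18s} real {out[name]['real_mean']:.3f} "
              f"vs null {out[name]['null_mean']:.3f} "
              f"(KS D={out[name]['ks_d']:.3f}, p={out[name]['ks_p']:.2e})")
    out["oof_mean_scores"] = [round(float(s), 6) for s in cv.mean_oof_scores]
    out["labels"] = [int(v) for v in y]
    (RESULTS / "cv_validation.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {RESULTS / 'cv_validation.json'}")


if __name__ == "__main__":
    main()
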