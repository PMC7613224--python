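"""Simulate the study cohort: 284 unwell patients, 23 with solid tumors.

Cancer cases carry the modelled metabolic signature (lipoprotein
resonances down; glucose, NAC1 and threonine up at |log2FC| = 0.7) on top
of lognormal biological variability.  Writes the sample metadata and the
true generating concentrations; spectra themselves are regenerated on
demand from the seed.
"""

import json

from common import COHORT_CONFIG, RESULTS, SCRATCH, ensure_dirs, get_cohort

from metabodx import SOLID_TUMOR_EFFECTS


def main():
    ensure_dirs()
    cohort = get_cohort()
    n_pos = int(cohort.labels.sum())
    print(f"simulated {len(cohort.spectra)} plasma spectra "
          f"({COHORT_CONFIG.points_per_spectrum} points, 0-10 ppm)")
    print(f"solid-tumor cases: {n_pos} ({100 * n_pos / len(cohort.spectra):.1f}%)")
    print("injected effects:",
          ", ".join(f"{e.metabolite} {e.log2_fold_change:+.1f}"
                    for e in SOLID_TUMOR_EFFECTS))

    cohort.metadata.to_csv(SCRATCH / "metadata.csv", index=False)
    cohort.truth.to_csv(SCRATCH / "truth.csv")

    fc = {}
    for e in SOLID_TUMOR_EFFECTS:
        pos = cohort.truth.loc[cohort.labels == 1, e.metabolite].mean()
        neg = cohort.truth.loc[cohort.labels == 0, e.metabolite].mean()
        fc[e.metabolite] = {"injected_log2fc": e.log2_fold_change,
                            "realised_fold_change": round(float(pos / neg), 3)}
        print(f"  {e.metabolite:18s} realised concentration fold change "
              f"{pos / neg:.2f} (target {2 ** e.log2_fold_change:.2f})")

    summary = {
        "n_samples": len(cohort.spectra),
        "n_positive": n_pos,
        "prevalence": round(n_pos / len(cohort.spectra), 4),
        "seed": COHORT_CONFIG.seed,
        "effects": fc,
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {RESULTS / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
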