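"""Univariate panel for the VIP-significant metabolites.

Sums the unscaled bucket integrals of each flagged metabolite's
resonances, reports fold changes of cancer vs noncancer means and Student
t tests, and checks recovery of the injected effect directions.
"""

import pandas as pd

from common import RESULTS, ensure_dirs, get_bucket_table

from metabodx import (SOLID_TUMOR_EFFECTS, build_peak_library,
                      definitions_from_library, fold_changes,
                      metabolite_integrals, student_t)


def main():
    ensure_dirs()
    library = build_peak_library()
    table, meta = get_bucket_table(library)
    sig = pd.read_csv(RESULTS / "vip_significant.csv")
    named = sorted({m for cell in sig["metabolites"] for m in cell.split("/")
                    if m != "unassigned"})
    defs = [d for d in definitions_from_library(library)
            if d.metabolite in named]
    print(f"univariate panel over {len(defs)} VIP-flagged metabolites")

    integrals = metabolite_integrals(table, defs)
    fc = fold_changes(integrals, table.labels, reference=0)
    injected = {e.metabolite: e.log2_fold_change for e in SOLID_TUMOR_EFFECTS}

    rows = []
    for d in defs:
        vals = integrals[d.metabolite].to_numpy()
        tt = student_t(vals[table.labels == 1], vals[table.labels == 0])
        rows.append({
            "metabolite": d.metabolite,
            "fold_change": round(float(fc[d.metabolite]), 3),
            "t": round(tt["t"], 2),
            "p_value": tt["p_value"],
            "injected_log2fc": injected.get(d.metabolite, 0.0),
        })
    out = pd.DataFrame(rows).sort_values("p_value")
    out.to_csv(RESULTS / "univariate_panel.csv", index=False)
    for r in out.itertuples():
        direction = "up" if r.fold_change > 1 else "down"
        print(f"  {r.metabolite:18s} fold change {r.fold_change:5.2f} ({direction}), "
              f"t={r.t:6.2f}, p={r.p_value:.2e} "
              f"(injected log2FC {r.injected_log2fc:+.1f})")
    print(f"wrote {RESULTS / 'univariate_panel.csv'}")


if __name__ == "__main__":
    main()
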