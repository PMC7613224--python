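"""Shared configuration for the numbered analysis scripts.

Every script uses the same seeded study-scale cohort (n = 284, ~8%
solid-tumor prevalence, six injected discriminators) so that the stages
compose into one coherent study replica.  The bucket table is cached under
scratch/ (regenerated when absent); small result tables go to results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np  # noqa: E402

from metabodx import (CohortConfig, assemble_bucket_table,  # noqa: E402
                      build_peak_library, reference_to_lactate,
                      simulate_cohort, split_by_order)
from metabodx import io as mio  # noqa: E402

SEED = 1
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

COHORT_CONFIG = CohortConfig(
    n_samples=284,
    prevalence=0.082,          # 23 of 284 carry solid tumors
    points_per_spectrum=4096,
    seed=SEED,
)
SPLIT_COUNTS = (192, 92)       # modelling / independent test, by referral order


def ensure_dirs():
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)


def get_cohort(library=None):
    return simulate_cohort(COHORT_CONFIG, library or build_peak_library())


def get_bucket_table(library=None, cohort=None):
    """Referenced + bucketed study cohort; cached as CSV under scratch/."""
    ensure_dirs()
    cached = SCRATCH / "buckets.csv"
    meta_path = SCRATCH / "metadata.csv"
    if cached.exists() and meta_path.exists():
        import pandas as pd
        meta = pd.read_csv(meta_path)
        table = mio.read_bucket_table(cached, meta["label"].to_numpy())
        return table, meta
    cohort = cohort or get_cohort(library)
    spectra = [reference_to_lactate(s) for s in cohort.spectra]
    table = assemble_bucket_table(spectra, cohort.labels)
    mio.write_bucket_table(table, cached)
    meta = cohort.metadata
    meta.to_csv(meta_path, index=False)
    return table, meta


def modeling_test_rows(table, meta):
    modeling_ids, test_ids = split_by_order(meta, counts=SPLIT_COUNTS)
    row = {sid: i for i, sid in enumerate(table.sample_ids)}
    return (np.array([row[s] for s in modeling_ids]),
            np.array([row[s] for s in test_ids]))
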