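"""Post-hoc per-metabolite analyses.

After the multivariate model flags discriminant buckets, each metabolite's
resonance integrals are summed from the *unscaled* bucket table (the
univariate panel reports concentrations, not Pareto-scaled values), and
group differences are assessed with fold changes and Student t tests;
covariate checks use Pearson correlation.

Resonance definitions may overlap (overlapping resonances share buckets in
crowded spectral regions); overlaps are permitted and flagged, not
resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError
from .preprocessing import BucketTable
from .synthetic import MetabolitePeak


@dataclass(frozen=True)
class ResonanceDefinition:
    """Bucket ppm intervals contributing to one metabolite's integral."""

    metabolite: str
    intervals: tuple  # ((lo, hi), ...) in ppm, closed intervals over centers

    def __post_init__(self):
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        if len(ivs) == 0:
            raise ValidationError(f"{self.metabolite}: needs at least one interval")
        for lo, hi in ivs:
            if hi < lo:
                raise ValidationError(f"{self.metabolite}: interval [{lo}, {hi}] inverted")
        object.__setattr__(self, "intervals", ivs)


def definitions_from_library(library, pad: float = 0.015):
    """Derive resonance definitions from a peak library: one closed
    interval of +/- pad (at least the half linewidth) around each
    position."""
    defs = []
    for peak in library:
        if not isinstance(peak, MetabolitePeak):
            raise ValidationError("library entries must be MetabolitePeak")
        half = max(pad, peak.linewidth / 2)
        defs.append(ResonanceDefinition(
            peak.name, tuple((p - half, p + half) for p in peak.positions)
        ))
    return defs


def metabolite_integrals(t: BucketTable, defs) -> pd.DataFrame:
    """Per-sample metabolite integrals: sum of unscaled bucket integrals
    whose centers fall inside any of the metabolite's intervals."""
    if t.scaled:
        raise ValidationError("metabolite integrals must be computed on unscaled buckets")
    centers = t.bucket_centers
    cols = {}
    for d in defs:
        mask = np.zeros(centers.size, dtype=bool)
        for lo, hi in d.intervals:
            mask |= (centers >= lo) & (centers <= hi)
        if not mask.any():
            raise DataError(f"no buckets overlap any interval of {d.metabolite!r}")
        cols[d.metabolite] = t.matrix[:, mask].sum(axis=1)
    return pd.DataFrame(cols, index=t.sample_ids)


def fold_changes(integrals: pd.DataFrame, labels, reference=0) -> pd.Series:
    """mean(group) / mean(reference group), per metabolite.

    A zero reference mean yields NaN for that metabolite.
    """
    labels = np.asarray(labels)
    ref = integrals.loc[labels == reference]
    other = integrals.loc[labels != reference]
    if len(ref) == 0 or len(other) == 0:
        raise ValidationError("both classes must be non-empty")
    ref_mean = ref.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = other.mean(axis=0) / ref_mean
    fc[ref_mean == 0] = np.nan
    return fc


def student_t(group_a, group_b, welch: bool = False) -> dict:
    """Classical two-sample Student t test (equal variance by default;
    Welch behind a flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("groups must be finite")
    if not welch and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise DataError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(res.statistic), "p_value": float(res.pvalue)}


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH false-discovery-rate adjusted p-values.

    The univariate panel applies no multiple-testing correction by default
    (the tests follow VIP pre-selection); this adjustment is opt-in.
    """
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x, y) -> dict:
    """Pearson correlation with r and r^2 reported together."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("x and y must be equal-length, n >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DataError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r2": float(r * r), "p_value": float(p)}
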