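"""Spectral preprocessing: referencing, bucketing, Pareto scaling.

Raw 1D plasma spectra arrive as (ppm, intensity) traces that have already
been phased and baseline corrected upstream.  This module turns them into
the samples x buckets integral matrix consumed by the multivariate models:

* chemical-shift referencing to the lactate doublet at 1.33 ppm,
* integration into fixed-width buckets over a working region with the
  residual-water band excluded,
* Pareto scaling ((x - mean) / sqrt(sd)) fitted on a training set and
  applied unchanged to held-out data,
* group mean and difference spectra for display.

All operations accept axes stored in either direction (NMR convention is
descending ppm) and normalise to ascending internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, ValidationError

#: Default working region in ppm (left edge inclusive).
DEFAULT_REGION = (0.20, 9.68)
#: Default bucket width in ppm.
DEFAULT_BUCKET_WIDTH = 0.01
#: Default residual-water exclusion, half-open in ppm.
DEFAULT_WATER_EXCLUSION = ((4.50, 5.00),)
#: Lactate methyl doublet reference position.
LACTATE_PPM = 1.33
#: Default search window for the lactate apex.
DEFAULT_LACTATE_WINDOW = (1.20, 1.45)


@dataclass
class Spectrum:
    """One sample's 1D NMR trace.

    Parameters
    ----------
    ppm
        Strictly monotone chemical-shift axis (either direction).
    intensity
        Intensities, same length as ``ppm``; must be finite.
    sample_id
        Sample identifier.
    meta
        Free-form provenance (applied reference shift, simulation seed, ...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise ValidationError(
                f"axis/intensity length mismatch ({self.ppm.size} vs {self.intensity.size})"
            )
        if self.ppm.size < 2:
            raise ValidationError("spectrum needs at least two points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)) or not np.all(np.isfinite(self.ppm)):
            raise ValidationError("spectrum contains non-finite values")

    @property
    def ascending(self) -> bool:
        return bool(self.ppm[1] > self.ppm[0])

    def to_ascending(self) -> "Spectrum":
        """Return a view-equivalent spectrum with an ascending axis."""
        if self.ascending:
            return self
        return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(),
                        self.sample_id, dict(self.meta))

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(),
                        self.sample_id, dict(self.meta))


@dataclass
class ScalingModel:
    """Fitted Pareto scaling parameters: (x - mean) / sqrt(sd)."""

    mean: np.ndarray
    scale: np.ndarray          # sqrt of the per-column sample sd (ddof=1)
    degenerate: np.ndarray     # boolean mask of zero-variance columns
    n_fitted: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (self.mean.shape == self.scale.shape == self.degenerate.shape):
            raise ValidationError("scaling parameter length mismatch")


@dataclass
class BucketTable:
    """Samples x buckets integral matrix with its ppm grid.

    ``labels`` (optional) are integer class indicators, 1 = positive class.
    """

    matrix: np.ndarray
    bucket_centers: np.ndarray
    bucket_width: float
    sample_ids: list
    labels: np.ndarray | None = None
    excluded_regions: tuple = ()
    scaled: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.bucket_centers = np.asarray(self.bucket_centers, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("bucket matrix must be 2-D")
        if self.matrix.shape[1] != self.bucket_centers.size:
            raise ValidationError("column count does not match bucket centers")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValidationError("sample id count does not match rows")
        if self.bucket_centers.size > 1 and not np.all(np.diff(self.bucket_centers) > 0):
            raise ValidationError("bucket centers must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != self.matrix.shape[0]:
                raise ValidationError("label count does not match rows")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.matrix.shape[1]

    def subset(self, rows) -> "BucketTable":
        """Row subset (boolean mask or index array), keeping the grid."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return BucketTable(
            self.matrix[rows],
            self.bucket_centers,
            self.bucket_width,
            [self.sample_ids[i] for i in rows],
            None if self.labels is None else self.labels[rows],
            self.excluded_regions,
            self.scaled,
        )


# ---------------------------------------------------------------------------
# referencing


def _robust_noise(intensity: np.ndarray) -> float:
    # MAD-based noise scale over the whole trace; robust to sparse peaks
    med = np.median(intensity)
    return 1.4826 * np.median(np.abs(intensity - med))


def reference_to_lactate(s: Spectrum,
                         search_window: tuple[float, float] = DEFAULT_LACTATE_WINDOW,
                         target: float = LACTATE_PPM,
                         snr_min: float = 5.0) -> Spectrum:
    """Shift the ppm axis so the window maximum sits exactly on the lactate
    doublet position (1.33 ppm by default).

    If the window holds no data points a :class:`DataError` is raised.  If the
    window maximum does not rise ``snr_min`` robust-noise units above the
    spectrum's median level, no shift is applied and
    ``meta['reference_warning']`` is set — there is no peak to lock on to.
    The applied shift is recorded in ``meta['reference_shift']``.
    """
    lo, hi = min(search_window), max(search_window)
    asc = s.to_ascending()
    mask = (asc.ppm >= lo) & (asc.ppm <= hi)
    if not mask.any():
        raise DataError(f"no data points in referencing window [{lo}, {hi}]")
    widx = np.flatnonzero(mask)
    apex_rel = int(np.argmax(asc.intensity[widx]))
    apex_ppm = asc.ppm[widx[apex_rel]]
    apex_val = asc.intensity[widx[apex_rel]]
    noise = _robust_noise(asc.intensity)
    med = np.median(asc.intensity)
    out = s.copy()
    if apex_val - med <= snr_min * noise:
        out.meta["reference_warning"] = True
        out.meta["reference_shift"] = 0.0
        return out
    shift = target - apex_ppm
    out.ppm = out.ppm + shift
    out.meta["reference_shift"] = float(shift)
    out.meta["reference_warning"] = False
    return out


# ---------------------------------------------------------------------------
# bucketing


def _piecewise_linear_cumulative(ppm: np.ndarray, intensity: np.ndarray):
    """Cumulative trapezoid integral of the trace at its grid points."""
    seg = 0.5 * (intensity[1:] + intensity[:-1]) * np.diff(ppm)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _integral_to(ppm, intensity, cum, x):
    """Exact integral of the piecewise-linear trace from axis start to x."""
    x = np.asarray(x, dtype=float)
    i = np.clip(np.searchsorted(ppm, x, side="right") - 1, 0, ppm.size - 2)
    x0 = ppm[i]
    dx = x - x0
    slope = (intensity[i + 1] - intensity[i]) / (ppm[i + 1] - ppm[i])
    return cum[i] + intensity[i] * dx + 0.5 * slope * dx * dx


def bucket_edges(region: tuple[float, float] = DEFAULT_REGION,
                 width: float = DEFAULT_BUCKET_WIDTH,
                 excluded: Sequence[tuple[float, float]] = DEFAULT_WATER_EXCLUSION):
    """Left/right edges and centers of retained buckets.

    Buckets are half-open intervals [left, left + width) ascending in ppm,
    kept only when fully inside the region; any bucket overlapping an
    excluded interval (by more than 1e-12 ppm) is dropped.
    """
    lo, hi = region
    if width <= 0:
        raise ValidationError("bucket width must be positive")
    if hi <= lo:
        raise ValidationError("region must have positive extent")
    n = int(np.floor((hi - lo) / width + 1e-9))
    idx = np.arange(n)
    lefts = lo + idx * width
    rights = lo + (idx + 1) * width
    keep = rights <= hi + 1e-9
    for (elo, ehi) in excluded:
        overlap = np.minimum(rights, ehi) - np.maximum(lefts, elo)
        keep &= ~(overlap > 1e-12)
    lefts, rights = lefts[keep], rights[keep]
    return lefts, rights, 0.5 * (lefts + rights)


def bucket_spectrum(s: Spectrum,
                    region: tuple[float, float] = DEFAULT_REGION,
                    width: float = DEFAULT_BUCKET_WIDTH,
                    excluded: Sequence[tuple[float, float]] = DEFAULT_WATER_EXCLUSION):
    """Integrate a spectrum into fixed-width buckets.

    Returns ``(integrals, centers)``.  The integral over each bucket is the
    exact trapezoidal area of the (piecewise-linear) intensity between the
    bucket edges, with linear interpolation at edges that fall between grid
    points.
    """
    asc = s.to_ascending()
    lo, hi = region
    if asc.ppm[0] > lo + 1e-12 or asc.ppm[-1] < hi - 1e-12:
        raise DataError(
            f"spectrum {s.sample_id!r} covers [{asc.ppm[0]:.3f}, {asc.ppm[-1]:.3f}] "
            f"but the bucket region is [{lo}, {hi}]"
        )
    in_region = (asc.ppm >= lo) & (asc.ppm <= hi)
    spacing = np.diff(asc.ppm[in_region])
    if spacing.size == 0 or np.max(spacing) > width / 2:
        raise DataError(
            f"axis too coarse for {width}-ppm buckets "
            f"(max spacing {np.max(spacing) if spacing.size else np.inf:.4g}); "
            "need at least two points per bucket"
        )
    lefts, rights, centers = bucket_edges(region, width, excluded)
    cum = _piecewise_linear_cumulative(asc.ppm, asc.intensity)
    integrals = (_integral_to(asc.ppm, asc.intensity, cum, rights)
                 - _integral_to(asc.ppm, asc.intensity, cum, lefts))
    return integrals, centers


def assemble_bucket_table(spectra: Sequence[Spectrum],
                          labels=None,
                          region: tuple[float, float] = DEFAULT_REGION,
                          width: float = DEFAULT_BUCKET_WIDTH,
                          excluded: Sequence[tuple[float, float]] = DEFAULT_WATER_EXCLUSION
                          ) -> BucketTable:
    """Bucket every spectrum onto one shared grid and stack rows in input order."""
    if len(spectra) == 0:
        raise ValidationError("no spectra supplied")
    ids = [s.sample_id for s in spectra]
    seen = set()
    for sid in ids:
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
    rows = []
    centers = None
    for s in spectra:
        integ, c = bucket_spectrum(s, region, width, excluded)
        centers = c if centers is None else centers
        rows.append(integ)
    return BucketTable(np.vstack(rows), centers, width, ids,
                       None if labels is None else np.asarray(labels),
                       tuple(tuple(e) for e in excluded))


# ---------------------------------------------------------------------------
# Pareto scaling


def fit_pareto(t: BucketTable) -> ScalingModel:
    """Fit Pareto scaling on a (training) bucket table.

    scale_j = sqrt(sd_j) with the n-1 denominator; zero-variance columns are
    flagged degenerate and later map to 0.
    """
    if t.n_samples < 2:
        raise ValidationError("Pareto fitting needs at least two samples")
    mean = t.matrix.mean(axis=0)
    sd = t.matrix.std(axis=0, ddof=1)
    degenerate = sd <= 0.0
    scale = np.where(degenerate, 1.0, np.sqrt(np.where(degenerate, 1.0, sd)))
    return ScalingModel(mean=mean, scale=scale, degenerate=degenerate,
                        n_fitted=t.n_samples)


def apply_pareto(t: BucketTable, m: ScalingModel) -> BucketTable:
    """Apply a fitted scaling model; never refits on the data it is given."""
    if t.n_buckets != m.mean.size:
        raise ValidationError(
            f"bucket count mismatch: table has {t.n_buckets}, model fitted on {m.mean.size}"
        )
    scaled = (t.matrix - m.mean) / m.scale
    scaled[:, m.degenerate] = 0.0
    out = dataclasses.replace(t, matrix=scaled, scaled=True)
    return out


# ---------------------------------------------------------------------------
# mean / difference spectra


def _check_same_axis(a: Spectrum, b: Spectrum):
    if a.ppm.size != b.ppm.size or not np.allclose(a.ppm, b.ppm, atol=1e-12, rtol=0):
        raise ValidationError("spectra are not on an identical ppm axis")


def mean_spectrum(spectra: Sequence[Spectrum], group_id: str = "mean") -> Spectrum:
    """Sum the group's spectra pointwise and divide by the group size."""
    if len(spectra) == 0:
        raise ValidationError("empty group")
    first = spectra[0].to_ascending()
    total = np.zeros_like(first.intensity)
    for s in spectra:
        s = s.to_ascending()
        _check_same_axis(first, s)
        total += s.intensity
    return Spectrum(first.ppm.copy(), total / len(spectra), group_id,
                    {"n": len(spectra)})


def difference_spectrum(group_a_mean: Spectrum, group_b_mean: Spectrum) -> Spectrum:
    """First argument minus second, pointwise, on an identical axis."""
    a = group_a_mean.to_ascending()
    b = group_b_mean.to_ascending()
    _check_same_axis(a, b)
    return Spectrum(a.ppm.copy(), a.intensity - b.intensity,
                    f"{a.sample_id}-minus-{b.sample_id}")
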